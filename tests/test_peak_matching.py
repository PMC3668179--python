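import numpy as np
import pytest

from arisakit.clone_library import collapse_to_otus, dedupe_clones
from arisakit.peak_matching import (
    ARISAProfile,
    bin_peaks,
    build_presence_matrix,
    discard_artefact_peaks,
    flag_contaminants,
    match_peaks_to_clones,
)

from conftest import make_clone


def profile(sample, *sizes, height=100.0):
    return ARISAProfile(sample_id=sample, peaks=tuple((float(s), height) for s in sizes))


class TestBinning:
    def test_same_bin_merged_max_height(self):
        p = ARISAProfile("s1", ((398.2, 10.0), (398.4, 30.0)))
        out = bin_peaks(p)
        assert out.peaks == ((398.0, 30.0),)

    def test_empty_profile(self):
        assert bin_peaks(profile("s1")).peaks == ()

    def test_rounding_oracle(self):
        out = bin_peaks(profile("s1", 519.6, 520.9))
        assert out.bins() == {520, 521}

    def test_half_rounds_up(self):
        assert bin_peaks(profile("s1", 100.0, 519.5)).bins() == {520}

    def test_out_of_range_dropped(self):
        out = bin_peaks(profile("s1", 50.0, 1050.0, 400.0))
        assert out.bins() == {400}


def _setup(clone_lengths, sample_bins, sample_of_clone=None):
    """Single-class toy study: clones in sample s1 (or given), given bins."""
    clones = []
    for k, length in enumerate(clone_lengths):
        s = (sample_of_clone or {}).get(k, "s1")
        clones.append(make_clone(f"{s}|{k}", s, length - 131, "ACGT"[k % 4]))
    uniques = dedupe_clones(clones)
    otus = collapse_to_otus(uniques)
    profiles = {s: bin_peaks(profile(s, *bins)) for s, bins in sample_bins.items()}
    class_map = {s: "chick" for s in sample_bins}
    return profiles, uniques, class_map, otus


class TestMatching:
    def test_offset_within_window_assigned(self):
        profiles, uniques, class_map, otus = _setup([401], {"s1": [398]})
        (a,) = match_peaks_to_clones(profiles, uniques, class_map, otus)
        assert (a.peak_bin, a.offset, a.support) == (398, 3, 1)

    def test_outside_window_unassigned(self):
        profiles, uniques, class_map, otus = _setup([400], {"s1": [380]})
        assert match_peaks_to_clones(profiles, uniques, class_map, otus) == []

    def test_greedy_matches_exhaustive_oracle_on_tied_support(self):
        # clones 520 and 521 bp, bins {519, 521}: zero-offset pairing wins,
        # then 520 -> 519; exhaustive search over admissible assignments
        # confirms this minimises total |offset| at equal support
        profiles, uniques, class_map, otus = _setup([520, 521], {"s1": [519, 521]})
        assigns = match_peaks_to_clones(profiles, uniques, class_map, otus)
        got = {a.clone_length: a.peak_bin for a in assigns}
        assert got == {521: 521, 520: 519}

        import itertools

        best = None
        for combo in itertools.product([519, 521, None], repeat=2):
            total_support = sum(1 for b in combo if b is not None)
            offsets = [
                abs(length - b)
                for length, b in zip([520, 521], combo)
                if b is not None and -6 <= length - b <= 15
            ]
            if len(offsets) != total_support:
                continue  # inadmissible
            key = (-total_support, sum(offsets))
            if best is None or key < best[0]:
                best = (key, combo)
        assert dict(zip([520, 521], best[1])) == {520: 519, 521: 521}

    def test_support_counts_cooccurring_samples(self):
        # clone of length 400 cloned in s1 and s2; bin 400 in both, 399 in s1
        clones = [
            make_clone("s1|0", "s1", 400 - 131, "A", igs=None),
            make_clone("s2|0", "s2", 400 - 131, "A", igs=None),
        ]
        # identical sequences across samples -> one unique clone
        igs = "ACGT" * 67 + "A"  # 269 bp
        clones = [
            make_clone("s1|0", "s1", 0, "A", igs=igs),
            make_clone("s2|0", "s2", 0, "A", igs=igs),
        ]
        uniques = dedupe_clones(clones)
        otus = collapse_to_otus(uniques)
        profiles = {
            "s1": bin_peaks(profile("s1", 400, 399)),
            "s2": bin_peaks(profile("s2", 400)),
        }
        class_map = {"s1": "chick", "s2": "chick"}
        (a,) = match_peaks_to_clones(profiles, uniques, class_map, otus)
        assert (a.peak_bin, a.support) == (400, 2)

    def test_two_otus_may_share_one_bin(self):
        clones = [
            make_clone("s1|0", "s1", 400 - 131, "A"),
            make_clone("s1|1", "s1", 401 - 131, "C"),
        ]
        uniques = dedupe_clones(clones)
        otus = collapse_to_otus(uniques)
        profiles = {"s1": bin_peaks(profile("s1", 400.4))}
        assigns = match_peaks_to_clones(profiles, uniques, {"s1": "chick"}, otus)
        assert len(assigns) == 2
        assert {a.peak_bin for a in assigns} == {400}

    def test_offsets_always_inside_window(self):
        rng = np.random.default_rng(5)
        lengths = sorted(set(rng.integers(300, 700, size=12).tolist()))
        bins = sorted(set(rng.integers(290, 710, size=25).tolist()))
        profiles, uniques, class_map, otus = _setup(lengths, {"s1": bins})
        for a in match_peaks_to_clones(profiles, uniques, class_map, otus):
            assert -6 <= a.offset <= 15


class TestArtefactsAndContaminants:
    def test_unassigned_bins_discarded(self):
        profiles, uniques, class_map, otus = _setup([401], {"s1": [398, 602]})
        assigns = match_peaks_to_clones(profiles, uniques, class_map, otus)
        filtered, report = discard_artefact_peaks(profiles, assigns, class_map)
        assert filtered["s1"].bins() == {398}
        assert report.loc[0, "n_discarded"] == 1
        assert report.loc[0, "discarded_bins"] == "602"

    def test_nothing_discarded_when_all_assigned(self):
        profiles, uniques, class_map, otus = _setup([401], {"s1": [398]})
        assigns = match_peaks_to_clones(profiles, uniques, class_map, otus)
        _, report = discard_artefact_peaks(profiles, assigns, class_map)
        assert report["n_discarded"].sum() == 0

    def test_control_clone_flags_otu(self):
        clones = [make_clone("k1|0", "k1", 300, "A")]
        uniques = dedupe_clones(clones)
        otus = collapse_to_otus(uniques)
        flagged = flag_contaminants(otus, [], {}, {"k1"})
        assert flagged == {1}

    def test_control_bin_flags_otu(self):
        profiles, uniques, class_map, otus = _setup([401], {"s1": [398]})
        assigns = match_peaks_to_clones(profiles, uniques, class_map, otus)
        control = {"k1": bin_peaks(profile("k1", 398.2))}
        assert flag_contaminants(otus, assigns, control, {"k1"}) == {1}

    def test_no_controls_no_flags(self):
        profiles, uniques, class_map, otus = _setup([401], {"s1": [398]})
        assert flag_contaminants(otus, [], {}, set()) == set()


class TestPresenceMatrix:
    def test_multioperon_counts_once(self):
        # one OTU with operons at 349+441 bp (offsets 0), another sample sees one
        clones = [
            make_clone("s1|0", "s1", 349 - 131, "G"),
            make_clone("s1|1", "s1", 441 - 131, "G"),
        ]
        uniques = dedupe_clones(clones)
        otus = collapse_to_otus(uniques)
        assert len(otus) == 1
        profiles = {
            "s1": bin_peaks(profile("s1", 349, 441)),
            "s2": bin_peaks(profile("s2", 349)),
        }
        class_map = {"s1": "chick", "s2": "chick"}
        assigns = match_peaks_to_clones(profiles, uniques, class_map, otus)
        filtered, _ = discard_artefact_peaks(profiles, assigns, class_map)
        m = build_presence_matrix(filtered, assigns, otus, class_map)
        assert m.loc["s1", 1] == 1 and m.loc["s2", 1] == 1
        assert m.to_numpy().sum() == 2

    def test_empty_profile_zero_row(self):
        profiles, uniques, class_map, otus = _setup([401], {"s1": [398], "s2": []})
        assigns = match_peaks_to_clones(profiles, uniques, class_map, otus)
        filtered, _ = discard_artefact_peaks(profiles, assigns, class_map)
        m = build_presence_matrix(filtered, assigns, otus, class_map)
        assert m.loc["s2"].sum() == 0

    def test_contaminant_column_absent_and_others_unchanged(self):
        clones = [
            make_clone("s1|0", "s1", 400 - 131, "A"),
            make_clone("s1|1", "s1", 500 - 131, "C"),
        ]
        uniques = dedupe_clones(clones)
        otus = collapse_to_otus(uniques)
        profiles = {"s1": bin_peaks(profile("s1", 400, 500))}
        class_map = {"s1": "chick"}
        assigns = match_peaks_to_clones(profiles, uniques, class_map, otus)
        filtered, _ = discard_artefact_peaks(profiles, assigns, class_map)
        full = build_presence_matrix(filtered, assigns, otus, class_map)
        drop = build_presence_matrix(
            filtered, assigns, otus, class_map, contaminants={1}
        )
        assert 1 not in drop.columns
        assert (drop[2] == full[2]).all()

    def test_matching_is_stable_on_filtered_profiles(self):
        """Re-running matching on its own filtered output changes nothing."""
        rng = np.random.default_rng(11)
        lengths = sorted(set(rng.integers(300, 900, size=15).tolist()))
        bins = [length for length in lengths] + [250, 999]
        profiles, uniques, class_map, otus = _setup(lengths, {"s1": bins})
        assigns = match_peaks_to_clones(profiles, uniques, class_map, otus)
        filtered, _ = discard_artefact_peaks(profiles, assigns, class_map)
        again = match_peaks_to_clones(filtered, uniques, class_map, otus)
        assert {(a.clone_id, a.peak_bin) for a in again} == {
            (a.clone_id, a.peak_bin) for a in assigns
        }
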