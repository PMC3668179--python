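"""Assign ARISA electrophoretic peaks to clones and build presence matrices.

Fragment analysis reports fractional fragment sizes; profiles are first
binned to integer base pairs. Within each age class, every unique clone is
then matched to at most one peak bin using a size window on
(clone length - peak size) and a cross-sample co-occurrence score: a
candidate bin is better supported the more same-class samples contain both
the cloned sequence and the peak. Peaks that no clone claims are treated
as electrophoretic artefacts and dropped; OTUs seen in negative-control
samples (by clone or by peak) are flagged as contaminants. The end product
is a binary samples x OTUs presence matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clone_library import OTU, UniqueClone

__all__ = [
    "ARISAProfile",
    "PeakAssignment",
    "DEFAULT_STANDARD_RANGE",
    "bin_peaks",
    "match_peaks_to_clones",
    "discard_artefact_peaks",
    "flag_contaminants",
    "build_presence_matrix",
]

logger = logging.getLogger(__name__)

#: Detectable range of the internal size standard, in bp.
DEFAULT_STANDARD_RANGE = (105.0, 1007.0)


@dataclass(frozen=True)
class ARISAProfile:
    """Per-sample list of sized peaks (size in bp, height in arbitrary units)."""

    sample_id: str
    peaks: tuple[tuple[float, float], ...]

    def bins(self) -> set[int]:
        """Integer peak sizes; only meaningful after :func:`bin_peaks`."""
        return {int(size) for size, _ in self.peaks}


@dataclass(frozen=True)
class PeakAssignment:
    """One (age class, clone) -> peak bin assignment."""

    age_class: str
    otu_id: int
    clone_id: str
    clone_length: int
    peak_bin: int
    offset: int  # clone_length - peak_bin
    support: int  # co-occurring same-class samples


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def bin_peaks(
    profile: ARISAProfile,
    bin_width: float = 1.0,
    standard_range: tuple[float, float] = DEFAULT_STANDARD_RANGE,
) -> ARISAProfile:
    """Round peak sizes to integer bins; merge same-bin peaks keeping max height.

    Peaks outside the size-standard range cannot be sized reliably and are
    dropped with a warning. Output peaks are sorted by bin.
    """
    lo, hi = standard_range
    binned: dict[int, float] = {}
    n_dropped = 0
    for size, height in profile.peaks:
        if size < lo or size > hi:
            n_dropped += 1
            continue
        b = int(_round_half_up(size / bin_width) * bin_width)
        binned[b] = max(binned.get(b, 0.0), height)
    if n_dropped:
        logger.warning(
            "sample %s: dropped %d peak(s) outside the size-standard range "
            "[%g, %g] bp", profile.sample_id, n_dropped, lo, hi,
        )
    peaks = tuple((float(b), h) for b, h in sorted(binned.items()))
    return ARISAProfile(sample_id=profile.sample_id, peaks=peaks)


def match_peaks_to_clones(
    profiles: Mapping[str, ARISAProfile],
    unique_clones: Sequence[UniqueClone],
    class_map: Mapping[str, str],
    otus: Sequence[OTU],
    window_low: int = 6,
    window_high: int = 15,
) -> list[PeakAssignment]:
    """Match each unique clone to at most one peak bin per age class.

    A candidate pair (clone u, bin b) is admissible iff
    ``clone_length - b`` lies in ``[-window_low, +window_high]`` (clones
    usually run a few bp longer than the sized fragment, occasionally
    shorter). Its score is the number of same-class samples in which u was
    cloned *and* bin b was observed. Candidates are taken greedily by
    descending score, ties broken by smaller \\|offset\\| then smaller bin.
    Clones are exclusive (one bin each); bins are not -- unrelated OTUs can
    share a fragment length. Clones with no admissible, co-occurring bin
    remain unassigned.
    """
    if window_low < 0 or window_high < 0:
        raise ValueError("window bounds must be non-negative")
    clone_to_otu: dict[str, int] = {}
    for otu in otus:
        for u in otu.members:
            clone_to_otu[u.clone_id] = otu.otu_id

    sample_bins = {s: p.bins() for s, p in profiles.items()}
    classes = sorted(set(class_map.values()))
    assignments: list[PeakAssignment] = []

    for cls in classes:
        cls_samples = [s for s, c in class_map.items() if c == cls]
        cls_with_profiles = [s for s in cls_samples if s in profiles]
        class_bins: set[int] = set()
        for s in cls_with_profiles:
            class_bins.update(sample_bins[s])

        candidates: list[tuple[int, int, int, int, int]] = []
        # (support, |offset|, bin, clone_index, offset) per admissible pair
        for ci, u in enumerate(unique_clones):
            cloned_in = [s for s in cls_with_profiles if s in u.occurrences]
            if not cloned_in:
                if any(s in u.occurrences for s in cls_samples):
                    logger.warning(
                        "clone %s observed in class %s but no profiles exist "
                        "for its samples; left unassigned", u.clone_id, cls,
                    )
                continue
            length = u.total_length
            for b in range(length - window_high, length + window_low + 1):
                if b not in class_bins:
                    continue
                support = sum(1 for s in cloned_in if b in sample_bins[s])
                if support >= 1:
                    candidates.append((support, abs(length - b), b, ci, length - b))

        candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
        assigned_clones: set[int] = set()
        for support, _, b, ci, offset in candidates:
            if ci in assigned_clones:
                continue
            assigned_clones.add(ci)
            u = unique_clones[ci]
            assignments.append(
                PeakAssignment(
                    age_class=cls,
                    otu_id=clone_to_otu.get(u.clone_id, 0),
                    clone_id=u.clone_id,
                    clone_length=u.total_length,
                    peak_bin=b,
                    offset=offset,
                    support=support,
                )
            )
    assignments.sort(key=lambda a: (a.age_class, a.otu_id, a.peak_bin))
    return assignments


def assigned_bins_by_class(assignments: Iterable[PeakAssignment]) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {}
    for a in assignments:
        out.setdefault(a.age_class, set()).add(a.peak_bin)
    return out


def discard_artefact_peaks(
    profiles: Mapping[str, ARISAProfile],
    assignments: Sequence[PeakAssignment],
    class_map: Mapping[str, str],
) -> tuple[dict[str, ARISAProfile], pd.DataFrame]:
    """Drop every peak whose bin no clone of the sample's class claims.

    Returns the filtered profiles and a per-sample artefact report
    (columns: sample_id, age_class, n_kept, n_discarded, discarded_bins).
    """
    by_class = assigned_bins_by_class(assignments)
    filtered: dict[str, ARISAProfile] = {}
    rows = []
    for sample, profile in profiles.items():
        cls = class_map.get(sample)
        keep_bins = by_class.get(cls, set())
        kept = tuple(p for p in profile.peaks if int(p[0]) in keep_bins)
        discarded = sorted(int(p[0]) for p in profile.peaks if int(p[0]) not in keep_bins)
        filtered[sample] = ARISAProfile(sample_id=sample, peaks=kept)
        rows.append(
            {
                "sample_id": sample,
                "age_class": cls,
                "n_kept": len(kept),
                "n_discarded": len(discarded),
                "discarded_bins": ",".join(str(b) for b in discarded),
            }
        )
    report = pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)
    return filtered, report


def flag_contaminants(
    otus: Sequence[OTU],
    assignments: Sequence[PeakAssignment],
    control_profiles: Mapping[str, ARISAProfile],
    control_samples: Iterable[str],
) -> set[int]:
    """Flag OTUs of probable reagent origin.

    An OTU is a contaminant iff any member clone was cloned from a control
    sample, or any of its assigned peak bins occurs in a control profile.
    Flagged OTUs are removed from downstream matrices but kept in reports.
    """
    control_samples = set(control_samples)
    if not control_samples:
        logger.warning("no control samples provided; contaminant screen is empty")
        return set()
    control_bins: set[int] = set()
    for p in control_profiles.values():
        control_bins.update(p.bins())

    otu_bins: dict[int, set[int]] = {}
    for a in assignments:
        otu_bins.setdefault(a.otu_id, set()).add(a.peak_bin)

    flagged: set[int] = set()
    for otu in otus:
        if otu.samples() & control_samples:
            flagged.add(otu.otu_id)
        elif otu_bins.get(otu.otu_id, set()) & control_bins:
            flagged.add(otu.otu_id)
    return flagged


def build_presence_matrix(
    filtered_profiles: Mapping[str, ARISAProfile],
    assignments: Sequence[PeakAssignment],
    otus: Sequence[OTU],
    class_map: Mapping[str, str],
    contaminants: Iterable[int] = (),
    control_class: str = "control",
) -> pd.DataFrame:
    """Binary samples x OTUs matrix from filtered profiles and assignments.

    cell(s, o) = 1 iff at least one peak bin assigned to OTU o for s's age
    class is present in s's filtered profile (multi-operon OTUs count once).
    Control samples are excluded from the rows; contaminant OTUs and OTUs
    with no peak assignment at all are excluded from the columns.
    """
    contaminants = set(contaminants)
    bins_by_class_otu: dict[tuple[str, int], set[int]] = {}
    for a in assignments:
        bins_by_class_otu.setdefault((a.age_class, a.otu_id), set()).add(a.peak_bin)

    assigned_otus = sorted({a.otu_id for a in assignments} - contaminants - {0})
    samples = sorted(
        s for s in filtered_profiles if class_map.get(s) != control_class
    )
    data = []
    for s in samples:
        cls = class_map.get(s)
        bins = filtered_profiles[s].bins()
        if not bins:
            logger.warning("sample %s has no surviving peaks; all-zero row kept", s)
        row = [
            1 if bins & bins_by_class_otu.get((cls, o), set()) else 0
            for o in assigned_otus
        ]
        data.append(row)
    matrix = pd.DataFrame(data, index=samples, columns=assigned_otus, dtype=int)
    matrix.index.name = "sample_id"
    matrix.columns.name = "otu_id"
    return matrix
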