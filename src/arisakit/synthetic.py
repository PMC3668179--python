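"""Synthetic ARISA study generator with full ground truth.

Emulates a two-age-class cloacal survey: per-class OTU pools with a small
shared set, 1-9 rRNA operons per OTU, amplicons of ~300-1100 bp, a
systematic per-fragment clone-vs-peak size offset, unequal cloning depth
between classes, artefact peaks, and contaminant OTUs recovered from
saline-control samples. Every emitted file round-trips through the
package's readers, and a :class:`SimTruth` records the generating state so
pipeline output can be scored against it.

Design notes that matter for exactness guarantees:

* Offsets are drawn once per (OTU, operon) and reused in every sample --
  electrophoretic mobility bias is a property of the fragment, which is
  what makes cross-sample co-occurrence matching work.
* Operon lengths are unique across the whole OTU pool by default, so in
  the zero-noise configuration the presence matrix is exactly
  reconstructable (set ``unique_operon_lengths=False`` to allow the
  one-peak/two-OTUs collisions seen in real data).
* After the abundance-weighted clone draws, any (class, OTU, operon) whose
  peak is detectable but which was never cloned in that class receives one
  guaranteed clone: the generator emulates a cloning effort comprehensive
  enough to classify every peak of the common OTUs.
* Artefact bins are drawn outside the class's set of true peak bins, so in
  the noiseless case the artefact-filter report equals the injected count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import io as aio
from .clone_library import CloneRecord, make_clone_record
from .peak_matching import ARISAProfile
from .taxonomy import RANKS, Lineage

__all__ = ["SimConfig", "SimTruth", "SimDataset", "simulate_dataset", "truth_report"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator (defaults follow the field study)."""

    n_adults: int = 22
    n_chicks: int = 21
    n_controls: int = 4
    chick_age_range: tuple[int, int] = (5, 30)

    n_otus_adult_only: int = 24
    n_otus_chick_only: int = 33
    n_otus_shared: int = 7
    n_contaminants: int = 12

    operon_extra_p: float = 2 / 3  # geometric P(success); mean operons ~1.5
    max_operons: int = 9
    amplicon_length_range: tuple[int, int] = (304, 1090)
    detectable_length_range: tuple[int, int] = (304, 1000)
    core_length: int = 131

    adult_richness_mean: float = 9.2
    adult_richness_sd: float = 2.3
    chick_richness_mean: float = 5.8
    chick_richness_sd: float = 3.0
    age_richness_r: float = 0.45

    clone_depth_adult: tuple[float, float] = (47.0, 28.0)
    clone_depth_chick: tuple[float, float] = (20.2, 6.7)
    clone_depth_control: tuple[float, float] = (12.0, 3.0)
    clone_depth_min: int = 8

    offset_mean: float = 1.0
    offset_sd: float = 3.6
    offset_range: tuple[int, int] = (-6, 15)
    fractional_jitter: float = 0.25

    artefact_rate_adult: float = 12.7
    artefact_rate_chick: float = 7.6
    artefact_rate_control: float = 2.0

    contaminant_prevalence: float = 0.5  # per control sample
    contaminant_leak_prob: float = 0.1  # per bird sample

    phylum_mix: tuple[tuple[str, float], ...] = (
        ("Firmicutes", 0.50),
        ("Actinobacteria", 0.375),
        ("Proteobacteria", 0.125),
    )
    abundance_sigma: float = 1.0
    hit_disagreement_rate: float = 0.0
    ref_leaf_prob: float = 0.7
    unique_operon_lengths: bool = True

    def zero_noise(self) -> "SimConfig":
        """Measurement-noise-free variant: exact sizes, no artefacts."""
        return dataclasses.replace(
            self,
            offset_mean=0.0,
            offset_sd=0.0,
            artefact_rate_adult=0.0,
            artefact_rate_chick=0.0,
            artefact_rate_control=0.0,
            hit_disagreement_rate=0.0,
        )

    def validate(self) -> None:
        if self.adult_richness_mean > self.n_otus_adult_only + self.n_otus_shared:
            raise ValueError("adult richness mean exceeds the adult OTU pool")
        if self.chick_richness_mean > self.n_otus_chick_only + self.n_otus_shared:
            raise ValueError("chick richness mean exceeds the chick OTU pool")
        lo, hi = self.offset_range
        if lo > hi:
            raise ValueError("offset_range reversed")
        if not (0 < self.operon_extra_p <= 1):
            raise ValueError("operon_extra_p must be in (0, 1]")
        if self.fractional_jitter >= 0.5:
            raise ValueError("fractional_jitter must stay below half a bin")


@dataclass
class SimTruth:
    """Everything the generator knows, for scoring pipeline output."""

    config: SimConfig
    otus: pd.DataFrame  # true_id, pool, phylum, lineage, core, operon/offset lists
    presence: pd.DataFrame  # bird samples x true otu ids (incl. contaminants)
    contaminant_ids: frozenset[int]
    artefact_bins: dict[str, list[int]]
    metadata: pd.DataFrame
    tree_leaf_of_otu: dict[int, str]

    @property
    def cloacal_ids(self) -> list[int]:
        return [i for i in self.presence.columns if i not in self.contaminant_ids]


@dataclass
class SimDataset:
    """In-memory synthetic dataset plus its ground truth."""

    clones: list[CloneRecord]
    profiles: dict[str, ARISAProfile]  # raw, fractional sizes
    metadata: pd.DataFrame
    hits: pd.DataFrame
    tree: TreeNode
    reference_lineages: dict[str, Lineage]
    truth: SimTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all inputs plus a truth/ directory; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "clones": outdir / "clones.fasta",
            "peaks": outdir / "peaks.csv",
            "metadata": outdir / "metadata.tsv",
            "hits": outdir / "hits.tsv",
            "tree": outdir / "tree.nwk",
            "reference_lineages": outdir / "reference_lineages.tsv",
        }
        aio.write_clone_fasta(paths["clones"], self.clones)
        aio.write_peak_table(paths["peaks"], self.profiles)
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        self.hits.to_csv(paths["hits"], sep="\t", index=False)
        aio.write_tree(self.tree, paths["tree"])
        pd.DataFrame(
            {
                "leaf": list(self.reference_lineages),
                "lineage": [l.to_string() for l in self.reference_lineages.values()],
            }
        ).to_csv(paths["reference_lineages"], sep="\t", index=False)
        truth_dir = outdir / "truth"
        truth_dir.mkdir(exist_ok=True)
        self.truth.presence.to_csv(truth_dir / "presence.tsv", sep="\t")
        self.truth.otus.to_csv(truth_dir / "otus.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"otu_id": sorted(self.truth.contaminant_ids)}
        ).to_csv(truth_dir / "contaminants.tsv", sep="\t", index=False)
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _build_lineages(
    rng: np.random.Generator, config: SimConfig
) -> tuple[list[Lineage], list[Lineage]]:
    """Synthetic lineages for cloacal and contaminant OTU pools.

    Cloacal phyla follow ``phylum_mix``; contaminants are mostly
    Alphaproteobacteria, as reagent contaminants tend to be. Genera hold
    1-4 OTUs each so that the phylogeny has multi-OTU clades.
    """
    n_cloacal = (
        config.n_otus_adult_only + config.n_otus_chick_only + config.n_otus_shared
    )
    phyla = [p for p, _ in config.phylum_mix]
    weights = np.array([w for _, w in config.phylum_mix], dtype=float)
    counts = np.floor(weights / weights.sum() * n_cloacal).astype(int)
    while counts.sum() < n_cloacal:  # distribute rounding remainder
        counts[int(np.argmax(weights - counts / n_cloacal))] += 1

    classes_of = {
        "Firmicutes": ["Bacilli", "Clostridia"],
        "Actinobacteria": ["Actinomycetia", "Acidimicrobiia"],
        "Proteobacteria": ["Alphaproteobacteria", "Betaproteobacteria", "Gammaproteobacteria"],
    }

    def make_pool(phylum: str, n: int, tag: str) -> list[Lineage]:
        out: list[Lineage] = []
        g = 0
        while len(out) < n:
            g += 1
            cls = classes_of.get(phylum, [f"{phylum}_classis"])[
                int(rng.integers(len(classes_of.get(phylum, ["x"]))))
            ]
            order = f"{cls[:6]}ales{1 + int(rng.integers(2))}"
            family = f"{order[:-1]}ceae{1 + int(rng.integers(2))}"
            genus = f"{tag}{phylum[:4]}Genus{g:02d}"
            size = int(rng.integers(1, 5))
            for s in range(min(size, n - len(out))):
                names = [phylum, cls, order, "", family, genus, f"{genus} sp{s + 1}"]
                out.append(Lineage(tuple(names)))
        return out

    cloacal: list[Lineage] = []
    for phylum, n in zip(phyla, counts):
        cloacal.extend(make_pool(phylum, int(n), "C"))

    # contaminant mix: 7 Alpha, 2 Beta, 1 Gamma, 2 Firmicutes at n=12; scale
    contam_template = (
        ["Proteobacteria:Alphaproteobacteria"] * 7
        + ["Proteobacteria:Betaproteobacteria"] * 2
        + ["Proteobacteria:Gammaproteobacteria"] * 1
        + ["Firmicutes:Bacilli"] * 2
    )
    contam: list[Lineage] = []
    for k in range(config.n_contaminants):
        phylum, cls = contam_template[k % len(contam_template)].split(":")
        genus = f"XContamGenus{k:02d}"
        contam.append(
            Lineage((phylum, cls, f"{cls[:6]}ales", "", f"{cls[:6]}aceae", genus, f"{genus} sp1"))
        )
    return cloacal, contam


def _draw_operon_lengths(
    rng: np.random.Generator, config: SimConfig, n_otus: int
) -> list[list[int]]:
    """Operon counts (1 + capped geometric) and lengths per OTU.

    The first operon of every OTU is drawn from the detectable length
    range; extra operons may run past it (their peaks fall off the size
    standard, as the longest clones in real libraries do).
    """
    counts = 1 + np.minimum(
        rng.geometric(config.operon_extra_p, size=n_otus) - 1, config.max_operons - 1
    )
    lo, hi = config.amplicon_length_range
    dlo, dhi = config.detectable_length_range
    # lengths just past the sizing standard (1002-1022 bp) are excluded:
    # such fragments give no peak yet their clones sit inside the matching
    # window of in-range peaks, which would anchor them onto the wrong bin;
    # longer clones (>= 1023 bp) stay, like the real unassignable long clones
    ambiguous = set(range(dhi + 2, 1007 + 15 + 1))
    allowed_extras = [v for v in range(lo, hi + 1) if v not in ambiguous]
    if config.unique_operon_lengths:
        first_pool = list(rng.permutation(np.arange(dlo, dhi + 1)))
        extra_pool = list(rng.permutation(np.array(allowed_extras)))
        used: set[int] = set()
        lengths: list[list[int]] = []
        for n_op in counts:
            while True:
                first = int(first_pool.pop())
                if first not in used:
                    break
            mine = [first]
            used.add(first)
            while len(mine) < n_op:
                cand = int(extra_pool.pop())
                if cand not in used:
                    mine.append(cand)
                    used.add(cand)
            lengths.append(sorted(mine))
        return lengths
    lengths = []
    for n_op in counts:
        mine = {int(rng.integers(dlo, dhi + 1))}
        while len(mine) < n_op:
            cand = int(rng.integers(lo, hi + 1))
            if cand not in ambiguous:
                mine.add(cand)
        lengths.append(sorted(mine))
    return lengths


def _draw_offsets(
    rng: np.random.Generator, config: SimConfig, n: int
) -> list[int]:
    """Systematic clone-minus-peak offsets, one per operon."""
    lo, hi = config.offset_range
    if config.offset_sd == 0:
        return [int(round(config.offset_mean))] * n
    out = []
    for _ in range(n):
        while True:
            x = int(round(rng.normal(config.offset_mean, config.offset_sd)))
            if lo <= x <= hi:
                out.append(x)
                break
    return out


def _build_tree(
    rng: np.random.Generator,
    otu_table: pd.DataFrame,
    leaf_of_otu: Mapping[int, str],
    config: SimConfig,
) -> tuple[TreeNode, dict[str, Lineage]]:
    """Random phylogeny whose topology follows the synthetic taxonomy.

    OTUs are merged genus-first, then up the rank scale, with exponential
    branch lengths. A reference leaf (a congener with a known lineage,
    for placement-based classification) is attached as a sister to each
    OTU leaf with probability ``ref_leaf_prob``.
    """
    ref_lineages: dict[str, Lineage] = {}

    def leaf_node(row) -> TreeNode:
        leaf = TreeNode(name=leaf_of_otu[row.true_id])
        leaf.length = float(rng.exponential(0.02) + 0.005)
        if rng.random() < config.ref_leaf_prob:
            ref = TreeNode(name=f"REF_{row.true_id}")
            ref.length = float(rng.exponential(0.02) + 0.005)
            lineage = Lineage.from_string(row.lineage)
            ref_lineages[ref.name] = lineage.truncate(RANKS.index("genus") + 1)
            cherry = TreeNode(children=[leaf, ref])
            cherry.name = "0.97"  # placement support for the sister pairing
            cherry.length = float(rng.exponential(0.02) + 0.005)
            return cherry
        return leaf

    def merge(nodes: list[TreeNode], scale: float) -> TreeNode:
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            parent = TreeNode(children=[a, b])
            parent.name = f"{rng.uniform(0.85, 1.0):.2f}"
            parent.length = float(rng.exponential(scale) + 0.005)
            nodes.append(parent)
        return nodes[0]

    def group_merge(frame: pd.DataFrame, ranks: list[str], scale: float) -> TreeNode:
        if not ranks:
            return merge([leaf_node(row) for row in frame.itertuples()], scale)
        rank = ranks[0]
        subtrees = [
            group_merge(sub, ranks[1:], scale * 0.6)
            for _, sub in frame.groupby(frame["lineage"].str.split(";").str[RANKS.index(rank)], sort=True)
        ]
        return merge(subtrees, scale)

    root = group_merge(otu_table, ["phylum", "class", "family", "genus"], 0.15)
    root.length = None
    root.name = None
    return root, ref_lineages


def simulate_dataset(config: SimConfig | None = None, seed: int = 0) -> SimDataset:
    """Generate a complete synthetic study; same seed, same bytes."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    n_cloacal = (
        config.n_otus_adult_only + config.n_otus_chick_only + config.n_otus_shared
    )
    n_total = n_cloacal + config.n_contaminants
    cloacal_lineages, contam_lineages = _build_lineages(rng, config)

    # --- OTU pool: cores, operons, offsets, class pools -------------------
    cores: set[str] = set()
    core_of: list[str] = []
    for _ in range(n_total):
        while True:
            core = _random_seq(rng, config.core_length)
            if core not in cores:
                cores.add(core)
                core_of.append(core)
                break
    operons = _draw_operon_lengths(rng, config, n_total)
    offsets = [_draw_offsets(rng, config, len(ops)) for ops in operons]

    # assign cloacal OTUs to class pools genus-block-wise so that age
    # classes occupy distinct lineages (the age signal the study reports)
    genus_of = [lin["genus"] for lin in cloacal_lineages]
    genera_order = sorted(set(genus_of))
    rng.shuffle(genera_order)
    ordered = [i for g in genera_order for i in range(n_cloacal) if genus_of[i] == g]
    pools = {}
    for k, i in enumerate(ordered):
        if k < config.n_otus_adult_only:
            pools[i] = "adult_only"
        elif k < config.n_otus_adult_only + config.n_otus_shared:
            pools[i] = "shared"
        else:
            pools[i] = "chick_only"

    rows = []
    for i in range(n_total):
        contaminant = i >= n_cloacal
        lineage = contam_lineages[i - n_cloacal] if contaminant else cloacal_lineages[i]
        rows.append(
            {
                "true_id": i + 1,
                "pool": "contaminant" if contaminant else pools[i],
                "phylum": lineage["phylum"],
                "lineage": lineage.to_string(),
                "core": core_of[i],
                "operon_lengths": ",".join(str(x) for x in operons[i]),
                "offsets": ",".join(str(x) for x in offsets[i]),
            }
        )
    otu_table = pd.DataFrame(rows)
    contaminant_ids = frozenset(range(n_cloacal + 1, n_total + 1))
    adult_pool = [r["true_id"] for r in rows if r["pool"] in ("adult_only", "shared")]
    chick_pool = [r["true_id"] for r in rows if r["pool"] in ("chick_only", "shared")]

    # per-OTU popularity: lognormal weights give the singleton-heavy tail
    popularity = rng.lognormal(0.0, config.abundance_sigma, size=n_total)

    # --- samples, presence, ages ------------------------------------------
    adults = [f"A{k + 1:02d}" for k in range(config.n_adults)]
    chicks = [f"C{k + 1:02d}" for k in range(config.n_chicks)]
    controls = [f"K{k + 1:02d}" for k in range(config.n_controls)]
    ages = rng.integers(
        config.chick_age_range[0], config.chick_age_range[1] + 1, size=config.n_chicks
    )

    age_lo, age_hi = config.chick_age_range
    age_mean = (age_lo + age_hi) / 2.0
    age_sd = np.sqrt(((age_hi - age_lo + 1) ** 2 - 1) / 12.0)
    slope = config.age_richness_r * config.chick_richness_sd / age_sd
    intercept = config.chick_richness_mean - slope * age_mean
    resid_sd = config.chick_richness_sd * np.sqrt(1 - config.age_richness_r**2)

    presence = pd.DataFrame(
        0, index=adults + chicks, columns=range(1, n_total + 1), dtype=int
    )

    def fill_class(samples: list[str], targets: list[int], pool: list[int]) -> None:
        """Assign OTU sets of the drawn sizes; every pool OTU gets a home.

        Richness targets are honoured exactly; coverage is achieved by
        seating each pool OTU in one individual first (capacity-
        proportional), then topping samples up by popularity-weighted
        draws. The study's pools are, by construction, observed OTUs.
        """
        chosen: dict[str, set[int]] = {s: set() for s in samples}
        targets = dict(zip(samples, targets))
        for o in rng.permutation(pool):
            o = int(o)
            cap = np.array([targets[s] - len(chosen[s]) for s in samples], dtype=float)
            if cap.sum() <= 0:  # all seats taken: grow a random individual
                s = samples[int(rng.integers(len(samples)))]
                targets[s] += 1
            else:
                s = samples[int(rng.choice(len(samples), p=cap / cap.sum()))]
            chosen[s].add(o)
        for s in samples:
            free = sorted(set(pool) - chosen[s])
            need = targets[s] - len(chosen[s])
            if need > 0 and free:
                w = popularity[np.array(free) - 1]
                picks = rng.choice(len(free), size=min(need, len(free)), replace=False, p=w / w.sum())
                chosen[s].update(free[j] for j in picks)
            presence.loc[s, sorted(chosen[s])] = 1

    adult_targets = [
        int(np.clip(round(rng.normal(config.adult_richness_mean, config.adult_richness_sd)), 1, len(adult_pool)))
        for _ in adults
    ]
    chick_targets = [
        int(np.clip(round(intercept + slope * age + rng.normal(0, resid_sd)), 1, len(chick_pool)))
        for age in ages
    ]
    fill_class(adults, adult_targets, adult_pool)
    fill_class(chicks, chick_targets, chick_pool)
    # contaminant leakage into bird samples
    for s in adults + chicks:
        for cid in contaminant_ids:
            if rng.random() < config.contaminant_leak_prob:
                presence.loc[s, cid] = 1

    control_presence = pd.DataFrame(0, index=controls, columns=range(1, n_total + 1), dtype=int)
    for s in controls:
        for cid in sorted(contaminant_ids):
            if rng.random() < config.contaminant_prevalence:
                control_presence.loc[s, cid] = 1
    for cid in sorted(contaminant_ids):  # every contaminant seen in >=1 control
        if control_presence[cid].sum() == 0:
            control_presence.loc[controls[int(rng.integers(len(controls)))], cid] = 1

    presence.index.name = "sample_id"
    presence.columns.name = "otu_id"

    metadata = pd.DataFrame(
        {
            "sample_id": adults + chicks + controls,
            "age_class": ["adult"] * len(adults) + ["chick"] * len(chicks) + ["control"] * len(controls),
            "age_days": [np.nan] * len(adults) + list(map(float, ages)) + [np.nan] * len(controls),
        }
    )
    class_map = dict(zip(metadata["sample_id"], metadata["age_class"]))
    all_presence = pd.concat([presence, control_presence])

    # --- clones -----------------------------------------------------------
    igs_of: dict[tuple[int, int], str] = {}
    for i in range(n_total):
        for oi, length in enumerate(operons[i]):
            igs_of[(i + 1, oi)] = _random_seq(rng, length - config.core_length)

    depth_params = {
        "adult": config.clone_depth_adult,
        "chick": config.clone_depth_chick,
        "control": config.clone_depth_control,
    }
    sample_abund: dict[str, dict[int, float]] = {}
    clone_specs: list[tuple[str, int, int]] = []  # (sample, true_id, operon_idx)
    for s in all_presence.index:
        present = [int(o) for o in all_presence.columns if all_presence.loc[s, o]]
        if not present:
            sample_abund[s] = {}
            continue
        w = popularity[np.array(present) - 1] * rng.lognormal(0, 0.5, size=len(present))
        sample_abund[s] = dict(zip(present, w))
        mu, sd = depth_params[class_map[s]]
        depth = max(config.clone_depth_min, int(round(rng.normal(mu, sd))))
        probs = w / w.sum()
        picks = rng.choice(len(present), size=depth, p=probs)
        for j in picks:
            tid = present[j]
            oi = int(rng.integers(len(operons[tid - 1])))
            clone_specs.append((s, tid, oi))

    # coverage guarantee per (class, OTU, detectable operon)
    std_lo, std_hi = 105, 1007
    cloned: set[tuple[str, int, int]] = {
        (class_map[s], tid, oi) for s, tid, oi in clone_specs
    }
    for cls in ("adult", "chick", "control"):
        cls_samples = [s for s in all_presence.index if class_map[s] == cls]
        if not cls_samples:
            continue
        sub = all_presence.loc[cls_samples]
        for tid in sub.columns[sub.sum(axis=0) > 0]:
            tid = int(tid)
            for oi, length in enumerate(operons[tid - 1]):
                peak = length - offsets[tid - 1][oi]
                if not (std_lo <= peak <= std_hi):
                    continue
                if (cls, tid, oi) in cloned:
                    continue
                host = max(
                    (s for s in cls_samples if all_presence.loc[s, tid]),
                    key=lambda s: sample_abund[s].get(tid, 0.0),
                )
                clone_specs.append((host, tid, oi))
                cloned.add((cls, tid, oi))

    clone_specs.sort()
    clones: list[CloneRecord] = []
    serial: dict[str, int] = {}
    clone_otu: list[tuple[str, int]] = []  # (clone_id, true_id)
    for s, tid, oi in clone_specs:
        serial[s] = serial.get(s, 0) + 1
        cid = f"{s}|{serial[s]:03d}"
        seq = igs_of[(tid, oi)] + core_of[tid - 1]
        clones.append(make_clone_record(cid, s, seq, config.core_length))
        clone_otu.append((cid, tid))

    # --- peaks ------------------------------------------------------------
    class_true_bins: dict[str, set[int]] = {"adult": set(), "chick": set(), "control": set()}
    for cls in class_true_bins:
        cls_samples = [s for s in all_presence.index if class_map[s] == cls]
        if not cls_samples:
            continue
        sub = all_presence.loc[cls_samples]
        for tid in sub.columns[sub.sum(axis=0) > 0]:
            tid = int(tid)
            for oi, length in enumerate(operons[tid - 1]):
                class_true_bins[cls].add(length - offsets[tid - 1][oi])
    all_true_bins = set().union(*class_true_bins.values())

    artefact_rates = {
        "adult": config.artefact_rate_adult,
        "chick": config.artefact_rate_chick,
        "control": config.artefact_rate_control,
    }
    profiles: dict[str, ARISAProfile] = {}
    artefact_bins: dict[str, list[int]] = {}
    for s in all_presence.index:
        cls = class_map[s]
        peaks = []
        for tid in all_presence.columns[all_presence.loc[s] > 0]:
            tid = int(tid)
            for oi, length in enumerate(operons[tid - 1]):
                size = float(length - offsets[tid - 1][oi])
                if config.fractional_jitter:
                    size += float(rng.uniform(-config.fractional_jitter, config.fractional_jitter))
                peaks.append((size, float(rng.lognormal(7.0, 1.0))))
        n_art = int(rng.poisson(artefact_rates[cls]))
        # controls must not echo cloacal bins, or they would falsely flag OTUs
        forbidden = all_true_bins if cls == "control" else class_true_bins[cls]
        my_art: list[int] = []
        while len(my_art) < n_art:
            b = int(rng.integers(std_lo, std_hi + 1))
            if b not in forbidden and b not in my_art:
                my_art.append(b)
                peaks.append((float(b), float(rng.lognormal(6.0, 1.0))))
        artefact_bins[s] = sorted(my_art)
        peaks.sort()
        profiles[s] = ARISAProfile(sample_id=s, peaks=tuple(peaks))

    # --- hit table --------------------------------------------------------
    lineage_by_tid = {int(r.true_id): Lineage.from_string(r.lineage) for r in otu_table.itertuples()}
    hit_rows = []
    tids = sorted(lineage_by_tid)
    for cid, tid in clone_otu:
        subject_tid = tid
        if config.hit_disagreement_rate and rng.random() < config.hit_disagreement_rate:
            subject_tid = tids[int(rng.integers(len(tids)))]
        lineage = lineage_by_tid[subject_tid]
        hit_rows.append(
            {
                "clone_id": cid,
                "subject": lineage["species"],
                "lineage": lineage.to_string(),
                "score": float(np.clip(round(rng.normal(199, 25)), 90, 243)),
                "evalue": float(10.0 ** -rng.uniform(50, 120)),
            }
        )
    hits = pd.DataFrame(hit_rows)

    # --- tree -------------------------------------------------------------
    leaf_of_otu = {}
    for cid, tid in clone_otu:
        if tid not in leaf_of_otu or cid < leaf_of_otu[tid]:
            leaf_of_otu[tid] = cid
    missing = [t for t in range(1, n_total + 1) if t not in leaf_of_otu]
    if missing:  # cannot happen with the coverage guarantee, but be explicit
        raise RuntimeError(f"OTUs with no clones: {missing}")
    tree, ref_lineages = _build_tree(rng, otu_table, leaf_of_otu, config)

    truth = SimTruth(
        config=config,
        otus=otu_table,
        presence=presence,
        contaminant_ids=contaminant_ids,
        artefact_bins=artefact_bins,
        metadata=metadata,
        tree_leaf_of_otu=leaf_of_otu,
    )
    return SimDataset(
        clones=clones,
        profiles=profiles,
        metadata=metadata,
        hits=hits,
        tree=tree,
        reference_lineages=ref_lineages,
        truth=truth,
    )


def truth_report(
    truth: SimTruth,
    presence_matrix: pd.DataFrame,
    otus,
    flagged_contaminants: set[int],
) -> dict:
    """Score pipeline output against the generating truth.

    ``otus`` are the pipeline's OTU objects; they are matched to true OTUs
    by their 23S core sequence. Returns confusion counts for presence
    cells, contaminant-flag recovery, the shared-OTU-count error and
    per-class richness-mean errors.
    """
    core_to_tid = {r.core: int(r.true_id) for r in truth.otus.itertuples()}
    pipe_to_true: dict[int, int] = {}
    for otu in otus:
        tid = core_to_tid.get(otu.representative_23s)
        if tid is None:
            raise ValueError(f"pipeline OTU {otu.otu_id} has an unknown 23S core")
        pipe_to_true[otu.otu_id] = tid

    cloacal = [t for t in truth.presence.columns if t not in truth.contaminant_ids]
    samples = list(truth.presence.index)
    recovered = pd.DataFrame(0, index=samples, columns=cloacal, dtype=int)
    for col in presence_matrix.columns:
        tid = pipe_to_true.get(int(col))
        if tid in recovered.columns:
            recovered.loc[presence_matrix.index, tid] = presence_matrix[col].to_numpy()
    true_cl = truth.presence[cloacal]
    tp = int(((recovered == 1) & (true_cl == 1)).to_numpy().sum())
    fp = int(((recovered == 1) & (true_cl == 0)).to_numpy().sum())
    fn = int(((recovered == 0) & (true_cl == 1)).to_numpy().sum())
    tn = int(((recovered == 0) & (true_cl == 0)).to_numpy().sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0

    flagged_true = {pipe_to_true[o] for o in flagged_contaminants if o in pipe_to_true}
    truth_set = set(truth.contaminant_ids)

    class_of = dict(zip(truth.metadata["sample_id"], truth.metadata["age_class"]))
    rich_err = {}
    for cls in ("adult", "chick"):
        cls_samples = [s for s in samples if class_of[s] == cls]
        rich_err[cls] = float(
            recovered.loc[cls_samples].sum(axis=1).mean()
            - true_cl.loc[cls_samples].sum(axis=1).mean()
        )

    true_shared = int(
        ((true_cl.loc[[s for s in samples if class_of[s] == "adult"]].sum() > 0)
         & (true_cl.loc[[s for s in samples if class_of[s] == "chick"]].sum() > 0)).sum()
    )
    rec_shared = int(
        ((recovered.loc[[s for s in samples if class_of[s] == "adult"]].sum() > 0)
         & (recovered.loc[[s for s in samples if class_of[s] == "chick"]].sum() > 0)).sum()
    )

    return {
        "presence": {"tp": tp, "fp": fp, "fn": fn, "tn": tn, "f1": f1},
        "contaminants": {
            "n_true": len(truth_set),
            "n_flagged": len(flagged_true),
            "missed": sorted(truth_set - flagged_true),
            "false_flags": sorted(flagged_true - truth_set),
            "all_recovered": flagged_true >= truth_set,
        },
        "shared_otu_error": rec_shared - true_shared,
        "richness_mean_error": rich_err,
    }
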