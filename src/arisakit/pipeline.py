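"""End-to-end orchestration: clone library -> OTUs -> peak matching ->
filtering -> taxonomy -> rarefaction -> assemblage statistics -> UniFrac
suite, with all stage outputs written to an output directory alongside a
manifest that records the seed and parameters."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import io as aio
from .assemblage_stats import (
    GroupComparisonResult,
    SharedOTUCounts,
    compare_group_richness,
    correlate_age_richness,
    richness_per_sample,
    shared_otu_count,
    singleton_fraction,
)
from .clone_library import OTU, collapse_to_otus, dedupe_clones
from .peak_matching import (
    bin_peaks,
    build_presence_matrix,
    discard_artefact_peaks,
    flag_contaminants,
    match_peaks_to_clones,
)
from .phylocommunity import (
    jackknife_support,
    lineage_specific,
    p_test,
    pcoa,
    unifrac_matrix,
    unifrac_significance,
    upgma,
)
from .rarefaction import rarefaction_curve
from .taxonomy import Lineage, consensus_assign, placement_lineage, summarize_taxa

__all__ = ["AnalysisParams", "RunConfig", "AnalysisResult", "analyze", "run_full_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisParams:
    """Tunables of the analysis stages (defaults follow the study's settings)."""

    core_length: int = 131
    window_low: int = 6
    window_high: int = 15
    consensus_mode: str = "tree_emphasis"
    support_threshold: float = 0.7
    n_perm: int = 100
    jackknife_keep: int = 5
    min_descendants: int = 4
    rarefaction_step: int = 10
    seed: int = 0
    community: bool = True
    jackknife: bool = False
    control_class: str = "control"


@dataclass(frozen=True)
class RunConfig(AnalysisParams):
    """File-based run: paths plus :class:`AnalysisParams`."""

    clones_path: str = ""
    peaks_path: str = ""
    metadata_path: str = ""
    hits_path: str = ""
    tree_path: str = ""
    reference_lineages_path: str = ""
    outdir: str = "arisakit_out"
    delimiter: str = "|"


@dataclass
class AnalysisResult:
    otus: list[OTU]
    assignments: list
    artefact_report: pd.DataFrame
    contaminants: set[int]
    presence: pd.DataFrame
    taxonomy: pd.DataFrame
    phylum_summary: dict
    rarefaction: dict  # class -> RarefactionCurve
    richness: pd.DataFrame
    shared: SharedOTUCounts
    singleton_fractions: dict
    age_correlation: GroupComparisonResult | None
    group_comparison: GroupComparisonResult | None
    community: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _otu_hit_lineage(otu: OTU, hits: pd.DataFrame) -> Lineage:
    sub = hits[hits["clone_id"].isin(otu.member_clone_ids)]
    if sub.empty:
        return Lineage.empty()
    best = sub.sort_values(["score", "clone_id"], ascending=[False, True]).iloc[0]
    return Lineage.from_string(str(best["lineage"]))


def analyze(
    clones,
    profiles,
    metadata: pd.DataFrame,
    hits: pd.DataFrame | None = None,
    tree: TreeNode | None = None,
    reference_lineages: Mapping[str, Lineage] | None = None,
    params: AnalysisParams | None = None,
) -> AnalysisResult:
    """Run the full analysis on in-memory inputs."""
    params = params or AnalysisParams()
    class_map = dict(zip(metadata["sample_id"].astype(str), metadata["age_class"]))
    control_samples = {s for s, c in class_map.items() if c == params.control_class}

    # 1. clone library -> OTUs
    uniques = dedupe_clones(clones)
    otus = collapse_to_otus(uniques, class_map=class_map)
    clone_to_otu = {cid: o.otu_id for o in otus for cid in o.member_clone_ids}

    # 2. peak binning, matching, filtering
    binned = {s: bin_peaks(p) for s, p in profiles.items()}
    assignments = match_peaks_to_clones(
        binned, uniques, class_map, otus,
        window_low=params.window_low, window_high=params.window_high,
    )
    filtered, artefact_report = discard_artefact_peaks(binned, assignments, class_map)
    contaminants = flag_contaminants(
        otus, assignments,
        {s: binned[s] for s in control_samples if s in binned},
        control_samples,
    )
    presence = build_presence_matrix(
        filtered, assignments, otus, class_map,
        contaminants=contaminants, control_class=params.control_class,
    )

    # 3. taxonomy
    tax_rows = []
    lineages: dict[int, Lineage] = {}
    leaf_of_otu: dict[int, str] = {}
    if tree is not None:
        for tip in tree.tips():
            o = clone_to_otu.get(tip.name)
            if o is not None and o not in leaf_of_otu:
                leaf_of_otu[o] = tip.name
    for otu in otus:
        hit = _otu_hit_lineage(otu, hits) if hits is not None else Lineage.empty()
        placement = Lineage.empty()
        if tree is not None and reference_lineages and otu.otu_id in leaf_of_otu:
            placement = placement_lineage(
                tree, leaf_of_otu[otu.otu_id], reference_lineages,
                support_threshold=params.support_threshold,
            )
        assigned, label = consensus_assign(hit, placement, mode=params.consensus_mode)
        lineages[otu.otu_id] = assigned
        tax_rows.append(
            {
                "otu_id": otu.otu_id,
                "hit_lineage": hit.to_string(),
                "placement_lineage": placement.to_string(),
                "assigned_lineage": assigned.to_string(),
                "most_derived_position": label,
                "phylum": assigned["phylum"] or "unresolved",
                "contaminant": otu.otu_id in contaminants,
            }
        )
    taxonomy_table = pd.DataFrame(tax_rows)
    cloacal_lineages = {o: l for o, l in lineages.items() if o not in contaminants}
    phylum_summary = summarize_taxa(cloacal_lineages, "phylum") if cloacal_lineages else {}

    # 4. rarefaction per age class (clone counts per cloacal OTU)
    curves = {}
    for cls in sorted({c for c in class_map.values() if c != params.control_class}):
        counts = []
        for otu in otus:
            if otu.otu_id in contaminants:
                continue
            n = sum(
                count
                for u in otu.members
                for s, count in u.occurrences.items()
                if class_map.get(s) == cls
            )
            if n > 0:
                counts.append(n)
        if counts:
            curves[cls] = rarefaction_curve(counts, step=params.rarefaction_step)

    # 5. assemblage statistics
    richness = richness_per_sample(presence, metadata)
    class_sets = {
        o.otu_id: (o.found_in_classes - {params.control_class})
        for o in otus
        if o.otu_id not in contaminants
    }
    shared = shared_otu_count(class_sets)
    singles = {}
    for cls in ("adult", "chick"):
        try:
            singles[cls] = singleton_fraction(presence, class_map, cls)
        except ValueError:
            pass
    age_corr = None
    group_cmp = None
    try:
        age_corr = correlate_age_richness(richness, seed=params.seed)
    except (ValueError, KeyError) as exc:
        logger.warning("age-richness correlation skipped: %s", exc)
    try:
        group_cmp = compare_group_richness(richness, seed=params.seed + 1)
    except ValueError as exc:
        logger.warning("group richness comparison skipped: %s", exc)

    # 6. community phylogenetics on the presence matrix
    community: dict = {}
    if params.community and tree is not None:
        community = _community_suite(
            tree, otus, presence, leaf_of_otu, contaminants, params
        )

    manifest = {
        "seed": params.seed,
        "params": {
            k: v
            for k, v in dataclasses.asdict(params).items()
            if not k.endswith("_path") and k != "outdir"
        },
        "n_clones": len(list(clones)),
        "n_unique_clones": len(uniques),
        "n_otus": len(otus),
        "n_contaminants": len(contaminants),
        "n_samples": len(presence.index),
    }
    return AnalysisResult(
        otus=otus,
        assignments=assignments,
        artefact_report=artefact_report,
        contaminants=contaminants,
        presence=presence,
        taxonomy=taxonomy_table,
        phylum_summary=phylum_summary,
        rarefaction=curves,
        richness=richness,
        shared=shared,
        singleton_fractions=singles,
        age_correlation=age_corr,
        group_comparison=group_cmp,
        community=community,
        manifest=manifest,
    )


def _community_suite(tree, otus, presence, leaf_of_otu, contaminants, params):
    leaves = {leaf_of_otu[o] for o in presence.columns if o in leaf_of_otu}
    if len(leaves) < 3:
        logger.warning("too few OTUs on the tree for community analysis")
        return {}
    sub = tree.shear(sorted(leaves))
    sub.prune()

    env_sets = {}
    for s in presence.index:
        lv = {
            leaf_of_otu[o]
            for o in presence.columns
            if presence.loc[s, o] and o in leaf_of_otu
        }
        if lv:
            env_sets[s] = lv
        else:
            logger.warning("sample %s has no OTUs on the tree; excluded", s)

    out: dict = {}
    if len(env_sets) >= 2:
        dm = unifrac_matrix(sub, env_sets)
        out["unifrac_matrix"] = dm
        out["pcoa"] = pcoa(dm)
        out["upgma"] = upgma(dm)
        if params.jackknife:
            ref, support = jackknife_support(
                sub, env_sets, keep=params.jackknife_keep,
                n_perm=params.n_perm, seed=params.seed + 2,
            )
            out["jackknife_tree"] = ref
            out["jackknife_support"] = support

    # age-class labelling of OTU leaves; shared OTUs have no single class
    label_of: dict[str, str] = {}
    for o in otus:
        classes = o.found_in_classes - {params.control_class}
        if o.otu_id in contaminants or o.otu_id not in leaf_of_otu:
            continue
        if len(classes) == 1 and leaf_of_otu[o.otu_id] in leaves:
            label_of[leaf_of_otu[o.otu_id]] = next(iter(classes))
    if len(set(label_of.values())) == 2:
        out["unifrac_significance_p"] = unifrac_significance(
            sub, label_of, n_perm=params.n_perm, seed=params.seed + 3
        )
        p, changes = p_test(sub, label_of, n_perm=params.n_perm, seed=params.seed + 4)
        out["p_test_p"] = p
        out["p_test_changes"] = changes
        out["lineage_specific"] = lineage_specific(
            sub, label_of, min_descendants=params.min_descendants
        )
    return out


def run_full_pipeline(config: RunConfig) -> AnalysisResult:
    """Load inputs from files, analyse, and write the result bundle."""
    clones = aio.read_clone_fasta(
        config.clones_path, core_length=config.core_length, delimiter=config.delimiter
    )
    profiles = aio.read_peak_table(config.peaks_path)
    metadata = aio.read_metadata(config.metadata_path)
    hits = aio.read_hit_table(config.hits_path) if config.hits_path else None
    tree = aio.read_tree(config.tree_path) if config.tree_path else None
    refs = (
        aio.read_lineage_table(config.reference_lineages_path)
        if config.reference_lineages_path
        else None
    )
    result = analyze(clones, profiles, metadata, hits, tree, refs, params=config)
    write_result_bundle(result, config.outdir)
    return result


def write_result_bundle(result: AnalysisResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aio.write_otu_table(outdir / "otus.tsv", result.otus)
    pd.DataFrame([dataclasses.asdict(a) for a in result.assignments]).to_csv(
        outdir / "peak_assignments.tsv", sep="\t", index=False
    )
    result.artefact_report.to_csv(outdir / "artefact_report.tsv", sep="\t", index=False)
    aio.write_presence_matrix(outdir / "presence_matrix.tsv", result.presence)
    result.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
    for cls, curve in result.rarefaction.items():
        curve.to_frame().to_csv(outdir / f"rarefaction_{cls}.tsv", sep="\t", index=False)
    result.richness.to_csv(outdir / "richness.tsv", sep="\t", index=False)
    if "unifrac_matrix" in result.community:
        result.community["unifrac_matrix"].to_csv(outdir / "unifrac.tsv", sep="\t")
        result.community["pcoa"].coordinates.to_csv(outdir / "pcoa.tsv", sep="\t")
        aio.write_tree(result.community["upgma"], outdir / "upgma.nwk")
    if "jackknife_tree" in result.community:
        aio.write_tree(result.community["jackknife_tree"], outdir / "upgma_jackknife.nwk")
    if "lineage_specific" in result.community:
        result.community["lineage_specific"].to_csv(
            outdir / "lineage_specific.tsv", sep="\t", index=False
        )
    summary = {
        "manifest": result.manifest,
        "shared_otus": dataclasses.asdict(result.shared),
        "phylum_summary": result.phylum_summary,
        "singleton_fractions": result.singleton_fractions,
        "contaminants": sorted(result.contaminants),
        "community_pvalues": {
            k: result.community[k]
            for k in ("unifrac_significance_p", "p_test_p", "p_test_changes")
            if k in result.community
        },
    }
    if result.age_correlation:
        summary["age_richness"] = dataclasses.asdict(result.age_correlation)
    if result.group_comparison:
        summary["group_richness"] = dataclasses.asdict(result.group_comparison)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (set, frozenset, tuple)):
        return sorted(x) if isinstance(x, (set, frozenset)) else list(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")
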