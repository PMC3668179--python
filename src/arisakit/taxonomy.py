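"""Consensus taxonomic assignment from similarity hits and tree placement.

Two independent lines of evidence are combined per OTU: the lineage of its
best similarity hit (precomputed, e.g. a BLAST best hit against a reference
database) and a lineage read off a reference phylogeny (the smallest
well-supported clade around the query that contains reference taxa).
When the two agree at some rank the OTU is assigned at the deepest such
rank; when they conflict the default policy trusts the tree, falling back
to shallower ranks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import skbio

__all__ = [
    "RANKS",
    "Lineage",
    "HitRecord",
    "placement_lineage",
    "consensus_assign",
    "summarize_taxa",
]

#: Rank scale, shallow to deep. "suborder" is included because actinobacterial
#: classifications in common use resolve to suborders (e.g. Corynebacterineae).
RANKS = ("phylum", "class", "order", "suborder", "family", "genus", "species")


@dataclass(frozen=True)
class Lineage:
    """Ordered rank names; empty string marks an unresolved rank."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(f"a Lineage carries {len(RANKS)} ranks, got {len(self.names)}")

    @classmethod
    def from_string(cls, text: str, sep: str = ";") -> "Lineage":
        parts = [p.strip() for p in text.split(sep)] if text else []
        parts += [""] * (len(RANKS) - len(parts))
        return cls(tuple(parts[: len(RANKS)]))

    @classmethod
    def empty(cls) -> "Lineage":
        return cls(("",) * len(RANKS))

    def to_string(self, sep: str = ";") -> str:
        return sep.join(self.names)

    def __getitem__(self, rank: str) -> str:
        return self.names[RANKS.index(rank)]

    def depth(self) -> int:
        """Index of the deepest filled rank plus one (0 for an empty lineage)."""
        d = 0
        for i, name in enumerate(self.names):
            if name:
                d = i + 1
        return d

    def deepest_rank(self) -> str | None:
        d = self.depth()
        return RANKS[d - 1] if d else None

    def truncate(self, depth: int) -> "Lineage":
        return Lineage(self.names[:depth] + ("",) * (len(RANKS) - depth))

    def is_empty(self) -> bool:
        return self.depth() == 0

    def rank_label(self) -> str:
        """Human-readable label like ``"Genus: Corynebacterium"``."""
        d = self.depth()
        if not d:
            return "unclassified"
        return f"{RANKS[d - 1].capitalize()}: {self.names[d - 1]}"


@dataclass(frozen=True)
class HitRecord:
    """Best similarity hit for one clone."""

    clone_id: str
    subject: str
    lineage: Lineage
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.score < 0 or self.evalue < 0:
            raise ValueError(f"hit for {self.clone_id}: score and evalue must be >= 0")


def common_prefix(lineages: Sequence[Lineage]) -> Lineage:
    """Longest common rank prefix: stop at the first rank where names differ."""
    if not lineages:
        return Lineage.empty()
    out: list[str] = []
    for i in range(len(RANKS)):
        names = {lin.names[i] for lin in lineages}
        if len(names) != 1:
            break
        out.append(names.pop())
    out += [""] * (len(RANKS) - len(out))
    return Lineage(tuple(out))


def _node_support(node: "skbio.TreeNode") -> float:
    # Unlabelled internal nodes are treated as fully supported; an explicit
    # numeric label (bootstrap fraction / posterior) overrides that.
    if node.name is None or node.name == "":
        return 1.0
    try:
        return float(node.name)
    except ValueError:
        return 1.0


def placement_lineage(
    tree: "skbio.TreeNode",
    query_leaf: str,
    reference_lineages: Mapping[str, Lineage],
    support_threshold: float = 0.7,
) -> Lineage:
    """Lineage implied by the query's position in a reference phylogeny.

    Walks from the query leaf toward the root; at the first ancestor whose
    support is at least ``support_threshold`` and whose clade contains at
    least one reference leaf, returns the longest common rank prefix of the
    reference lineages in that clade. Returns an empty lineage when no such
    ancestor exists.
    """
    try:
        node = tree.find(query_leaf)
    except skbio.tree.MissingNodeError as exc:
        raise ValueError(f"query leaf {query_leaf!r} not found in tree") from exc
    if not node.is_tip():
        raise ValueError(f"query {query_leaf!r} is not a leaf")
    ancestor = node.parent
    while ancestor is not None:
        if _node_support(ancestor) >= support_threshold:
            refs = [
                reference_lineages[tip.name]
                for tip in ancestor.tips()
                if tip.name in reference_lineages and tip is not node
            ]
            if refs:
                return common_prefix(refs)
        ancestor = ancestor.parent
    return Lineage.empty()


def consensus_assign(
    hit: Lineage, placement: Lineage, mode: str = "tree_emphasis"
) -> tuple[Lineage, str]:
    """Combine hit and placement lineages into one assignment.

    Where the two agree at a rank (and at every shallower rank that both
    fill) the assignment is made at the deepest agreeing rank. On a genuine
    conflict, mode ``"tree_emphasis"`` keeps the placement lineage as long
    as it does not contradict the hit's phylum, while ``"strict"`` truncates
    to the deepest rank before the first conflict. Returns the assigned
    lineage and its rank label.
    """
    if mode not in ("tree_emphasis", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    if hit.is_empty() and placement.is_empty():
        return Lineage.empty(), "unclassified"
    if placement.is_empty():
        assigned = hit.truncate(1)  # no tree evidence: fall back to hit phylum
        return assigned, assigned.rank_label()
    if hit.is_empty():
        return placement, placement.rank_label()

    first_conflict = None
    deepest_agree = 0
    for i in range(len(RANKS)):
        h, p = hit.names[i], placement.names[i]
        if h and p:
            if h == p:
                if first_conflict is None:
                    deepest_agree = i + 1
            elif first_conflict is None:
                first_conflict = i

    if first_conflict is None:
        if deepest_agree == 0:
            # no rank filled by both and no conflict: trust the deeper record
            assigned = placement if placement.depth() >= hit.depth() else hit
            return assigned, assigned.rank_label()
        assigned = placement.truncate(deepest_agree)
        return assigned, assigned.rank_label()

    if mode == "strict":
        assigned = placement.truncate(deepest_agree)
        return assigned, assigned.rank_label()
    # tree_emphasis: follow the tree unless it contradicts the hit's phylum
    if first_conflict == 0:
        return Lineage.empty(), "unclassified"
    return placement, placement.rank_label()


def summarize_taxa(
    otu_lineages: Mapping[int, Lineage], rank: str = "phylum"
) -> dict[str, float]:
    """Proportion of OTUs per taxon at ``rank`` (unresolved OTUs bucketed).

    Proportions are over OTUs, not clones, and sum to 1 including the
    ``"unresolved"`` bucket.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if not otu_lineages:
        return {}
    counts: Counter[str] = Counter()
    for lineage in otu_lineages.values():
        name = lineage[rank]
        counts[name if name else "unresolved"] += 1
    total = sum(counts.values())
    return {taxon: n / total for taxon, n in sorted(counts.items())}
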