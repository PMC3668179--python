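"""Clone library handling: region splitting, deduplication and OTU collapsing.

An ARISA amplicon spans the 16S-23S intergenic spacer (IGS) plus a short
conserved fragment of the 23S rRNA gene (131 bp with the primer system the
package defaults to). Because the reverse primer anchors inside the 23S
gene, the conserved fragment sits at the 3' end of the sequenced clone; the
variable IGS is everything upstream of it.

Clones sharing an identical 23S fragment are collapsed into one OTU: a
single organism carries several rRNA operons whose spacers differ in
length, so one OTU legitimately owns several amplicon ("operon") lengths.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CloneRecord",
    "UniqueClone",
    "OTU",
    "split_regions",
    "make_clone_record",
    "dedupe_clones",
    "collapse_to_otus",
]

_VALID_ALPHABET = frozenset("ACGTN")

DEFAULT_CORE_LENGTH = 131


def split_regions(
    sequence: str, core_length: int = DEFAULT_CORE_LENGTH, core_end: str = "3prime"
) -> tuple[str, str]:
    """Split an amplicon into (igs_region, core23s_region).

    With ``core_end="3prime"`` (the default, matching a reverse primer that
    anchors inside the 23S gene) the conserved core is the terminal
    ``core_length`` bases and the IGS is the remainder. ``core_end="5prime"``
    is available for primer systems that read the core first.
    """
    if core_length < 1:
        raise ValueError("core_length must be a positive integer")
    if len(sequence) < core_length:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than the "
            f"{core_length}-bp conserved core; cannot split regions"
        )
    if core_end == "3prime":
        return sequence[:-core_length], sequence[-core_length:]
    if core_end == "5prime":
        return sequence[core_length:], sequence[:core_length]
    raise ValueError(f"core_end must be '3prime' or '5prime', got {core_end!r}")


@dataclass(frozen=True)
class CloneRecord:
    """One sequenced IGS+23S amplicon with its sample of origin."""

    clone_id: str
    sample_id: str
    sequence: str
    igs_region: str
    core23s_region: str

    @property
    def total_length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_ALPHABET
        if bad:
            raise ValueError(
                f"clone {self.clone_id}: invalid characters {sorted(bad)} "
                "in sequence (alphabet is A, C, G, T, N)"
            )
        if self.igs_region + self.core23s_region != self.sequence:
            raise ValueError(
                f"clone {self.clone_id}: igs_region + core23s_region does "
                "not reconstruct the sequence"
            )


def make_clone_record(
    clone_id: str,
    sample_id: str,
    sequence: str,
    core_length: int = DEFAULT_CORE_LENGTH,
    core_end: str = "3prime",
) -> CloneRecord:
    """Build a :class:`CloneRecord`, splitting IGS and 23S core regions."""
    sequence = sequence.upper()
    igs, core = split_regions(sequence, core_length, core_end)
    return CloneRecord(
        clone_id=clone_id,
        sample_id=sample_id,
        sequence=sequence,
        igs_region=igs,
        core23s_region=core,
    )


@dataclass(frozen=True)
class UniqueClone:
    """A distinct amplicon sequence plus the samples that yielded it.

    ``occurrences`` maps sample_id -> number of raw clones of this exact
    sequence recovered from that sample.
    """

    representative: CloneRecord
    member_clone_ids: tuple[str, ...]
    occurrences: Mapping[str, int]

    @property
    def sequence(self) -> str:
        return self.representative.sequence

    @property
    def core23s_region(self) -> str:
        return self.representative.core23s_region

    @property
    def total_length(self) -> int:
        return self.representative.total_length

    @property
    def clone_id(self) -> str:
        return self.representative.clone_id


def dedupe_clones(clones: Iterable[CloneRecord]) -> list[UniqueClone]:
    """Collapse raw clones into unique sequences with per-sample counts.

    Output order is deterministic: sorted by sequence string. The
    representative of each unique sequence is the member with the
    lexicographically smallest clone_id.
    """
    by_seq: dict[str, list[CloneRecord]] = {}
    for clone in clones:
        by_seq.setdefault(clone.sequence, []).append(clone)
    uniques = []
    for seq in sorted(by_seq):
        members = sorted(by_seq[seq], key=lambda c: c.clone_id)
        counts = Counter(c.sample_id for c in members)
        uniques.append(
            UniqueClone(
                representative=members[0],
                member_clone_ids=tuple(c.clone_id for c in members),
                occurrences=dict(sorted(counts.items())),
            )
        )
    return uniques


@dataclass
class OTU:
    """Set of unique clones sharing one 23S core (one organism, >=1 operons)."""

    otu_id: int
    representative_23s: str
    members: list[UniqueClone] = field(repr=False)
    member_clone_ids: frozenset[str]
    operon_lengths: tuple[int, ...]
    found_in_classes: frozenset[str] = frozenset()

    @property
    def n_operons(self) -> int:
        return len(self.operon_lengths)

    def samples(self) -> set[str]:
        out: set[str] = set()
        for u in self.members:
            out.update(u.occurrences)
        return out


def _core_matches(a: str, b: str, tolerance: int) -> bool:
    # N is treated as never matching: merging distinct cores on an ambiguous
    # base would silently conflate organisms.
    if len(a) != len(b):
        return False
    mismatches = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mismatches += 1
            if mismatches > tolerance:
                return False
    return True


def collapse_to_otus(
    unique_clones: Sequence[UniqueClone],
    mismatch_tolerance: int = 0,
    class_map: Mapping[str, str] | None = None,
) -> list[OTU]:
    """Partition unique clones into OTUs by identity of the 23S core.

    Under the default tolerance of 0 mismatches two clones share an OTU iff
    their 23S cores are byte-identical (exact N excluded). A positive
    tolerance allows that many mismatches but requires all cores to be the
    same length. OTU ids are 1..K in order of first appearance in the input
    (which :func:`dedupe_clones` has already sorted by sequence), so reruns
    are bit-identical.

    ``class_map`` (sample_id -> age class) fills ``found_in_classes``.
    """
    if mismatch_tolerance < 0:
        raise ValueError("mismatch_tolerance must be >= 0")
    if mismatch_tolerance > 0:
        lengths = {len(u.core23s_region) for u in unique_clones}
        if len(lengths) > 1:
            raise ValueError(
                "nonzero mismatch_tolerance requires equal-length 23S cores; "
                f"got lengths {sorted(lengths)}"
            )

    groups: list[list[UniqueClone]] = []
    reps: list[str] = []
    for u in unique_clones:
        placed = False
        if mismatch_tolerance == 0:
            # exact mode: dict-free linear scan kept for symmetry with the
            # tolerant path; libraries are small enough that this is fine
            for gi, rep in enumerate(reps):
                if rep == u.core23s_region and "N" not in rep:
                    groups[gi].append(u)
                    placed = True
                    break
        else:
            for gi, rep in enumerate(reps):
                if _core_matches(rep, u.core23s_region, mismatch_tolerance):
                    groups[gi].append(u)
                    placed = True
                    break
        if not placed:
            groups.append([u])
            reps.append(u.core23s_region)

    otus = []
    for i, members in enumerate(groups, start=1):
        classes: set[str] = set()
        if class_map is not None:
            for u in members:
                for sample in u.occurrences:
                    if sample in class_map:
                        classes.add(class_map[sample])
        otus.append(
            OTU(
                otu_id=i,
                representative_23s=members[0].core23s_region,
                members=list(members),
                member_clone_ids=frozenset(
                    cid for u in members for cid in u.member_clone_ids
                ),
                operon_lengths=tuple(sorted({u.total_length for u in members})),
                found_in_classes=frozenset(classes),
            )
        )
    return otus
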