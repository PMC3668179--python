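"""File formats: clone FASTA, peak-table CSV, metadata/hit/lineage TSV, newick.

Clone ids follow the convention ``<sample>|<serial>`` (delimiter
configurable); the sample of origin is parsed out of the id.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import skbio
from Bio import SeqIO

from .clone_library import OTU, CloneRecord, make_clone_record
from .peak_matching import ARISAProfile
from .taxonomy import Lineage

__all__ = [
    "read_clone_fasta",
    "write_clone_fasta",
    "read_peak_table",
    "write_peak_table",
    "read_metadata",
    "read_hit_table",
    "read_lineage_table",
    "read_tree",
    "write_tree",
    "write_otu_table",
    "write_presence_matrix",
    "read_presence_matrix",
]


def read_clone_fasta(
    path: str | Path,
    core_length: int = 131,
    delimiter: str = "|",
    core_end: str = "3prime",
) -> list[CloneRecord]:
    """Read a clone library; clone ids carry the sample of origin."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        clone_id = rec.id
        if delimiter not in clone_id:
            raise ValueError(
                f"clone id {clone_id!r} lacks the {delimiter!r} sample delimiter"
            )
        sample_id = clone_id.split(delimiter, 1)[0]
        records.append(
            make_clone_record(clone_id, sample_id, str(rec.seq), core_length, core_end)
        )
    return records


def write_clone_fasta(path: str | Path, clones: Sequence[CloneRecord]) -> None:
    with open(path, "w") as fh:
        for c in clones:
            fh.write(f">{c.clone_id}\n{c.sequence}\n")


def read_peak_table(path: str | Path) -> dict[str, ARISAProfile]:
    """Peak CSV with columns sample_id, size_bp, height -> one profile per sample."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"sample_id", "size_bp", "height"}
    if not required <= set(df.columns):
        raise ValueError(f"peak table must have columns {sorted(required)}")
    profiles = {}
    for sample, group in df.groupby("sample_id", sort=True):
        peaks = tuple(
            (float(r.size_bp), float(r.height))
            for r in group.sort_values("size_bp").itertuples()
        )
        profiles[str(sample)] = ARISAProfile(sample_id=str(sample), peaks=peaks)
    return profiles


def write_peak_table(path: str | Path, profiles: Mapping[str, ARISAProfile]) -> None:
    rows = [
        {"sample_id": s, "size_bp": size, "height": height}
        for s in sorted(profiles)
        for size, height in profiles[s].peaks
    ]
    pd.DataFrame(rows, columns=["sample_id", "size_bp", "height"]).to_csv(
        path, index=False, float_format=lambda x: repr(float(x))
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, age_class in {adult, chick, control}, age_days."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "age_class"} <= set(df.columns):
        raise ValueError("metadata must have sample_id and age_class columns")
    if "age_days" not in df.columns:
        df["age_days"] = pd.NA
    return df


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Similarity best-hit TSV: clone_id, subject, lineage, score, evalue."""
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str})
    required = {"clone_id", "subject", "lineage", "score", "evalue"}
    if not required <= set(df.columns):
        raise ValueError(f"hit table must have columns {sorted(required)}")
    return df


def read_lineage_table(path: str | Path) -> dict[str, Lineage]:
    """Reference-leaf lineage TSV: leaf, lineage (semicolon-delimited ranks)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"leaf", "lineage"} <= set(df.columns):
        raise ValueError("lineage table must have leaf and lineage columns")
    return {r.leaf: Lineage.from_string(r.lineage) for r in df.itertuples()}


def read_tree(path: str | Path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")


def write_tree(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def write_otu_table(path: str | Path, otus: Sequence[OTU]) -> None:
    rows = []
    for otu in otus:
        rows.append(
            {
                "otu_id": otu.otu_id,
                "representative_23s": otu.representative_23s,
                "n_unique_clones": len(otu.members),
                "members": ",".join(sorted(otu.member_clone_ids)),
                "operon_lengths": ",".join(str(x) for x in otu.operon_lengths),
                "found_in": ",".join(sorted(otu.found_in_classes)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_presence_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t")


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [int(c) for c in df.columns]
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    df.columns.name = "otu_id"
    return df
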