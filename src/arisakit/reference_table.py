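"""Packaged reference OTU table from the kittiwake cloacal survey.

One row per (OTU, operon): ARISA peak size (blank where no peak could be
assigned), clone length, their printed difference, best BLAST match with
score, most derived phylogenetic position, phylum, and the age classes the
OTU was found in (Ad, Ch, or both). The table covers the 64 OTUs of
cloacal origin.
"""

from __future__ import annotations

import importlib.resources
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["load_reference_table", "validate_reference_table", "summarize_reference_table"]


def load_reference_table() -> pd.DataFrame:
    with importlib.resources.files("arisakit.data").joinpath(
        "kittiwake_otu_table.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"found_in": str})
    for col in ("arisa_peak", "clone_length", "blast_score"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["difference"] = pd.to_numeric(df["difference"], errors="coerce")
    return df


def validate_reference_table(df: pd.DataFrame) -> list[str]:
    """Invariant checks; returns warnings (malformed rows raise)."""
    warnings = []
    required = {
        "otu_id", "arisa_peak", "clone_length", "difference",
        "blast_match", "blast_score", "most_derived_position", "phylum", "found_in",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference table lacks columns: {sorted(missing)}")
    bad_ids = df.index[(df["otu_id"] < 1) | (df["otu_id"] > 64)].tolist()
    if bad_ids:
        raise ValueError(f"otu_id outside 1..64 at rows {bad_ids}")
    bad_found = df.index[~df["found_in"].isin(["Ad", "Ch", "Ad, Ch"])].tolist()
    if bad_found:
        raise ValueError(f"unparseable found_in at rows {bad_found}")
    both = df.dropna(subset=["arisa_peak", "clone_length", "difference"])
    mism = both[both["difference"] != both["clone_length"] - both["arisa_peak"]]
    for row in mism.itertuples():
        warnings.append(
            f"row {row.Index}: printed difference {row.difference:+.0f} != "
            f"clone - peak = {row.clone_length - row.arisa_peak:+.0f}"
        )
    return warnings


def _classes(found_in: str) -> set[str]:
    return {c.strip() for c in found_in.split(",")}


def summarize_reference_table(df: pd.DataFrame | None = None) -> dict:
    """Recompute the headline counts from the reference table.

    Returns OTU totals per age class, the shared count, phylum fractions
    over OTUs, and clone-vs-peak offset statistics (recomputed from the
    size columns, not the printed difference).
    """
    if df is None:
        df = load_reference_table()
    validate_reference_table(df)
    per_otu = df.groupby("otu_id").agg(
        found_in=("found_in", "first"), phylum=("phylum", "first")
    )
    classes = per_otu["found_in"].map(_classes)
    n_adult = int(classes.map(lambda c: "Ad" in c).sum())
    n_chick = int(classes.map(lambda c: "Ch" in c).sum())
    n_shared = int(classes.map(lambda c: {"Ad", "Ch"} <= c).sum())
    n_otus = len(per_otu)
    phylum_fractions = (per_otu["phylum"].value_counts() / n_otus).to_dict()

    both = df.dropna(subset=["arisa_peak", "clone_length"])
    offsets = (both["clone_length"] - both["arisa_peak"]).to_numpy(dtype=float)
    return {
        "n_otus": n_otus,
        "n_adult": n_adult,
        "n_chick": n_chick,
        "n_shared": n_shared,
        "identity_holds": n_otus == n_adult + n_chick - n_shared,
        "phylum_fractions": phylum_fractions,
        "n_matched_rows": int(len(both)),
        "offset_mean": float(np.mean(offsets)),
        "offset_sd": float(np.std(offsets, ddof=1)),
        "offset_range": (int(offsets.min()), int(offsets.max())),
        "operons_per_otu_mean": float(df.groupby("otu_id").size().mean()),
        "operons_per_otu_range": (
            int(df.groupby("otu_id").size().min()),
            int(df.groupby("otu_id").size().max()),
        ),
    }
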