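"""Per-sample richness and age-class comparisons of ARISA assemblages.

Richness here is the row sum of the binary presence matrix (fingerprint
data, not clone counts). Group comparisons report classical statistics
(Pearson r / F, Mann-Whitney U) alongside seeded permutation p-values,
which are the defaults for inference at these sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparisonResult",
    "SharedOTUCounts",
    "richness_per_sample",
    "shared_otu_count",
    "singleton_fraction",
    "correlate_age_richness",
    "compare_group_richness",
]


@dataclass
class GroupComparisonResult:
    statistic_name: str
    statistic: float
    p_value: float  # permutation p (the default inference)
    parametric: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)  # label -> {"n", "mean", "sd"}

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class SharedOTUCounts:
    n_adult: int
    n_chick: int
    n_shared: int
    n_total: int


def richness_per_sample(
    matrix: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Join per-sample OTU counts with metadata.

    ``metadata`` needs columns sample_id, age_class and (for chicks)
    age_days. Samples present in the matrix but absent from the metadata
    (or vice versa for non-control samples) raise an explicit error.
    """
    meta = metadata.set_index("sample_id")
    missing = sorted(set(matrix.index) - set(meta.index))
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    counts = matrix.sum(axis=1).astype(int)
    out = pd.DataFrame(
        {
            "sample_id": matrix.index,
            "age_class": meta.loc[matrix.index, "age_class"].to_numpy(),
            "otu_count": counts.to_numpy(),
        }
    )
    if "age_days" in meta.columns:
        out["age_days"] = meta.loc[matrix.index, "age_days"].to_numpy()
    return out.sort_values("sample_id").reset_index(drop=True)


def shared_otu_count(
    class_sets: Mapping[int, Iterable[str]],
    class_a: str = "adult",
    class_b: str = "chick",
) -> SharedOTUCounts:
    """Counts of OTUs found in each class, shared, and total.

    ``class_sets`` maps otu_id -> the classes the OTU was found in
    (contaminants should already be excluded). The identity
    n_total = n_a + n_b - n_shared holds by construction.
    """
    n_a = n_b = n_shared = n_total = 0
    for classes in class_sets.values():
        classes = set(classes)
        in_a, in_b = class_a in classes, class_b in classes
        n_a += in_a
        n_b += in_b
        n_shared += in_a and in_b
        n_total += in_a or in_b
    counts = SharedOTUCounts(n_a, n_b, n_shared, n_total)
    assert counts.n_total == counts.n_adult + counts.n_chick - counts.n_shared
    return counts


def singleton_fraction(
    matrix: pd.DataFrame, class_map: Mapping[str, str], age_class: str
) -> float:
    """Fraction of a class's OTUs present in exactly one individual."""
    samples = [s for s in matrix.index if class_map.get(s) == age_class]
    if not samples:
        raise ValueError(f"no samples of class {age_class!r} in matrix")
    sub = matrix.loc[samples]
    col_sums = sub.sum(axis=0)
    present = col_sums[col_sums >= 1]
    if present.empty:
        raise ValueError(f"class {age_class!r} has no OTUs present")
    return float((present == 1).sum() / present.size)


def _perm_p_two_sided(
    observed: float, null_values: np.ndarray, n_perm: int
) -> float:
    exceed = int(np.sum(np.abs(null_values) >= abs(observed)))
    return (1 + exceed) / (1 + n_perm)


def correlate_age_richness(
    table: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> GroupComparisonResult:
    """Pearson correlation of chick age with per-individual richness.

    The reported p-value is a two-sided label-permutation p on r; the
    parametric r/F/p are included for comparability.
    """
    chicks = table[(table["age_class"] == "chick") & table["age_days"].notna()]
    if len(chicks) < 3:
        raise ValueError("need at least 3 chicks with known ages")
    age = chicks["age_days"].to_numpy(dtype=float)
    rich = chicks["otu_count"].to_numpy(dtype=float)
    if np.std(age) == 0 or np.std(rich) == 0:
        raise ValueError("zero variance in age or richness; correlation undefined")
    r, p_param = stats.pearsonr(age, rich)
    n = len(chicks)
    f_stat = r**2 * (n - 2) / (1 - r**2) if abs(r) < 1 else np.inf
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = np.corrcoef(age, rng.permutation(rich))[0, 1]
    return GroupComparisonResult(
        statistic_name="pearson_r",
        statistic=float(r),
        p_value=_perm_p_two_sided(r, null, n_perm),
        parametric={"r": float(r), "F": float(f_stat), "df": (1, n - 2), "p": float(p_param)},
        groups={"chick": {"n": n, "mean": float(rich.mean()), "sd": float(rich.std(ddof=1))}},
    )


def compare_group_richness(
    table: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    class_a: str = "adult",
    class_b: str = "chick",
) -> GroupComparisonResult:
    """Adult-vs-chick comparison of per-individual richness.

    Reports group means +/- SD, the Mann-Whitney U statistic, and a
    two-sided permutation p on the mean difference (default inference).
    """
    a = table.loc[table["age_class"] == class_a, "otu_count"].to_numpy(dtype=float)
    b = table.loc[table["age_class"] == class_b, "otu_count"].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both classes must be non-empty")
    groups = {}
    for label, x in ((class_a, a), (class_b, b)):
        groups[label] = {
            "n": int(x.size),
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else float("nan"),
        }
    u_stat, p_u = stats.mannwhitneyu(a, b, alternative="two-sided")
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(pooled)
        null[k] = perm[: a.size].mean() - perm[a.size :].mean()
    return GroupComparisonResult(
        statistic_name="mean_difference",
        statistic=float(obs),
        p_value=_perm_p_two_sided(obs, null, n_perm),
        parametric={"U": float(u_stat), "p_mannwhitney": float(p_u)},
        groups=groups,
    )
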