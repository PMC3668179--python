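"""Analytical (hypergeometric) rarefaction with variance-based 95% limits.

For a library of S OTUs with counts N_i (total N), the expected richness in
a uniform random subsample of n clones drawn without replacement is

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)]

and the variance of the richness indicator sum is

    Var[S_n] = sum_i q_i (1 - q_i)
             + 2 sum_{i<j} [C(N - N_i - N_j, n) / C(N, n) - q_i q_j],

with q_i = C(N - N_i, n) / C(N, n) the probability that OTU i is entirely
missed. Binomial coefficients are evaluated in log space so libraries in
the thousands of clones are safe. 95% limits are the normal approximation
E +/- 1.96 sqrt(Var), clamped to [0, S].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "RarefactionCurve",
    "expected_richness",
    "richness_variance",
    "rarefaction_curve",
]


def _validate(counts: Sequence[int]) -> np.ndarray:
    c = np.asarray(counts, dtype=np.int64)
    if c.size == 0:
        raise ValueError("counts must contain at least one OTU")
    if np.any(c < 1):
        raise ValueError("all OTU counts must be >= 1")
    return c


def _log_choose(a: np.ndarray, b: int) -> np.ndarray:
    """log C(a, b) elementwise, with C(a, b) = 0 (log -> -inf) when a < b."""
    a = np.asarray(a, dtype=np.float64)
    out = np.full(a.shape, -np.inf)
    ok = a >= b
    out[ok] = gammaln(a[ok] + 1) - gammaln(b + 1) - gammaln(a[ok] - b + 1)
    return out


def _miss_probs(c: np.ndarray, n: int) -> np.ndarray:
    """q_i = P(OTU i absent from a subsample of size n)."""
    N = int(c.sum())
    denom = _log_choose(np.array([N]), n)[0]
    return np.exp(_log_choose(N - c, n) - denom)


def expected_richness(counts: Sequence[int], n: int) -> float:
    """E[S_n]: expected OTU count in a subsample of n clones."""
    c = _validate(counts)
    N = int(c.sum())
    if not 0 <= n <= N:
        raise ValueError(f"subsample size n={n} outside [0, N={N}]")
    if n == 0:
        return 0.0
    return float(np.sum(1.0 - _miss_probs(c, n)))


def richness_variance(counts: Sequence[int], n: int) -> float:
    """Var[S_n] of the richness indicator sum (exact, hypergeometric)."""
    c = _validate(counts)
    N = int(c.sum())
    if not 0 <= n <= N:
        raise ValueError(f"subsample size n={n} outside [0, N={N}]")
    if n == 0 or n == N:
        return 0.0
    q = _miss_probs(c, n)
    denom = _log_choose(np.array([N]), n)[0]
    pair_sum = N - c[:, None] - c[None, :]  # S x S matrix of N - N_i - N_j
    qq = np.exp(_log_choose(pair_sum, n) - denom)  # joint-miss probabilities
    cov = qq - q[:, None] * q[None, :]
    iu = np.triu_indices(c.size, k=1)
    var = float(np.sum(q * (1.0 - q)) + 2.0 * np.sum(cov[iu]))
    return max(var, 0.0)


@dataclass
class RarefactionCurve:
    """Rarefaction grid with expectation, variance and 95% limits."""

    n: np.ndarray
    expected: np.ndarray
    variance: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    total_richness: int
    total_clones: int
    plateaued: bool

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n": self.n,
                "expected_richness": self.expected,
                "variance": self.variance,
                "lower95": self.lower,
                "upper95": self.upper,
            }
        )


def rarefaction_curve(counts: Sequence[int], step: int = 1) -> RarefactionCurve:
    """Full rarefaction curve on the grid n = 0, step, ..., N.

    The curve is flagged as plateaued when the last 10% of the sampling
    effort adds fewer than half an OTU: E[S_N] - E[S_(0.9 N)] < 0.5.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    c = _validate(counts)
    N = int(c.sum())
    S = int(c.size)
    grid = list(range(0, N, step))
    if grid[-1] != N:
        grid.append(N)
    ns = np.array(grid, dtype=np.int64)

    exp_vals = np.empty(ns.size)
    var_vals = np.empty(ns.size)
    for k, n in enumerate(ns):
        if n == 0:
            exp_vals[k] = 0.0
            var_vals[k] = 0.0
            continue
        exp_vals[k] = expected_richness(c, int(n))
        var_vals[k] = richness_variance(c, int(n)) if n != N else 0.0

    sd = np.sqrt(var_vals)
    lower = np.clip(exp_vals - 1.96 * sd, 0.0, S)
    upper = np.clip(exp_vals + 1.96 * sd, 0.0, S)

    n90 = int(0.9 * N)
    plateaued = (expected_richness(c, N) - expected_richness(c, n90)) < 0.5
    return RarefactionCurve(
        n=ns,
        expected=exp_vals,
        variance=var_vals,
        lower=lower,
        upper=upper,
        total_richness=S,
        total_clones=N,
        plateaued=plateaued,
    )
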