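"""One-sample Wilcoxon signed-rank trend test on significance-direction codes.

A panel of univariate case-control results is summarised as a triplet
``(n_up, n_null, n_down)``: how many variables were significantly higher in
patients, not significantly different, and significantly lower.  Coding the
panel as +1/0/-1 and asking whether the +1s outweigh the -1s is a one-sample
location test; the signed-rank version used here handles the (usually large)
block of zeros by the Pratt convention and applies a continuity-corrected
normal approximation.  This is the meta-statistic that turns dozens of
per-variable tests into a single "prevailing trend" p-value, sidestepping
per-variable multiplicity correction.

Conventions (all three matter for the printed numbers to reproduce):

* **Pratt zero handling** -- zeros are ranked together with the non-zero
  values (they occupy the lowest ranks because |0| is smallest), then their
  ranks are dropped from both the positive and negative rank sums.
* **Cureton tie correction** -- the null variance is reduced by
  ``sum(t^3 - t) / 48`` over tie groups of the non-zero absolute values,
  and by the zero-block terms ``m(m+1)(2m+1)/24``.
* **Continuity correction** -- 0.5 is subtracted from ``|W+ - mu|`` before
  standardising; if ``|W+ - mu| <= 0.5`` the z statistic is exactly 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TrendCounts", "TrendResult", "trend_test", "signed_rank_general"]


@dataclass(frozen=True)
class TrendCounts:
    """Counts of significantly-up / non-significant / significantly-down
    variables in a panel."""

    n_up: int
    n_null: int
    n_down: int

    def __post_init__(self) -> None:
        if min(self.n_up, self.n_null, self.n_down) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_up + self.n_null + self.n_down

    def codes(self) -> np.ndarray:
        """Expand to the +1/0/-1 code vector the test acts on."""
        return np.concatenate(
            [
                np.ones(self.n_up),
                np.zeros(self.n_null),
                -np.ones(self.n_down),
            ]
        )

    def __str__(self) -> str:  # the (u/m/d) notation used in reports
        return f"({self.n_up}/{self.n_null}/{self.n_down})"


@dataclass(frozen=True)
class TrendResult:
    """Signed-rank trend test outcome."""

    w_plus: float
    mu: float
    sigma: float
    z: float
    p_two_sided: float
    direction: str  # "up", "down" or "none"

    @property
    def p_rounded(self) -> float:
        """p at the 3-decimal display precision used in reports."""
        return round(self.p_two_sided, 3)


def _direction(w_plus: float, mu: float, z: float) -> str:
    if z == 0.0:
        return "none"
    return "up" if w_plus > mu else "down"


def _finish(w_plus: float, mu: float, var: float) -> TrendResult:
    if var <= 0:
        raise ValueError("null variance is zero; no non-zero codes to rank")
    sigma = math.sqrt(var)
    diff = w_plus - mu
    if abs(diff) <= 0.5:
        z = 0.0
    else:
        z = (diff - math.copysign(0.5, diff)) / sigma
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = min(p, 1.0)
    return TrendResult(
        w_plus=w_plus,
        mu=mu,
        sigma=sigma,
        z=z,
        p_two_sided=p,
        direction=_direction(w_plus, mu, z),
    )


def trend_test(counts: TrendCounts, exact: bool = False) -> TrendResult:
    """Trend test on a direction-count triplet.

    Closed form of the signed-rank test on the expanded +1/0/-1 vector:
    the ``m`` zeros occupy ranks ``1..m`` and are discarded (Pratt); the
    ``k = u + d`` non-zero codes are one big tie group sharing the mid-rank
    ``m + (k + 1)/2``.

    Parameters
    ----------
    counts
        The (up, null, down) triplet.
    exact
        Use the exact two-sided sign-permutation p instead of the normal
        approximation.  With a single tie group the permutation distribution
        of W+ is binomial, so this is a two-sided binomial test on
        ``u`` out of ``k``.  Provided for methodological comparison; the
        normal approximation is the default and is what reports use.

    Returns
    -------
    TrendResult with ``p = 1`` and direction ``"none"`` when ``k = 0``.
    """
    u, m, d = counts.n_up, counts.n_null, counts.n_down
    k = u + d
    n = counts.n
    if k == 0:
        return TrendResult(
            w_plus=0.0, mu=0.0, sigma=0.0, z=0.0, p_two_sided=1.0, direction="none"
        )
    if exact:
        p = float(min(1.0, 2.0 * stats.binom.sf(max(u, d) - 1, k, 0.5)))
        mid_rank = m + (k + 1) / 2.0
        w_plus = u * mid_rank
        mu = (n * (n + 1) / 2.0 - m * (m + 1) / 2.0) / 2.0
        direction = "none" if u == d else ("up" if u > d else "down")
        return TrendResult(
            w_plus=w_plus, mu=mu, sigma=float("nan"), z=float("nan"),
            p_two_sided=p, direction=direction,
        )
    mid_rank = m + (k + 1) / 2.0
    w_plus = u * mid_rank
    mu = (n * (n + 1) / 2.0 - m * (m + 1) / 2.0) / 2.0
    var = (
        n * (n + 1) * (2 * n + 1) - m * (m + 1) * (2 * m + 1)
    ) / 24.0 - (k**3 - k) / 48.0
    return _finish(w_plus, mu, var)


def signed_rank_general(values, exact: bool = False) -> TrendResult:
    """Full signed-rank test on arbitrary reals (Pratt zeros, tie-corrected).

    Generalisation of :func:`trend_test`; on an expanded code vector the two
    agree exactly, which is the cross-check the test suite enforces.

    Zeros are ranked with everything else and then dropped from the rank
    sums.  The tie correction ``sum(t^3 - t)/48`` runs over tie groups of the
    *non-zero* absolute values; the zero block is accounted for by the
    ``m``-terms of the mean and variance.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if np.any(~np.isfinite(x)):
        raise ValueError("values must be finite")
    m = int(np.sum(x == 0))
    nz = x[x != 0]
    k = nz.size
    n = x.size
    if k == 0:
        return TrendResult(
            w_plus=0.0, mu=0.0, sigma=0.0, z=0.0, p_two_sided=1.0, direction="none"
        )
    ranks = stats.rankdata(np.abs(x))  # zeros get the lowest (tied) ranks
    nz_ranks = ranks[x != 0]
    w_plus = float(np.sum(nz_ranks[nz > 0]))
    mu = (n * (n + 1) / 2.0 - m * (m + 1) / 2.0) / 2.0
    if exact:
        if k > 20:
            raise ValueError("exact enumeration limited to 20 non-zero values")
        diff_obs = abs(w_plus - mu)
        total = 0
        hits = 0
        for signs in itertools.product((0, 1), repeat=k):
            w = float(np.sum(nz_ranks[np.array(signs, dtype=bool)]))
            total += 1
            if abs(w - mu) >= diff_obs - 1e-12:
                hits += 1
        p = hits / total
        direction = "none" if w_plus == mu else ("up" if w_plus > mu else "down")
        return TrendResult(
            w_plus=w_plus, mu=mu, sigma=float("nan"), z=float("nan"),
            p_two_sided=p, direction=direction,
        )
    var = (
        n * (n + 1) * (2 * n + 1) - m * (m + 1) * (2 * m + 1)
    ) / 24.0
    # tie groups among the non-zero absolute values
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    var -= float(np.sum(tie_counts.astype(float) ** 3 - tie_counts)) / 48.0
    return _finish(w_plus, mu, var)
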