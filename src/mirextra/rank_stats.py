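"""One-sided Wilcoxon rank-sum testing of hexamer count distributions.

For every hexamer the normalized counts of the changed genes are compared
against those of the unchanged background with a one-sided Wilcoxon
rank-sum test (alternative: changed stochastically greater). Because the
count data are heavily tied (most genes carry zero occurrences of a given
hexamer), the exact null distribution must account for ties: we compute the
permutation distribution of the rank sum over all C(n1+n2, n1) group
labelings with a shift-algorithm dynamic program on doubled midranks.

The exact distribution is used when ``n1 * n2 <= EXACT_LIMIT``; beyond that
the normal approximation with tie-corrected variance and continuity
correction (scipy's asymptotic Mann-Whitney U) takes over. Reported
p-values are floored at :data:`P_FLOOR` and transformed to -ln(p), the
scale on which results are ranked and displayed; the floor caps -lnp at
about 43.75.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ExpressionInput

P_FLOOR = 1e-19
LNP_CAP = -math.log(P_FLOOR)
EXACT_LIMIT = 10_000


@dataclass(frozen=True)
class HexamerResult:
    """Enrichment result for one hexamer."""

    hexamer: str
    p_value: float
    lnp: float
    n_changed: int
    n_unchanged: int


@dataclass(frozen=True)
class LnpHistogram:
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]


def _validate_sample(values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError(f"{name} sample is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} sample contains non-finite values")
    return arr


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact P(rank-sum of x >= observed) under exchangeability, with ties.

    Midranks of the pooled sample are doubled to integers; a dynamic
    program over (subset size, score sum) counts, for each possible rank
    sum, how many of the C(N, n1) subsets of size n1 attain it. Counts are
    held in float64: they are ratios of huge integers and only the relative
    tail mass matters, so the ~1e-15 relative rounding is negligible.
    """
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(np.int64)
    observed = int(ranks2[:n1].sum())

    # work on the smaller side for a smaller DP table
    if n1 > len(y):
        n1 = len(y)
        total2 = int(ranks2.sum())
        observed = total2 - observed
        observed_is_complement = True
    else:
        observed_is_complement = False

    scores = np.sort(ranks2)[::-1]
    smax = int(scores[:n1].sum())  # largest achievable rank sum for n1 picks
    table = np.zeros((n1 + 1, smax + 1), dtype=np.float64)
    table[0, 0] = 1.0
    for idx, r in enumerate(scores):
        r = int(r)
        kmax = min(n1, idx + 1)
        for k in range(kmax, 0, -1):
            table[k, r:] += table[k - 1, : smax + 1 - r]
    dist = table[n1]

    total = math.comb(len(ranks2), n1)
    if observed_is_complement:
        # P(W_x >= w) == P(W_small <= total2 - w)
        tail = dist[: observed + 1].sum()
    else:
        tail = dist[observed:].sum()
    return min(1.0, float(tail) / total)


def wilcoxon_one_sided(x_changed, y_unchanged) -> float:
    """P-value that the changed sample is stochastically greater.

    Exact tie-aware permutation distribution when ``n1*n2 <= EXACT_LIMIT``,
    otherwise the normal approximation with tie correction and continuity
    correction. Constant pooled data give p = 1 (the statistic cannot
    exceed its observed value).
    """
    x = _validate_sample(x_changed, "changed")
    y = _validate_sample(y_unchanged, "unchanged")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(x) * len(y) <= EXACT_LIMIT:
        return _exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="greater", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def floor_and_lnp(p: float) -> tuple[float, float]:
    """Floor a p-value at :data:`P_FLOOR` and return (p_floored, -ln p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    p_floored = max(p, P_FLOOR)
    return p_floored, -math.log(p_floored)


def test_all_hexamers(
    matrix: pd.DataFrame, expression: ExpressionInput
) -> list[HexamerResult]:
    """Run the one-sided rank-sum test for every hexamer column.

    Genes in the expression input absent from the matrix are excluded from
    both samples; at least two genes per side must remain. Results are
    sorted by p ascending, ties broken by hexamer lexicographic order.
    """
    gene_index = set(matrix.index)
    changed = sorted(expression.changed & gene_index)
    unchanged = sorted(expression.unchanged & gene_index)
    if len(changed) < 2 or len(unchanged) < 2:
        raise ValueError(
            f"need >= 2 genes with UTRs on each side, got {len(changed)} changed / "
            f"{len(unchanged)} unchanged"
        )
    x_block = matrix.loc[changed].to_numpy()
    y_block = matrix.loc[unchanged].to_numpy()
    results = []
    for j, hexamer in enumerate(matrix.columns):
        p = wilcoxon_one_sided(x_block[:, j], y_block[:, j])
        p_floored, lnp = floor_and_lnp(p)
        results.append(
            HexamerResult(hexamer, p_floored, lnp, len(changed), len(unchanged))
        )
    results.sort(key=lambda r: (r.p_value, r.hexamer))
    return results


def lnp_histogram(
    results: list[HexamerResult], bin_width: float = 1.0
) -> LnpHistogram:
    """Histogram of -lnp values over [0, cap] with half-open bins.

    Bins are [k*w, (k+1)*w); the final bin is closed so the cap itself is
    counted. The counts sum to the number of hexamers tested.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not results:
        raise ValueError("no results to histogram")
    n_bins = math.ceil(LNP_CAP / bin_width)
    edges = np.arange(n_bins + 1) * bin_width
    lnps = np.array([r.lnp for r in results])
    counts, _ = np.histogram(lnps, bins=edges)
    return LnpHistogram(tuple(edges.tolist()), tuple(int(c) for c in counts))


def display_2dp(value: float) -> float:
    """Truncate to 2 decimals for report display (the cap prints 43.74)."""
    return math.floor(value * 100) / 100


def results_to_frame(results: list[HexamerResult]) -> pd.DataFrame:
    """Tabulate results with rank and a 2-decimal display column."""
    frame = pd.DataFrame(
        {
            "hexamer": [r.hexamer for r in results],
            "p_value": [r.p_value for r in results],
            "lnp": [r.lnp for r in results],
            "lnp_2dp": [display_2dp(r.lnp) for r in results],
            "n_changed": [r.n_changed for r in results],
            "n_unchanged": [r.n_unchanged for r in results],
        }
    )
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame
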