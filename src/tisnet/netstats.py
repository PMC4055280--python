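"""Degree distributions, hub detection, and expression-degree correlation.

Hubs are the nodes whose PPI degree ranks in the top 5% of an interactome;
ties at the boundary are excluded together so the hub fraction never
exceeds the nominal 5%. The expression-degree analysis computes a Spearman
rank correlation between per-tissue RPKM and per-tissue PPI degree, both
unbinned over all eligible genes and after binning genes into 10
equally-sized RPKM bins and correlating the bin medians.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

#: exact permutation p-values below this sample size, t-approximation above
EXACT_P_BELOW = 10


# ---------------------------------------------------------------------------
# rank correlation with small-sample exact p


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x, y, exact_below: int = EXACT_P_BELOW) -> tuple[float, float]:
    """Spearman rho and two-sided p.

    For n < ``exact_below`` the p-value is computed by exhaustive
    enumeration of all permutations of one variable (the null distribution
    of rho is then exact); for larger n the usual large-sample
    approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2:
        return float("nan"), float("nan")
    rho = _spearman_rho(x, y)
    if math.isnan(rho):
        return rho, float("nan")
    if n < exact_below:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= target:
                count += 1
            total += 1
        return rho, count / total
    res = stats.spearmanr(x, y)
    return rho, float(res.pvalue)


# ---------------------------------------------------------------------------
# hubs


def detect_hubs(g, quantile: float = 0.95) -> tuple[set[str], int | None]:
    """Nodes whose degree ranks in the top (1 - quantile) of the interactome.

    ``g`` is a graph or a node -> degree mapping. Returns
    ``(hubs, threshold)`` where hubs are the nodes with degree strictly
    above the threshold. The threshold is the smallest degree d such that
    strictly-greater-than-d captures at most (1 - quantile) of the nodes,
    so boundary ties are excluded together and the hub fraction is
    guaranteed not to exceed the nominal one.
    """
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must be in [0, 1]")
    degrees = dict(g.degree()) if isinstance(g, nx.Graph) else dict(g)
    n = len(degrees)
    if n == 0:
        return set(), None
    allowed = int(math.floor((1 - quantile) * n + 1e-9))
    ordered = sorted(degrees.values(), reverse=True)
    if allowed >= n:
        threshold = min(ordered) - 1
    else:
        threshold = ordered[allowed]
    hubs = {v for v, d in degrees.items() if d > threshold}
    return hubs, threshold


def degree_histogram(g: nx.Graph) -> tuple[dict[int, int], float]:
    """Exact degree histogram and the fraction of nodes with degree <= 5."""
    counts: dict[int, int] = {}
    for _, d in g.degree():
        counts[d] = counts.get(d, 0) + 1
    n = g.number_of_nodes()
    frac_le5 = sum(c for d, c in counts.items() if d <= 5) / n if n else float("nan")
    return dict(sorted(counts.items())), frac_le5


# ---------------------------------------------------------------------------
# expression-degree correlation


@dataclass
class CorrelationReport:
    tissue: str | None
    n_eligible: int
    unbinned_rho: float
    unbinned_p: float
    binned_rho: float | None
    binned_p: float | None
    bins: pd.DataFrame | None  # bin, n, median_rpkm, median_degree


def expression_degree_correlation(
    rpkm: dict[str, float],
    degree: dict[str, int],
    n_bins: int = 10,
    tissue: str | None = None,
) -> CorrelationReport:
    """Correlate per-gene RPKM with PPI degree in one tissue.

    Eligible genes have RPKM readout above 0 and at least one PPI in the
    tissue. The binned variant sorts eligible genes by RPKM (ties broken by
    gene id, so binning is deterministic), splits them into ``n_bins``
    equal-count bins with any remainder spread over the lowest bins, and
    correlates bin-median RPKM with bin-median degree.
    """
    eligible = sorted(
        (g for g in rpkm if rpkm[g] > 0 and degree.get(g, 0) >= 1),
        key=lambda g: (rpkm[g], g),
    )
    n = len(eligible)
    if n == 0:
        return CorrelationReport(tissue, 0, float("nan"), float("nan"), None, None, None)
    xs = np.array([rpkm[g] for g in eligible])
    ys = np.array([degree[g] for g in eligible], dtype=float)
    rho, p = spearman(xs, ys)

    if n < n_bins:
        warnings.warn(
            f"only {n} eligible genes for {n_bins} bins; binned correlation skipped"
        )
        return CorrelationReport(tissue, n, rho, p, None, None, None)

    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    rows = []
    start = 0
    for b, size in enumerate(sizes):
        chunk = slice(start, start + size)
        rows.append((b, size, float(np.median(xs[chunk])), float(np.median(ys[chunk]))))
        start += size
    bins = pd.DataFrame(rows, columns=["bin", "n", "median_rpkm", "median_degree"])
    brho, bp = spearman(bins["median_rpkm"], bins["median_degree"])
    return CorrelationReport(tissue, n, rho, p, brho, bp, bins)
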