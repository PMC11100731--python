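"""Surface-protein normalization, rank binning and nonparametric statistics.

Antibody-capture (ADT) counts are log-transformed and Z-scored within
sequencing batch; cells are then ranked and split 30/40/30 into low/mid/
high bins (the same rule bins SHM). Group comparisons use the classical
rank tests — Mann-Whitney for two independent groups, Kruskal-Wallis for
three or more, Friedman for three or more related groups — with exact
p-values by enumeration for small tie-free samples and the usual
normal/chi-square approximations (tie-corrected) otherwise. Post-hoc
all-vs-all pairwise comparisons use Dunn-type rank z-tests with Holm
adjustment.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: maximum total sample size for exact-enumeration p-values
EXACT_N_MAX = 10
#: maximum number of enumerable group assignments for the exact path
#: (guards degenerate configurations like ten singleton groups)
EXACT_ASSIGNMENTS_MAX = 50_000

BIN_LABELS = ("low", "mid", "high")


# ---------------------------------------------------------------------------
# normalization and binning
# ---------------------------------------------------------------------------

def normalize_adt(counts: pd.Series, batches: pd.Series) -> pd.Series:
    """Per-batch log/Z normalization of antibody-capture counts.

    Within each batch: ``z = (log1p(count) - mean) / sd`` with the sample
    (n-1) standard deviation of log1p counts in that batch.

    Raises
    ------
    ValueError
        For a batch with fewer than 2 cells or zero variance (named).
    """
    counts = counts.astype(float)
    logx = np.log1p(counts)
    out = pd.Series(np.nan, index=counts.index, name="cd19_z")
    for batch, idx in batches.groupby(batches).groups.items():
        vals = logx.loc[idx]
        if len(vals) < 2:
            raise ValueError(f"batch {batch!r} has fewer than 2 cells")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"batch {batch!r} has zero variance in log counts")
        out.loc[idx] = (vals - vals.mean()) / sd
    return out


def assign_bins(
    values: pd.Series,
    fractions: tuple[float, float, float] = (0.3, 0.4, 0.3),
) -> pd.Series:
    """Rank values and label the bottom/middle/top slices low/mid/high.

    With n cells and fractions (l, m, h): the ``floor(l*n)`` lowest values
    become ``low``, the ``floor(h*n)`` highest become ``high``, the rest
    ``mid``. Ties are broken deterministically by barcode (index)
    lexicographic order, so the bin sizes are always exact; a warning is
    logged when tied values straddle a bin boundary.

    Raises
    ------
    ValueError
        If fewer than 3 values, or fractions do not sum to 1.
    """
    l, m, h = fractions
    if abs(l + m + h - 1.0) > 1e-9:
        raise ValueError("bin fractions must sum to 1")
    if min(l, m, h) < 0:
        raise ValueError("bin fractions must be nonnegative")
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 values to bin")
    order = pd.DataFrame({"v": values.astype(float)})
    order["bc"] = order.index.astype(str)
    order = order.sort_values(["v", "bc"], kind="stable")
    n_low = math.floor(l * n)
    n_high = math.floor(h * n)
    labels = np.array(["mid"] * n, dtype=object)
    labels[:n_low] = "low"
    if n_high:
        labels[n - n_high:] = "high"
    v = order["v"].to_numpy()
    if (n_low and n_low < n and v[n_low - 1] == v[n_low]) or (
        n_high and n_high < n and v[n - n_high] == v[n - n_high - 1]
    ):
        logger.warning("tied values straddle a bin boundary; "
                       "split deterministically by barcode order")
    out = pd.Series(labels, index=order.index, name="bin")
    return out.reindex(values.index)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    """Outcome of one rank test.

    ``posthoc`` holds the all-vs-all pairwise table (group_a, group_b,
    statistic, p, p_adj) and is present exactly when there are >= 3
    groups; ``method`` records whether p came from exact enumeration or
    the large-sample approximation.
    """
    name: str
    kind: str
    group_labels: list[str]
    group_sizes: list[int]
    statistic: float
    pvalue: float
    method: str
    posthoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "test": self.name,
            "kind": self.kind,
            "groups": ";".join(self.group_labels),
            "sizes": ";".join(str(s) for s in self.group_sizes),
            "statistic": self.statistic,
            "p": self.pvalue,
            "method": self.method,
        }


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def _mw_u(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2


def _exact_mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating rank assignments."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _mw_u(ranks[:n1].sum(), n1)
    total = math.comb(n1 + n2, n1)
    all_ranks = np.arange(1, n1 + n2 + 1)
    u_lo = min(u_obs, n1 * n2 - u_obs)
    u_hi = max(u_obs, n1 * n2 - u_obs)
    count = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = _mw_u(all_ranks[list(combo)].sum(), n1)
        if u <= u_lo + 1e-9 or u >= u_hi - 1e-9:
            count += 1
    return u_obs, count / total


def _kw_statistic(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12 / (n * (n + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / correction if correction > 0 else np.nan


def _assignments(indices: list[int], sizes: list[int]):
    """All partitions of ``indices`` into ordered groups of given sizes."""
    if len(sizes) == 1:
        yield [list(indices)]
        return
    for combo in itertools.combinations(indices, sizes[0]):
        rest = [i for i in indices if i not in combo]
        for tail in _assignments(rest, sizes[1:]):
            yield [list(combo)] + tail


def _n_assignments(sizes: list[int]) -> int:
    total = math.factorial(sum(sizes))
    for s in sizes:
        total //= math.factorial(s)
    return total


def _exact_kruskal(groups: list[np.ndarray]) -> tuple[float, float]:
    """Exact Kruskal-Wallis p by enumerating group assignments of ranks.

    Tie-free samples only; H reduces to 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)
    over group rank sums, which keeps the inner loop cheap.
    """
    h_obs = _kw_statistic(groups)
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    ranks = list(range(1, n + 1))
    scale = 12.0 / (n * (n + 1))
    shift = 3.0 * (n + 1)
    count = total = 0
    for assign in _assignments(list(range(n)), sizes):
        h = scale * sum(
            sum(ranks[i] for i in idx) ** 2 / len(idx) for idx in assign
        ) - shift
        total += 1
        if h >= h_obs - 1e-9:
            count += 1
    return h_obs, count / total


def _friedman_statistic(block_ranks: np.ndarray) -> float:
    # block_ranks: n_blocks x k within-block ranks
    n, k = block_ranks.shape
    rbar = block_ranks.mean(axis=0)
    return 12 * n / (k * (k + 1)) * ((rbar - (k + 1) / 2) ** 2).sum()


def _exact_friedman(data: np.ndarray) -> tuple[float, float]:
    """Exact Friedman p by enumerating within-block rank permutations.

    ``data`` is n_blocks x k. Under the null each block's rank vector is
    an independent uniform permutation of 1..k.
    """
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    stat_obs = _friedman_statistic(ranks)
    n, k = data.shape
    perms = [np.array(p, dtype=float) for p in itertools.permutations(range(1, k + 1))]
    count = total = 0
    for choice in itertools.product(perms, repeat=n):
        total += 1
        if _friedman_statistic(np.vstack(choice)) >= stat_obs - 1e-9:
            count += 1
    return stat_obs, count / total


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All-vs-all Dunn rank z-tests with Holm adjustment."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    start = 0
    for g in labels:
        k = len(groups[g])
        mean_rank[g] = ranks[start:start + k].mean()
        start += k
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    rows = []
    for a, b in itertools.combinations(labels, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = math.sqrt((n * (n + 1) / 12 - tie_term) * (1 / na + 1 / nb))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else np.nan
        p = 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"group_a": a, "group_b": b, "statistic": z, "p": p})
    out = pd.DataFrame(rows)
    mask = out["p"].notna()
    out["p_adj"] = np.nan
    if mask.any():
        out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method="holm")[1]
    return out


def _friedman_posthoc(data: np.ndarray, labels: list[str]) -> pd.DataFrame:
    """Pairwise rank z-tests on within-block mean ranks, Holm adjusted."""
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    n, k = data.shape
    rbar = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6 * n))
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        z = (rbar[i] - rbar[j]) / se
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "statistic": z, "p": 2 * sps.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="holm")[1]
    return out


def rank_test(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    kind: str,
    name: str = "",
) -> TestResult:
    """Run a nonparametric group comparison.

    Parameters
    ----------
    groups
        Mapping label -> sample (or a list; labels then g1, g2, ...).
        For ``friedman`` every sample is one treatment measured on the
        same blocks, in block order, and all must have equal length.
    kind
        ``mann_whitney`` (exactly 2 independent groups),
        ``kruskal_wallis`` (>= 3 independent groups) or
        ``friedman`` (>= 3 related groups).

    Exact enumeration p-values are used when the total sample size is at
    most ``EXACT_N_MAX`` and there are no ties; otherwise the classical
    approximations with tie correction. Tests with >= 3 groups carry an
    all-vs-all post-hoc pairwise table.
    """
    if isinstance(groups, dict):
        labels = list(groups)
        data = [np.asarray(groups[g], dtype=float) for g in labels]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"g{i + 1}" for i in range(len(data))]
    sizes = [len(d) for d in data]
    if any(s == 0 for s in sizes):
        raise ValueError("empty group passed to rank_test")
    if kind == "mann_whitney" and len(data) != 2:
        raise ValueError("mann_whitney requires exactly 2 groups")
    if kind == "kruskal_wallis" and len(data) < 3:
        raise ValueError("kruskal_wallis requires >= 3 groups")
    if kind == "friedman":
        if len(data) < 3:
            raise ValueError("friedman requires >= 3 treatments")
        if len(set(sizes)) != 1:
            raise ValueError("friedman requires equal block counts per treatment")
    if kind not in ("mann_whitney", "kruskal_wallis", "friedman"):
        raise ValueError(f"unknown test kind {kind!r}")
    pooled = np.concatenate(data)
    n_total = len(pooled)
    if np.all(pooled == pooled[0]):
        # a fully constant sample carries no evidence of any difference
        posthoc = None
        if len(data) >= 3:
            posthoc = pd.DataFrame(
                [{"group_a": a, "group_b": b, "statistic": 0.0,
                  "p": 1.0, "p_adj": 1.0}
                 for a, b in itertools.combinations(labels, 2)])
        return TestResult(name=name or kind, kind=kind, group_labels=labels,
                          group_sizes=sizes, statistic=0.0, pvalue=1.0,
                          method="degenerate", posthoc=posthoc)
    exact_ok = n_total <= EXACT_N_MAX and not _has_ties(pooled)

    if kind == "mann_whitney":
        if len(data) != 2:
            raise ValueError("mann_whitney requires exactly 2 groups")
        if exact_ok:
            stat, p = _exact_mann_whitney(data[0], data[1])
            method = "exact"
        else:
            res = sps.mannwhitneyu(data[0], data[1], alternative="two-sided",
                                   method="asymptotic")
            stat, p, method = float(res.statistic), float(res.pvalue), "asymptotic"
        posthoc = None
    elif kind == "kruskal_wallis":
        if len(data) < 3:
            raise ValueError("kruskal_wallis requires >= 3 groups")
        if exact_ok and _n_assignments(sizes) <= EXACT_ASSIGNMENTS_MAX:
            stat, p = _exact_kruskal(data)
            method = "exact"
        else:
            res = sps.kruskal(*data)
            stat, p, method = float(res.statistic), float(res.pvalue), "asymptotic"
        posthoc = _dunn_posthoc(dict(zip(labels, data)))
    elif kind == "friedman":
        if len(data) < 3:
            raise ValueError("friedman requires >= 3 treatments")
        if len(set(sizes)) != 1:
            raise ValueError("friedman requires equal block counts per treatment")
        block_data = np.column_stack(data)  # n_blocks x k
        if exact_ok:
            stat, p = _exact_friedman(block_data)
            method = "exact"
        else:
            res = sps.friedmanchisquare(*data)
            stat, p, method = float(res.statistic), float(res.pvalue), "asymptotic"
        posthoc = _friedman_posthoc(block_data, labels)
    else:
        raise ValueError(f"unknown test kind {kind!r}")

    return TestResult(
        name=name or kind, kind=kind, group_labels=labels, group_sizes=sizes,
        statistic=float(stat), pvalue=float(p), method=method, posthoc=posthoc,
    )


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 3 pairs, or a constant vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def gene_bin_association(
    expression: pd.Series,
    grouping: pd.Series,
    name: str = "gene_association",
) -> tuple[TestResult, pd.DataFrame]:
    """Test one gene's expression across bins or structure groups.

    Runs Mann-Whitney (2 groups) or Kruskal-Wallis (>= 3 groups) on the
    expression values grouped by label, and returns alongside a per-group
    median/IQR table. Groups with zero cells are dropped with a warning;
    fewer than 2 remaining groups is an error.
    """
    df = pd.DataFrame({"expr": expression.astype(float), "grp": grouping})
    df = df[df["grp"].notna()]
    groups: dict[str, np.ndarray] = {}
    for g, sub in df.groupby("grp", observed=True):
        vals = sub["expr"].to_numpy()
        if len(vals) == 0:
            logger.warning("group %r has zero cells; dropped", g)
            continue
        groups[str(g)] = vals
    if len(groups) < 2:
        raise ValueError("fewer than 2 non-empty groups")
    kind = "mann_whitney" if len(groups) == 2 else "kruskal_wallis"
    result = rank_test(groups, kind=kind, name=name)
    summary = pd.DataFrame([
        {
            "group": g,
            "n": len(v),
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
        }
        for g, v in groups.items()
    ])
    return result, summary
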