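"""Cohort statistics: Pearson, Kruskal-Wallis, Steel-Dwass, Fisher exact.

The Steel-Dwass all-pairs procedure re-ranks each pair of groups jointly,
standardizes the Wilcoxon rank-sum statistic with tie correction, and refers
sqrt(2)*|t| to the studentized range distribution for k groups with infinite
degrees of freedom (the asymptotic form used by commercial packages).  An
exact max-T permutation mode is available for small samples: it enumerates
every reassignment of the pooled values to groups of the observed sizes and
reports, per pair, the fraction of reassignments whose largest pairwise
|statistic| reaches the observed one.

Pearson, Kruskal-Wallis and the 2x2 Fisher exact test delegate to
scipy.stats; the 2xk Fisher-Freeman-Halton overall test is computed by
direct enumeration of tables with the observed margins (k <= 4).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import stats as sps


def _as_groups(sample: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if len(sample) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for k, v in sample.items():
        a = np.asarray(v, dtype=float)
        if a.size == 0:
            raise ValueError(f"group {k!r} is empty")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {k!r} contains non-finite values")
        out[k] = a
    return out


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with the two-tailed t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=x.size)


def kruskal_wallis(sample: dict[str, np.ndarray]) -> tuple[float, float]:
    """Tie-corrected H statistic and chi-square p-value (k-1 df)."""
    groups = list(_as_groups(sample).values())
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def normal_range_sf(q: float, k: int) -> float:
    """P(range of k iid standard normals >= q)."""
    if q <= 0:
        return 1.0
    phi, Phi = sps.norm.pdf, sps.norm.cdf

    def integrand(z):
        return phi(z) * (Phi(z) - Phi(z - q)) ** (k - 1)

    cdf, _ = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    return float(min(max(1.0 - k * cdf, 0.0), 1.0))


def _pair_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized tie-corrected Wilcoxon rank-sum statistic for one pair."""
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    big_n = n + m
    r_sum = ranks[:n].sum()
    expect = n * (big_n + 1) / 2.0
    var = n * m / (big_n * (big_n - 1.0)) * (np.sum(ranks**2) - big_n * (big_n + 1.0) ** 2 / 4.0)
    if var <= 0:
        return 0.0
    return float((r_sum - expect) / math.sqrt(var))


def steel_dwass(
    sample: dict[str, np.ndarray],
    method: str = "asymptotic",
) -> dict[tuple[str, str], float]:
    """All-pairs Steel-Dwass p-values.

    ``method="asymptotic"`` refers sqrt(2)|t| to the studentized range with
    k groups and infinite df.  ``method="exact"`` enumerates all
    reassignments of the pooled data (feasible for about n <= 8 per group)
    and returns max-T permutation p-values, which control the family-wise
    error in the same way.
    """
    groups = _as_groups(sample)
    labels = list(groups)
    k = len(labels)
    if k < 3:
        raise ValueError("Steel-Dwass requires at least 3 groups")
    if any(groups[g].size == 1 for g in labels):
        warnings.warn("group of size 1: asymptotic p-values unreliable")
    obs = {
        (a, b): _pair_statistic(groups[a], groups[b])
        for a, b in itertools.combinations(labels, 2)
    }
    if method == "asymptotic":
        return {
            pair: normal_range_sf(math.sqrt(2.0) * abs(t), k)
            for pair, t in obs.items()
        }
    if method == "exact":
        max_t = _max_t_distribution(groups)
        return {
            pair: float(np.mean(max_t >= abs(t) - 1e-12))
            for pair, t in obs.items()
        }
    raise ValueError(f"unknown method {method!r}")


def _tie_stat(u: np.ndarray, n1: int, n2: int, tie_s3) -> np.ndarray:
    """Standardized rank-sum from Mann-Whitney counts and tie sums.

    ``u`` counts (wins + half-ties) of group 1 over group 2; ``tie_s3`` is
    sum(t^3 - t) over tie groups of the pooled pair.
    """
    big_n = n1 + n2
    r_sum = u + n1 * (n1 + 1) / 2.0
    expect = n1 * (big_n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((big_n + 1.0) - np.asarray(tie_s3) / (big_n * (big_n - 1.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, (r_sum - expect) / np.sqrt(var), 0.0)
    return t


def _max_t_distribution(groups: dict[str, np.ndarray]) -> np.ndarray:
    """max over pairs of |standardized rank-sum| for every reassignment.

    Implemented for three groups by enumerating the first group's index
    set and vectorising over the second group's choices; feasible up to
    roughly 8 per group.
    """
    labels = list(groups)
    if len(labels) != 3:
        raise ValueError("exact enumeration is implemented for exactly 3 groups")
    sizes = [groups[g].size for g in labels]
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    n_assign = math.comb(n_total, sizes[0]) * math.comb(n_total - sizes[0], sizes[1])
    if n_assign > 5_000_000:
        raise ValueError(f"{n_assign} reassignments: too many for exact enumeration")

    # pairwise win/tie matrix and value codes for tie correction
    M = (pooled[:, None] > pooled[None, :]) + 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(M, 0.0)
    uniq, codes = np.unique(pooled, return_inverse=True)
    onehot = np.eye(uniq.size)[codes]  # (n_total, n_values)

    n1, n2, n3 = sizes
    out = np.empty(n_assign)
    pos = 0
    all_idx = np.arange(n_total)
    for a_tuple in itertools.combinations(range(n_total), n1):
        a = np.array(a_tuple)
        in_a = np.zeros(n_total, bool)
        in_a[a] = True
        rest = all_idx[~in_a]
        # all size-n2 subsets of rest as boolean masks
        b_choices = np.array(list(itertools.combinations(range(rest.size), n2)))
        nb = b_choices.shape[0]
        bmask = np.zeros((nb, rest.size))
        bmask[np.arange(nb)[:, None], b_choices] = 1.0

        s_a = M[a, :].sum(axis=0)[rest]          # wins of A over each rest element
        s_rest_a = M[rest][:, a].sum(axis=1)     # wins of each rest element over A
        cnt_a = onehot[a].sum(axis=0)
        cnt_rest = onehot[rest].sum(axis=0)
        cnt_b = bmask @ onehot[rest]
        cnt_c = cnt_rest - cnt_b

        u_ab = bmask @ s_a
        u_ac = s_a.sum() - u_ab
        m_rest = M[np.ix_(rest, rest)]
        q = bmask @ m_rest                        # wins of B over each rest element
        u_bc = q.sum(axis=1) - (q * bmask).sum(axis=1)

        s3 = lambda cnt: ((cnt) ** 3 - cnt).sum(axis=-1)
        t_ab = _tie_stat(u_ab, n1, n2, s3(cnt_a + cnt_b))
        t_ac = _tie_stat(u_ac, n1, n3, s3(cnt_a + cnt_c))
        t_bc = _tie_stat(u_bc, n2, n3, s3(cnt_b + cnt_c))
        out[pos:pos + nb] = np.max(np.abs(np.stack([t_ab, t_ac, t_bc])), axis=0)
        pos += nb
    assert pos == n_assign
    return out


def fisher_pairwise_bonferroni(
    table: np.ndarray,
    labels: list[str] | None = None,
) -> tuple[float, dict[tuple[str, str], float]]:
    """Overall 2xk Fisher-Freeman-Halton p and Bonferroni pairwise 2x2 p's.

    The overall p enumerates all 2xk tables with the observed margins and
    sums the probabilities of those no more probable than the observed one.
    Each pairwise two-sided 2x2 p is multiplied by the number of pairs and
    capped at 1.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2xk contingency table")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    k = table.shape[1]
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: empty margin")
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    overall = _freeman_halton(table)
    pairs = list(itertools.combinations(range(k), 2))
    adj = {}
    for i, j in pairs:
        sub = table[:, [i, j]]
        _, p = sps.fisher_exact(sub, alternative="two-sided")
        adj[(labels[i], labels[j])] = min(1.0, float(p) * len(pairs))
    return overall, adj


def _freeman_halton(table: np.ndarray) -> float:
    col = table.sum(axis=0)
    r0 = int(table[0].sum())
    n = int(table.sum())
    log_denom = _log_comb(n, r0)

    def log_prob(top: tuple[int, ...]) -> float:
        return sum(_log_comb(int(c), int(a)) for c, a in zip(col, top)) - log_denom

    obs = log_prob(tuple(int(a) for a in table[0]))
    k = len(col)

    total = 0.0
    ranges = [range(0, int(c) + 1) for c in col[:-1]]
    for head in itertools.product(*ranges):
        last = r0 - sum(head)
        if last < 0 or last > col[-1]:
            continue
        lp = log_prob(head + (last,))
        if lp <= obs + 1e-9:
            total += math.exp(lp)
    return float(min(total, 1.0))


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def sens_spec(scores, labels, cutoff: float) -> tuple[float, float]:
    """Sensitivity and specificity of the rule ``positive iff score >= cutoff``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    calls = scores >= cutoff
    tp = np.sum(calls & labels)
    fn = np.sum(~calls & labels)
    tn = np.sum(~calls & ~labels)
    fp = np.sum(calls & ~labels)
    return float(tp / (tp + fn)), float(tn / (tn + fp))
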