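"""The study's statistical battery, from explicit formulas.

Normality is checked with a Kolmogorov–Smirnov statistic against a
normal law fitted to the sample; because the parameters are estimated,
the p-value is calibrated by Monte-Carlo simulation of the null
(the Lilliefors construction) rather than read from the plain KS law.
Group comparisons use the pooled-variance Student's t, one- or two-way
fixed-effects ANOVA assembled from explicit sums of squares, and Tukey's
HSD with p-values from the studentized-range distribution.  Groups that
do not differ significantly share a letter in summary tables, mirroring
the usual figure annotation convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, DesignError, ParameterError

DEFAULT_ALPHA = 0.05
_KS_MC_REPLICATES = 10_000
_KS_MC_SEED = 20260101  # fixed: the null calibration is part of the method


@dataclass
class AnovaResult:
    f_value: float
    df_between: int
    df_within: int
    p_value: float
    ms_between: float
    ms_within: float


@dataclass
class TukeyResult:
    """All pairwise comparisons of one group family."""

    labels: list[str]
    pairs: list[tuple[str, str]]
    diffs: np.ndarray          # mean_i - mean_j per pair
    q: np.ndarray              # studentized-range statistic per pair
    p_adj: np.ndarray          # family-wise adjusted p per pair
    alpha: float

    def significant(self) -> list[tuple[str, str]]:
        return [p for p, padj in zip(self.pairs, self.p_adj) if padj < self.alpha]


@dataclass
class GroupSummary:
    labels: list[str]
    n: list[int]
    mean: list[float]
    sd: list[float]
    letters: list[str]


def _ks_stat_fitted(x: np.ndarray) -> float:
    """KS distance between the empirical CDF and a normal fitted to x."""
    n = x.size
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("constant sample: normal fit undefined (SD = 0)")
    z = np.sort((x - mu) / sd)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(max(np.max(i / n - cdf), np.max(cdf - (i - 1) / n)))


def ks_normality(sample, n_replicates: int = _KS_MC_REPLICATES,
                 seed: int = _KS_MC_SEED) -> tuple[float, float]:
    """Lilliefors-type normality test: (KS statistic, Monte-Carlo p).

    The null distribution of the statistic-with-estimated-parameters is
    simulated with ``n_replicates`` standard-normal samples of the same
    size; the default seed is fixed so the calibration is reproducible.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ParameterError(f"need n >= 4 for the normality test, got {x.size}")
    d_obs = _ks_stat_fitted(x)
    rng = np.random.default_rng(seed)
    n = x.size
    sims = rng.standard_normal((n_replicates, n))
    sims = np.sort((sims - sims.mean(axis=1, keepdims=True))
                   / sims.std(axis=1, ddof=1, keepdims=True), axis=1)
    cdf = sps.norm.cdf(sims)
    i = np.arange(1, n + 1)
    d_null = np.maximum((i / n - cdf).max(axis=1), (cdf - (i - 1) / n).max(axis=1))
    p = (1 + np.count_nonzero(d_null >= d_obs)) / (1 + n_replicates)
    return d_obs, float(p)


def t_test_two_sample(x, y) -> tuple[float, int, float]:
    """Pooled-variance Student's t; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("each sample needs n >= 2")
    df = x.size + y.size - 2
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        raise DegenerateDataError("zero pooled variance with unequal means")
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ParameterError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ParameterError(f"group {i} has n = {g.size} < 2")
    return gs


def one_way_anova(groups) -> AnovaResult:
    """Fixed-effects one-way ANOVA from explicit sums of squares."""
    gs = _check_groups(groups)
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = all_vals.size - len(gs)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = 0.0 if ms_b == 0 else np.inf
    else:
        f = ms_b / ms_w
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(float(f), df_b, df_w, p, float(ms_b), float(ms_w))


def two_way_anova(cells: dict[tuple[str, str], list]) -> dict[str, AnovaResult]:
    """Balanced fixed-effects two-way ANOVA with interaction.

    *cells* maps (factor-A level, factor-B level) to that cell's
    replicate values; every cell must hold the same number (>= 2) of
    replicates.  Returns one :class:`AnovaResult` per effect, keyed
    ``"A"``, ``"B"`` and ``"AxB"``.
    """
    a_levels = sorted({a for a, _ in cells})
    b_levels = sorted({b for _, b in cells})
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise DesignError("need >= 2 levels of each factor")
    sizes = set()
    data = {}
    for a in a_levels:
        for b in b_levels:
            if (a, b) not in cells:
                raise DesignError(f"missing cell ({a}, {b}): unbalanced design")
            vals = np.asarray(cells[(a, b)], dtype=float)
            sizes.add(vals.size)
            data[(a, b)] = vals
    if len(sizes) != 1:
        raise DesignError(f"unequal cell sizes {sorted(sizes)}: unbalanced design")
    r = sizes.pop()
    if r < 2:
        raise DesignError("need >= 2 replicates per cell")
    I, J = len(a_levels), len(b_levels)
    cell_means = np.array([[data[(a, b)].mean() for b in b_levels] for a in a_levels])
    grand = np.mean([v for vals in data.values() for v in vals])
    a_means = cell_means.mean(axis=1)
    b_means = cell_means.mean(axis=0)
    ss_a = J * r * ((a_means - grand) ** 2).sum()
    ss_b = I * r * ((b_means - grand) ** 2).sum()
    inter = cell_means - a_means[:, None] - b_means[None, :] + grand
    ss_ab = r * (inter ** 2).sum()
    ss_e = sum(((data[(a, b)] - data[(a, b)].mean()) ** 2).sum()
               for a in a_levels for b in b_levels)
    df = {"A": I - 1, "B": J - 1, "AxB": (I - 1) * (J - 1)}
    df_e = I * J * (r - 1)
    ms_e = ss_e / df_e
    out = {}
    for effect, ss in (("A", ss_a), ("B", ss_b), ("AxB", ss_ab)):
        ms = ss / df[effect]
        f = ms / ms_e if ms_e > 0 else (0.0 if ms == 0 else np.inf)
        p = float(sps.f.sf(f, df[effect], df_e)) if np.isfinite(f) else 0.0
        out[effect] = AnovaResult(float(f), df[effect], df_e, p, float(ms), float(ms_e))
    return out


def tukey_q_statistics(groups, labels: list[str] | None = None
                       ) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray, int, int]:
    """Pairwise studentized-range statistics for Tukey's HSD.

    Returns (pairs, mean differences, q values, k, within-group df).
    q uses the Tukey–Kramer harmonic-n form, so unequal group sizes are
    handled.  Exposed separately because the q statistics alone suffice
    when comparing against a studentized-range critical value (e.g. in
    the family-wise error calibration), where the per-pair p integral
    would be needless work.
    """
    gs = _check_groups(groups)
    if labels is None:
        labels = [str(i) for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ParameterError("labels length must match group count")
    an = one_way_anova(gs)
    k = len(gs)
    pairs, diffs, qs = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            n_h = 2.0 / (1.0 / gs[i].size + 1.0 / gs[j].size)
            diff = gs[i].mean() - gs[j].mean()
            if an.ms_within == 0:
                q = 0.0 if diff == 0 else np.inf
            else:
                q = abs(diff) / np.sqrt(an.ms_within / n_h)
            pairs.append((labels[i], labels[j]))
            diffs.append(diff)
            qs.append(q)
    return pairs, np.array(diffs), np.array(qs), k, an.df_within


def tukey_hsd(groups, labels: list[str] | None = None,
              alpha: float = DEFAULT_ALPHA) -> TukeyResult:
    """Tukey's HSD over all group pairs.

    Adjusted p-values come from the studentized-range distribution with
    the one-way ANOVA's within-group df.
    """
    gs = _check_groups(groups)
    if labels is None:
        labels = [str(i) for i in range(len(gs))]
    pairs, diffs, qs, k, df_within = tukey_q_statistics(gs, labels)
    p_adj = np.where(np.isfinite(qs),
                     sps.studentized_range.sf(np.where(np.isfinite(qs), qs, 0.0),
                                              k, df_within),
                     0.0)
    p_adj = np.clip(p_adj, 0.0, 1.0)
    return TukeyResult(labels=list(labels), pairs=pairs, diffs=diffs,
                       q=qs, p_adj=p_adj, alpha=alpha)


def assign_letters(tk: TukeyResult) -> dict[str, str]:
    """Compact letter display from the Tukey non-significance graph.

    Greedy clique cover in label order: each letter marks a set of
    mutually non-significant groups; groups sharing no letter differ
    significantly.  After opening a new letter for a group, earlier
    groups compatible with every member absorb it too (so a chain
    A~B, B~C, A!=C yields a, ab, b).
    """
    sig = set(tk.significant())

    def differ(a: str, b: str) -> bool:
        return (a, b) in sig or (b, a) in sig

    cliques: list[list[str]] = []
    for g in tk.labels:
        placed = False
        for clique in cliques:
            if all(not differ(g, member) for member in clique):
                clique.append(g)
                placed = True
        if not placed:
            new = [g]
            for h in tk.labels:
                if h == g:
                    break
                if all(not differ(h, member) for member in new):
                    new.append(h)
            cliques.append(new)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in tk.labels}
    for idx, clique in enumerate(cliques):
        for g in tk.labels:
            if g in clique:
                letters[g] += alphabet[idx % len(alphabet)]
    return letters


def summarize_groups(values_by_group: dict[str, list],
                     alpha: float = DEFAULT_ALPHA) -> GroupSummary:
    """Per-group n, mean, sample SD (n-1) and Tukey letters."""
    labels = list(values_by_group)
    gs = _check_groups([values_by_group[g] for g in labels])
    tk = tukey_hsd(gs, labels=labels, alpha=alpha)
    letters = assign_letters(tk)
    return GroupSummary(
        labels=labels,
        n=[g.size for g in gs],
        mean=[float(g.mean()) for g in gs],
        sd=[float(g.std(ddof=1)) for g in gs],
        letters=[letters[g] for g in labels],
    )
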