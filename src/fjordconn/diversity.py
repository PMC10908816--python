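"""Alpha diversity, PERMANOVA, constrained ordination and univariate group tests.

Alpha diversity uses Hill numbers: order q=0 is observed richness, q=1 the
exponential of Shannon entropy (effective ASV count); evenness is reported
both as Shannon entropy over richness and as classical Pielou (entropy over
ln richness).  Beta-diversity hypotheses are tested with a permutational
ANOVA on the Aitchison distance matrix and with redundancy analysis (RDA) of
the CLR matrix on z-scored environmental predictors, including a greedy
forward selection with permutation entry tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# alpha diversity
# --------------------------------------------------------------------------

def hill_number(counts: np.ndarray, q: int) -> float:
    """Hill diversity of order q (0 = richness, 1 = exp Shannon entropy)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty sample")
    if q == 0:
        return float((counts > 0).sum())
    if q == 1:
        p = counts[counts > 0] / total
        return float(np.exp(-(p * np.log(p)).sum()))
    raise ValueError("only Hill orders 0 and 1 are supported")


def shannon_entropy(counts: np.ndarray) -> float:
    """Shannon entropy of sample proportions, in nats."""
    counts = np.asarray(counts, dtype=float)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def hill_diversity(counts: pd.DataFrame, n_boot: int = 100,
                   seed: int | None = None) -> pd.DataFrame:
    """Per-sample Hill diversity table with bootstrap standard errors.

    Columns: ``richness`` (q=0), ``shannon_entropy`` (nats), ``hill_shannon``
    (q=1), ``evenness_shannon_richness`` (entropy / richness), ``evenness_pielou``
    (entropy / ln richness; NaN for single-ASV samples), plus bootstrap
    standard errors of richness and Hill–Shannon from ``n_boot`` multinomial
    resamples at the observed sequencing depth.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample, row in counts.iterrows():
        c = row.to_numpy(dtype=float)
        if c.sum() <= 0:
            raise ValueError(f"sample {sample!r} has zero total count")
        rich = hill_number(c, 0)
        ent = shannon_entropy(c)
        rec = {"sample": sample, "richness": rich, "shannon_entropy": ent,
               "hill_shannon": float(np.exp(ent)),
               "evenness_shannon_richness": ent / rich,
               "evenness_pielou": ent / np.log(rich) if rich > 1 else np.nan}
        if n_boot > 0:
            depth = int(c.sum())
            p = c / c.sum()
            boot = rng.multinomial(depth, p, size=n_boot).astype(float)
            b_rich = (boot > 0).sum(axis=1)
            pb = boot / depth
            with np.errstate(divide="ignore", invalid="ignore"):
                lb = np.where(boot > 0, np.log(pb, where=boot > 0,
                                               out=np.zeros_like(pb)), 0.0)
            b_ent = -(pb * lb).sum(axis=1)
            rec["richness_se"] = float(b_rich.std(ddof=1))
            rec["hill_shannon_se"] = float(np.exp(b_ent).std(ddof=1))
        rows.append(rec)
    return pd.DataFrame(rows).set_index("sample")


def evenness(alpha: pd.DataFrame, variant: str = "shannon_over_richness") -> pd.Series:
    """Evenness per sample from a :func:`hill_diversity` table.

    ``variant='shannon_over_richness'`` (the default) divides Shannon
    entropy by richness; ``'pielou'``
    divides by ln(richness) (classical Pielou J'), undefined (NaN, with a
    warning) for single-ASV samples.
    """
    if variant == "shannon_over_richness":
        return alpha["shannon_entropy"] / alpha["richness"]
    if variant == "pielou":
        single = alpha["richness"] <= 1
        if single.any():
            logger.warning("Pielou evenness undefined for single-ASV "
                           "sample(s): %s", list(alpha.index[single]))
        return alpha["shannon_entropy"] / np.log(
            alpha["richness"].where(~single))
    raise ValueError("variant must be 'shannon_over_richness' or 'pielou'")


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    r2: float
    pseudo_f: float
    p: float
    n_perm: int
    df_between: int
    df_within: int


def _permanova_ss(d2: np.ndarray, codes: np.ndarray,
                  n_groups: int) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group codes.

    Uses the sums-of-squares identity SS = Σ_{i<j} d²_ij / n applied to the
    whole sample and within each group.
    """
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total, ss_within


def permanova(dm: DistanceMatrix | np.ndarray, groups,
              n_perm: int = 999, seed: int | None = None) -> PermanovaResult:
    """One-factor permutational multivariate ANOVA on a distance matrix.

    Partitions the total sum of squared distances into between- and within-
    group components (Gower decomposition), reports R² = SS_between/SS_total
    and the pseudo-F statistic, with a permutation p-value under free
    (unrestricted) relabelling of samples, using the add-one convention
    ``p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)``.
    """
    d = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, float)
    labels = pd.Categorical(np.asarray(groups))
    codes = labels.codes.astype(int)
    k = len(labels.categories)
    n = d.shape[0]
    if k < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if np.bincount(codes).max() == n:
        raise ValueError("degenerate design: one group holds all samples")
    if len(codes) != n:
        raise ValueError("group length does not match distance matrix")

    d2 = d ** 2
    ss_total, ss_within = _permanova_ss(d2, codes, k)
    ss_between = ss_total - ss_within
    df_b, df_w = k - 1, n - k
    f_obs = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, ssw = _permanova_ss(d2, codes[perm], k)
        ssb = ss_total - ssw
        f_perm = (ssb / df_b) / (ssw / df_w) if ssw > 0 else np.inf
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(r2=float(r2), pseudo_f=float(f_obs), p=float(p),
                           n_perm=n_perm, df_between=df_b, df_within=df_w)


# --------------------------------------------------------------------------
# RDA and forward selection
# --------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    site_scores: pd.DataFrame        # samples × constrained axes
    biplot_scores: pd.DataFrame      # predictors × constrained axes
    constrained_fraction: float
    axis_fractions: np.ndarray       # of total variance; sums to constrained
    p: float
    n_perm: int
    rank_deficient: bool = False


def _zscore(env: pd.DataFrame) -> pd.DataFrame:
    mu = env.mean(axis=0)
    sd = env.std(axis=0, ddof=1)
    sd = sd.replace(0.0, 1.0)
    return (env - mu) / sd


def _fit_rda(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Least-squares projection of Y on the column span of X.

    Returns (fitted values, R² = SS_fit/SS_total, rank_deficient flag).
    """
    rank = np.linalg.matrix_rank(X)
    deficient = rank < X.shape[1]
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fit = X @ B
    ss_total = (Y ** 2).sum()
    r2 = (fit ** 2).sum() / ss_total if ss_total > 0 else 0.0
    return fit, float(r2), deficient


def rda(y: pd.DataFrame, env: pd.DataFrame, n_perm: int = 999,
        seed: int | None = None, scale_env: bool = True) -> OrdinationResult:
    """Redundancy analysis of a CLR matrix on environmental predictors.

    The response is column-centred; predictors are z-scored (unless already
    scaled and ``scale_env=False``).  The fitted values' singular
    decomposition gives the constrained axes; ``constrained_fraction`` is the
    proportion of total response variance captured by the predictor span.
    The model p-value permutes rows of the predictor table against the
    response, comparing the pseudo-F of the whole model.
    """
    samples = list(y.index)
    if list(env.index) != samples:
        env = env.loc[samples]
    Y = y.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0, keepdims=True)
    Xdf = _zscore(env) if scale_env else env
    X = Xdf.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("RDA needs n_samples > n_predictors + 1")

    fit, r2, deficient = _fit_rda(Y, X)
    if deficient:
        logger.warning("collinear predictors: rank-deficient design, "
                       "using least-squares pseudo-inverse")
    U, s, Vt = np.linalg.svd(fit, full_matrices=False)
    ss_total = (Y ** 2).sum()
    n_axes = int(min(np.linalg.matrix_rank(X), (s > 1e-10 * s.max()).sum())) \
        if s.size and s.max() > 0 else 0
    axis_fracs = (s[:n_axes] ** 2) / ss_total if ss_total > 0 else np.zeros(0)
    scores = U[:, :n_axes] * s[:n_axes]
    site_scores = pd.DataFrame(
        scores, index=samples,
        columns=[f"RDA{i+1}" for i in range(n_axes)])
    # biplot scores: correlation of predictors with site scores
    bip = np.zeros((p, n_axes))
    for j in range(p):
        for a in range(n_axes):
            if scores[:, a].std() > 0 and X[:, j].std() > 0:
                bip[j, a] = np.corrcoef(X[:, j], scores[:, a])[0, 1]
    biplot = pd.DataFrame(bip, index=list(env.columns),
                          columns=site_scores.columns)

    rng = np.random.default_rng(seed)
    df_res = n - p - 1
    f_obs = (r2 / p) / ((1 - r2) / df_res) if r2 < 1 else np.inf
    hits = 0
    for _ in range(n_perm):
        Xp = X[rng.permutation(n)]
        _, r2p, _ = _fit_rda(Y, Xp)
        f_perm = (r2p / p) / ((1 - r2p) / df_res) if r2p < 1 else np.inf
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p_val = (1 + hits) / (1 + n_perm)
    return OrdinationResult(site_scores=site_scores, biplot_scores=biplot,
                            constrained_fraction=float(r2),
                            axis_fractions=np.asarray(axis_fracs),
                            p=float(p_val), n_perm=n_perm,
                            rank_deficient=deficient)


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class SelectionStep:
    predictor: str
    r2: float
    adj_r2: float
    p: float
    n_perm: int


def forward_select(y: pd.DataFrame, env: pd.DataFrame, alpha: float = 0.05,
                   perm_max: int = 200, seed: int | None = None,
                   ) -> list[SelectionStep]:
    """Greedy forward selection of RDA predictors with permutation entry tests.

    At each step the candidate giving the largest adjusted R² is tested by
    permuting the response rows against the candidate (holding selected
    predictors fixed via residualization); it enters only if its marginal
    permutation p-value is below ``alpha`` (add-one convention, at most
    ``perm_max`` permutations) and the running adjusted R² does not exceed
    the full-model adjusted R².  An empty selection is a valid outcome.
    """
    rng = np.random.default_rng(seed)
    samples = list(y.index)
    env = env.loc[samples]
    Y = y.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0, keepdims=True)
    Xall = _zscore(env).to_numpy(dtype=float)
    n, p_all = Xall.shape
    names = list(env.columns)

    _, r2_full, _ = _fit_rda(Y, Xall)
    adj_full = _adjusted_r2(r2_full, n, p_all)

    selected: list[int] = []
    steps: list[SelectionStep] = []
    remaining = list(range(p_all))
    n_perm = max(perm_max - 1, 99)

    while remaining:
        best = None
        for j in remaining:
            cols = selected + [j]
            _, r2, _ = _fit_rda(Y, Xall[:, cols])
            adj = _adjusted_r2(r2, n, len(cols))
            if best is None or adj > best[1]:
                best = (j, adj, r2)
        j, adj, r2 = best
        if adj > adj_full + 1e-12:
            break
        # marginal permutation test of candidate j given selected predictors
        if selected:
            Xs = Xall[:, selected]
            _, r2_base, _ = _fit_rda(Y, Xs)
        else:
            r2_base = 0.0
        df_res = n - len(selected) - 2
        stat_obs = (r2 - r2_base) / ((1 - r2) / df_res)
        hits = 0
        for _ in range(n_perm):
            pi = rng.permutation(n)
            cols = selected + [j]
            Xp = Xall[:, cols].copy()
            Xp[:, -1] = Xall[pi, j]
            _, r2p, _ = _fit_rda(Y, Xp)
            if selected:
                _, r2bp, _ = _fit_rda(Y, Xp[:, :-1])
            else:
                r2bp = 0.0
            stat_p = (r2p - r2bp) / ((1 - r2p) / df_res)
            if stat_p >= stat_obs - 1e-12:
                hits += 1
        p_val = (1 + hits) / (1 + n_perm)
        if p_val >= alpha:
            break
        selected.append(j)
        remaining.remove(j)
        steps.append(SelectionStep(predictor=names[j], r2=float(r2),
                                   adj_r2=float(adj), p=float(p_val),
                                   n_perm=n_perm))
    return steps


# --------------------------------------------------------------------------
# univariate group tests
# --------------------------------------------------------------------------

@dataclass
class TestResult:
    comparison: str
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str
    group_sizes: dict[str, int] = dc_field(default_factory=dict)


def group_tests(values, groups, scheme: str = "anova_welch") -> list[TestResult]:
    """Test a per-sample quantity across groups.

    ``scheme='anova_welch'`` runs a one-way ANOVA across all groups followed
    by pairwise Welch two-sample t-tests (unequal variances);
    ``scheme='kruskal'`` runs the non-parametric Kruskal–Wallis test across
    all groups.  Pairwise p-values are Bonferroni-adjusted across the
    pairwise family (``p_adj = min(1, p × m)``); groups with fewer than two
    samples are flagged and skipped for variance-based tests.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    groups = pd.Series(np.asarray(groups), index=values.index)
    by = {g: values[groups == g].to_numpy() for g in pd.unique(groups)}
    names = list(by)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    sizes = {g: len(v) for g, v in by.items()}
    results: list[TestResult] = []

    usable = [g for g in names if sizes[g] >= 2]
    skipped = [g for g in names if sizes[g] < 2]
    if skipped:
        logger.warning("groups with < 2 samples skipped for variance-based "
                       "tests: %s", skipped)

    if scheme == "kruskal":
        stat, p = stats.kruskal(*[by[g] for g in usable])
        results.append(TestResult("overall", float(stat), float(p), float(p),
                                  "kruskal-wallis",
                                  {g: sizes[g] for g in usable}))
        return results
    if scheme != "anova_welch":
        raise ValueError("scheme must be 'anova_welch' or 'kruskal'")

    stat, p = stats.f_oneway(*[by[g] for g in usable])
    results.append(TestResult("overall", float(stat), float(p), float(p),
                              "anova", {g: sizes[g] for g in usable}))
    pairs = list(itertools.combinations(usable, 2))
    m = len(pairs)
    for a, b in pairs:
        t, praw = stats.ttest_ind(by[a], by[b], equal_var=False)
        results.append(TestResult(f"{a} vs {b}", float(t), float(praw),
                                  float(min(1.0, praw * m)),
                                  "welch-t (bonferroni)",
                                  {a: sizes[a], b: sizes[b]}))
    return results
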