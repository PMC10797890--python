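"""Microbiome and metabolome statistics.

Alpha/beta diversity, genome-size-normalized relative abundance, the
Firmicutes/Bacteroidetes ratio, PLS-DA variable importance (VIP),
fold-change/p-value differential filters, and the cohort-level tests
(summary-statistics t-test, Wilcoxon rank-sum, Spearman with an age
covariate, Fisher's exact test, Benjamini-Hochberg FDR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .datatypes import AbundanceTable
from .errors import NeurofuseError

# ---------------------------------------------------------------------------
# abundance normalization and diversity


def relative_abundance(
    counts: AbundanceTable, genome_size: dict[str, float] | pd.Series | None = None
) -> AbundanceTable:
    """Convert read counts to relative abundance, optionally genome-size corrected.

    value = (count / genome_size) / sum_taxa(count / genome_size), per sample.
    With ``genome_size=None`` all sizes are treated as equal (plain closure).
    """
    if counts.kind != "counts":
        raise NeurofuseError("relative_abundance expects a counts table")
    taxa = list(counts.data.columns)
    if genome_size is None:
        sizes = np.ones(len(taxa))
    else:
        gs = pd.Series(genome_size)
        missing = [t for t in taxa if t not in gs.index]
        if missing:
            raise NeurofuseError(f"missing genome size for taxon {missing[0]!r}")
        sizes = gs[taxa].to_numpy(dtype=float)
        if (sizes <= 0).any():
            raise NeurofuseError("genome sizes must be positive")
    x = counts.data.to_numpy(dtype=float) / sizes
    totals = x.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise NeurofuseError("sample with zero total count")
    rel = pd.DataFrame(x / totals, index=counts.data.index, columns=taxa)
    return AbundanceTable(data=rel, taxonomy=counts.taxonomy, kind="relative")


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness: S_obs + F1^2/(2 F2), bias-corrected when F2 = 0.

    Requires integer counts (singletons/doubletons are undefined otherwise).
    """
    counts = np.asarray(counts)
    if not np.allclose(counts, np.round(counts)):
        raise NeurofuseError("Chao1 requires integer counts")
    counts = np.round(counts).astype(int)
    if counts.sum() == 0:
        raise NeurofuseError("empty sample")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def shannon(abundances: np.ndarray) -> float:
    """Shannon entropy -sum p ln p (natural log); accepts counts or relative."""
    p = _proportions(abundances)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(abundances: np.ndarray) -> float:
    """Gini-Simpson diversity 1 - sum p^2; accepts counts or relative."""
    p = _proportions(abundances)
    return float(1.0 - (p * p).sum())


def _proportions(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    total = x.sum()
    if total <= 0:
        raise NeurofuseError("empty sample")
    return x / total


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Chao1 (counts only), Shannon and Simpson indices."""
    rows = {}
    for sample, vec in table.data.iterrows():
        v = vec.to_numpy(dtype=float)
        rows[sample] = {
            "chao1": chao1(v) if table.kind == "counts" else np.nan,
            "shannon": shannon(v),
            "simpson": simpson(v),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity BC(i,j) = sum|x-y| / sum(x+y)."""
    data = table.data if isinstance(table, AbundanceTable) else table
    x = data.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise NeurofuseError("Bray-Curtis needs at least two samples")
    if (x.sum(axis=1) == 0).any():
        raise NeurofuseError("all-zero sample")
    mat = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(mat, index=data.index, columns=data.index)


def fb_ratio(table: AbundanceTable) -> pd.Series:
    """Per-sample Firmicutes/Bacteroidetes abundance ratio.

    Zero Bacteroidetes yields ``inf`` (flagged, not raised).
    """
    phyla = table.taxonomy["phylum"]
    firm = [t for t in table.data.columns if phyla.get(t) == "Firmicutes"]
    bact = [t for t in table.data.columns if phyla.get(t) == "Bacteroidetes"]
    if not firm or not bact:
        raise NeurofuseError("taxonomy must include Firmicutes and Bacteroidetes taxa")
    f = table.data[firm].sum(axis=1)
    b = table.data[bact].sum(axis=1)
    with np.errstate(divide="ignore"):
        ratio = f.to_numpy() / b.to_numpy()
    return pd.Series(ratio, index=table.data.index, name="fb_ratio")


# ---------------------------------------------------------------------------
# PLS-DA and VIP


class PLSDAVIP(BaseEstimator, TransformerMixin):
    """PLS1 discriminant analysis (NIPALS) with VIP feature importance.

    The class vector is coded +/-1 and column-centered together with X.
    After ``fit``: ``x_scores_`` (n, A), ``x_weights_`` (p, A, unit columns),
    ``x_loadings_`` (p, A), ``vip_`` (p,).  VIP_j = sqrt(p * sum_a SSY_a w_aj^2
    / sum_a SSY_a) where SSY_a is the y-variance captured by component a, so
    mean(VIP^2) = 1.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        classes = np.unique(y)
        if classes.size != 2:
            raise NeurofuseError("PLS-DA requires exactly two classes")
        if self.n_components >= min(n, p) + 1:
            raise NeurofuseError("n_components must be < min(n_samples, n_features)+1")
        yv = np.where(y == classes[1], 1.0, -1.0)
        if np.std(yv) == 0:
            raise NeurofuseError("zero-variance class vector")
        self.classes_ = classes
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = yv.mean()
        Xc = X - self.x_mean_
        yc = yv - self.y_mean_

        A = self.n_components
        W = np.zeros((p, A))
        T = np.zeros((n, A))
        P = np.zeros((p, A))
        q = np.zeros(A)
        ssy = np.zeros(A)
        Xa, ya = Xc.copy(), yc.copy()
        for a in range(A):
            w = Xa.T @ ya
            norm = np.linalg.norm(w)
            if norm < 1e-15:
                # remaining components carry nothing; truncate
                W, T, P, q, ssy = W[:, :a], T[:, :a], P[:, :a], q[:a], ssy[:a]
                break
            w /= norm
            t = Xa @ w
            tt = t @ t
            pl = Xa.T @ t / tt
            qa = ya @ t / tt
            Xa = Xa - np.outer(t, pl)
            ya = ya - qa * t
            W[:, a], T[:, a], P[:, a], q[a] = w, t, pl, qa
            ssy[a] = qa * qa * tt
        self.x_weights_, self.x_scores_, self.x_loadings_ = W, T, P
        self.y_loadings_ = q
        self.ss_y_ = ssy
        denom = ssy.sum()
        if denom <= 0:
            self.vip_ = np.zeros(p)
        else:
            self.vip_ = np.sqrt(p * (W**2 @ ssy) / denom)
        return self

    def transform(self, X):
        check_is_fitted(self, "x_weights_")
        Xc = np.asarray(X, dtype=float) - self.x_mean_
        # scores via the R = W (P'W)^-1 rotation
        R = self.x_weights_ @ np.linalg.pinv(self.x_loadings_.T @ self.x_weights_)
        return Xc @ R


def pls_da_vip(X, y, n_components: int = 2):
    """Fit :class:`PLSDAVIP`; return (scores, loadings, vip)."""
    m = PLSDAVIP(n_components=n_components).fit(X, y)
    return m.x_scores_, m.x_loadings_, m.vip_


# ---------------------------------------------------------------------------
# differential features


def benjamini_hochberg(pvalues: np.ndarray, alpha: float = 0.05):
    """BH step-up adjusted q-values and the reject flags at ``alpha``."""
    reject, q, _, _ = multipletests(np.asarray(pvalues, float), alpha=alpha, method="fdr_bh")
    return q, reject


@dataclass
class DifferentialCriteria:
    """Thresholds for differential-feature calls.

    fold change >= fc_hi or <= fc_lo, p < p_max, optionally VIP > vip_min and
    BH q < fdr_alpha.  Set ``vip_min``/``fdr_alpha`` to None to disable.
    """

    fc_hi: float = 2.0
    fc_lo: float = 0.5
    p_max: float = 0.05
    vip_min: float | None = 1.0
    fdr_alpha: float | None = 0.05


def differential_filter(
    X: pd.DataFrame,
    groups,
    criteria: DifferentialCriteria | None = None,
    vip: np.ndarray | None = None,
    test: str = "welch",
) -> pd.DataFrame:
    """Differential features between two groups on positive intensity data.

    Fold change is mean(group2)/mean(group1) on the raw scale; p-values are
    two-sided Welch t on log-transformed values (or Wilcoxon rank-sum with
    ``test='wilcoxon'``).  Returns a volcano-ready table (log2fc, p, q, vip,
    passed).
    """
    criteria = criteria or DifferentialCriteria()
    X = pd.DataFrame(X)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if labels.size != 2:
        raise NeurofuseError("differential_filter requires exactly two groups")
    g1, g2 = labels[0], labels[1]
    x1 = X.loc[groups == g1].to_numpy(dtype=float)
    x2 = X.loc[groups == g2].to_numpy(dtype=float)
    if x1.shape[0] < 2 or x2.shape[0] < 2:
        raise NeurofuseError("each group needs at least two samples")
    if (x1 <= 0).any() or (x2 <= 0).any():
        raise NeurofuseError(
            "non-positive values cannot be log-transformed; add a small offset first"
        )
    fc = x2.mean(axis=0) / x1.mean(axis=0)
    if test == "welch":
        _, p = stats.ttest_ind(np.log(x2), np.log(x1), equal_var=False, axis=0)
    elif test == "wilcoxon":
        p = np.array(
            [wilcoxon_rank_sum(x2[:, j], x1[:, j])[1] for j in range(X.shape[1])]
        )
    else:
        raise NeurofuseError(f"unknown test {test!r}")

    if vip is not None and len(vip) != X.shape[1]:
        raise NeurofuseError("vip length must match feature count")
    if vip is None and criteria.vip_min is not None:
        vip = pls_da_vip(X.to_numpy(dtype=float), groups, n_components=2)[2]

    q, _ = benjamini_hochberg(p)
    passed = ((fc >= criteria.fc_hi) | (fc <= criteria.fc_lo)) & (p < criteria.p_max)
    if criteria.vip_min is not None:
        passed &= np.asarray(vip) > criteria.vip_min
    if criteria.fdr_alpha is not None:
        passed &= q < criteria.fdr_alpha
    out = pd.DataFrame(
        {
            "log2fc": np.log2(fc),
            "p": p,
            "q": q,
            "vip": vip if vip is not None else np.nan,
            "passed": passed,
        },
        index=X.columns,
    )
    out.attrs["fc_direction"] = f"{g2}/{g1}"
    return out


# ---------------------------------------------------------------------------
# cohort-level tests


def summary_t_test(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics; returns (t, df, two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise NeurofuseError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise NeurofuseError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise NeurofuseError("zero variance with unequal means: t undefined")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = n1 + n2 - 2.0
    else:  # Welch-Satterthwaite
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum; exact for n <= 10 per group without ties,
    otherwise the tie-corrected normal approximation.  Returns (U, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise NeurofuseError("each group needs n >= 3")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise NeurofuseError("constant series has undefined rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(x, y, covariate) -> tuple[float, float]:
    """Spearman correlation of x and y controlling for a covariate.

    All three series are rank-transformed; x- and y-ranks are residualized on
    the covariate ranks by OLS and the residuals are Pearson-correlated, with
    the usual t-approximation on n-3 degrees of freedom.
    """
    rx = stats.rankdata(x).astype(float)
    ry = stats.rankdata(y).astype(float)
    rz = stats.rankdata(covariate).astype(float)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise NeurofuseError("constant series has undefined rank correlation")
    n = len(rx)
    if n < 4:
        raise NeurofuseError("partial correlation needs n >= 4")

    def _resid(v):
        z = np.column_stack([np.ones(n), rz])
        beta, *_ = np.linalg.lstsq(z, v, rcond=None)
        return v - z @ beta

    ex, ey = _resid(rx), _resid(ry)
    denom = np.sqrt((ex @ ex) * (ey @ ey))
    if denom == 0:
        return 0.0, 1.0
    rho = float(ex @ ey / denom)
    rho = max(-1.0, min(1.0, rho))
    df = n - 3
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1 - rho * rho))
    p = 2 * stats.t.sf(abs(t), df)
    return rho, float(p)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sidedness by the probability-mass rule: sum of hypergeometric
    probabilities of all tables (fixed margins) no more likely than observed.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise NeurofuseError("cells must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise NeurofuseError("degenerate table: a margin is zero")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)
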