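"""Quantitative-trait and case-control association machinery.

OLS and logistic (IRLS) fits with Wald tests, additive single-variant and
conditional two-SNP models, gene-level carrier collapsing with Fisher's exact
test, Pearson chi-square for 2x2 tables, effective-number-of-tests (Meff)
multiple-testing correction by greedy LD pruning, and Kaplan-Meier / log-rank
age-at-onset analysis.

Conventions: genotypes are coded additively (0/1/2 minor alleles); Fisher's
two-sided p-value follows the point-probability rule; the Pearson chi-square
carries no continuity correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "RegressionResult",
    "Contingency2x2",
    "MeffResult",
    "KMResult",
    "CollinearityError",
    "ols_fit",
    "logistic_fit",
    "single_variant_assoc",
    "gene_collapse_assoc",
    "fisher_exact_2x2",
    "chi2_2x2",
    "meff_threshold",
    "bonferroni_threshold",
    "km_logrank",
]


class CollinearityError(ValueError):
    """Raised when a design matrix is rank deficient; names the columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear or constant columns: "
            + ", ".join(self.columns)
        )


@dataclass
class RegressionResult:
    model_type: str  # "linear" | "logistic"
    params: pd.Series
    bse: pd.Series
    wald: pd.Series
    pvalues: pd.Series
    n: int
    converged: bool = True
    separation_flagged: bool = False
    rsquared: float | None = None

    def conf_int(self, z: float = 1.96) -> pd.DataFrame:
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"low": lo, "high": hi})


def _as_design(X, add_intercept: bool) -> pd.DataFrame:
    X = pd.DataFrame(X).copy()
    X = X.astype(float)
    if add_intercept and "const" not in X.columns:
        X.insert(0, "const", 1.0)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    """Identify collinear / redundant columns by incremental rank growth."""
    arr = X.to_numpy(float)
    bad: list[str] = []
    rank = 0
    for j, col in enumerate(X.columns):
        r = np.linalg.matrix_rank(arr[:, : j + 1])
        if r == rank:
            bad.append(str(col))
        rank = r
    if bad:
        raise CollinearityError(bad)


def ols_fit(y, X, add_intercept: bool = True) -> RegressionResult:
    """Ordinary least squares with Wald t-tests.

    Raises :class:`CollinearityError` naming the offending columns on a
    rank-deficient design (including a constant predictor).
    """
    import statsmodels.api as sm

    X = _as_design(X, add_intercept)
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1]:
        raise ValueError("need n > number of design columns")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    return RegressionResult(
        model_type="linear",
        params=res.params,
        bse=res.bse,
        wald=res.tvalues,
        pvalues=pd.Series(res.pvalues, index=res.params.index),
        n=len(y),
        rsquared=float(res.rsquared),
    )


def logistic_fit(y, X, add_intercept: bool = True, tol: float = 1e-8,
                 maxiter: int = 100) -> RegressionResult:
    """Logistic regression by IRLS with Wald z-tests.

    Quasi-/complete separation is detected (diverging coefficients or fitted
    probabilities pinned at 0/1 that perfectly classify) and flagged on the
    result rather than raising or silently diverging.
    """
    import statsmodels.api as sm

    X = _as_design(X, add_intercept)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("logistic outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    _check_rank(X)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            maxiter=maxiter, tol=tol
        )
    fitted = np.asarray(res.fittedvalues)
    eps = 1e-8
    pinned = ((fitted > 1 - eps) & (y == 1)) | ((fitted < eps) & (y == 0))
    separation = bool(
        np.any(np.abs(res.params.to_numpy()) > 15.0) or pinned.any()
    )
    return RegressionResult(
        model_type="logistic",
        params=res.params,
        bse=res.bse,
        wald=res.params / res.bse,
        pvalues=pd.Series(res.pvalues, index=res.params.index),
        n=len(y),
        converged=bool(res.converged),
        separation_flagged=separation,
    )


def single_variant_assoc(
    cohort: pd.DataFrame,
    variant: str,
    phenotype,
    covariates: Sequence[str] | pd.DataFrame = (),
    conditional_snps: Sequence[str] = (),
) -> RegressionResult:
    """Additive single-variant quantitative-trait association.

    ``phenotype`` is either a column name or an array aligned with ``cohort``.
    ``conditional_snps`` adds further genotype columns to the design (the
    conditional two-SNP analysis); a perfectly collinear conditioning SNP
    raises :class:`CollinearityError` rather than fabricating estimates.
    """
    if variant not in cohort.columns:
        raise KeyError(f"variant {variant!r} not in cohort table")
    y = cohort[phenotype] if isinstance(phenotype, str) else phenotype
    X = pd.DataFrame({variant: cohort[variant].astype(float)})
    for snp in conditional_snps:
        X[snp] = cohort[snp].astype(float)
    if isinstance(covariates, pd.DataFrame):
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    else:
        for c in covariates:
            X[c] = pd.to_numeric(cohort[c], errors="raise").to_numpy()
    return ols_fit(np.asarray(y, float), X)


@dataclass(frozen=True)
class Contingency2x2:
    """2x2 count table; rows = exposure +/-, columns = outcome +/-.

    ``a`` exposed/outcome+, ``b`` exposed/outcome-, ``c`` unexposed/outcome+,
    ``d`` unexposed/outcome-. The cross-product odds ratio is ad/bc.
    """

    a: int
    b: int
    c: int
    d: int
    label: str = ""

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) <= 0:
            raise ValueError("table total must be > 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    def __add__(self, other: "Contingency2x2") -> "Contingency2x2":
        return Contingency2x2(self.a + other.a, self.b + other.b,
                              self.c + other.c, self.d + other.d)


def _coerce_table(table) -> Contingency2x2:
    if isinstance(table, Contingency2x2):
        return table
    arr = np.asarray(table, dtype=np.int64).reshape(4)
    return Contingency2x2(*map(int, arr))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (point-probability rule, fixed margins)."""
    t = _coerce_table(table)
    return float(_st.fisher_exact(t.as_array(), alternative="two-sided")[1])


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for a 2x2 table."""
    t = _coerce_table(table)
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: zero margin")
    n = t.total
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(_st.chi2.sf(stat, 1))


def gene_collapse_assoc(
    cohort: pd.DataFrame,
    variants: Sequence[str],
    group,
) -> tuple[Contingency2x2, float]:
    """Gene-collapsed carrier test: carriers of any qualifying allele vs group.

    ``group`` is a boolean array or column name (True = group 1, e.g. CDR>0 or
    low-Abeta cases). Returns the carrier-by-group table (exposure = carrier,
    outcome = group 1) and the two-sided Fisher p.
    """
    variants = list(variants)
    if not variants:
        raise ValueError("empty gene variant set")
    missing = [v for v in variants if v not in cohort.columns]
    if missing:
        raise KeyError(f"variants not in cohort: {missing}")
    grp = cohort[group] if isinstance(group, str) else group
    grp = np.asarray(grp).astype(bool)
    carrier = cohort[variants].to_numpy(float).sum(axis=1) > 0
    table = Contingency2x2(
        int((carrier & grp).sum()),
        int((carrier & ~grp).sum()),
        int((~carrier & grp).sum()),
        int((~carrier & ~grp).sum()),
    )
    return table, fisher_exact_2x2(table)


# ---------------------------------------------------------------------------
# effective number of tests


@dataclass
class MeffResult:
    m: int
    meff: int
    r2_threshold: float
    alpha: float
    threshold: float
    kept: list[int] = field(default_factory=list)
    method: str = "prune"


def bonferroni_threshold(meff: int, alpha: float = 0.05) -> float:
    if meff < 1:
        raise ValueError("meff must be >= 1")
    return alpha / meff


def meff_threshold(genotypes, r2: float = 0.8, alpha: float = 0.05,
                   method: str = "prune") -> MeffResult:
    """Effective number of independent tests for an LD-correlated SNP set.

    ``prune`` (default): greedy pruning in column order — a SNP is dropped
    when its squared correlation with any retained SNP exceeds ``r2``; Meff is
    the retained count. ``eigen``: a simpleM-style spectral count, the number
    of leading eigenvalues of the genotype correlation matrix needed to reach
    99.5% of the total variance (offered as an alternative, with no claim of
    equivalence to the pruning count).
    """
    G = np.asarray(pd.DataFrame(genotypes).to_numpy(float))
    if G.ndim != 2 or G.shape[1] == 0:
        raise ValueError("genotype matrix must be 2-D with >= 1 SNP")
    m = G.shape[1]
    sd = G.std(axis=0)

    if method == "prune":
        kept: list[int] = []
        for j in range(m):
            drop = False
            if sd[j] > 0:
                for k in kept:
                    if sd[k] == 0:
                        continue
                    r = np.corrcoef(G[:, j], G[:, k])[0, 1]
                    if r * r > r2:
                        drop = True
                        break
            if not drop:
                kept.append(j)
        meff = len(kept)
    elif method == "eigen":
        keep = sd > 0
        if keep.sum() == 0:
            meff, kept = 1, []
        else:
            corr = np.corrcoef(G[:, keep].T)
            corr = np.atleast_2d(corr)
            eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
            cum = np.cumsum(eig) / eig.sum()
            meff = int(np.searchsorted(cum, 0.995) + 1)
            kept = []
    else:
        raise ValueError(f"unknown method {method!r}")
    meff = max(1, min(meff, m))
    return MeffResult(m, meff, r2, alpha, bonferroni_threshold(meff, alpha),
                      list(kept), method)


# ---------------------------------------------------------------------------
# survival


@dataclass
class KMResult:
    curves: dict  # group -> DataFrame(time, survival)
    statistic: float
    pvalue: float
    df: int


def km_logrank(time, event, group) -> KMResult:
    """Kaplan-Meier curves per group and the log-rank test across groups."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    group = np.asarray(group)
    if np.any(time <= 0):
        raise ValueError("event/censoring times must be > 0")
    labels = pd.unique(group)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups for a log-rank test")
    for lab in labels:
        if not event[group == lab].any():
            raise ValueError(f"group {lab!r} has no events")

    curves = {}
    for lab in labels:
        sel = group == lab
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event_observed=event[sel], label=str(lab))
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = multivariate_logrank_test(time, group, event)
    return KMResult(curves, float(res.test_statistic), float(res.p_value),
                    df=len(labels) - 1)
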