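"""CSF biomarker preparation: cross-platform normalisation, covariate
residualisation, extreme-tail pool selection, ratio phenotypes and
amyloid-deposition dichotomisation.

Raw Abeta42/tau/ptau concentrations (pg/mL) are natural-log transformed and
mean-centered within platform (centering only — the variance is deliberately
not rescaled), residualized on covariates by OLS, and the residual tails
define the sequencing pools. Deposition status is raw Abeta42 strictly below
a platform-specific cutoff (500 pg/mL plate ELISA, 192 pg/mL bead assay).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import RegressionResult, ols_fit

__all__ = [
    "DEFAULT_CUTOFFS",
    "log_standardize",
    "residualize",
    "select_extremes",
    "compute_ratios",
    "dichotomize_deposition",
    "covariate_design",
    "prepare_phenotypes",
]

DEFAULT_CUTOFFS: Mapping[str, float] = {"A": 500.0, "B": 192.0}

PHENOTYPES = ("abeta42", "tau", "ptau", "tau_abeta_ratio", "ptau_abeta_ratio")


def log_standardize(values, platforms) -> np.ndarray:
    """Natural-log transform and center to mean zero within each platform.

    Centering only: platforms measured on ~10-fold different scales become
    comparable in location while per-platform variance is preserved.
    """
    values = np.asarray(values, dtype=float)
    platforms = np.asarray(platforms)
    if values.shape != platforms.shape:
        raise ValueError("values and platform labels must align")
    if np.any(values <= 0):
        raise ValueError("biomarker values must be strictly positive")
    out = np.log(values)
    for lab in pd.unique(platforms):
        sel = platforms == lab
        if sel.sum() < 2:
            raise ValueError(f"platform {lab!r} has fewer than 2 subjects")
        out[sel] -= out[sel].mean()
    return out


def covariate_design(cohort: pd.DataFrame,
                     covariates: Sequence[str] = ("age", "sex", "cdr", "site"),
                     ) -> pd.DataFrame:
    """Numeric design columns for the standard covariates.

    sex -> female indicator; site -> platform-B indicator; CDR enters as a
    numeric ordinal; anything else is taken as already numeric.
    """
    cols = {}
    for c in covariates:
        if c == "sex":
            cols["female"] = (cohort["sex"].astype(str) == "F").astype(float)
        elif c == "site":
            cols["site_b"] = (cohort["site"].astype(str) == "B").astype(float)
        else:
            cols[c] = pd.to_numeric(cohort[c], errors="raise").astype(float)
    return pd.DataFrame(cols).reset_index(drop=True)


def residualize(y, design: pd.DataFrame) -> tuple[np.ndarray, RegressionResult]:
    """OLS residuals of ``y`` on the covariate design (intercept added).

    Residuals are orthogonal to every design column; a rank-deficient design
    raises an error naming the collinear columns.
    """
    fit = ols_fit(y, design)
    X = design.to_numpy(float)
    yhat = fit.params["const"] + X @ fit.params.drop("const").to_numpy()
    return np.asarray(y, float) - yhat, fit


def compute_ratios(tau, ptau, abeta42) -> tuple[np.ndarray, np.ndarray]:
    """Raw tau:Abeta42 and ptau:Abeta42 ratios (elementwise).

    Ratios are formed on raw values and then log-transformed / centered like
    the primary phenotypes.
    """
    tau = np.asarray(tau, float)
    ptau = np.asarray(ptau, float)
    abeta42 = np.asarray(abeta42, float)
    if np.any(abeta42 <= 0):
        raise ValueError("Abeta42 must be strictly positive")
    return tau / abeta42, ptau / abeta42


def _tail_ids(values: np.ndarray, subject_ids: np.ndarray, k: int,
              tail: str) -> set:
    """Exactly-k tail membership with a deterministic tie rule:
    rank by value, then by subject id (stable)."""
    order = np.lexsort((subject_ids, values))
    chosen = order[:k] if tail == "low" else order[-k:]
    return set(subject_ids[chosen])


def select_extremes(residuals: pd.DataFrame, fraction: float = 0.15,
                    ) -> pd.DataFrame:
    """Assign subjects to extreme-phenotype sequencing pools.

    ``residuals`` is indexed by subject id with columns ``abeta42``, ``tau``,
    ``ptau`` (covariate-adjusted values). The AD-like pool is the union of the
    bottom-``fraction`` Abeta42 tail and the top tails of tau and ptau; the
    opposite pool is the union of the reversed tails. A subject qualifying for
    both pools is flagged ``conflicted`` and assigned to neither. Each tail
    holds exactly ceil(fraction * n) subjects.
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("tail fraction must be in (0, 0.5)")
    for col in ("abeta42", "tau", "ptau"):
        if col not in residuals.columns:
            raise KeyError(f"residuals must contain column {col!r}")
    n = len(residuals)
    k = math.ceil(fraction * n)
    if k < 1 or 2 * k > n:
        raise ValueError("cohort too small for non-overlapping tails")
    ids = residuals.index.to_numpy()

    tails = {}
    for col in ("abeta42", "tau", "ptau"):
        v = residuals[col].to_numpy(float)
        tails[(col, "low")] = _tail_ids(v, ids, k, "low")
        tails[(col, "high")] = _tail_ids(v, ids, k, "high")

    ad_like = tails[("abeta42", "low")] | tails[("tau", "high")] | tails[("ptau", "high")]
    opposite = tails[("abeta42", "high")] | tails[("tau", "low")] | tails[("ptau", "low")]
    conflicted = ad_like & opposite

    out = pd.DataFrame(index=residuals.index)
    for col in ("abeta42", "tau", "ptau"):
        lab = np.full(n, "none", dtype=object)
        lab[np.isin(ids, list(tails[(col, "low")]))] = "low"
        lab[np.isin(ids, list(tails[(col, "high")]))] = "high"
        out[f"{col}_tail"] = lab
    pool = np.full(n, "none", dtype=object)
    pool[np.isin(ids, list(ad_like - conflicted))] = "pool_AD_like"
    pool[np.isin(ids, list(opposite - conflicted))] = "pool_opposite"
    out["pool"] = pool
    out["conflicted"] = np.isin(ids, list(conflicted))
    return out


def dichotomize_deposition(abeta42_raw, platforms,
                           cutoffs: Mapping[str, float] | None = None,
                           ) -> pd.DataFrame:
    """Amyloid-deposition status: raw Abeta42 strictly below the platform cutoff.

    A value exactly at the cutoff counts as no deposition.
    """
    cutoffs = dict(DEFAULT_CUTOFFS if cutoffs is None else cutoffs)
    abeta42_raw = np.asarray(abeta42_raw, float)
    platforms = np.asarray(platforms)
    unknown = sorted(set(platforms) - set(cutoffs))
    if unknown:
        raise KeyError(f"no deposition cutoff configured for platform(s) {unknown}")
    cut = np.array([cutoffs[p] for p in platforms])
    status = np.where(abeta42_raw < cut, "deposition", "no_deposition")
    return pd.DataFrame({"platform": platforms, "cutoff": cut, "status": status})


def prepare_phenotypes(cohort: pd.DataFrame,
                       covariates: Sequence[str] = ("age", "sex", "cdr", "site"),
                       ) -> pd.DataFrame:
    """Standardize, residualize and extend with ratio phenotypes.

    Returns a frame indexed by subject id with one column per phenotype in
    ``PHENOTYPES`` holding the covariate-adjusted residual of the
    platform-centered log value.
    """
    platforms = cohort["site"].to_numpy()
    design = covariate_design(cohort, covariates)
    raw = {
        "abeta42": cohort["abeta42_raw"].to_numpy(float),
        "tau": cohort["tau_raw"].to_numpy(float),
        "ptau": cohort["ptau_raw"].to_numpy(float),
    }
    raw["tau_abeta_ratio"], raw["ptau_abeta_ratio"] = compute_ratios(
        raw["tau"], raw["ptau"], raw["abeta42"]
    )
    out = {}
    for name, values in raw.items():
        std = log_standardize(values, platforms)
        out[name], _ = residualize(std, design)
    return pd.DataFrame(out, index=pd.Index(cohort["subject_id"], name="subject_id"))
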