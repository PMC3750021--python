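"""Stratified odds ratios and SNP-by-SNP interaction analysis.

Per-stratum cross-product odds ratios with Woolf (log-scale Wald, z = 1.96)
confidence intervals, Fisher and chi-square p-values, pooled-count joint
analyses, APOE-e4 dose strata, and the subject-level table builder for
amyloid-deposition risk stratified by variant carriage.

Orientation convention (fixed throughout): rows are exposure +/-, columns are
outcome +/-, cell a = exposed with outcome, so OR = ad/bc. The bundled
reference count tables record their own exposure/outcome mapping per row.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _st

from .stats import Contingency2x2, chi2_2x2, fisher_exact_2x2

__all__ = [
    "ORResult",
    "StratifiedAnalysis",
    "woolf_or_ci",
    "stratified_or",
    "joint_counts",
    "apoe_dose_strata",
    "deposition_risk_table",
    "load_reference_tables",
    "reference_table_report",
]

Z_95 = 1.96  # matches the convention behind the reproducible printed intervals


@dataclass
class ORResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    log_or_se: float
    p_fisher: float
    p_chi2: float | None
    degenerate: bool
    table: Contingency2x2 | None
    label: str = ""


def woolf_or_ci(table, z: float = Z_95, label: str = "") -> ORResult:
    """Cross-product odds ratio with the Woolf confidence interval.

    OR = ad/bc; SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d);
    CI = exp(log OR +/- z * SE). No continuity correction: a zero cell yields
    a degenerate OR (0 or inf) with an undefined CI and a flag, never a silent
    Haldane-style adjustment.
    """
    t = table if isinstance(table, Contingency2x2) else Contingency2x2(*np.ravel(table))
    a, b, c, d = t.a, t.b, t.c, t.d
    p_fisher = fisher_exact_2x2(t)
    try:
        _, p_chi2 = chi2_2x2(t)
    except ValueError:
        p_chi2 = None
    if min(a, b, c, d) == 0:
        if a * d == 0 and b * c == 0:
            orr = math.nan
        elif a * d == 0:
            orr = 0.0
        else:
            orr = math.inf
        return ORResult(orr, math.nan, math.nan, math.nan, p_fisher, p_chi2,
                        degenerate=True, table=t, label=label)
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ORResult(orr, orr * math.exp(-z * se), orr * math.exp(z * se), se,
                    p_fisher, p_chi2, degenerate=False, table=t, label=label)


@dataclass
class StratifiedAnalysis:
    strata: dict  # label -> ORResult (insertion order; first = reference)
    reference: str
    interaction_log_or: float | None
    interaction_se: float | None
    interaction_p: float | None
    degenerate: bool = False
    #: per-stratum interaction terms vs the reference when > 2 strata
    interactions: dict = field(default_factory=dict)

    @property
    def or_ratio(self) -> float | None:
        return (math.exp(self.interaction_log_or)
                if self.interaction_log_or is not None else None)


def stratified_or(tables: Mapping[str, "Contingency2x2"]) -> StratifiedAnalysis:
    """Per-stratum odds ratios and the Wald interaction (log-OR ratio) test.

    The interaction estimate between a stratum and the (first) reference
    stratum is ln(OR_stratum / OR_ref) with SE = sqrt(SE_ref^2 + SE_stratum^2)
    and a two-sided normal p-value; it equals the product-term coefficient of
    the saturated logistic model. A degenerate stratum (zero cell) suppresses
    the interaction estimate and flags the analysis.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 strata")
    strata = {lab: woolf_or_ci(t, label=lab) for lab, t in tables.items()}
    labels = list(strata)
    ref = labels[0]
    degenerate = any(r.degenerate for r in strata.values())

    interactions = {}
    for lab in labels[1:]:
        r0, r1 = strata[ref], strata[lab]
        if r0.degenerate or r1.degenerate:
            interactions[lab] = (None, None, None)
            continue
        est = math.log(r1.oddsratio / r0.oddsratio)
        se = math.sqrt(r0.log_or_se ** 2 + r1.log_or_se ** 2)
        p = 2.0 * _st.norm.sf(abs(est) / se)
        interactions[lab] = (est, se, float(p))
    first = interactions[labels[1]]
    return StratifiedAnalysis(strata, ref, first[0], first[1], first[2],
                              degenerate=degenerate, interactions=interactions)


def joint_counts(tables: Iterable) -> tuple[Contingency2x2, ORResult]:
    """Pooled-count joint analysis: elementwise sum, then the Woolf OR."""
    tables = [t if isinstance(t, Contingency2x2) else Contingency2x2(*np.ravel(t))
              for t in tables]
    if not tables:
        raise ValueError("no tables to pool")
    pooled = tables[0]
    for t in tables[1:]:
        pooled = pooled + t
    return pooled, woolf_or_ci(pooled, label="joint")


def apoe_dose_strata(counts: pd.DataFrame) -> dict[str, dict[int, ORResult]]:
    """APOE-e4 dose analysis: OR of dose 1 and dose 2 vs dose 0 per stratum.

    ``counts`` needs columns stratum, dose (0/1/2), cases, controls. Within
    each stratum, dose 0 is the reference; exposure = the given dose, outcome
    = case. Empty dose cells yield degenerate, flagged ORs.
    """
    required = {"stratum", "dose", "cases", "controls"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts must have columns {sorted(required)}")
    out: dict[str, dict[int, ORResult]] = {}
    for stratum, grp in counts.groupby("stratum", sort=False):
        by_dose = {int(r.dose): (int(r.cases), int(r.controls))
                   for r in grp.itertuples()}
        if 0 not in by_dose:
            raise ValueError(f"stratum {stratum!r} lacks a dose-0 reference row")
        ref_cases, ref_controls = by_dose[0]
        out[stratum] = {}
        for dose in sorted(d for d in by_dose if d != 0):
            cases, controls = by_dose[dose]
            table = Contingency2x2(cases, controls, ref_cases, ref_controls,
                                   label=f"{stratum}:dose{dose}")
            out[stratum][dose] = woolf_or_ci(table, label=f"{stratum}:dose{dose}")
    return out


def deposition_risk_table(cohort: pd.DataFrame, variant: str,
                          cutoffs: Mapping[str, float] | None = None,
                          ) -> StratifiedAnalysis:
    """Amyloid-deposition risk by APOE-e4 carriage, stratified on the variant.

    Builds the 2x2 tables (exposure = APOE-e4 carriage, outcome = deposition,
    i.e. raw Abeta42 below the platform cutoff) within variant non-carriers
    (reference stratum) and carriers, then delegates to :func:`stratified_or`.
    """
    from .phenotypes import dichotomize_deposition

    if variant not in cohort.columns:
        raise KeyError(f"variant {variant!r} not in cohort")
    dep = dichotomize_deposition(cohort["abeta42_raw"], cohort["site"],
                                 cutoffs)["status"].to_numpy() == "deposition"
    e4 = cohort["apoe4_dose"].to_numpy() > 0
    carrier = cohort[variant].to_numpy() > 0

    def _table(sel: np.ndarray, label: str) -> Contingency2x2 | None:
        if not sel.any():
            return None
        return Contingency2x2(
            int((sel & e4 & dep).sum()),
            int((sel & e4 & ~dep).sum()),
            int((sel & ~e4 & dep).sum()),
            int((sel & ~e4 & ~dep).sum()),
            label=label,
        )

    tables = {
        "non_carrier": _table(~carrier, "non_carrier"),
        "carrier": _table(carrier, "carrier"),
    }
    if any(t is None for t in tables.values()):
        # an empty stratum: per-stratum results where possible, no interaction
        strata = {
            lab: (woolf_or_ci(t, label=lab) if t is not None else
                  ORResult(math.nan, math.nan, math.nan, math.nan, 1.0, None,
                           degenerate=True, table=None, label=lab))
            for lab, t in tables.items()
        }
        return StratifiedAnalysis(strata, "non_carrier", None, None, None,
                                  degenerate=True,
                                  interactions={"carrier": (None, None, None)})
    return stratified_or(tables)


# ---------------------------------------------------------------------------
# bundled reference count tables


def load_reference_tables() -> pd.DataFrame:
    """Published stratified count tables for the E318G x APOE-e4 risk model.

    Each row is one 2x2 table with its exposure/outcome mapping, the printed
    OR/CI/p it accompanied, and flags recording which printed values reproduce
    exactly (at 1-decimal precision) from the counts by the cross-product /
    Woolf formulas. Covariate-adjusted printed ORs do not reproduce from raw
    counts and carry zero flags.
    """
    ref = importlib.resources.files("csfpool").joinpath("data/stratified_counts.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise RuntimeError("bundled reference count tables are missing or empty")
    return df


def reference_table_report(tables: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute OR/CI/Fisher-p for every reference table and diff vs printed.

    Computed values are compared at the printed precision (1 decimal for ORs
    and CI bounds) wherever the row's reproducibility flag is set; mismatches
    are reported in the ``or_ok`` / ``low_ok`` / ``high_ok`` columns.
    """
    df = load_reference_tables() if tables is None else tables
    if df.empty:
        raise ValueError("empty reference table set")
    rows = []
    for row in df.to_dict("records"):
        res = woolf_or_ci(Contingency2x2(row["a"], row["b"], row["c"], row["d"]))
        rec = dict(row)
        rec.update(
            computed_or=round(res.oddsratio, 1),
            computed_low=round(res.ci_low, 1),
            computed_high=round(res.ci_high, 1),
            computed_fisher_p=res.p_fisher,
            or_ok=not row["or_match"] or round(res.oddsratio, 1) == row["printed_or"],
            low_ok=not row["low_match"] or round(res.ci_low, 1) == row["printed_low"],
            high_ok=not row["high_match"] or round(res.ci_high, 1) == row["printed_high"],
        )
        rows.append(rec)
    return pd.DataFrame(rows)
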