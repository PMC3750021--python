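"""Rare-variant calling from pooled amplicon reads.

The caller follows the control-calibrated contract of pooled-DNA base
calling: a per-read-cycle substitution error model is fit on a variant-free
negative-control amplicon; every site receives an exact one-sided binomial
tail p-value for its strongest alternate base against the cycle-weighted
error rate; the detection threshold is the least stringent p-value that
recovers every engineered positive-control spike (sensitivity 100% by
construction), and specificity is read off the negative control. Follow-up
filtering keeps missense/nonsense/splice calls with estimated pool MAF below
5% and at least 30-fold per-allele coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .synthetic import (
    Amplicon,
    PanelConfig,
    ReadSet,
    build_amplicon_panel,
    default_error_profile,
    simulate_pool_reads,
    _BASES,
)

__all__ = [
    "PlacedReads",
    "ErrorModel",
    "PoolVariantCall",
    "Calibration",
    "CalibrationError",
    "place_reads",
    "tally_site_counts",
    "fit_error_model",
    "score_site",
    "score_sites",
    "calibrate_threshold",
    "call_and_filter",
    "write_vcf",
    "read_vcf",
    "calibration_run",
]

FOLLOWUP_CONSEQUENCES = ("missense", "nonsense", "splice")
MIN_PER_ALLELE_COVERAGE = 30.0


class CalibrationError(RuntimeError):
    pass


@dataclass
class PlacedReads:
    amplicon_ids: tuple[str, ...]
    amplicon_index: np.ndarray
    starts: np.ndarray
    seqs: np.ndarray
    read_length: int
    n_input: int
    n_discarded: int


def place_reads(readset: ReadSet, panel: list[Amplicon],
                max_mismatches: int = 2) -> PlacedReads:
    """Verify read placements against the panel and discard poor matches.

    Reads carry their source amplicon and offset (from the simulator or from
    FASTQ read names); each is checked as an ungapped match at that offset and
    discarded when it exceeds ``max_mismatches`` mismatches.
    """
    by_id = {a.amplicon_id: a for a in panel}
    keep = np.zeros(readset.n_reads, dtype=bool)
    L = readset.read_length
    panel_ids = tuple(a.amplicon_id for a in panel)
    remap = np.full(len(readset.amplicon_ids), -1, dtype=np.int32)
    for i, amp_id in enumerate(readset.amplicon_ids):
        if amp_id in by_id:
            remap[i] = panel_ids.index(amp_id)

    new_index = np.full(readset.n_reads, -1, dtype=np.int32)
    for i, amp_id in enumerate(readset.amplicon_ids):
        sel = np.nonzero(readset.amplicon_index == i)[0]
        if sel.size == 0:
            continue
        amp = by_id.get(amp_id)
        if amp is None or remap[i] < 0:
            continue
        if L > len(amp):
            raise ValueError(
                f"reads of length {L} exceed amplicon {amp_id} ({len(amp)} bp)"
            )
        ref = amp.codes
        starts = readset.starts[sel]
        in_bounds = (starts >= 0) & (starts + L <= len(amp))
        ok = np.zeros(sel.size, dtype=bool)
        ib = np.nonzero(in_bounds)[0]
        if ib.size:
            windows = ref[starts[ib, None] + np.arange(L)]
            mism = (windows != readset.seqs[sel[ib]]).sum(axis=1)
            ok[ib] = mism <= max_mismatches
        keep[sel[ok]] = True
        new_index[sel] = remap[i]

    kept = np.nonzero(keep)[0]
    return PlacedReads(
        amplicon_ids=panel_ids,
        amplicon_index=new_index[kept],
        starts=readset.starts[kept],
        seqs=readset.seqs[kept],
        read_length=L,
        n_input=readset.n_reads,
        n_discarded=int(readset.n_reads - kept.size),
    )


@dataclass
class SiteCounts:
    """Per-site, per-base, per-cycle read-base tallies for one amplicon."""

    amplicon_id: str
    ref_codes: np.ndarray  # (n_sites,)
    counts: np.ndarray  # (n_sites, 4, read_length) int64

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    def depth_by_cycle(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def tally_site_counts(placed: PlacedReads, panel: list[Amplicon],
                      ) -> dict[str, SiteCounts]:
    L = placed.read_length
    cycles = np.arange(L)
    out: dict[str, SiteCounts] = {}
    for ai, amp in enumerate(panel):
        sel = np.nonzero(placed.amplicon_index == ai)[0]
        counts = np.zeros((len(amp), 4, L), dtype=np.int64)
        if sel.size:
            sites = (placed.starts[sel, None] + cycles).ravel()
            bases = placed.seqs[sel].ravel()
            cyc = np.broadcast_to(cycles, (sel.size, L)).ravel()
            np.add.at(counts, (sites, bases, cyc), 1)
        out[amp.amplicon_id] = SiteCounts(amp.amplicon_id, amp.codes, counts)
    return out


@dataclass
class ErrorModel:
    """Per-cycle substitution rates estimated from the negative control.

    Rates use a Jeffreys-style floor, (mismatches + 0.5) / (bases + 1), so a
    perfectly clean control still yields a small non-zero rate.
    """

    rates: np.ndarray  # (read_length,)
    total_bases: np.ndarray  # (read_length,)
    train_prefix: int


def fit_error_model(placed: PlacedReads, panel: list[Amplicon],
                    train_prefix: int = 900) -> ErrorModel:
    """Fit per-cycle error rates from negative-control alignments.

    Only bases landing in the first ``train_prefix`` positions of the
    negative-control amplicon train the model.
    """
    negatives = [a for a in panel if a.control_role == "negative"]
    if not negatives:
        raise CalibrationError("panel has no negative-control amplicon")
    neg = negatives[0]
    ai = [a.amplicon_id for a in panel].index(neg.amplicon_id)
    sel = np.nonzero(placed.amplicon_index == ai)[0]
    if sel.size == 0:
        raise CalibrationError("no negative-control reads: cannot fit error model")
    L = placed.read_length
    ref = neg.codes
    positions = placed.starts[sel, None] + np.arange(L)
    in_prefix = positions < train_prefix
    mismatch = placed.seqs[sel] != ref[positions]
    total = in_prefix.sum(axis=0).astype(float)
    mm = (mismatch & in_prefix).sum(axis=0).astype(float)
    rates = (mm + 0.5) / (total + 1.0)
    return ErrorModel(rates=rates, total_bases=total, train_prefix=train_prefix)


@dataclass
class PoolVariantCall:
    amplicon_id: str
    site: int
    ref: str
    alt: str
    k: int
    n: int
    error_rate: float
    pvalue: float
    maf_estimate: float
    per_allele_coverage: float
    low_coverage: bool
    consequence: str = "intronic"


def _site_stats(counts: SiteCounts, model: ErrorModel, pool_chromosomes: int):
    """Vectorised per-site evidence: top alternate base, exact binomial tail."""
    depth_by_cycle = counts.depth_by_cycle()  # (sites, L)
    depth = depth_by_cycle.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_any = depth_by_cycle @ model.rates / np.where(depth > 0, depth, 1)
    e = e_any / 3.0  # any-mismatch rate -> one specific alternate base

    per_base = counts.counts.sum(axis=2)  # (sites, 4)
    alt_counts = per_base.copy()
    alt_counts[np.arange(len(alt_counts)), counts.ref_codes] = -1
    alt_code = alt_counts.argmax(axis=1)
    k = per_base[np.arange(len(per_base)), alt_code]
    k = np.where(depth > 0, k, 0)

    p = np.ones(len(depth))
    nz = depth > 0
    p[nz] = _st.binom.sf(k[nz] - 1, depth[nz], e[nz])
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    maf = np.round(k / np.where(depth > 0, depth, 1) * pool_chromosomes) / pool_chromosomes
    pac = depth / pool_chromosomes
    return alt_code, k, depth, e, p, maf, pac


def score_sites(counts: SiteCounts, model: ErrorModel, pool_chromosomes: int,
                amplicon: Amplicon | None = None) -> pd.DataFrame:
    """Score every covered site of one amplicon; returns a call table.

    p-value is the exact binomial upper tail P(X >= k | n, e) with e the
    coverage-weighted per-cycle error rate divided by 3 (specific alternate
    base). The pool MAF estimate is k/n rounded to the nearest multiple of
    1/(2N); sites with per-allele coverage below 30 are flagged.
    """
    if pool_chromosomes < 2:
        raise ValueError("pool must contain at least one subject (2N >= 2)")
    alt_code, k, depth, e, p, maf, pac = _site_stats(counts, model, pool_chromosomes)
    covered = depth > 0
    sites = np.nonzero(covered)[0]
    csq = np.full(len(depth), "intronic", dtype=object)
    if amplicon is not None:
        for pos, sp in amplicon.variant_sites.items():
            csq[pos] = sp.consequence
    return pd.DataFrame(
        {
            "amplicon_id": counts.amplicon_id,
            "site": sites,
            "ref": [_BASES[c] for c in counts.ref_codes[sites]],
            "alt": [_BASES[c] for c in alt_code[sites]],
            "k": k[sites],
            "n": depth[sites],
            "error_rate": e[sites],
            "pvalue": p[sites],
            "maf_estimate": maf[sites],
            "per_allele_coverage": pac[sites],
            "low_coverage": pac[sites] < MIN_PER_ALLELE_COVERAGE,
            "consequence": csq[sites],
        }
    )


def per_alt_pvalues(counts: SiteCounts, model: ErrorModel) -> np.ndarray:
    """Exact binomial tail for every (site, alternate base) pair.

    Returns an (n_sites, 4) array of upper-tail p-values with NaN in the
    reference-base column and at uncovered sites. Each alternate base is a
    pre-specified hypothesis, so these tails are individually superuniform
    under the error-model null; the per-site call (strongest alternate)
    selects the minimum of three, which the control calibration absorbs.
    """
    depth_by_cycle = counts.depth_by_cycle()
    depth = depth_by_cycle.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_any = depth_by_cycle @ model.rates / np.where(depth > 0, depth, 1)
    e = e_any / 3.0
    per_base = counts.counts.sum(axis=2)
    p = np.ones((len(depth), 4))
    nz = depth > 0
    p[nz] = _st.binom.sf(per_base[nz] - 1, depth[nz, None], e[nz, None])
    p[~nz] = np.nan
    p[np.arange(len(depth)), counts.ref_codes] = np.nan
    return p


def score_site(counts_by_base_cycle, ref: str, model: ErrorModel,
               pool_chromosomes: int, amplicon_id: str = "amp",
               site: int = 0) -> PoolVariantCall:
    """Score a single site from its (4, read_length) base-by-cycle counts."""
    arr = np.asarray(counts_by_base_cycle, dtype=np.int64)
    if arr.shape != (4, len(model.rates)):
        raise ValueError("counts must be (4, read_length)")
    n = int(arr.sum())
    if n <= 0:
        raise ValueError("site depth must be > 0")
    ref_code = _BASES.index(ref)
    sc = SiteCounts(amplicon_id, np.array([ref_code], np.uint8), arr[None])
    alt_code, k, depth, e, p, maf, pac = _site_stats(sc, model, pool_chromosomes)
    if int(k[0]) > n:
        raise ValueError("alt count exceeds depth")
    return PoolVariantCall(
        amplicon_id, site, ref, _BASES[alt_code[0]], int(k[0]), int(depth[0]),
        float(e[0]), float(p[0]), float(maf[0]), float(pac[0]),
        bool(pac[0] < MIN_PER_ALLELE_COVERAGE),
    )


def score_panel(counts: dict[str, SiteCounts], model: ErrorModel,
                pool_chromosomes: int, panel: list[Amplicon]) -> pd.DataFrame:
    by_id = {a.amplicon_id: a for a in panel}
    frames = [
        score_sites(sc, model, pool_chromosomes, by_id.get(amp_id))
        for amp_id, sc in counts.items()
    ]
    return pd.concat(frames, ignore_index=True)


@dataclass
class Calibration:
    threshold: float
    sensitivity: float
    specificity: float
    n_positive_sites: int
    n_negative_flagged: int
    negative_length: int
    positive_pvalues: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_positive_sites": self.n_positive_sites,
            "n_negative_flagged": self.n_negative_flagged,
            "negative_length": self.negative_length,
        }


def calibrate_threshold(calls: pd.DataFrame, truth: pd.DataFrame,
                        panel: list[Amplicon]) -> Calibration:
    """Set the p-value cutoff from the engineered positive-control spikes.

    The threshold is the largest (least stringent) p-value observed at a
    positive-control truth site, so every spike is recovered (p <= threshold
    is inclusive and sensitivity is 100% by construction). Specificity is
    1 - (flagged sites / length) on the variant-free negative control.
    """
    pos_ids = {a.amplicon_id for a in panel if a.control_role == "positive"}
    negatives = [a for a in panel if a.control_role == "negative"]
    if not pos_ids:
        raise CalibrationError("no positive-control amplicon in panel")
    if not negatives:
        raise CalibrationError("no negative-control amplicon in panel")
    neg = negatives[0]

    pos_truth = truth[truth["amplicon_id"].isin(pos_ids)]
    if pos_truth.empty:
        raise CalibrationError("no positive-control truth sites")
    merged = pos_truth.merge(calls, on=["amplicon_id", "site"], how="left",
                             suffixes=("_truth", ""))
    if merged["pvalue"].isna().any():
        raise CalibrationError("positive-control site missing from call table")
    pvals = merged["pvalue"].to_numpy(float)
    threshold = float(pvals.max())
    sensitivity = float((pvals <= threshold).mean())

    neg_calls = calls[calls["amplicon_id"] == neg.amplicon_id]
    flagged = int((neg_calls["pvalue"].to_numpy(float) <= threshold).sum())
    specificity = 1.0 - flagged / len(neg)
    return Calibration(threshold, sensitivity, specificity, len(pos_truth),
                       flagged, len(neg), sorted(map(float, pvals)))


def call_and_filter(calls: pd.DataFrame, panel: list[Amplicon],
                    threshold: float, maf_cutoff: float = 0.05,
                    min_per_allele: float = MIN_PER_ALLELE_COVERAGE,
                    consequences: tuple[str, ...] = FOLLOWUP_CONSEQUENCES,
                    ) -> pd.DataFrame:
    """Apply the calibrated threshold and the follow-up filters.

    A call passes when p <= threshold, per-allele coverage >= 30, its
    consequence is missense/nonsense/splice, and the estimated pool MAF is
    below ``maf_cutoff``. Control amplicons never pass to follow-up.
    """
    control_ids = {a.amplicon_id for a in panel if a.control_role != "none"}
    out = calls.copy()
    out["significant"] = out["pvalue"] <= threshold
    out["pass"] = (
        out["significant"]
        & (out["per_allele_coverage"] >= min_per_allele)
        & out["consequence"].isin(consequences)
        & (out["maf_estimate"] < maf_cutoff)
        & (out["maf_estimate"] > 0)
        & ~out["amplicon_id"].isin(control_ids)
    )
    return out


# ---------------------------------------------------------------------------
# VCF output (1-based positions; amplicons as contigs)

_VCF_INFO = (
    '##INFO=<ID=K,Number=1,Type=Integer,Description="Alternate allele read count">\n'
    '##INFO=<ID=N,Number=1,Type=Integer,Description="Site read depth">\n'
    '##INFO=<ID=E,Number=1,Type=Float,Description="Expected per-base error rate">\n'
    '##INFO=<ID=P,Number=1,Type=Float,Description="Exact binomial tail p-value">\n'
    '##INFO=<ID=MAF,Number=1,Type=Float,Description="Estimated pool minor allele frequency">\n'
    '##INFO=<ID=PAC,Number=1,Type=Float,Description="Per-allele coverage">\n'
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence annotation">\n'
)


def write_vcf(calls: pd.DataFrame, panel: list[Amplicon], path,
              only_pass: bool = False) -> None:
    rows = calls[calls["pass"]] if only_pass and "pass" in calls else calls
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=csfpool\n")
        for amp in panel:
            fh.write(f"##contig=<ID={amp.amplicon_id},length={len(amp)}>\n")
        fh.write(_VCF_INFO)
        fh.write('##FILTER=<ID=fail,Description="Did not pass follow-up filters">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in rows.to_dict("records"):
            filt = "PASS" if row.get("pass", True) else "fail"
            info = (
                f"K={row['k']};N={row['n']};E={row['error_rate']:.10g};"
                f"P={row['pvalue']:.10g};MAF={row['maf_estimate']:.10g};"
                f"PAC={row['per_allele_coverage']:.10g};CSQ={row['consequence']}"
            )
            fh.write(
                f"{row['amplicon_id']}\t{row['site'] + 1}\t.\t{row['ref']}"
                f"\t{row['alt']}\t.\t{filt}\t{info}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Read a call VCF back into the call-table layout (0-based sites)."""
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        rows.append(
            {
                "amplicon_id": rec.CHROM,
                "site": rec.POS - 1,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
                "k": int(rec.INFO["K"]),
                "n": int(rec.INFO["N"]),
                "error_rate": float(rec.INFO["E"]),
                "pvalue": float(rec.INFO["P"]),
                "maf_estimate": float(rec.INFO["MAF"]),
                "per_allele_coverage": float(rec.INFO["PAC"]),
                "consequence": str(rec.INFO["CSQ"]),
                "pass": rec.FILTER is None,  # cyvcf2 reports PASS as None
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end calibration experiment on control amplicons


def calibration_run(seed: int, pool_size: int = 114,
                    depth_per_allele: float = 30.0,
                    error_profile: np.ndarray | None = None,
                    n_positive_sites: int = 10,
                    positive_frequency: float = 1.0 / 250.0,
                    positive_length: int = 500,
                    negative_length: int = 1908,
                    read_length: int = 36,
                    train_prefix: int = 900,
                    max_mismatches: int = 3) -> Calibration:
    """Simulate a control-only sequencing run and calibrate the caller.

    Builds a positive-control amplicon with ``n_positive_sites`` engineered
    spikes at ``positive_frequency`` and a variant-free negative control,
    sequences both at ``depth_per_allele * 2 * pool_size`` per site, fits the
    error model on the negative control and calibrates the threshold on the
    spikes.
    """
    cfg = PanelConfig(
        genes={"CTRLGENE": max(read_length * 3, 120)},
        variant_sites={},
        negative_control_length=negative_length,
        positive_control_length=positive_length,
        n_positive_sites=n_positive_sites,
        positive_frequency=positive_frequency,
        seed=seed,
    )
    panel = [a for a in build_amplicon_panel(cfg) if a.control_role != "none"]
    pool = pd.DataFrame({"subject_id": [f"P{i}" for i in range(pool_size)]})
    if error_profile is None:
        error_profile = default_error_profile(read_length)
    readset, truth = simulate_pool_reads(
        pool, panel, depth_per_allele=depth_per_allele,
        error_profile=error_profile, seed=seed, read_length=read_length,
        pool_id="controls",
    )
    placed = place_reads(readset, panel, max_mismatches=max_mismatches)
    model = fit_error_model(placed, panel, train_prefix=train_prefix)
    counts = tally_site_counts(placed, panel)
    calls = score_panel(counts, model, 2 * pool_size, panel)
    return calibrate_threshold(calls, truth, panel)
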