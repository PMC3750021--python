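"""Synthetic cohorts, amplicon panels and pooled short-read sets.

This module generates data with the statistical structure the downstream
analysis assumes, so the whole pipeline is testable without access-controlled
cohort data:

* a two-platform CSF biomarker cohort (platform A emulates a plate-ELISA
  series with median Abeta42 ~551 pg/mL, platform B a bead-based series with
  median ~155 pg/mL, a roughly 10-fold scale difference),
* a low-frequency coding variant (default MAF 0.017) whose effect on amyloid
  deposition is APOE-e4 dependent (stratum odds ratios 4.5 vs 18 by default),
* an amplicon panel with spiked positive-control sites (1 mutant copy per
  250) and a 1908-bp variant-free negative control,
* 36-bp single-end pooled reads with per-cycle substitution errors.

All randomness flows through a single integer seed; the same seed reproduces
output bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "CohortConfig",
    "PanelConfig",
    "Amplicon",
    "SitePlan",
    "ReadSet",
    "FastqParseError",
    "default_error_profile",
    "simulate_cohort",
    "build_amplicon_panel",
    "simulate_pool_reads",
    "write_fastq",
    "read_fastq",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "ld_genotype_pair",
]

# ---------------------------------------------------------------------------
# base encoding

_BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(_BASES)}
_CODE_TO_BASE = np.frombuffer(_BASES.encode(), dtype=np.uint8)


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0..3."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    if not np.isin(arr, _CODE_TO_BASE).all():
        raise ValueError("sequence contains characters outside ACGT")
    return out


def codes_to_seq(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def default_error_profile(read_length: int = 36, start: float = 0.001,
                          end: float = 0.005) -> np.ndarray:
    """Per-cycle substitution probability, rising linearly along the read.

    Short-read substitution error grows with cycle number; the default ramps
    from 0.1% at cycle 0 to 0.5% at the final cycle.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    return np.linspace(start, end, read_length)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortConfig:
    """Generating parameters for the two-platform CSF cohort.

    Effect sizes are on the (natural-)log biomarker scale; because the
    downstream standardisation centers but does not rescale, a generating
    beta equals the regression beta on the standardized scale.
    """

    n_site_a: int = 475
    n_site_b: int = 259
    variant_id: str = "PSEN1_E318G"
    maf: float = 0.017
    #: additional variants (id -> MAF) with no phenotypic effect
    other_variants: Mapping[str, float] = field(default_factory=dict)
    apoe4_frac_a: float = 0.39
    apoe4_frac_b: float = 0.47
    # variant effects (log scale, per minor allele)
    beta_tau: float = 0.14
    beta_ptau: float = 0.12
    beta_abeta: float = -0.05
    # deposition stratum odds ratios for APOE-e4 carriage
    or_apoe_alone: float = 4.5
    or_variant_and_apoe: float = 18.0
    baseline_deposition_odds: float = 0.62
    # platform location parameters (medians, pg/mL) and log-scale SDs
    abeta_median_a: float = 551.0
    abeta_median_b: float = 155.0
    tau_median_a: float = 283.0
    tau_median_b: float = 82.0
    ptau_median_a: float = 54.0
    ptau_median_b: float = 29.5
    sigma_abeta: float = 0.40
    sigma_tau: float = 0.50
    sigma_ptau: float = 0.50
    # covariate effects (log scale)
    beta_age_tau: float = 0.010
    beta_female_tau: float = 0.05
    beta_cdr_tau: float = 0.25
    beta_apoe_tau: float = 0.05
    beta_age_abeta: float = -0.005
    beta_cdr_abeta: float = -0.15
    age_center: float = 72.0
    # demographics per platform
    age_mean_a: float = 69.0
    age_sd_a: float = 10.0
    age_mean_b: float = 76.0
    age_sd_b: float = 7.0
    female_frac_a: float = 0.60
    female_frac_b: float = 0.39
    cdr0_frac_a: float = 0.73
    cdr0_frac_b: float = 0.40
    # deposition cutoffs used to anchor the Abeta42 scale (pg/mL)
    cutoff_a: float = 500.0
    cutoff_b: float = 192.0
    # age at onset
    aao_mean: float = 78.2
    aao_carrier_shift: float = -4.3
    aao_sd: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_site_a < 0 or self.n_site_b < 0 or self.n_site_a + self.n_site_b <= 0:
            raise ValueError("cohort size must be positive")
        for vid, maf in {self.variant_id: self.maf, **self.other_variants}.items():
            if not 0.0 < maf < 0.5:
                raise ValueError(f"MAF for {vid} must be in (0, 0.5), got {maf}")
        if min(self.or_apoe_alone, self.or_variant_and_apoe,
               self.baseline_deposition_odds) <= 0:
            raise ValueError("odds ratios must be > 0")


_CDR_NONZERO = np.array([0.5, 1.0, 2.0, 3.0])
_CDR_NONZERO_P = np.array([0.60, 0.30, 0.08, 0.02])


def _truncated_lognormal(rng: np.random.Generator, mu: np.ndarray, sigma: float,
                         log_cutoff: np.ndarray, below: np.ndarray) -> np.ndarray:
    """Sample log-normal values forced below/above a cutoff, vectorised.

    Inverse-CDF sampling of a normal truncated to (-inf, c) when ``below``
    else (c, inf), then exponentiated.
    """
    zc = (log_cutoff - mu) / sigma
    pc = _st.norm.cdf(zc)
    u = rng.random(mu.size)
    # map u into the allowed CDF interval
    q = np.where(below, u * pc, pc + u * (1.0 - pc))
    q = np.clip(q, 1e-12, 1.0 - 1e-12)
    return np.exp(mu + sigma * _st.norm.ppf(q))


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a two-platform cohort with genotypes, biomarkers and AAO.

    Genotypes are drawn under Hardy-Weinberg at the configured MAF. Log
    biomarkers are platform intercept + covariate effects + variant effects +
    Gaussian noise. Amyloid-deposition status is drawn first from a logistic
    liability whose only terms are APOE-e4 carriage and its product with
    variant carriage, so the stratified 2x2 odds ratios match
    ``or_apoe_alone`` / ``or_variant_and_apoe`` in expectation; raw Abeta42 is
    then sampled on the matching side of the platform cutoff. Case status and
    age at onset come from a latent-onset model (onset shifted
    ``aao_carrier_shift`` years for carriers, prevalence matched per platform),
    so carriers are both over-represented among cases and earlier-onset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_site_a + config.n_site_b
    site = np.array(["A"] * config.n_site_a + ["B"] * config.n_site_b)
    is_b = site == "B"

    age = np.where(
        is_b,
        rng.normal(config.age_mean_b, config.age_sd_b, n),
        rng.normal(config.age_mean_a, config.age_sd_a, n),
    ).clip(40, 95)
    female = rng.random(n) < np.where(is_b, config.female_frac_b, config.female_frac_a)
    frac_e4 = np.where(is_b, config.apoe4_frac_b, config.apoe4_frac_a)
    q_e4 = 1.0 - np.sqrt(1.0 - frac_e4)
    apoe4_dose = rng.binomial(2, q_e4)

    genotypes = {config.variant_id: rng.binomial(2, config.maf, n)}
    for vid, maf in config.other_variants.items():
        genotypes[vid] = rng.binomial(2, maf, n)
    g = genotypes[config.variant_id]

    carrier = g > 0
    e4 = apoe4_dose > 0

    # Latent dementia-onset age with the carrier shift; a subject is a case
    # when onset falls within a site-level margin of the current age, the
    # margin chosen so each platform hits its configured case prevalence.
    # Carriers of the earlier-onset allele are thereby both over-represented
    # among cases and earlier-onset within them.
    onset = (config.aao_mean + config.aao_carrier_shift * carrier
             + config.aao_sd * rng.standard_normal(n))
    margin = onset - age
    case = np.zeros(n, dtype=bool)
    for sel, frac0 in ((~is_b, config.cdr0_frac_a), (is_b, config.cdr0_frac_b)):
        if sel.any():
            case[sel] = margin[sel] <= np.quantile(margin[sel], 1.0 - frac0)
    cdr = np.where(case, rng.choice(_CDR_NONZERO, size=n, p=_CDR_NONZERO_P), 0.0)
    aao = np.where(case, onset.clip(45, 100), age)
    logit = (
        math.log(config.baseline_deposition_odds)
        + np.where(e4, math.log(config.or_apoe_alone), 0.0)
        + np.where(e4 & carrier,
                   math.log(config.or_variant_and_apoe / config.or_apoe_alone), 0.0)
    )
    deposition = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    mu_abeta = (
        np.where(is_b, math.log(config.abeta_median_b), math.log(config.abeta_median_a))
        + config.beta_age_abeta * (age - config.age_center)
        + config.beta_cdr_abeta * cdr
        + config.beta_abeta * g
    )
    log_cut = np.where(is_b, math.log(config.cutoff_b), math.log(config.cutoff_a))
    abeta = _truncated_lognormal(rng, mu_abeta, config.sigma_abeta, log_cut, deposition)

    common = (
        config.beta_age_tau * (age - config.age_center)
        + config.beta_female_tau * female
        + config.beta_cdr_tau * cdr
        + config.beta_apoe_tau * apoe4_dose
    )
    mu_tau = (
        np.where(is_b, math.log(config.tau_median_b), math.log(config.tau_median_a))
        + common + config.beta_tau * g
    )
    mu_ptau = (
        np.where(is_b, math.log(config.ptau_median_b), math.log(config.ptau_median_a))
        + common + config.beta_ptau * g
    )
    tau = np.exp(mu_tau + config.sigma_tau * rng.standard_normal(n))
    ptau = np.exp(mu_ptau + config.sigma_ptau * rng.standard_normal(n))

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "site": site,
            "age": np.round(age, 2),
            "sex": np.where(female, "F", "M"),
            "cdr": cdr,
            "apoe4_dose": apoe4_dose,
            "case_status": np.where(case, "case", "control"),
            "aao": np.round(aao, 2),
            "censored": ~case,
            "abeta42_raw": np.round(abeta, 3),
            "tau_raw": np.round(tau, 3),
            "ptau_raw": np.round(ptau, 3),
        }
    )
    for vid, geno in genotypes.items():
        df[vid] = geno
    return df


def genotype_columns(cohort: pd.DataFrame) -> list[str]:
    """Columns of a cohort table that hold genotype dosages (0/1/2)."""
    fixed = {
        "subject_id", "site", "age", "sex", "cdr", "apoe4_dose", "case_status",
        "aao", "censored", "abeta42_raw", "tau_raw", "ptau_raw",
    }
    return [c for c in cohort.columns if c not in fixed]


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ld_genotype_pair(n: int, maf_causal: float, maf_proxy: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two diallelic genotype vectors in LD with D' = 1.

    With complete D' and ``maf_proxy <= maf_causal`` every proxy minor allele
    rides on a causal minor-allele haplotype, giving
    r^2 = maf_proxy (1 - maf_causal) / ((1 - maf_proxy) maf_causal).
    """
    if not 0 < maf_proxy <= maf_causal < 0.5:
        raise ValueError("require 0 < maf_proxy <= maf_causal < 0.5")
    u = rng.random((n, 2))
    hap_causal = u < maf_causal
    hap_proxy = u < maf_proxy
    return hap_causal.sum(axis=1), hap_proxy.sum(axis=1)


# ---------------------------------------------------------------------------
# amplicon panel


@dataclass(frozen=True)
class SitePlan:
    """A planned variant site within an amplicon."""

    variant_id: str
    alt: str
    consequence: str  # missense | nonsense | splice | synonymous | intronic | control
    designed_frequency: float | None = None  # set for engineered control spikes


@dataclass
class Amplicon:
    amplicon_id: str
    gene: str
    sequence: str
    genomic_offset: int
    control_role: str = "none"  # none | positive | negative
    variant_sites: dict[int, SitePlan] = field(default_factory=dict)

    def __post_init__(self):
        if self.control_role not in ("none", "positive", "negative"):
            raise ValueError(f"bad control_role {self.control_role!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return seq_to_codes(self.sequence)


_DEFAULT_GENES = {"APP": 400, "PSEN1": 400, "PSEN2": 400, "GRN": 400,
                  "MAPT": 400, "APOE": 400}


@dataclass
class PanelConfig:
    genes: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_GENES))
    #: variant_id -> (gene, consequence); placed at deterministic offsets
    variant_sites: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {"PSEN1_E318G": ("PSEN1", "missense")}
    )
    negative_control_length: int = 1908
    positive_control_length: int = 500
    n_positive_sites: int = 10
    positive_frequency: float = 1.0 / 250.0
    seed: int = 0


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return codes_to_seq(rng.integers(0, 4, length).astype(np.uint8))


def build_amplicon_panel(config: PanelConfig) -> list[Amplicon]:
    """Build a toy amplicon panel: one amplicon per gene plus two controls.

    The positive control carries ``n_positive_sites`` engineered alternate
    sites at designed pool frequency ``positive_frequency`` (default 1/250);
    the negative control (default 1908 bp) carries no true variants.
    """
    if not config.genes:
        raise ValueError("at least one gene is required to build a panel")
    rng = np.random.default_rng(config.seed)
    panel: list[Amplicon] = []
    seen: set[str] = set()
    offset = 0

    by_gene: dict[str, list[tuple[str, str]]] = {}
    for vid, (gene, csq) in config.variant_sites.items():
        if gene not in config.genes:
            raise ValueError(f"variant {vid} refers to unknown gene {gene}")
        by_gene.setdefault(gene, []).append((vid, csq))

    def _add(amp: Amplicon) -> None:
        if amp.amplicon_id in seen:
            raise ValueError(f"duplicate amplicon id {amp.amplicon_id}")
        seen.add(amp.amplicon_id)
        panel.append(amp)

    for gene, length in config.genes.items():
        seq = _random_sequence(rng, length)
        codes = seq_to_codes(seq)
        sites: dict[int, SitePlan] = {}
        planned = by_gene.get(gene, [])
        for i, (vid, csq) in enumerate(planned):
            pos = (i + 1) * length // (len(planned) + 1)
            alt = _BASES[(int(codes[pos]) + 1) % 4]
            sites[pos] = SitePlan(vid, alt, csq)
        _add(Amplicon(f"{gene}_amp", gene, seq, offset, "none", sites))
        offset += length

    pos_seq = _random_sequence(rng, config.positive_control_length)
    pos_codes = seq_to_codes(pos_seq)
    pos_sites: dict[int, SitePlan] = {}
    for i in range(config.n_positive_sites):
        pos = (i + 1) * config.positive_control_length // (config.n_positive_sites + 1)
        alt = _BASES[(int(pos_codes[pos]) + 1) % 4]
        pos_sites[pos] = SitePlan(f"POSCTRL_{i}", alt, "control",
                                  config.positive_frequency)
    _add(Amplicon("positive_control", "p53_vector", pos_seq, offset,
                  "positive", pos_sites))
    offset += config.positive_control_length

    _add(Amplicon("negative_control", "pCMV6_XL5",
                  _random_sequence(rng, config.negative_control_length),
                  offset, "negative", {}))
    return panel


def panel_length(panel: list[Amplicon]) -> int:
    return sum(len(a) for a in panel)


def panel_to_yaml(panel: list[Amplicon], path) -> None:
    import yaml

    doc = [
        {
            "amplicon_id": a.amplicon_id,
            "gene": a.gene,
            "genomic_offset": a.genomic_offset,
            "control_role": a.control_role,
            "sequence": a.sequence,
            "variant_sites": {
                int(pos): {
                    "variant_id": sp.variant_id,
                    "alt": sp.alt,
                    "consequence": sp.consequence,
                    "designed_frequency": sp.designed_frequency,
                }
                for pos, sp in sorted(a.variant_sites.items())
            },
        }
        for a in panel
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def panel_from_yaml(path) -> list[Amplicon]:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    panel = []
    for entry in doc:
        sites = {
            int(pos): SitePlan(d["variant_id"], d["alt"], d["consequence"],
                               d.get("designed_frequency"))
            for pos, d in (entry.get("variant_sites") or {}).items()
        }
        panel.append(Amplicon(entry["amplicon_id"], entry["gene"],
                              entry["sequence"], entry["genomic_offset"],
                              entry["control_role"], sites))
    return panel


# ---------------------------------------------------------------------------
# pooled reads


@dataclass
class ReadSet:
    """Fixed-length single-end reads with their true placements.

    Sequences are stored as a uint8 code matrix; placement metadata (source
    amplicon and 0-based start offset) is encoded into read names on FASTQ
    output and recovered on input.
    """

    pool_id: str
    read_length: int
    amplicon_ids: tuple[str, ...]
    amplicon_index: np.ndarray  # (n,) int32, index into amplicon_ids
    starts: np.ndarray  # (n,) int32, 0-based
    seqs: np.ndarray  # (n, read_length) uint8

    @property
    def n_reads(self) -> int:
        return len(self.starts)

    def sequences(self) -> Iterator[str]:
        for row in self.seqs:
            yield codes_to_seq(row)

    def read_names(self) -> Iterator[str]:
        for i in range(self.n_reads):
            yield (f"{self.pool_id}|{self.amplicon_ids[self.amplicon_index[i]]}"
                   f"|{self.starts[i]}|{i}")


class FastqParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"{message} (near line {line})")
        self.line = line


def simulate_pool_reads(
    pool_members: pd.DataFrame,
    panel: list[Amplicon],
    depth_per_allele: float = 30.0,
    error_profile: np.ndarray | None = None,
    seed: int = 0,
    read_length: int = 36,
    pool_id: str = "pool",
) -> tuple[ReadSet, pd.DataFrame]:
    """Simulate pooled amplicon reads plus control reads, with a truth table.

    The target interior per-site depth is ``depth_per_allele * 2N`` where N is
    the pool size. Each planned cohort-variant site contributes alternate
    alleles at frequency k/(2N), k being the summed minor-allele dosage of the
    pool members; engineered control sites use their designed frequency.
    Per-cycle substitution errors are injected independently per base.
    """
    n_subjects = len(pool_members)
    if n_subjects == 0:
        raise ValueError("empty pool")
    if depth_per_allele <= 0:
        raise ValueError("depth_per_allele must be > 0")
    if error_profile is None:
        error_profile = default_error_profile(read_length)
    error_profile = np.asarray(error_profile, dtype=float)
    if error_profile.shape != (read_length,):
        raise ValueError("error_profile must have one rate per read cycle")

    rng = np.random.default_rng(seed)
    two_n = 2 * n_subjects
    depth = depth_per_allele * two_n
    L = read_length

    truth_rows = []
    all_idx, all_starts, all_seqs = [], [], []
    amp_ids = tuple(a.amplicon_id for a in panel)

    for ai, amp in enumerate(panel):
        m = len(amp)
        if m < L:
            raise ValueError(f"amplicon {amp.amplicon_id} shorter than read length")
        n_positions = m - L + 1
        n_reads = int(round(depth * n_positions / L))
        starts = rng.integers(0, n_positions, n_reads).astype(np.int32)
        ref = amp.codes
        seqs = ref[starts[:, None] + np.arange(L)]

        for pos in sorted(amp.variant_sites):
            sp = amp.variant_sites[pos]
            if sp.designed_frequency is not None:
                freq = sp.designed_frequency
                k = np.nan
            else:
                dosage = pool_members.get(sp.variant_id)
                k = float(dosage.sum()) if dosage is not None else 0.0
                freq = k / two_n
            truth_rows.append(
                {
                    "amplicon_id": amp.amplicon_id,
                    "site": pos,
                    "ref": _BASES[ref[pos]],
                    "alt": sp.alt,
                    "variant_id": sp.variant_id,
                    "consequence": sp.consequence,
                    "carrier_chromosomes": k,
                    "frequency": freq,
                }
            )
            if freq > 0:
                covering = np.nonzero((starts <= pos) & (starts > pos - L))[0]
                mut = covering[rng.random(covering.size) < freq]
                seqs[mut, pos - starts[mut]] = _BASE_TO_CODE[sp.alt]

        # per-cycle substitution errors
        for c in range(L):
            hit = np.nonzero(rng.random(n_reads) < error_profile[c])[0]
            if hit.size:
                shift = rng.integers(1, 4, hit.size).astype(np.uint8)
                seqs[hit, c] = (seqs[hit, c] + shift) % 4

        all_idx.append(np.full(n_reads, ai, dtype=np.int32))
        all_starts.append(starts)
        all_seqs.append(seqs)

    readset = ReadSet(
        pool_id=pool_id,
        read_length=L,
        amplicon_ids=amp_ids,
        amplicon_index=np.concatenate(all_idx),
        starts=np.concatenate(all_starts),
        seqs=np.concatenate(all_seqs),
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["amplicon_id", "site", "ref", "alt", "variant_id",
                 "consequence", "carrier_chromosomes", "frequency"],
    )
    return readset, truth


def write_fastq(readset: ReadSet, path) -> None:
    """Write reads as FASTQ; placement metadata goes into the read names.

    Quality strings are a constant placeholder (the caller's error model is
    cycle-based, not quality-based).
    """
    qual = "I" * readset.read_length
    with open(path, "w") as fh:
        chunk: list[str] = []
        for name, seq in zip(readset.read_names(), readset.sequences()):
            chunk.append(f"@{name}\n{seq}\n+\n{qual}\n")
            if len(chunk) >= 10000:
                fh.write("".join(chunk))
                chunk.clear()
        fh.write("".join(chunk))


def read_fastq(path) -> ReadSet:
    """Parse a FASTQ written by :func:`write_fastq` back into a ReadSet."""
    from Bio import SeqIO

    names, seqs = [], []
    n_done = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            names.append(rec.id)
            seqs.append(str(rec.seq))
            n_done += 1
    except ValueError as exc:
        raise FastqParseError(str(exc), line=4 * n_done + 1) from exc

    if not names:
        return ReadSet("pool", 0, (), np.empty(0, np.int32),
                       np.empty(0, np.int32), np.empty((0, 0), np.uint8))
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise FastqParseError("reads have mixed lengths", line=1)
    L = lengths.pop()

    amp_ids: list[str] = []
    amp_lookup: dict[str, int] = {}
    idx = np.empty(len(names), np.int32)
    starts = np.empty(len(names), np.int32)
    pool_id = None
    for i, name in enumerate(names):
        try:
            pool, amp, start, _serial = name.split("|")
        except ValueError as exc:
            raise FastqParseError(f"read name {name!r} lacks placement metadata",
                                  line=4 * i + 1) from exc
        pool_id = pool if pool_id is None else pool_id
        if amp not in amp_lookup:
            amp_lookup[amp] = len(amp_ids)
            amp_ids.append(amp)
        idx[i] = amp_lookup[amp]
        starts[i] = int(start)
    mat = np.empty((len(names), L), np.uint8)
    for i, s in enumerate(seqs):
        mat[i] = seq_to_codes(s)
    return ReadSet(pool_id or "pool", L, tuple(amp_ids), idx, starts, mat)
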