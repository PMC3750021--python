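"""Pool caller: placement, error-model fitting, exact binomial scoring,
control calibration, follow-up filtering and VCF round trip."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from csfpool import (
    CalibrationError,
    PanelConfig,
    build_amplicon_panel,
    calibrate_threshold,
    calibration_run,
    call_and_filter,
    fit_error_model,
    place_reads,
    read_vcf,
    score_panel,
    score_site,
    simulate_pool_reads,
    tally_site_counts,
    write_vcf,
)
from csfpool.caller import ErrorModel, PlacedReads
from csfpool.synthetic import Amplicon, SitePlan, seq_to_codes

from conftest import BASE_SEED


def _toy_panel(gene_len=150, neg_len=300, pos_len=150, n_spikes=2, seed=0):
    return build_amplicon_panel(PanelConfig(
        genes={"PSEN1": gene_len}, negative_control_length=neg_len,
        positive_control_length=pos_len, n_positive_sites=n_spikes, seed=seed))


def _pool(n=114):
    df = pd.DataFrame({"subject_id": [f"P{i}" for i in range(n)]})
    df["PSEN1_E318G"] = 0
    df.loc[0, "PSEN1_E318G"] = 1
    return df


class TestPlaceReads:
    def test_error_free_reads_all_placed(self):
        panel = _toy_panel()
        for amp in panel:
            amp.variant_sites.clear()  # no true variants, no errors
        rs, _ = simulate_pool_reads(_pool(5), panel, depth_per_allele=2,
                                    error_profile=np.zeros(36), seed=1)
        placed = place_reads(rs, panel, max_mismatches=0)
        assert placed.n_discarded == 0
        assert len(placed.starts) == rs.n_reads

    def test_read_exceeding_mismatch_budget_discarded(self):
        panel = _toy_panel()
        rs, _ = simulate_pool_reads(_pool(5), panel, depth_per_allele=1,
                                    error_profile=np.zeros(36), seed=2)
        # corrupt 3 bases of the first read
        rs.seqs[0, :3] = (rs.seqs[0, :3] + 1) % 4
        placed = place_reads(rs, panel, max_mismatches=2)
        assert placed.n_discarded == 1

    def test_empty_readset(self):
        from csfpool import ReadSet

        empty = ReadSet("p", 36, (), np.empty(0, np.int32),
                        np.empty(0, np.int32), np.empty((0, 36), np.uint8))
        placed = place_reads(empty, _toy_panel())
        assert placed.n_input == 0 and len(placed.starts) == 0

    def test_read_longer_than_amplicon_rejected(self):
        amp = Amplicon("short", "g", "ACGTACGT", 0)
        from csfpool import ReadSet

        rs = ReadSet("p", 36, ("short",), np.zeros(1, np.int32),
                     np.zeros(1, np.int32), np.zeros((1, 36), np.uint8))
        with pytest.raises(ValueError, match="exceed"):
            place_reads(rs, [amp])


def _placed_negative(n_reads, mismatch_cycles=(), neg_len=300, seed=0):
    """Hand-built negative-control alignments: reads at offset 0."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), neg_len))
    amp = Amplicon("negative_control", "vec", seq, 0, "negative", {})
    ref = amp.codes
    seqs = np.tile(ref[:36], (n_reads, 1))
    for c in mismatch_cycles:
        seqs[:, c] = (seqs[:, c] + 1) % 4
    placed = PlacedReads(("negative_control",), np.zeros(n_reads, np.int32),
                         np.zeros(n_reads, np.int32), seqs, 36, n_reads, 0)
    return placed, amp


class TestErrorModel:
    def test_jeffreys_floor_on_clean_control(self):
        placed, amp = _placed_negative(10000)
        model = fit_error_model(placed, [amp], train_prefix=100)
        assert model.rates[0] == pytest.approx(0.5 / 10001)

    def test_all_mismatched_rate_near_one(self):
        placed, amp = _placed_negative(100, mismatch_cycles=range(36))
        model = fit_error_model(placed, [amp], train_prefix=100)
        assert np.all(model.rates <= 1.0)
        assert np.all(model.rates > 0.99)

    def test_planted_uniform_error_recovered(self):
        """0.002 per cycle, >= 1e5 bases/cycle: every estimate in [.0016, .0024]."""
        panel = _toy_panel(neg_len=2000)
        pool = pd.DataFrame({"subject_id": ["a"] * 10})
        rs, _ = simulate_pool_reads(pool, panel, depth_per_allele=200,
                                    error_profile=np.full(36, 0.002),
                                    seed=BASE_SEED)
        placed = place_reads(rs, panel, max_mismatches=36)
        model = fit_error_model(placed, panel, train_prefix=2000)
        assert model.total_bases.min() >= 1e5
        assert np.all(model.rates >= 0.0016) and np.all(model.rates <= 0.0024)

    def test_no_negative_control_reads_is_an_error(self):
        panel = _toy_panel()
        from csfpool import ReadSet

        empty = ReadSet("p", 36, (), np.empty(0, np.int32),
                        np.empty(0, np.int32), np.empty((0, 36), np.uint8))
        placed = place_reads(empty, panel)
        with pytest.raises(CalibrationError, match="negative-control"):
            fit_error_model(placed, panel)


def _const_model(rate_any=0.3, L=36):
    return ErrorModel(np.full(L, rate_any), np.full(L, 1e5), 900)


class TestScoring:
    def test_zero_alt_count_gives_p_one(self):
        counts = np.zeros((4, 36), dtype=np.int64)
        counts[0, 0] = 50  # all reference
        call = score_site(counts, "A", _const_model(), 228)
        assert call.pvalue == 1.0 and call.k == 0

    def test_exact_binomial_tail_example(self):
        # n=10, specific-alt error 0.1, k=5 -> P(X>=5) = 1.6349e-3
        counts = np.zeros((4, 36), dtype=np.int64)
        counts[0, 0] = 5
        counts[1, 0] = 5
        call = score_site(counts, "A", _const_model(0.3), 228)
        oracle = sum(st.binom.pmf(k, 10, 0.1) for k in range(5, 11))
        assert call.pvalue == pytest.approx(1.6349e-3, rel=1e-3)
        assert call.pvalue == pytest.approx(oracle)

    def test_maf_estimate_rounds_to_chromosome_multiple(self):
        counts = np.zeros((4, 36), dtype=np.int64)
        counts[0, 0] = 22600
        counts[1, 0] = 200
        call = score_site(counts, "A", _const_model(), 228)
        assert call.maf_estimate == pytest.approx(2 / 228)
        assert call.n == 22800 and call.per_allele_coverage == pytest.approx(100.0)

    def test_p_monotone_in_alt_count(self):
        pvals = []
        for k in (1, 3, 5, 9):
            counts = np.zeros((4, 36), dtype=np.int64)
            counts[0, 0] = 50 - k
            counts[1, 0] = k
            pvals.append(score_site(counts, "A", _const_model(), 228).pvalue)
        assert all(a > b for a, b in zip(pvals, pvals[1:]))

    def test_cycle_weighted_error_rate(self):
        # half the coverage at a low-error cycle, half at a high-error cycle
        rates = np.zeros(36)
        rates[0], rates[1] = 0.003, 0.009
        model = ErrorModel(rates, np.full(36, 1e5), 900)
        counts = np.zeros((4, 36), dtype=np.int64)
        counts[0, 0] = 50
        counts[0, 1] = 50
        call = score_site(counts, "A", model, 228)
        assert call.error_rate == pytest.approx(0.006 / 3)


class TestCalibration:
    def test_threshold_recovers_all_spikes(self):
        cal = calibration_run(seed=BASE_SEED, negative_length=900,
                              train_prefix=450, positive_length=300)
        assert cal.sensitivity == 1.0
        assert cal.specificity >= 0.95
        assert cal.threshold == max(cal.positive_pvalues)

    def test_threshold_monotone_in_spikes(self):
        cal5 = calibration_run(seed=BASE_SEED, n_positive_sites=5,
                               negative_length=600, train_prefix=300,
                               positive_length=300)
        cal10 = calibration_run(seed=BASE_SEED, n_positive_sites=10,
                                negative_length=600, train_prefix=300,
                                positive_length=300)
        assert cal10.threshold >= min(cal5.positive_pvalues)
        assert cal10.threshold == max(cal10.positive_pvalues)

    def test_tied_maximum_pvalues_both_called(self):
        calls = pd.DataFrame({
            "amplicon_id": ["positive_control"] * 2 + ["negative_control"],
            "site": [10, 20, 5],
            "pvalue": [1e-6, 1e-6, 0.5],
        })
        truth = pd.DataFrame({"amplicon_id": ["positive_control"] * 2,
                              "site": [10, 20]})
        panel = _toy_panel(neg_len=100, pos_len=150)
        panel = [a for a in panel if a.control_role != "none"]
        cal = calibrate_threshold(calls, truth, panel)
        assert cal.threshold == 1e-6 and cal.sensitivity == 1.0

    def test_no_positive_controls_is_an_error(self):
        panel = [a for a in _toy_panel() if a.control_role == "negative"]
        calls = pd.DataFrame({"amplicon_id": [], "site": [], "pvalue": []})
        with pytest.raises(CalibrationError):
            calibrate_threshold(calls, pd.DataFrame({"amplicon_id": [], "site": []}),
                                panel)

    def test_null_pvalues_superuniform(self):
        """Error-only reads: per-alternate exact binomial tails stay at or
        below their nominal level (the conservatism of the exact test)."""
        from csfpool.caller import per_alt_pvalues

        panel = _toy_panel(neg_len=1000)
        panel = [a for a in panel if a.control_role == "negative"]
        pool = pd.DataFrame({"subject_id": ["a"] * 10})
        profile = np.full(36, 0.003)
        hits = {0.01: 0, 0.001: 0}
        total = 0
        for rep in range(30):
            rs, _ = simulate_pool_reads(pool, panel, depth_per_allele=50,
                                        error_profile=profile,
                                        seed=BASE_SEED + rep)
            placed = place_reads(rs, panel, max_mismatches=36)
            model = fit_error_model(placed, panel, train_prefix=500)
            counts = tally_site_counts(placed, panel)
            p = per_alt_pvalues(counts["negative_control"], model)
            p = p[500:]  # held out from training
            finite = np.isfinite(p)
            total += int(finite.sum())
            for alpha in hits:
                hits[alpha] += int((p[finite] <= alpha).sum())
        for alpha, h in hits.items():
            assert h / total <= alpha * 1.25 + 3 / total


@pytest.fixture(scope="module")
def scored_run():
    cfg = PanelConfig(
        genes={"PSEN1": 200},
        variant_sites={"PSEN1_E318G": ("PSEN1", "missense")},
        negative_control_length=900, positive_control_length=300,
        n_positive_sites=10, seed=3)
    panel = build_amplicon_panel(cfg)
    # add a synonymous doubleton next to the missense singleton
    gene = [a for a in panel if a.control_role == "none"][0]
    pos2 = 150
    alt = "ACGT"[(int(gene.codes[pos2]) + 1) % 4]
    gene.variant_sites[pos2] = SitePlan("PSEN1_syn", alt, "synonymous")
    pool = _pool(114)
    pool["PSEN1_syn"] = 0
    pool.loc[[1, 2], "PSEN1_syn"] = 1
    rs, truth = simulate_pool_reads(pool, panel, depth_per_allele=35,
                                    seed=BASE_SEED)
    placed = place_reads(rs, panel, max_mismatches=3)
    model = fit_error_model(placed, panel, train_prefix=450)
    calls = score_panel(tally_site_counts(placed, panel), model, 228, panel)
    cal = calibrate_threshold(calls, truth, panel)
    filtered = call_and_filter(calls, panel, cal.threshold)
    return panel, truth, cal, filtered

class TestFilterAndVcf:
    def test_planted_missense_singleton_in_followup(self, scored_run):
        panel, truth, cal, filtered = scored_run
        row = truth[truth["variant_id"] == "PSEN1_E318G"].iloc[0]
        hit = filtered[(filtered["amplicon_id"] == "PSEN1_amp")
                       & (filtered["site"] == row.site)]
        assert bool(hit["pass"].iloc[0])
        assert hit["maf_estimate"].iloc[0] == pytest.approx(1 / 228)

    def test_synonymous_site_excluded_despite_significance(self, scored_run):
        panel, truth, cal, filtered = scored_run
        row = truth[truth["variant_id"] == "PSEN1_syn"].iloc[0]
        hit = filtered[(filtered["amplicon_id"] == "PSEN1_amp")
                       & (filtered["site"] == row.site)]
        assert bool(hit["significant"].iloc[0])
        assert not bool(hit["pass"].iloc[0])

    def test_common_variant_excluded(self, scored_run):
        panel, truth, cal, filtered = scored_run
        fake = filtered.iloc[[0]].assign(maf_estimate=0.06, consequence="missense",
                                         significant=True,
                                         per_allele_coverage=100.0,
                                         amplicon_id="PSEN1_amp")
        out = call_and_filter(fake, panel, threshold=1.0)
        assert not out["pass"].any()

    def test_controls_never_pass_followup(self, scored_run):
        panel, truth, cal, filtered = scored_run
        ctrl = filtered[filtered["amplicon_id"].isin(
            ["positive_control", "negative_control"])]
        assert not ctrl["pass"].any()

    def test_vcf_round_trip(self, scored_run, tmp_path):
        panel, truth, cal, filtered = scored_run
        calls = filtered[filtered["significant"]].reset_index(drop=True)
        path = tmp_path / "calls.vcf"
        write_vcf(calls, panel, path)
        back = read_vcf(path)
        assert len(back) == len(calls)
        for col in ("amplicon_id", "site", "ref", "alt", "k", "n"):
            assert list(back[col]) == list(calls[col])
        for col in ("pvalue", "maf_estimate", "error_rate", "per_allele_coverage"):
            assert np.allclose(back[col], calls[col], rtol=1e-6)
        assert list(back["pass"]) == list(calls["pass"])


def test_end_to_end_singleton_recall():
    """Singleton variants at 30x average per-allele coverage are detected
    (p at or below the control-calibrated threshold) with sensitivity >= 0.95
    across seeds — a stochastic bound on the design claim."""
    n_seeds = 50
    recovered = 0
    total = 0
    for i in range(n_seeds):
        cfg = PanelConfig(
            genes={"PSEN1": 300},
            variant_sites={f"V{j}": ("PSEN1", "missense") for j in range(4)},
            negative_control_length=1000, positive_control_length=300,
            n_positive_sites=10, seed=i)
        panel = build_amplicon_panel(cfg)
        pool = pd.DataFrame({"subject_id": [f"P{k}" for k in range(114)]})
        for j in range(4):
            pool[f"V{j}"] = 0
            pool.loc[j, f"V{j}"] = 1
        rs, truth = simulate_pool_reads(pool, panel, depth_per_allele=30,
                                        seed=BASE_SEED + i)
        placed = place_reads(rs, panel, max_mismatches=3)
        model = fit_error_model(placed, panel, train_prefix=500)
        calls = score_panel(tally_site_counts(placed, panel), model, 228, panel)
        cal = calibrate_threshold(calls, truth, panel)
        filtered = call_and_filter(calls, panel, cal.threshold)
        planted = truth[truth["consequence"] == "missense"]
        merged = planted.merge(filtered, on=["amplicon_id", "site"])
        recovered += int(merged["significant"].sum())
        total += len(planted)
    assert total == 4 * n_seeds
    assert recovered / total >= 0.95
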