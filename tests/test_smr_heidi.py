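import numpy as np
import pytest
from scipy import stats

from xwaskit.io_formats import GwasTable, ProbeInfo
from xwaskit.smr_heidi import (
    AlignedRegion,
    AlignedSnp,
    SmrConfig,
    harmonize_region,
    heidi_test,
    run_probe,
    select_heidi_snps,
    select_top_instrument,
    smr_test,
    wald_ratio,
)
from xwaskit.synthetic_data import (
    ScenarioSpec,
    _rng,
    build_region_model,
    draw_summary_stats,
    make_ld_panel,
)

from conftest import make_snp

PROBE = ProbeInfo(probe_id="p1", gene="GENE1", chrom="1", probe_pos=10_000)


def region_from_arrays(p_zx, b_zx=None, se_zx=None, b_zy=None, se_zy=None, ld=None,
                       positions=None):
    """Build an AlignedRegion directly from statistic arrays."""
    m = len(p_zx)
    b_zx = np.full(m, 0.5) if b_zx is None else np.asarray(b_zx, float)
    se_zx = np.full(m, 0.01) if se_zx is None else np.asarray(se_zx, float)
    b_zy = np.full(m, 0.1) if b_zy is None else np.asarray(b_zy, float)
    se_zy = np.full(m, 0.01) if se_zy is None else np.asarray(se_zy, float)
    positions = np.arange(m) * 100 + 9000 if positions is None else positions
    snps = [
        AlignedSnp(
            snp_id=f"rs{i}", pos=int(positions[i]), a1="A", a2="G",
            b_zx=float(b_zx[i]), se_zx=float(se_zx[i]), p_zx=float(p_zx[i]),
            b_zy=float(b_zy[i]), se_zy=float(se_zy[i]),
            p_zy=0.5, freq_gwas=0.3, freq_xqtl=0.3, freq_ref=0.3,
        )
        for i in range(m)
    ]
    ld = np.eye(m) if ld is None else np.asarray(ld, float)
    return AlignedRegion(probe=PROBE, snps=snps, ld=ld)


def simulated_inputs(scenario="causal", seed=5, **kwargs):
    spec = ScenarioSpec(scenario=scenario, seed=seed, **kwargs)
    model = build_region_model(spec)
    panel, _ = make_ld_panel(spec, model)
    summ = draw_summary_stats(model, _rng(seed, 3, 0))
    gwas = GwasTable(snps={r.snp_id: r for r in summ.gwas_records()})
    return model, panel, summ, gwas


class TestHarmonize:
    def test_swapped_alleles_flip_sign_and_freq(self, simple_panel):
        # panel a1 frequency for rs1 is 0.5, so use nearby frequencies
        xq = make_snp("rs1", a1="A", a2="G", beta=0.5, freq=0.45, pos=1000)
        gw = make_snp("rs1", a1="G", a2="A", beta=0.2, freq=0.55, pos=1000)
        probe = ProbeInfo(probe_id="p", gene="G", chrom="1", probe_pos=1000)
        region = harmonize_region(probe, GwasTable(snps={"rs1": gw}), [xq], simple_panel)
        assert len(region) == 1
        s = region.snps[0]
        assert s.b_zy == -0.2 and s.freq_gwas == pytest.approx(0.45)
        assert s.b_zx == 0.5  # xQTL orientation defines the effect allele

    def test_freq_mismatch_dropped(self, simple_panel):
        # panel rs1 has a1-frequency 0.5; a GWAS freq of 0.10 mismatches by
        # 0.40 > 0.15 while the xQTL freq matches the panel
        xq = make_snp("rs1", freq=0.45, pos=1000)
        gw = make_snp("rs1", freq=0.10, pos=1000)
        probe = ProbeInfo(probe_id="p", gene="G", chrom="1", probe_pos=1000)
        region = harmonize_region(probe, GwasTable(snps={"rs1": gw}), [xq], simple_panel)
        assert len(region) == 0
        assert region.counters["freq_mismatch"] == 1

    def test_strand_ambiguous_dropped(self, simple_panel):
        xq = make_snp("rs1", a1="A", a2="T", pos=1000)
        gw = make_snp("rs1", a1="A", a2="T", pos=1000)
        probe = ProbeInfo(probe_id="p", gene="G", chrom="1", probe_pos=1000)
        region = harmonize_region(probe, GwasTable(snps={"rs1": gw}), [xq], simple_panel)
        assert len(region) == 0
        assert region.counters["strand_ambiguous"] == 1

    def test_cis_window_enforced(self, simple_panel):
        cfg = SmrConfig(cis_window_bp=500)
        xq_near = make_snp("rs1", freq=0.45, pos=1000)
        xq_far = make_snp("rs3", a1="G", a2="A", freq=0.6, pos=3000)
        gw = {"rs1": make_snp("rs1", freq=0.45, pos=1000),
              "rs3": make_snp("rs3", a1="G", a2="A", freq=0.6, pos=3000)}
        probe = ProbeInfo(probe_id="p", gene="G", chrom="1", probe_pos=1000)
        region = harmonize_region(probe, GwasTable(snps=gw), [xq_near, xq_far],
                                  simple_panel, cfg)
        assert [s.snp_id for s in region.snps] == ["rs1"]
        assert region.counters["outside_cis_window"] == 1

    def test_allele_flip_invariance_of_record(self):
        """Flipping one SNP's (a1, a2, beta, freq) in the GWAS input leaves
        the final SmrRecord unchanged."""
        model, panel, summ, gwas = simulated_inputs()
        rec1 = run_probe(model.probe, gwas, summ.xqtl_records(), panel)
        flipped = dict(gwas.snps)
        key = model.snp_ids[model.causal]
        flipped[key] = flipped[key].flipped()
        rec2 = run_probe(model.probe, GwasTable(snps=flipped), summ.xqtl_records(), panel)
        assert rec1 == rec2


class TestTopInstrument:
    def test_smallest_p_selected(self):
        region = region_from_arrays([1e-9, 1e-7])
        assert select_top_instrument(region) == 0

    def test_no_instrument_below_threshold(self):
        region = region_from_arrays([5e-8, 1e-6])
        assert select_top_instrument(region) is None

    def test_tie_broken_by_larger_z(self):
        region = region_from_arrays(
            [1e-9, 1e-9], b_zx=[0.59, 0.61], se_zx=[0.1, 0.1]
        )
        assert select_top_instrument(region) == 1

    def test_tie_broken_by_position_last(self):
        region = region_from_arrays([1e-9, 1e-9])
        assert select_top_instrument(region) == 0


class TestWaldRatio:
    def test_delta_method_arithmetic(self):
        b, se = wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert b == pytest.approx(0.2)
        assert se == pytest.approx(0.2 * np.sqrt(0.05), rel=1e-12)

    def test_zero_numerator(self):
        b, se = wald_ratio(1.0, 0.1, 0.0, 0.02)
        assert b == 0.0 and se == 0.02

    def test_zero_instrument_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.1, 0.1, 0.02)

    def test_delta_se_matches_sampling_oracle(self):
        """Empirical SD of the ratio over 1e6 draws within 5% of the
        first-order delta SE."""
        rng = np.random.default_rng(314)
        zx = rng.normal(0.5, 0.05, size=10 ** 6)
        zy = rng.normal(0.1, 0.02, size=10 ** 6)
        _b, se = wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert np.std(zy / zx) == pytest.approx(se, rel=0.05)


class TestSmrTest:
    def test_zero_outcome_z(self):
        t, p = smr_test(5.0, 0.0)
        assert t == 0.0 and p == 1.0

    def test_equal_z_gives_half_square(self):
        t, _ = smr_test(3.0, 3.0)
        assert t == pytest.approx(4.5)

    def test_chi2_tail_example(self):
        t, p = smr_test(10.0, 4.0)
        assert t == pytest.approx(1600 / 116)
        assert p == pytest.approx(stats.chi2.sf(1600 / 116, 1), rel=1e-12)
        assert p == pytest.approx(2.04e-4, rel=0.01)

    def test_symmetry_and_monotonicity(self):
        for zx, zy in [(2.0, 5.0), (1.3, -0.4), (-6.0, 2.0)]:
            assert smr_test(zx, zy)[0] == pytest.approx(smr_test(zy, zx)[0])
        ts = [smr_test(4.0, zy)[0] for zy in np.linspace(0, 8, 30)]
        assert all(b >= a for a, b in zip(ts, ts[1:]))
        zx, zy = 7.0, 3.0
        t, _ = smr_test(zx, zy)
        assert 0 < t <= min(zx ** 2, zy ** 2)


class TestHeidiSelection:
    def ld_from_r_top(self, r_top):
        m = len(r_top) + 1
        ld = np.eye(m)
        ld[0, 1:] = ld[1:, 0] = r_top
        return ld

    def test_too_few_survivors_skips_heidi(self):
        ld = self.ld_from_r_top([0.5, 0.5])
        region = region_from_arrays([1e-10, 1e-4, 1e-4], ld=ld)
        assert select_heidi_snps(region, 0) == []

    def test_capped_at_heidi_max(self):
        m = 31
        r_top = np.full(m - 1, 0.5)
        region = region_from_arrays(
            [1e-10] + [10 ** -(4 + i / 10) for i in range(m - 1)],
            ld=self.ld_from_r_top(r_top),
        )
        chosen = select_heidi_snps(region, 0)
        assert len(chosen) == 20
        ps = [region.snps[i].p_zx for i in chosen]
        others = [region.snps[i].p_zx for i in range(1, m) if i not in chosen]
        assert max(ps) <= min(others)

    def test_high_and_low_ld_pruned_against_top(self):
        r_top = [np.sqrt(0.95), 0.5, 0.5, 0.5, 0.1]
        region = region_from_arrays([1e-10] + [1e-4] * 5,
                                    ld=self.ld_from_r_top(r_top))
        chosen = select_heidi_snps(region, 0)
        assert 1 not in chosen  # r2 = 0.95 > 0.9
        assert 5 not in chosen  # r2 = 0.01 < 0.05
        assert chosen == [2, 3, 4]

    def test_candidate_p_threshold(self):
        region = region_from_arrays([1e-10, 1e-4, 1e-4, 1e-4, 2e-3],
                                    ld=self.ld_from_r_top([0.5] * 4))
        assert 4 not in select_heidi_snps(region, 0)


class TestHeidiTest:
    def test_identical_ratios_give_zero_statistic(self):
        # b_zy proportional to b_zx => all Wald ratios equal
        b_zx = np.array([0.5, 0.45, 0.4, 0.35])
        region = region_from_arrays(
            [1e-10, 1e-6, 1e-6, 1e-6], b_zx=b_zx, b_zy=0.2 * b_zx,
            ld=np.eye(4) * 0.5 + 0.5,
        )
        t, p, nsnp = heidi_test(region, 0, [1, 2, 3])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0 and nsnp == 4

    def test_equal_weights_reduce_to_plain_chi2(self):
        """A unit-eigenvalue spectrum gives exactly the chi-square tail
        (uncorrelated ratio differences)."""
        from xwaskit.smr_heidi import _weighted_chi2_sf

        cfg = SmrConfig()
        for t, m in [(3.2, 5), (11.1, 5), (25.0, 12)]:
            p = _weighted_chi2_sf(t, np.ones(m), cfg)
            assert p == stats.chi2.sf(t, m)

    def test_precise_top_instrument_approaches_plain_chi2(self):
        """When the top SNP's errors are negligible the ratio differences
        decorrelate (their only shared term is the top ratio), so the
        HEIDI p approaches the plain chi-square tail at r = I."""
        rng = np.random.default_rng(8)
        m = 6
        b_zx = rng.uniform(0.3, 0.6, size=m)
        b_zy = 0.2 * b_zx + rng.normal(0, 0.005, size=m)
        se_zx = np.full(m, 0.01)
        se_zy = np.full(m, 0.01)
        se_zx[0] = se_zy[0] = 1e-6
        region = region_from_arrays(
            np.full(m, 1e-8), b_zx=b_zx, se_zx=se_zx, b_zy=b_zy, se_zy=se_zy,
            ld=np.eye(m),
        )
        t, p, _ = heidi_test(region, 0, list(range(1, m)))
        assert p == pytest.approx(stats.chi2.sf(t, m - 1), rel=1e-4)

    def test_minimum_snp_boundary_runs(self):
        model, panel, summ, gwas = simulated_inputs(seed=9)
        cfg = SmrConfig(heidi_max=3)
        rec = run_probe(model.probe, gwas, summ.xqtl_records(), panel, cfg)
        assert rec.nsnp_heidi == 4
        assert rec.p_heidi is not None

    @pytest.mark.parametrize("method", ["imhof", "satterthwaite"])
    def test_tail_methods_agree_in_bulk(self, method):
        region_model, panel, summ, gwas = simulated_inputs(scenario="linkage", seed=3)
        cfg = SmrConfig(heidi_tail_method=method)
        rec = run_probe(region_model.probe, gwas, summ.xqtl_records(), panel, cfg)
        assert rec.p_heidi is not None and 0 < rec.p_heidi <= 1


class TestRunProbe:
    def test_no_record_without_genomewide_instrument(self):
        model, panel, summ, gwas = simulated_inputs()
        weak = [s for s in summ.xqtl_records()]
        # inflate xQTL p-values above the instrument threshold
        weak = [
            type(s)(snp_id=s.snp_id, a1=s.a1, a2=s.a2, freq=s.freq, beta=s.beta,
                    se=s.se, p=max(s.p, 1e-6), n=s.n, chrom=s.chrom, pos=s.pos)
            for s in weak
        ]
        assert run_probe(model.probe, gwas, weak, panel) is None

    def test_causal_region_detected_with_clean_heidi(self):
        """Causal simulations: strong SMR signal, HEIDI not rejecting."""
        spec = ScenarioSpec(scenario="causal", seed=21)
        model = build_region_model(spec)
        panel, _ = make_ld_panel(spec, model)
        hits = 0
        n_seeds = 50
        for i in range(n_seeds):
            summ = draw_summary_stats(model, _rng(21, 3, i))
            gwas = GwasTable(snps={r.snp_id: r for r in summ.gwas_records()})
            rec = run_probe(model.probe, gwas, summ.xqtl_records(), panel)
            if rec and rec.p_smr < 1e-4 and (rec.p_heidi or 0) > 0.01:
                hits += 1
        assert hits >= 0.8 * n_seeds
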