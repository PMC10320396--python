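import json

import numpy as np
import pytest
from scipy import stats

from xwaskit.synthetic_data import (
    FixtureSpec,
    MultiStudySpec,
    ScenarioSpec,
    _orthant_upper,
    _bvn_upper,
    _rng,
    _sample_dosages,
    analytic_dosage_corr,
    build_region_model,
    draw_summary_stats,
    latent_to_dosage_corr,
    make_ld_panel,
    simulate_individual_region,
    simulate_pattern_pvalues,
    write_fixture_set,
)


class TestLdModel:
    def test_owens_t_orthant_matches_quadrature(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            c1, c2 = rng.normal(size=2)
            rho = rng.uniform(-0.95, 0.95)
            assert float(_bvn_upper(c1, c2, rho)) == pytest.approx(
                _orthant_upper(c1, c2, rho), abs=1e-9
            )

    def test_independent_latents_give_near_zero_ld(self):
        spec = ScenarioSpec(m_snps=10, ld_rho=0.0, n_ref=1000, seed=5)
        model = build_region_model(spec)
        panel, _ = make_ld_panel(spec, model)
        r = panel.correlation(model.snp_ids)
        off = r[~np.eye(10, dtype=bool)]
        assert np.mean(np.abs(off)) < 0.05

    def test_adjacent_empirical_r_matches_analytic(self):
        spec = ScenarioSpec(
            m_snps=6, ld_rho=0.9, maf_low=0.3, maf_high=0.3001, n_ref=2000, seed=6
        )
        model = build_region_model(spec)
        panel, r_true = make_ld_panel(spec, model)
        r_emp = panel.correlation(model.snp_ids)
        assert abs(r_emp[0, 1] - r_true[0, 1]) < 0.1
        # analytic value for maf 0.3, latent rho 0.9
        assert r_true[0, 1] == pytest.approx(
            latent_to_dosage_corr(model.mafs[0], model.mafs[1], 0.9), rel=1e-12
        )

    def test_panel_deterministic_under_seed(self):
        spec = ScenarioSpec(m_snps=5, seed=7)
        p1, _ = make_ld_panel(spec)
        p2, _ = make_ld_panel(spec)
        assert np.array_equal(p1.dosages, p2.dosages)

    def test_dosage_corr_matrix_is_valid_correlation(self):
        spec = ScenarioSpec(seed=8)
        model = build_region_model(spec)
        lam = np.linalg.eigvalsh(model.R)
        assert lam.min() > 0
        assert np.allclose(np.diag(model.R), 1.0)


class TestSummaryRegion:
    def test_null_gwas_p_uniform_across_regions(self):
        """Per-SNP GWAS p-values under the null are Uniform(0,1): one
        fixed SNP tracked over 2,000 independent replicates."""
        spec = ScenarioSpec(scenario="null", m_snps=8, seed=9)
        model = build_region_model(spec)
        ps = np.array(
            [draw_summary_stats(model, _rng(9, 3, i)).p_y[2] for i in range(2000)]
        )
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_causal_instrument_power(self):
        """b_zx = 0.5 at n_xqtl = 30,000 yields a genome-wide significant
        top xQTL SNP in >= 99% of replicates."""
        spec = ScenarioSpec(scenario="causal", seed=10)
        model = build_region_model(spec)
        hits = sum(
            draw_summary_stats(model, _rng(10, 3, i)).p_x.min() < 5e-8
            for i in range(100)
        )
        assert hits >= 99

    def test_fast_and_slow_paths_agree_in_distribution(self):
        """Two-sample KS on the causal-SNP effect estimate: the MVN
        summary draw matches individual-level per-SNP least squares."""
        spec = ScenarioSpec(
            scenario="causal", m_snps=12, n_xqtl=5000, n_gwas=5000, seed=11
        )
        model = build_region_model(spec)
        n_seeds = 200
        fast = np.array(
            [draw_summary_stats(model, _rng(11, 30, i)).bhat_y[model.causal]
             for i in range(n_seeds)]
        )
        slow = np.array(
            [simulate_individual_region(model, _rng(11, 31, i)).bhat_y[model.causal]
             for i in range(n_seeds)]
        )
        assert stats.ks_2samp(fast, slow).pvalue > 0.01
        assert abs(fast.mean() - slow.mean()) < 2 * np.hypot(
            fast.std() / np.sqrt(n_seeds), slow.std() / np.sqrt(n_seeds)
        ) + 1e-9

    def test_linkage_picks_second_causal_near_target_r(self):
        spec = ScenarioSpec(scenario="linkage", linkage_r=0.6, seed=12)
        model = build_region_model(spec)
        assert model.causal2 is not None
        assert abs(model.R[model.causal, model.causal2] - 0.6) < 0.15


class TestPatternPvalues:
    def test_all_null_point_mass_gives_uniform(self):
        spec = MultiStudySpec(
            n_genes=10_000, n_studies=2, pattern_probs=(1.0, 0.0, 0.0, 0.0), seed=13
        )
        matrix, labels = simulate_pattern_pvalues(spec)
        assert np.all(labels == 0)
        assert matrix.P.mean() == pytest.approx(0.5, abs=0.01)

    def test_associated_entries_have_small_p(self):
        k = 2 ** 3
        probs = np.zeros(k)
        probs[0], probs[-1] = 0.99, 0.01
        spec = MultiStudySpec(
            n_genes=20_000, n_studies=3, pattern_probs=tuple(probs),
            alt_scale=10.0, seed=14,
        )
        matrix, labels = simulate_pattern_pvalues(spec)
        alt_p = matrix.P[labels == k - 1]
        assert np.median(alt_p) < 1e-3

    def test_deterministic_under_seed(self):
        spec = MultiStudySpec(n_genes=500, n_studies=2, seed=15)
        m1, l1 = simulate_pattern_pvalues(spec)
        m2, l2 = simulate_pattern_pvalues(spec)
        assert np.array_equal(m1.P, m2.P) and np.array_equal(l1, l2)


class TestFixtureBundle:
    def test_truth_manifest_lists_every_probe(self, fixture_bundle):
        truth = fixture_bundle["truth"]
        fx = fixture_bundle["fx"]
        assert len(truth["regions"]) == fx.n_probes
        scenarios = [r["scenario"] for r in truth["regions"].values()]
        assert scenarios.count("causal") == fx.n_causal
        assert scenarios.count("linkage") == fx.n_linkage
        assert scenarios.count("null") == fx.n_null
        on_disk = json.loads((fixture_bundle["dir"] / "truth.json").read_text())
        assert on_disk["planted_gene"] == truth["planted_gene"]

    def test_bundle_files_parse_back(self, fixture_bundle):
        from xwaskit.io_formats import (
            read_genotype_panel,
            read_gmt,
            read_gwas_table,
            read_xqtl_dataset,
        )

        root = fixture_bundle["dir"]
        truth = fixture_bundle["truth"]
        gwas = read_gwas_table(root / "gwas_studyA.ma")
        ds = read_xqtl_dataset(root / "xqtl_effects.tsv", root / "probe_annot.tsv")
        panel = read_genotype_panel(root / "panel.tsv")
        fx = fixture_bundle["fx"]
        assert len(ds) == fx.n_probes
        assert len(gwas) == fx.n_probes * fx.m_snps
        assert panel.dosages.shape == (fx.n_ref, fx.n_probes * fx.m_snps)
        sets = read_gmt(root / "sets.gmt")
        assert truth["planted_set"] in sets

    def test_case_control_study_roundtrips_through_log_or(self, fixture_bundle):
        from xwaskit.io_formats import read_gwas_table

        root = fixture_bundle["dir"]
        truth = fixture_bundle["truth"]
        cc = truth["case_control_study"]
        raw = read_gwas_table(root / f"gwas_{cc}.ma", effect_is_or=False)
        logged = read_gwas_table(root / f"gwas_{cc}.ma", effect_is_or=True)
        some = list(raw.snps)[:20]
        for s in some:
            assert raw.get(s).beta > 0  # written as odds ratios
            assert logged.get(s).beta == pytest.approx(
                np.log(raw.get(s).beta), rel=1e-10
            )
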