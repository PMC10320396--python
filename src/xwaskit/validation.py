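"""Simulation-based calibration and recovery measurements.

Each routine simulates inputs with known truth through
:mod:`xwaskit.synthetic_data`, runs the pipeline's actual analysis path,
and returns the measured operating characteristics (type-I error, power,
coverage, recovery error).  The same routines back the statistical test
suite and the reproduction script, so the numbers reported there are
always recomputed from scratch.
"""

from __future__ import annotations

import os

import numpy as np
from scipy import stats

from . import pipeline
from .concordance import fit_concordance, pattern_matrix
from .enrichment import enrich_sets
from .io_formats import GwasTable
from .smr_heidi import SmrConfig, _weighted_chi2_sf, run_probe
from .synthetic_data import (
    FixtureSpec,
    MultiStudySpec,
    ScenarioSpec,
    _rng,
    build_region_model,
    draw_summary_stats,
    make_ld_panel,
    simulate_pattern_pvalues,
    write_fixture_set,
)

__all__ = [
    "run_scenario_records",
    "smr_null_calibration",
    "effect_recovery",
    "heidi_discrimination",
    "satterthwaite_vs_montecarlo",
    "cauchy_null_ks",
    "concordance_recovery",
    "enrichment_null_fpr",
    "end_to_end_recovery",
]


def run_scenario_records(
    scenario: str,
    seed: int,
    n_regions: int,
    config: SmrConfig = SmrConfig(),
    **spec_kwargs,
):
    """Simulate ``n_regions`` summary-statistic replicates of one cis
    region and push each through the full per-probe path (harmonization,
    instrument selection, SMR, HEIDI) against a sampled reference panel.

    The region model (MAFs, LD, effects) and the panel are drawn once, as
    for a real locus analyzed against one reference; cohort-level
    sampling noise is redrawn per replicate.
    """
    spec = ScenarioSpec(scenario=scenario, seed=seed, **spec_kwargs)
    model = build_region_model(spec)
    panel, _r_true = make_ld_panel(spec, model)
    records = []
    for i in range(n_regions):
        summ = draw_summary_stats(model, _rng(seed, 3, i))
        gwas = GwasTable(snps={r.snp_id: r for r in summ.gwas_records()})
        rec = run_probe(model.probe, gwas, summ.xqtl_records(), panel, config)
        if rec is not None:
            records.append(rec)
    return records


def smr_null_calibration(seed: int, n_regions: int = 2000, alpha: float = 0.05):
    """Type-I error of the SMR test under b_zy = 0 with a strong instrument."""
    records = run_scenario_records("null", seed, n_regions)
    p = np.array([r.p_smr for r in records])
    return {
        "n_regions": len(records),
        "rejection_rate": float((p < alpha).mean()),
        "alpha": alpha,
    }


def effect_recovery(seed: int, n_regions: int = 500, b_xy_true: float = 0.3):
    """Median Wald-ratio estimate and 95% CI coverage under causality."""
    records = run_scenario_records("causal", seed, n_regions, b_xy_true=b_xy_true)
    b = np.array([r.b_smr for r in records])
    se = np.array([r.se_smr for r in records])
    covered = np.abs(b - b_xy_true) <= 1.96 * se
    return {
        "n_regions": len(records),
        "b_xy_true": b_xy_true,
        "median_b_xy": float(np.median(b)),
        "coverage_95": float(covered.mean()),
    }


def heidi_discrimination(
    seed: int, n_regions: int = 500, alpha: float = 0.01, linkage_r: float = 0.6
):
    """HEIDI rejection rates under one shared causal variant (should be
    conservative) versus two causal variants in LD (should have power)."""
    out = {}
    for scenario in ("causal", "linkage"):
        records = run_scenario_records(scenario, seed, n_regions, linkage_r=linkage_r)
        ph = np.array([r.p_heidi for r in records if r.p_heidi is not None])
        out[f"{scenario}_rejection"] = float((ph < alpha).mean())
        out[f"{scenario}_n"] = int(ph.size)
    out["alpha"] = alpha
    return out


def satterthwaite_vs_montecarlo(
    seed: int, n_configs: int = 20, n_draws: int = 10 ** 6
):
    """Accuracy of the Satterthwaite weighted-chi-square tail.

    For random AR(1) correlation structures, a statistic is placed at a
    Satterthwaite p in [1e-3, 0.5] and re-evaluated by Monte-Carlo
    sampling of sum lambda_k chi2_1; reports the worst p ratio.
    """
    rng = np.random.default_rng(seed)
    config = SmrConfig()
    worst = 1.0
    ratios = []
    for _ in range(n_configs):
        m = int(rng.integers(4, 16))
        rho = float(rng.uniform(0.3, 0.9))
        corr = rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        lam = np.linalg.eigvalsh(corr)
        p_target = float(10 ** rng.uniform(-3, np.log10(0.5)))
        s1, s2 = lam.sum(), (lam ** 2).sum()
        t = (s2 / s1) * stats.chi2.isf(p_target, df=s1 ** 2 / s2)
        p_sat = _weighted_chi2_sf(t, lam, config)
        draws = rng.chisquare(1.0, size=(n_draws, m)) @ lam
        p_mc = (np.count_nonzero(draws >= t) + 1) / (n_draws + 1)
        ratio = max(p_sat / p_mc, p_mc / p_sat)
        ratios.append(ratio)
        worst = max(worst, ratio)
    return {
        "n_configs": n_configs,
        "n_draws": n_draws,
        "max_p_ratio": float(worst),
        "mean_p_ratio": float(np.mean(ratios)),
    }


def cauchy_null_ks(seed: int, n_sim: int = 10_000, k: int = 5):
    """Uniformity of the Cauchy combination of i.i.d. uniform p-values."""
    from .gene_level import cauchy_combine

    rng = np.random.default_rng(seed)
    combined = np.array(
        [cauchy_combine(rng.uniform(size=k)) for _ in range(n_sim)]
    )
    ks = stats.kstest(combined, "uniform")
    return {"n_sim": n_sim, "k": k, "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue)}


def concordance_recovery(
    seed: int, n_genes: int = 20_000, n_studies: int = 3, alt_scale: float = 10.0
):
    """Pattern-weight recovery and PP call precision on planted patterns.

    Pattern weights: 0.9 on the all-null pattern, the rest spread evenly.
    The mixture is fitted with alt_props equal to the generator's true
    per-study alternative proportion (known in simulation).
    """
    spec = MultiStudySpec(
        n_genes=n_genes, n_studies=n_studies, alt_scale=alt_scale, seed=seed
    )
    matrix, labels = simulate_pattern_pvalues(spec)
    probs = spec.resolved_pattern_probs()
    q = pattern_matrix(n_studies)
    marginal_alt = probs @ q  # true per-study alternative proportion
    fit, _post, pp = fit_concordance(matrix, alt_props=marginal_alt)
    pi_err = np.abs(fit.pi - probs)
    truth_assoc = q[labels] > 0
    calls = pp > 0.95
    precision = float(truth_assoc[calls].mean()) if calls.any() else 1.0
    diffs = np.diff(fit.loglik_trace)
    return {
        "n_genes": n_genes,
        "n_studies": n_studies,
        "max_pi_error": float(pi_err.max()),
        "pp_precision": precision,
        "n_pp_calls": int(calls.sum()),
        "loglik_monotone": bool((diffs >= -1e-8).all()),
        "scales": [mx.scale for mx in fit.mixtures],
        "converged": fit.converged,
    }


def enrichment_null_fpr(
    seed: int,
    n_seeds: int = 100,
    universe_size: int = 10_000,
    query_size: int = 200,
    n_sets: int = 50,
    set_size: int = 30,
    q_threshold: float = 0.05,
):
    """False-positive rate of the enrichment stage on random gene sets."""
    universe = [f"U{i:05d}" for i in range(universe_size)]
    fractions = []
    for s in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 5, s]))
        query = list(rng.choice(universe, size=query_size, replace=False))
        sets = {
            f"S{j:03d}": list(rng.choice(universe, size=set_size, replace=False))
            for j in range(n_sets)
        }
        records = enrich_sets(query, sets, universe=universe, exclude_mhc=False)
        fractions.append(np.mean([r.q < q_threshold for r in records]))
    return {
        "n_seeds": n_seeds,
        "mean_fraction_significant": float(np.mean(fractions)),
        "q_threshold": q_threshold,
    }


def _dir_bytes(root) -> dict[str, bytes]:
    out = {}
    for dirpath, _dirnames, filenames in os.walk(root):
        for fn in filenames:
            path = os.path.join(dirpath, fn)
            with open(path, "rb") as fh:
                out[os.path.relpath(path, root)] = fh.read()
    return out


def end_to_end_recovery(
    seed: int, work_dir, fx: FixtureSpec = FixtureSpec(), check_rerun: bool = True
):
    """Full simulate -> xwas -> concord -> enrich run on the fixture bundle.

    Checks recovery of the planted shared gene (PP > 0.95 in all studies)
    and the planted enriched set (q < 0.05), and byte-identity of a rerun
    with the same master seed.
    """
    run_dirs = [os.path.join(work_dir, "run1")]
    if check_rerun:
        run_dirs.append(os.path.join(work_dir, "run2"))
    results = []
    for rd in run_dirs:
        truth = write_fixture_set(rd, master_seed=seed, fx=fx)
        results.append(pipeline.run_bundle(rd))
    truth = truth  # same in both runs
    res = results[0]
    matrix, pp = res["study_matrix"], res["pp"]
    gi = matrix.genes.index(truth["planted_gene"])
    planted_pp = pp[gi]
    set_q = {r.set_name: r.q for r in res["enrichment"]}
    byte_identical = True
    if check_rerun:
        b1 = _dir_bytes(run_dirs[0])
        b2 = _dir_bytes(run_dirs[1])
        byte_identical = b1.keys() == b2.keys() and all(
            b1[k] == b2[k] for k in b1
        )
    return {
        "planted_gene": truth["planted_gene"],
        "planted_gene_min_pp": float(planted_pp.min()),
        "planted_set_q": float(set_q[truth["planted_set"]]),
        "max_random_set_q": float(
            max(v for k, v in set_q.items() if k != truth["planted_set"])
        ),
        "n_suggestive_union": res["n_suggestive_union"],
        "byte_identical_rerun": bool(byte_identical),
    }
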