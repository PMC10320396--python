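"""Synthetic GWAS/xQTL summary statistics with known ground truth.

The generator emulates the statistical structure of the pipeline's real
inputs at desk scale:

* **LD**: each cis region is a Gaussian-copula haplotype model — latent
  standard normals with AR(1) correlation ``ld_rho`` are thresholded at
  the allele-frequency quantile, and two independent haplotypes sum to a
  diploid dosage in {0, 1, 2}.  The dosage correlation implied by the
  latent model is available analytically (bivariate-normal orthant
  probabilities), so simulated LD has a known truth.
* **Molecular level**: x = b_zx g_c + e_x with standardized dosages and
  unit phenotype variance, giving one strong cis-xQTL at the causal SNP.
* **Trait**: under *causality* y = b_xy x + e_y; under *pleiotropy*
  y = b_xy x + direct_zy g_c + e_y (same variant, two paths); under
  *linkage* y = b_zy g_c2 + e_y with a second causal SNP whose dosage
  correlation with g_c is closest to ``linkage_r``; under *null* y = e_y.
* **Summary statistics**: the *fast path* draws the vector of per-SNP
  marginal estimates directly from its sampling distribution,
  beta_hat ~ N(R beta_marg, D R D / n) with D the per-SNP residual SDs —
  exactly the covariance a per-SNP least-squares scan would have.  The
  *slow path* simulates individuals and runs the per-SNP regressions; it
  serves as the oracle for the fast path.
* **Multi-study gene-level p-values**: genes draw one of 2^J binary
  association patterns; associated entries get t ~ a_true chi2_2 mapped
  back through p = exp(-t/2), null entries are Uniform(0, 1).

All randomness flows from one master seed through
``numpy.random.SeedSequence([master_seed, *tags])`` where the tags name
the region/study/purpose, so every artifact is reproducible and
independent parts have independent streams.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .io_formats import (
    GenotypePanel,
    GwasTable,
    ProbeInfo,
    SnpAssoc,
    XqtlDataset,
    write_gmt,
    write_gwas_table,
    write_genotype_panel,
    write_xqtl_dataset,
)

__all__ = [
    "ScenarioSpec",
    "MultiStudySpec",
    "RegionModel",
    "RegionSummary",
    "build_region_model",
    "latent_to_dosage_corr",
    "make_ld_panel",
    "draw_summary_stats",
    "simulate_individual_region",
    "simulate_summary_region",
    "simulate_pattern_pvalues",
    "write_fixture_set",
    "FixtureSpec",
]

SCENARIOS = ("causal", "pleiotropy", "linkage", "null")

# non-strand-ambiguous allele pairs only; ambiguity handling is exercised
# by dedicated tests, not by default simulations
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class ScenarioSpec:
    """One cis region's generating model.

    Effects are per standard deviation of standardized dosage on a
    unit-variance phenotype; ``b_zx_causal = 0.5`` is a strong cis-xQTL
    (25% of variance), ``b_xy_true = 0.3`` a sizeable mediated effect.
    Under *linkage* the trait-side causal effect is
    ``b_zx_causal * b_xy_true`` so the GWAS signal matches the causal
    scenario's.
    """

    scenario: str = "causal"
    m_snps: int = 30
    maf_low: float = 0.1
    maf_high: float = 0.5
    ld_rho: float = 0.8
    b_xy_true: float = 0.3
    b_zx_causal: float = 0.5
    direct_zy: float = 0.1
    linkage_r: float = 0.6
    n_xqtl: int = 30_000
    n_gwas: int = 100_000
    n_ref: int = 500
    snp_spacing_bp: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0.01 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("maf range must lie in (0.01, 0.5]")
        if not abs(self.ld_rho) < 1:
            raise ValueError("|ld_rho| must be < 1")
        if self.n_ref < 50:
            raise ValueError("n_ref must be >= 50")
        if not abs(self.b_zx_causal) < 1:
            raise ValueError("|b_zx_causal| must be < 1 (unit-variance phenotype)")


@dataclass(frozen=True)
class MultiStudySpec:
    """Generator for a G x J gene-level p-value matrix with planted patterns."""

    n_genes: int = 20_000
    n_studies: int = 3
    pattern_probs: tuple[float, ...] = ()  # length 2^J; empty -> 0.9 null, rest uniform
    alt_scale: float | tuple[float, ...] = 10.0
    seed: int = 0

    def resolved_pattern_probs(self) -> np.ndarray:
        k = 2 ** self.n_studies
        if not self.pattern_probs:
            probs = np.full(k, 0.1 / (k - 1))
            probs[0] = 0.9
            return probs
        probs = np.asarray(self.pattern_probs, dtype=float)
        if probs.size != k or abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
            raise ValueError("pattern_probs must be a length-2^J simplex vector")
        return probs


def _rng(master_seed: int, *tags: int) -> np.random.Generator:
    """Child generator for a named purpose; documented seed-derivation
    scheme: SeedSequence([master, tag1, tag2, ...])."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, tags)]))


# ---------------------------------------------------------------------------
# LD model


def _orthant_upper(c1: float, c2: float, rho: float) -> float:
    """P(Z1 > c1, Z2 > c2) for standard bivariate normal with correlation rho."""
    if abs(rho) < 1e-14:
        return float(stats.norm.sf(c1) * stats.norm.sf(c2))
    if rho > 1 - 1e-12:
        return float(stats.norm.sf(max(c1, c2)))
    if rho < -1 + 1e-12:
        return float(max(0.0, stats.norm.sf(c1) - stats.norm.cdf(c2)))
    s = math.sqrt(1.0 - rho * rho)

    def integrand(z):
        return stats.norm.pdf(z) * stats.norm.sf((c2 - rho * z) / s)

    val, _err = integrate.quad(integrand, c1, np.inf, limit=200)
    return float(val)


def _bvn_upper(h: np.ndarray, k: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """P(Z1 > h, Z2 > k) for standard bivariate normals, vectorized.

    Uses Owen's T representation of the bivariate normal CDF (exact to
    machine precision and fast); ``_orthant_upper`` is the scalar
    quadrature cross-check.
    """
    from scipy.special import owens_t

    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    # P(Z1 > h, Z2 > k) = Phi2(-h, -k; rho); compute Phi2(x, y; rho)
    x, y = -h, -k
    # avoid the removable singularity at x = 0 or y = 0
    x = np.where(np.abs(x) < 1e-12, 1e-12, x)
    y = np.where(np.abs(y) < 1e-12, 1e-12, y)
    r2 = np.sqrt(np.clip(1.0 - rho * rho, 1e-30, None))
    ax = (y - rho * x) / (x * r2)
    ay = (x - rho * y) / (y * r2)
    beta = np.where((x * y < 0) | ((x * y == 0) & (x + y < 0)), 0.5, 0.0)
    phi2 = (
        0.5 * (stats.norm.cdf(x) + stats.norm.cdf(y))
        - owens_t(x, ax)
        - owens_t(y, ay)
        - beta
    )
    phi2 = np.clip(phi2, 0.0, 1.0)
    # degenerate correlations
    lo = np.minimum(stats.norm.cdf(x), stats.norm.cdf(y))
    hi = np.maximum(0.0, stats.norm.cdf(x) + stats.norm.cdf(y) - 1.0)
    phi2 = np.where(rho > 1 - 1e-12, lo, phi2)
    phi2 = np.where(rho < -1 + 1e-12, hi, phi2)
    return phi2


def latent_to_dosage_corr(maf_i, maf_j, rho):
    """Pearson correlation of thresholded-haplotype dosages implied by a
    latent correlation ``rho`` (equal to the allele-indicator correlation;
    summing two independent haplotypes leaves the correlation unchanged)."""
    maf_i = np.asarray(maf_i, dtype=float)
    maf_j = np.asarray(maf_j, dtype=float)
    c_i = stats.norm.isf(maf_i)
    c_j = stats.norm.isf(maf_j)
    p11 = _bvn_upper(c_i, c_j, rho)
    cov = p11 - maf_i * maf_j
    out = cov / np.sqrt(maf_i * (1 - maf_i) * maf_j * (1 - maf_j))
    return float(out) if out.ndim == 0 else out


def analytic_dosage_corr(mafs: np.ndarray, ld_rho: float) -> np.ndarray:
    """Full m x m analytic dosage correlation for the AR(1) latent model."""
    mafs = np.asarray(mafs, dtype=float)
    m = len(mafs)
    ii, jj = np.triu_indices(m, k=1)
    vals = latent_to_dosage_corr(mafs[ii], mafs[jj], ld_rho ** (jj - ii).astype(float))
    r = np.eye(m)
    r[ii, jj] = vals
    r[jj, ii] = vals
    return r


def _sample_dosages(
    mafs: np.ndarray, ld_rho: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n x m diploid dosages from the thresholded AR(1) haplotype model."""
    m = len(mafs)
    cuts = stats.norm.isf(mafs)
    dos = np.zeros((n, m))
    for _hap in range(2):
        z = np.empty((n, m))
        z[:, 0] = rng.standard_normal(n)
        innov_sd = math.sqrt(1.0 - ld_rho ** 2)
        for j in range(1, m):
            z[:, j] = ld_rho * z[:, j - 1] + innov_sd * rng.standard_normal(n)
        dos += (z > cuts[None, :]).astype(float)
    return dos


# ---------------------------------------------------------------------------
# region model


@dataclass
class RegionModel:
    """Deterministic part of one cis region: SNP map, LD, true marginals."""

    spec: ScenarioSpec
    probe: ProbeInfo
    snp_ids: list[str]
    positions: np.ndarray
    alleles: list[tuple[str, str]]
    mafs: np.ndarray
    R: np.ndarray  # analytic dosage correlation
    beta_x: np.ndarray  # true per-SNP marginal xQTL effects
    beta_y: np.ndarray  # true per-SNP marginal GWAS effects
    causal: int
    causal2: int | None


@dataclass
class RegionSummary:
    """One draw of summary statistics for a region (both roles)."""

    model: RegionModel
    bhat_x: np.ndarray
    se_x: np.ndarray
    p_x: np.ndarray
    bhat_y: np.ndarray
    se_y: np.ndarray
    p_y: np.ndarray

    def xqtl_records(self) -> list[SnpAssoc]:
        mdl = self.model
        return [
            SnpAssoc(
                snp_id=mdl.snp_ids[j],
                a1=mdl.alleles[j][0],
                a2=mdl.alleles[j][1],
                freq=float(mdl.mafs[j]),
                beta=float(self.bhat_x[j]),
                se=float(self.se_x[j]),
                p=float(self.p_x[j]),
                n=mdl.spec.n_xqtl,
                chrom=mdl.probe.chrom,
                pos=int(mdl.positions[j]),
            )
            for j in range(len(mdl.snp_ids))
        ]

    def gwas_records(self) -> list[SnpAssoc]:
        mdl = self.model
        return [
            SnpAssoc(
                snp_id=mdl.snp_ids[j],
                a1=mdl.alleles[j][0],
                a2=mdl.alleles[j][1],
                freq=float(mdl.mafs[j]),
                beta=float(self.bhat_y[j]),
                se=float(self.se_y[j]),
                p=float(self.p_y[j]),
                n=mdl.spec.n_gwas,
                chrom=mdl.probe.chrom,
                pos=int(mdl.positions[j]),
            )
            for j in range(len(mdl.snp_ids))
        ]


def build_region_model(
    spec: ScenarioSpec,
    probe_id: str = "probe1",
    gene: str = "GENE1",
    chrom: str = "1",
    probe_pos: int = 10_000_000,
    paradigm: str = "expression",
    region_tag: int = 0,
) -> RegionModel:
    """Draw the fixed part of a region (MAFs, alleles, truth) and compute
    its analytic LD and true marginal effects."""
    rng = _rng(spec.seed, 1, region_tag)
    m = spec.m_snps
    mafs = rng.uniform(spec.maf_low, spec.maf_high, size=m)
    alleles = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=m)]
    start = probe_pos - (m // 2) * spec.snp_spacing_bp
    positions = start + np.arange(m) * spec.snp_spacing_bp
    R = analytic_dosage_corr(mafs, spec.ld_rho)
    causal = m // 2
    causal2: int | None = None
    beta_x = spec.b_zx_causal * R[:, causal]
    if spec.scenario == "null":
        beta_y = np.zeros(m)
    elif spec.scenario == "causal":
        beta_y = spec.b_xy_true * spec.b_zx_causal * R[:, causal]
    elif spec.scenario == "pleiotropy":
        beta_y = (spec.b_xy_true * spec.b_zx_causal + spec.direct_zy) * R[:, causal]
    else:  # linkage: a second causal variant for the trait
        others = [j for j in range(m) if j != causal]
        causal2 = min(others, key=lambda j: abs(R[causal, j] - spec.linkage_r))
        b_zy = spec.b_zx_causal * spec.b_xy_true
        beta_y = b_zy * R[:, causal2]
    probe = ProbeInfo(
        probe_id=probe_id, gene=gene, chrom=chrom, probe_pos=probe_pos, paradigm=paradigm
    )
    return RegionModel(
        spec=spec,
        probe=probe,
        snp_ids=[f"rs{region_tag}_{j:02d}" for j in range(m)],
        positions=positions,
        alleles=alleles,
        mafs=mafs,
        R=R,
        beta_x=beta_x,
        beta_y=beta_y,
        causal=causal,
        causal2=causal2,
    )


def _marginal_from_joint(model: RegionModel):
    """True marginal coefficient vectors and per-SNP residual SDs.

    The stored beta_x/beta_y are already marginal (R beta_joint); the
    residual SD of the per-SNP regression is sqrt(1 - beta_marg^2) for a
    unit-variance phenotype and standardized dosage.
    """
    sd_x = np.sqrt(np.clip(1.0 - model.beta_x ** 2, 0.05, None))
    sd_y = np.sqrt(np.clip(1.0 - model.beta_y ** 2, 0.05, None))
    return sd_x, sd_y


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return np.clip(stats.chi2.sf(z * z, df=1), 1e-300, 1.0)


def draw_summary_stats(model: RegionModel, rng: np.random.Generator) -> RegionSummary:
    """Fast path: draw per-SNP marginal estimates for both roles from
    their joint sampling distribution, beta_hat ~ N(beta, D R D / n)."""
    sd_x, sd_y = _marginal_from_joint(model)
    L = np.linalg.cholesky(model.R + 1e-10 * np.eye(len(model.snp_ids)))
    bhat_x = model.beta_x + sd_x * (L @ rng.standard_normal(L.shape[0])) / math.sqrt(
        model.spec.n_xqtl
    )
    bhat_y = model.beta_y + sd_y * (L @ rng.standard_normal(L.shape[0])) / math.sqrt(
        model.spec.n_gwas
    )
    se_x = sd_x / math.sqrt(model.spec.n_xqtl)
    se_y = sd_y / math.sqrt(model.spec.n_gwas)
    return RegionSummary(
        model=model,
        bhat_x=bhat_x,
        se_x=se_x,
        p_x=_two_sided_p(bhat_x / se_x),
        bhat_y=bhat_y,
        se_y=se_y,
        p_y=_two_sided_p(bhat_y / se_y),
    )


def _per_snp_ols(g_std: np.ndarray, pheno: np.ndarray):
    """Marginal least squares of a phenotype on each standardized dosage."""
    n = g_std.shape[0]
    bhat = g_std.T @ pheno / n
    resid_var = np.maximum(pheno.var() - bhat ** 2, 1e-12)
    se = np.sqrt(resid_var / n)
    return bhat, se


def simulate_individual_region(model: RegionModel, rng: np.random.Generator) -> RegionSummary:
    """Slow path: simulate individuals and run per-SNP regressions.

    The xQTL and GWAS cohorts are drawn independently (two-sample design).
    """
    spec = model.spec

    def cohort(n: int, make_pheno) -> tuple[np.ndarray, np.ndarray]:
        dos = _sample_dosages(model.mafs, spec.ld_rho, n, rng)
        sd = dos.std(axis=0)
        sd[sd == 0] = 1.0
        g = (dos - dos.mean(axis=0)) / sd
        return _per_snp_ols(g, make_pheno(g))

    def pheno_x(g):
        e = rng.standard_normal(g.shape[0]) * math.sqrt(1.0 - spec.b_zx_causal ** 2)
        return spec.b_zx_causal * g[:, model.causal] + e

    def pheno_y(g):
        x = pheno_x(g)
        if spec.scenario == "null":
            return rng.standard_normal(g.shape[0])
        if spec.scenario == "causal":
            ey = rng.standard_normal(g.shape[0]) * math.sqrt(1.0 - spec.b_xy_true ** 2)
            return spec.b_xy_true * x + ey
        if spec.scenario == "pleiotropy":
            raw = spec.b_xy_true * x + spec.direct_zy * g[:, model.causal]
            ey = rng.standard_normal(g.shape[0])
            return raw + ey
        b_zy = spec.b_zx_causal * spec.b_xy_true
        ey = rng.standard_normal(g.shape[0]) * math.sqrt(1.0 - b_zy ** 2)
        return b_zy * g[:, model.causal2] + ey

    bhat_x, se_x = cohort(spec.n_xqtl, pheno_x)
    bhat_y, se_y = cohort(spec.n_gwas, pheno_y)
    return RegionSummary(
        model=model,
        bhat_x=bhat_x,
        se_x=se_x,
        p_x=_two_sided_p(bhat_x / se_x),
        bhat_y=bhat_y,
        se_y=se_y,
        p_y=_two_sided_p(bhat_y / se_y),
    )


def make_ld_panel(
    spec: ScenarioSpec, model: RegionModel | None = None, panel_tag: int = 2
) -> tuple[GenotypePanel, np.ndarray]:
    """Sample a reference dosage panel and return it with the analytic
    dosage correlation of the generating model."""
    if model is None:
        model = build_region_model(spec)
    rng = _rng(spec.seed, panel_tag)
    dos = _sample_dosages(model.mafs, spec.ld_rho, spec.n_ref, rng)
    meta = pd.DataFrame(
        {
            "snp_id": model.snp_ids,
            "chrom": model.probe.chrom,
            "pos": model.positions.astype(int),
            "a1": [a for a, _ in model.alleles],
            "a2": [b for _, b in model.alleles],
        }
    )
    return GenotypePanel(dosages=dos, meta=meta), model.R.copy()


def simulate_summary_region(
    spec: ScenarioSpec, region_tag: int = 0, fast: bool = True, **model_kwargs
):
    """Convenience wrapper: build the region model and draw one summary
    replicate.  Returns (summary, truth dict)."""
    model = build_region_model(spec, region_tag=region_tag, **model_kwargs)
    rng = _rng(spec.seed, 3, region_tag)
    summ = draw_summary_stats(model, rng) if fast else simulate_individual_region(model, rng)
    truth = {
        "scenario": spec.scenario,
        "b_xy_true": spec.b_xy_true if spec.scenario in ("causal", "pleiotropy") else 0.0,
        "causal_snp": model.snp_ids[model.causal],
        "causal_snp2": None if model.causal2 is None else model.snp_ids[model.causal2],
    }
    return summ, truth


# ---------------------------------------------------------------------------
# multi-study gene-level p-values


def simulate_pattern_pvalues(spec: MultiStudySpec):
    """G x J p-value matrix with per-gene planted association patterns.

    Returns (StudyMatrix-ready dict, labels): ``P`` the matrix, ``genes``,
    ``studies``, and ``labels`` the integer pattern index of each gene.
    """
    from .concordance import StudyMatrix, pattern_matrix

    probs = spec.resolved_pattern_probs()
    j = spec.n_studies
    scales = np.broadcast_to(np.asarray(spec.alt_scale, dtype=float), (j,))
    rng = _rng(spec.seed, 4)
    q = pattern_matrix(j)
    labels = rng.choice(len(probs), size=spec.n_genes, p=probs)
    is_alt = q[labels]  # G x J
    p_null = rng.uniform(size=(spec.n_genes, j))
    t_alt = scales[None, :] * rng.chisquare(2.0, size=(spec.n_genes, j))
    p_alt = np.clip(np.exp(-t_alt / 2.0), 1e-300, 1.0)
    P = np.where(is_alt > 0, p_alt, p_null)
    P = np.clip(P, 1e-300, 1.0)
    genes = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    studies = [f"study{s + 1}" for s in range(j)]
    return StudyMatrix(genes=genes, studies=studies, P=P), labels


# ---------------------------------------------------------------------------
# complete fixture bundle


@dataclass(frozen=True)
class FixtureSpec:
    """Layout of the default end-to-end fixture bundle.

    Three studies share one xQTL dataset and LD panel (as tissues share a
    reference) and draw independent GWAS cohorts; study B is emitted as a
    case-control scan (odds-ratio column) to exercise the log-OR path.
    Scenario labels are shared across studies, so causal genes are
    associated everywhere — including one designated planted gene — and a
    planted gene set collects 20 causal genes.
    """

    n_causal: int = 100
    n_linkage: int = 50
    n_null: int = 50
    studies: tuple[str, ...] = ("studyA", "studyB", "studyC")
    m_snps: int = 25
    n_ref: int = 500
    n_gwas: int = 100_000
    n_xqtl: int = 30_000
    universe_size: int = 10_000
    planted_set_size: int = 30
    planted_set_causal: int = 20
    n_random_sets: int = 9
    random_set_size: int = 30

    @property
    def n_probes(self) -> int:
        return self.n_causal + self.n_linkage + self.n_null


def _region_scenarios(fx: FixtureSpec) -> list[str]:
    return (
        ["causal"] * fx.n_causal + ["linkage"] * fx.n_linkage + ["null"] * fx.n_null
    )


def write_fixture_set(out_dir, master_seed: int = 0, fx: FixtureSpec = FixtureSpec()):
    """Emit a complete, self-consistent input bundle plus truth manifest.

    Files written: ``gwas_<study>.ma`` per study, ``xqtl_effects.tsv`` +
    ``probe_annot.tsv``, ``panel.tsv``, ``gene_annot.tsv``,
    ``universe.txt``, ``sets.gmt``, and ``truth.json``.
    """
    os.makedirs(out_dir, exist_ok=True)
    scenarios = _region_scenarios(fx)
    n = fx.n_probes

    # gene map: first 20 causal probes pair into 10 two-probe genes; the
    # last 10 null probes carry no gene symbol
    genes: list[str] = []
    for i in range(n):
        if i < 20:
            genes.append(f"G{i // 2 + 1:04d}")
        elif i >= n - 10:
            genes.append("")
        else:
            genes.append(f"G{i - 10 + 1:04d}")
    planted_gene = "G0001"

    probes: dict[str, ProbeInfo] = {}
    effects: dict[str, list[SnpAssoc]] = {}
    gwas_tables = {s: {} for s in fx.studies}
    panel_blocks = []
    panel_meta = []
    truth_regions = {}
    for i, scen in enumerate(scenarios):
        chrom = str(i % 22 + 1)
        probe_pos = 10_000_000 + (i // 22) * 6_000_000
        spec = ScenarioSpec(
            scenario=scen,
            m_snps=fx.m_snps,
            n_ref=fx.n_ref,
            n_gwas=fx.n_gwas,
            n_xqtl=fx.n_xqtl,
            seed=master_seed,
        )
        model = build_region_model(
            spec,
            probe_id=f"PRB{i + 1:04d}",
            gene=genes[i],
            chrom=chrom,
            probe_pos=probe_pos,
            region_tag=i,
        )
        # shared xQTL statistics for all studies
        xq = draw_summary_stats(model, _rng(master_seed, 10, i))
        probes[model.probe.probe_id] = model.probe
        effects[model.probe.probe_id] = xq.xqtl_records()
        # independent GWAS draw per study (re-using the xQTL stats of xq
        # would couple the roles; only bhat_y is taken from these draws)
        for s_idx, study in enumerate(fx.studies):
            gw = draw_summary_stats(model, _rng(master_seed, 11, i, s_idx))
            for rec in gw.gwas_records():
                gwas_tables[study][rec.snp_id] = rec
        pan_dos = _sample_dosages(model.mafs, spec.ld_rho, fx.n_ref, _rng(master_seed, 12, i))
        panel_blocks.append(pan_dos)
        panel_meta.append(
            pd.DataFrame(
                {
                    "snp_id": model.snp_ids,
                    "chrom": chrom,
                    "pos": model.positions.astype(int),
                    "a1": [a for a, _ in model.alleles],
                    "a2": [b for _, b in model.alleles],
                }
            )
        )
        truth_regions[model.probe.probe_id] = {
            "scenario": scen,
            "gene": genes[i],
            "b_xy_true": spec.b_xy_true if scen == "causal" else 0.0,
            "causal_snp": model.snp_ids[model.causal],
        }

    panel = GenotypePanel(
        dosages=np.hstack(panel_blocks), meta=pd.concat(panel_meta, ignore_index=True)
    )
    write_genotype_panel(panel, os.path.join(out_dir, "panel.tsv"))
    ds = XqtlDataset(probes=probes, effects=effects)
    write_xqtl_dataset(
        ds,
        os.path.join(out_dir, "xqtl_effects.tsv"),
        os.path.join(out_dir, "probe_annot.tsv"),
    )
    case_control_study = fx.studies[1] if len(fx.studies) > 1 else None
    for study in fx.studies:
        table = GwasTable(snps=gwas_tables[study], is_case_control=study == case_control_study)
        write_gwas_table(
            table,
            os.path.join(out_dir, f"gwas_{study}.ma"),
            effect_is_or=study == case_control_study,
        )

    # gene universe, coordinates, and gene sets
    tested_genes = sorted({g for g in genes if g})
    filler = [f"U{i + 1:05d}" for i in range(fx.universe_size - len(tested_genes))]
    universe = tested_genes + filler
    with open(os.path.join(out_dir, "universe.txt"), "w") as fh:
        fh.write("\n".join(universe) + "\n")
    annot_rows = []
    gene_seen = set()
    for i in range(n):
        g = genes[i]
        if g and g not in gene_seen:
            gene_seen.add(g)
            annot_rows.append((g, str(i % 22 + 1), 10_000_000 + (i // 22) * 6_000_000))
    for j, g in enumerate(filler):
        annot_rows.append((g, "1", 200_000_000 + j * 1_000))
    with open(os.path.join(out_dir, "gene_annot.tsv"), "w") as fh:
        fh.write("gene\tchrom\tstart\n")
        for g, c, s in annot_rows:
            fh.write(f"{g}\t{c}\t{s}\n")

    causal_genes = sorted({genes[i] for i in range(fx.n_causal) if genes[i]})
    rng_sets = _rng(master_seed, 13)
    planted = causal_genes[: fx.planted_set_causal] + list(
        rng_sets.choice(filler, size=fx.planted_set_size - fx.planted_set_causal, replace=False)
    )
    sets = {"SET_PLANTED": sorted(planted)}
    for k in range(fx.n_random_sets):
        members = rng_sets.choice(filler, size=fx.random_set_size, replace=False)
        sets[f"SET_RANDOM{k + 1:02d}"] = sorted(members)
    write_gmt(sets, os.path.join(out_dir, "sets.gmt"))

    # ready-to-run TOML config per study (paths relative to the bundle dir)
    for study in fx.studies:
        cc = study == case_control_study
        with open(os.path.join(out_dir, f"run_{study}.toml"), "w") as fh:
            fh.write(
                "[inputs]\n"
                f'gwas = "gwas_{study}.ma"\n'
                f"gwas_is_case_control = {str(cc).lower()}\n"
                f"gwas_effect_is_or = {str(cc).lower()}\n"
                'xqtl_effects = "xqtl_effects.tsv"\n'
                'probe_annot = "probe_annot.tsv"\n'
                'panel = "panel.tsv"\n\n'
                f'[study]\nlabel = "{study}"\n\n'
                f'[output]\ndir = "out/{study}"\n'
            )

    truth = {
        "master_seed": master_seed,
        "studies": list(fx.studies),
        "case_control_study": case_control_study,
        "planted_gene": planted_gene,
        "planted_set": "SET_PLANTED",
        "n_probes": n,
        "fixture": asdict(fx),
        "regions": truth_regions,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
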