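"""Per-probe causal-association inference from two-sample summary statistics.

The analysis asks, for each molecular probe (transcript, protein, CpG),
whether its level mediates genetic risk for a trait.  With b_zx the effect
of an instrument SNP on the molecular level and b_zy its effect on the
trait, the Wald ratio b_xy = b_zy / b_zx estimates the effect of the level
on the trait, and the SMR statistic

    T_SMR = z_zx^2 z_zy^2 / (z_zx^2 + z_zy^2)  ~  chi2_1 under H0: b_xy = 0

tests it using only the top cis instrument.  A significant T_SMR is
compatible with either a single shared causal variant (causality or
pleiotropy) or with two distinct variants in LD (linkage).  The HEIDI test
discriminates these by checking whether Wald ratios computed at multiple
LD-linked instruments are homogeneous: under a single shared causal
variant every instrument estimates the same b_xy, while linkage makes the
ratios drift with LD.

The two cohorts (xQTL and GWAS) are assumed non-overlapping, so b_zx and
b_zy estimates are independent; LD r comes from a reference dosage panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .gene_level import adjust_for_heidi
from .io_formats import (
    AMBIGUOUS_PAIRS,
    GenotypePanel,
    GwasTable,
    ProbeInfo,
    SmrRecord,
    SnpAssoc,
)

__all__ = [
    "SmrConfig",
    "AlignedSnp",
    "AlignedRegion",
    "SmrRecord",
    "harmonize_region",
    "select_top_instrument",
    "wald_ratio",
    "smr_test",
    "select_heidi_snps",
    "heidi_test",
    "run_probe",
    "run_dataset",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmrConfig:
    """Analysis parameters.

    Defaults follow standard SMR practice: a 2 Mb cis window, genome-wide
    instrument threshold, HEIDI instruments admitted at p < 1.57e-3
    (chi2_1 > 10) and pruned against the top SNP at r^2 > 0.9 / < 0.05,
    between 3 and 20 HEIDI SNPs, a 15% allele-frequency mismatch filter,
    and no SMR p-value penalty once p_HEIDI >= 0.01.
    """

    cis_window_bp: int = 2_000_000
    instrument_p: float = 5e-8
    heidi_select_p: float = 1.57e-3
    heidi_min: int = 3
    heidi_max: int = 20
    prune_r2_high: float = 0.9
    prune_r2_low: float = 0.05
    freq_mismatch: float = 0.15
    heidi_adjust_floor: float = 0.01
    heidi_tail_method: str = "imhof"  # or "satterthwaite" / "montecarlo"
    heidi_mc_draws: int = 100_000
    heidi_mc_seed: int = 20_230_803
    heidi_ridge: float = 1e-8

    def __post_init__(self) -> None:
        if not 0 < self.prune_r2_low < self.prune_r2_high <= 1:
            raise ValueError("need 0 < prune_r2_low < prune_r2_high <= 1")
        if self.heidi_min < 3:
            raise ValueError("heidi_min must be >= 3")
        if self.heidi_tail_method not in ("imhof", "satterthwaite", "montecarlo"):
            raise ValueError(f"unknown heidi_tail_method {self.heidi_tail_method!r}")


@dataclass(frozen=True)
class AlignedSnp:
    """A SNP present in GWAS, xQTL and LD panel, on one effect allele."""

    snp_id: str
    pos: int
    a1: str
    a2: str
    b_zx: float
    se_zx: float
    p_zx: float
    b_zy: float
    se_zy: float
    p_zy: float
    freq_gwas: float
    freq_xqtl: float
    freq_ref: float


@dataclass
class AlignedRegion:
    """A probe's cis region after harmonization.

    ``ld`` is the reference-panel Pearson r restricted to the surviving
    SNPs, sign-corrected so that every correlation refers to the shared
    effect alleles.
    """

    probe: ProbeInfo
    snps: list[AlignedSnp]
    ld: np.ndarray
    counters: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snps)


def _maf(f: float) -> float:
    return min(f, 1.0 - f)


def harmonize_region(
    probe: ProbeInfo,
    gwas: GwasTable,
    xqtl_snps: Sequence[SnpAssoc],
    panel: GenotypePanel,
    config: SmrConfig = SmrConfig(),
) -> AlignedRegion:
    """Align GWAS, xQTL and panel records of one cis region on a common
    effect allele.

    The xQTL a1 defines the effect allele.  Records whose alleles are
    swapped get beta negated and freq reflected; strand-ambiguous (A/T,
    C/G) SNPs are dropped, as are SNPs outside the cis window, SNPs with
    incompatible allele sets, monomorphic panel SNPs, and SNPs whose
    minor-allele frequencies disagree by more than ``freq_mismatch``
    between any two sources.  Per-rule drop counts are kept in
    ``region.counters``.
    """
    counters = {
        "snps_total": len(xqtl_snps),
        "outside_cis_window": 0,
        "missing_in_gwas": 0,
        "missing_in_panel": 0,
        "strand_ambiguous": 0,
        "allele_mismatch": 0,
        "monomorphic_panel": 0,
        "freq_mismatch": 0,
        "kept": 0,
    }
    kept: list[AlignedSnp] = []
    ref_signs: list[float] = []
    for xq in xqtl_snps:
        if xq.pos is None or abs(xq.pos - probe.probe_pos) > config.cis_window_bp:
            counters["outside_cis_window"] += 1
            continue
        if (xq.a1, xq.a2) in AMBIGUOUS_PAIRS:
            counters["strand_ambiguous"] += 1
            continue
        gw = gwas.get(xq.snp_id)
        if gw is None:
            counters["missing_in_gwas"] += 1
            continue
        if not panel.has(xq.snp_id):
            counters["missing_in_panel"] += 1
            continue
        # orient GWAS record to the xQTL effect allele
        if (gw.a1, gw.a2) == (xq.a1, xq.a2):
            pass
        elif (gw.a1, gw.a2) == (xq.a2, xq.a1):
            gw = gw.flipped()
        else:
            counters["allele_mismatch"] += 1
            continue
        # orient the panel column
        j = panel.index[xq.snp_id]
        pa1 = panel.meta["a1"].iat[j]
        pa2 = panel.meta["a2"].iat[j]
        if (pa1, pa2) == (xq.a1, xq.a2):
            sign, f_ref = 1.0, panel.freq(xq.snp_id)
        elif (pa1, pa2) == (xq.a2, xq.a1):
            sign, f_ref = -1.0, 1.0 - panel.freq(xq.snp_id)
        else:
            counters["allele_mismatch"] += 1
            continue
        if panel.monomorphic[j]:
            counters["monomorphic_panel"] += 1
            continue
        mafs = [_maf(gw.freq), _maf(xq.freq), _maf(f_ref)]
        if max(mafs) - min(mafs) > config.freq_mismatch:
            counters["freq_mismatch"] += 1
            continue
        kept.append(
            AlignedSnp(
                snp_id=xq.snp_id,
                pos=int(xq.pos),
                a1=xq.a1,
                a2=xq.a2,
                b_zx=xq.beta,
                se_zx=xq.se,
                p_zx=xq.p,
                b_zy=gw.beta,
                se_zy=gw.se,
                p_zy=gw.p,
                freq_gwas=gw.freq,
                freq_xqtl=xq.freq,
                freq_ref=f_ref,
            )
        )
        ref_signs.append(sign)
    counters["kept"] = len(kept)
    if kept:
        s = np.asarray(ref_signs)
        ld = panel.correlation([a.snp_id for a in kept]) * np.outer(s, s)
    else:
        ld = np.zeros((0, 0))
    return AlignedRegion(probe=probe, snps=kept, ld=ld, counters=counters)


def select_top_instrument(region: AlignedRegion, config: SmrConfig = SmrConfig()):
    """Index of the top cis instrument, or None when no SNP reaches the
    instrument threshold.  Ties on p are broken by larger \\|z_zx\\|, then
    smaller position."""
    best = None
    best_key = None
    for i, s in enumerate(region.snps):
        key = (s.p_zx, -abs(s.b_zx / s.se_zx), s.pos)
        if best_key is None or key < best_key:
            best, best_key = i, key
    if best is None or region.snps[best].p_zx >= config.instrument_p:
        return None
    return best


def wald_ratio(b_zx: float, se_zx: float, b_zy: float, se_zy: float):
    """Wald-ratio estimate b_xy = b_zy / b_zx with first-order delta SE.

    se_xy = |b_xy| sqrt(se_zy^2/b_zy^2 + se_zx^2/b_zx^2); when b_zy = 0
    the delta form degenerates and se_xy = se_zy / |b_zx|.
    """
    if b_zx == 0:
        raise ZeroDivisionError("undefined instrument: b_zx = 0")
    b_xy = b_zy / b_zx
    if b_zy == 0:
        return 0.0, se_zy / abs(b_zx)
    se_xy = abs(b_xy) * np.sqrt((se_zy / b_zy) ** 2 + (se_zx / b_zx) ** 2)
    return float(b_xy), float(se_xy)


def smr_test(z_zx: float, z_zy: float):
    """SMR chi-square statistic and p-value.

    T_SMR = z_zx^2 z_zy^2 / (z_zx^2 + z_zy^2), referred to chi2_1.
    """
    zx2 = z_zx * z_zx
    zy2 = z_zy * z_zy
    if zx2 == 0:
        raise ZeroDivisionError("undefined instrument: z_zx = 0")
    t = zx2 * zy2 / (zx2 + zy2)
    # chi2.sf underflows to 0 beyond ~1e-308; keep p in (0, 1]
    return float(t), float(max(stats.chi2.sf(t, df=1), 1e-300))


def select_heidi_snps(
    region: AlignedRegion, top: int, config: SmrConfig = SmrConfig()
) -> list[int]:
    """Instrument set for HEIDI (excluding the top SNP).

    Candidates have p_zx < ``heidi_select_p``; SNPs with r^2 > 0.9 or
    < 0.05 against the top SNP are pruned; among mutually near-duplicate
    candidates (r^2 > 0.9) the smaller p_zx survives; at most
    ``heidi_max`` SNPs are kept (smallest p_zx) and fewer than
    ``heidi_min`` yields the empty set (HEIDI skipped).
    """
    r = region.ld
    cands = []
    for i, s in enumerate(region.snps):
        if i == top or not s.p_zx < config.heidi_select_p:
            continue
        r2_top = r[i, top] ** 2
        if np.isnan(r2_top) or r2_top > config.prune_r2_high or r2_top < config.prune_r2_low:
            continue
        cands.append(i)
    # greedy near-duplicate pruning in order of ascending p_zx keeps the
    # better-powered member of each r^2 > prune_r2_high pair
    cands.sort(key=lambda i: (region.snps[i].p_zx,
                              -abs(region.snps[i].b_zx / region.snps[i].se_zx),
                              region.snps[i].pos))
    chosen: list[int] = []
    for i in cands:
        if any(r[i, j] ** 2 > config.prune_r2_high for j in chosen):
            continue
        chosen.append(i)
        if len(chosen) == config.heidi_max:
            break
    if len(chosen) < config.heidi_min:
        return []
    return chosen


class HeidiNumericalError(RuntimeError):
    """Covariance of ratio differences is not usable even after ridging."""


def _imhof_sf(t: float, lam: np.ndarray) -> float:
    """Imhof (1961) inversion of the characteristic function of
    sum_k lam_k chi2_1: P(Q > t) = 1/2 + (1/pi) int_0^inf
    sin(theta(u)) / (u rho(u)) du, deterministic and accurate through the
    tails relevant here."""
    import warnings

    from scipy.integrate import IntegrationWarning, quad

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * t * u
        rho = np.prod(1.0 + (lam * u) ** 2) ** 0.25
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        # absolute accuracy ~1e-9 is orders beyond what the test needs;
        # the oscillatory tail sometimes trips the subdivision heuristic
        warnings.simplefilter("ignore", IntegrationWarning)
        val, _err = quad(integrand, 0.0, np.inf, limit=120, epsabs=1e-9, epsrel=1e-7)
    return 0.5 + val / np.pi


def _weighted_chi2_sf(t: float, lam: np.ndarray, config: SmrConfig) -> float:
    """Upper tail of sum_k lam_k chi2_1 at t.

    The default is exact Imhof characteristic-function inversion; a
    Satterthwaite two-moment approximation (scale a = sum lam^2 /
    sum lam, dof nu = (sum lam)^2 / sum lam^2, accurate in the bulk but
    optimistic beyond p ~ 1e-3 for concentrated spectra) and a fixed-seed
    Monte-Carlo estimate are available via config.  Equal weights reduce
    to the plain chi-square tail exactly in every mode but montecarlo.
    """
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    if config.heidi_tail_method == "montecarlo":
        rng = np.random.default_rng(config.heidi_mc_seed)
        draws = rng.chisquare(1.0, size=(config.heidi_mc_draws, lam.size)) @ lam
        return float((np.count_nonzero(draws >= t) + 1) / (config.heidi_mc_draws + 1))
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        return float(stats.chi2.sf(t / lam[0], df=lam.size))
    if config.heidi_tail_method == "imhof":
        return float(min(max(_imhof_sf(t, lam), 0.0), 1.0))
    s1 = float(lam.sum())
    s2 = float((lam ** 2).sum())
    a = s2 / s1
    nu = s1 ** 2 / s2
    return float(stats.chi2.sf(t / a, df=nu))


def heidi_test(
    region: AlignedRegion,
    top: int,
    snp_set: Sequence[int],
    config: SmrConfig = SmrConfig(),
):
    """HEIDI heterogeneity test against the top instrument.

    For each instrument i the Wald ratio b_i = b_zy,i / b_zx,i is compared
    with the top-SNP ratio; under a single shared causal variant all d_i =
    b_i - b_top vanish in expectation.  The covariance of the d vector is
    assembled from the summary-statistic standard errors and the LD r
    matrix (xQTL and GWAS cohorts independent), each standardized
    difference contributes z_i^2 to T_HEIDI, and the null distribution of
    T_HEIDI = sum z_i^2 is the eigenvalue-weighted chi-square implied by
    the correlation of d.

    Returns (t_heidi, p_heidi, nsnp) with nsnp counting the top SNP.
    Raises HeidiNumericalError when Cov(d) is not positive definite after
    ridging.
    """
    idx = [top] + list(snp_set)
    b_zx = np.array([region.snps[i].b_zx for i in idx])
    se_zx = np.array([region.snps[i].se_zx for i in idx])
    b_zy = np.array([region.snps[i].b_zy for i in idx])
    se_zy = np.array([region.snps[i].se_zy for i in idx])
    r = region.ld[np.ix_(idx, idx)]
    if np.isnan(r).any():
        raise HeidiNumericalError("LD matrix contains NaN")
    b = b_zy / b_zx
    # Cov(b_i, b_j) = r_ij (se_zy_i se_zy_j + b_i b_j se_zx_i se_zx_j) / (b_zx_i b_zx_j)
    num = np.outer(se_zy, se_zy) + np.outer(b, b) * np.outer(se_zx, se_zx)
    cov_b = r * num / np.outer(b_zx, b_zx)
    m = len(idx) - 1
    d = b[1:] - b[0]
    cov_d = (
        cov_b[1:, 1:]
        - cov_b[1:, [0]]
        - cov_b[[0], 1:]
        + cov_b[0, 0]
    )
    cov_d = cov_d + config.heidi_ridge * np.eye(m)
    var_d = np.diag(cov_d)
    if np.any(var_d <= 0):
        raise HeidiNumericalError("non-positive variance of ratio difference")
    sd = np.sqrt(var_d)
    corr_d = cov_d / np.outer(sd, sd)
    lam = np.linalg.eigvalsh(corr_d)
    if lam[0] < -1e-8 * max(1.0, lam[-1]):
        raise HeidiNumericalError("Cov(d) not positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    z = d / sd
    t = float(z @ z)
    p = 1.0 if t < 1e-12 else _weighted_chi2_sf(t, lam, config)
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return t, p, m + 1


def run_probe(
    probe: ProbeInfo,
    gwas: GwasTable,
    xqtl_snps: Sequence[SnpAssoc],
    panel: GenotypePanel,
    config: SmrConfig = SmrConfig(),
) -> SmrRecord | None:
    """Full per-probe analysis: harmonize, pick the top instrument, SMR
    test, HEIDI test, HEIDI-penalized p-value.

    Returns None when no SNP reaches the instrument threshold.
    """
    region = harmonize_region(probe, gwas, xqtl_snps, panel, config)
    return run_region(region, config)


def run_region(region: AlignedRegion, config: SmrConfig = SmrConfig()) -> SmrRecord | None:
    top = select_top_instrument(region, config)
    if top is None:
        return None
    s = region.snps[top]
    b_xy, se_xy = wald_ratio(s.b_zx, s.se_zx, s.b_zy, s.se_zy)
    _, p_smr = smr_test(s.b_zx / s.se_zx, s.b_zy / s.se_zy)
    snp_set = select_heidi_snps(region, top, config)
    p_heidi: float | None = None
    nsnp: int | None = None
    if snp_set:
        try:
            _, p_heidi, nsnp = heidi_test(region, top, snp_set, config)
        except HeidiNumericalError:
            log.warning("HEIDI failed numerically for probe %s", region.probe.probe_id)
            p_heidi, nsnp = None, None
    p_adj = adjust_for_heidi(p_smr, p_heidi, floor=config.heidi_adjust_floor)
    return SmrRecord(
        probe_id=region.probe.probe_id,
        probe_chrom=region.probe.chrom,
        gene=region.probe.gene,
        probe_pos=region.probe.probe_pos,
        top_snp=s.snp_id,
        a1=s.a1,
        a2=s.a2,
        freq=s.freq_xqtl,
        b_gwas=s.b_zy,
        se_gwas=s.se_zy,
        p_gwas=s.p_zy,
        b_xqtl=s.b_zx,
        se_xqtl=s.se_zx,
        p_xqtl=s.p_zx,
        b_smr=b_xy,
        se_smr=se_xy,
        p_smr=p_smr,
        p_heidi=p_heidi,
        nsnp_heidi=nsnp,
        p_smr_adj=p_adj,
    )


def run_dataset(gwas, xqtl, panel, config: SmrConfig = SmrConfig()):
    """Run every probe of an XqtlDataset; returns (records, counters).

    ``counters`` aggregates the harmonization drop counts plus probe-level
    tallies (no instrument, HEIDI skipped/failed).
    """
    totals: dict[str, int] = {
        "probes_total": len(xqtl.probes),
        "probes_no_snps": 0,
        "probes_no_instrument": 0,
        "probes_heidi_skipped": 0,
        "probes_heidi_failed": 0,
        "probes_reported": 0,
    }
    records: list[SmrRecord] = []
    for probe_id in sorted(xqtl.probes):
        snps = xqtl.effects.get(probe_id, [])
        if not snps:
            totals["probes_no_snps"] += 1
            continue
        region = harmonize_region(xqtl.probes[probe_id], gwas, snps, panel, config)
        for key, val in region.counters.items():
            totals[f"snp_{key}"] = totals.get(f"snp_{key}", 0) + val
        rec = run_region(region, config)
        if rec is None:
            totals["probes_no_instrument"] += 1
            continue
        if rec.nsnp_heidi is None:
            # distinguish skip (too few instruments) from numeric failure
            if select_heidi_snps(region, select_top_instrument(region, config), config):
                totals["probes_heidi_failed"] += 1
            else:
                totals["probes_heidi_skipped"] += 1
        totals["probes_reported"] += 1
        records.append(rec)
    return records, totals
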