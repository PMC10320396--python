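"""Post-SMR arithmetic: HEIDI penalty, Cauchy combination, thresholds.

Rather than discarding probes with small HEIDI p-values outright (which
over-penalizes regions where reference-panel LD mismatches the GWAS
cohort), the probe SMR p-value is penalized smoothly:

    p'_SMR = p_SMR / min(p_HEIDI / 0.01, 1)

so no penalty applies once p_HEIDI >= 0.01 and the penalty grows as
p_HEIDI falls below it.  Probe-level adjusted p-values are then combined
into one p-value per gene with the Cauchy (ACAT) method, whose null
distribution is standard Cauchy under arbitrary dependence between
probes.  Genes are flagged as suggestive (p < 1/m, the level expected to
be crossed once per scan by chance) and Bonferroni-significant
(p < alpha/m).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneStat, SmrRecord

__all__ = [
    "adjust_for_heidi",
    "cauchy_combine",
    "combine_by_gene",
    "threshold_flags",
    "GeneStat",
]


def adjust_for_heidi(p_smr: float, p_heidi: float | None, floor: float = 0.01) -> float:
    """HEIDI-penalized SMR p-value, capped at 1.

    ``p_heidi`` of None (HEIDI not run) leaves the SMR p unpenalized.
    """
    if not 0.0 < p_smr <= 1.0:
        raise ValueError(f"p_smr must be in (0,1], got {p_smr}")
    if p_heidi is None:
        return p_smr
    if not 0.0 < p_heidi <= 1.0:
        raise ValueError(f"p_heidi must be in (0,1], got {p_heidi}")
    return min(1.0, p_smr / min(p_heidi / floor, 1.0))


_P_TINY = 1e-300
_P_HIGH = 1.0 - 1e-15


def cauchy_combine(p_values: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Cauchy (ACAT) combination of p-values.

    T = sum_i w_i tan((0.5 - p_i) pi) with sum w_i = 1; the combined
    p-value is the standard-Cauchy upper tail of T.  The tangent term is
    evaluated as cot(pi p) = 1/tan(pi p), which is exact and keeps full
    relative precision at both ends of (0, 1); for small p it equals the
    tail expansion w_i/(p_i pi).  Inputs of exactly 1 are clipped just
    below 1 and inputs below 1e-300 to 1e-300 (the representable floor
    before the tangent term overflows).
    """
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        raise ValueError("cauchy_combine needs at least one p-value")
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if weights is None:
        w = np.full(ps.size, 1.0 / ps.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != ps.size or np.any(w < 0):
            raise ValueError("weights must be non-negative and match p_values")
        w = w / w.sum()
    ps = np.clip(ps, _P_TINY, _P_HIGH)
    terms = 1.0 / np.tan(math.pi * ps)
    t = float(w @ terms)
    if t > 1e15:
        return math.atan2(1.0, t) / math.pi  # = atan(1/t)/pi, stable far tail
    return 0.5 - math.atan(t) / math.pi


def combine_by_gene(
    records: Iterable[SmrRecord],
    probe_gene: Mapping[str, str] | None = None,
    study: str = "study",
) -> list[GeneStat]:
    """One Cauchy-combined p-value per gene from probe-level adjusted p.

    ``probe_gene`` overrides the gene symbol carried on each record (used
    when CpG probes are mapped to genes by an external table).  Probes
    without a gene symbol are dropped.  Output is sorted by gene symbol.
    """
    per_gene: dict[str, list[float]] = {}
    for rec in records:
        gene = rec.gene
        if probe_gene is not None:
            gene = probe_gene.get(rec.probe_id, gene)
        if not gene:
            continue
        per_gene.setdefault(gene, []).append(rec.p_smr_adj)
    out = []
    for gene in sorted(per_gene):
        ps = per_gene[gene]
        out.append(
            GeneStat(
                gene=gene,
                study=study,
                p_combined=ps[0] if len(ps) == 1 else cauchy_combine(ps),
                n_probes=len(ps),
            )
        )
    return out


def threshold_flags(
    gene_stats: Iterable[GeneStat], m_tests: int, alpha: float = 0.05
) -> list[GeneStat]:
    """Set suggestive (p < 1/m) and Bonferroni (p < alpha/m) flags.

    ``m_tests`` is the number of tests in the study's scan — probes for
    probe-level flags, mapped genes for gene-level flags; both inequalities
    are strict.
    """
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    out = []
    for g in gene_stats:
        out.append(
            GeneStat(
                gene=g.gene,
                study=g.study,
                p_combined=g.p_combined,
                n_probes=g.n_probes,
                suggestive=g.p_combined < 1.0 / m_tests,
                bonferroni=g.p_combined < alpha / m_tests,
            )
        )
    return out
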