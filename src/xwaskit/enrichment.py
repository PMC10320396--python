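"""Gene-set enrichment of suggestive gene lists.

Hypergeometric over-representation test against a fixed gene universe
(default 54,619 coding and non-coding genes), with optional exclusion of
the MHC region (chr6:25-35 Mb, GRCh37) whose extreme LD produces
clustered spurious signals, and Benjamini-Hochberg FDR across sets
(q < 0.05 by convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Collection, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentRecord",
    "DEFAULT_UNIVERSE_SIZE",
    "MHC_REGION",
    "filter_mhc",
    "hypergeom_test",
    "bh_fdr",
    "enrich_sets",
]

log = logging.getLogger(__name__)

DEFAULT_UNIVERSE_SIZE = 54_619
MHC_REGION = ("6", 25_000_000, 35_000_000)  # chrom, start (incl), end (excl)


@dataclass
class EnrichmentRecord:
    set_name: str
    k: int  # overlap count
    n_query: int  # query size after filters
    K_set: int  # set size within the universe
    N_universe: int
    p: float
    q: float | None = None
    overlap_genes: list[str] | None = None


def filter_mhc(
    genes: Sequence[str],
    annot: pd.DataFrame,
    region: tuple[str, int, int] = MHC_REGION,
) -> list[str]:
    """Drop genes located in the MHC region.

    ``annot`` has columns gene/chrom/start; the interval is half-open
    [start, end).  Genes missing from the annotation are kept and logged.
    """
    chrom, lo, hi = region
    coords = {
        row.gene: (str(row.chrom), int(row.start)) for row in annot.itertuples(index=False)
    }
    kept = []
    for g in genes:
        if g not in coords:
            log.info("gene %s has no coordinates; kept in enrichment query", g)
            kept.append(g)
            continue
        c, pos = coords[g]
        if c == chrom and lo <= pos < hi:
            continue
        kept.append(g)
    return kept


def hypergeom_test(
    query: Collection[str],
    gene_set: Collection[str],
    universe: Collection[str] | int = DEFAULT_UNIVERSE_SIZE,
) -> EnrichmentRecord:
    """Upper-tail hypergeometric over-representation test.

    With an explicit universe gene list, query and set are intersected
    with it (dropped query genes are logged); with an integer universe
    only the size is fixed and membership is taken on trust.  p = P(X >= k)
    for X hypergeometric(N, K_set, n_query).
    """
    query = set(query)
    gene_set = set(gene_set)
    if isinstance(universe, int):
        n_universe = universe
        k_set = len(gene_set)
    else:
        uni = set(universe)
        n_universe = len(uni)
        dropped = query - uni
        if dropped:
            log.warning("%d query genes outside the universe dropped", len(dropped))
        query = query & uni
        gene_set = gene_set & uni
        k_set = len(gene_set)
    if not query:
        raise ValueError("empty query after universe filtering")
    n_query = len(query)
    overlap = sorted(query & gene_set)
    k = len(overlap)
    # survival function at k-1 gives P(X >= k); exact and log-stable in scipy
    p = float(stats.hypergeom.sf(k - 1, n_universe, k_set, n_query))
    p = min(p, 1.0)
    return EnrichmentRecord(
        set_name="",
        k=k,
        n_query=n_query,
        K_set=k_set,
        N_universe=n_universe,
        p=p,
        overlap_genes=overlap,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted values (step-up, capped at 1)."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        raise ValueError("bh_fdr needs at least one p-value")
    return multipletests(ps, method="fdr_bh")[1]


def enrich_sets(
    query: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Collection[str] | int = DEFAULT_UNIVERSE_SIZE,
    annot: pd.DataFrame | None = None,
    exclude_mhc: bool = True,
) -> list[EnrichmentRecord]:
    """Test a query gene list against every set; BH-FDR across sets.

    Results are sorted by (p, set_name) for deterministic output.
    """
    genes = list(dict.fromkeys(query))  # de-duplicate, preserve order
    if exclude_mhc and annot is not None:
        genes = filter_mhc(genes, annot)
    records = []
    for name in sorted(gene_sets):
        rec = hypergeom_test(genes, gene_sets[name], universe)
        rec.set_name = name
        records.append(rec)
    qs = bh_fdr([r.p for r in records])
    for rec, q in zip(records, qs):
        rec.q = float(q)
    records.sort(key=lambda r: (r.p, r.set_name))
    return records
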