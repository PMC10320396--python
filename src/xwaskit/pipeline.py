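"""Workflow orchestration: simulate -> xwas -> concord -> enrich.

Each stage reads and writes flat text tables so that every intermediate
is independently inspectable and testable; a run log records the count of
records passing or failing every filter.  All stages are deterministic
given the config and master seed.
"""

from __future__ import annotations

import os
import tomllib
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import concordance as conc
from . import enrichment as enr
from . import gene_level, io_formats
from .io_formats import GeneStat
from .smr_heidi import SmrConfig, run_dataset

__all__ = [
    "RunConfig",
    "load_run_config",
    "run_xwas",
    "run_concordance",
    "run_enrichment",
    "sweep_alt_props",
]


@dataclass
class RunConfig:
    """One study's end-to-end configuration (paths resolved)."""

    gwas_path: str
    xqtl_effects_path: str
    probe_annot_path: str
    panel_path: str
    out_dir: str
    study: str = "study"
    gwas_is_case_control: bool = False
    gwas_effect_is_or: bool = False
    smr: SmrConfig = dc_field(default_factory=SmrConfig)

    def validate(self) -> None:
        for name in ("gwas_path", "xqtl_effects_path", "probe_annot_path", "panel_path"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} does not exist: {path}")


def load_run_config(path) -> RunConfig:
    """Read a flat TOML run config; relative paths resolve against the
    config file's directory."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    inputs = raw.get("inputs", {})
    smr_kwargs = raw.get("smr", {})
    return RunConfig(
        gwas_path=resolve(inputs["gwas"]),
        xqtl_effects_path=resolve(inputs["xqtl_effects"]),
        probe_annot_path=resolve(inputs["probe_annot"]),
        panel_path=resolve(inputs["panel"]),
        out_dir=resolve(raw.get("output", {}).get("dir", "out")),
        study=raw.get("study", {}).get("label", "study"),
        gwas_is_case_control=bool(inputs.get("gwas_is_case_control", False)),
        gwas_effect_is_or=bool(inputs.get("gwas_effect_is_or", False)),
        smr=SmrConfig(**smr_kwargs),
    )


def _write_log(path, lines) -> None:
    with open(path, "w") as fh:
        for ln in lines:
            fh.write(ln + "\n")


def run_xwas(config: RunConfig):
    """Run one study: harmonize -> SMR -> HEIDI -> adjust -> gene level.

    Writes ``probes_<study>.tsv`` (probe-level records),
    ``genes_<study>.tsv`` (gene-level Cauchy-combined p-values with
    suggestive/Bonferroni flags) and ``log_<study>.txt`` (filter
    counters).  Returns (records, gene_stats, counters).
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    gwas = io_formats.read_gwas_table(
        config.gwas_path,
        is_case_control=config.gwas_is_case_control,
        effect_is_or=config.gwas_effect_is_or,
    )
    xqtl = io_formats.read_xqtl_dataset(config.xqtl_effects_path, config.probe_annot_path)
    panel = io_formats.read_genotype_panel(config.panel_path)
    records, counters = run_dataset(gwas, xqtl, panel, config.smr)
    io_formats.write_results_table(
        records, os.path.join(config.out_dir, f"probes_{config.study}.tsv")
    )
    m_probes = max(counters["probes_reported"], 1)
    gene_stats = gene_level.combine_by_gene(records, study=config.study)
    m_genes = max(len(gene_stats), 1)
    gene_stats = gene_level.threshold_flags(gene_stats, m_tests=m_genes)
    counters["m_probes_tested"] = m_probes
    counters["m_genes_mapped"] = m_genes
    io_formats.write_gene_stats(
        gene_stats,
        os.path.join(config.out_dir, f"genes_{config.study}.tsv"),
        header_counts={"m_probes_tested": m_probes, "m_genes_mapped": m_genes},
    )
    _write_log(
        os.path.join(config.out_dir, f"log_{config.study}.txt"),
        [f"{k}\t{v}" for k, v in sorted(counters.items())],
    )
    return records, gene_stats, counters


def _load_gene_matrix(gene_tsv_paths):
    """Intersect gene-level tables on gene symbol into a StudyMatrix."""
    tables = []
    for path in gene_tsv_paths:
        stats = io_formats.read_gene_stats(path)
        if not stats:
            raise ValueError(f"empty gene table {path}")
        study = stats[0].study
        tables.append((study, {g.gene: g.p_combined for g in stats}))
    studies = [s for s, _ in tables]
    if len(set(studies)) != len(studies):
        raise ValueError("duplicate study labels across gene tables")
    shared = sorted(set.intersection(*(set(d) for _, d in tables)))
    if len(shared) < 100:
        raise ValueError(
            f"only {len(shared)} genes shared across studies; "
            "need >= 100 for mixture density estimation"
        )
    P = np.array([[d[g] for _, d in tables] for g in shared])
    return conc.StudyMatrix(genes=shared, studies=studies, P=P)


def run_concordance(
    gene_tsv_paths,
    out_dir,
    alt_props: float = 1e-3,
    pp_threshold: float = 0.95,
    tol: float = 1e-6,
    max_iter: int = 1000,
):
    """Joint concordance across >= 2 completed study runs.

    Writes ``concordance_pp.tsv`` (per-gene PP per study, best pattern and
    its posterior) and ``concordance_significant.tsv`` (gene x study pairs
    with PP > threshold).  Returns (fit, StudyMatrix, PP).
    """
    if len(gene_tsv_paths) < 2:
        raise ValueError("concordance needs at least 2 study gene tables")
    matrix = _load_gene_matrix(gene_tsv_paths)
    fit, post, pp = conc.fit_concordance(matrix, alt_props=alt_props, tol=tol, max_iter=max_iter)
    os.makedirs(out_dir, exist_ok=True)
    best = post.argmax(axis=1)
    with open(os.path.join(out_dir, "concordance_pp.tsv"), "w") as fh:
        fh.write("# alt_props=" + io_formats._fmt(alt_props) + "\n")
        for j, study in enumerate(matrix.studies):
            fh.write(f"# scale_{study}=" + io_formats._fmt(fit.mixtures[j].scale) + "\n")
        header = "gene\t" + "\t".join(f"PP_{s}" for s in matrix.studies)
        fh.write(header + "\tbest_pattern\tbest_posterior\n")
        for i, gene in enumerate(matrix.genes):
            pps = "\t".join(io_formats._fmt(pp[i, j]) for j in range(len(matrix.studies)))
            patt = "".join(str(int(b)) for b in fit.patterns[best[i]])
            fh.write(f"{gene}\t{pps}\t{patt}\t{io_formats._fmt(post[i, best[i]])}\n")
    with open(os.path.join(out_dir, "concordance_significant.tsv"), "w") as fh:
        fh.write("gene\tstudy\tPP\n")
        for i, gene in enumerate(matrix.genes):
            for j, study in enumerate(matrix.studies):
                if pp[i, j] > pp_threshold:
                    fh.write(f"{gene}\t{study}\t{io_formats._fmt(pp[i, j])}\n")
    return fit, matrix, pp


def sweep_alt_props(gene_tsv_paths, out_dir, grid, pp_threshold: float = 0.95):
    """Sensitivity sweep: count of PP > threshold calls per alt_props value."""
    matrix = _load_gene_matrix(gene_tsv_paths)
    rows = []
    for ap in grid:
        _fit, _post, pp = conc.fit_concordance(matrix, alt_props=ap)
        rows.append((ap, int((pp > pp_threshold).sum())))
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "alt_props_sweep.tsv"), "w") as fh:
        fh.write("alt_props\tn_significant\n")
        for ap, count in rows:
            fh.write(f"{io_formats._fmt(ap)}\t{count}\n")
    return rows


def run_enrichment(
    query_genes,
    gmt_path,
    out_path,
    universe=None,
    gene_annot_path=None,
    exclude_mhc: bool = True,
    q_threshold: float = 0.05,
):
    """Hypergeometric enrichment of a gene list against a GMT file.

    ``universe`` may be an integer size, a path to a one-gene-per-line
    list, or None for the default universe size.  Returns the records.
    """
    sets = io_formats.read_gmt(gmt_path)
    if universe is None:
        uni = enr.DEFAULT_UNIVERSE_SIZE
    elif isinstance(universe, int):
        uni = universe
    elif isinstance(universe, (list, set, tuple)):
        uni = list(universe)
    else:
        with open(universe) as fh:
            uni = [ln.strip() for ln in fh if ln.strip()]
    annot = io_formats.read_gene_annotation(gene_annot_path) if gene_annot_path else None
    records = enr.enrich_sets(
        query_genes, sets, universe=uni, annot=annot, exclude_mhc=exclude_mhc
    )
    with open(out_path, "w") as fh:
        fh.write("set_name\tk\tn_query\tK_set\tN_universe\tp\tq\tsignificant\toverlap_genes\n")
        for r in records:
            fh.write(
                f"{r.set_name}\t{r.k}\t{r.n_query}\t{r.K_set}\t{r.N_universe}\t"
                f"{io_formats._fmt(r.p)}\t{io_formats._fmt(r.q)}\t"
                f"{int(r.q < q_threshold)}\t{','.join(r.overlap_genes or [])}\n"
            )
    return records


def run_bundle(bundle_dir, out_dir=None, alt_props: float = 1e-3, pp_threshold: float = 0.95):
    """Run every stage on a simulated input bundle.

    Executes one xwas run per ``run_<study>.toml`` in the bundle, then the
    joint concordance, then enrichment of the union of suggestive genes
    against the bundle's gene sets.  Returns a summary dict with output
    paths and headline counts.
    """
    import glob

    configs = sorted(glob.glob(os.path.join(bundle_dir, "run_*.toml")))
    if not configs:
        raise FileNotFoundError(f"no run_*.toml configs in {bundle_dir}")
    out_dir = out_dir or os.path.join(bundle_dir, "out")
    gene_tsvs = []
    studies = []
    suggestive: list[str] = []
    for cfg_path in configs:
        cfg = load_run_config(cfg_path)
        cfg.out_dir = os.path.join(out_dir, cfg.study)
        _records, gene_stats, _counters = run_xwas(cfg)
        path = os.path.join(cfg.out_dir, f"genes_{cfg.study}.tsv")
        gene_tsvs.append(path)
        studies.append(cfg.study)
        suggestive.extend(g.gene for g in gene_stats if g.suggestive)
    fit, matrix, pp = run_concordance(
        gene_tsvs, os.path.join(out_dir, "concord"),
        alt_props=alt_props, pp_threshold=pp_threshold,
    )
    query = sorted(set(suggestive))
    enrich_path = os.path.join(out_dir, "enrichment.tsv")
    records = run_enrichment(
        query,
        os.path.join(bundle_dir, "sets.gmt"),
        enrich_path,
        universe=os.path.join(bundle_dir, "universe.txt"),
        gene_annot_path=os.path.join(bundle_dir, "gene_annot.tsv"),
    )
    return {
        "studies": studies,
        "gene_tsvs": gene_tsvs,
        "out_dir": out_dir,
        "concord_fit": fit,
        "study_matrix": matrix,
        "pp": pp,
        "enrichment": records,
        "n_suggestive_union": len(query),
    }


def suggestive_genes(gene_tsv_path) -> list[str]:
    """Genes flagged suggestive in a gene-level table (enrichment query)."""
    return [g.gene for g in io_formats.read_gene_stats(gene_tsv_path) if g.suggestive]
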