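"""Readers and writers for every external representation the pipeline touches.

Formats supported:

* GWAS summary statistics in the COJO ``.ma`` dialect
  (whitespace-delimited, header ``SNP A1 A2 freq b se p N``).
* cis-xQTL summary statistics as a two-file flat-text dialect: a probe
  annotation TSV (``probe_id gene chrom probe_pos paradigm``) plus an
  effect TSV (``probe_id SNP Chr BP A1 A2 freq b se p``).
* An LD reference panel as a plain dosage TSV (five metadata rows, then
  one row of 0..2 dosages per reference individual).
* GMT gene-set files and the probe/gene annotation table.
* Result tables (probe-level SMR records, gene-level statistics).

Coordinates are 1-based; alleles are stored uppercase.  All writers format
floats with 12 significant digits so that write→read round trips are the
identity at that precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpAssoc",
    "ProbeInfo",
    "GwasTable",
    "XqtlDataset",
    "GenotypePanel",
    "SmrRecord",
    "GeneStat",
    "FormatError",
    "read_gwas_table",
    "read_xqtl_dataset",
    "read_genotype_panel",
    "write_genotype_panel",
    "read_gmt",
    "write_gmt",
    "read_gene_annotation",
    "write_results_table",
    "read_results_table",
    "write_gene_stats",
    "read_gene_stats",
]

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class SnpAssoc:
    """One SNP's association record, in either the GWAS or the xQTL role.

    ``beta`` is the additive effect of ``a1`` (the effect allele) on the
    trait or molecular level; for case-control traits it is the log
    odds ratio.  ``chrom``/``pos`` may be absent for the ``.ma`` dialect,
    which carries no coordinates.
    """

    snp_id: str
    a1: str
    a2: str
    freq: float
    beta: float
    se: float
    p: float
    n: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not 0.0 <= self.freq <= 1.0:
            raise ValueError(f"{self.snp_id}: freq must be in [0,1], got {self.freq}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"{self.snp_id}: p must be in (0,1], got {self.p}")
        if self.a1 == self.a2:
            raise ValueError(f"{self.snp_id}: a1 and a2 must differ")

    @property
    def z(self) -> float:
        return self.beta / self.se

    def flipped(self) -> "SnpAssoc":
        """The same record expressed for the other allele."""
        return SnpAssoc(
            snp_id=self.snp_id,
            a1=self.a2,
            a2=self.a1,
            freq=1.0 - self.freq,
            beta=-self.beta,
            se=self.se,
            p=self.p,
            n=self.n,
            chrom=self.chrom,
            pos=self.pos,
        )


@dataclass(frozen=True)
class ProbeInfo:
    """A molecular probe: expression/protein array probe or CpG site."""

    probe_id: str
    gene: str  # HGNC symbol, or "" when the probe maps to no gene
    chrom: str
    probe_pos: int
    paradigm: str = "expression"  # expression | protein | methylation

    def __post_init__(self) -> None:
        if self.probe_pos <= 0:
            raise ValueError(f"{self.probe_id}: probe_pos must be > 0")
        if self.paradigm not in ("expression", "protein", "methylation"):
            raise ValueError(f"{self.probe_id}: unknown paradigm {self.paradigm!r}")


@dataclass
class GwasTable:
    """GWAS summary statistics keyed by SNP id."""

    snps: dict[str, SnpAssoc]
    is_case_control: bool = False

    def __len__(self) -> int:
        return len(self.snps)

    def get(self, snp_id: str) -> SnpAssoc | None:
        return self.snps.get(snp_id)


@dataclass
class XqtlDataset:
    """cis-xQTL summary statistics: probe annotation plus per-probe SNP effects."""

    probes: dict[str, ProbeInfo]
    effects: dict[str, list[SnpAssoc]]

    def usable_probes(self) -> list[str]:
        return [p for p, snps in self.effects.items() if snps]

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class GenotypePanel:
    """An LD reference panel of allele dosages.

    ``dosages`` is n_ref x m with values in [0, 2] counting copies of
    ``a1``; LD is the plain Pearson correlation of dosage columns.
    Monomorphic SNPs are flagged; correlations involving them are NaN.
    """

    dosages: np.ndarray
    meta: pd.DataFrame  # columns: snp_id, chrom, pos, a1, a2

    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        if d.ndim != 2:
            raise FormatError("dosage matrix must be 2-dimensional")
        if d.shape[0] < 2:
            raise FormatError(f"need at least 2 reference individuals, got {d.shape[0]}")
        if d.shape[1] != len(self.meta):
            raise FormatError("dosage columns do not align with SNP metadata")
        if np.nanmin(d) < 0 or np.nanmax(d) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        self.dosages = d
        ids = list(self.meta["snp_id"])
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate snp_id in genotype panel")
        self.index = {s: j for j, s in enumerate(ids)}
        self._mono = d.std(axis=0) == 0.0
        self._freqs = d.mean(axis=0) / 2.0

    @property
    def n_ref(self) -> int:
        return self.dosages.shape[0]

    @property
    def monomorphic(self) -> np.ndarray:
        return self._mono

    def freq(self, snp_id: str) -> float:
        """Frequency of a1 in the reference panel."""
        return float(self._freqs[self.index[snp_id]])

    def has(self, snp_id: str) -> bool:
        return snp_id in self.index

    def correlation(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Pairwise Pearson r of dosages for the requested SNPs.

        Rows/columns of monomorphic SNPs are NaN off-diagonal; the
        diagonal is exactly 1 for polymorphic SNPs.
        """
        cols = [self.index[s] for s in snp_ids]
        sub = self.dosages[:, cols]
        sd = sub.std(axis=0)
        mono = sd == 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(sub, rowvar=False)
        r = np.atleast_2d(r)
        r[mono, :] = np.nan
        r[:, mono] = np.nan
        np.fill_diagonal(r, np.where(mono, np.nan, 1.0))
        return r


@dataclass
class SmrRecord:
    """Per-probe output of the SMR + HEIDI analysis.

    ``p_heidi``/``nsnp_heidi`` are None when HEIDI was not run (fewer than
    the minimum number of usable instruments) or failed numerically.
    """

    probe_id: str
    probe_chrom: str
    gene: str
    probe_pos: int
    top_snp: str
    a1: str
    a2: str
    freq: float
    b_gwas: float
    se_gwas: float
    p_gwas: float
    b_xqtl: float
    se_xqtl: float
    p_xqtl: float
    b_smr: float
    se_smr: float
    p_smr: float
    p_heidi: float | None
    nsnp_heidi: int | None
    p_smr_adj: float


@dataclass
class GeneStat:
    """Gene-level combined p-value for one study (trait x tissue x paradigm)."""

    gene: str
    study: str
    p_combined: float
    n_probes: int
    suggestive: bool = False
    bonferroni: bool = False


# ---------------------------------------------------------------------------
# readers


_MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]


def read_gwas_table(
    path, is_case_control: bool = False, effect_is_or: bool = False
) -> GwasTable:
    """Read GWAS summary statistics in the COJO ``.ma`` dialect.

    With ``effect_is_or`` the ``b`` column holds odds ratios; they are
    log-transformed (``beta = ln OR``) and ``se`` is taken as the standard
    error of ln(OR), following standard SMR practice for case-control
    traits.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"SNP": str, "A1": str, "A2": str})
    for col in _MA_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"GWAS table {path} is missing required column {col!r}")
    dup = df["SNP"][df["SNP"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate snp_id in GWAS table: {dup.iloc[0]!r}")
    snps: dict[str, SnpAssoc] = {}
    for row in df.itertuples(index=False):
        beta = float(row.b)
        if effect_is_or:
            if beta <= 0:
                raise ValueError(f"{row.SNP}: odds ratio must be > 0, got {beta}")
            beta = math.log(beta)
        n = None if pd.isna(row.N) else float(row.N)
        snps[row.SNP] = SnpAssoc(
            snp_id=row.SNP,
            a1=str(row.A1).upper(),
            a2=str(row.A2).upper(),
            freq=float(row.freq),
            beta=beta,
            se=float(row.se),
            p=float(row.p),
            n=n,
        )
    return GwasTable(snps=snps, is_case_control=is_case_control)


def write_gwas_table(table: GwasTable, path, effect_is_or: bool = False) -> None:
    """Write a GwasTable in the ``.ma`` dialect (inverse of read_gwas_table)."""
    with open(path, "w") as fh:
        fh.write("SNP A1 A2 freq b se p N\n")
        for s in table.snps.values():
            b = math.exp(s.beta) if effect_is_or else s.beta
            n = "NA" if s.n is None else _fmt(s.n)
            fh.write(
                f"{s.snp_id} {s.a1} {s.a2} {_fmt(s.freq)} {_fmt(b)} "
                f"{_fmt(s.se)} {_fmt(s.p)} {n}\n"
            )


_ANNOT_COLUMNS = ["probe_id", "gene", "chrom", "probe_pos", "paradigm"]
_ESD_COLUMNS = ["probe_id", "SNP", "Chr", "BP", "A1", "A2", "freq", "b", "se", "p"]


def read_xqtl_dataset(esd_path, probe_annot_path) -> XqtlDataset:
    """Read the flat-text xQTL dialect: probe annotation + per-SNP effects.

    Probes with no effect rows are retained (usable_probes() excludes
    them); an effect row naming an unannotated probe is an error.
    """
    annot = pd.read_csv(
        probe_annot_path, sep="\t", dtype={"probe_id": str, "gene": str, "chrom": str}
    )
    for col in _ANNOT_COLUMNS:
        if col not in annot.columns:
            raise FormatError(f"probe annotation is missing column {col!r}")
    annot["gene"] = annot["gene"].fillna("")
    probes: dict[str, ProbeInfo] = {}
    for row in annot.itertuples(index=False):
        if row.probe_id in probes:
            raise FormatError(f"duplicate probe_id {row.probe_id!r} in annotation")
        probes[row.probe_id] = ProbeInfo(
            probe_id=row.probe_id,
            gene=row.gene,
            chrom=str(row.chrom),
            probe_pos=int(row.probe_pos),
            paradigm=row.paradigm,
        )
    effects: dict[str, list[SnpAssoc]] = {p: [] for p in probes}
    eff = pd.read_csv(
        esd_path, sep="\t", dtype={"probe_id": str, "SNP": str, "Chr": str}
    )
    if eff.empty and not set(_ESD_COLUMNS) <= set(eff.columns):
        # an entirely empty effect file (header optional) is permitted
        return XqtlDataset(probes=probes, effects=effects)
    for col in _ESD_COLUMNS:
        if col not in eff.columns:
            raise FormatError(f"xQTL effect file is missing column {col!r}")
    seen: set[tuple[str, str]] = set()
    for row in eff.itertuples(index=False):
        if row.probe_id not in probes:
            raise FormatError(
                f"effect row references unknown probe {row.probe_id!r}"
            )
        key = (row.probe_id, row.SNP)
        if key in seen:
            raise FormatError(f"duplicate SNP {row.SNP!r} for probe {row.probe_id!r}")
        seen.add(key)
        effects[row.probe_id].append(
            SnpAssoc(
                snp_id=row.SNP,
                a1=str(row.A1).upper(),
                a2=str(row.A2).upper(),
                freq=float(row.freq),
                beta=float(row.b),
                se=float(row.se),
                p=float(row.p),
                chrom=str(row.Chr),
                pos=int(row.BP),
            )
        )
    return XqtlDataset(probes=probes, effects=effects)


def write_xqtl_dataset(dataset: XqtlDataset, esd_path, probe_annot_path) -> None:
    with open(probe_annot_path, "w") as fh:
        fh.write("\t".join(_ANNOT_COLUMNS) + "\n")
        for info in dataset.probes.values():
            fh.write(
                f"{info.probe_id}\t{info.gene}\t{info.chrom}\t"
                f"{info.probe_pos}\t{info.paradigm}\n"
            )
    with open(esd_path, "w") as fh:
        fh.write("\t".join(_ESD_COLUMNS) + "\n")
        for probe_id, snps in dataset.effects.items():
            for s in snps:
                fh.write(
                    f"{probe_id}\t{s.snp_id}\t{s.chrom}\t{s.pos}\t{s.a1}\t{s.a2}\t"
                    f"{_fmt(s.freq)}\t{_fmt(s.beta)}\t{_fmt(s.se)}\t{_fmt(s.p)}\n"
                )


_PANEL_META_ROWS = ["snp_id", "chrom", "pos", "a1", "a2"]


def read_genotype_panel(path) -> GenotypePanel:
    """Read the plain dosage TSV: 5 metadata rows, then one row per individual.

    Layout (tab-separated)::

        snp_id  rs1   rs2  ...
        chrom   1     1    ...
        pos     1000  2000 ...
        a1      A     C    ...
        a2      G     T    ...
        ind1    0     2    ...
        ind2    1     1    ...
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < len(_PANEL_META_ROWS) + 2:
        raise FormatError("genotype panel needs 5 metadata rows and >= 2 individuals")
    meta_vals = {}
    for i, name in enumerate(_PANEL_META_ROWS):
        parts = lines[i].split("\t")
        if parts[0] != name:
            raise FormatError(f"panel metadata row {i + 1} must start with {name!r}")
        meta_vals[name] = parts[1:]
    meta = pd.DataFrame(
        {
            "snp_id": meta_vals["snp_id"],
            "chrom": meta_vals["chrom"],
            "pos": [int(x) for x in meta_vals["pos"]],
            "a1": [x.upper() for x in meta_vals["a1"]],
            "a2": [x.upper() for x in meta_vals["a2"]],
        }
    )
    from io import StringIO

    body = "\n".join(ln.split("\t", 1)[1] for ln in lines[len(_PANEL_META_ROWS):])
    dosages = np.loadtxt(StringIO(body), delimiter="\t", ndmin=2)
    if dosages.size and (dosages.min() < 0 or dosages.max() > 2):
        raise ValueError("panel dosages must lie in [0, 2]")
    return GenotypePanel(dosages=dosages, meta=meta)


def write_genotype_panel(panel: GenotypePanel, path) -> None:
    m = panel.meta
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(m["snp_id"]) + "\n")
        fh.write("chrom\t" + "\t".join(str(c) for c in m["chrom"]) + "\n")
        fh.write("pos\t" + "\t".join(str(p) for p in m["pos"]) + "\n")
        fh.write("a1\t" + "\t".join(m["a1"]) + "\n")
        fh.write("a2\t" + "\t".join(m["a2"]) + "\n")
        for i in range(panel.n_ref):
            row = "\t".join(_fmt(x) for x in panel.dosages[i])
            fh.write(f"ind{i + 1}\t{row}\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, then member symbols."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln in fh:
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise FormatError(f"duplicate gene set {name!r} in GMT")
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, descriptions=None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write(name + "\t" + desc + "\t" + "\t".join(genes) + "\n")


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene coordinate table: columns ``gene``, ``chrom``, ``start``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    for col in ("gene", "chrom", "start"):
        if col not in df.columns:
            raise FormatError(f"gene annotation is missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# result tables


_RESULT_COLUMNS = [
    "probeID", "ProbeChr", "Gene", "Probe_bp", "topSNP", "A1", "A2", "Freq",
    "b_GWAS", "se_GWAS", "p_GWAS", "b_eQTL", "se_eQTL", "p_eQTL",
    "b_SMR", "se_SMR", "p_SMR", "p_HEIDI", "nsnp_HEIDI", "p_SMR_adj",
]


def _fmt(x) -> str:
    """12-significant-digit text rendering; exact round trip at that precision."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    if isinstance(x, (int, np.integer)) and not isinstance(x, bool):
        return str(int(x))
    return f"{float(x):.12g}"


def write_results_table(records: Iterable[SmrRecord], path) -> None:
    """Write probe-level SMR records as a TSV mirroring SMR tool output columns."""
    with open(path, "w") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for r in records:
            fields = [
                r.probe_id, r.probe_chrom, r.gene, str(r.probe_pos), r.top_snp,
                r.a1, r.a2, _fmt(r.freq),
                _fmt(r.b_gwas), _fmt(r.se_gwas), _fmt(r.p_gwas),
                _fmt(r.b_xqtl), _fmt(r.se_xqtl), _fmt(r.p_xqtl),
                _fmt(r.b_smr), _fmt(r.se_smr), _fmt(r.p_smr),
                _fmt(r.p_heidi),
                "NA" if r.nsnp_heidi is None else str(r.nsnp_heidi),
                _fmt(r.p_smr_adj),
            ]
            fh.write("\t".join(fields) + "\n")


def read_results_table(path) -> list[SmrRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"probeID": str, "ProbeChr": str,
                                            "Gene": str, "topSNP": str,
                                            "A1": str, "A2": str},
                     na_values=["NA"], keep_default_na=False)
    for col in _RESULT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"results table is missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SmrRecord(
                probe_id=row.probeID,
                probe_chrom=row.ProbeChr,
                gene="" if pd.isna(row.Gene) else row.Gene,
                probe_pos=int(row.Probe_bp),
                top_snp=row.topSNP,
                a1=row.A1,
                a2=row.A2,
                freq=float(row.Freq),
                b_gwas=float(row.b_GWAS),
                se_gwas=float(row.se_GWAS),
                p_gwas=float(row.p_GWAS),
                b_xqtl=float(row.b_eQTL),
                se_xqtl=float(row.se_eQTL),
                p_xqtl=float(row.p_eQTL),
                b_smr=float(row.b_SMR),
                se_smr=float(row.se_SMR),
                p_smr=float(row.p_SMR),
                p_heidi=None if pd.isna(row.p_HEIDI) else float(row.p_HEIDI),
                nsnp_heidi=None if pd.isna(row.nsnp_HEIDI) else int(row.nsnp_HEIDI),
                p_smr_adj=float(row.p_SMR_adj),
            )
        )
    return out


def write_gene_stats(stats: Iterable[GeneStat], path, header_counts=None) -> None:
    """Gene-level TSV; optional ``#`` header lines record the test counts
    used for the suggestive/Bonferroni denominators."""
    with open(path, "w") as fh:
        for key, val in (header_counts or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("gene\tstudy\tp_combined\tn_probes\tsuggestive\tbonferroni\n")
        for g in stats:
            fh.write(
                f"{g.gene}\t{g.study}\t{_fmt(g.p_combined)}\t{g.n_probes}\t"
                f"{int(g.suggestive)}\t{int(g.bonferroni)}\n"
            )


def read_gene_stats(path) -> list[GeneStat]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str, "study": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GeneStat(
                gene=row.gene,
                study=row.study,
                p_combined=float(row.p_combined),
                n_probes=int(row.n_probes),
                suggestive=bool(row.suggestive),
                bonferroni=bool(row.bonferroni),
            )
        )
    return out
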