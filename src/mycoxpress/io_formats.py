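"""Tabular I/O for every external format the pipeline touches.

All tables are plain TSV. Matrices are genes-in-rows, samples-in-columns;
sample identity is always by id, never by column position. Result writers
prepend ``# key=value`` header comments recording run parameters so that a
result file is self-describing; the matching readers skip them.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ORGANS = ("flower", "stem", "underground")
TROPHIC_MODES = ("MH", "AT")

#: columns of the standard 12-column tabular hit format (outfmt 6), to which
#: a 13th semicolon-separated lineage column is appended.
HIT_TABLE_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "lineage",
)


class TableFormatError(ValueError):
    """Raised when an input table violates its format contract."""


@dataclass(frozen=True)
class HitRecord:
    """Best protein hit of one assembled contig, with its taxonomy lineage.

    The lineage is ordered root→leaf (e.g. Eukaryota … Streptophyta …) so
    clade membership is a simple name lookup.
    """

    contig_id: str
    subject_id: str
    bitscore: float
    evalue: float
    taxon_lineage: tuple[str, ...]

    def __post_init__(self):
        if self.evalue < 0:
            raise TableFormatError(f"negative evalue for {self.contig_id}")
        if not self.taxon_lineage:
            raise TableFormatError(f"empty lineage for {self.contig_id}")


@dataclass
class OrthogroupMap:
    """Orthogroup id → per-species gene lists.

    ``members[og][species]`` is the (possibly empty) list of that species'
    genes in the orthogroup. Species order is preserved from the input
    header; each gene belongs to at most one orthogroup.
    """

    species: tuple[str, ...]
    members: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, og: str) -> bool:
        return og in self.members

    def orthogroup_ids(self) -> list[str]:
        return list(self.members)

    def genes(self, og: str, species: str) -> list[str]:
        return self.members[og][species]

    def species_with_genes(self, og: str) -> frozenset[str]:
        """Species contributing at least one gene to the orthogroup."""
        return frozenset(s for s, g in self.members[og].items() if g)

    def gene_to_orthogroup(self, species: str) -> dict[str, str]:
        """Invert the map for one species (gene id → orthogroup id)."""
        out: dict[str, str] = {}
        for og, per_sp in self.members.items():
            for g in per_sp[species]:
                out[g] = og
        return out

    def gene_counts(self, og: str) -> dict[str, int]:
        return {s: len(g) for s, g in self.members[og].items()}

    def n_genes(self, og: str) -> int:
        return sum(len(g) for g in self.members[og].values())


@dataclass
class CountMatrix:
    """Raw integer read counts (genes × samples) with sample metadata.

    ``meta`` is indexed by sample id with columns ``species``, ``organ``,
    ``individual`` and ``trophic``; the count columns are aligned to the
    metadata order on construction.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        validate_meta(self.meta)
        unknown = [s for s in self.counts.columns if s not in self.meta.index]
        if unknown:
            raise TableFormatError(f"samples missing from metadata: {unknown}")
        self.counts = self.counts[list(self.meta.index[self.meta.index.isin(self.counts.columns)])]
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise TableFormatError("counts must be integers")
        if (arr < 0).any():
            raise TableFormatError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)].copy(),
                           self.meta.loc[list(sample_ids)].copy())


def validate_meta(meta: pd.DataFrame) -> None:
    required = {"species", "organ", "individual", "trophic"}
    missing = required - set(meta.columns)
    if missing:
        raise TableFormatError(f"metadata missing columns: {sorted(missing)}")
    bad_organ = set(meta["organ"]) - set(ORGANS)
    if bad_organ:
        raise TableFormatError(f"unknown organs: {sorted(bad_organ)}")
    bad_trophic = set(meta["trophic"]) - set(TROPHIC_MODES)
    if bad_trophic:
        raise TableFormatError(f"unknown trophic modes: {sorted(bad_trophic)}")
    key = meta[["species", "organ", "individual"]].apply(tuple, axis=1)
    if key.duplicated().any():
        dups = key[key.duplicated()].tolist()
        raise TableFormatError(f"duplicate (species, organ, individual): {dups}")


def check_paired_design(meta: pd.DataFrame) -> None:
    """Require exactly one underground and one stem sample per individual.

    The cross-species ratio analysis is built on within-individual
    underground/stem pairs; anything else is a design error.
    """
    sub = meta[meta["organ"].isin(["underground", "stem"])]
    for (sp, ind), grp in sub.groupby(["species", "individual"]):
        organs = sorted(grp["organ"])
        if organs != ["stem", "underground"]:
            raise TableFormatError(
                f"individual {sp}/{ind} lacks a full underground/stem pair: {organs}")


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


# ---------------------------------------------------------------------------
# best-hit tables


def read_hit_table(path) -> list[HitRecord]:
    """Read an outfmt-6-style hit table (+ lineage column); best hit per contig.

    Several hits per contig may be present (searches are typically run with a
    large max-target cap); the reduction keeps, per contig, the hit with the
    highest bitscore, breaking ties by smallest evalue then lexicographically
    smallest subject id, so the result is a deterministic total order.
    """
    best: dict[str, HitRecord] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(HIT_TABLE_COLUMNS):
                raise TableFormatError(
                    f"{path}:{lineno}: expected ≥{len(HIT_TABLE_COLUMNS)} columns "
                    f"(12 standard + lineage), got {len(fields)}")
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from None
            lineage = tuple(c.strip() for c in fields[12].split(";") if c.strip())
            if not lineage:
                raise TableFormatError(f"{path}:{lineno}: empty lineage column")
            rec = HitRecord(fields[0], fields[1], bitscore, evalue, lineage)
            cur = best.get(rec.contig_id)
            if cur is None or _hit_order_key(rec) < _hit_order_key(cur):
                best[rec.contig_id] = rec
    return list(best.values())


def _hit_order_key(rec: HitRecord):
    # max bitscore, then min evalue, then lexicographic subject id
    return (-rec.bitscore, rec.evalue, rec.subject_id)


def write_hit_table(records: Iterable[HitRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            std = [r.contig_id, r.subject_id, "0", "0", "0", "0",
                   "0", "0", "0", "0", repr(r.evalue), repr(r.bitscore)]
            fh.write("\t".join(std + [";".join(r.taxon_lineage)]) + "\n")


# ---------------------------------------------------------------------------
# orthogroup tables


def read_orthogroups(path) -> OrthogroupMap:
    """Read an orthogroup membership table (Orthogroups.tsv dialect).

    Header: ``Orthogroup<TAB>species1<TAB>species2…``; each row an orthogroup
    id followed by comma-separated gene lists (empty cell = no genes).
    """
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise TableFormatError(f"{path}: header must list species names")
        species = tuple(header[1:])
        omap = OrthogroupMap(species=species)
        seen_genes: dict[str, str] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(species) + 1:
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(species) + 1} columns, got {len(cells)}")
            og = cells[0]
            if og in omap.members:
                raise TableFormatError(f"{path}:{lineno}: duplicate orthogroup id {og}")
            per_sp = {}
            for sp, cell in zip(species, cells[1:]):
                genes = [g.strip() for g in cell.split(",") if g.strip()]
                for g in genes:
                    if g in seen_genes:
                        raise TableFormatError(
                            f"{path}:{lineno}: gene {g} already in orthogroup {seen_genes[g]}")
                    seen_genes[g] = og
                per_sp[sp] = genes
            omap.members[og] = per_sp
    return omap


def write_orthogroups(omap: OrthogroupMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(("Orthogroup",) + omap.species) + "\n")
        for og, per_sp in omap.members.items():
            cells = [", ".join(per_sp[s]) for s in omap.species]
            fh.write("\t".join([og] + cells) + "\n")


# ---------------------------------------------------------------------------
# count matrices and metadata


def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise TableFormatError(f"{path}: metadata needs a sample_id column")
    meta = meta.set_index("sample_id")
    validate_meta(meta)
    return meta


def read_counts(path, meta_path) -> CountMatrix:
    """Read a TSV count matrix and its sample metadata into a CountMatrix.

    Counts must be non-negative integers; a fractional or negative cell is an
    error naming the offending gene and sample (multi-mapping estimates are
    rejected — the pipeline works on raw per-contig counts).
    """
    meta = read_meta(meta_path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.isna().any(axis=None):
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise TableFormatError(f"{path}: missing values in rows {bad[:5]}")
    for sample in df.columns:
        col = df[sample]
        if not np.issubdtype(col.dtype, np.number):
            raise TableFormatError(f"{path}: non-numeric counts in sample {sample}")
        frac = col[col != np.floor(col)]
        if len(frac):
            raise TableFormatError(
                f"{path}: non-integer count {frac.iloc[0]} for gene "
                f"{frac.index[0]} in sample {sample}")
        neg = col[col < 0]
        if len(neg):
            raise TableFormatError(
                f"{path}: negative count for gene {neg.index[0]} in sample {sample}")
    df = df.astype("int64")
    unknown = [s for s in df.columns if s not in meta.index]
    if unknown:
        raise TableFormatError(f"{path}: samples not in metadata: {unknown}")
    df = df[[s for s in meta.index if s in df.columns]]
    return CountMatrix(df, meta.loc[list(df.columns)])


def write_counts(cm: CountMatrix, counts_path, meta_path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# gene→term maps and result tables


def read_term_map(path) -> dict[str, list[str]]:
    """Read a two-column (gene, term) TSV into term → member-gene lists."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: need two columns (gene, term)")
    gene_col, term_col = df.columns[:2]
    out: dict[str, list[str]] = {}
    for gene, term in zip(df[gene_col], df[term_col]):
        out.setdefault(term, []).append(gene)
    return out


def write_term_map(term_map: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tterm\n")
        for term, genes in term_map.items():
            for g in genes:
                fh.write(f"{g}\t{term}\n")


def write_result_table(df: pd.DataFrame, path, params: Mapping | None = None,
                       index: bool = False) -> None:
    """Write a result TSV with ``# key=value`` header comments."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (params or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_result_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_fasta_ids(path) -> list[str]:
    """Contig ids of a FASTA file (sequences themselves are never used)."""
    from Bio import SeqIO
    with _open_text(path) as fh:
        return [rec.id for rec in SeqIO.parse(fh, "fasta")]


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise TableFormatError(f"{path}: config must be a YAML mapping")
    return cfg
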