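"""Readers and writers for every external representation the pipeline touches.

Internal coordinates are 0-based half-open everywhere; GFF3 I/O converts
from/to the standard's 1-based inclusive convention.  Numeric table cells
may use either "." or "," as the decimal separator (including comma
mantissas in scientific notation, e.g. ``8,20E-04``), mirroring the dialect
of the published supplementary tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from kanseek.errors import FormatError, ValidationError

_IUPAC_LETTERS = set("ACGTUMRWSYKVHDBNX")

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: strand-aware body span and nested CDS span."""

    gene_id: str
    chrom: str
    strand: str
    body_start: int
    body_end: int
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (self.body_start < self.body_end):
            raise ValidationError(f"gene {self.gene_id}: body_start must be < body_end")
        if not (self.body_start <= self.cds_start < self.cds_end <= self.body_end):
            raise ValidationError(f"gene {self.gene_id}: CDS [{self.cds_start},{self.cds_end}) not nested in body [{self.body_start},{self.body_end})")

    @property
    def tss(self) -> int:
        """Position of the 5'-most base of the gene body in its own orientation."""
        return self.body_start if self.strand == "+" else self.body_end - 1


@dataclass(frozen=True)
class BindingRegion:
    """One ChIP-enriched interval with summit and per-replicate statistics."""

    region_id: str
    chrom: str
    start: int
    end: int
    summit: int | None = None
    enrichment: tuple[float, ...] = ()
    fdr: tuple[float, ...] = ()
    rank: int | None = None

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValidationError(f"region {self.region_id}: start must be < end")
        if self.summit is None:
            object.__setattr__(self, "summit", (self.start + self.end) // 2)
        if not (self.start <= self.summit < self.end):
            raise ValidationError(f"region {self.region_id}: summit {self.summit} outside [{self.start},{self.end})")
        object.__setattr__(self, "enrichment", tuple(float(e) for e in self.enrichment))
        object.__setattr__(self, "fdr", tuple(float(f) for f in self.fdr))
        if len(self.enrichment) < 1 or len(self.enrichment) != len(self.fdr):
            raise ValidationError(f"region {self.region_id}: enrichment and fdr lists must have equal length >= 1")
        if any((not math.isfinite(e)) or e <= 0 for e in self.enrichment):
            raise ValidationError(f"region {self.region_id}: enrichment values must be finite and > 0")


@dataclass(frozen=True)
class RegulationTableRow:
    """Per-gene down-regulation flags at the two post-induction timepoints."""

    gene_id: str
    down_80: bool
    down_160: bool

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")


# ---------------------------------------------------------------------------
# Numeric cell parsing (comma/dot decimal dialect)
# ---------------------------------------------------------------------------


def parse_decimal(cell: str) -> float:
    """Parse a numeric cell accepting "." or "," as decimal separator.

    ``"4,3"`` -> 4.3 and ``"2,66E-39"`` -> 2.66e-39; plain dot-decimal and
    integer cells parse unchanged.
    """
    text = str(cell).strip()
    if not text:
        raise FormatError("empty cell where a number was expected")
    try:
        return float(text)
    except ValueError:
        pass
    try:
        return float(text.replace(",", ".", 1))
    except ValueError:
        raise FormatError(f"cannot parse numeric cell {cell!r}") from None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered name -> sequence mapping.

    Names are taken from the header up to the first whitespace; sequences are
    upper-cased.  Raises :class:`FormatError` for a malformed leading line
    and for an empty file.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}: line {lineno}: expected FASTA header starting with '>'")
            break
        else:
            raise FormatError(f"{path}: empty FASTA input")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC_LETTERS
        if bad:
            raise FormatError(f"{path}: record {rec.id}: non-IUPAC letters {sorted(bad)}")
        if rec.id not in records:
            records[rec.id] = seq
    if not records:
        raise FormatError(f"{path}: empty FASTA input")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene + CDS features from a GFF3 file into :class:`GeneModel` list.

    The CDS span of a gene is the union extent of all its CDS descendants;
    genes without CDS features default to a CDS covering the whole body.
    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Output is sorted by (chrom, body_start, gene_id).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in seen:
            raise ValidationError(f"duplicate gene ID {gene_id!r} in {path}")
        seen.add(gene_id)
        if feat.strand not in {"+", "-"}:
            raise ValidationError(f"gene {gene_id}: missing or invalid strand {feat.strand!r}")
        body_start, body_end = feat.start - 1, feat.end
        cds_feats = list(db.children(feat, featuretype="CDS"))
        if cds_feats:
            cds_start = min(c.start for c in cds_feats) - 1
            cds_end = max(c.end for c in cds_feats)
            if cds_start < body_start or cds_end > body_end:
                raise ValidationError(f"gene {gene_id}: CDS extent [{cds_start},{cds_end}) outside gene body [{body_start},{body_end})")
        else:
            cds_start, cds_end = body_start, body_end
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand,
                body_start=body_start,
                body_end=body_end,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.body_start, g.gene_id))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "kanseek") -> None:
    """Write gene + CDS features, converting back to 1-based inclusive."""
    ordered = sorted(genes, key=lambda g: (g.chrom, g.body_start, g.gene_id))
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for g in ordered:
            handle.write(
                f"{g.chrom}\t{source}\tgene\t{g.body_start + 1}\t{g.body_end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            handle.write(
                f"{g.chrom}\t{source}\tCDS\t{g.cds_start + 1}\t{g.cds_end}\t.\t{g.strand}\t0\tID=cds-{g.gene_id};Parent={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Binding-region tables
# ---------------------------------------------------------------------------

REGION_TABLE_COLUMNS = [
    "region_id",
    "chrom",
    "start",
    "end",
    "summit",
    "enrichment_rep1",
    "enrichment_rep2",
    "fdr_rep1",
    "fdr_rep2",
    "rank",
]


def read_region_table(path: str | Path) -> list[BindingRegion]:
    """Read a TSV of binding regions, tolerant of the comma-decimal dialect.

    Required columns: chrom, start, end, and at least one ``enrichment*``
    column with a matching ``fdr*`` column.  Optional: region_id (else
    auto-numbered), summit (else interval midpoint), rank.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).fillna("")
    cols = {c.lower().strip(): c for c in df.columns}
    for required in ("chrom", "start", "end"):
        if required not in cols:
            raise FormatError(f"{path}: missing required column {required!r}")
    enr_cols = [c for c in df.columns if c.lower().startswith("enrichment")]
    fdr_cols = [c for c in df.columns if c.lower().startswith("fdr")]
    if not enr_cols or len(enr_cols) != len(fdr_cols):
        raise FormatError(f"{path}: need matching enrichment*/fdr* column pairs")
    regions: list[BindingRegion] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        rowd = dict(zip(df.columns, row))
        try:
            start = int(rowd[cols["start"]])
            end = int(rowd[cols["end"]])
            if start < 0 or end < 0:
                raise FormatError("negative coordinates")
            summit_txt = rowd.get(cols.get("summit", ""), "").strip() if "summit" in cols else ""
            summit = int(summit_txt) if summit_txt else None
            rank_txt = rowd.get(cols.get("rank", ""), "").strip() if "rank" in cols else ""
            rank = int(rank_txt) if rank_txt else None
            enrichment = tuple(parse_decimal(rowd[c]) for c in enr_cols)
            fdr = tuple(parse_decimal(rowd[c]) for c in fdr_cols)
            region_id = rowd[cols["region_id"]].strip() if "region_id" in cols else f"R{i + 1:05d}"
            region = BindingRegion(
                region_id=region_id,
                chrom=str(rowd[cols["chrom"]]).strip(),
                start=start,
                end=end,
                summit=summit,
                enrichment=enrichment,
                fdr=fdr,
                rank=rank,
            )
        except (FormatError, ValidationError, ValueError) as exc:
            raise FormatError(f"{path}: line {line}: {exc}") from exc
        if any(f > 1 for f in region.fdr):
            warnings.warn(
                f"{path}: line {line}: FDR value > 1 preserved as printed", stacklevel=2
            )
        regions.append(region)
    return regions


def _fmt(value: float, decimal: str = ".") -> str:
    text = f"{value:.6g}"
    return text.replace(".", ",") if decimal == "," else text


def write_region_table(regions: Sequence[BindingRegion], path: str | Path, decimal: str = ".") -> None:
    n_rep = len(regions[0].enrichment) if regions else 2
    enr_cols = [f"enrichment_rep{i + 1}" for i in range(n_rep)]
    fdr_cols = [f"fdr_rep{i + 1}" for i in range(n_rep)]
    header = ["region_id", "chrom", "start", "end", "summit", *enr_cols, *fdr_cols, "rank"]
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for r in regions:
            fields = [
                r.region_id,
                r.chrom,
                str(r.start),
                str(r.end),
                str(r.summit),
                *(_fmt(e, decimal) for e in r.enrichment),
                *(_fmt(f, decimal) for f in r.fdr),
                "" if r.rank is None else str(r.rank),
            ]
            handle.write("\t".join(fields) + "\n")


def write_bed(regions: Sequence[BindingRegion], path: str | Path) -> None:
    """BED6 export: score = replicate-1 enrichment x100 truncated, strand '.'."""
    with open(path, "w") as handle:
        for r in regions:
            score = int(r.enrichment[0] * 100)
            handle.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# Regulation (yes/-) tables
# ---------------------------------------------------------------------------


def _parse_flag(token: str, line: int) -> bool:
    token = str(token).strip()
    if token.lower() == "yes":
        return True
    if token in {"-", ""}:
        return False
    raise FormatError(f"line {line}: unrecognized regulation flag {token!r} (expected 'yes' or '-')")


def read_regulation_table(
    path: str | Path,
    gene_col: str | None = None,
    col_80: str | None = None,
    col_160: str | None = None,
) -> list[RegulationTableRow]:
    """Read a per-gene yes/- down-regulation table.

    Blank flags count as "-"; duplicate gene rows are collapsed by logical
    OR per timepoint (the published tables print flags on the first row of a
    gene only).  Column names default to the first column for the gene and
    any columns containing "80"/"160".
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).fillna("")
    if gene_col is None:
        lowered = {c.lower(): c for c in df.columns}
        gene_col = lowered.get("gene_id") or lowered.get("agi") or df.columns[0]
    if col_80 is None:
        col_80 = next(c for c in df.columns if "80" in c)
    if col_160 is None:
        col_160 = next(c for c in df.columns if "160" in c)
    merged: dict[str, list[bool]] = {}
    for i, row in df.iterrows():
        line = int(i) + 2
        gene = str(row[gene_col]).strip()
        if not gene:
            raise FormatError(f"{path}: line {line}: empty gene identifier")
        d80 = _parse_flag(row[col_80], line)
        d160 = _parse_flag(row[col_160], line)
        if gene in merged:
            merged[gene][0] |= d80
            merged[gene][1] |= d160
        else:
            merged[gene] = [d80, d160]
    return [RegulationTableRow(gene_id=g, down_80=f[0], down_160=f[1]) for g, f in merged.items()]


def write_regulation_table(rows: Sequence[RegulationTableRow], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\t80 min\t160 min\n")
        for r in sorted(rows, key=lambda r: r.gene_id):
            handle.write(f"{r.gene_id}\t{'yes' if r.down_80 else '-'}\t{'yes' if r.down_160 else '-'}\n")


# ---------------------------------------------------------------------------
# Binding-site tables (per-gene anchor positions for factor comparison)
# ---------------------------------------------------------------------------


def read_site_table(path: str | Path) -> dict[str, list[int]]:
    """Read a TSV of (gene_id, position) rows into a gene -> positions map."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).fillna("")
    lowered = {c.lower(): c for c in df.columns}
    gene_col = lowered.get("gene_id", df.columns[0])
    pos_col = lowered.get("position", df.columns[1])
    sites: dict[str, list[int]] = {}
    for i, row in df.iterrows():
        line = int(i) + 2
        gene = str(row[gene_col]).strip()
        try:
            pos = int(str(row[pos_col]).strip())
        except ValueError:
            raise FormatError(f"{path}: line {line}: non-integer position {row[pos_col]!r}") from None
        sites.setdefault(gene, []).append(pos)
    return sites


def write_site_table(sites: Mapping[str, Sequence[int]], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\tposition\n")
        for gene in sorted(sites):
            for pos in sites[gene]:
                handle.write(f"{gene}\t{pos}\n")


# ---------------------------------------------------------------------------
# Packaged fixture tables
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("table1", "table2", "table3")


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture table ("table1", "table2" or "table3")."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return Path(str(resources.files("kanseek").joinpath(f"data/{name}.tsv")))


_NUMERIC_FIXTURE_PREFIXES = ("enrichment", "fdr", "distance", "orp-rank", "rev distance", "kan1 distance")


def read_fixture_table(name_or_path: str | Path) -> pd.DataFrame:
    """Read a packaged (or user) fixture table, parsing comma-decimal cells.

    Numeric columns (enrichment, FDR, distances, rank) become floats with
    NaN for blank cells; flag and label columns stay as strings with blanks
    preserved as empty strings.
    """
    path = fixture_path(str(name_or_path)) if str(name_or_path) in FIXTURE_NAMES else Path(name_or_path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).fillna("")
    for col in df.columns:
        if col.lower().startswith(_NUMERIC_FIXTURE_PREFIXES):
            df[col] = df[col].map(lambda v: float("nan") if not str(v).strip() else parse_decimal(v))
    return df
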