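"""Readers and writers for the external table dialects the pipeline touches.

Every other module consumes only the in-memory domain types produced here:
per-read (or per-contig) taxonomic classifications in the Kaiju per-read
output dialect, profile-HMM per-domain hit tables in the HMMER domtblout
dialect, two-column contig->bin membership tables, and CheckM-style bin QC
summaries. All coordinates stay 1-based inclusive as in the source dialects.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import CANONICAL_RANKS

__all__ = [
    "ReadClassificationRecord",
    "ContigTaxonomyRecord",
    "HmmHitRecord",
    "BinMembership",
    "BinQcRecord",
    "ParseError",
    "read_kaiju_table",
    "read_contig_taxonomy",
    "read_domtblout",
    "read_bin_tables",
    "read_ani_matrix",
    "read_sample_scales",
    "write_table",
    "lineage_to_dict",
]


class ParseError(ValueError):
    """Malformed input table; message names the file and line."""


@dataclasses.dataclass(frozen=True)
class ReadClassificationRecord:
    """One read's taxonomic assignment.

    ``lineage`` is an ordered tuple of (rank, name) pairs following the
    seven canonical ranks superkingdom..species, possibly truncated.
    Unclassified reads carry a null taxon id and an empty lineage.
    """

    read_id: str
    status: str  # "classified" | "unclassified"
    taxon_id: int | None
    lineage: tuple[tuple[str, str], ...]
    sample_id: str

    def __post_init__(self) -> None:
        if self.status not in ("classified", "unclassified"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "unclassified" and (self.taxon_id is not None or self.lineage):
            raise ValueError("unclassified record must have null taxon and empty lineage")
        ranks = [r for r, _ in self.lineage]
        expected = [r for r in CANONICAL_RANKS if r in ranks]
        if ranks != expected or len(set(ranks)) != len(ranks):
            raise ValueError(f"lineage ranks out of order or repeated: {ranks}")

    def rank_name(self, rank: str) -> str | None:
        for r, name in self.lineage:
            if r == rank:
                return name
        return None


# A contig classification is structurally a read classification; the alias
# keeps call sites honest about what is being classified.
ContigTaxonomyRecord = ReadClassificationRecord


@dataclasses.dataclass(frozen=True)
class HmmHitRecord:
    """One accepted profile-HMM domain hit on a contig translation."""

    contig_id: str
    sample_id: str
    gene_symbol: str
    model_length: int
    bit_score: float
    e_value: float
    ali_from: int
    ali_to: int

    def __post_init__(self) -> None:
        if self.ali_from > self.ali_to:
            raise ValueError("ali_from > ali_to")
        if self.e_value < 0:
            raise ValueError("negative e-value")
        if self.model_length <= 0:
            raise ValueError("non-positive model length")


@dataclasses.dataclass(frozen=True)
class BinMembership:
    bin_id: str
    contig_id: str
    sample_id: str


@dataclasses.dataclass(frozen=True)
class BinQcRecord:
    bin_id: str
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"completeness {self.completeness} outside [0, 100]")
        if self.contamination < 0.0:
            raise ValueError(f"negative contamination {self.contamination}")


def _parse_lineage(field: str) -> tuple[tuple[str, str], ...]:
    """Split a semicolon-separated lineage string into (rank, name) pairs.

    Names map positionally onto the seven canonical ranks
    superkingdom..species; trailing empty fields (the dialect ends lines
    with ';') are dropped.
    """
    names = [part.strip() for part in field.split(";")]
    names = [n for n in names if n and n.upper() != "NA"]
    if len(names) > len(CANONICAL_RANKS):
        names = names[: len(CANONICAL_RANKS)]
    return tuple(zip(CANONICAL_RANKS, names))


def read_kaiju_table(path: str | Path, sample_id: str) -> list[ReadClassificationRecord]:
    """Parse a Kaiju-dialect per-read classification table.

    Tab-separated: status (C/U), read id, taxon id, optional
    semicolon-separated lineage names. Blank lines and trailing whitespace
    are tolerated; a repeated read id within the file is an error.
    """
    path = Path(path)
    records: list[ReadClassificationRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            status_tok = fields[0].strip()
            read_id = fields[1].strip()
            if status_tok not in ("C", "U"):
                raise ParseError(f"{path}:{lineno}: bad status token {status_tok!r}")
            if read_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicated read id {read_id!r}")
            seen.add(read_id)
            if status_tok == "U":
                records.append(
                    ReadClassificationRecord(read_id, "unclassified", None, (), sample_id)
                )
                continue
            taxon_id = None
            if len(fields) >= 3 and fields[2].strip():
                try:
                    taxon_id = int(fields[2].strip())
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad taxon id {fields[2]!r}") from exc
            lineage: tuple[tuple[str, str], ...] = ()
            if len(fields) >= 4:
                lineage = _parse_lineage(fields[3])
            records.append(
                ReadClassificationRecord(read_id, "classified", taxon_id, lineage, sample_id)
            )
    return records


# Contig classifications use the identical dialect.
read_contig_taxonomy = read_kaiju_table


_DOMTBLOUT_MIN_COLS = 23  # standard per-domain table width before description


def read_domtblout(
    path: str | Path,
    sample_id: str,
    catalog,
) -> tuple[list[HmmHitRecord], int]:
    """Parse a HMMER per-domain hit table (domtblout dialect).

    One record per non-comment line whose query model resolves — directly
    or via the catalog's KO-code alias map — to a catalog gene symbol.
    Per-domain conditional E-value and domain bit score are kept (domain
    granularity; aggregation happens downstream). Lines whose model is not
    in the catalog are skipped and tallied.

    Returns (records, skipped_count).
    """
    path = Path(path)
    records: list[HmmHitRecord] = []
    skipped = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBLOUT_MIN_COLS:
                raise ParseError(
                    f"{path}:{lineno}: {len(fields)} columns < domtblout minimum "
                    f"{_DOMTBLOUT_MIN_COLS}"
                )
            target_name = fields[0]
            query_name = fields[3]
            symbol = catalog.resolve(query_name)
            if symbol is None:
                skipped += 1
                continue
            qlen = int(fields[5])
            if qlen <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive model length {qlen}")
            i_evalue = float(fields[12])
            dom_score = float(fields[13])
            ali_from = int(fields[17])
            ali_to = int(fields[18])
            if math.isnan(i_evalue) or i_evalue < 0:
                raise ParseError(f"{path}:{lineno}: bad i-Evalue {fields[12]!r}")
            records.append(
                HmmHitRecord(
                    contig_id=target_name,
                    sample_id=sample_id,
                    gene_symbol=symbol,
                    model_length=qlen,
                    bit_score=dom_score,
                    e_value=i_evalue,
                    ali_from=ali_from,
                    ali_to=ali_to,
                )
            )
    return records, skipped


def read_bin_tables(
    membership_path: str | Path,
    qc_path: str | Path,
    sample_id: str,
) -> tuple[list[BinMembership], list[BinQcRecord]]:
    """Read contig->bin membership (two-column TSV) and a CheckM-style QC table.

    Bins present in the QC table but without any contigs are retained (the
    caller sees them with empty contig lists). A contig assigned to two
    bins is an error.
    """
    membership_path = Path(membership_path)
    qc_path = Path(qc_path)

    memberships: list[BinMembership] = []
    contig_bin: dict[str, str] = {}
    with membership_path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{membership_path}:{lineno}: expected 2 columns")
            contig_id, bin_id = fields[0].strip(), fields[1].strip()
            prev = contig_bin.get(contig_id)
            if prev is not None and prev != bin_id:
                raise ParseError(
                    f"{membership_path}:{lineno}: contig {contig_id!r} assigned to "
                    f"both {prev!r} and {bin_id!r}"
                )
            if prev is None:
                contig_bin[contig_id] = bin_id
                memberships.append(BinMembership(bin_id, contig_id, sample_id))

    qc = pd.read_csv(qc_path, sep="\t")
    cols = {c.lower().strip(): c for c in qc.columns}

    def _col(*names: str) -> str:
        for n in names:
            if n in cols:
                return cols[n]
        raise ParseError(f"{qc_path}: missing column; expected one of {names}")

    bin_col = _col("bin_id", "bin id", "bin")
    comp_col = _col("completeness")
    cont_col = _col("contamination")
    qc_records: list[BinQcRecord] = []
    for _, row in qc.iterrows():
        try:
            qc_records.append(
                BinQcRecord(str(row[bin_col]), float(row[comp_col]), float(row[cont_col]))
            )
        except ValueError as exc:
            raise ParseError(f"{qc_path}: bin {row[bin_col]!r}: {exc}") from exc
    return memberships, qc_records


def read_ani_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square ANI matrix TSV (header row and index column of bin ids)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.columns = [str(c) for c in mat.columns]
    mat.index = [str(i) for i in mat.index]
    if list(mat.columns) != list(mat.index):
        raise ParseError(f"{path}: row and column bin ids differ")
    return mat.astype(float)


def read_sample_scales(path: str | Path) -> pd.DataFrame:
    """Read a per-sample scale table: sample_id, genome_equivalents, library_reads."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "genome_equivalents", "library_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df["genome_equivalents"] <= 0).any():
        raise ParseError(f"{path}: genome_equivalents must be positive")
    return df


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    format: str = "tsv",
    sort_by: Sequence[str] | None = None,
) -> None:
    """Write a result table deterministically (stable row and column order).

    Rows sort by ``sort_by`` when given, else by all columns left to right;
    format is ``tsv`` or ``csv``. An empty table yields a header-only file.
    """
    if format not in ("tsv", "csv"):
        raise ValueError(f"unsupported format {format!r}")
    sep = "\t" if format == "tsv" else ","
    out = table.copy()
    keys = list(sort_by) if sort_by else list(out.columns)
    if len(out) and keys:
        out = out.sort_values(keys, kind="mergesort")
    out.to_csv(path, sep=sep, index=False, lineterminator="\n")


def lineage_to_dict(record: ReadClassificationRecord) -> Mapping[str, str]:
    return dict(record.lineage)


def records_to_frame(records: Iterable[ReadClassificationRecord]) -> pd.DataFrame:
    """Flatten classification records into a DataFrame with one rank per column."""
    rows = []
    for rec in records:
        row = {
            "read_id": rec.read_id,
            "sample_id": rec.sample_id,
            "status": rec.status,
            "taxon_id": rec.taxon_id,
        }
        row.update({rank: None for rank in CANONICAL_RANKS})
        row.update(dict(rec.lineage))
        rows.append(row)
    cols = ["read_id", "sample_id", "status", "taxon_id", *CANONICAL_RANKS]
    return pd.DataFrame(rows, columns=cols)
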