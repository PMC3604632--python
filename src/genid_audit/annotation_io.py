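"""Reading and writing gene-annotation and SNP-position tables.

Every loaded table carries a :class:`Provenance` (database name, release,
genome build, access date).  Downstream report rendering refuses tables
without one: silent database versioning is the failure mode this package
exists to prevent.

Coordinate convention
---------------------
All coordinates are **1-based, inclusive** on both ends, matching the
``start-end`` ranges of published annotation tables.  Chromosome labels are
stored without a ``chr`` prefix (``chr22`` and ``22`` are the same label;
scaffold names such as ``Un_gl000244`` are kept verbatim after the prefix
strip).  Note that different vendors disagree on 0- vs 1-based positions —
the SNP audit surfaces candidate off-by-one pairs rather than resolving
them.
"""

from __future__ import annotations

import datetime
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import yaml

__all__ = [
    "Provenance",
    "GeneInterval",
    "GeneRecord",
    "GeneTable",
    "MappedPosition",
    "SnpRecord",
    "TableSchemaError",
    "TableParseError",
    "TableIntegrityError",
    "ValidationError",
    "normalize_chromosome",
    "read_gene_table",
    "write_gene_table",
    "read_snp_table",
    "write_snp_table",
    "UNAVAILABLE_TEXT",
    "LISTED_NO_POSITION_TEXT",
]

UNAVAILABLE_TEXT = "Information Not available"
LISTED_NO_POSITION_TEXT = "SNP is listed, but no position information given"

RSID_RE = re.compile(r"^rs\d+$")
_COORD_RE = re.compile(r"^(\d+)\s*-\s*(\d+)$")
_LOCATION_RE = re.compile(r"^(?:chr)?([\w.]+)\s*:\s*(\d+)$", re.IGNORECASE)

GENE_TABLE_FIXED_COLUMNS = ("GeneID", "Symbol", "Synonyms", "Chromosome", "Description")
SNP_TABLE_COLUMNS = (
    "rsid", "database", "version", "genome_build", "ncbi_build",
    "dbsnp_build", "access_date", "chromosome", "position", "status",
)


class TableSchemaError(ValueError):
    """A required column is missing or the header does not match the dialect."""


class TableParseError(ValueError):
    """A cell could not be parsed; the message names the row and column."""


class TableIntegrityError(ValueError):
    """The table violates a record-level invariant (e.g. duplicate GeneID)."""


class ValidationError(ValueError):
    """A value violates a domain-type invariant."""


def normalize_chromosome(label: str) -> str:
    """Strip a leading ``chr`` prefix and surrounding whitespace.

    ``chr22`` -> ``22``; ``chrUn_gl000244`` -> ``Un_gl000244``; scaffold
    names are otherwise kept verbatim.
    """
    label = label.strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


@dataclass(frozen=True)
class Provenance:
    """Where an annotation fact came from: database, release, build, date.

    ``access_date`` is an ISO-8601 date string or ``"unknown"``.
    """

    database_name: str
    version: str
    genome_build: str
    ncbi_build: str = "Not specified"
    dbsnp_build: str = "Not specified"
    access_date: str = "unknown"

    def __post_init__(self) -> None:
        if not self.database_name.strip():
            raise ValidationError("Provenance.database_name must be non-empty")
        if not self.genome_build.strip():
            raise ValidationError("Provenance.genome_build must be non-empty")
        if self.access_date != "unknown":
            try:
                datetime.date.fromisoformat(self.access_date)
            except ValueError as exc:
                raise ValidationError(
                    f"access_date must be ISO-8601 or 'unknown', got {self.access_date!r}"
                ) from exc

    def to_dict(self) -> dict:
        return {
            "database_name": self.database_name,
            "version": self.version,
            "genome_build": self.genome_build,
            "ncbi_build": self.ncbi_build,
            "dbsnp_build": self.dbsnp_build,
            "access_date": self.access_date,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Provenance":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass(frozen=True)
class GeneInterval:
    """A gene's span on one genome build, 1-based inclusive.

    ``available=False`` encodes a gene absent from (or unplaced in) that
    build; start and end are then None.
    """

    build: str
    chromosome: str
    start: int | None = None
    end: int | None = None
    available: bool = True

    def __post_init__(self) -> None:
        if self.available:
            if self.start is None or self.end is None:
                raise ValidationError(
                    f"available interval on {self.build} requires start and end"
                )
            if not (1 <= self.start <= self.end):
                raise ValidationError(
                    f"interval on {self.build} must satisfy 1 <= start <= end, "
                    f"got {self.start}-{self.end}"
                )
        elif self.start is not None or self.end is not None:
            raise ValidationError("unavailable interval must not carry coordinates")

    @property
    def length(self) -> int | None:
        if not self.available:
            return None
        return self.end - self.start + 1  # type: ignore[operator]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: stable integer id, official symbol, synonyms,
    chromosome, and one interval per genome build."""

    gene_id: int
    official_symbol: str
    synonyms: tuple[str, ...]
    chromosome: str
    description: str
    intervals: Mapping[str, GeneInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gene_id <= 0:
            raise ValidationError(f"gene_id must be positive, got {self.gene_id}")
        if not self.official_symbol.strip():
            raise ValidationError(f"gene {self.gene_id}: official_symbol is empty")
        lowered = {s.casefold() for s in self.synonyms}
        if self.official_symbol.casefold() in lowered:
            raise ValidationError(
                f"gene {self.gene_id}: official symbol "
                f"{self.official_symbol!r} listed among its own synonyms"
            )

    def interval(self, build: str) -> GeneInterval:
        try:
            return self.intervals[build]
        except KeyError:
            raise KeyError(
                f"gene {self.gene_id} ({self.official_symbol}) has no entry "
                f"for build {build!r}; known builds: {sorted(self.intervals)}"
            ) from None


@dataclass
class GeneTable:
    """A collection of gene records plus the provenance they were loaded under."""

    records: list[GeneRecord]
    provenance: Provenance

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self, gene_id: int) -> GeneRecord:
        for rec in self.records:
            if rec.gene_id == gene_id:
                return rec
        raise KeyError(f"no gene with id {gene_id}")

    @property
    def builds(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            for b in rec.intervals:
                seen.setdefault(b)
        return tuple(seen)


_STATUS_VALUES = ("mapped", "listed_no_position", "not_available")


@dataclass(frozen=True)
class MappedPosition:
    """One (database, version, build) placement of an rsID.

    status invariants: ``mapped`` iff chromosome and position are both
    present; ``listed_no_position`` encodes a database that lists the SNP
    without coordinates; ``not_available`` encodes an explicit NA.
    """

    source: Provenance
    chromosome: str | None = None
    position: int | None = None
    status: str = "mapped"

    def __post_init__(self) -> None:
        if self.status not in _STATUS_VALUES:
            raise ValidationError(f"unknown status {self.status!r}")
        has_both = self.chromosome is not None and self.position is not None
        if (self.status == "mapped") != has_both:
            raise ValidationError(
                "status='mapped' requires chromosome and position; other "
                f"statuses forbid them (status={self.status!r}, "
                f"chromosome={self.chromosome!r}, position={self.position!r})"
            )
        if self.position is not None and self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class SnpRecord:
    """An rsID with every placement reported for it across databases."""

    rsid: str
    positions: tuple[MappedPosition, ...] = ()

    def __post_init__(self) -> None:
        if not RSID_RE.match(self.rsid):
            raise ValidationError(f"rsid {self.rsid!r} does not match 'rs<digits>'")

    def mapped(self) -> tuple[MappedPosition, ...]:
        return tuple(p for p in self.positions if p.status == "mapped")


# ---------------------------------------------------------------------------
# provenance sidecars


def _parse_comment_provenance(comments: Sequence[str]) -> Provenance | None:
    keys = {}
    aliases = {
        "db": "database_name", "database": "database_name",
        "database_name": "database_name", "version": "version",
        "build": "genome_build", "genome_build": "genome_build",
        "ncbi_build": "ncbi_build", "dbsnp_build": "dbsnp_build",
        "access_date": "access_date",
    }
    for line in comments:
        body = line.lstrip("#").strip()
        if "=" not in body:
            continue
        key, _, value = body.partition("=")
        key = key.strip().lower()
        if key in aliases:
            keys[aliases[key]] = value.strip()
    if "database_name" in keys and "genome_build" in keys:
        return Provenance(**keys)
    return None


def _load_yaml_sidecar(path: Path) -> Provenance | None:
    sidecar = path.with_suffix(path.suffix + ".provenance.yaml")
    if not sidecar.exists():
        return None
    data = yaml.safe_load(sidecar.read_text(encoding="utf-8"))
    if not isinstance(data, Mapping):
        raise TableSchemaError(f"provenance sidecar {sidecar} is not a mapping")
    return Provenance.from_dict(data)


# ---------------------------------------------------------------------------
# gene tables


def _split_table(path: Path) -> tuple[list[str], list[str]]:
    comments, rows = [], []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            comments.append(line)
        elif line.strip():
            rows.append(line)
    return comments, rows


def read_gene_table(path: str | Path, provenance: Provenance | None = None) -> GeneTable:
    """Load a tab-separated gene-annotation table.

    Dialect: columns ``GeneID  Symbol  Synonyms  Chromosome  Description``
    followed by one ``start-end`` column per build named in the header.
    Synonyms are pipe-delimited; ``-`` means none.  A coordinate cell of
    ``Information Not available`` yields an unavailable interval.

    Provenance resolution order: explicit argument, then a YAML sidecar
    (``<name>.tsv.provenance.yaml``), then ``#key=value`` header comments.
    """
    path = Path(path)
    comments, rows = _split_table(path)
    if provenance is None:
        provenance = _load_yaml_sidecar(path) or _parse_comment_provenance(comments)
    if provenance is None:
        raise TableSchemaError(
            f"{path}: no provenance given and none found in sidecar or header "
            "comments (#db=..., #version=..., #build=...)"
        )
    if not rows:
        raise TableSchemaError(f"{path}: missing header row")
    header = rows[0].split("\t")
    for col in GENE_TABLE_FIXED_COLUMNS:
        if col not in header:
            raise TableSchemaError(f"{path}: missing required column {col!r}")
    if header[: len(GENE_TABLE_FIXED_COLUMNS)] != list(GENE_TABLE_FIXED_COLUMNS):
        raise TableSchemaError(
            f"{path}: fixed columns must lead the header in the order "
            f"{GENE_TABLE_FIXED_COLUMNS}"
        )
    builds = header[len(GENE_TABLE_FIXED_COLUMNS):]
    if not builds:
        raise TableSchemaError(f"{path}: at least one build coordinate column required")

    records: list[GeneRecord] = []
    seen_ids: set[int] = set()
    for rownum, line in enumerate(rows[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise TableParseError(
                f"{path} row {rownum}: expected {len(header)} columns, got {len(cells)}"
            )
        row = dict(zip(header, cells))
        try:
            gene_id = int(row["GeneID"])
        except ValueError:
            raise TableParseError(
                f"{path} row {rownum} column GeneID: {row['GeneID']!r} is not an integer"
            ) from None
        if gene_id in seen_ids:
            raise TableIntegrityError(f"{path} row {rownum}: duplicate GeneID {gene_id}")
        seen_ids.add(gene_id)

        syn_cell = row["Synonyms"].strip()
        synonyms = () if syn_cell in ("-", "") else tuple(
            s.strip() for s in syn_cell.split("|") if s.strip()
        )
        chromosome = normalize_chromosome(row["Chromosome"])

        intervals: dict[str, GeneInterval] = {}
        for build in builds:
            cell = row[build].strip()
            if cell == UNAVAILABLE_TEXT or cell == "":
                intervals[build] = GeneInterval(
                    build=build, chromosome=chromosome, available=False
                )
                continue
            m = _COORD_RE.match(cell)
            if not m:
                raise TableParseError(
                    f"{path} row {rownum} column {build}: malformed coordinate "
                    f"cell {cell!r} (expected 'start-end' or {UNAVAILABLE_TEXT!r})"
                )
            start, end = int(m.group(1)), int(m.group(2))
            try:
                intervals[build] = GeneInterval(build, chromosome, start, end)
            except ValidationError as exc:
                raise TableParseError(f"{path} row {rownum} column {build}: {exc}") from None

        records.append(
            GeneRecord(
                gene_id=gene_id,
                official_symbol=row["Symbol"].strip(),
                synonyms=synonyms,
                chromosome=chromosome,
                description=row["Description"].strip(),
                intervals=intervals,
            )
        )
    return GeneTable(records=records, provenance=provenance)


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    """Write a gene table in the dialect :func:`read_gene_table` reads.

    Provenance is embedded as ``#key=value`` header comments so the
    round-trip is self-contained.
    """
    path = Path(path)
    builds = table.builds
    prov = table.provenance
    lines = [
        f"# db={prov.database_name}",
        f"# version={prov.version}",
        f"# build={prov.genome_build}",
        f"# ncbi_build={prov.ncbi_build}",
        f"# dbsnp_build={prov.dbsnp_build}",
        f"# access_date={prov.access_date}",
        "\t".join(GENE_TABLE_FIXED_COLUMNS + builds),
    ]
    for rec in table.records:
        cells = [
            str(rec.gene_id),
            rec.official_symbol,
            "|".join(rec.synonyms) if rec.synonyms else "-",
            rec.chromosome,
            rec.description,
        ]
        for build in builds:
            iv = rec.intervals.get(build)
            if iv is None or not iv.available:
                cells.append(UNAVAILABLE_TEXT)
            else:
                cells.append(f"{iv.start}-{iv.end}")
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# SNP tables


def _parse_location_cell(cell: str) -> tuple[str | None, int | None, str]:
    """Parse a combined location cell: 'chr22: 14459242', the listed-but-no-
    position sentence, or 'NA'."""
    cell = cell.strip()
    if cell == LISTED_NO_POSITION_TEXT:
        return None, None, "listed_no_position"
    if cell in ("NA", "", "-"):
        return None, None, "not_available"
    m = _LOCATION_RE.match(cell)
    if not m:
        raise TableParseError(f"malformed location cell {cell!r}")
    return normalize_chromosome(m.group(1)), int(m.group(2)), "mapped"


def read_snp_table(path: str | Path, on_bad_rsid: str = "error") -> list[SnpRecord]:
    """Load a tab-separated SNP position table into :class:`SnpRecord` s.

    One row per (rsid, database, version, build, chromosome, position)
    mapping; rows are grouped by rsid preserving first-seen order.  Either
    separate ``chromosome``/``position``/``status`` columns or a single
    ``location`` column ('chrN:pos' strings and the published sentinel
    texts) are accepted.

    on_bad_rsid: 'error' raises on an rsid not matching ``rs<digits>``;
    'warn' emits a warning and keeps the row out of the result.
    """
    if on_bad_rsid not in ("error", "warn"):
        raise ValueError(f"on_bad_rsid must be 'error' or 'warn', got {on_bad_rsid!r}")
    path = Path(path)
    _, rows = _split_table(path)
    if not rows:
        raise TableSchemaError(f"{path}: missing header row")
    header = rows[0].split("\t")
    combined = "location" in header
    required = ["rsid", "database", "version", "genome_build"]
    required += ["location"] if combined else ["chromosome", "position", "status"]
    for col in required:
        if col not in header:
            raise TableSchemaError(f"{path}: missing required column {col!r}")

    grouped: dict[str, list[MappedPosition]] = {}
    for rownum, line in enumerate(rows[1:], start=2):
        cells = line.split("\t")
        if len(cells) < len(header):
            cells += [""] * (len(header) - len(cells))
        row = dict(zip(header, cells))
        rsid = row["rsid"].strip()
        if not RSID_RE.match(rsid):
            msg = f"{path} row {rownum}: rsid {rsid!r} does not match 'rs<digits>'"
            if on_bad_rsid == "error":
                raise ValidationError(msg)
            warnings.warn(msg)
            continue
        source = Provenance(
            database_name=row["database"].strip(),
            version=row["version"].strip(),
            genome_build=row["genome_build"].strip(),
            ncbi_build=row.get("ncbi_build", "Not specified").strip() or "Not specified",
            dbsnp_build=row.get("dbsnp_build", "Not specified").strip() or "Not specified",
            access_date=row.get("access_date", "unknown").strip() or "unknown",
        )
        if combined:
            try:
                chromosome, position, status = _parse_location_cell(row["location"])
            except TableParseError as exc:
                raise TableParseError(f"{path} row {rownum} column location: {exc}") from None
        else:
            status = row["status"].strip() or "mapped"
            chrom_cell = row["chromosome"].strip()
            pos_cell = row["position"].strip()
            chromosome = normalize_chromosome(chrom_cell) if chrom_cell else None
            if status == "mapped":
                if not pos_cell.isdigit():
                    raise TableParseError(
                        f"{path} row {rownum} column position: {pos_cell!r} is "
                        "not a number but status is 'mapped'"
                    )
                position = int(pos_cell)
            else:
                position = None
                chromosome = chromosome or None
        try:
            mp = MappedPosition(source=source, chromosome=chromosome,
                                position=position, status=status)
        except ValidationError as exc:
            raise TableParseError(f"{path} row {rownum}: {exc}") from None
        grouped.setdefault(rsid, []).append(mp)

    return [SnpRecord(rsid=r, positions=tuple(ps)) for r, ps in grouped.items()]


def write_snp_table(snps: Sequence[SnpRecord], path: str | Path) -> None:
    """Write SNP records in the column dialect :func:`read_snp_table` reads."""
    path = Path(path)
    lines = ["\t".join(SNP_TABLE_COLUMNS)]
    for snp in snps:
        for mp in snp.positions:
            s = mp.source
            lines.append("\t".join([
                snp.rsid, s.database_name, s.version, s.genome_build,
                s.ncbi_build, s.dbsnp_build, s.access_date,
                mp.chromosome or "", "" if mp.position is None else str(mp.position),
                mp.status,
            ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
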