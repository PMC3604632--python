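"""Provenance-stamped audit reports.

A result that cannot be traced to a named database release is not
reproducible, so every report embeds the database name, version, genome
build and access date of every input table, and rendering refuses inputs
lacking provenance.  Reports serialize to JSON (schema-checked,
round-trip-lossless), TSV (one section per file) and a human-readable
text summary.

Percentages are rendered at one decimal place with round-half-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Any, Mapping, Sequence

from . import __version__
from .annotation_io import Provenance

__all__ = [
    "AuditReport",
    "MissingProvenanceError",
    "ReportSchemaError",
    "render_report",
    "parse_report_json",
    "validate_report_dict",
    "format_percent",
    "exit_code",
    "EXIT_CLEAN",
    "EXIT_ERROR",
    "EXIT_WARNINGS",
]

EXIT_CLEAN = 0
EXIT_ERROR = 1
EXIT_WARNINGS = 3

SECTION_NAMES = ("resolution", "ambiguity_census", "snp_census", "concordance", "shifts")


class MissingProvenanceError(ValueError):
    """An input table has no usable provenance; the message names it."""


class ReportSchemaError(ValueError):
    """A report document does not match the expected structure."""


def format_percent(numerator: int | float, denominator: int | float) -> str:
    """Render numerator/denominator as a percentage at one decimal place,
    round-half-up (805555 over 54212080 renders as '1.5%')."""
    if denominator == 0:
        return "0.0%"
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return f"{pct.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"


@dataclass
class AuditReport:
    """Assembled audit findings plus the provenance of every input.

    ``sections`` holds plain JSON-serializable mappings keyed by section
    name (resolution, ambiguity_census, snp_census, concordance, shifts);
    ``warnings`` is a flat list of ``{"kind": ..., "message": ...}``
    entries (dual-role terms, build mismatches, off-by-one flags, ...).
    """

    provenances: list[Provenance]
    sections: dict[str, Any] = field(default_factory=dict)
    warnings: list[dict] = field(default_factory=list)
    tool_version: str = __version__
    timestamp: str = "unknown"

    def add_warning(self, kind: str, message: str) -> None:
        self.warnings.append({"kind": kind, "message": message})

    def to_dict(self) -> dict:
        return {
            "tool": "genid-audit",
            "tool_version": self.tool_version,
            "timestamp": self.timestamp,
            "provenances": [p.to_dict() for p in self.provenances],
            "sections": self.sections,
            "warnings": self.warnings,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AuditReport":
        validate_report_dict(dict(d))
        return cls(
            provenances=[Provenance.from_dict(p) for p in d["provenances"]],
            sections=dict(d["sections"]),
            warnings=list(d["warnings"]),
            tool_version=d["tool_version"],
            timestamp=d["timestamp"],
        )


_PROVENANCE_KEYS = (
    "database_name", "version", "genome_build", "ncbi_build",
    "dbsnp_build", "access_date",
)


def validate_report_dict(doc: Any) -> None:
    """Structural check of a report document; raises ReportSchemaError.

    Required: tool/tool_version/timestamp strings, a non-empty provenances
    list whose entries carry all six provenance keys with non-empty
    database_name and genome_build, a sections mapping with known section
    names, and a warnings list of {kind, message} mappings.
    """
    if not isinstance(doc, Mapping):
        raise ReportSchemaError("report document must be a mapping")
    for key in ("tool", "tool_version", "timestamp"):
        if not isinstance(doc.get(key), str):
            raise ReportSchemaError(f"missing or non-string field {key!r}")
    provs = doc.get("provenances")
    if not isinstance(provs, list) or not provs:
        raise ReportSchemaError("provenances must be a non-empty list")
    for i, p in enumerate(provs):
        if not isinstance(p, Mapping):
            raise ReportSchemaError(f"provenances[{i}] must be a mapping")
        for k in _PROVENANCE_KEYS:
            if not isinstance(p.get(k), str):
                raise ReportSchemaError(f"provenances[{i}] missing field {k!r}")
        if not p["database_name"].strip() or not p["genome_build"].strip():
            raise ReportSchemaError(
                f"provenances[{i}]: database_name and genome_build must be non-empty"
            )
    sections = doc.get("sections")
    if not isinstance(sections, Mapping):
        raise ReportSchemaError("sections must be a mapping")
    for name in sections:
        if name not in SECTION_NAMES:
            raise ReportSchemaError(
                f"unknown section {name!r}; expected one of {SECTION_NAMES}"
            )
    warns = doc.get("warnings")
    if not isinstance(warns, list):
        raise ReportSchemaError("warnings must be a list")
    for i, w in enumerate(warns):
        if not isinstance(w, Mapping) or "kind" not in w or "message" not in w:
            raise ReportSchemaError(f"warnings[{i}] must carry 'kind' and 'message'")


def _require_provenance(report: AuditReport) -> None:
    if not report.provenances:
        raise MissingProvenanceError(
            "report has no input provenances; every input table must be "
            "loaded with a database name, version, build and access date"
        )
    for i, p in enumerate(report.provenances):
        if not p.database_name.strip() or not p.genome_build.strip():
            raise MissingProvenanceError(
                f"input table #{i + 1} lacks a database name or genome build"
            )


def _render_json(report: AuditReport) -> str:
    doc = report.to_dict()
    validate_report_dict(doc)
    return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def _provenance_lines(report: AuditReport) -> list[str]:
    lines = []
    for p in report.provenances:
        lines.append(
            f"  - {p.database_name} | version {p.version} | build "
            f"{p.genome_build} | NCBI {p.ncbi_build} | dbSNP {p.dbsnp_build} "
            f"| accessed {p.access_date}"
        )
    return lines


def _flatten(prefix: str, value: Any, out: list[tuple[str, str]]) -> None:
    if isinstance(value, Mapping):
        for k, v in value.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, out)
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            _flatten(f"{prefix}[{i}]", v, out)
    else:
        out.append((prefix, "" if value is None else str(value)))


def _render_tsv(report: AuditReport) -> dict[str, str]:
    """One TSV document per section, plus a 'provenance' and a 'warnings'
    document.  Values are flattened to key<TAB>value rows."""
    docs: dict[str, str] = {}
    prov_rows = ["field\tvalue"]
    for i, p in enumerate(report.provenances):
        for k, v in p.to_dict().items():
            prov_rows.append(f"input{i + 1}.{k}\t{v}")
    docs["provenance"] = "\n".join(prov_rows) + "\n"
    for name, payload in report.sections.items():
        flat: list[tuple[str, str]] = []
        _flatten("", payload, flat)
        docs[name] = "\n".join(["key\tvalue"] + [f"{k}\t{v}" for k, v in flat]) + "\n"
    warn_rows = ["kind\tmessage"] + [f"{w['kind']}\t{w['message']}" for w in report.warnings]
    docs["warnings"] = "\n".join(warn_rows) + "\n"
    return docs


def _summarize_section(name: str, payload: Any) -> list[str]:
    lines = [f"[{name}]"]
    if name == "snp_census" and isinstance(payload, Mapping):
        total = payload.get("n_total_rsids", 0)
        multi_chrom = payload.get("n_multi_chromosome_rsids", 0)
        for k, v in payload.items():
            lines.append(f"  {k}: {v}")
        lines.append(
            f"  multi-chromosome rsIDs: {multi_chrom} of {total} "
            f"({format_percent(multi_chrom, total)})"
        )
    elif isinstance(payload, Mapping):
        for k, v in payload.items():
            if isinstance(v, (str, int, float, bool)) or v is None:
                lines.append(f"  {k}: {v}")
            else:
                lines.append(f"  {k}: {json.dumps(v, ensure_ascii=False)}")
    else:
        lines.append(f"  {json.dumps(payload, ensure_ascii=False)}")
    return lines


def _render_text(report: AuditReport) -> str:
    lines = [
        f"genid-audit report (tool version {report.tool_version}, "
        f"run {report.timestamp})",
        "input provenance:",
        *_provenance_lines(report),
    ]
    for name in SECTION_NAMES:
        if name in report.sections:
            lines.extend(_summarize_section(name, report.sections[name]))
    if report.warnings:
        lines.append(f"warnings ({len(report.warnings)}):")
        for w in report.warnings:
            lines.append(f"  [{w['kind']}] {w['message']}")
    else:
        lines.append("warnings: none")
    return "\n".join(lines) + "\n"


def render_report(report: AuditReport, format: str = "json") -> str | dict[str, str]:
    """Serialize an audit report.

    json -> one schema-validated string (lossless round-trip through
    :func:`parse_report_json`); tsv -> a dict of section name to TSV
    document (one section per file); text -> a human-readable summary.
    All formats embed every input's database name, version, build and
    access date.  Raises :class:`MissingProvenanceError` if any input
    lacks provenance.
    """
    _require_provenance(report)
    if format == "json":
        return _render_json(report)
    if format == "tsv":
        return _render_tsv(report)
    if format == "text":
        return _render_text(report)
    raise ValueError(f"unknown format {format!r}; expected json, tsv or text")


def parse_report_json(text: str) -> AuditReport:
    """Inverse of ``render_report(..., 'json')``."""
    return AuditReport.from_dict(json.loads(text))


def exit_code(report: AuditReport) -> int:
    """Pipeline gating: 0 when clean, 3 when hygiene warnings are present."""
    return EXIT_WARNINGS if report.warnings else EXIT_CLEAN
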