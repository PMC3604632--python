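"""Cross-build gene-boundary shifts, stale-coordinate lookups, and
build-matched SNP-to-gene assignment.

Gene boundaries move between genome assemblies — usually by a handful of
bases, occasionally by megabases (the high-affinity Fc receptor FCAMR
moved almost two million bases from Hg18 to Hg19).  Coordinates are only
comparable within one build: querying an Hg19 annotation with Hg17
coordinates can return an entirely different gene.  This module quantifies
boundary shifts, replays stale lookups to show what they would retrieve,
and refuses SNP-to-gene assignment across mismatched builds unless
explicitly overridden.

No coordinate conversion is performed here; converting between assemblies
is the job of chain-file tools (liftOver).  This module only detects and
refuses mismatches.

Interval arithmetic is 1-based inclusive throughout; the intersection
length of two intervals is ``min(e1, e2) - max(s1, s2) + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .annotation_io import GeneInterval, GeneRecord, GeneTable, normalize_chromosome

__all__ = [
    "DEFAULT_SHIFT_THRESHOLD",
    "ShiftResult",
    "OverlapHit",
    "SnpGeneResult",
    "BuildMismatchError",
    "boundary_shift",
    "stale_lookup_check",
    "snp_to_gene",
]

#: Default boundary-shift flag threshold, in bp.  Megabase-scale moves are
#: the ones that silently relocate a gene past its neighbours.
DEFAULT_SHIFT_THRESHOLD = 1_000_000


class BuildMismatchError(ValueError):
    """Raised when a query and an annotation use different genome builds."""


@dataclass(frozen=True)
class ShiftResult:
    """Signed boundary displacement of one gene between two builds.

    Deltas are ``to - from``; antisymmetric under swapping the builds.
    ``comparable=False`` (with a reason) means one side's interval is
    unavailable and no deltas are defined.
    """

    gene_id: int
    official_symbol: str
    build_from: str
    build_to: str
    comparable: bool
    delta_start: int | None = None
    delta_end: int | None = None
    threshold: int = DEFAULT_SHIFT_THRESHOLD
    reason: str = ""

    @property
    def max_abs_shift(self) -> int | None:
        if not self.comparable:
            return None
        return max(abs(self.delta_start), abs(self.delta_end))  # type: ignore[arg-type]

    @property
    def large_shift_flag(self) -> bool:
        return self.large_shift(self.threshold)

    def large_shift(self, threshold: int = DEFAULT_SHIFT_THRESHOLD) -> bool:
        return self.comparable and self.max_abs_shift > threshold  # type: ignore[operator]

    def to_dict(self, threshold: int | None = None) -> dict:
        threshold = self.threshold if threshold is None else threshold
        return {
            "gene_id": self.gene_id,
            "official_symbol": self.official_symbol,
            "build_from": self.build_from,
            "build_to": self.build_to,
            "comparable": self.comparable,
            "delta_start": self.delta_start,
            "delta_end": self.delta_end,
            "max_abs_shift": self.max_abs_shift,
            "large_shift_flag": self.large_shift(threshold),
            "reason": self.reason,
        }


@dataclass(frozen=True)
class OverlapHit:
    """One gene whose interval intersects a query, with the overlap size."""

    gene_id: int
    official_symbol: str
    chromosome: str
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValueError("an overlap hit requires >= 1 bp of intersection")

    def to_dict(self) -> dict:
        return {"gene_id": self.gene_id, "official_symbol": self.official_symbol,
                "chromosome": self.chromosome, "overlap_bp": self.overlap_bp}


@dataclass(frozen=True)
class SnpGeneResult:
    """Genes assigned to a SNP position, stamped with both build labels.

    ``build_mismatch`` is True only when the caller forced an assignment
    across builds; such results are watermarked, not trusted.
    """

    hits: tuple[OverlapHit, ...]
    query_build: str
    annotation_build: str
    flank: int

    @property
    def build_mismatch(self) -> bool:
        return self.query_build != self.annotation_build

    def to_dict(self) -> dict:
        d = {
            "hits": [h.to_dict() for h in self.hits],
            "query_build": self.query_build,
            "annotation_build": self.annotation_build,
            "flank": self.flank,
            "build_mismatch": self.build_mismatch,
        }
        if self.build_mismatch:
            d["watermark"] = "BUILD MISMATCH"
        return d


def boundary_shift(
    record: GeneRecord,
    build_from: str,
    build_to: str,
    threshold: int = DEFAULT_SHIFT_THRESHOLD,
) -> ShiftResult:
    """Signed start/end displacement of one gene between two builds.

    Both builds must have entries in the record's interval map (an unknown
    label raises KeyError); an entry marked unavailable yields a
    not-comparable result naming the missing side.
    """
    iv_from = record.interval(build_from)
    iv_to = record.interval(build_to)
    missing = [iv.build for iv in (iv_from, iv_to) if not iv.available]
    if missing:
        return ShiftResult(
            gene_id=record.gene_id, official_symbol=record.official_symbol,
            build_from=build_from, build_to=build_to, comparable=False,
            threshold=threshold,
            reason=f"interval unavailable on build(s): {', '.join(missing)}",
        )
    return ShiftResult(
        gene_id=record.gene_id, official_symbol=record.official_symbol,
        build_from=build_from, build_to=build_to, comparable=True,
        delta_start=iv_to.start - iv_from.start,  # type: ignore[operator]
        delta_end=iv_to.end - iv_from.end,  # type: ignore[operator]
        threshold=threshold,
    )


def _build_trees(
    records: Iterable[GeneRecord], build: str, flank: int = 0
) -> dict[str, IntervalTree]:
    """One interval tree per chromosome over [start-flank, end+flank].

    1-based inclusive intervals become half-open [start, end+1) tree
    entries.
    """
    trees: dict[str, IntervalTree] = {}
    for rec in records:
        iv = rec.intervals.get(build)
        if iv is None or not iv.available:
            continue
        chrom = normalize_chromosome(iv.chromosome)
        lo = max(1, iv.start - flank)  # type: ignore[operator]
        hi = iv.end + flank  # type: ignore[operator]
        trees.setdefault(chrom, IntervalTree()).addi(lo, hi + 1, rec)
    return trees


def _sorted_hits(raw: list[tuple[int, GeneRecord]]) -> tuple[OverlapHit, ...]:
    # descending overlap, ties by ascending gene_id
    raw.sort(key=lambda t: (-t[0], t[1].gene_id))
    return tuple(
        OverlapHit(gene_id=rec.gene_id, official_symbol=rec.official_symbol,
                   chromosome=rec.chromosome, overlap_bp=bp)
        for bp, rec in raw
    )


def stale_lookup_check(
    query: GeneInterval,
    annotation: Sequence[GeneRecord] | GeneTable,
    annotation_build: str,
) -> tuple[OverlapHit, ...]:
    """Replay an interval lookup against an annotation build.

    Returns every gene whose ``annotation_build`` interval intersects the
    query, sorted by descending overlap length.  The query carries its own
    build label, so a stale query (coordinates from an older build) is
    visible in the output: when ``query.build != annotation_build`` the
    hits show what a coordinate-only lookup *would* return — possibly the
    wrong gene entirely.
    """
    if not query.available:
        raise ValueError("query interval carries no coordinates")
    records = annotation.records if isinstance(annotation, GeneTable) else annotation
    trees = _build_trees(records, annotation_build)
    chrom = normalize_chromosome(query.chromosome)
    tree = trees.get(chrom)
    if tree is None:
        return ()
    raw = []
    for node in tree.overlap(query.start, query.end + 1):  # type: ignore[operator]
        rec: GeneRecord = node.data
        iv = rec.intervals[annotation_build]
        overlap = min(iv.end, query.end) - max(iv.start, query.start) + 1  # type: ignore[operator, type-var]
        raw.append((overlap, rec))
    return _sorted_hits(raw)


def snp_to_gene(
    position: tuple[str, str, int],
    annotation: Sequence[GeneRecord] | GeneTable,
    annotation_build: str,
    flank: int = 0,
    force: bool = False,
) -> SnpGeneResult:
    """Assign a SNP position to genes whose flanked interval contains it.

    ``position`` is a (build, chromosome, bp) triple.  A gene is hit when
    ``start - flank <= bp <= end + flank`` on ``annotation_build``.  If the
    position's build differs from the annotation's the call refuses with
    :class:`BuildMismatchError` naming both builds, unless ``force=True``
    — then the result is watermarked ``BUILD MISMATCH``.
    """
    build, chromosome, bp = position
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    if bp < 1:
        raise ValueError(f"position must be >= 1, got {bp}")
    if build != annotation_build and not force:
        raise BuildMismatchError(
            f"query position is on build {build!r} but the annotation is "
            f"{annotation_build!r}; coordinates are not comparable across "
            "builds — convert first (e.g. liftOver) or pass force=True to "
            "get a watermarked result"
        )
    records = annotation.records if isinstance(annotation, GeneTable) else annotation
    trees = _build_trees(records, annotation_build, flank=flank)
    chrom = normalize_chromosome(chromosome)
    tree = trees.get(chrom)
    raw = []
    if tree is not None:
        for node in tree.at(bp):
            rec: GeneRecord = node.data
            iv = rec.intervals[annotation_build]
            overlap = min(iv.end, bp) - max(iv.start, bp) + 1  # type: ignore[operator, type-var]
            # a point query inside the flank but outside the gene body still
            # counts as a hit; report 1 bp in that case
            raw.append((max(overlap, 1), rec))
    return SnpGeneResult(hits=_sorted_hits(raw), query_build=build,
                         annotation_build=annotation_build, flank=flank)
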