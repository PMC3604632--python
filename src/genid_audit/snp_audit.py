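"""Auditing rsID multi-mapping and cross-database position concordance.

A single rsID can carry several genomic placements — across database
versions, across genome builds, and even across chromosomes within one
build (segmental duplications are a common cause).  Conversely one base
pair coordinate can be claimed by many rsIDs.  Either situation silently
changes which gene a variant maps to, so this module counts both
directions of multi-mapping and reports per-SNP concordance, including
candidate 0/1-based coordinate-convention discrepancies between vendors.

Counting conventions
--------------------
Exact duplicate placements (same rsid, source, build, chromosome,
position, status) are deduplicated before counting: multi-source tables
legitimately repeat concordant rows.  "Distinct" means exact equality
after chromosome normalization; scaffold placements (``Un_gl000244``)
count as distinct chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .annotation_io import MappedPosition, SnpRecord, normalize_chromosome

__all__ = [
    "MultimapCensus",
    "OffByOneFlag",
    "ConcordanceReport",
    "multimap_census",
    "position_concordance",
    "filter_positions",
]


def filter_positions(
    snp: SnpRecord,
    database: str | None = None,
    build: str | None = None,
    dbsnp_build: str | None = None,
) -> SnpRecord:
    """Restrict an rsID's placements to one database / build / dbSNP release.

    Returns a new record; placements failing any given criterion are
    dropped.  Useful for auditing a single (database, version) slice of a
    pooled multi-source table.
    """
    kept = tuple(
        mp for mp in snp.positions
        if (database is None or mp.source.database_name == database)
        and (build is None or mp.source.genome_build == build)
        and (dbsnp_build is None or mp.source.dbsnp_build == dbsnp_build)
    )
    return SnpRecord(rsid=snp.rsid, positions=kept)


@dataclass(frozen=True)
class MultimapCensus:
    """Corpus-wide multi-mapping counts.

    ``fraction_multi_chromosome`` uses the rsID count as denominator;
    ``n_total_mappings`` (deduplicated mapped placements) is reported
    alongside so the alternative denominator is always available.
    """

    n_total_rsids: int
    n_total_mappings: int
    n_multi_coordinate_rsids: int
    n_multi_chromosome_rsids: int
    fraction_multi_chromosome: float
    n_shared_coordinates: int
    max_rsids_per_coordinate: int
    within_build: str

    def to_dict(self) -> dict:
        return {
            "n_total_rsids": self.n_total_rsids,
            "n_total_mappings": self.n_total_mappings,
            "n_multi_coordinate_rsids": self.n_multi_coordinate_rsids,
            "n_multi_chromosome_rsids": self.n_multi_chromosome_rsids,
            "fraction_multi_chromosome": self.fraction_multi_chromosome,
            "n_shared_coordinates": self.n_shared_coordinates,
            "max_rsids_per_coordinate": self.max_rsids_per_coordinate,
            "within_build": self.within_build,
        }


@dataclass(frozen=True)
class OffByOneFlag:
    """Two placements of one rsID on the same build and chromosome whose
    positions differ by exactly 1 bp and that come from different source
    databases — the signature of a 0- vs 1-based convention mismatch."""

    build: str
    chromosome: str
    position_low: int
    position_high: int
    sources_low: tuple[str, ...]
    sources_high: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "build": self.build,
            "chromosome": self.chromosome,
            "position_low": self.position_low,
            "position_high": self.position_high,
            "sources_low": list(self.sources_low),
            "sources_high": list(self.sources_high),
        }


@dataclass(frozen=True)
class ConcordanceReport:
    """Per-rsID cross-database concordance summary.

    ``positions_by_group`` maps (build, chromosome) to the sorted distinct
    positions observed there; every mapped placement of the input lands in
    exactly one group.  Placements without coordinates are listed under
    ``unmapped`` and never counted as discordant positions.
    """

    rsid: str
    distinct_chromosomes: tuple[str, ...]
    positions_by_group: Mapping[tuple[str, str], tuple[int, ...]]
    off_by_one_flags: tuple[OffByOneFlag, ...]
    unmapped: tuple[MappedPosition, ...]

    @property
    def is_concordant(self) -> bool:
        return (len(self.distinct_chromosomes) <= 1
                and all(len(ps) == 1 for ps in self.positions_by_group.values()))

    def to_dict(self) -> dict:
        return {
            "rsid": self.rsid,
            "distinct_chromosomes": list(self.distinct_chromosomes),
            "groups": [
                {"build": b, "chromosome": c, "positions": list(ps)}
                for (b, c), ps in sorted(self.positions_by_group.items())
            ],
            "off_by_one_flags": [f.to_dict() for f in self.off_by_one_flags],
            "unmapped": [
                {"status": mp.status, "source": mp.source.to_dict()}
                for mp in self.unmapped
            ],
        }


def _dedup_key(rsid: str, mp: MappedPosition):
    return (rsid, mp.source, mp.chromosome, mp.position, mp.status)


def _dedup_mapped(snp: SnpRecord) -> list[MappedPosition]:
    seen, out = set(), []
    for mp in snp.positions:
        key = _dedup_key(snp.rsid, mp)
        if key not in seen:
            seen.add(key)
            out.append(mp)
    return out


def multimap_census(
    snps: Iterable[SnpRecord],
    within_build: str = "all",
) -> MultimapCensus:
    """Count multi-coordinate and multi-chromosome rsIDs and shared coordinates.

    With ``within_build="all"`` (default) placements from every build are
    pooled and distinctness is judged on (build, chromosome, position)
    triples, so the same locus reported under two builds counts as two
    coordinates.  With a build label, only that build's placements are
    counted and distinctness is judged on (chromosome, position).

    Multi-chromosome counts rsIDs placed on >=2 distinct chromosomes within
    the same scope.  Shared-coordinate counts run over the same keys in the
    opposite direction: coordinates claimed by >=2 distinct rsIDs.
    """
    snps = list(snps)
    n_total = len(snps)
    n_mappings = 0
    n_multi_coord = 0
    n_multi_chrom = 0
    coord_claims: dict[tuple, set[str]] = {}

    for snp in snps:
        coords: set[tuple] = set()
        chroms: set[str] = set()
        for mp in _dedup_mapped(snp):
            if mp.status != "mapped":
                continue
            build = mp.source.genome_build
            if within_build != "all" and build != within_build:
                continue
            chrom = normalize_chromosome(mp.chromosome)  # type: ignore[arg-type]
            key = (build, chrom, mp.position) if within_build == "all" \
                else (chrom, mp.position)
            coords.add(key)
            chroms.add(chrom)
            coord_claims.setdefault((build, chrom, mp.position), set()).add(snp.rsid)
        n_mappings += len(coords)
        if len(coords) >= 2:
            n_multi_coord += 1
        if len(chroms) >= 2:
            n_multi_chrom += 1

    shared = {c: rs for c, rs in coord_claims.items() if len(rs) >= 2}
    return MultimapCensus(
        n_total_rsids=n_total,
        n_total_mappings=n_mappings,
        n_multi_coordinate_rsids=n_multi_coord,
        n_multi_chromosome_rsids=n_multi_chrom,
        fraction_multi_chromosome=(n_multi_chrom / n_total) if n_total else 0.0,
        n_shared_coordinates=len(shared),
        max_rsids_per_coordinate=max(
            (len(rs) for rs in coord_claims.values()), default=0
        ),
        within_build=within_build,
    )


def position_concordance(snp: SnpRecord) -> ConcordanceReport:
    """Group one rsID's placements by (build, chromosome) and flag candidate
    0/1-based discrepancies.

    A flag is emitted per distinct adjacent position pair (p, p+1) within a
    (build, chromosome) group when the two positions are reported by
    different source databases; two positions from a single source
    differing by 1 appear as plain discordance (two positions in the
    group), not as a flag.
    """
    groups: dict[tuple[str, str], dict[int, set[str]]] = {}
    unmapped: list[MappedPosition] = []
    chroms: dict[str, None] = {}
    for mp in _dedup_mapped(snp):
        if mp.status != "mapped":
            unmapped.append(mp)
            continue
        chrom = normalize_chromosome(mp.chromosome)  # type: ignore[arg-type]
        chroms.setdefault(chrom)
        key = (mp.source.genome_build, chrom)
        groups.setdefault(key, {}).setdefault(mp.position, set()).add(  # type: ignore[arg-type]
            mp.source.database_name
        )

    flags: list[OffByOneFlag] = []
    for (build, chrom), by_pos in sorted(groups.items()):
        positions = sorted(by_pos)
        for lo, hi in zip(positions, positions[1:]):
            if hi - lo != 1:
                continue
            src_lo, src_hi = by_pos[lo], by_pos[hi]
            # different sources on the two sides of the 1-bp gap
            if src_lo != src_hi or len(src_lo) > 1:
                flags.append(OffByOneFlag(
                    build=build, chromosome=chrom,
                    position_low=lo, position_high=hi,
                    sources_low=tuple(sorted(src_lo)),
                    sources_high=tuple(sorted(src_hi)),
                ))

    return ConcordanceReport(
        rsid=snp.rsid,
        distinct_chromosomes=tuple(chroms),
        positions_by_group={k: tuple(sorted(v)) for k, v in groups.items()},
        off_by_one_flags=tuple(flags),
        unmapped=tuple(unmapped),
    )
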