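"""Synthetic annotation and SNP tables with planted, known ground truth.

The full-scale public censuses (tens of thousands of gene symbols, tens of
millions of rsIDs) require historical database dumps, so correctness here
is established structurally: every ambiguity and multi-mapping statistic
the audit modules compute can be *planted* in a synthetic table at an
exact count, and recovery is checked count-for-count.  Counts, not rates,
are planted so recovery checks are exact integer comparisons.

Structure, not scale, is emulated: synthetic gene symbols use a collision
free alphabet (``G000001`` ... with synonyms derived by suffixing), so the
only ambiguity present is the ambiguity planted.

The module also ships the two published case-study fixtures: a six-gene
annotation table spanning three genome builds (the TOSO/FAIM3 and ADRA1A
naming tangles, plus the FCAMR build shift), and the full multi-database
position report for SNP rs2844871.  A third fixture variant plants a
synthetic OPTC-like record into the Hg19 annotation to reproduce the
stale-coordinate wrong-gene retrieval; the planted coordinates are
fabricated (only the retrieval behaviour is meaningful, not the numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from .annotation_io import (
    GeneInterval,
    GeneRecord,
    GeneTable,
    MappedPosition,
    Provenance,
    SnpRecord,
    read_gene_table,
    read_snp_table,
)

__all__ = [
    "ShiftModel",
    "GeneTableSpec",
    "SnpTableSpec",
    "GeneGroundTruth",
    "SnpGroundTruth",
    "InfeasibleSpecError",
    "generate_gene_table",
    "generate_snp_table",
    "load_fixture",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("table1", "table1_hg19_plus_optc", "table2")

_CHROMOSOMES = tuple(str(c) for c in range(1, 23))


class InfeasibleSpecError(ValueError):
    """The requested planted counts cannot coexist in one table."""


@dataclass(frozen=True)
class ShiftModel:
    """Per-gene bp offset between consecutive builds.

    Most genes drift by a small zero-centred offset (sd ``small_sd`` bp,
    clipped at 10 sd so a "small" shift can never cross the large-shift
    threshold); ``n_large`` genes additionally jump by ±``large_shift`` bp
    on the final build transition — the heavy-tail component emulating
    megabase-scale boundary moves between assemblies.
    """

    small_sd: float = 2_000.0
    large_shift: int = 2_000_000
    n_large: int = 0


@dataclass(frozen=True)
class GeneTableSpec:
    """Recipe for a synthetic gene-annotation table.

    Planted quantities: ``n_dual_role`` terms that are official for one
    gene and a synonym of another; ``n_multi_gene_synonyms`` terms shared
    as synonyms by two genes; ``shift_model.n_large`` genes with a
    large boundary shift; ``n_unavailable`` genes missing from the
    earliest build.
    """

    n_genes: int
    n_dual_role: int = 0
    n_multi_gene_synonyms: int = 0
    synonyms_per_gene: tuple[int, int] = (0, 3)
    builds: tuple[str, ...] = ("Hg17", "Hg18", "Hg19")
    shift_model: ShiftModel = field(default_factory=ShiftModel)
    n_unavailable: int = 0
    seed: int = 0


@dataclass(frozen=True)
class SnpTableSpec:
    """Recipe for a synthetic SNP position table (one genome build).

    ``n_multi_coordinate`` rsIDs carry two distinct placements; of those,
    ``n_multi_chromosome`` place on two chromosomes and
    ``n_off_by_one_pairs`` place 1 bp apart from different sources (the
    coordinate-convention signature) — hence
    ``n_multi_chromosome + n_off_by_one_pairs <= n_multi_coordinate``.

    ``n_shared_coordinates`` coordinates are claimed by multiple rsIDs;
    the first carries ``max_multiplicity`` rsIDs, the rest two each.
    ``n_shared_coordinates=None`` derives 1 when ``max_multiplicity >= 2``
    else 0, so requesting a maximum multiplicity alone is sufficient.
    """

    n_rsids: int
    n_multi_coordinate: int = 0
    n_multi_chromosome: int = 0
    n_shared_coordinates: int | None = None
    max_multiplicity: int = 0
    n_off_by_one_pairs: int = 0
    build: str = "Hg19"
    seed: int = 0

    @property
    def shared_coordinates(self) -> int:
        if self.n_shared_coordinates is not None:
            return self.n_shared_coordinates
        return 1 if self.max_multiplicity >= 2 else 0


@dataclass(frozen=True)
class GeneGroundTruth:
    """Exactly what was planted in a synthetic gene table."""

    dual_role_terms: tuple[str, ...]
    multi_gene_synonyms: Mapping[str, tuple[int, ...]]
    large_shift_gene_ids: tuple[int, ...]
    unavailable_gene_ids: tuple[int, ...]
    n_unique_symbols: int
    n_unique_synonyms: int


@dataclass(frozen=True)
class SnpGroundTruth:
    """Exactly what was planted in a synthetic SNP table."""

    multi_coordinate_rsids: tuple[str, ...]
    multi_chromosome_rsids: tuple[str, ...]
    off_by_one_rsids: tuple[str, ...]
    shared_coordinates: Mapping[tuple[str, str, int], tuple[str, ...]]
    expected_max_rsids_per_coordinate: int


# ---------------------------------------------------------------------------
# gene tables


def generate_gene_table(spec: GeneTableSpec) -> tuple[GeneTable, GeneGroundTruth]:
    """Deterministically generate an annotation table matching ``spec``.

    Identical spec (seed included) always yields an identical table.
    Raises :class:`InfeasibleSpecError` rather than silently truncating an
    impossible request.
    """
    d, m = spec.n_dual_role, spec.n_multi_gene_synonyms
    if min(spec.n_genes, d, m, spec.n_unavailable, spec.shift_model.n_large) < 0:
        raise InfeasibleSpecError("all spec counts must be non-negative")
    if 2 * d + 2 * m > spec.n_genes:
        raise InfeasibleSpecError(
            f"{d} dual-role terms and {m} multi-gene synonyms need at least "
            f"{2 * d + 2 * m} genes; spec has {spec.n_genes}"
        )
    if spec.n_unavailable > spec.n_genes or spec.shift_model.n_large > spec.n_genes:
        raise InfeasibleSpecError("n_unavailable / n_large exceed n_genes")
    if not spec.builds:
        raise InfeasibleSpecError("at least one build is required")
    if spec.n_unavailable > 0 and len(spec.builds) < 2:
        raise InfeasibleSpecError(
            "unavailable-on-earliest-build genes need at least two builds"
        )
    lo, hi = spec.synonyms_per_gene
    if not (0 <= lo <= hi):
        raise InfeasibleSpecError(f"bad synonyms_per_gene range {spec.synonyms_per_gene}")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    ids = list(range(1, n + 1))
    officials = {gid: f"G{gid:06d}" for gid in ids}
    synonyms: dict[int, list[str]] = {
        gid: [f"G{gid:06d}S{j + 1}" for j in range(int(rng.integers(lo, hi + 1)))]
        for gid in ids
    }

    # dual-role: official symbol of gene A also a synonym of gene B
    dual_terms = []
    for k in range(d):
        a, b = ids[k], ids[d + k]
        synonyms[b].append(officials[a])
        dual_terms.append(officials[a])

    # multi-gene synonyms: one shared term per host pair
    shared: dict[str, tuple[int, ...]] = {}
    for k in range(m):
        g1, g2 = ids[2 * d + 2 * k], ids[2 * d + 2 * k + 1]
        term = f"SHARED{k + 1:05d}"
        synonyms[g1].append(term)
        synonyms[g2].append(term)
        shared[term] = (g1, g2)

    large_ids = tuple(ids[n - spec.shift_model.n_large:]) if spec.shift_model.n_large else ()
    unavailable_ids = tuple(ids[: spec.n_unavailable])

    sm = spec.shift_model
    clip = 10 * sm.small_sd
    records = []
    for gid in ids:
        chrom = str(rng.choice(_CHROMOSOMES))
        start = int(rng.integers(5_000_000, 200_000_000))
        length = int(rng.integers(5_000, 200_000))
        intervals: dict[str, GeneInterval] = {}
        for j, build in enumerate(spec.builds):
            if j > 0:
                offset = int(np.clip(rng.normal(0.0, sm.small_sd), -clip, clip))
                if gid in large_ids and j == len(spec.builds) - 1:
                    offset += int(rng.choice((-1, 1))) * sm.large_shift
                start += offset
            if gid in unavailable_ids and j == 0:
                intervals[build] = GeneInterval(build, chrom, available=False)
            else:
                intervals[build] = GeneInterval(build, chrom, start, start + length - 1)
        records.append(GeneRecord(
            gene_id=gid, official_symbol=officials[gid],
            synonyms=tuple(synonyms[gid]), chromosome=chrom,
            description=f"synthetic gene {gid}", intervals=intervals,
        ))

    provenance = Provenance(
        database_name="SyntheticAnnotation", version=f"seed{spec.seed}",
        genome_build="|".join(spec.builds),
    )
    all_synonym_terms = {s.casefold() for syns in synonyms.values() for s in syns}
    truth = GeneGroundTruth(
        dual_role_terms=tuple(dual_terms),
        multi_gene_synonyms=shared,
        large_shift_gene_ids=large_ids,
        unavailable_gene_ids=unavailable_ids,
        n_unique_symbols=n,
        n_unique_synonyms=len(all_synonym_terms),
    )
    return GeneTable(records=records, provenance=provenance), truth


# ---------------------------------------------------------------------------
# SNP tables


def _synthetic_sources(build: str) -> tuple[Provenance, ...]:
    return tuple(
        Provenance(database_name=f"SyntheticSNPDB-{tag}", version=f"v{i + 1}",
                   genome_build=build, dbsnp_build=str(130 + i))
        for i, tag in enumerate("ABC")
    )


def generate_snp_table(spec: SnpTableSpec) -> tuple[list[SnpRecord], SnpGroundTruth]:
    """Deterministically generate a SNP table matching ``spec``.

    Planted positions are mutually non-adjacent (no two planted
    coordinates within 1 bp of each other) except for the deliberate
    off-by-one pairs, so every census statistic recovers its planted value
    exactly.
    """
    n = spec.n_rsids
    n_shared = spec.shared_coordinates
    if min(n, spec.n_multi_coordinate, spec.n_multi_chromosome,
           spec.max_multiplicity, spec.n_off_by_one_pairs, n_shared) < 0:
        raise InfeasibleSpecError("all spec counts must be non-negative")
    if spec.n_multi_chromosome + spec.n_off_by_one_pairs > spec.n_multi_coordinate:
        raise InfeasibleSpecError(
            "multi-chromosome and off-by-one rsIDs are both multi-coordinate: "
            f"{spec.n_multi_chromosome} + {spec.n_off_by_one_pairs} > "
            f"{spec.n_multi_coordinate}"
        )
    if n_shared > 0 and spec.max_multiplicity < 2:
        raise InfeasibleSpecError("shared coordinates need max_multiplicity >= 2")
    n_sharers = (spec.max_multiplicity + 2 * (n_shared - 1)) if n_shared else 0
    if spec.n_multi_coordinate + n_sharers > n:
        raise InfeasibleSpecError(
            f"{spec.n_multi_coordinate} multi-coordinate rsIDs plus {n_sharers} "
            f"coordinate-sharing rsIDs exceed n_rsids={n}"
        )

    rng = np.random.default_rng(spec.seed)
    sources = _synthetic_sources(spec.build)
    used: set[tuple[str, int]] = set()

    def new_pos(chrom: str | None = None) -> tuple[str, int]:
        while True:
            c = chrom if chrom is not None else str(rng.choice(_CHROMOSOMES))
            p = int(rng.integers(1_000_000, 200_000_000))
            if not any((c, q) in used for q in (p - 1, p, p + 1)):
                used.add((c, p))
                return c, p

    rsids = [f"rs{1_000_000 + i + 1}" for i in range(n)]
    records: list[SnpRecord] = []
    multi_coord: list[str] = []
    multi_chrom: list[str] = []
    off_by_one: list[str] = []
    shared: dict[tuple[str, str, int], tuple[str, ...]] = {}

    i = 0
    for _ in range(spec.n_multi_chromosome):
        rsid = rsids[i]; i += 1
        c1, p1 = new_pos()
        c2 = str(rng.choice([c for c in _CHROMOSOMES if c != c1]))
        c2, p2 = new_pos(c2)
        records.append(SnpRecord(rsid, (
            MappedPosition(sources[0], c1, p1),
            MappedPosition(sources[1], c2, p2),
        )))
        multi_coord.append(rsid); multi_chrom.append(rsid)

    for _ in range(spec.n_off_by_one_pairs):
        rsid = rsids[i]; i += 1
        c, p = new_pos()
        used.add((c, p + 1))
        records.append(SnpRecord(rsid, (
            MappedPosition(sources[0], c, p),
            MappedPosition(sources[1], c, p + 1),
        )))
        multi_coord.append(rsid); off_by_one.append(rsid)

    n_plain = spec.n_multi_coordinate - spec.n_multi_chromosome - spec.n_off_by_one_pairs
    for _ in range(n_plain):
        rsid = rsids[i]; i += 1
        c, p1 = new_pos()
        c, p2 = new_pos(c)
        records.append(SnpRecord(rsid, (
            MappedPosition(sources[0], c, p1),
            MappedPosition(sources[1], c, p2),
        )))
        multi_coord.append(rsid)

    for j in range(n_shared):
        c, p = new_pos()
        k = spec.max_multiplicity if j == 0 else 2
        claimants = []
        for _ in range(k):
            rsid = rsids[i]; i += 1
            records.append(SnpRecord(rsid, (
                MappedPosition(sources[i % len(sources)], c, p),
            )))
            claimants.append(rsid)
        shared[(spec.build, c, p)] = tuple(claimants)

    while i < n:
        rsid = rsids[i]; i += 1
        c, p = new_pos()
        records.append(SnpRecord(rsid, (
            MappedPosition(sources[i % len(sources)], c, p),
        )))

    if n_shared:
        expected_max = spec.max_multiplicity
    else:
        expected_max = 1 if n else 0
    truth = SnpGroundTruth(
        multi_coordinate_rsids=tuple(multi_coord),
        multi_chromosome_rsids=tuple(multi_chrom),
        off_by_one_rsids=tuple(off_by_one),
        shared_coordinates=shared,
        expected_max_rsids_per_coordinate=expected_max,
    )
    return records, truth


# ---------------------------------------------------------------------------
# published fixtures


def _data_path(name: str):
    return resources.files("genid_audit").joinpath(f"data/{name}")


def load_fixture(name: str):
    """Load a packaged case-study fixture.

    - ``table1`` -> :class:`GeneTable` of the six published gene records
      with Hg17/Hg18/Hg19 intervals verbatim.
    - ``table1_hg19_plus_optc`` -> the same table plus a synthetic
      OPTC-like record (gene 26254) whose Hg19 interval is fabricated to
      cover FAIM3's published Hg17 span, for stale-lookup demonstrations.
    - ``table2`` -> list with one :class:`SnpRecord` (rs2844871) carrying
      every published (database, version, build, location) row.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    if name == "table2":
        with resources.as_file(_data_path("table2.tsv")) as p:
            return read_snp_table(p)
    with resources.as_file(_data_path("table1.tsv")) as p:
        table = read_gene_table(p)
    if name == "table1":
        return table
    # synthetic OPTC-like record: gene id and symbol are real, but the Hg19
    # coordinates are FABRICATED to coincide with FAIM3's Hg17 interval so
    # that a stale Hg17-coordinate lookup against Hg19 retrieves the wrong
    # gene; only the retrieval behaviour is meaningful.
    faim3_hg17 = table.by_id(9214).intervals["Hg17"]
    optc = GeneRecord(
        gene_id=26254, official_symbol="OPTC", synonyms=("OPT",),
        chromosome="1",
        description="opticin (synthetic stand-in record, fabricated Hg19 coordinates)",
        intervals={
            "Hg17": GeneInterval("Hg17", "1", available=False),
            "Hg18": GeneInterval("Hg18", "1", available=False),
            "Hg19": GeneInterval("Hg19", "1", faim3_hg17.start, faim3_hg17.end),
        },
    )
    return GeneTable(records=table.records + [optc], provenance=table.provenance)
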