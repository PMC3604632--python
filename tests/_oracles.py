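"""Independent brute-force oracles used to cross-check the audit modules.

These deliberately avoid the indexed/grouped code paths of the package:
censuses are recomputed with nested loops over raw (term, gene) and
(rsid, placement) pairs, and overlap queries with a linear interval scan.
"""

from __future__ import annotations

from genid_audit.annotation_io import GeneRecord, SnpRecord, normalize_chromosome


def brute_force_ambiguity_census(records: list[GeneRecord]) -> dict:
    """Double loop over (term, gene) pairs; no index structure."""
    def norm(t: str) -> str:
        return t.strip().casefold()

    terms = set()
    for rec in records:
        terms.add(norm(rec.official_symbol))
        for s in rec.synonyms:
            terms.add(norm(s))

    n_symbols = n_synonyms = n_dual = n_multi = 0
    for term in terms:
        official_genes = [r.gene_id for r in records if norm(r.official_symbol) == term]
        synonym_genes = [
            r.gene_id for r in records if any(norm(s) == term for s in r.synonyms)
        ]
        if official_genes:
            n_symbols += 1
        if synonym_genes:
            n_synonyms += 1
        if official_genes and synonym_genes:
            n_dual += 1
        if len(synonym_genes) >= 2:
            n_multi += 1
    return {
        "n_unique_symbols": n_symbols,
        "n_unique_synonyms": n_synonyms,
        "n_dual_role_terms": n_dual,
        "n_multi_gene_synonyms": n_multi,
    }


def brute_force_multimap_census(snps: list[SnpRecord], within_build: str = "all") -> dict:
    """Nested-loop recount of the multi-mapping census."""
    per_rsid_coords: dict[str, list] = {}
    per_rsid_chroms: dict[str, list] = {}
    all_claims: list[tuple] = []  # ((build, chrom, pos), rsid)

    for snp in snps:
        coords, chroms = [], []
        seen_rows = []
        for mp in snp.positions:
            row = (mp.source, mp.chromosome, mp.position, mp.status)
            if row in seen_rows:  # exact duplicate rows are deduplicated
                continue
            seen_rows.append(row)
            if mp.status != "mapped":
                continue
            build = mp.source.genome_build
            if within_build != "all" and build != within_build:
                continue
            chrom = normalize_chromosome(mp.chromosome)
            key = (build, chrom, mp.position) if within_build == "all" else (chrom, mp.position)
            if key not in coords:
                coords.append(key)
            if chrom not in chroms:
                chroms.append(chrom)
            claim = ((build, chrom, mp.position), snp.rsid)
            if claim not in all_claims:
                all_claims.append(claim)
        per_rsid_coords[snp.rsid] = coords
        per_rsid_chroms[snp.rsid] = chroms

    n_total = len(snps)
    n_multi_coord = sum(1 for c in per_rsid_coords.values() if len(c) >= 2)
    n_multi_chrom = sum(1 for c in per_rsid_chroms.values() if len(c) >= 2)
    coords_seen = []
    shared = 0
    max_mult = 0
    for coord, _ in all_claims:
        if coord in coords_seen:
            continue
        coords_seen.append(coord)
        claimants = [r for c, r in all_claims if c == coord]
        if len(claimants) >= 2:
            shared += 1
        max_mult = max(max_mult, len(claimants))
    return {
        "n_total_rsids": n_total,
        "n_multi_coordinate_rsids": n_multi_coord,
        "n_multi_chromosome_rsids": n_multi_chrom,
        "n_shared_coordinates": shared,
        "max_rsids_per_coordinate": max_mult,
        "fraction_multi_chromosome": (n_multi_chrom / n_total) if n_total else 0.0,
    }


def brute_force_overlaps(records, build: str, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
    """Linear scan: (gene_id, overlap_bp) for every gene intersecting
    [start, end] (1-based inclusive) on one build, descending overlap with
    gene_id tie-break."""
    hits = []
    for rec in records:
        iv = rec.intervals.get(build)
        if iv is None or not iv.available:
            continue
        if normalize_chromosome(iv.chromosome) != normalize_chromosome(chrom):
            continue
        ov = min(iv.end, end) - max(iv.start, start) + 1
        if ov >= 1:
            hits.append((rec.gene_id, ov))
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits
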