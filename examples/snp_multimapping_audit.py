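"""Audit the placements of one SNP across databases and versions.

rs2844871 is reported at different positions — and on different
chromosomes — depending on which database and which release is consulted.
The concordance report groups placements by (build, chromosome) and flags
the 1-bp Hg18 chr22 disagreement between vendors, the signature of a
0- vs 1-based coordinate convention mismatch.
"""

from genid_audit import load_fixture, multimap_census, position_concordance

(snp,) = load_fixture("table2")
report = position_concordance(snp)

print(f"{snp.rsid}: {len(snp.positions)} database rows")
print(f"distinct chromosomes: {list(report.distinct_chromosomes)}")
for (build, chrom), positions in sorted(report.positions_by_group.items()):
    print(f"  {build} chr{chrom}: positions {list(positions)}")
for flag in report.off_by_one_flags:
    print(f"  OFF-BY-ONE {flag.build} chr{flag.chromosome}: "
          f"{flag.position_low} ({', '.join(flag.sources_low)}) vs "
          f"{flag.position_high} ({', '.join(flag.sources_high)})")
print(f"rows listed without coordinates: {len(report.unmapped)}")

census = multimap_census([snp], within_build="Hg19")
print(f"Hg19 census: {census.n_multi_coordinate_rsids} multi-coordinate, "
      f"{census.n_multi_chromosome_rsids} multi-chromosome of "
      f"{census.n_total_rsids} rsID(s)")
# One rsID on four chromosomes: any SNP-to-gene assignment that ignores the
# database version silently picks one of several genes.
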