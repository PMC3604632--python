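"""Cross-build boundary shifts, stale lookups, and build-matched mapping.

FCAMR's boundaries moved 1,933,377 bp between Hg18 and Hg19; and querying
an Hg19 annotation with FAIM3's Hg17 coordinates retrieves a different
gene entirely.  SNP-to-gene assignment therefore refuses mismatched builds
unless explicitly forced.
"""

from genid_audit import (
    BuildMismatchError,
    boundary_shift,
    load_fixture,
    snp_to_gene,
    stale_lookup_check,
)

table = load_fixture("table1")

shift = boundary_shift(table.by_id(83953), "Hg18", "Hg19", threshold=10**6)
print(f"FCAMR Hg18->Hg19: delta_start={shift.delta_start:,} bp, "
      f"flagged={shift.large_shift_flag}")

# replay a stale lookup: FAIM3's Hg17 interval against an Hg19 annotation
plus = load_fixture("table1_hg19_plus_optc")
hits = stale_lookup_check(table.by_id(9214).intervals["Hg17"], plus, "Hg19")
print("stale Hg17 coordinates retrieve:",
      [(h.official_symbol, h.gene_id) for h in hits], "(not FAIM3!)")

# build-matched assignment works; mismatched builds are refused
result = snp_to_gene(("Hg19", "1", 207080000), table, "Hg19", flank=0)
print("Hg19 chr1:207,080,000 ->",
      [(h.official_symbol, h.gene_id) for h in result.hits])
try:
    snp_to_gene(("Hg18", "1", 207080000), table, "Hg19")
except BuildMismatchError as exc:
    print("mismatched query refused:", exc)
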