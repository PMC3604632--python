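"""Resolve a collaborator's gene list against an annotation release.

The list mixes an obsolete synonym (TOSO), plain official symbols, and the
dual-role term ADRA1A — official symbol of the alpha-1A receptor (gene 148,
chromosome 8) AND a synonym of the alpha-1D receptor (gene 146, chromosome
20).  Under the strict policy the dual-role term is flagged, never guessed.
"""

from genid_audit import build_index, load_fixture, resolve_terms

table = load_fixture("table1")
index = build_index(table)

gene_list = ["TOSO", "PIGR", "FCAMR", "ADRA1A", "ADRA1B", "ADRA1D"]
report = resolve_terms(index, gene_list, policy="strict")

print(f"annotation: {table.provenance.database_name} "
      f"({table.provenance.version}, builds {table.provenance.genome_build})")
for entry in report.entries:
    status = "NEEDS REVIEW" if entry.needs_review else f"gene {entry.gene_id}"
    print(f"  {entry.term:8s} -> {status:12s} [{entry.classification.term_class.value}]"
          + (f"  {entry.note}" if entry.note else ""))

# TOSO resolves via synonym to FAIM3 (gene 9214); ADRA1A is flagged because
# auto-picking either candidate silently chooses between chromosomes 8 and 20.
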