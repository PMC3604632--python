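"""Plant known ambiguity/multi-mapping counts and recover them exactly.

The generator plants integer counts (dual-role terms, shared synonyms,
multi-coordinate rsIDs, a coordinate claimed by many rsIDs) and the audit
censuses recover each planted value exactly — the correctness argument
for table sizes where no public ground truth exists.
"""

from genid_audit import (
    GeneTableSpec,
    SnpTableSpec,
    ambiguity_census,
    build_index,
    generate_gene_table,
    generate_snp_table,
    multimap_census,
)

table, truth = generate_gene_table(GeneTableSpec(
    n_genes=100, n_dual_role=5, n_multi_gene_synonyms=7, seed=42))
census = ambiguity_census(build_index(table))
print(f"planted 5 dual-role terms     -> recovered {census.n_dual_role_terms}")
print(f"planted 7 multi-gene synonyms -> recovered {census.n_multi_gene_synonyms}")
print(f"  planted dual-role terms: {list(truth.dual_role_terms)}")

snps, _ = generate_snp_table(SnpTableSpec(
    n_rsids=500, n_multi_coordinate=20, n_multi_chromosome=8,
    max_multiplicity=97, seed=7))
c = multimap_census(snps, within_build="Hg19")
print(f"planted 20 multi-coordinate rsIDs -> recovered {c.n_multi_coordinate_rsids}")
print(f"planted  8 multi-chromosome rsIDs -> recovered {c.n_multi_chromosome_rsids}")
print(f"planted one coordinate with 97 rsIDs -> max multiplicity {c.max_rsids_per_coordinate}")
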