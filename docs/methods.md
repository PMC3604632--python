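# Methods

## Problem setting

Variant-to-gene workflows move through four steps: choose a candidate gene
pool, annotate the genes, fix their genomic boundaries, and intersect with
marker positions. Each step depends on a named database release, and each
is a place where unstated versioning corrupts results: gene names collide
across the symbol/synonym vocabulary, rsIDs carry multiple placements that
differ between releases, and coordinates are meaningful only within one
genome build. `genid-audit` treats these as first-class audit targets
rather than assuming clean inputs.

## Data model and conventions

- **Coordinates** are 1-based and inclusive on both ends, matching the
  `start-end` ranges printed by the major annotation browsers. Intersection
  length is `min(e1, e2) − max(s1, s2) + 1`. This convention is stated
  prominently because vendors genuinely disagree: the packaged rs2844871
  case carries an Hg18 chr22 placement reported as 14459242 by one source
  and 14459243 by others — a likely 0/1-based discrepancy that the audit
  surfaces but deliberately does not resolve.
- **Chromosome labels** are stored without a `chr` prefix; scaffold names
  (`Un_gl000244`) are kept verbatim after the prefix strip and count as
  distinct chromosomes, consistent with how multi-placement SNPs are
  reported.
- **Provenance** (database name, release/version, genome build, NCBI
  build, dbSNP build, access date) is attached to every loaded table and
  embedded in every report; rendering a report from an unprovenanced table
  raises. This is enforced at the API boundary because missing version
  information is the root failure the package audits.
- **Gene tables** are TSV with fixed leading columns (GeneID, Symbol,
  Synonyms, Chromosome, Description) and one `start-end` column per build;
  synonyms are pipe-delimited with `-` meaning none; `Information Not
  available` encodes an interval absent from a build. SNP tables are TSV
  with per-row provenance columns; a combined `location` column
  (`chrN:pos` plus the published sentinel texts) is also accepted.

## Symbol resolution

Term comparison is case-insensitive with case-preserving storage
(investigator lists arrive as `Toso`, `TOSO`, ...); the normalization is
recorded with the index provenance. Classification partitions terms into
six classes by the sizes of the official-candidate and synonym-candidate
sets; `OFFICIAL_MULTIPLE` (a term official for ≥ 2 records) is not a
natural category of a well-formed release but real inputs can produce it,
so it is classified and reported as an integrity warning rather than
crashing or being silently merged.

Resolution policies: `strict` auto-resolves only uniquely-official and
uniquely-synonym terms; `official_first` additionally resolves a dual-role
term to its unique official candidate while recording a warning and the
full candidate sets. Dual-role and multi-gene-synonym terms are never
resolved silently under any policy, and no frequency-based tie-breaking is
attempted — there is no defensible prior over which gene a collaborator
meant.

## SNP multi-mapping audit

Exact duplicate placements (same rsid, source, chromosome, position,
status) are deduplicated before counting, because pooled multi-source
tables legitimately repeat concordant rows. With `within_build="all"`
(default) distinctness is judged on (build, chromosome, position) triples
— the same locus under two builds counts as two coordinates; with a build
label, only that build's placements are counted on (chromosome, position)
pairs. The within-build view is the informative one for hygiene:
build-driven differences are expected, whereas multiple placements within
one build are anomalies. The multi-chromosome fraction is reported against
the rsID count, with the deduplicated mapping count carried alongside so
both denominators are available. Rows without coordinates
(`listed_no_position`, `not_available`) are listed separately and never
counted as discordant positions.

Off-by-one flags are emitted per distinct adjacent position pair (p, p+1)
within a (build, chromosome) group when the two positions are reported by
different source databases; adjacent positions from a single source are
plain discordance. Flagging per position pair, not per source pair, keeps
the count well-defined when several sources print the same position.

## Coordinate concordance

Boundary shifts are signed (`to − from`, hence antisymmetric) and computed
only when both builds carry an available interval; an interval present but
marked unavailable yields a not-comparable result with a reason, while an
unknown build label is a lookup error. The default large-shift threshold
is 1 Mb — megabase-scale moves are the ones that relocate a gene past its
neighbours, and the packaged case study (FCAMR, 1,933,377 bp) clears it
with margin; the threshold is a parameter everywhere it is used.

Overlap queries run on per-chromosome interval trees (the `intervaltree`
package; inclusive intervals become half-open `[start, end+1)` entries).
Ties in overlap length break by ascending GeneID for determinism.
SNP-to-gene assignment uses a symmetric flank: a gene is hit when
`start − flank ≤ position ≤ end + flank`. A query whose build differs from
the annotation's is refused with an error naming both builds; `force=True`
returns a result watermarked `BUILD MISMATCH` instead. No chain-file
conversion is performed — detection and refusal, not lifting, is the
design goal.

## Synthetic tables and what they show

The generators plant integer counts, not rates, so recovery checks are
exact: d dual-role terms (gene A's official symbol appended to gene B's
synonyms over disjoint gene pairs), m shared synonyms (one `SHAREDnnnnn`
term on two host genes), large-shift genes (±2 Mb jump on the final build
transition over a small-drift background of sd 2 kb, clipped at 10 sd so
background drift can never cross the 1 Mb flag threshold), genes absent
from the earliest build, multi-coordinate / multi-chromosome / off-by-one
rsIDs, and coordinates claimed by a chosen number of rsIDs. The synthetic
symbol alphabet (`G000001` + suffix-derived synonyms) cannot collide
except where planted, and planted SNP positions are mutually non-adjacent
except for deliberate off-by-one pairs. Infeasible count combinations
raise rather than truncate; because a planted off-by-one pair makes its
rsID multi-coordinate, specs must satisfy
`n_multi_chromosome + n_off_by_one_pairs ≤ n_multi_coordinate`.

What passing synthetic tests shows: the censuses count exactly what they
claim to count, at any table size, under known ground truth. What they do
not show: behaviour on the messiness of real releases — withdrawn records,
case-variant duplicates, vendor-specific header quirks — beyond what the
two packaged published fixtures exercise. Structure, not scale, is
emulated: no attempt is made to simulate a full release's tens of
thousands of symbols or tens of millions of rsIDs, whose global census
values would require the historical database dumps themselves.

## Numerical and formatting choices

Percentages render at one decimal with round-half-up (`Decimal`
arithmetic), so 805,555 / 54,212,080 prints as `1.5%`. JSON reports are
schema-checked and serialize with sorted keys, making
serialize → parse → serialize byte-identical. Report exit codes are 0
(clean), 3 (hygiene warnings: dual-role terms, off-by-one flags, build
mismatches), 1 (errors), so shell pipelines can gate on hygiene.

## Problem sizes

Test-suite and acceptance-script runs use fixture tables of 6 genes / 19
SNP rows, synthetic gene tables up to 1,000 genes, and synthetic SNP
corpora up to 1,000 rsIDs; brute-force oracle cross-checks (nested-loop
censuses, linear interval scans) run at these sizes in seconds. Planted
recovery is checked across 50 randomly drawn feasible specs per run.

## Known limitations

- No fuzzy or edit-distance matching of gene names, and no repair of
  spreadsheet-corrupted symbols; a misspelled term classifies as UNKNOWN.
- No rsID merge-history resolution: two rsIDs later merged upstream are
  counted as distinct.
- No transcript-level (exon/UTR) resolution; genes are intervals.
- Case-insensitive normalization may merge terms a case-sensitive census
  would count separately; the normalization used is recorded in report
  provenance rather than guessed to match any particular upstream count.
- Cross-build conversion is out of scope by design; users needing lifted
  coordinates should convert upstream and re-audit.
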