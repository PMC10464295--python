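# Methods

## Coordinate model

All coordinates are 1-based. Each alignment row carries an `offset`: the
full-protein residue number of its first aligned residue, so the k-th
non-gap character of a row is residue `offset + k − 1`. Reference
positions are reported in the residue numbering of the reference
*structure* (author numbering), taken from the PDB file itself, never
from UniProt coordinates; at load time the ungapped reference row and the
structure must agree in length or the run aborts with a consistency
error before writing anything.

Mapping a variant is the composition of two injective partial maps:
residue → column on the variant's own row, then column → reference
residue through the reference row. Every input variant yields exactly
one outcome status (`mapped`, `excluded_reference_gap`,
`excluded_out_of_domain`, `excluded_ref_mismatch`, `unmatched_gene`),
so input counts are conserved and the exclusion log is complete by
construction. Genes with several alignment rows (multi-domain kinases)
are resolved by domain membership; a residue in-domain in two rows of
the same gene is an unresolvable error rather than a silent choice.

Reference amino-acid verification defaults ON: a variant whose stated
reference residue disagrees with the alignment cell is excluded and
logged rather than treated as fatal, since isoform/version mismatches
between clinical archives and an alignment are expected in real data.

## Filters and disease classes

* Pathogenic branch: clinical significance in {Pathogenic, Likely
  pathogenic}, matched case- and punctuation-insensitively; composite
  assertions ("Pathogenic/Likely pathogenic") qualify.
* Benign branch: significance Benign (Likely benign optional, default
  off) **and** population allele frequency ≥ 0.01, inclusive. Records
  lacking a frequency are dropped and logged.
* Protein changes that are not single amino-acid substitutions
  (frameshift, nonsense, indel, duplication, extension, synonymous) are
  dropped at parse time with a machine-readable reason code. Three HGVS
  dialects are accepted: `p.Val600Glu`, `p.V600E`, `V600E`.

The cancer / non-cancer condition split is a reproducible surrogate for
what is in practice a manual curation step: an exact-match override
table is consulted first, then a substring keyword lexicon (carcinoma,
melanoma, leukemia, neoplas-, tumor, sarcoma, blastoma, myeloma,
adenoma, glioma, GIST, malignan-, …), with non-cancer as the fallback.
Uninformative strings ("not provided", "not specified") are ignored via
overrides. Every run emits an audit table of each distinct condition,
its class and whether it came from a keyword or an override, so a user
can inspect and correct the split with their own override TSV. A record
whose conditions span both classes belongs to both (counted once per
class); a record with only ignored conditions is logged and dropped.

## Counting and hotspot selection

The dedup unit is the input record × class (SNV-level counting); an
optional `collapse_aa` mode collapses to distinct gene/amino-acid
changes instead. Benign counts are tracked per position but never enter
hotspot selection or the chi-square test.

Hotspots per class are the top 5% of *mutated* positions (count ≥ 1 for
that class), not of all alignment columns — otherwise the number of
hotspots would scale with domain length rather than with the data. With
m candidates, k = ⌈0.05·m⌉ positions are taken after sorting by count
descending, residue number ascending; every position tied with the k-th
count is included, so selection is deterministic, order-independent and
invariant under duplicating all records.

## Statistics

Per position the observed class frequencies are c_i/C and n_i/N, the
expected frequency is (c_i+n_i)/(C+N), and the representation ratio is
observed/expected; the two class ratios always sit on opposite sides of
1 (or both at 1). Significance uses the Pearson chi-square test on the
2×2 table [[c_i, C−c_i], [n_i, N−n_i]] with one degree of freedom —
position-vs-rest, class-vs-class, the table implied by the
observed/expected definitions. Yates continuity correction is ON by
default (the default behaviour of R's `chisq.test` on 2×2 tables, the
convention of the statistical environment this analysis is normally run
in); a flag restores the uncorrected statistic. Positions with any
expected cell < 5 are flagged (`small_expected`) but kept. No
multiple-testing correction is applied by default, matching the raw
p < 0.05 convention of this analysis type; a Benjamini–Hochberg option
is provided as a clearly separate extension. Degenerate tables: an
unmutated position is undefined and skipped; a table whose complementary
margin is empty carries no evidence and returns χ² = 0, p = 1.

Labels: `over_cancer` when p < α and ratio > 1, `over_noncancer` when
p < α and ratio < 1, else `not_significant`.

## B-factor annotation

Per-residue integer counts are written into the B-factor field
(columns 61–66, `%6.2f`) of CA-only PDB v3.3 ATOM records; occupancy is
1.00. Counts above 999 overflow the fixed-width field and are a hard
error rather than being clipped, because clipping would silently corrupt
the primary visual output; real per-position counts are two orders of
magnitude below the limit. The declared PDB dialect is strict — single
model, one chain, CA only, no altlocs, no insertion codes — and
violations are format errors. Round-tripping write → read recovers every
count in [0, 999] exactly.

## Synthetic data generator

The generator emulates the statistical structure of the real inputs, not
their biology:

* **MSA** — random sequences over the 20-residue alphabet. Row 0 is the
  reference and is never gapped at its own columns; `ref_length // 25`
  extra insert columns (reference gapped, other rows occupied with
  probability 0.5) exercise reference-gap exclusion. Non-reference rows
  are gapped independently per reference column with probability
  `gap_fraction` (default 0.15) and carry random residue-number offsets
  in [1, 500] to force nontrivial coordinate arithmetic.
* **Background mutations** — per row, per class, Poisson with mean
  `background_rate` per ungapped residue (default 0.02), placed
  uniformly over the row's residues. `background_rate` is defined
  per residue so that expected background scales with domain length;
  the uniform placement is the simplest null model and is an assumption,
  not an inference about real kinase mutability.
* **Planted hotspots** — Poisson(`mean_mutations`) mutations of one
  class at one reference position, spread uniformly over the rows
  ungapped in that column (reference-only with a warning if no other row
  qualifies).
* **Conditions/significance** — significances drawn uniformly from
  {Pathogenic, Likely pathogenic}; conditions drawn from per-class pools
  seeded with realistic ClinVar-style strings; a configurable fraction
  (default 5%) of records additionally draws a condition from the other
  pool, exercising dual-class counting.
* **Benign records** — allele frequencies log-uniform in (1e-4, 0.5],
  with one record forced below 1% and one forced to exactly 0.01 so the
  inclusive threshold boundary is always exercised; planted benign
  hotspots draw frequencies ≥ 0.01.
* **Truth sidecar** — every record's true reference position and class,
  written next to the inputs and never read by any analysis stage.

Identical configurations (including seed) produce byte-identical files.
What passing tests on this generator do **not** show: real kinase
sequence composition or phylogeny, realistic per-gene mutability,
transcript/isoform mismatches, or the actual ClinVar condition
vocabulary beyond the seeded pools. The run manifest records wall-clock
timings, so reruns are byte-identical in every output except
`manifest.json`.

## Verification problem sizes

The acceptance checks run at sizes chosen to give tight Monte-Carlo
tolerances while keeping a full verification run under a minute or two:
500 random alignments (≤ 20 rows × 50 columns) for the brute-force
mapping oracle; 10,000 random 2×2 tables for the chi-square oracle
(agreement to 1e-9); 100 replicate cohorts of 100 proteins × 250
residues with three planted cancer hotspots (Poisson mean 25, background
0.02/residue) for planted-signal recovery (≥ 95% of replicates must
recover and correctly label all three); 200 null replicates for type-I
calibration (mean significant fraction ≤ 0.07 at α = 0.05); 1,000
random count maps for B-factor round trips.

## Known limitations

* The condition lexicon reproduces figure-legend-style examples but is
  not guaranteed to reproduce any particular manual curation; the audit
  table plus overrides are the intended correction path.
* The chi-square 2×2 construction is one natural reading of the
  observed/expected definitions; with very small class totals its
  normal approximation is weak (hence the `small_expected` flag).
* Only single amino-acid substitutions are analyzed; nucleotide-level
  context, codon structure and in-frame indels are out of scope.
* No mmCIF input, no database clients, no figure rendering — figure-level
  data are exported as tables/JSON for downstream plotting tools.
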