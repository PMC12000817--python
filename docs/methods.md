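# Methods

This note documents the models, conventions and design choices behind
`mitovulture`, in the spirit of a package vignette: what each stage computes,
which knobs matter, and what the synthetic generators do and do not emulate.

## Coordinates and the gene table

All coordinates are 1-based and inclusive, the convention of published
mitogenome gene tables. Minus-strand rows given high-to-low are normalized
to `start ≤ end` with strand `-` on input, so one internal representation
serves all modules; any dash glyph (hyphen, en dash, minus sign) in the
direction column is read as the minus strand, since published tables mix
them. Overlapping features are permitted — real avian mitogenomes overlap
genes (*ATP8*/*ATP6*; *trnM*/*trnQ* abutting on opposite strands) — and
wrap-around (origin-spanning) features are rejected explicitly rather than
mishandled.

Declared lengths and declared start/stop codons are stored verbatim and
*validated*, never repaired: `validate_feature_table` reports declared-vs-
computed length mismatches, CDS spans that are not codon multiples, and
overlaps, as findings rather than errors. On the packaged *S. calvus* table
this surfaces exactly one mismatch — the ND3 row declares 354 bp over a
351 bp span — which is an inconsistency internal to the published table and
is deliberately preserved.

**Protein-coding span.** `pcg_span_stats` sums CDS lengths without
deduplicating overlaps, because that is how such spans are reported in the
literature (plain summation reproduces the published 11,407 bp exactly).
The declared length of a row is preferred over the computed span so that the
statistic reproduces the source table's own arithmetic even at the
inconsistent ND3 row; with no declared lengths the two are identical.

**Rounding.** Composition is reported to 1 decimal and fractions to 2
decimals, both rounded half away from zero, matching printed precision in
the field. N bases are excluded from the composition denominator (a choice;
sources are typically silent), and an all-N sequence is an error.

## Genetic codes and translation

Codon tables come from NCBI translation tables 2 (vertebrate mitochondrial,
the default: AGA/AGG/TAA/TAG stops, ATA = Met, TGA = Trp, starts including
ATG and GTG) and 1 (standard), via Biopython. Translation reports internal
stop codons as findings rather than raising — a comparative pipeline must
describe imperfect annotations — and flags trailing partial codons, which
are normal for mitochondrial genes whose stops are completed by
polyadenylation (e.g. the 784 bp COX3).

## RSCU

RSCU is computed over the pooled codon pool of all protein-coding genes by
default (matching how codon-usage figures are usually presented), with
per-gene tables available by passing a single CDS. Families are defined by
the active code, so under the vertebrate mitochondrial code the four stops
form their own family and the family-sum invariant
`Σ_family RSCU = |family|` holds for every used family; unused families are
flagged, not errored. Codons are reported in the DNA alphabet with an RNA
rendering option. Ranking is by raw count, ties broken lexicographically so
output is deterministic.

## Microsatellite scan

The scanner reports maximal perfect tandem repeats of primitive motifs of
length 1–6 bp. For motif length *k*, a region has period *k* where
`s[i] == s[i+k]` chains hold; each maximal run yields one hit covering its
whole repeats only (`end − start + 1 = k × repeats`; a trailing partial
period is excluded). Runs whose motif is a power of a shorter motif are
suppressed, because the shorter-motif scan reports the identical span. Runs
never cross N. Scanning is linear even for circular genomes, as in standard
SSR tools, so origin-spanning repeats are out of scope, as are compound and
interrupted repeats.

Thresholds default to minimum repeat counts (4, 3, 3, 3, 3, 3) for motif
lengths 1–6 — conservative MISA-like settings for a ~17 kb genome — and are
fully configurable (`--ssr-min 1:4,2:3,...`). Published SSR censuses of this
genome used unstated and evidently much more permissive settings (their
totals are not internally consistent between text and table), so absolute
hit counts are configuration-dependent and are not a target; the scanner's
correctness is instead guaranteed by set-equality with an exhaustive
brute-force oracle on random sequences.

A hit is assigned to the feature containing its *start* position; when
overlapping features both cover it, the first in table order wins
(documented, deterministic); starts covered by nothing are pooled as
"(unidentified region)". The census matrix pools penta- and hexanucleotide
repeats into one column, as the published tables do, and its margins always
sum to the number of hits.

## Group-conserved substitution sites

A column qualifies when every row of clade A carries one standard residue,
every row of clade B carries one standard residue, and the two differ. Any
gap or non-standard character in a qualifying row disqualifies the column —
a strict rule chosen for determinism where sources are silent. Positions are
reported per gene in the ungapped coordinates of the first clade-A taxon
(the focal taxon, for focal analyses). The focal variant finds columns where
the focal taxon differs from a residue shared by *all* other group members.

Residues are classed as hydrophobic {A,V,L,I,M,F,W,Y}, polar uncharged
{S,T,N,Q}, positive {K,R,H}, negative {D,E} and special-case {C,G,P}. For
the cross-class decision each special-case residue is its own singleton
class: Cys (disulfide bonds), Gly (backbone flexibility) and Pro (backbone
rigidity) are not chemically interchangeable, so a C→G swap counts as
cross-class even though both carry the "Special case" label. Special-residue
tallies count a site once per special residue it involves on either side.

The packaged reference lists transcribe the published OWV/NWV (67 sites) and
*S. calvus*-vs-Gypini (43 sites) tables verbatim. The default scheme
reproduces all 134 printed class labels of the former and 85 of the 86
labels of the latter; the one exception (ND3 108, Thr printed as
hydrophobic) is a mislabeling in the source, kept verbatim and asserted as
the known exception. Several rows of the 43-site table print identical
residues in both columns; they are preserved as printed and exercised
label-by-label, since a substitution object requires two distinct residues.

## Distances

The default distance is the uncorrected p-distance with pairwise deletion,
reported as a percentage to 2 decimals: per pair, columns with a gap or
ambiguity in either row are excluded and `d = 100 × mismatches / used`.
Poisson correction (`−100 ln(1 − p)`) and complete deletion are exposed
because distance tools differ in their defaults and published values rarely
state them. Under pairwise deletion the concatenated distance equals the
used-site-weighted mean of per-gene distances, which the tests assert.

## Synthetic data

The generators emulate the study system so every stage is testable offline:

* `generate_mitogenome` realizes a feature layout (default: the packaged
  *S. calvus* table, 17,750 bp). CDS regions are written codon by codon —
  declared start codon, interior codons drawn from a bias map, declared stop,
  and a truncated `T`/`TA` for non-codon-multiple spans — reverse-
  complemented on the minus strand; non-CDS positions are drawn to meet the
  AT target (default 54.1%, the composition reported for this genome) in
  expectation. The default codon bias follows the AT target per base so the
  whole-genome composition tracks the target; at 50% it reduces to uniform
  sense-codon usage. Later CDS overwrite earlier ones over shared bases
  (overlap is biological reality); opposite-strand CDS overlaps are rejected
  as infeasible. The truth object carries the codon tallies of the final
  extracted CDS set, so codon-counting recovery is exact by construction.
* `plant_ssrs` overwrites chosen spans with perfect repeats and forces the
  single flanking base on each side away from the motif boundary, so no
  plant extends beyond its declared repeat count and the scanner recovers
  each plant as exactly one covering hit.
* `generate_clade_alignments` builds two gapless clades (default 5 vs 6
  taxa, the sizes of the Gypini and Cathartidae sets) from a random ancestor
  with planted group-conserved pairs, planted focal-private residues and
  optional extra between-clade divergence (round(q × length) differing
  columns per gene; with no noise every cross-clade p-distance is then
  exactly 100q). Within-group noise substitutes residues uniformly over the
  19 alternatives at rate `noise_rate` (default 0.01) at non-planted
  columns. In constraint mode — the default, used for exact-recovery tests —
  at most one row mutates per column, never the focal row and never in a
  single-member group, so noise can make columns polymorphic but can never
  fabricate a spurious group-conserved or focal-private site. Unconstrained
  mode exists for power exploration and offers no such guarantee.

All sampling is integer-based from a seeded NumPy generator, so a fixed seed
reproduces byte-identical artifacts across platforms; the `simulate` CLI
subcommand writes the dataset plus its truth files and a manifest.

What the generators do **not** emulate: realistic amino-acid substitution
models (mtREV/JTT), indels and alignment uncertainty, rate heterogeneity
across sites, and origin-spanning features. Passing recovery tests therefore
demonstrates algorithmic correctness under clean, known-truth conditions,
not robustness to alignment error in real data.

## Problem sizes in tests

The test suite runs entirely on packaged tables and synthetic data: oracle
equivalence uses 100 random 300–500 bp sequences for the SSR scanner,
random 9-taxon alignments for the site detector, 20 seeded constraint-mode
simulations for planted-site recovery, and full 17.7 kb synthetic genomes
for profile/codon recovery. These sizes give exhaustive-oracle coverage at
interactive runtimes.

## Known limitations

* GenBank flat files and GFF3 are not parsed; inputs are FASTA plus the
  ten-column gene-table TSV dialect.
* Distances are model-free (no Γ rates, no mtREV); tree building, selection
  tests and ancestral reconstruction are out of scope.
* The pipeline consumes alignments; it does not produce them.
* Composition and distance values for the real accession set depend on
  fetching sequences and on aligner choice, and are therefore only
  approximately comparable to printed values.
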