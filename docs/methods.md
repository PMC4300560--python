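# Methods

This note documents the models, rules and numerical choices behind each
stage of the survey, what the synthetic data emulate (and do not), and the
design decisions taken where more than one reasonable option existed.

## Synthetic genomes

`simulate.generate_genome` builds, per species, three genomic contexts:

* **rDNA locus** — `n_rdna_units` tandem copies of the unit
  ETS–18S–ITS1–5.8S–ITS2–28S–NTS (default segment lengths 860, 2000, 340,
  160, 430, 4000, 1500 bp, the classic dipteran layout). A fraction
  `insertion_rate_28S` of 28S copies is interrupted mid-gene by a fixed
  non-ribosomal element (600 bp by default), the textbook reason rDNA
  assemblies fail; the element is drawn once per run so the failure mode is
  reproducible.
* **5S locus** — `n_5s_units` tandem repeats of `five_s_unit_length`
  (default 500 bp): the 120 bp mature gene, three spacer bases, the CTTTT
  Pol III terminator, then random spacer.
* **Gene scaffold** — planted miRNA precursors (90 bp, with a recorded
  22 nt mature), canonical C/D-box snoRNAs whose 12–18 nt guides are exact
  antisense to a window of that species' 18S, and tRNA genes with anticodons
  drawn uniformly over sense codons, each separated by ≥ 250 bp of random
  background.

Background sequence is i.i.d. uniform A/C/G/T — a neutral null for the
motif screens. Species sequences diverge **star-wise**: each species' copy
of a segment is mutated independently from one ancestral sequence with
substitutions at `per_site_polymorphism_rate` per site (default 0.01,
matching the ~96–100% intra-genus identity typical of 5.8S/5S genes). The
star model makes the number of polymorphic alignment columns exactly
binomial, which the test suite exploits; it deliberately carries **no
phylogenetic signal**. Tree-correlated sequences come from
`evolve_alignment`, which evolves sites along the true bifurcating tree the
generator also emits (uniform random topology, branch lengths uniform in
[0.02, 0.08] expected substitutions/site). Indels are off by default
(`indel_rate` is reserved); real rDNA spacers evolve largely by indel and
are not modelled.

Reads are uniformly placed substrings with independent per-base
substitution errors (`read_error_rate`, default 0.5%) and random strand; no
quality values, no paired ends, no coverage waves. Read length and coverage
defaults (100 bp, 20×) are free parameters of the simulation, not claims
about any particular sequencing campaign. Evidence tracks report each
planted miRNA with the source's sensitivity, start jitter uniform in
±20 bp, and Poisson false hits at `fp_per_kb`; confidences are uniform in
the source's configured range. Consequently, passing tests demonstrate the
*integration logic* (filtering, clustering, voting) under controlled error
rates — not the behaviour of any real predictor's score distribution.

## Consensus assembly

Recruitment uses overlap (free-end-gap) pairwise alignment with match +1,
mismatch −1, gap −2.1 (Biopython's C aligner). The non-integer gap penalty
is deliberate: at −2 a single gap is score-equal to two mismatches, so
co-optimal alignments with different identities exist and the recruited set
would depend on an arbitrary traceback; the 0.1 offset removes that tie
class. A read is recruited when its best alignment on either strand reaches
`min_identity` (default 0.85) over `min_overlap` aligned pairs (default
50). Defaults are chosen so that reads from genes diverged at
intra-genus levels (~85–100% identity) are recruited while random sequence
is not. Recruitment is intentionally query-biased — reads diverging beyond
the identity floor from the current query are invisible — mirroring the
BLAST-seeded procedure it models; no correction is attempted.

Consensus calling is per-column majority: call = most frequent base when
coverage ≥ `min_coverage` (default 2) and its fraction ≥
`majority_fraction` (default 0.5); ties and thin columns give N (IUPAC
codes are not emitted; single-base consensi match how such alignments are
conventionally displayed). Iteration re-queries with the previous
consensus (N-stripped) and stops on a fixed point or after `rounds_max`
rounds (flagged unconverged); the consensus may grow by up to
`read_length − min_overlap` per flank per round as overhanging reads extend
it. Coordinates are tracked across rounds so the final consensus is
reported in the coordinates of the original seed query.

Boundary delineation slides a `window` (default 20 bp) along two 5′-anchored
sequences and returns the last position up to which every window's identity
stays ≥ `identity_floor` (default 0.8) — the "similarity drop" criterion
for locating a gene end against a diverged reference. The Pol III
terminator search returns the 1-based downstream position of the first
CTTTT after the gene end within `search_span` (default 100 bp); motifs
straddling the gene end are not downstream and are ignored.

## Alignment profiling

The symbol conventions are: `-` is a real gap (participates as mismatch),
`.` is sequence never identified for that species (excluded from both
consensus voting and polymorphism calls). A column is polymorphic iff some
species carries an A/C/G/T there that differs from the consensus. All
printed percentages round half away from zero — integer window shares,
one-decimal identities and densities — because that is the convention the
summary tables use (7/42 → 17, 13/42 → 31). Report positions are 1-based
on the consensus.

## miRNA calling

Scaffold chopping uses 521 bp windows stepping 345 bp (overlap exactly
176 bp), the window layout of the *ab initio* predictors. Confidence
thresholds are per-source (defaults: 0.80 for the two *ab initio* lines,
0.90 for the comparative screen, none for homology/mature mapping, which
carry their own stringency). Clustering is single linkage with transitive
closure: same-scaffold, same-strand hits join when they overlap **or**
their starts differ by < 40 bp ("within an area of 40 bp" read as a strict
bound); opposite strands never join, even at identical coordinates, since
sense and antisense hairpins are distinct genes. A cluster becomes a gene
when ≥ 2 distinct evidence lines support it and at least one **member
hit** is > 70 bp (the rule speaks of the predicted hit's length; a
`span_semantics` flag switches to merged-span length). Filtering precedes
clustering. Mature mapping is exact (zero mismatches) on both strands,
confidence fixed at 1.0. Catalog comparison counts a gene as common when
its span overlaps a gene of the other catalog on the same scaffold and
strand, and reports `100 · common/|this|` to one decimal.

## C/D-box snoRNA screen

Box C must match RUGAUGA with its GAU core (positions 3–5) exact and at
most one mismatch among the peripheral positions; box D (CUGA) is exact.
Box C start to box D end must span 40–200 bp, the canonical C/D snoRNA
size range. The guide is the 10–21 nt immediately 5′ of box D; every guide
base must pair with the antiparallel target base, Watson–Crick or G:U
wobble, with ≤ 2 wobbles (standard for methylation guides). The additive
score `2·WC + 1·GU + 5·exact-C + 5·exact-D` with retention at > 20 is a
transparent surrogate for probabilistic log-odds snoRNA models — it is
**not** a reimplementation of any of them — calibrated so that a canonical
gene (exact boxes, ≥ 10 nt perfect guide: score ≥ 30) always clears the
threshold while random sequence rarely does (measured < 1 false candidate
per 10 kb of uniform background at defaults). For each box pair the
best-scoring guide length/placement wins; overlapping same-strand
candidates collapse to the highest score. Stem classification compares the
6 terminal 5′ bases with the reverse complement of the 6 terminal 3′
bases: the longest run of contiguous Watson–Crick pairs maps to ≥ 5 strong
stem / 4 terminal / 3 possible / else none. H/ACA snoRNAs are out of
scope: their motifs are too weakly conserved for this kind of primary-
sequence screen.

## tRNA census

Isotypes are validated against anticodons through the standard genetic
code (anticodon → reverse-complement codon → amino acid; selenocysteine =
TCA anticodon reading the recoded TGA). Pseudogenes are excluded from
isotype totals and reported in a separate column (an
`include_pseudogenes` flag folds them in), so percent shares describe the
functional repertoire. Genome size is a required input (assembly length /
10⁶). Outlier flagging tests each (species, isotype) cell with a
**two-sided Fisher exact test** of (k, n−k) against the pooled counts of
the remaining species, Bonferroni-corrected over all tested cells. A
binomial test of k against the pooled *proportion* was considered and
rejected: treating the estimated proportion as fixed inflates the
familywise false-flag rate far above α (measured ~20% at 5 species × 300
genes), whereas the Fisher construction keeps it below α while still
flagging a doubled isoacceptor count at realistic census sizes.

## Phylogenetics

Concatenation fills taxa missing from a partition with `?`, which carries
no state anywhere downstream. Site classes use only A/C/G/T as states:
constant = one state, variable = ≥ 2 states, parsimony-informative = ≥ 2
states each in ≥ 2 taxa; stateless columns count toward nothing, so
constant + variable equals the number of columns with ≥ 1 unambiguous
state. Neighbor-Joining is the classic Saitou–Nei agglomeration with the
Q-criterion; ties break to the lowest index pair so output is
deterministic for a given taxon order; negative branch lengths are clamped
to zero by default; an all-zero distance matrix returns an explicit star
tree. Distances are p-distance or JC69 (−¾ ln(1 − 4p/3)), with saturated
pairs (p ≥ 0.75) capped at a configurable maximum (default 5.0
substitutions/site). Likelihood and Bayesian inference, model selection
and branch support are out of scope.

## Problem sizes in the test and acceptance suites

The suites run the full methods at reduced but statistically meaningful
sizes, chosen as the smallest at which each property is sharply testable:
consensus recovery uses a 300 bp gene with 150 bp flanks at 20× coverage
over 50 (tests) / 30 (acceptance script) replicates; oracle equivalence
uses 200 random hit sets of ≤ 100 hits and 50-read recruitment sets;
outlier calibration uses 200 five-species null censuses of 300 genes; NJ
recovery uses eight taxa and 1500 bp alignments over 50 / 30 seeds; the
snoRNA false-positive measurement scans 20 × 15 kb of uniform background.

## Known limitations

* The star divergence model is analytically convenient but phylogenetically
  structureless; conclusions about tree inference rest solely on
  `evolve_alignment`.
* The snoRNA score is a surrogate; absolute scores are not comparable to
  log-odds scores of probabilistic models, only the retention behaviour is
  calibrated.
* Recruitment inherits the query bias of the seeded procedure it models.
* 28S insertion elements are a single fixed sequence per run; real
  insertions are heterogeneous repeat families.
* tRNA gene bodies in the simulator are random sequence with valid
  bookkeeping (isotype/anticodon), not folded cloverleaves; the census
  logic, not the detector, is under test.
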