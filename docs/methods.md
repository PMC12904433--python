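# Methods

This note documents the models, conventions and design choices behind
`superbarcode`, in the spirit of a methods appendix: what each
component computes, under which assumptions, and what the synthetic
data used by the test suite does and does not establish.

## Variant extraction from alignments

The substrate is a gapped multiple alignment of whole plastomes (or
nrDNA units) from a congeneric panel, produced upstream by any standard
aligner; the package consumes the alignment and never realigns.

**SNPs.** A pairwise SNP is a column where both samples carry a base in
`{A,C,G,T}` and the bases differ.  Ambiguity codes and `N` never count:
a column holding only `{A,N}` is treated as monomorphic.  This is
deliberately conservative — low-coverage positions and heteroplasmy
artifacts are common in plastome assemblies, and counting them would
inflate divergence estimates.

**InDels.** The unit is the *event*: one maximal contiguous run of gap
columns with a constant gapped-sample set counts once, regardless of
length.  Event counting matches the scale at which plastome InDel
numbers are conventionally reported (tens of events per genome pair,
versus thousands of gap columns); the gap-column count (*InDel sites*)
is reported alongside for transparency, since the alternative
convention cannot always be ruled out when reading published counts.

**Terminal gaps** (leading/trailing runs) are excluded from pairwise
counts by default as alignment-edge artifacts, with a flag to include
them.

**Coordinates** are 0-based half-open internally and 1-based inclusive
in every table and file.  SNP density uses a sliding window (default
600 bp window, 200 bp step) over the ungapped coordinates of a chosen
reference row; alignment columns where the reference is gapped are
dropped, and trailing partial windows are normalized by their actual
span rather than the nominal window.

## Diagnostic screening

A locus is diagnostic for target species *s* when it perfectly
separates *s* from every other labeled sample:

* SNP: all *s* samples fixed for one base, all non-target samples fixed
  for a different base (strict mode).  A *relaxed* mode drops non-target
  fixation and only requires that no non-target sample carries the
  target base — useful when the non-target side is heterogeneous.
* InDel: a gap-run event whose gapped-sample set is exactly the *s*
  sample set (deletion) or exactly its complement (insertion), with
  length strictly greater than 10 bp by default.  The strict inequality
  follows the screening rule used for gel-scorable InDel markers; a
  flag allows `>=`.

Columns containing `N`/ambiguity are discarded in strict mode and
ignored per sample in relaxed mode.  Species represented by a single
sample trivially satisfy fixation; a warning is logged because
intraspecific variation is then unassessed.  Candidate ranking is
deterministic (InDels before SNPs; InDels by descending length then
position) because long InDels give the cheapest, most robust assays.

## In-silico PCR, dominant markers and CAPS

Primer matching expands IUPAC codes on the primer side only; degenerate
template symbols are treated as mismatching everything (conservative).
Matching is exact by default (`max_mismatch=0`), reflecting that marker
validation is presence/absence on real templates; mismatch tolerance
and the 3′-terminal exact-match anchor length are per-primer settings.
Product sizes include both primer footprints — the standard convention,
and the one under which the shipped panel's printed sizes are exact.
Circular templates are scanned across the origin, and amplification is
invariant under template rotation.

Dominant (allele-specific) markers are modeled by forcing a ≥1 bp
3′ anchor: a template mismatch under the primer's 3′-terminal base —
the diagnostic SNP — abolishes the product.  CAPS markers digest the
amplicon with a user-supplied enzyme (recognition site + top-strand cut
offset, both strands scanned); fragment lengths always sum to the
amplicon length.  The published *Agrimonia* panel does not name the
restriction enzymes of its two CAPS assays, so the enzyme is
configuration; the synthetic genome builder uses EcoRI (`GAATTC`,
offset 1) as its convention.

A lane with several distinct product sizes is scored `none`
(uninterpretable) rather than guessed.  Observed fragment lists are
compared to expected lists with a size tolerance that defaults to 0
in silico; a few-bp tolerance supports comparison with empirical gels.

## Haplotype classification

Species profiles over a marker panel take values `A`/`B`/`absent`
(dominant markers map their non-amplifying group to `absent`).  A
sample is called to a species only at Hamming distance 0 to exactly one
profile.  Anything else is `novel`, reported with the nearest profiles
(ties in lexicographic order, all listed) and the disagreeing markers.
Novel profiles are never auto-added to the reference table: a congener
sharing alleles at some loci — the situation that motivates reporting
partial matches — remains a preliminary observation until a user
explicitly extends the table.

## Quadripartite structure

IR detection finds maximal *exact* inverted-repeat pairs by seeding
25-mers of the (doubled, for circularity) sequence against its reverse
complement and merging seed runs along diagonals; assembled plastome
IRs are typically identical, so a mismatch-tolerant mode is out of
scope.  The default minimum IR length of 1000 bp excludes small
dispersed repeats.  The longest pair defines IRa/IRb; the longer
single-copy arc is the LSC (tie-break: the arc clockwise of the first
repeat copy), and the output is rotation-normalized with the LSC
starting at position 1.  By construction `len(IRa) == len(IRb)` and the
four region lengths sum to the genome length; detection is invariant
under rotation and reverse complementation.

## Distance phylogenetics

Uncorrected p-distances (pairwise deletion by default — congeneric
plastome alignments are gap-sparse, and pairwise deletion preserves
signal) feed canonical Saitou–Nei neighbor joining: iteratively join
the pair minimizing the Q-criterion, with ties broken by the
lexicographic pair of cluster names and negative branch lengths clamped
to zero with the deficit moved to the sister edge (path lengths are
preserved; the clamp only fires on non-additive input).  NJ is exact on
additive matrices, which the tests exploit as an oracle, and the
implementation is cross-checked against an independent NJ
implementation on random additive inputs.  Supports come from a seeded
column-resampling bootstrap: resample alignment columns with
replacement, rebuild the tree, and report the percentage of replicates
containing each original bipartition.  Distance-based inference is the
package's deliberate scope; likelihood methods are not reimplemented,
and the claims tested here are topological (species exclusivity), which
NJ resolves comfortably at plastome-scale divergence.

## The synthetic generator

`simulate_species_set` emulates the features of a real congeneric
plastome panel that the pipeline depends on, with a complete truth set:

* **Geometry.**  Circular genomes with LSC/IRa/SSC/IRb layout.  The
  default 15 kb genome (2,600 bp IRs, 1,870 bp SSC) is a ~1:10 scale
  model of a real plastome keeping the region proportions; the
  `paper_scale` preset generates full-size genomes whose detected
  LSC/IR/SSC and total lengths fall inside the ranges observed across
  assembled *Agrimonia* plastomes (the master length is chosen so this
  holds after each sample's planted deletions).  The test suite runs at
  15 kb for speed; full-size generation is exercised by the acceptance
  script.
* **Divergence.**  Species evolve on the fixed tree
  `(((pilosa, coreana), nipponica), eupatoria)` — the topology
  recovered for the real genus — under uniform random substitutions.
  Defaults: 0.002 substitutions/site between sister species and 0.0003
  within species, matching the order of magnitude observed for real
  panels (hundreds of interspecific vs tens of intraspecific SNPs per
  genome) and preserving the interspecific ≫ intraspecific premise that
  makes super-barcoding work.  Every mutated column carries exactly one
  event, which keeps the derived truth exact; substitutions on a branch
  subtending exactly one species (or all but one) are themselves
  diagnostic and are book-kept as truth alongside the deliberately
  planted loci.
* **Planted features.**  Per species: 3 diagnostic SNP columns and
  InDel blocks of 12 and 20 bp, placed in mutation-protected windows so
  recovery at precision = recall = 1.0 is well-defined.  The published
  eight-marker panel is planted with its real primer sequences and
  printed product sizes; expected band patterns are verified against
  the package's own in-silico PCR at generation time, and the IR
  boundary bases are fixed non-complementary so detected region lengths
  equal the planted ones exactly.
* **Not modeled.**  Random InDel evolution (all InDels are planted),
  rate heterogeneity, IR boundary shifts, recombination, heteroplasmy,
  and sequencing error.  Passing tests on synthetic data therefore
  establish the correctness of the algorithms under the stated model,
  not robustness to assembly artifacts in real data — the conservative
  N/ambiguity handling above is the main guard there.

`simulate_divergent_pair` separately plants an exact number of SNPs and
InDel events (default 64 and 31, the most divergent conspecific pair
observed in real panels) into a full-length aligned pair, for exact
count-recovery checks.

The paper-scale preset allocates its 36 accessions as 26/3/4/3 across
the four species; the real validation panel's per-species counts are
not published, so a majority of the pharmacopoeia species was assumed.

## Numerical and interface choices

* All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give byte-identical outputs everywhere, including FASTA files.
* Marker definitions carry the species classification of each pattern
  label, so profile tables derive mechanically from a panel.
* An empty lane matches an empty expected fragment list: for dominant
  markers the non-target group scores its pattern label, which the
  classifier maps to the `absent` state.
* Problem sizes in the shipped tests: 15 kb genomes, 8 samples,
  100–200 bootstrap replicates — chosen so the full suite runs in
  seconds while every code path, including full-size generation in the
  acceptance script, is exercised.

## Known limitations

* Exact-repeat IR detection will under-segment genomes whose two IRs
  differ (rare in finished plastome assemblies, possible in drafts).
* Diagnostic screening assumes correct species labels; a single
  mislabeled sample suppresses every true diagnostic site for its
  species rather than producing wrong ones (fixation fails) — a safe
  but silent failure mode.
* Primer matching is combinatorial, not thermodynamic: no melting
  temperatures, primer-dimer or secondary-structure checks.  Primers
  are inputs, not designed.
* The classifier is exact-match by design; probabilistic assignment and
  mixture (contamination) deconvolution are out of scope.
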