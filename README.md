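# superbarcode

Whole-plastome **super-barcoding** for species authentication of closely
related plants, built around the marker system developed for the four
*Agrimonia* species traded as medicinal material in Korea (*A. pilosa*,
*A. coreana*, *A. nipponica*, *A. eupatoria*).  These species are nearly
indistinguishable from vegetative material, so authentication relies on
molecular assays derived from complete plastid genomes (~155 kb).  The
package is aimed at researchers who have assembled and aligned plastomes
(or nrDNA units) of a congeneric species panel and want to go from that
alignment to validated PCR-scorable markers and species calls.

## What it does

Given a gapped multi-FASTA alignment with a sample → species table, the
library covers the full pipeline:

* **Variant extraction** — pairwise and column-wise SNPs, InDel *events*
  (one maximal gap run = one event) and sliding-window SNP density
  tracks (default 600 bp window, 200 bp step) in reference coordinates.
* **Diagnostic screening** — a site is diagnostic for species *s* when
  the *s* samples are fixed for one allele and every other sample
  carries a different one; InDel candidates additionally require length
  > 10 bp (gel-resolvable).  Candidates are annotated against gene/IGS
  intervals and ranked deterministically.
* **In-silico genotyping** — PCR amplicon prediction on circular or
  linear templates with IUPAC-aware, 3′-anchored primer matching; three
  marker chemistries: codominant InDel (allele size difference),
  dominant SNP (allele-specific primer, presence/absence) and
  codominant CAPS (restriction digestion of the amplicon).  The
  published eight-marker *Agrimonia* panel (AP1–AE2) ships with the
  package, primers included.
* **Haplotype classification** — samples are assigned to species only on
  an exact multilocus profile match; anything else is reported as a
  *novel* haplotype with the nearest species and disagreeing markers,
  so congeners outside the panel surface instead of being forced in.
* **Plastome structure** — detection of the quadripartite
  LSC/IRa/SSC/IRb architecture via maximal exact inverted-repeat search,
  with rotation normalization (LSC first).
* **Phylogenetics** — p-distances, canonical Saitou–Nei neighbor
  joining (exact on additive matrices) and column-resampling bootstrap
  supports, to verify that each species forms an exclusive clade.
* **Simulation** — a seed-deterministic generator of mini-plastome
  species sets (default 15 kb, scalable to full size) with a complete
  truth set: planted diagnostic loci, planted marker loci reproducing
  the published primer sequences and product sizes, known quadripartite
  coordinates and a known species tree.

## Worked example

`examples/pcr_caps_demo.py` amplifies a toy circular template with the
published AP1 primer pair and digests the product with EcoRI:

```
product: 450 bp at 301..750
EcoRI digest: [282, 168] (sum 450 bp)
```

The 450 bp product is the shared AP1 amplicon; the 282 + 168 bp digest
is the cut (pattern A) lane that identifies *A. pilosa*, while the other
species stay uncut at 450 bp.  `examples/genotype_panel.py` runs the
whole panel on a simulated species set:

```
          AE2    AE1    AN1       AC1    AN2    AP2    AC2        AP1
sample
Ap_1    B:148  B:124  B:182     B:250    B:-  A:201  B:143  A:282,168
Ac_1    B:148  B:124  B:182  A:196,54    B:-    B:-  A:163      B:450
An_1    B:148  B:124  A:210     B:250  A:260    B:-  B:143      B:450
Ae_1    A:188  A:180  B:182     B:250    B:-    B:-  B:143      B:450

Haplotype calls:
  Ap_1   -> A. pilosa      (profile distance 0)
  Ac_1   -> A. coreana     (profile distance 0)
  An_1   -> A. nipponica   (profile distance 0)
  Ae_1   -> A. eupatoria   (profile distance 0)
```

Each cell is the scored pattern label with the lane's fragment sizes in
bp (`B:-` is an empty lane of a dominant marker).  Every sample matches
exactly one species profile, which is the species call.  The other
examples cover diagnostic screening (`diagnostic_screen.py`) and
structure detection plus tree building (`structure_and_tree.py`).

A thin CLI mirrors the library (`superbarcode simulate | variants |
density | diagnose | pcr | genotype | classify | structure | tree`).

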