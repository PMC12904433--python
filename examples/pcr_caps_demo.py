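"""In-silico PCR and CAPS digestion with the published AP1 primers.

Builds a small circular template carrying the published AP1 primer
sites around a 405 bp insert with an EcoRI site positioned so the cut
falls 282 bp into the product, then amplifies and digests.  The product
is the published 450 bp amplicon; the digest yields the published
282 + 168 bp pattern that distinguishes A. pilosa (cut) from the other
species (uncut).
"""

import numpy as np

import superbarcode as sb

rng = np.random.default_rng(0)
F = "TCCCGAATATTCAACCGATTA"
R = "CCCTTTGTGTATACCTTTTCAAAT"
enzyme = sb.ECORI

# interior: 405 bp so the product is 21 + 405 + 24 = 450 bp,
# with the EcoRI site starting 281 bp in (cut offset 1 -> cut at 282)
interior = "".join("ACGT"[i] for i in rng.integers(0, 4, 405))
while enzyme.recognition in interior:
    interior = "".join("ACGT"[i] for i in rng.integers(0, 4, 405))
site_at = 281 - len(F)
interior = interior[:site_at] + enzyme.recognition + interior[site_at + 6 :]

flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
template = sb.SequenceRecord(
    "toy", flank + F + interior + sb.reverse_complement(R) + flank, circular=True
)

(amplicon,) = sb.amplify(template, sb.PrimerPair("AP1", F, R))
print(f"product: {amplicon.length} bp at {amplicon.start}..{amplicon.end}")
fragments = sb.digest(amplicon, enzyme)
print(f"EcoRI digest: {fragments} (sum {sum(fragments)} bp)")
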