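"""Affinity/hypergeometric TF association on a planted promoter set.

Ranks genes by PWM binding affinity and by condition specificity, then
minimizes the hypergeometric overlap tail over a grid of rank cutoffs.
The PWM planted into the high-specificity genes should get the smallest
p-value; information-content-matched decoys should not.
"""

import numpy as np

from lpsmotif import associate_library
from lpsmotif.io import PWM, PromoterSequence

rng = np.random.default_rng(7)
WORD = "ACGTTGCAAT"


def sharp(word, accession):
    idx = {b: i for i, b in enumerate("ACGT")}
    probs = np.full((len(word), 4), 0.01)
    for k, c in enumerate(word):
        probs[k, idx[c]] = 0.97
    return PWM(accession, accession, probs)


library = [sharp(WORD, "PLANTED")] + [
    sharp(w, f"DECOY{i + 1}") for i, w in enumerate(
        ["TTAACGGCAA", "CCGGATTACC", "GGCCTTAAGG"])]

promoters, specificity = [], {}
for i in range(60):
    seq = list("".join(rng.choice(list("ACGT"), 200)))
    is_specific = i < 15
    if is_specific:  # plant a binding site into the induced class
        off = int(rng.integers(0, 190))
        seq[off:off + len(WORD)] = list(WORD)
    gene = f"g{i:03d}"
    promoters.append(PromoterSequence(gene, "".join(seq)))
    specificity[gene] = 4.0 + rng.normal(0, 0.2) if is_specific else rng.normal(0, 0.2)

for r in associate_library(library, promoters, specificity, cutoff_grid=(5, 10, 15, 30)):
    print(f"{r.matrix_accession:<8} best_p={r.best_p:.3g} "
          f"cutoffs={r.best_cutoffs} overlap={r.overlap_k}")
print("best_p is the minimum hypergeometric tail over the cutoff grid: the "
      "probability of at least that much overlap between the top-affinity "
      "and top-specificity gene lists by chance.  Lower is better.")
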