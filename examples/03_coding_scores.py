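"""The four per-ORF coding-potential statistics, on controlled inputs.

ORF score (3-nt periodicity of P-sites), ribosome release score (Ribo/RNA
coverage drop after the stop), Fickett TESTCODE and the hexamer usage
score, plus the mORF-percentile threshold rule.
"""

import numpy as np

from riboscreen import (
    fickett,
    hexamer_score,
    hexamer_train,
    orf_score,
    orf_score_threshold,
    rrs,
)

# Periodic footprints concentrate in frame 0: strongly positive score
print("ORF score (30,0,0)  :", round(orf_score((30, 0, 0))[0], 3))   # log2(61)
print("ORF score (10,10,10):", orf_score((10, 10, 10))[0])           # no rhythm
print("ORF score (0,30,0)  :", round(orf_score((0, 30, 0))[0], 3))   # wrong frame

# Ribosome release: ORF body FPKM 8 vs 3'UTR 1 on Ribo, 4 vs 2 on RNA
print("RRS (8,1,4,2)       :", rrs(8, 1, 4, 2)[0])  # log2((8/1)/(4/2)) = 2

# Sequence statistics
rng = np.random.default_rng(0)
coding_like = "ATGGCTGCTGAAGCTGCTAAAGCTGAA" * 4
random_seq = "".join(rng.choice(list("ACGT"), size=108))
print("Fickett coding-like :", round(fickett(coding_like), 4))
print("Fickett random      :", round(fickett(random_seq), 4))

table = hexamer_train([coding_like], [random_seq])
print("hexamer, coding-like:", round(hexamer_score(coding_like, table)[0], 3))
print("hexamer, random     :", round(hexamer_score(random_seq, table)[0], 3))

# The screening threshold: 5th percentile of annotated-mORF scores
morf_scores = rng.normal(12, 2, size=50)
print("mORF p5 threshold   :", round(orf_score_threshold(morf_scores), 3))
# A noncanonical ORF is called translated only if its ORF score reaches
# the 5th percentile of the protein-coding calibration set.
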