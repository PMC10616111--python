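"""Enumerate, classify and annotate ORFs on a transcript.

Shows the ORF catalog of a hand-built coding transcript (uORF + mORF) and
the effect of the start-codon mutation ATG -> ATT: the mutated ORF — and
only that ORF — disappears from the catalog.
"""

from riboscreen import Transcript, catalog_transcript, longest_peptide

# 5' pad, a 9-nt uORF, spacer, then a 27-nt main ORF and a 3' tail
seq = "CCACCACC" + "ATGAAATAG" + "CCACCA" + "ATGGTTGTTGTTGTTGTTGTTGTTTAG" + "CCACCACCACC"
t = Transcript("demo", seq, "protein_coding", cds=(23, 50))

for o in catalog_transcript(t, min_nt=3):
    print(f"{o.orf_class:<6s} {o.start:3d}-{o.end:<3d} {o.peptide_len_aa:3d} aa  utr3={o.utr3}")
print("longest peptide:", longest_peptide(t).length_aa, "aa")

# mutate the uORF start codon: ATG -> ATT
mut = Transcript("demo_mut", seq[:8] + "ATT" + seq[11:], "protein_coding", cds=(23, 50))
print("\nafter mutating the uORF start codon:")
for o in catalog_transcript(mut, min_nt=3):
    print(f"{o.orf_class:<6s} {o.start:3d}-{o.end:<3d} {o.peptide_len_aa:3d} aa")
# The uORF vanishes; the mORF (equal to the annotated CDS) is untouched.
# A noncanonical ORF's 3'UTR runs from its stop codon to the next downstream
# ATG in any frame; the mORF's runs to the transcript end.
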