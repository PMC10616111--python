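# Methods

## Scope and model

`riboscreen` screens transcript-space ribosome-profiling data for actively
translated small ORFs on lncRNAs. Two footprint signatures define
translation here: P-site frame locking (3-nt periodicity) within the ORF
body, and ribosome release at the stop codon (footprint density collapsing
in the downstream region while RNA-seq coverage does not). The screen
combines these with an expression floor and a two-condition differential
test, calibrating the periodicity threshold on the annotated protein-coding
ORFs of the same run.

All coordinates are 0-based half-open in transcript space. An ORF interval
includes its stop codon; `coding_nt = end − start − 3` excludes it, and
peptide length is `coding_nt / 3` (initiator Met counted, stop not). A
492-nt ORF therefore encodes a 163-aa peptide.

## ORF catalog

* Start codons: ATG only. The screen's biology is ATG-dependent (mutating a
  start to ATT abolishes the product), and near-cognate starts are out of
  scope.
* Nested ORFs sharing a stop codon collapse to the 5'-most ATG
  (`collapse_nested=False` emits all).
* Classes: mORF (interval equals the annotated CDS), uORF (ends at or
  before the CDS start), dORF (starts at or after the CDS end), lncORF (on
  lncRNAs). ORFs overlapping the CDS without equalling it are catalogued as
  `overlapping` and excluded from screening — the screen's taxonomy has no
  defined gate for them.
* Operational 3'UTR: for the mORF, CDS end → transcript end; for
  noncanonical ORFs, stop codon → next downstream ATG in any frame
  (rationale: a downstream ATG could re-initiate and contaminate the
  release signal), falling back to the transcript end when no ATG exists
  downstream. Zero-length regions are flagged `no_utr3` and the ORF then
  fails the RRS gate with that reason.
* The noncanonical catalog is windowed to 90–297 coding nt by default
  (30–99 aa): the sORF convention is < 300 nt, and peptides below ~30 aa
  are rarely recoverable. Both bounds are configurable; the annotated mORF
  is always catalogued regardless of the window.

## Quantification

* P-site: footprint 5' end + 12 nt, the canonical 80S offset, configurable.
  RNA-seq fragments use their midpoint as a positional proxy (only relative
  coverage matters for RRS).
* ORF-body counts exclude the stop codon (`[start, end−3)`): terminating
  ribosomes dwell on the stop and distort frame statistics. The FPKM length
  for the body is correspondingly `coding_nt`.
* `lib_total` for FPKM is the library's total assigned P-sites across all
  transcripts. Multimapping is not modelled; reads are counted once at
  their given placement.

## Scores

* **ORF score**: `log2(1 + Σ (Fi − F̄)²/F̄)` over frame counts pooled across
  all Ribo libraries, negated unless F0 is the strict maximum; all-zero
  counts give 0 with flag `zero_ribo`. The statistic grows with counts —
  which is why the threshold is calibrated on the same run's mORFs (5th
  percentile, linear interpolation, ≥ 20 calibration ORFs required) rather
  than fixed in absolute terms.
* **RRS**: computed on pooled counts with a pseudocount ε = 0.5 added in
  count space *before* FPKM conversion, so zero 3'UTR counts yield a large
  finite score instead of infinity; ε = 0 reproduces the raw formula and
  flags degenerate zeros instead of scoring them.
* **Fickett TESTCODE**: straight from the embedded classical lookup tables
  (position asymmetry max/(min+1) per base, content fractions, weighted
  probabilities summed over the 8 sub-scores).
* **Hexamer score**: mean over in-frame hexamers (step 3) of
  `log(f_coding/f_noncoding)`, with add-1 pseudo-occurrence smoothing of
  both frequency estimates. Coding frequencies count in-frame hexamers of
  the run's own mORF coding regions; noncoding frequencies count all
  offsets (step 1) of lncRNA sequence outside catalogued ORFs — noncoding
  sequence has no frame, so all offsets are equally informative. With
  `noncoding_step=3` the counting is symmetric and identical corpora yield
  an all-zero table.

## Differential translation

The two-condition test is implemented in-package rather than delegated:

* Median-of-ratios size factors over ORFs nonzero in every library,
  rescaled to geometric mean 1; library-total fallback (with a warning)
  when no such ORF exists.
* A single pooled method-of-moments common dispersion,
  `φ = Σ(n_g−1)(s²_g − m_g) / Σ(n_g−1)m_g²` over all ORFs and groups,
  floored at 1e-4; with one replicate per group a configured prior (0.1)
  is used. The pooled ratio is much stabler than per-ORF moment estimates
  at 3 replicates.
* Exact-style conditional test: group sums of NB counts (on normalized,
  rounded pseudo-counts) conditioned on their total follow a negative
  hypergeometric law with shape `n_g/φ`; the two-sided p-value sums all
  splits no more probable than the observed one. log₂FC is condition 2 over
  condition 1 on normalized means with pseudocount 0.5.
* BH step-up FDR over all tested ORFs.

Calibration (checked in the tests and the acceptance script): at NB
dispersion 0.1, n = 3 vs 3, null mean 100, the empirical type-I error at
nominal 0.05 lies in [0.03, 0.07]; power for a planted 4-fold change at
mean 200, dispersion 0.05 exceeds 0.9. The null mean of 100 was chosen to
sit well inside the test's asymptotic regime. No claim is made of numerical
identity with any external differential-expression package. A
translational-efficiency mode (testing Ribo/RNA ratio changes) is a
deliberate non-goal of the default screen, which tests Ribo abundance.

## The combined screen

Default gates, each configurable (`ScreenConfig`):

| gate | rule | default |
|---|---|---|
| expression | group-mean Ribo FPKM over the ORF body, max over conditions | ≥ 1 |
| differential | \|log₂FC\| ≥ log₂(fc_min) and FDR < fdr_max | fc 2, FDR 0.05 |
| periodicity | ORF score ≥ mORF 5th percentile (`orf_score_rule="none"` ablates) | on |
| release | RRS > rrs_min; `no_utr3` fails with reason | 0 |
| sequence | Fickett / hexamer minima | off (reported only) |

"Expression in at least one sample group" is read as the group-mean Ribo
FPKM; the final pass is the conjunction of enabled gates, and candidates
are the passing lncORFs. With no RNA-seq libraries the release gate is
disabled with a prominent warning and the pass recomputed without it.
Output ordering is deterministic (transcript_id, start).

## Synthetic data: what it emulates, and what it does not

The generator plants a known truth for every downstream stage. Defaults
(the study conditions used throughout the tests and acceptance run):
30 coding transcripts (CDS 300–900 nt; uORF probability 0.5, dORF 0.3),
100 lncRNAs each with exactly one sORF of 90–297 coding nt, 20% of them
translated; periodicity 0.85 and 3'UTR leak 0.05 (typical of good
ribosome-profiling libraries); footprint lengths 26–32 nt; 3 replicates ×
2 conditions × 150,000 reads per library for both assays; planted Ribo
fold change 4 on the translated lncORFs; lognormal transcript abundances
(σ = 1.5) shared between assays; per-ORF translational efficiency
lognormal (σ = 0.5); per-library signal jitter (σ = 0.1); uniform
background at 2% of a transcript's abundance per nt.

Design choices worth knowing:

* **Planted positives are robustly expressed.** Translated-lncORF host
  abundances are drawn from the upper half of the lognormal (|z| rather
  than z): the positives model induced, well-translated lncRNAs — the
  population the screen is meant to find. Planting positives below the
  detection floor would measure the simulator, not the method.
* **Sequence hygiene is exact, not probabilistic.** Planted-ORF interiors
  use only the 42 sense codons that cannot form an ATG in any frame within
  or across codons, and background segments are ATG-scrubbed; on lncRNAs a
  short marker ORF (15 coding nt, below the catalog window) pins the
  operational 3'UTR boundary. Consequences: ground truth matches the
  catalog exactly; no decoy ORF beyond the configured cap can occur; and
  mutating a planted start codon removes exactly one ORF (no nested ATG is
  unmasked). The cost is mild compositional unrealism inside planted ORFs.
* **Exact library sizes** via multinomial sampling over per-position rates
  (frame-0 weight `3dp`, other frames `3d(1−p)/2`, 3'UTR `leak·d`,
  read-through ORFs continue the frame pattern through the 3'UTR); P-sites
  are restricted to positions representable by a legal read, and read
  lengths are uniform over the configured range.
* Optional decoy populations: `n_aperiodic` lncORFs receive full ORF-level
  signal at periodicity 1/3 (with the fold change), so only the
  periodicity gate rejects them — used to demonstrate each gate is live;
  `frac_readthrough` makes translated ORFs continue through their 3'UTR,
  collapsing RRS toward 0.

Not modelled: genome space and splicing, sequencing errors, UMIs,
multimapping, length-dependent P-site offsets, nonuniform RNA-seq coverage,
and realistic codon usage inside planted ORFs. Passing tests therefore
demonstrate correctness of the statistics and the recovery of planted
signal structure, not performance on real libraries with their messier
offset calibration and overlapping-ORF landscapes.

## Numerical conventions

* Percentiles: linear interpolation between order statistics.
* P-site frame of position p in an ORF starting at s: `(p − s) mod 3`.
* Exact-test p-values computed in log space (gammaln/logsumexp) with a
  1e-10 slack when collecting outcomes "no more probable than observed";
  all-zero ORFs get p = 1, log₂FC = 0, flagged.
* Determinism: a single explicit seed drives generation and simulation
  through independent child streams; reruns are byte-identical. Scores are
  pure functions of their inputs.

## Problem sizes

The default scenario (130 transcripts, 1.8 M reads, ~380 screenable ORFs)
runs the full screen in a few seconds; the calibration simulations use
2000 null and 500 powered ORFs. These sizes give stable estimates (binomial
SE ≈ 0.005 on the type-I error) while keeping the whole suite fast.
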