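"""Per-ORF coding-potential statistics.

Four statistics are computed per ORF:

* **ORF score** — signed, log-scaled deviation of P-site frame counts from
  uniformity: with mean frame count ``F̄``, ``log2(1 + Σ (F_i − F̄)² / F̄)``,
  negated unless frame 0 is the strict maximum.  Positive values indicate
  the 3-nt periodicity of active translation.
* **RRS (ribosome release score)** — ``log2`` of the Ribo/RNA FPKM double
  ratio between the ORF body and its operational 3'UTR.  Genuine
  translation releases ribosomes at the stop codon, so footprint density
  collapses downstream while RNA coverage does not.
* **Fickett score** — the classical TESTCODE position-asymmetry/composition
  statistic, straight from the embedded lookup tables.
* **Hexamer score** — mean log-ratio of in-frame hexamer frequencies under a
  coding vs a noncoding usage table trained on reference corpora.

Also provided: the screening threshold rule — the empirical 5th percentile
of the ORF scores of annotated protein-coding main ORFs (linear
interpolation), below which a noncanonical ORF is not called translated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import fickett_tables as _ft

DEFAULT_RRS_PSEUDOCOUNT = 0.5
HEXAMERS = None  # built lazily


@dataclass
class ScoreSet:
    orf_id: str
    orf_score: Optional[float] = None
    rrs: Optional[float] = None
    fickett: Optional[float] = None
    hexamer: Optional[float] = None
    flags: set = field(default_factory=set)


def orf_score(frame_counts: Sequence[float]) -> tuple[float, set]:
    """Signed periodicity score from in-ORF P-site frame counts (F0, F1, F2).

    Returns (score, flags).  All-zero counts yield 0.0 with flag
    ``zero_ribo``; the score is negated unless F0 strictly exceeds both
    other frames.
    """
    f0, f1, f2 = (float(x) for x in frame_counts)
    if min(f0, f1, f2) < 0:
        raise ValueError(f"negative frame counts {frame_counts}")
    total = f0 + f1 + f2
    if total == 0:
        return 0.0, {"zero_ribo"}
    mean = total / 3.0
    dev = sum((f - mean) ** 2 for f in (f0, f1, f2)) / mean
    score = math.log2(1.0 + dev)
    if not (f0 > f1 and f0 > f2):
        score = -score
    return score + 0.0, set()  # normalise -0.0


def rrs(
    ribo_fpkm_orf: float,
    ribo_fpkm_utr3: float,
    rna_fpkm_orf: float,
    rna_fpkm_utr3: float,
) -> tuple[Optional[float], set]:
    """Ribosome release score from four FPKM values.

    ``log2((Ribo_orf/Ribo_utr3) / (RNA_orf/RNA_utr3))``.  Zero handling is
    the caller's job (apply a pseudocount in count space before FPKM, see
    :func:`rrs_from_counts`); a zero denominator or an all-zero input here
    is flagged and no value returned.
    """
    vals = (ribo_fpkm_orf, ribo_fpkm_utr3, rna_fpkm_orf, rna_fpkm_utr3)
    if any(v < 0 or math.isnan(v) for v in vals):
        return None, {"no_utr3"} if any(math.isnan(v) for v in vals) else {"zero_ribo"}
    if ribo_fpkm_utr3 == 0 or rna_fpkm_utr3 == 0 or ribo_fpkm_orf == 0 or rna_fpkm_orf == 0:
        flags = set()
        if ribo_fpkm_orf == 0 or ribo_fpkm_utr3 == 0:
            flags.add("zero_ribo")
        if rna_fpkm_orf == 0 or rna_fpkm_utr3 == 0:
            flags.add("zero_rna")
        return None, flags
    return math.log2((ribo_fpkm_orf / ribo_fpkm_utr3) / (rna_fpkm_orf / rna_fpkm_utr3)), set()


def rrs_from_counts(
    ribo_count_orf: float,
    ribo_count_utr3: float,
    rna_count_orf: float,
    rna_count_utr3: float,
    orf_len: int,
    utr3_len: int,
    ribo_total: int,
    rna_total: int,
    pseudocount: float = DEFAULT_RRS_PSEUDOCOUNT,
) -> tuple[Optional[float], set]:
    """RRS with the pseudocount applied in count space before FPKM conversion.

    With ``pseudocount=0`` this reproduces the raw double-ratio formula
    (and flags degenerate zeros instead of returning a value).
    """
    from .quant import fpkm

    if utr3_len <= 0:
        return None, {"no_utr3"}
    e = pseudocount
    return rrs(
        fpkm(ribo_count_orf + e, orf_len, ribo_total),
        fpkm(ribo_count_utr3 + e, utr3_len, ribo_total),
        fpkm(rna_count_orf + e, orf_len, rna_total),
        fpkm(rna_count_utr3 + e, utr3_len, rna_total),
    )


# ---------------------------------------------------------------------------
# Fickett TESTCODE


def _lookup(value: float, bounds, probs) -> float:
    for i, b in enumerate(bounds):
        if value >= b:
            return probs[i]
    return probs[-1]


def fickett(sequence: str) -> float:
    """Fickett TESTCODE value of a nucleotide sequence (>= 6 nt, ACGT only)."""
    seq = sequence.upper()
    if len(seq) < 6:
        raise ValueError(f"sequence too short for Fickett statistic ({len(seq)} nt)")
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            raise ValueError(f"invalid character {ch!r} at position {i}")
    score = 0.0
    n = len(seq)
    for base in "ACGT":
        pos_counts = [
            sum(1 for j in range(k, n, 3) if seq[j] == base) for k in range(3)
        ]
        pos_value = max(pos_counts) / (min(pos_counts) + 1.0)
        content = seq.count(base) / n
        score += (
            _lookup(pos_value, _ft.POSITION_BOUNDS, _ft.POSITION_PROB[base])
            * _ft.POSITION_WEIGHT[base]
        )
        score += (
            _lookup(content, _ft.CONTENT_BOUNDS, _ft.CONTENT_PROB[base])
            * _ft.CONTENT_WEIGHT[base]
        )
    return score


# ---------------------------------------------------------------------------
# Hexamer usage bias


def _all_hexamers() -> list[str]:
    global HEXAMERS
    if HEXAMERS is None:
        from itertools import product

        HEXAMERS = ["".join(p) for p in product("ACGT", repeat=6)]
    return HEXAMERS


def _hexamer_counts(seqs: Iterable[str], step: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in seqs:
        s = s.upper()
        for i in range(0, len(s) - 5, step):
            h = s[i : i + 6]
            if all(c in "ACGT" for c in h):
                counts[h] = counts.get(h, 0) + 1
    return counts


def hexamer_train(
    coding_seqs: Sequence[str],
    noncoding_seqs: Sequence[str],
    alpha: float = 1.0,
    noncoding_step: int = 1,
) -> dict[str, float]:
    """Train the hexamer log-ratio table.

    Coding frequencies use in-frame hexamer steps of 3; noncoding sequences
    have no frame, so all offsets count (step 1, configurable — with
    ``noncoding_step=3`` the counting is symmetric and identical corpora
    yield an all-zero table).  Each of the 4096 hexamers maps to
    ``log(f_coding / f_noncoding)`` with add-``alpha`` pseudo-occurrence
    smoothing of both frequency estimates, so every entry is finite.
    """
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("both a coding and a noncoding corpus are required")
    cc = _hexamer_counts(coding_seqs, step=3)
    nc = _hexamer_counts(noncoding_seqs, step=noncoding_step)
    tot_c = sum(cc.values()) + alpha * 4096
    tot_n = sum(nc.values()) + alpha * 4096
    table = {}
    for h in _all_hexamers():
        fc = (cc.get(h, 0) + alpha) / tot_c
        fn = (nc.get(h, 0) + alpha) / tot_n
        table[h] = math.log(fc / fn)
    return table


def hexamer_score(sequence: str, table: dict[str, float]) -> tuple[Optional[float], set]:
    """Mean table value over in-frame hexamers (steps of 3) of an ORF's coding region."""
    seq = sequence.upper()
    if len(seq) < 6:
        return None, {"too_short"}
    vals = [table[seq[i : i + 6]] for i in range(0, len(seq) - 5, 3)]
    return float(np.mean(vals)), set()


def save_hexamer_table(table: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        for h in _all_hexamers():
            fh.write(f"{h}\t{table[h]:.10g}\n")


def load_hexamer_table(path) -> dict[str, float]:
    table = {}
    with open(path) as fh:
        for line in fh:
            h, v = line.split("\t")
            table[h] = float(v)
    return table


# ---------------------------------------------------------------------------
# Threshold rule


def orf_score_threshold(morf_scores: Sequence[float], min_n: int = 20, q: float = 5.0) -> float:
    """Empirical 5th percentile (linear interpolation) of mORF ORF scores.

    The calibration set must hold at least ``min_n`` scores; noncanonical
    ORFs scoring at or above the returned value are called translated.
    """
    scores = np.asarray(list(morf_scores), dtype=float)
    if scores.size < min_n:
        raise ValueError(
            f"only {scores.size} protein-coding ORF scores; at least {min_n} "
            "are needed to calibrate the threshold — enlarge the calibration set"
        )
    return float(np.percentile(scores, q, method="linear"))
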