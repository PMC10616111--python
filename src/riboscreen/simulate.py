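"""Synthetic ribosome-profiling data with planted ground truth.

Generates a toy transcriptome mixing protein-coding transcripts (annotated
mORF, optional uORF and dORF) with lncRNAs each carrying exactly one planted
ATG-initiated sORF, then simulates two-condition Ribo-seq and RNA-seq
alignments in transcript coordinates.  Translated ORFs receive footprints
with a tunable 3-nt periodicity and a sharp coverage drop after the stop
codon (a configurable fraction leaks into the operational 3'UTR);
untranslated ORFs see only uniform background; RNA-seq coverage is
position-uniform.  Condition 2 multiplies the footprint rate of a designated
subset of lncORFs by a planted fold change.

Sequence construction guarantees that the only ATG triplets on a transcript
are planted ORF starts (plus, on lncRNAs, a short downstream marker ORF that
pins the operational 3'UTR boundary): planted-ORF interiors use only sense
codons that cannot form ATG in any frame, within or across codons, and all
background segments are ATG-scrubbed.  This makes ground truth exact — the
decoy cap holds trivially, the operational 3'UTR of each planted ORF is
known in advance, and mutating a planted start codon removes exactly one ORF.

Everything is driven by a single explicit seed; identical scenarios produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .orfs import STOP_CODONS, Transcript, orf_id_for

MARKER_CODING_NT = 15  # ATG + 5 codons + TAG: pins the 3'UTR boundary on lncRNAs
MARKER_LEN = MARKER_CODING_NT + 6

# sense codons that can never create an ATG in any frame: no in-frame stop,
# not ATG itself, last base != A (blocks A|TG across a junction) and last two
# bases != AT (blocks AT|G across a junction)
SAFE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "CGT"
    if a + b + c not in STOP_CODONS
    and a + b + c != "ATG"
    and not (b == "A" and c == "T")
)


@dataclass
class SimScenario:
    """Parameters of one simulated screen; the seed is always explicit."""

    seed: int
    n_coding: int = 30
    n_lnc: int = 100
    frac_translated_lnc: float = 0.2
    periodicity: float = 0.85
    utr_leak: float = 0.05
    reads_per_lib_ribo: int = 150_000
    reads_per_lib_rna: int = 150_000
    fc_translated: float = 4.0
    n_reps: int = 3
    footprint_len_range: tuple[int, int] = (26, 32)
    # transcript architecture
    p_uorf: float = 0.5
    p_dorf: float = 0.3
    decoy_cap: int = 60
    sorf_len_range: tuple[int, int] = (90, 297)
    cds_len_range: tuple[int, int] = (300, 900)
    uorf_len_range: tuple[int, int] = (24, 60)
    dorf_len_range: tuple[int, int] = (24, 60)
    lnc_len_range: Optional[tuple[int, int]] = None
    # signal model
    abundance_sigma: float = 1.5
    te_sigma: float = 0.5
    uorf_density: float = 0.3
    dorf_density: float = 0.1
    background: float = 0.02
    rep_noise_sd: float = 0.1
    fc_subset_frac: float = 1.0
    frac_readthrough: float = 0.0
    n_aperiodic: int = 0
    psite_offset: int = 12
    rna_read_len: int = 50

    _PAD5 = (20, 80)
    _SPACER = (6, 20)
    _GAP3 = (10, 30)
    _LNC_UTR3 = (45, 120)
    _TAIL = (40, 120)

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an explicit integer")
        for name in ("frac_translated_lnc", "utr_leak", "p_uorf", "p_dorf",
                     "fc_subset_frac", "frac_readthrough"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 or (name == "utr_leak" and v >= 1.0):
                raise ValueError(f"{name}={v} outside its allowed range")
        if not (1.0 / 3.0 <= self.periodicity <= 1.0):
            raise ValueError(f"periodicity={self.periodicity} must lie in [1/3, 1]")
        for name in ("reads_per_lib_ribo", "reads_per_lib_rna", "n_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.footprint_len_range
        if not (0 < lo <= hi):
            raise ValueError(f"footprint_len_range={self.footprint_len_range} invalid")
        if not (0 <= self.psite_offset < lo):
            raise ValueError(
                f"psite_offset={self.psite_offset} outside footprint length "
                f"range {self.footprint_len_range}"
            )
        for name in ("sorf_len_range", "cds_len_range", "uorf_len_range", "dorf_len_range"):
            a, b = getattr(self, name)
            if not (3 <= a <= b):
                raise ValueError(f"{name}={getattr(self, name)} invalid")
        if self.n_aperiodic > round(self.n_lnc * (1 - self.frac_translated_lnc)):
            raise ValueError(
                f"n_aperiodic={self.n_aperiodic} exceeds the number of "
                "untranslated lncRNAs"
            )
        if self.lnc_len_range is not None:
            need = (
                self._PAD5[0] + self.sorf_len_range[0] + 3
                + self._LNC_UTR3[0] + MARKER_LEN + self._TAIL[0]
            )
            if self.lnc_len_range[1] < need:
                raise ValueError(
                    f"lnc_len_range={self.lnc_len_range} cannot host an sORF from "
                    f"sorf_len_range={self.sorf_len_range}: at least {need} nt "
                    "are required (5' pad + sORF + 3'UTR + marker + tail)"
                )


def _bg(rng: np.random.Generator, n: int) -> str:
    """Random background sequence with every ATG scrubbed (G -> C)."""
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    s = bytearray(alphabet[rng.integers(0, 4, size=n)].tobytes())
    i = 0
    while True:
        j = s.find(b"ATG", i)
        if j == -1:
            break
        s[j + 2] = ord("C")
        i = j + 1
    return s.decode()


def _orf_seq(rng: np.random.Generator, coding_nt: int) -> str:
    """ATG + safe interior codons + TAG; total length coding_nt + 3."""
    if coding_nt < 3 or coding_nt % 3:
        raise ValueError(f"coding_nt={coding_nt} must be a positive multiple of 3")
    n_inner = coding_nt // 3 - 1
    inner = "".join(
        SAFE_CODONS[k] for k in rng.integers(0, len(SAFE_CODONS), size=n_inner)
    )
    return "ATG" + inner + "TAG"


def _scrub_junctions(seq: str, protected: np.ndarray, allowed_starts: set[int]) -> str:
    """Mutate stray ATGs (not planted starts) at a position outside any
    planted ORF body; C substitutions cannot create new ATGs."""
    s = bytearray(seq.encode())
    i = 0
    while True:
        j = bytes(s).find(b"ATG", i)
        if j == -1:
            break
        if j in allowed_starts:
            i = j + 1
            continue
        for k in (j, j + 1, j + 2):
            if not protected[k]:
                s[k] = ord("C")
                break
        else:  # pragma: no cover - impossible by construction
            raise AssertionError(f"stray ATG at {j} entirely inside planted ORFs")
        i = j + 1
    return s.decode()


def _draw_len(rng: np.random.Generator, lo: int, hi: int, multiple3: bool = False) -> int:
    v = int(rng.integers(lo, hi + 1))
    if multiple3:
        v -= v % 3
        v = max(v, lo + (3 - lo % 3) % 3)
    return v


def generate_transcriptome(
    scenario: SimScenario,
) -> tuple[list[Transcript], pd.DataFrame, pd.DataFrame]:
    """Build the planted transcriptome.

    Returns (transcripts, annotation, ground_truth).  The annotation table
    has columns transcript_id / biotype / cds_start / cds_end (0-based
    half-open); ground truth one row per planted ORF with its class,
    translated flag, planted fold change and operational 3'UTR boundary.
    """
    scenario.validate()
    rng = np.random.default_rng([int(scenario.seed), 0])

    n_trans_lnc = int(round(scenario.n_lnc * scenario.frac_translated_lnc))
    lnc_status = np.array(
        ["translated"] * n_trans_lnc + ["untranslated"] * (scenario.n_lnc - n_trans_lnc)
    )
    rng.shuffle(lnc_status)
    untransl_idx = np.flatnonzero(lnc_status == "untranslated")
    aper = rng.choice(untransl_idx, size=scenario.n_aperiodic, replace=False) if scenario.n_aperiodic else []
    lnc_status[list(aper)] = "aperiodic"
    transl_idx = np.flatnonzero(lnc_status == "translated")
    n_fc = int(round(len(transl_idx) * scenario.fc_subset_frac))
    fc_set = set(rng.choice(transl_idx, size=n_fc, replace=False)) if n_fc else set()
    n_rt = int(round(len(transl_idx) * scenario.frac_readthrough))
    rt_set = set(rng.choice(transl_idx, size=n_rt, replace=False)) if n_rt else set()

    transcripts: list[Transcript] = []
    ann_rows = []
    truth_rows = []

    def add_truth(tid, start, end, cls, translated, fc, utr3, density, aperiodic=False, readthrough=False):
        truth_rows.append(
            {
                "orf_id": orf_id_for(tid, start, end),
                "transcript_id": tid,
                "start": start,
                "end": end,
                "orf_class": cls,
                "translated": bool(translated),
                "fc": float(fc),
                "utr3_start": utr3[0],
                "utr3_end": utr3[1],
                "rel_density": float(density),
                "aperiodic": bool(aperiodic),
                "readthrough": bool(readthrough),
            }
        )

    for i in range(scenario.n_coding):
        tid = f"coding_{i + 1:03d}"
        parts: list[str] = []
        planted: list[tuple[int, int]] = []  # bodies incl. stop
        pos = 0

        def put(s: str) -> int:
            nonlocal pos
            parts.append(s)
            start = pos
            pos += len(s)
            return start

        put(_bg(rng, _draw_len(rng, *SimScenario._PAD5)))
        uorf = None
        if rng.random() < scenario.p_uorf:
            u_nt = _draw_len(rng, *scenario.uorf_len_range, multiple3=True)
            u_start = put(_orf_seq(rng, u_nt))
            uorf = (u_start, u_start + u_nt + 3)
            planted.append(uorf)
            put(_bg(rng, _draw_len(rng, *SimScenario._SPACER)))
        cds_nt = _draw_len(rng, *scenario.cds_len_range, multiple3=True)
        cds_start = put(_orf_seq(rng, cds_nt))
        cds = (cds_start, cds_start + cds_nt + 3)
        planted.append(cds)
        put(_bg(rng, _draw_len(rng, *SimScenario._GAP3)))
        dorf = None
        if rng.random() < scenario.p_dorf:
            d_nt = _draw_len(rng, *scenario.dorf_len_range, multiple3=True)
            d_start = put(_orf_seq(rng, d_nt))
            dorf = (d_start, d_start + d_nt + 3)
            planted.append(dorf)
        put(_bg(rng, _draw_len(rng, *SimScenario._TAIL)))

        seq = "".join(parts)
        protected = np.zeros(len(seq), bool)
        for a, b in planted:
            protected[a:b] = True
        seq = _scrub_junctions(seq, protected, {a for a, _ in planted})
        L = len(seq)
        transcripts.append(Transcript(tid, seq, "protein_coding", cds))
        ann_rows.append({"transcript_id": tid, "biotype": "protein_coding",
                         "cds_start": cds[0], "cds_end": cds[1]})
        add_truth(tid, cds[0], cds[1], "mORF", True, 1.0, (cds[1], L), 1.0)
        if uorf is not None:
            add_truth(tid, uorf[0], uorf[1], "uORF", True, 1.0,
                      (uorf[1], cds[0]), scenario.uorf_density)
        if dorf is not None:
            add_truth(tid, dorf[0], dorf[1], "dORF", True, 1.0,
                      (dorf[1], L), scenario.dorf_density)

    for i in range(scenario.n_lnc):
        tid = f"lnc_{i + 1:03d}"
        status = lnc_status[i]
        pad5 = _bg(rng, _draw_len(rng, *SimScenario._PAD5))
        s_nt = _draw_len(rng, *scenario.sorf_len_range, multiple3=True)
        orf = _orf_seq(rng, s_nt)
        utr3_len = _draw_len(rng, *SimScenario._LNC_UTR3)
        tail_len = _draw_len(rng, *SimScenario._TAIL)
        if scenario.lnc_len_range is not None:
            target = _draw_len(rng, *scenario.lnc_len_range)
            fixed = len(pad5) + len(orf) + utr3_len + MARKER_LEN
            tail_len = max(SimScenario._TAIL[0], target - fixed)
        utr3_seq = _bg(rng, utr3_len)
        marker = _orf_seq(rng, MARKER_CODING_NT)
        tail = _bg(rng, tail_len)
        seq = pad5 + orf + utr3_seq + marker + tail
        o_start = len(pad5)
        o_end = o_start + len(orf)
        m_start = o_end + utr3_len
        planted_iv = [(o_start, o_end), (m_start, m_start + MARKER_LEN)]
        protected = np.zeros(len(seq), bool)
        for a, b in planted_iv:
            protected[a:b] = True
        seq = _scrub_junctions(seq, protected, {o_start, m_start})
        transcripts.append(Transcript(tid, seq, "lncRNA"))
        ann_rows.append({"transcript_id": tid, "biotype": "lncRNA",
                         "cds_start": pd.NA, "cds_end": pd.NA})
        add_truth(
            tid, o_start, o_end, "lncORF",
            translated=(status == "translated"),
            fc=scenario.fc_translated if (i in fc_set or status == "aperiodic") else 1.0,
            utr3=(o_end, m_start),
            density=1.0 if status in ("translated", "aperiodic") else 0.0,
            aperiodic=(status == "aperiodic"),
            readthrough=(i in rt_set),
        )

    truth = pd.DataFrame(truth_rows)
    annotation = pd.DataFrame(ann_rows)
    _verify(transcripts, truth, scenario)
    return transcripts, annotation, truth


def _verify(transcripts: list[Transcript], truth: pd.DataFrame, scenario: SimScenario) -> None:
    """Planted ORFs intact; no unplanned ATG anywhere (decoy cap trivially met)."""
    by_tid = truth.groupby("transcript_id")
    markers_ok = 0
    for t in transcripts:
        starts = set()
        if t.id in by_tid.groups:
            g = by_tid.get_group(t.id)
            for _, row in g.iterrows():
                s, e = int(row["start"]), int(row["end"])
                assert t.sequence[s : s + 3] == "ATG", (t.id, s)
                assert t.sequence[e - 3 : e] in STOP_CODONS, (t.id, e)
                starts.add(s)
                if row["orf_class"] == "lncORF":
                    starts.add(int(row["utr3_end"]))  # marker start
                    markers_ok += 1
        idx = -1
        while (idx := t.sequence.find("ATG", idx + 1)) != -1:
            if idx not in starts:
                raise AssertionError(f"unplanned ATG at {t.id}:{idx}")


# ---------------------------------------------------------------------------
# Read simulation


def library_table(scenario: SimScenario) -> pd.DataFrame:
    rows = []
    for cond in (1, 2):
        for rep in range(1, scenario.n_reps + 1):
            for assay in ("ribo", "rna"):
                rows.append(
                    {
                        "library_id": f"{assay}_c{cond}_r{rep}",
                        "assay": assay,
                        "condition": f"cond{cond}",
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def simulate_reads(
    scenario: SimScenario,
    transcripts: list[Transcript],
    truth: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate all libraries of the two-condition design.

    Returns (alignments, libraries): a BED-like table (transcript_id, start,
    end, library_id, assay, strand) and the per-library metadata.  Each
    library's row count equals its scenario size exactly.
    """
    scenario.validate()
    rng = np.random.default_rng([int(scenario.seed), 1])
    libs = library_table(scenario)

    tids = [t.id for t in transcripts]
    tlen = np.array([len(t) for t in transcripts])
    t_index = {tid: k for k, tid in enumerate(tids)}
    offsets = np.concatenate([[0], np.cumsum(tlen)])
    total_len = int(offsets[-1])
    off = scenario.psite_offset
    max_fp = scenario.footprint_len_range[1]

    # abundance shared across assays; translated-lncORF hosts are modelled as
    # induced, robustly expressed (upper half of the lognormal)
    z = rng.normal(size=len(tids))
    host_translated = set(truth.loc[truth["translated"], "transcript_id"])
    lnc_hosts = {tid for tid in tids if tid.startswith("lnc")}
    z = np.where(
        [tid in host_translated and tid in lnc_hosts for tid in tids], np.abs(z), z
    )
    abundance = np.exp(scenario.abundance_sigma * z)

    orf_te = np.exp(rng.normal(0, scenario.te_sigma, size=len(truth)))
    signal = truth[truth["rel_density"] > 0].copy()
    signal_te = orf_te[signal.index.to_numpy()]

    valid_lo = offsets[:-1] + off
    valid_hi = offsets[:-1] + tlen - max_fp + off  # inclusive

    frames_all = {}
    for k, row in enumerate(signal.itertuples()):
        gs = offsets[t_index[row.transcript_id]]
        body = np.arange(gs + row.start, gs + row.end - 3)
        frames_all[k] = (body, (body - (gs + row.start)) % 3)

    aln_parts = []
    for lib in libs.itertuples():
        cond2 = lib.condition == "cond2"
        if lib.assay == "ribo":
            jit = np.exp(rng.normal(0, scenario.rep_noise_sd, size=len(signal)))
            w = np.zeros(total_len)
            if scenario.background > 0:
                for k in range(len(tids)):
                    w[valid_lo[k] : valid_hi[k] + 1] += scenario.background * abundance[k]
            for k, row in enumerate(signal.itertuples()):
                ti = t_index[row.transcript_id]
                d = abundance[ti] * signal_te[k] * row.rel_density * jit[k]
                if cond2:
                    d *= row.fc
                per = 1.0 / 3.0 if row.aperiodic else scenario.periodicity
                body, fr = frames_all[k]
                w[body] += np.where(fr == 0, 3 * d * per, 3 * d * (1 - per) / 2)
                gs = offsets[ti]
                u_lo = max(int(gs + row.utr3_start), int(valid_lo[ti]))
                u_hi = min(int(gs + row.utr3_end), int(valid_hi[ti] + 1))
                if u_hi > u_lo:
                    if row.readthrough:
                        upos = np.arange(u_lo, u_hi)
                        ufr = (upos - (gs + row.start)) % 3
                        w[u_lo:u_hi] += np.where(ufr == 0, 3 * d * per, 3 * d * (1 - per) / 2)
                    else:
                        w[u_lo:u_hi] += scenario.utr_leak * d
            # P-sites outside the representable read window cannot occur
            for k in range(len(tids)):
                w[offsets[k] : valid_lo[k]] = 0.0
                w[valid_hi[k] + 1 : offsets[k + 1]] = 0.0
            counts = rng.multinomial(scenario.reads_per_lib_ribo, w / w.sum())
            nz = np.flatnonzero(counts)
            psites = np.repeat(nz, counts[nz])
            lens = rng.integers(
                scenario.footprint_len_range[0], max_fp + 1, size=len(psites)
            )
            t_of = np.searchsorted(offsets, psites, side="right") - 1
            starts = psites - offsets[t_of] - off
            ends = starts + lens
        else:
            wt = abundance * tlen
            per_t = rng.multinomial(scenario.reads_per_lib_rna, wt / wt.sum())
            t_of = np.repeat(np.arange(len(tids)), per_t)
            starts = rng.integers(0, tlen[t_of] - scenario.rna_read_len + 1)
            ends = starts + scenario.rna_read_len
        aln_parts.append(
            pd.DataFrame(
                {
                    "transcript_id": np.array(tids, dtype=object)[t_of],
                    "start": starts.astype(int),
                    "end": ends.astype(int),
                    "library_id": lib.library_id,
                    "assay": lib.assay,
                    "strand": "+",
                }
            )
        )
    alignments = pd.concat(aln_parts, ignore_index=True)
    return alignments, libs


def simulate_scenario(
    scenario: SimScenario,
) -> tuple[list[Transcript], pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """generate_transcriptome + simulate_reads in one call.

    Returns (transcripts, annotation, truth, alignments, libraries).
    """
    transcripts, annotation, truth = generate_transcriptome(scenario)
    alignments, libraries = simulate_reads(scenario, transcripts, truth)
    return transcripts, annotation, truth, alignments, libraries
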