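"""Footprint quantification: P-site assignment, per-ORF counts, FPKM.

A ribosome footprint is reduced to a single P-site coordinate, by default
+12 nt from its 5' end (the canonical 80S offset); RNA-seq fragments use
their midpoint as a positional proxy.  Counts over an ORF body exclude the
stop codon — terminating ribosomes distort frame statistics — and the region
length used for FPKM is correspondingly ``coding_nt``.  FPKM is
``count / ((region_len/1e3) * (lib_total/1e6))`` with ``lib_total`` the total
number of assigned P-sites in the library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .orfs import OrfRecord

DEFAULT_PSITE_OFFSET = 12

ALIGNMENT_COLUMNS = ["transcript_id", "start", "end", "library_id", "assay", "strand"]


@dataclass(frozen=True)
class FootprintAlignment:
    """One aligned read in transcript space, reduced to its essentials."""

    transcript_id: str
    start: int
    length: int
    library_id: str
    assay: str  # "ribo" | "rna"


@dataclass
class OrfQuant:
    orf_id: str
    library_id: str
    assay: str
    count_orf: int
    count_utr3: int
    fpkm_orf: float
    fpkm_utr3: float
    frame_counts: tuple[int, int, int]


def psite(alignment: FootprintAlignment, offset: int = DEFAULT_PSITE_OFFSET) -> int:
    """P-site position of a read: 5' end + offset (ribo); midpoint for RNA."""
    if alignment.assay == "rna":
        return alignment.start + alignment.length // 2
    if not 0 <= offset < alignment.length:
        raise ValueError(
            f"offset {offset} out of range for read length {alignment.length}"
        )
    return alignment.start + offset


def psite_positions(alignments: pd.DataFrame, offset: int = DEFAULT_PSITE_OFFSET) -> pd.Series:
    """Vectorized P-site for a BED-like alignment table (start/end half-open)."""
    length = alignments["end"] - alignments["start"]
    if (length <= 0).any():
        raise ValueError("alignment with non-positive length")
    is_rna = alignments["assay"].to_numpy() == "rna"
    ribo_len = length[~is_rna]
    if len(ribo_len) and not ((0 <= offset) and (offset < ribo_len.min())):
        raise ValueError(f"offset {offset} out of range for shortest ribo read")
    pos = alignments["start"] + np.where(is_rna, length // 2, offset)
    return pos.astype(int)


def fpkm(count: float, region_len: int, lib_total: int) -> float:
    """Fragments per kilobase of region per million mapped reads."""
    if region_len <= 0:
        raise ValueError(f"degenerate region of length {region_len}")
    if lib_total <= 0:
        raise ValueError(f"non-positive library total {lib_total}")
    return count / ((region_len / 1e3) * (lib_total / 1e6))


def count_orf(
    orf: OrfRecord,
    alignments: pd.DataFrame,
    lib_totals: Mapping[tuple[str, str], int],
    offset: int = DEFAULT_PSITE_OFFSET,
) -> list[OrfQuant]:
    """Per-(library, assay) P-site counts and FPKM for one ORF.

    P-sites in ``[start, end-3)`` count toward the ORF body with frame
    ``(p - start) mod 3``; P-sites in the operational 3'UTR toward
    ``count_utr3``.  ``lib_totals`` maps (library_id, assay) to the library's
    total assigned P-sites.
    """
    aln = alignments[alignments["transcript_id"] == orf.transcript_id]
    pos = psite_positions(aln, offset)
    body_lo, body_hi = orf.start, orf.end - 3
    out = []
    for (lib, assay), idx in aln.groupby(["library_id", "assay"], observed=True).groups.items():
        p = pos.loc[idx].to_numpy()
        in_body = p[(p >= body_lo) & (p < body_hi)]
        frames = np.bincount((in_body - body_lo) % 3, minlength=3)
        if orf.utr3 is not None:
            u_lo, u_hi = orf.utr3
            n_utr = int(((p >= u_lo) & (p < u_hi)).sum())
            f_utr = fpkm(n_utr, u_hi - u_lo, lib_totals[(lib, assay)])
        else:
            n_utr, f_utr = 0, float("nan")
        out.append(
            OrfQuant(
                orf_id=orf.orf_id,
                library_id=lib,
                assay=assay,
                count_orf=int(len(in_body)),
                count_utr3=n_utr,
                fpkm_orf=fpkm(len(in_body), orf.coding_nt, lib_totals[(lib, assay)]),
                fpkm_utr3=f_utr,
                frame_counts=(int(frames[0]), int(frames[1]), int(frames[2])),
            )
        )
    return out


def library_totals(alignments: pd.DataFrame) -> dict[tuple[str, str], int]:
    """Total mapped P-sites per (library_id, assay)."""
    return (
        alignments.groupby(["library_id", "assay"], observed=True)
        .size()
        .to_dict()
    )


def quantify_catalog(
    orfs: Iterable[OrfRecord],
    alignments: pd.DataFrame,
    offset: int = DEFAULT_PSITE_OFFSET,
    lib_totals: Optional[Mapping[tuple[str, str], int]] = None,
) -> pd.DataFrame:
    """Vectorized per-ORF × per-library quantification table.

    One row per (orf_id, library_id, assay) with counts, frame counts and
    FPKM.  Libraries with zero P-sites on an ORF still get a row (count 0),
    so downstream matrices are dense.
    """
    if lib_totals is None:
        lib_totals = library_totals(alignments)
    libs = sorted(lib_totals.keys())
    lib_index = {lib: i for i, lib in enumerate(libs)}
    nlibs = len(libs)

    pos_all = psite_positions(alignments, offset).to_numpy()
    codes_all = np.fromiter(
        (lib_index[k] for k in zip(alignments["library_id"], alignments["assay"])),
        dtype=int,
        count=len(alignments),
    )
    by_tid: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tid, g in alignments.groupby("transcript_id", observed=True):
        loc = alignments.index.get_indexer(g.index)
        by_tid[tid] = (pos_all[loc], codes_all[loc])

    rows = []
    for orf in orfs:
        p, code = by_tid.get(orf.transcript_id, (np.empty(0, int), np.empty(0, int)))
        body = (p >= orf.start) & (p < orf.end - 3)
        # one bincount over library-code x frame gives all frame counts at once
        fb = np.bincount(
            code[body] * 3 + (p[body] - orf.start) % 3, minlength=nlibs * 3
        ).reshape(nlibs, 3)
        if orf.utr3 is not None:
            u_lo, u_hi = orf.utr3
            u_len = u_hi - u_lo
            in_utr = (p >= u_lo) & (p < u_hi)
            utr = np.bincount(code[in_utr], minlength=nlibs)
        else:
            utr = np.zeros(nlibs, int)
        for i, lib in enumerate(libs):
            tot = lib_totals[lib]
            f_utr = fpkm(int(utr[i]), u_len, tot) if orf.utr3 is not None else float("nan")
            rows.append(
                {
                    "orf_id": orf.orf_id,
                    "library_id": lib[0],
                    "assay": lib[1],
                    "count_orf": int(fb[i].sum()),
                    "count_utr3": int(utr[i]),
                    "fpkm_orf": fpkm(int(fb[i].sum()), orf.coding_nt, tot),
                    "fpkm_utr3": f_utr,
                    "f0": int(fb[i, 0]),
                    "f1": int(fb[i, 1]),
                    "f2": int(fb[i, 2]),
                }
            )
    return pd.DataFrame(rows)
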