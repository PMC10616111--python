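"""Readers and writers for the pipeline's on-disk formats.

FASTA via Biopython; annotation as a TSV (transcript_id, biotype,
cds_start, cds_end; 0-based half-open) with a GTF export (transcript + CDS
features, 1-based inclusive per the format); alignments as a 6-column
BED-like TSV (transcript_id, start, end, library_id, assay, strand) with an
optional SAM export via pysam for format compatibility; ground truth and
all result tables as TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .orfs import Transcript
from .quant import ALIGNMENT_COLUMNS


def write_fasta(transcripts: Iterable[Transcript], path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description=t.biotype) for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, annotation: Optional[pd.DataFrame] = None) -> list[Transcript]:
    """Read transcripts; biotype/CDS from the annotation table when given,
    else every record is treated as a lncRNA."""
    ann = None
    if annotation is not None:
        ann = annotation.set_index("transcript_id")
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if ann is not None and rec.id in ann.index:
            row = ann.loc[rec.id]
            if row["biotype"] == "protein_coding":
                out.append(
                    Transcript(rec.id, seq, "protein_coding",
                               (int(row["cds_start"]), int(row["cds_end"])))
                )
                continue
        out.append(Transcript(rec.id, seq, "lncRNA"))
    return out


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    for col in ("cds_start", "cds_end"):
        ann[col] = ann[col].astype("Int64")
    return ann


def write_gtf(transcripts: Iterable[Transcript], path) -> None:
    """GTF export in transcript coordinates (1-based inclusive)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'transcript_id "{t.id}"; gene_biotype "{t.biotype}";'
            fh.write(
                f"{t.id}\triboscreen\ttranscript\t1\t{len(t)}\t.\t+\t.\t{attrs}\n"
            )
            if t.cds is not None:
                s, e = t.cds
                fh.write(
                    f"{t.id}\triboscreen\tCDS\t{s + 1}\t{e}\t.\t+\t0\t{attrs}\n"
                )


def write_alignments(alignments: pd.DataFrame, path) -> None:
    alignments[ALIGNMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_alignments(path) -> pd.DataFrame:
    aln = pd.read_csv(path, sep="\t")
    missing = set(ALIGNMENT_COLUMNS) - set(aln.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    return aln


def write_sam(
    alignments: pd.DataFrame,
    transcripts: Iterable[Transcript],
    path,
) -> None:
    """Unspliced SAM export in transcript space (header carries lengths)."""
    import pysam

    tlist = list(transcripts)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": t.id, "LN": len(t)} for t in tlist],
    }
    seqs = {t.id: t.sequence for t in tlist}
    tid_index = {t.id: i for i, t in enumerate(tlist)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, row in enumerate(alignments.itertuples()):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{row.library_id}.{i}"
            a.reference_id = tid_index[row.transcript_id]
            a.reference_start = int(row.start)
            length = int(row.end) - int(row.start)
            a.cigarstring = f"{length}M"
            a.query_sequence = seqs[row.transcript_id][row.start : row.end]
            a.mapping_quality = 255
            a.flag = 0
            a.set_tag("LB", row.library_id)
            out.write(a)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_scenario_bundle(
    outdir,
    transcripts,
    annotation: pd.DataFrame,
    truth: pd.DataFrame,
    alignments: pd.DataFrame,
    libraries: pd.DataFrame,
) -> dict[str, Path]:
    """Write one simulated scenario as its standard file set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "transcripts.fa",
        "gtf": outdir / "transcripts.gtf",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "ground_truth.tsv",
        "alignments": outdir / "alignments.tsv",
        "libraries": outdir / "libraries.tsv",
    }
    write_fasta(transcripts, paths["fasta"])
    write_gtf(transcripts, paths["gtf"])
    write_annotation(annotation, paths["annotation"])
    write_truth(truth, paths["truth"])
    write_alignments(alignments, paths["alignments"])
    libraries.to_csv(paths["libraries"], sep="\t", index=False)
    return paths
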