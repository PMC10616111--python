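"""The combined multi-score screen for translated lncRNA small ORFs.

Pipeline: ORF catalog -> footprint quantification -> coding-potential
scores -> differential translation -> combined filters.  The default gate
is the conjunction

    group-mean Ribo FPKM >= 1  AND  |log2FC| >= 1 with FDR < 0.05
    AND  ORF score >= 5th percentile of the annotated mORF scores
    AND  RRS > 0

with Fickett and hexamer scores reported (optional gates, off by default).
ORFs overlapping the annotated CDS without equalling it are catalogued but
excluded from screening.  Candidates are the passing lncORFs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import difftrans, quant, scores
from .orfs import OrfRecord, Transcript, catalog_transcript


@dataclass
class ScreenConfig:
    """Thresholds and conventions of the combined screen."""

    fpkm_min: float = 1.0
    fc_min: float = 2.0
    fdr_max: float = 0.05
    sorf_max_nt: int = 300
    orf_min_nt: int = 90
    orf_score_rule: str = "p5_of_mORFs"
    orf_score_percentile: float = 5.0
    min_morf_calibration: int = 20
    rrs_min: Optional[float] = 0.0
    fickett_min: Optional[float] = None
    hexamer_min: Optional[float] = None
    psite_offset: int = quant.DEFAULT_PSITE_OFFSET
    pseudocount: float = scores.DEFAULT_RRS_PSEUDOCOUNT
    condition1: Optional[str] = None
    condition2: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("fpkm_min", "fc_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must lie in (0, 1]")
        if self.orf_score_rule not in ("p5_of_mORFs", "none"):
            raise ValueError(f"unknown orf_score_rule {self.orf_score_rule!r}")

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


SCREENABLE_CLASSES = ("mORF", "uORF", "dORF", "lncORF")


def build_catalog(
    transcripts: list[Transcript], config: ScreenConfig
) -> tuple[list[OrfRecord], pd.DataFrame]:
    """Catalog every transcript; screenable = non-overlapping classes with
    noncanonical coding length within [orf_min_nt, sorf_max_nt)."""
    records: list[OrfRecord] = []
    for t in transcripts:
        records.extend(
            catalog_transcript(
                t, min_nt=config.orf_min_nt, max_nt=config.sorf_max_nt - 3
            )
        )
    rows = []
    for o in records:
        rows.append(
            {
                "orf_id": o.orf_id,
                "transcript_id": o.transcript_id,
                "start": o.start,
                "end": o.end,
                "orf_class": o.orf_class,
                "coding_nt": o.coding_nt,
                "peptide_len_aa": o.peptide_len_aa,
                "utr3_start": o.utr3[0] if o.utr3 else pd.NA,
                "utr3_end": o.utr3[1] if o.utr3 else pd.NA,
                "screenable": o.orf_class in SCREENABLE_CLASSES,
                "flags": ",".join(sorted(o.flags)),
            }
        )
    df = pd.DataFrame(rows).sort_values(["transcript_id", "start"]).reset_index(drop=True)
    return records, df


def summarize_classes(catalog: pd.DataFrame, bin_aa: int = 30) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class count and length summary plus a peptide-length histogram."""
    rows = []
    hist_rows = []
    edges = None
    for cls in SCREENABLE_CLASSES:
        sub = catalog[catalog["orf_class"] == cls]
        rows.append(
            {
                "orf_class": cls,
                "count": len(sub),
                "mean_coding_nt": sub["coding_nt"].mean() if len(sub) else pd.NA,
                "median_coding_nt": sub["coding_nt"].median() if len(sub) else pd.NA,
            }
        )
        if edges is None:
            top = max(int(catalog["peptide_len_aa"].max()) + bin_aa, bin_aa) if len(catalog) else bin_aa
            edges = np.arange(0, top + bin_aa, bin_aa)
        h, _ = np.histogram(sub["peptide_len_aa"], bins=edges)
        for lo, n in zip(edges[:-1], h):
            hist_rows.append({"orf_class": cls, "aa_bin_lo": int(lo), "aa_bin_hi": int(lo + bin_aa), "count": int(n)})
    return pd.DataFrame(rows), pd.DataFrame(hist_rows)


def _hexamer_corpora(
    transcripts: list[Transcript], catalog: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Coding corpus: annotated mORF coding regions.  Noncoding corpus:
    lncRNA sequence outside any catalogued ORF."""
    coding = []
    noncoding = []
    orf_iv = catalog.groupby("transcript_id")[["start", "end"]]
    for t in transcripts:
        if t.biotype == "protein_coding":
            s, e = t.cds  # type: ignore[misc]
            coding.append(t.sequence[s : e - 3])
        else:
            mask = np.zeros(len(t), bool)
            if t.id in orf_iv.groups:
                for _, row in orf_iv.get_group(t.id).iterrows():
                    mask[row["start"] : row["end"]] = True
            seg = []
            for i, ch in enumerate(t.sequence):
                if mask[i]:
                    if len(seg) >= 6:
                        noncoding.append("".join(seg))
                    seg = []
                else:
                    seg.append(ch)
            if len(seg) >= 6:
                noncoding.append("".join(seg))
    return coding, noncoding


def run_screen(
    transcripts: list[Transcript],
    alignments: pd.DataFrame,
    libraries: pd.DataFrame,
    config: Optional[ScreenConfig] = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full screen; returns (per-ORF results, summary).

    The results table joins ORF record, score set, differential statistics
    and filter flags, one row per screenable ORF, ordered by
    (transcript_id, start).  The summary holds the ORF-score threshold, the
    filter attrition funnel over lncORFs, and any stage warnings.
    """
    config = config or ScreenConfig()
    config.validate()
    known = {t.id for t in transcripts}
    stray = set(alignments["transcript_id"]) - known
    if stray:
        raise ValueError(f"alignments reference unknown transcripts: {sorted(stray)[:5]}")

    records, catalog = build_catalog(transcripts, config)
    rec_by_id = {o.orf_id: o for o in records}
    screenable = catalog[catalog["screenable"]].copy()

    ribo_libs = libraries.loc[libraries["assay"] == "ribo", "library_id"].tolist()
    rna_libs = libraries.loc[libraries["assay"] == "rna", "library_id"].tolist()
    if not ribo_libs:
        raise ValueError("no Ribo-seq libraries in metadata")
    rrs_enabled = bool(rna_libs)
    stage_warnings = []
    if not rrs_enabled:
        msg = "no RNA-seq libraries: RRS stage disabled, final pass recomputed without it"
        warnings.warn(msg, stacklevel=2)
        stage_warnings.append(msg)

    lib_totals = quant.library_totals(alignments)
    q = quant.quantify_catalog(
        (rec_by_id[i] for i in screenable["orf_id"]),
        alignments,
        offset=config.psite_offset,
        lib_totals=lib_totals,
    )
    qr = q[q["assay"] == "ribo"]

    # ORF score on frame counts pooled over all Ribo libraries
    pooled = qr.groupby("orf_id")[["f0", "f1", "f2", "count_orf", "count_utr3"]].sum()
    orf_score_by_id, oflags = {}, {}
    for oid, row in pooled.iterrows():
        s, fl = scores.orf_score((row["f0"], row["f1"], row["f2"]))
        orf_score_by_id[oid] = s
        oflags[oid] = fl
    screenable["orf_score"] = screenable["orf_id"].map(orf_score_by_id)

    morf_scores = screenable.loc[screenable["orf_class"] == "mORF", "orf_score"]
    threshold = scores.orf_score_threshold(
        morf_scores, min_n=config.min_morf_calibration, q=config.orf_score_percentile
    )

    # RRS on pooled counts with the pseudocount applied in count space
    ribo_total = sum(lib_totals[(l, "ribo")] for l in ribo_libs)
    rna_total = sum(lib_totals.get((l, "rna"), 0) for l in rna_libs) if rrs_enabled else 0
    if rrs_enabled:
        qn = q[q["assay"] == "rna"].groupby("orf_id")[["count_orf", "count_utr3"]].sum()
    rrs_by_id = {}
    for _, row in screenable.iterrows():
        oid = row["orf_id"]
        rec = rec_by_id[oid]
        if not rrs_enabled or rec.utr3 is None:
            rrs_by_id[oid] = np.nan
            if rec.utr3 is None:
                oflags[oid] = oflags.get(oid, set()) | {"no_utr3"}
            continue
        val, fl = scores.rrs_from_counts(
            pooled.loc[oid, "count_orf"],
            pooled.loc[oid, "count_utr3"],
            qn.loc[oid, "count_orf"],
            qn.loc[oid, "count_utr3"],
            rec.coding_nt,
            rec.utr3[1] - rec.utr3[0],
            ribo_total,
            rna_total,
            pseudocount=config.pseudocount,
        )
        rrs_by_id[oid] = val if val is not None else np.nan
        oflags[oid] = oflags.get(oid, set()) | fl
    screenable["rrs"] = screenable["orf_id"].map(rrs_by_id)

    # sequence-only scores
    seq_by_tid = {t.id: t.sequence for t in transcripts}
    coding_corpus, noncoding_corpus = _hexamer_corpora(transcripts, catalog)
    hex_table = (
        scores.hexamer_train(coding_corpus, noncoding_corpus)
        if coding_corpus and noncoding_corpus
        else None
    )
    fick, hexa = [], []
    for _, row in screenable.iterrows():
        cds_seq = seq_by_tid[row["transcript_id"]][row["start"] : row["end"] - 3]
        fick.append(scores.fickett(cds_seq))
        if hex_table is not None:
            h, _fl = scores.hexamer_score(cds_seq, hex_table)
            hexa.append(h if h is not None else np.nan)
        else:
            hexa.append(np.nan)
    screenable["fickett"] = fick
    screenable["hexamer"] = hexa

    # group-mean Ribo FPKM and the expression gate
    lib_cond = libraries.set_index("library_id")["condition"]
    conds = sorted(lib_cond.loc[ribo_libs].unique())
    cond1 = config.condition1 or conds[0]
    cond2 = config.condition2 or (conds[1] if len(conds) > 1 else conds[0])
    fpkm_wide = qr.pivot_table(index="orf_id", columns="library_id", values="fpkm_orf")
    gm = {
        c: fpkm_wide[[l for l in ribo_libs if lib_cond[l] == c]].mean(axis=1)
        for c in (cond1, cond2)
    }
    screenable["mean_fpkm_cond1"] = screenable["orf_id"].map(gm[cond1])
    screenable["mean_fpkm_cond2"] = screenable["orf_id"].map(gm[cond2])

    # differential translation on Ribo counts
    count_mat = (
        qr.pivot_table(index="orf_id", columns="library_id", values="count_orf")
        .loc[screenable["orf_id"]]
    )
    if cond1 == cond2:
        raise ValueError("need two distinct conditions for the differential stage")
    diff = difftrans.differential_translation(
        count_mat, libraries[libraries["assay"] == "ribo"], cond1, cond2
    ).set_index("orf_id")
    screenable["log2fc"] = screenable["orf_id"].map(diff["log2fc"])
    screenable["pvalue"] = screenable["orf_id"].map(diff["pvalue"])
    screenable["fdr"] = screenable["orf_id"].map(diff["fdr"])

    # filter flags
    screenable["pass_fpkm"] = (
        screenable[["mean_fpkm_cond1", "mean_fpkm_cond2"]].max(axis=1) >= config.fpkm_min
    )
    screenable["pass_diff"] = (
        (screenable["log2fc"].abs() >= np.log2(config.fc_min))
        & (screenable["fdr"] < config.fdr_max)
    )
    if config.orf_score_rule == "none":
        screenable["pass_orfscore"] = True  # periodicity gate ablated
    else:
        screenable["pass_orfscore"] = screenable["orf_score"] >= threshold
    if rrs_enabled and config.rrs_min is not None:
        screenable["pass_rrs"] = screenable["rrs"] > config.rrs_min
        screenable.loc[screenable["rrs"].isna(), "pass_rrs"] = False
    else:
        screenable["pass_rrs"] = True
    opt = pd.Series(True, index=screenable.index)
    if config.fickett_min is not None:
        opt &= screenable["fickett"] >= config.fickett_min
    if config.hexamer_min is not None:
        opt &= screenable["hexamer"] >= config.hexamer_min
    screenable["pass_optional"] = opt
    screenable["pass"] = (
        screenable["pass_fpkm"]
        & screenable["pass_diff"]
        & screenable["pass_orfscore"]
        & screenable["pass_rrs"]
        & screenable["pass_optional"]
    )
    screenable["flags"] = screenable["orf_id"].map(
        lambda o: ",".join(sorted(oflags.get(o, set())))
    )
    screenable = screenable.sort_values(["transcript_id", "start"]).reset_index(drop=True)

    lnc = screenable[screenable["orf_class"] == "lncORF"]
    funnel = [("screenable_lncORFs", len(lnc))]
    mask = pd.Series(True, index=lnc.index)
    for name in ("pass_fpkm", "pass_diff", "pass_orfscore", "pass_rrs", "pass_optional"):
        mask &= lnc[name]
        funnel.append((name, int(mask.sum())))
    summary = {
        "orf_score_threshold": float(threshold),
        "n_morf_calibration": int((screenable["orf_class"] == "mORF").sum()),
        "conditions": (cond1, cond2),
        "funnel": funnel,
        "n_candidates": int(lnc["pass"].sum()),
        "rrs_enabled": rrs_enabled,
        "warnings": stage_warnings,
        "config": dataclasses.asdict(config),
    }
    return screenable, summary


def candidate_lncorfs(results: pd.DataFrame) -> pd.DataFrame:
    return results[(results["orf_class"] == "lncORF") & results["pass"]].reset_index(drop=True)


def evaluate_against_truth(results: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Sensitivity/specificity of the final pass over planted lncORFs."""
    t = truth[truth["orf_class"] == "lncORF"].set_index("orf_id")
    lnc = results[results["orf_class"] == "lncORF"]
    lnc = lnc[lnc["orf_id"].isin(t.index)]
    is_pos = t.loc[lnc["orf_id"], "translated"].to_numpy(dtype=bool)
    called = lnc["pass"].to_numpy(dtype=bool)
    tp = int((called & is_pos).sum())
    fn = int((~called & is_pos).sum())
    tn = int((~called & ~is_pos).sum())
    fp = int((called & ~is_pos).sum())
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def report(results: pd.DataFrame, summary: dict, outdir=None) -> str:
    """Human-readable summary; optionally writes the machine tables."""
    lines = ["riboscreen combined screen", "=" * 26, ""]
    c1, c2 = summary["conditions"]
    lines.append(f"conditions compared : {c2} vs {c1}")
    lines.append(f"mORF calibration    : n={summary['n_morf_calibration']}, "
                 f"ORF-score threshold (5th pct) = {summary['orf_score_threshold']:.4f}")
    if not summary["rrs_enabled"]:
        lines.append("NOTE: RRS stage disabled (no RNA-seq libraries)")
    lines.append("")
    lines.append("filter attrition (lncORFs):")
    for name, n in summary["funnel"]:
        lines.append(f"  {name:<22s} {n:6d}")
    lines.append("")
    cand = candidate_lncorfs(results)
    lines.append(f"candidate translated lncORFs: {len(cand)}")
    for _, row in cand.iterrows():
        lines.append(
            f"  {row['orf_id']:<28s} {row['peptide_len_aa']:4d} aa  "
            f"ORFscore={row['orf_score']:7.3f}  RRS={row['rrs']:6.3f}  "
            f"log2FC={row['log2fc']:6.2f}  FDR={row['fdr']:.2e}"
        )
    text = "\n".join(lines) + "\n"
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        results.to_csv(outdir / "screen_results.tsv", sep="\t", index=False)
        cand.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        (outdir / "summary.txt").write_text(text)
    return text
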