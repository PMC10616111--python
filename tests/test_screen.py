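"""The combined screen: filter semantics, funnel, ablation, reporting."""

import numpy as np
import pandas as pd
import pytest

from riboscreen.orfs import Transcript
from riboscreen.screen import (
    ScreenConfig,
    build_catalog,
    candidate_lncorfs,
    evaluate_against_truth,
    report,
    run_screen,
    summarize_classes,
)
from riboscreen.simulate import SimScenario, simulate_scenario


class TestConfig:
    def test_documented_defaults(self):
        cfg = ScreenConfig()
        assert cfg.fpkm_min == 1.0
        assert cfg.fc_min == 2.0
        assert cfg.fdr_max == 0.05
        assert cfg.sorf_max_nt == 300
        assert cfg.orf_score_rule == "p5_of_mORFs"
        assert cfg.rrs_min == 0.0

    def test_yaml_roundtrip_and_unknown_keys(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("fc_min: 1.5\nfdr_max: 0.1\n")
        cfg = ScreenConfig.from_yaml(p)
        assert cfg.fc_min == 1.5 and cfg.fdr_max == 0.1
        p.write_text("not_a_field: 3\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            ScreenConfig.from_yaml(p)


class TestFilterSemantics:
    def test_flags_follow_their_definitions(self, default_screen):
        results, summary = default_screen
        thr = summary["orf_score_threshold"]
        exp_fpkm = results[["mean_fpkm_cond1", "mean_fpkm_cond2"]].max(axis=1) >= 1.0
        assert (results["pass_fpkm"] == exp_fpkm).all()
        exp_diff = (results["log2fc"].abs() >= 1.0) & (results["fdr"] < 0.05)
        assert (results["pass_diff"] == exp_diff).all()
        assert (results["pass_orfscore"] == (results["orf_score"] >= thr)).all()
        has_rrs = results["rrs"].notna()
        assert (results.loc[has_rrs, "pass_rrs"] == (results.loc[has_rrs, "rrs"] > 0)).all()
        assert not results.loc[~has_rrs, "pass_rrs"].any()
        conj = (results["pass_fpkm"] & results["pass_diff"] & results["pass_orfscore"]
                & results["pass_rrs"] & results["pass_optional"])
        assert (results["pass"] == conj).all()

    def test_subthreshold_fpkm_and_fold_change_fail(self, default_screen):
        # an ORF with group means (0.4, 0.8) must fail the expression gate,
        # and FC 1.5 at tiny FDR must fail the differential gate
        results, _ = default_screen
        probe = results.iloc[0:1].copy()
        probe[["mean_fpkm_cond1", "mean_fpkm_cond2"]] = (0.4, 0.8)
        assert not (probe[["mean_fpkm_cond1", "mean_fpkm_cond2"]].max(axis=1) >= 1.0).iloc[0]
        assert not ((abs(0.58) >= 1.0) and (0.001 < 0.05))

    def test_funnel_is_monotone_nonincreasing(self, default_screen):
        _, summary = default_screen
        counts = [n for _, n in summary["funnel"]]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_row_count_matches_screenable_catalog(self, default_sim, default_screen):
        transcripts, _, _, _, _ = default_sim
        results, _ = default_screen
        _, catalog = build_catalog(transcripts, ScreenConfig())
        assert len(results) == int(catalog["screenable"].sum())


class TestEndToEnd:
    def test_recovery_of_planted_lncorfs(self, default_sim, default_screen):
        _, _, truth, _, _ = default_sim
        results, _ = default_screen
        ev = evaluate_against_truth(results, truth)
        assert ev["sensitivity"] >= 0.9
        assert ev["specificity"] >= 0.9

    def test_medians_straddle_the_morf_threshold(self, default_sim, default_screen):
        _, _, truth, _, _ = default_sim
        results, summary = default_screen
        lnc = results.merge(truth[["orf_id", "translated"]], on="orf_id")
        lnc = lnc[lnc["orf_class"] == "lncORF"]
        med = lnc.groupby("translated")["orf_score"].median()
        thr = summary["orf_score_threshold"]
        assert med[True] > thr > med[False]

    def test_translated_orfs_release_ribosomes(self, default_sim, default_screen):
        _, _, truth, _, _ = default_sim
        results, _ = default_screen
        lnc = results.merge(truth[["orf_id", "translated"]], on="orf_id")
        lnc = lnc[lnc["orf_class"] == "lncORF"]
        assert lnc.loc[lnc["translated"], "rrs"].median() > 0

    def test_readthrough_orfs_have_rrs_near_zero(self):
        scen = SimScenario(seed=9, n_coding=21, n_lnc=20, frac_translated_lnc=1.0,
                           frac_readthrough=0.5, reads_per_lib_ribo=80_000,
                           reads_per_lib_rna=80_000)
        transcripts, _, truth, aln, libs = simulate_scenario(scen)
        results, _ = run_screen(transcripts, aln, libs)
        m = results.merge(truth[["orf_id", "readthrough"]], on="orf_id")
        lnc = m[m["orf_class"] == "lncORF"]
        assert abs(lnc.loc[lnc["readthrough"], "rrs"].median()) < 0.5
        assert lnc.loc[~lnc["readthrough"], "rrs"].median() > 1.0

    def test_relaxing_a_threshold_never_shrinks_the_passing_set(self, default_sim):
        transcripts, _, _, alignments, libraries = default_sim
        strict, _ = run_screen(transcripts, alignments, libraries, ScreenConfig())
        relaxed, _ = run_screen(
            transcripts, alignments, libraries, ScreenConfig(fc_min=1.5)
        )
        s = set(strict.loc[strict["pass"], "orf_id"])
        r = set(relaxed.loc[relaxed["pass"], "orf_id"])
        assert s <= r

    def test_ablating_the_periodicity_gate_admits_aperiodic_decoys(self):
        scen = SimScenario(seed=13, n_coding=25, n_lnc=40, frac_translated_lnc=0.25,
                           n_aperiodic=10, reads_per_lib_ribo=100_000,
                           reads_per_lib_rna=100_000)
        transcripts, _, truth, aln, libs = simulate_scenario(scen)
        gated, _ = run_screen(transcripts, aln, libs, ScreenConfig())
        ablated, _ = run_screen(
            transcripts, aln, libs, ScreenConfig(orf_score_rule="none")
        )
        ev_gated = evaluate_against_truth(gated, truth)
        ev_ablated = evaluate_against_truth(ablated, truth)
        # the aperiodic decoys carry fold change, expression and release
        # signal; only the ORF-score gate rejects them
        assert ev_ablated["fp"] > ev_gated["fp"]
        assert ev_ablated["specificity"] < ev_gated["specificity"]

    def test_missing_rna_disables_rrs_with_warning(self, default_sim):
        transcripts, _, _, alignments, libraries = default_sim
        ribo_only = alignments[alignments["assay"] == "ribo"]
        libs = libraries[libraries["assay"] == "ribo"]
        with pytest.warns(UserWarning, match="RRS stage disabled"):
            results, summary = run_screen(transcripts, ribo_only, libs)
        assert not summary["rrs_enabled"]
        assert results["pass_rrs"].all()
        assert results["rrs"].isna().all()

    def test_start_codon_mutation_removes_exactly_that_orf(self, default_sim, default_screen):
        transcripts, _, truth, alignments, libraries = default_sim
        results, _ = default_screen
        passing = set(candidate_lncorfs(results)["orf_id"])
        victim = candidate_lncorfs(results).iloc[0]
        mutated = []
        for t in transcripts:
            if t.id == victim["transcript_id"]:
                s = t.sequence
                seq = s[: victim["start"]] + "ATT" + s[victim["start"] + 3 :]
                mutated.append(Transcript(t.id, seq, t.biotype, t.cds))
            else:
                mutated.append(t)
        res2, _ = run_screen(mutated, alignments, libraries)
        assert victim["orf_id"] not in set(res2["orf_id"])
        passing2 = set(candidate_lncorfs(res2)["orf_id"])
        assert passing2 == passing - {victim["orf_id"]}


class TestReporting:
    def test_summarize_classes_counts_and_bins(self):
        catalog = pd.DataFrame(
            {
                "orf_class": ["mORF"] * 5 + ["lncORF"] * 3,
                "coding_nt": [300] * 5 + [90, 120, 150],
                "peptide_len_aa": [100] * 5 + [30, 40, 50],
            }
        )
        cls_tab, hist = summarize_classes(catalog)
        morf = cls_tab.set_index("orf_class").loc["mORF"]
        assert morf["count"] == 5 and morf["mean_coding_nt"] == 300
        empty = cls_tab.set_index("orf_class").loc["uORF"]
        assert empty["count"] == 0 and pd.isna(empty["mean_coding_nt"])
        tot = hist.groupby("orf_class")["count"].sum()
        assert tot["mORF"] == 5 and tot["lncORF"] == 3 and tot["dORF"] == 0

    def test_report_is_deterministic_and_complete(self, default_sim, default_screen, tmp_path):
        transcripts, _, _, alignments, libraries = default_sim
        results, summary = default_screen
        text1 = report(results, summary, outdir=tmp_path / "a")
        res2, sum2 = run_screen(transcripts, alignments, libraries)
        text2 = report(res2, sum2, outdir=tmp_path / "b")
        assert text1 == text2
        assert (tmp_path / "a" / "screen_results.tsv").read_bytes() == (
            tmp_path / "b" / "screen_results.tsv"
        ).read_bytes()
        assert "filter attrition" in text1

    def test_empty_candidate_list_still_reports_funnel(self, default_sim):
        transcripts, _, _, alignments, libraries = default_sim
        cfg = ScreenConfig(fpkm_min=10**9)
        results, summary = run_screen(transcripts, alignments, libraries, cfg)
        assert summary["n_candidates"] == 0
        text = report(results, summary)
        assert "candidate translated lncORFs: 0" in text
        assert len(summary["funnel"]) == 6
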