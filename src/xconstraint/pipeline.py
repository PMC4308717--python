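"""End-to-end driver: simulate the two-species panels, run every analysis
stage, and write deterministic TSV/JSON outputs.

The pipeline is a pure function of (config, seed): stage seeds are spawned
from one root seed and every file is written with a fixed numeric format, so
two runs with the same seed are bit-identical.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression, genome_signal, isoform_variance, reproducibility, splicing
from .io_core import ExpressionMatrix, write_matrix
from .simulate import (SPECIES, SimConfig, simulate_bin_pairs, simulate_expression,
                       simulate_isoforms, simulate_junctions, simulate_mark_tracks,
                       simulate_replicates)


def _stage_seeds(seed: int, n: int = 12) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_expression_stage(cfg: SimConfig, seeds: list[int], outdir: Path) -> dict:
    m1, m2, orth, truth = simulate_expression(cfg, seeds[0])
    filtered = {}
    for mat, s in ((m1, seeds[1]), (m2, seeds[2])):
        reps = simulate_replicates(mat, cfg.replicate_noise_sd, cfg.dropout_midpoint,
                                   cfg.dropout_slope, s)
        filtered[mat.species] = reproducibility.filter_reproducible(reps)
    f1, f2 = filtered[SPECIES[0]], filtered[SPECIES[1]]
    write_matrix(f1.values, outdir / "expression_filtered_sp1.tsv")
    write_matrix(f2.values, outdir / "expression_filtered_sp2.tsv")

    dnr = expression.compute_dnr(f1, f2, orth)
    fit = expression.fit_dnr_mixture(dnr["dnr"], seed=seeds[3])
    calls = expression.classify_constraint(dnr, fit.threshold)
    calls.index = dnr["id1"].to_numpy()

    truth_class = truth.genes.set_index("gene_1")["class"]
    defined = calls[calls != "undefined"]
    accuracy = float((defined == truth_class.reindex(defined.index)).mean())

    avg1 = expression.average_log_expression(f1)
    avg2 = expression.average_log_expression(f2)
    avg2_on1 = pd.Series(avg2.reindex(orth.pairs["id2"]).to_numpy(),
                         index=orth.pairs["id1"].to_numpy())
    matched_c, matched_u = expression.match_by_expression(
        calls, avg1, avg2_on1, bins=10, seed=seeds[4])

    lengths1 = truth.genes.set_index("gene_1")["exonic_length"].astype(float)
    lengths2 = truth.genes.set_index("gene_2")["exonic_length"].astype(float)
    constrained_ids1 = list(calls.index[calls == "constrained"])
    constrained_ids2 = list(orth.pairs.set_index("id1").loc[constrained_ids1, "id2"])
    outf1 = expression.output_fraction(f1, lengths1, constrained_ids1)
    outf2 = expression.output_fraction(f2, lengths2, constrained_ids2)

    log1 = np.log10(f1.values.where(f1.values > 0, expression.ZERO_REPLACEMENT))
    anova = expression.anova_decomposition(log1)
    breadth = expression.expression_breadth(f1)

    cc_con = expression.cross_species_corr(avg1, avg2_on1, matched_c)
    cc_unc = expression.cross_species_corr(avg1, avg2_on1, matched_u)

    out = dnr.copy()
    out["class"] = calls.to_numpy()
    out["dnr_true"] = truth.dnr_true.reindex(out["id1"]).to_numpy()
    out["class_true"] = truth_class.reindex(out["id1"]).to_numpy()
    out.to_csv(outdir / "dnr_classification.tsv", sep="\t", index=False,
               float_format="%.6g")
    pd.DataFrame({"sample": outf1.index, "fraction": outf1.to_numpy()}).to_csv(
        outdir / "output_fraction_sp1.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame({"sample": outf2.index, "fraction": outf2.to_numpy()}).to_csv(
        outdir / "output_fraction_sp2.tsv", sep="\t", index=False, float_format="%.6g")

    summary = {
        "n_orthologues": int(len(orth)),
        "n_dnr_defined": int((calls != "undefined").sum()),
        "n_constrained": int((calls == "constrained").sum()),
        "n_unconstrained": int((calls == "unconstrained").sum()),
        "constrained_fraction_of_defined": float(
            (calls == "constrained").sum() / max((calls != "undefined").sum(), 1)),
        "mixture_threshold": float(fit.threshold),
        "mixture_mu1": float(fit.mu1), "mixture_mu2": float(fit.mu2),
        "classification_accuracy": accuracy,
        "matched_set_size": len(matched_c),
        "output_fraction_sp1_mean": float(outf1.mean()),
        "output_fraction_sp2_mean": float(outf2.mean()),
        "anova_gene_fraction": anova["gene"],
        "anova_sample_fraction": anova["sample"],
        "anova_residual_fraction": anova["residual"],
        "breadth_mean_constrained": float(
            breadth.reindex(constrained_ids1).mean()),
        "breadth_mean_unconstrained": float(
            breadth.reindex(calls.index[calls == "unconstrained"]).mean()),
        "cross_species_cc_constrained": cc_con,
        "cross_species_cc_unconstrained": cc_unc,
    }
    _write_json(summary, outdir / "expression_summary.json")
    return summary


def run_splicing_stage(cfg: SimConfig, seeds: list[int], outdir: Path) -> dict:
    jt1, b1, jt2, b2, orth, truth = simulate_junctions(cfg, seeds[5])
    prof1 = splicing.compute_psi(jt1)
    prof2 = splicing.compute_psi(jt2)
    theta1 = splicing.compute_theta(jt1, b1)

    # pool both species per orthologous junction under the species-1 id
    id_map = dict(zip(orth.pairs["id2"], orth.pairs["id1"]))
    prof2m = prof2.copy()
    prof2m["junction"] = prof2m["junction"].map(id_map)
    prof2m = prof2m.dropna(subset=["junction"])
    pooled = pd.concat([prof1[prof1["junction"].isin(id_map.values())], prof2m],
                       ignore_index=True)
    species_of_sample = {s: ("sp1" if str(s).startswith(SPECIES[0][:1]) else "sp2")
                         for s in pooled["sample"].unique()}
    classified = splicing.classify_junctions(pooled, species_of_sample)
    flagged = splicing.constrained_junctions(classified)

    tclass = truth.junctions.set_index("id1")["class"]
    joined = flagged.join(tclass.rename("class_true"), how="inner")
    con = joined["class_true"] == "constrained_intermediate"
    var = joined["class_true"] == "variable"
    detection = float(joined.loc[con, "constrained_intermediate"].mean())
    false_flag = float(joined.loc[var, "constrained_intermediate"].mean())
    class_agree = {
        lab: float((joined.loc[joined["class_true"] == lab, "class"] == lab).mean())
        for lab in ("constitutive_high", "constitutive_low")}

    cc_mean, cc_sd = splicing.ortho_junction_concordance(prof1, prof2, orth)
    joined.reset_index(names="junction").to_csv(
        outdir / "junction_summary.tsv", sep="\t", index=False, float_format="%.6g")
    mean_theta = float(theta1["theta"].mean(skipna=True))
    summary = {
        "n_junctions": int(len(truth.junctions)),
        "constrained_junction_detection": detection,
        "variable_false_flag": false_flag,
        "constitutive_high_recovery": class_agree["constitutive_high"],
        "constitutive_low_recovery": class_agree["constitutive_low"],
        "psi_concordance_cc": cc_mean,
        "psi_sd_concordance_cc": cc_sd,
        "mean_theta": mean_theta,
    }
    _write_json(summary, outdir / "splicing_summary.json")
    return summary


def run_isoform_stage(cfg: SimConfig, seeds: list[int], outdir: Path) -> dict:
    mats, regimes = simulate_isoforms(cfg, seeds[6])
    cohort = isoform_variance.vls_cohort(mats, regimes, B=100, seed=seeds[7])
    cohort.to_csv(outdir / "vls_cohort.tsv", sep="\t", index=False, float_format="%.6g")
    by = cohort.set_index("class")["mean_ratio"]
    summary = {
        "vls_mean_expression_driven": float(by.get("expression_driven", np.nan)),
        "vls_mean_splicing_driven": float(by.get("splicing_driven", np.nan)),
        "vls_class_separation": float(by.get("expression_driven", np.nan)
                                      - by.get("splicing_driven", np.nan)),
        "vls_wilcoxon_p": float(cohort.attrs["wilcoxon_p"]),
    }
    _write_json(summary, outdir / "isoform_summary.json")
    return summary


def run_signal_stage(cfg: SimConfig, seeds: list[int], outdir: Path) -> dict:
    bins, bin_truth = simulate_bin_pairs(cfg, seeds[8])
    corr = genome_signal.binpair_correlation(bins)
    corr.by_class.to_csv(outdir / "binpair_cc_by_class.tsv", sep="\t", index=False,
                         float_format="%.6g")

    (genes1, cov1), (genes2, cov2), orth, mtruth = simulate_mark_tracks(cfg, seeds[9])
    w1 = genome_signal.gene_windows(cov1, genes1, anchor="TSS")
    w2 = genome_signal.gene_windows(cov2, genes2, anchor="TSS")
    div = genome_signal.mark_divergence(w1.mean(axis=1), w2.mean(axis=1), orth)
    classes = pd.Series(np.where(mtruth["shared"], "shared", "independent"),
                        index=mtruth["id1"])
    test = genome_signal.divergence_class_test(div, classes)

    shared_ids = mtruth.loc[mtruth["shared"], "id1"]
    prof = genome_signal.metagene_profile([cov1], genes1, "TSS", shared_ids,
                                          mark="mark", group="shared")
    prof.as_frame().to_csv(outdir / "metagene_shared.tsv", sep="\t", index=False,
                           float_format="%.6g")
    summary = {
        "binpair_cc": float(corr.cc),
        "binpair_cc_exonic": float(corr.by_class.set_index("stratum").loc["exonic", "cc"])
        if "exonic" in set(corr.by_class["stratum"]) else float("nan"),
        "mark_divergence_median_shared": test["median_shared"],
        "mark_divergence_median_independent": test["median_independent"],
        "mark_divergence_p": test["pvalue"],
    }
    _write_json(summary, outdir / "signal_summary.json")
    return summary


def run_pipeline(outdir, seed: int, cfg: SimConfig | None = None) -> dict:
    """Run every stage on the default synthetic panels; returns the combined
    summary (also written as ``summary.json``)."""
    cfg = cfg or SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed)
    summary: dict = {"seed": int(seed)}
    summary.update(run_expression_stage(cfg, seeds, outdir))
    summary.update(run_splicing_stage(cfg, seeds, outdir))
    summary.update(run_isoform_stage(cfg, seeds, outdir))
    summary.update(run_signal_stage(cfg, seeds, outdir))
    _write_json(summary, outdir / "summary.json")
    return summary
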