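#!/usr/bin/env python
"""Materialize the synthetic two-species input panels in standard formats.

Writes, under results/data/: replicate-level expression matrices (TSV),
the gene orthology table, splice-junction and boundary count tables,
the transcript-isoform abundance table, strand-agnostic coverage tracks
(bedGraph) for the chromatin marks, the orthologous bin-pair table and the
generator truth tables.  Everything is a pure function of --seed, so the
downstream scripts (which re-derive the same panels internally) analyse
exactly these data.
"""
import argparse
from pathlib import Path

import pandas as pd

from xconstraint.io_core import write_annotation, write_bedgraph, write_boundaries, \
    write_junctions, write_matrix, write_orthology
from xconstraint.pipeline import _stage_seeds
from xconstraint.simulate import (SimConfig, coverage_to_bedgraph, simulate_bin_pairs,
                                  simulate_expression, simulate_isoforms,
                                  simulate_junctions, simulate_mark_tracks,
                                  simulate_replicates)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig()
    seeds = _stage_seeds(args.seed)

    m1, m2, orth, truth = simulate_expression(cfg, seeds[0])
    for mat, s, tag in ((m1, seeds[1], "sp1"), (m2, seeds[2], "sp2")):
        reps = simulate_replicates(mat, cfg.replicate_noise_sd, cfg.dropout_midpoint,
                                   cfg.dropout_slope, s)
        write_matrix(reps.values, out / f"expression_replicates_{tag}.tsv")
    write_orthology(orth, out / "gene_orthology.tsv")
    truth.genes.to_csv(out / "gene_truth.tsv", sep="\t", index=False,
                       float_format="%.6g")
    print(f"expression panel: {cfg.n_genes} orthologues x {cfg.n_samples} biosamples "
          f"x 2 replicates per species")

    jt1, b1, jt2, b2, jorth, jtruth = simulate_junctions(cfg, seeds[5])
    write_junctions(jt1, out / "junctions_sp1.tsv")
    write_junctions(jt2, out / "junctions_sp2.tsv")
    write_boundaries(b1, out / "boundaries_sp1.tsv")
    write_boundaries(b2, out / "boundaries_sp2.tsv")
    write_orthology(jorth, out / "junction_orthology.tsv")
    jtruth.junctions.to_csv(out / "junction_truth.tsv", sep="\t", index=False,
                            float_format="%.6g")
    print(f"junction panel: {cfg.n_junctions} orthologous junctions, "
          f"{cfg.n_junction_samples} samples per species, depth ~{cfg.junction_depth:g}")

    mats, regimes = simulate_isoforms(cfg, seeds[6])
    rows = []
    for gene, ab in mats.items():
        for t in range(ab.shape[1]):
            row = {"transcript_id": f"{gene}.t{t}", "gene_id": gene}
            row.update({f"s{j}": ab[j, t] for j in range(ab.shape[0])})
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "isoform_abundances.tsv", sep="\t", index=False,
                              float_format="%.6g")
    regimes.rename_axis("gene_id").reset_index().to_csv(
        out / "isoform_truth.tsv", sep="\t", index=False)
    print(f"isoform panel: {cfg.n_isoform_genes} genes, "
          f"{cfg.n_isoform_samples} samples")

    bins, _ = simulate_bin_pairs(cfg, seeds[8])
    bins.to_csv(out / "bin_pairs.tsv", sep="\t", index=False, float_format="%.6g")
    (g1, c1), (g2, c2), morth, mtruth = simulate_mark_tracks(cfg, seeds[9])
    write_bedgraph(coverage_to_bedgraph(c1), out / "mark_sp1.bedgraph")
    write_bedgraph(coverage_to_bedgraph(c2), out / "mark_sp2.bedgraph")
    write_annotation(g1, out / "mark_genes_sp1.gtf")
    write_annotation(g2, out / "mark_genes_sp2.gtf")
    mtruth.to_csv(out / "mark_truth.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"signal panels: {cfg.n_bins} orthologous 100-nt bins; "
          f"{cfg.n_mark_genes} TSS mark profiles per species")
    print(f"wrote inputs to {out}")


if __name__ == "__main__":
    main()
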