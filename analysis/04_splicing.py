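#!/usr/bin/env python
"""Constrained splicing: intron-centric metrics over the junction panel.

Quantifies per-junction inclusion (psi) and completeness of splicing (theta),
classifies junctions as constitutive high/low or variable across all samples
of both species, flags variable junctions whose inclusion variance stays
under 20% of the Bernoulli maximum at intermediate mean inclusion, and
measures cross-species concordance of junction usage.
"""
import argparse
from pathlib import Path

from xconstraint.pipeline import _stage_seeds, run_splicing_stage
from xconstraint.simulate import SimConfig


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    s = run_splicing_stage(SimConfig(), _stage_seeds(args.seed), args.outdir)
    print(f"junction panel: {s['n_junctions']} orthologous junctions")
    print(f"constitutive recovery: high {s['constitutive_high_recovery']:.1%}, "
          f"low {s['constitutive_low_recovery']:.1%} "
          f"(all-samples rules are strict at finite depth)")
    print(f"inclusion-constrained detection: {s['constrained_junction_detection']:.1%} "
          f"of truly constrained junctions flagged; "
          f"{s['variable_false_flag']:.2%} false flags among variable junctions")
    print(f"cross-species concordance: cc(logit mean psi) = {s['psi_concordance_cc']:.2f}, "
          f"cc(sd psi) = {s['psi_sd_concordance_cc']:.2f}")
    print(f"mean completeness of splicing (theta): {s['mean_theta']:.3f}")


if __name__ == "__main__":
    main()
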