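"""Variance decomposition of transcript abundances: expression vs splicing.

Each sample of a gene is a point in R^T whose coordinates are transcript
abundances.  Under constant splicing (fixed isoform proportions, varying
total expression) the points lie on a ray through the origin.  The Vls/Vt
ratio is the fraction of the total variance captured after projecting the
(square-root rescaled) points onto that ray: 1 means purely expression-driven
variation, 0 means purely splicing-driven.  Two robustness refinements:
square-root rescaling of abundances tempers extreme major isoforms, and a
bootstrap over samples (median of resample ratios) mitigates outlier samples.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_B = 100


@dataclass
class VlsResult:
    ratio: float              # plain (non-bootstrap) ratio
    bootstrap_median: float
    bootstrap_iqr: float
    B: int
    seed: int


def vls_ratio(abundances: np.ndarray) -> float:
    """Fraction of transcript-abundance variance explained by gene expression.

    ``abundances`` is S samples x T transcripts, non-negative RPKM.  The
    constant-splicing ray direction u is the normalized mean of per-sample
    unit direction vectors of Y = sqrt(abundances) (all-zero samples are
    excluded from u but retained in the variances).  Vls is the variance of
    the projections Y_s . u, Vt the total variance of Y_s about the centroid;
    the ratio is clipped to [0, 1].  Single-transcript genes are 1 by
    convention; so is degenerate data with zero total variance.
    """
    Y = np.sqrt(np.asarray(abundances, dtype=float))
    if np.isnan(Y).any():
        raise ValueError("NaN abundances")
    S, T = Y.shape
    if S < 3:
        raise ValueError("need at least 3 samples")
    if T == 1:
        return 1.0
    norms = np.linalg.norm(Y, axis=1)
    nz = norms > 0
    if not nz.any():
        return float("nan")
    if nz.sum() < 3:
        raise ValueError("need at least 3 non-zero samples")
    u = (Y[nz] / norms[nz, None]).mean(axis=0)
    u = u / np.linalg.norm(u)
    proj = Y @ u
    vt = float(((Y - Y.mean(axis=0)) ** 2).sum() / (S - 1))
    if vt == 0:
        return 1.0
    vls = float(((proj - proj.mean()) ** 2).sum() / (S - 1))
    return float(np.clip(vls / vt, 0.0, 1.0))


def vls_bootstrap(abundances: np.ndarray, B: int = DEFAULT_B,
                  seed: int = 0) -> VlsResult:
    """Outlier-robust Vls/Vt: median (and IQR) over B sample bootstraps.

    Resamples with fewer than 3 distinct samples or zero total variance are
    redrawn (up to 10*B attempts); if no valid resample can be formed the
    plain ratio is reported with a warning.
    """
    Y = np.asarray(abundances, dtype=float)
    S = Y.shape[0]
    plain = vls_ratio(Y)
    rng = np.random.default_rng(seed)
    ratios: list[float] = []
    attempts = 0
    while len(ratios) < B and attempts < 10 * B:
        attempts += 1
        idx = rng.integers(0, S, size=S)
        if len(np.unique(idx)) < 3:
            continue
        sub = Y[idx]
        Ysub = np.sqrt(sub)
        if ((Ysub - Ysub.mean(axis=0)) ** 2).sum() == 0 and sub.shape[1] > 1:
            continue
        ratios.append(vls_ratio(sub))
    if not ratios:
        log.warning("bootstrap produced no valid resample; falling back to plain ratio")
        return VlsResult(ratio=plain, bootstrap_median=plain, bootstrap_iqr=0.0,
                         B=0, seed=seed)
    arr = np.array(ratios)
    return VlsResult(ratio=plain,
                     bootstrap_median=float(np.median(arr)),
                     bootstrap_iqr=float(np.percentile(arr, 75) - np.percentile(arr, 25)),
                     B=len(ratios), seed=seed)


def vls_cohort(matrices: dict[str, np.ndarray], calls: pd.Series,
               B: int = DEFAULT_B, seed: int = 0) -> pd.DataFrame:
    """Mean bootstrap Vls/Vt per gene class, with a rank-sum test between
    the two largest classes.

    ``calls`` maps gene id -> class label (e.g. constrained/unconstrained).
    Returns one row per class (mean ratio, n) and attaches the Wilcoxon
    rank-sum p-value as ``df.attrs['wilcoxon_p']``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    per_class: dict[str, list[float]] = {}
    for gene, ab in matrices.items():
        if gene not in calls.index:
            continue
        cls = calls.loc[gene]
        res = vls_bootstrap(ab, B=B, seed=int(rng.integers(0, 2**31 - 1)))
        per_class.setdefault(cls, []).append(res.bootstrap_median)
    for cls, vals in sorted(per_class.items()):
        rows.append({"class": cls, "mean_ratio": float(np.mean(vals)), "n": len(vals)})
    out = pd.DataFrame(rows)
    classes = sorted(per_class, key=lambda c: -len(per_class[c]))[:2]
    if len(classes) == 2 and all(len(per_class[c]) >= 2 for c in classes):
        p = float(stats.ranksums(per_class[classes[0]], per_class[classes[1]]).pvalue)
    else:
        p = float("nan")
    out.attrs["wilcoxon_p"] = p
    return out


def isoform_matrix_from_table(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Split a transcript TSV (transcript_id, gene_id, sample columns...) into
    per-gene S x T abundance arrays."""
    sample_cols = [c for c in table.columns if c not in ("transcript_id", "gene_id")]
    out = {}
    for gene, sub in table.groupby("gene_id", sort=True):
        out[gene] = sub[sample_cols].to_numpy(float).T  # samples x transcripts
    return out
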