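"""Evolutionarily constrained gene expression: the dynamic-range analysis.

The dynamic range (DNR) of a one-to-one orthologue is the log10 ratio between
its highest and lowest non-zero abundance across every sample of both
species; it is only defined when the gene is detected in at least two samples
of each species.  Across orthologues the DNR distribution is bimodal and is
decomposed into two Gaussians; the intersection point of the weighted
component densities separates genes with constrained expression (DNR at or
below the threshold, i.e. expression varying less than ~two orders of
magnitude across tissues and species) from unconstrained genes.

The module also carries the companion statistics of that analysis:
expression-matched control sets, the fraction of transcriptional output from
constrained genes, a two-factor ANOVA variance decomposition, expression
breadth, cross-species correlation of average expression, the
antisense-to-total transcription ratio and nuclear/cytosolic localization
variability.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from .io_core import ExpressionMatrix, OrthologyMap

log = logging.getLogger(__name__)

ZERO_REPLACEMENT = 1e-3  # effective RPKM substituted for zeros before logs
VARIANCE_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# DNR
# ---------------------------------------------------------------------------

def compute_dnr(m1: ExpressionMatrix, m2: ExpressionMatrix,
                orth: OrthologyMap) -> pd.DataFrame:
    """Dynamic range per orthologue pair.

    Pools non-zero values across all samples of both species (matrices are
    expected to be npIDR-filtered already, so zeros mean reproducibly
    undetected).  DNR = log10(max/min); NaN when fewer than two non-zero
    values in either species.  Orthology ids missing from a matrix leave the
    pair undefined with a warning.
    """
    v1 = m1.values
    v2 = m2.values
    id1 = orth.pairs["id1"].to_numpy()
    id2 = orth.pairs["id2"].to_numpy()

    present1 = np.isin(id1, v1.index)
    present2 = np.isin(id2, v2.index)
    n_missing = int((~present1).sum() + (~present2).sum())
    if n_missing:
        log.warning("%d orthology ids missing from the matrices; DNR undefined", n_missing)

    a1 = np.full((len(id1), v1.shape[1]), np.nan)
    a2 = np.full((len(id2), v2.shape[1]), np.nan)
    a1[present1] = v1.reindex(id1[present1]).to_numpy(float)
    a2[present2] = v2.reindex(id2[present2]).to_numpy(float)

    def nz_stats(a):
        pos = np.where(np.nan_to_num(a, nan=0.0) > 0, a, np.nan)
        n = np.sum(~np.isnan(pos), axis=1)
        mx = np.nanmax(np.where(np.isnan(pos), -np.inf, pos), axis=1)
        mn = np.nanmin(np.where(np.isnan(pos), np.inf, pos), axis=1)
        return n, mx, mn

    n1, mx1, mn1 = nz_stats(a1)
    n2, mx2, mn2 = nz_stats(a2)
    defined = (n1 >= 2) & (n2 >= 2)
    mx = np.maximum(mx1, mx2)
    mn = np.minimum(mn1, mn2)
    dnr = np.where(defined, np.log10(np.where(defined, mx, 1.0))
                   - np.log10(np.where(defined, mn, 1.0)), np.nan)
    return pd.DataFrame({
        "id1": id1, "id2": id2,
        "dnr": dnr,
        "max_rpkm": np.where(defined, mx, np.nan),
        "min_rpkm": np.where(defined, mn, np.nan),
        "n_expressed_1": n1.astype(int),
        "n_expressed_2": n2.astype(int),
    })


# ---------------------------------------------------------------------------
# two-Gaussian mixture and intersection threshold
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    w1: float
    w2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    threshold: float
    loglik: float
    n_iter: int


def _weighted_logdiff(x, w1, mu1, s1, w2, mu2, s2):
    return (math.log(w1) - math.log(s1) - 0.5 * ((x - mu1) / s1) ** 2
            - math.log(w2) + math.log(s2) + 0.5 * ((x - mu2) / s2) ** 2)


def mixture_intersection(w1, mu1, sigma1, w2, mu2, sigma2,
                         tol: float = 1e-6) -> float:
    """Root of w1*N(x; mu1, s1^2) = w2*N(x; mu2, s2^2) inside (mu1, mu2).

    The equality is a quadratic in x; the root between the means is refined
    by bisection/Brent to ``tol``.  Raises (reporting both analytic roots)
    when no root lies between the means.
    """
    if mu1 > mu2:
        (w1, mu1, sigma1), (w2, mu2, sigma2) = (w2, mu2, sigma2), (w1, mu1, sigma1)
    a = 0.5 * (1 / sigma1**2 - 1 / sigma2**2)
    b = mu2 / sigma2**2 - mu1 / sigma1**2
    c = (0.5 * (mu1**2 / sigma1**2 - mu2**2 / sigma2**2)
         + math.log(w1 / sigma1) - math.log(w2 / sigma2))
    if abs(a) < 1e-15:
        roots = [-c / b] if abs(b) > 1e-15 else []
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            roots = []
        else:
            roots = [(-b - math.sqrt(disc)) / (2 * a), (-b + math.sqrt(disc)) / (2 * a)]
    inside = [r for r in roots if mu1 < r < mu2]
    if not inside:
        raise ValueError(
            f"no density intersection in ({mu1:.4g}, {mu2:.4g}); analytic roots: {roots}")
    root = inside[0]
    # refine with Brent on the log-density difference around the analytic root
    f = lambda x: _weighted_logdiff(x, w1, mu1, sigma1, w2, mu2, sigma2)
    lo, hi = max(mu1, root - 10 * tol), min(mu2, root + 10 * tol)
    span = 0.1 * (mu2 - mu1)
    lo, hi = max(mu1 + 1e-12, root - span), min(mu2 - 1e-12, root + span)
    try:
        if f(lo) * f(hi) < 0:
            root = optimize.brentq(f, lo, hi, xtol=tol)
    except ValueError:
        pass
    return float(root)


def fit_dnr_mixture(dnr_values, seed: int = 0, tol: float = 1e-4,
                    max_iter: int = 500) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture to the DNR distribution.

    k-means++ initialization with 10 restarts (seeded, deterministic) and a
    variance floor of 1e-4; components are ordered mu1 < mu2 and the
    classification threshold is the intersection of the weighted densities
    between the means.
    """
    x = np.asarray(dnr_values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 50:
        raise ValueError(f"need >= 50 defined DNR values, got {len(x)}")
    gm = GaussianMixture(n_components=2, covariance_type="full",
                         reg_covar=VARIANCE_FLOOR, tol=tol, max_iter=max_iter,
                         n_init=10, init_params="k-means++",
                         random_state=int(seed))
    gm.fit(x.reshape(-1, 1))
    mus = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.reshape(-1))
    ws = gm.weights_.ravel()
    order = np.argsort(mus)
    mu1, mu2 = mus[order]
    s1, s2 = sigmas[order]
    w1, w2 = ws[order]
    if s1 <= math.sqrt(VARIANCE_FLOOR) * 1e-2 or s2 <= math.sqrt(VARIANCE_FLOOR) * 1e-2:
        raise ValueError("degenerate EM solution (sigma -> 0); raise the variance floor")
    thr = mixture_intersection(w1, mu1, s1, w2, mu2, s2, tol=1e-6)
    return MixtureFit(w1=float(w1), w2=float(w2), mu1=float(mu1), mu2=float(mu2),
                      sigma1=float(s1), sigma2=float(s2), threshold=thr,
                      loglik=float(gm.score(x.reshape(-1, 1)) * len(x)),
                      n_iter=int(gm.n_iter_))


def classify_constraint(dnr_table: pd.DataFrame, threshold: float) -> pd.Series:
    """Three-way call per orthologue: constrained (DNR <= threshold),
    unconstrained, or undefined (no DNR)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dnr = dnr_table["dnr"]
    call = np.where(dnr.isna(), "undefined",
                    np.where(dnr <= threshold, "constrained", "unconstrained"))
    return pd.Series(call, index=dnr_table.index, name="class")


# ---------------------------------------------------------------------------
# matched control sets
# ---------------------------------------------------------------------------

def match_by_expression(calls: pd.Series, avg_expr_sp1: pd.Series,
                        avg_expr_sp2: pd.Series, bins: int = 10,
                        seed: int = 0) -> tuple[list, list]:
    """Expression-matched constrained/unconstrained subsets of equal size.

    Genes are gridded on (avg species-1, avg species-2) log-expression
    quantile cells; within each cell k = min(#constrained, #unconstrained)
    genes are sampled without replacement from each class.  By construction
    the two subsets share the cell-level joint expression distribution.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    idx = calls.index
    usable = calls.isin(["constrained", "unconstrained"])
    usable &= avg_expr_sp1.reindex(idx).notna() & avg_expr_sp2.reindex(idx).notna()
    if not usable.any() or calls[usable].nunique() < 2:
        log.warning("no overlap between classes; matched subsets are empty")
        return [], []
    sub = pd.DataFrame({
        "call": calls[usable],
        "e1": avg_expr_sp1.reindex(idx)[usable],
        "e2": avg_expr_sp2.reindex(idx)[usable],
    })
    q1 = np.unique(np.quantile(sub["e1"], np.linspace(0, 1, bins + 1)))
    q2 = np.unique(np.quantile(sub["e2"], np.linspace(0, 1, bins + 1)))
    sub["c1"] = np.clip(np.searchsorted(q1, sub["e1"], side="right") - 1, 0, len(q1) - 2)
    sub["c2"] = np.clip(np.searchsorted(q2, sub["e2"], side="right") - 1, 0, len(q2) - 2)
    rng = np.random.default_rng(seed)
    take_c: list = []
    take_u: list = []
    for _, cell in sub.groupby(["c1", "c2"], sort=True):
        cons = cell.index[cell["call"] == "constrained"]
        unc = cell.index[cell["call"] == "unconstrained"]
        k = min(len(cons), len(unc))
        if k == 0:
            continue
        take_c.extend(rng.choice(cons, size=k, replace=False))
        take_u.extend(rng.choice(unc, size=k, replace=False))
    return take_c, take_u


# ---------------------------------------------------------------------------
# transcriptional output, ANOVA, breadth, correlations
# ---------------------------------------------------------------------------

def output_fraction(matrix: ExpressionMatrix, lengths: pd.Series,
                    constrained_ids) -> pd.Series:
    """Per-sample fraction of transcribed nucleotides from constrained genes.

    RPKM x exonic length approximates each gene's nucleotide output; the
    fraction is that output summed over constrained genes divided by the sum
    over all expressed genes.  NaN where a sample has no expression.
    """
    v = matrix.values.fillna(0.0)
    L = lengths.reindex(v.index)
    if L.isna().any():
        missing = list(L.index[L.isna()][:3])
        raise ValueError(f"missing exonic length for genes, e.g. {missing}")
    weighted = v.mul(L, axis=0)
    denom = weighted.sum(axis=0)
    num = weighted.loc[weighted.index.isin(set(constrained_ids))].sum(axis=0)
    out = num / denom.where(denom > 0)
    out.name = "output_fraction"
    return out


def anova_decomposition(log_matrix: pd.DataFrame) -> dict[str, float]:
    """Two-factor (gene x sample) additive variance decomposition.

    Balanced two-way sums of squares without interaction: the gene, sample
    and residual fractions of the total sum of squares (they sum to 1).
    Zeros must already be replaced (e.g. by 1e-3) and values log-transformed.
    """
    x = log_matrix.to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    grand = x.mean()
    gene_means = x.mean(axis=1)
    sample_means = x.mean(axis=0)
    ss_gene = x.shape[1] * np.sum((gene_means - grand) ** 2)
    ss_sample = x.shape[0] * np.sum((sample_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_resid = ss_total - ss_gene - ss_sample
    return {
        "gene": float(ss_gene / ss_total),
        "sample": float(ss_sample / ss_total),
        "residual": float(ss_resid / ss_total),
    }


def expression_breadth(matrix: ExpressionMatrix) -> pd.Series:
    """Number of samples in which each gene has non-zero expression."""
    v = matrix.values.fillna(0.0)
    out = (v > 0).sum(axis=1)
    out.name = "breadth"
    return out


def average_log_expression(matrix: ExpressionMatrix,
                           zero_replacement: float = ZERO_REPLACEMENT) -> pd.Series:
    """log10 of the per-gene average RPKM (average first, then log; zero
    averages replaced by ``zero_replacement``)."""
    avg = matrix.values.fillna(0.0).mean(axis=1)
    avg = avg.where(avg > 0, zero_replacement)
    out = np.log10(avg)
    out.name = "log10_avg_rpkm"
    return out


def cross_species_corr(avg1: pd.Series, avg2: pd.Series, subset) -> float:
    """Pearson correlation of per-gene log average expression on a gene subset."""
    ids = [g for g in subset if g in avg1.index and g in avg2.index]
    if len(ids) < 3:
        raise ValueError("need >= 3 genes with values in both species")
    x = avg1.loc[ids].to_numpy(float)
    y = avg2.loc[ids].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def antisense_ratio(sense_counts: pd.DataFrame,
                    antisense_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean and s.d. (over samples) of antisense/(sense+antisense).

    Samples where a gene has no reads on either strand are skipped; genes
    with no covered sample at all come back NaN."""
    s = sense_counts.to_numpy(float)
    a = antisense_counts.reindex(index=sense_counts.index,
                                 columns=sense_counts.columns).to_numpy(float)
    if (np.nan_to_num(s) < 0).any() or (np.nan_to_num(a) < 0).any():
        raise ValueError("negative read counts")
    tot = s + a
    ratio = np.where(tot > 0, a / np.where(tot > 0, tot, 1.0), np.nan)
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(ratio, axis=1)
        sd = np.nanstd(ratio, axis=1, ddof=1)
        n = np.sum(~np.isnan(ratio), axis=1)
    sd = np.where(n >= 2, sd, np.where(n == 1, 0.0, np.nan))
    return pd.DataFrame({"mean_ratio": mean, "sd_ratio": sd, "n_samples": n},
                        index=sense_counts.index)


def localization_stats(nuclear: ExpressionMatrix, cytosolic: ExpressionMatrix,
                       zero_replacement: float = ZERO_REPLACEMENT) -> pd.DataFrame:
    """Per-gene mean and s.d. of log10 nuclear-to-cytosolic abundance ratio.

    Samples must match between compartments; zeros are replaced by the
    effective floor before the ratio.  Genes absent from either matrix are
    skipped with a warning; a negative mean flags a mostly cytosolic gene.
    """
    common = nuclear.values.index.intersection(cytosolic.values.index)
    dropped = len(nuclear.values.index.union(cytosolic.values.index)) - len(common)
    if dropped:
        log.warning("%d genes absent from one compartment; skipped", dropped)
    ncols = [c for c in nuclear.sample_ids if c in cytosolic.sample_ids]
    n = nuclear.values.loc[common, ncols].fillna(0.0).to_numpy(float)
    c = cytosolic.values.loc[common, ncols].fillna(0.0).to_numpy(float)
    n = np.where(n > 0, n, zero_replacement)
    c = np.where(c > 0, c, zero_replacement)
    lr = np.log10(n / c)
    mean = lr.mean(axis=1)
    sd = lr.std(axis=1, ddof=1) if lr.shape[1] >= 2 else np.zeros(len(common))
    return pd.DataFrame({
        "mean_log_ratio": mean,
        "sd_log_ratio": sd,
        "cytosolic": mean < 0,
    }, index=common)
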