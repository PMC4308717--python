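"""Intron-centric splicing metrics and constrained-junction detection.

Per splice junction (D, A) and sample, with n(D, A) split reads supporting
the junction:

* psi5(D, A) = n(D, A) / sum over acceptors A' of n(D, A')   (donor side)
* psi3(D, A) = n(D, A) / sum over donors D' of n(D', A)      (acceptor side)
* pooled psi = 2 n(D, A) / (donor denominator + acceptor denominator)
* theta      = split / (split + boundary), where split is the sum of the two
  denominators and boundary is the exon-intron continuous read count at the
  two splice sites e(D) + e(A) -- a splicing-completeness measure.

Estimates with a denominator below ``min_count`` (default 10) are NA rather
than 0: a proportion from a handful of reads is noise, not signal.

Junctions are classified across all samples of both species as constitutive
high (psi > 0.85 everywhere), constitutive low (psi < 0.15 everywhere) or
variable; among variable junctions, those with intermediate mean inclusion
whose variance stays below 20% of the Bernoulli maximum m(1-m) are flagged as
constrained in splicing.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit

log = logging.getLogger(__name__)

DEFAULT_MIN_COUNT = 10
PSI_HIGH = 0.85
PSI_LOW = 0.15
BERNOULLI_FRACTION = 0.2
DEFAULT_EPS = 1e-3


def _junction_id(df: pd.DataFrame) -> pd.Series:
    return (df["chrom"].astype(str) + ":" + df["start"].astype(str) + "-"
            + df["end"].astype(str) + ":" + df["strand"].astype(str))


def _site_keys(df: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Donor and acceptor site keys; the donor is the intron start on '+'
    strand and the intron end on '-' strand."""
    plus = df["strand"] == "+"
    donor_pos = df["start"].where(plus, df["end"])
    acceptor_pos = df["end"].where(plus, df["start"])
    donor = df["chrom"].astype(str) + ":" + donor_pos.astype(str) + ":" + df["strand"].astype(str)
    acceptor = df["chrom"].astype(str) + ":" + acceptor_pos.astype(str) + ":" + df["strand"].astype(str)
    return donor, acceptor


def compute_psi(junctions: pd.DataFrame,
                min_count: int = DEFAULT_MIN_COUNT) -> pd.DataFrame:
    """psi5 / psi3 / pooled psi per junction per sample.

    ``junctions`` is the long table (chrom, start, end, strand, sample,
    count).  Denominators pool all junctions sharing the donor (resp.
    acceptor) splice site within a sample; each metric is NA when its own
    denominator falls below ``min_count``.
    """
    df = junctions.copy()
    if (df["count"] < 0).any():
        raise ValueError("negative split-read count")
    df["junction"] = _junction_id(df)
    donor, acceptor = _site_keys(df)
    df["donor_site"] = donor
    df["acceptor_site"] = acceptor
    df["den5"] = df.groupby(["donor_site", "sample"])["count"].transform("sum")
    df["den3"] = df.groupby(["acceptor_site", "sample"])["count"].transform("sum")
    n = df["count"].to_numpy(float)
    den5 = df["den5"].to_numpy(float)
    den3 = df["den3"].to_numpy(float)
    psi5 = np.where(den5 >= min_count, n / np.where(den5 > 0, den5, 1.0), np.nan)
    psi3 = np.where(den3 >= min_count, n / np.where(den3 > 0, den3, 1.0), np.nan)
    pooled_den = den5 + den3
    # both sides must clear min_count: a junction unique at its two sites has
    # den5 = den3 = n and must not pass on the doubled pooled denominator
    psi = np.where(np.minimum(den5, den3) >= min_count,
                   2.0 * n / np.where(pooled_den > 0, pooled_den, 1.0), np.nan)
    out = df[["junction", "chrom", "start", "end", "strand", "sample",
              "donor_site", "acceptor_site"]].copy()
    out["n"] = df["count"].to_numpy()
    out["den5"] = den5
    out["den3"] = den3
    out["psi5"] = psi5
    out["psi3"] = psi3
    out["psi"] = psi
    return out


def compute_theta(junctions: pd.DataFrame, boundaries: pd.DataFrame,
                  min_count: int = DEFAULT_MIN_COUNT) -> pd.DataFrame:
    """Completeness of splicing per junction per sample.

    theta = split / (split + e(D) + e(A)) with split the pooled donor and
    acceptor split-read totals.  A splice site missing from the boundary
    table counts 0 boundary reads (warned once)."""
    prof = compute_psi(junctions, min_count=0)
    b = boundaries.copy()
    b["site"] = (b["chrom"].astype(str) + ":" + b["pos"].astype(str))
    bmap = b.set_index(["site", "sample"])["count"]

    # site keys without strand for the boundary lookup
    plus = prof["strand"] == "+"
    donor_pos = prof["start"].where(plus, prof["end"])
    acceptor_pos = prof["end"].where(plus, prof["start"])
    dkey = list(zip(prof["chrom"].astype(str) + ":" + donor_pos.astype(str), prof["sample"]))
    akey = list(zip(prof["chrom"].astype(str) + ":" + acceptor_pos.astype(str), prof["sample"]))
    eD = bmap.reindex(dkey).to_numpy(float)
    eA = bmap.reindex(akey).to_numpy(float)
    n_missing = int(np.isnan(eD).sum() + np.isnan(eA).sum())
    if n_missing:
        log.warning("%d splice-site boundary records missing; treated as 0", n_missing)
    eD = np.nan_to_num(eD)
    eA = np.nan_to_num(eA)
    split = prof["den5"].to_numpy(float) + prof["den3"].to_numpy(float)
    total = split + eD + eA
    theta = np.where(total >= min_count,
                     split / np.where(total > 0, total, 1.0), np.nan)
    out = prof[["junction", "sample"]].copy()
    out["split"] = split
    out["boundary"] = eD + eA
    out["theta"] = theta
    return out


def summarize_junctions(profile: pd.DataFrame,
                        species_of_sample: dict[str, str]) -> pd.DataFrame:
    """Per-junction mean/variance of pooled psi plus per-species usable-sample
    counts, the substrate for classification."""
    df = profile.copy()
    df["species"] = df["sample"].map(species_of_sample)
    if df["species"].isna().any():
        raise ValueError("sample without species assignment")
    usable = df.dropna(subset=["psi"])
    grp = usable.groupby("junction")["psi"]
    mean = grp.mean()
    var = grp.var(ddof=1)
    nmin = grp.min()
    nmax = grp.max()
    n_by_sp = usable.groupby(["junction", "species"]).size().unstack(fill_value=0)
    out = pd.DataFrame({"mean_psi": mean, "var_psi": var,
                        "min_psi": nmin, "max_psi": nmax})
    for sp in sorted(set(species_of_sample.values())):
        out[f"n_{sp}"] = n_by_sp[sp].reindex(out.index, fill_value=0) if sp in n_by_sp else 0
    return out


def classify_junctions(profile: pd.DataFrame,
                       species_of_sample: dict[str, str],
                       hi: float = PSI_HIGH, lo: float = PSI_LOW) -> pd.DataFrame:
    """Constitutive-high / constitutive-low / variable calls per junction.

    A junction needs at least two usable (non-NA psi) samples in each species;
    otherwise it is unclassified.  High requires psi > hi in every usable
    sample of both species; low requires psi < lo everywhere.
    """
    summ = summarize_junctions(profile, species_of_sample)
    species = sorted(set(species_of_sample.values()))
    enough = np.ones(len(summ), dtype=bool)
    for sp in species:
        enough &= summ[f"n_{sp}"].to_numpy() >= 2
    cls = np.where(~enough, "unclassified",
                   np.where(summ["min_psi"] > hi, "constitutive_high",
                            np.where(summ["max_psi"] < lo, "constitutive_low",
                                     "variable")))
    summ["class"] = cls
    return summ


def constrained_flag(mean_psi, var_psi, frac: float = BERNOULLI_FRACTION,
                     lo: float = PSI_LOW, hi: float = PSI_HIGH):
    """Vectorized inclusion-constraint criterion: intermediate mean inclusion
    (lo < m < hi) with variance at most ``frac`` of the Bernoulli maximum
    m(1-m)."""
    m = np.asarray(mean_psi, dtype=float)
    v = np.asarray(var_psi, dtype=float)
    with np.errstate(invalid="ignore"):
        return (m > lo) & (m < hi) & (v <= frac * m * (1.0 - m))


def constrained_junctions(classified: pd.DataFrame,
                          frac: float = BERNOULLI_FRACTION,
                          lo: float = PSI_LOW, hi: float = PSI_HIGH) -> pd.DataFrame:
    """Flag variable junctions whose inclusion is constrained at intermediate
    levels across all samples of both species."""
    out = classified.copy()
    flag = constrained_flag(out["mean_psi"], out["var_psi"], frac=frac, lo=lo, hi=hi)
    out["constrained_intermediate"] = flag & (out["class"] == "variable")
    return out


def ortho_junction_concordance(profileA: pd.DataFrame, profileB: pd.DataFrame,
                               orth: "pd.DataFrame | object",
                               eps: float = DEFAULT_EPS) -> tuple[float, float]:
    """Cross-species concordance of junction usage.

    Returns (Pearson cc of logit mean psi, Pearson cc of psi s.d.) over
    orthologous junction pairs with defined values in both species.  Junction
    pairs at constant complete inclusion or exclusion in either species are
    excluded; means are clipped to [eps, 1-eps] before the logit.
    """
    pairs = orth.pairs if hasattr(orth, "pairs") else orth

    def per_junction(profile):
        usable = profile.dropna(subset=["psi"])
        grp = usable.groupby("junction")["psi"]
        return pd.DataFrame({
            "mean": grp.mean(), "sd": grp.std(ddof=1),
            "min": grp.min(), "max": grp.max(),
        })

    a = per_junction(profileA)
    b = per_junction(profileB)
    ja = a.reindex(pairs["id1"])
    jb = b.reindex(pairs["id2"])
    ok = ja["mean"].notna().to_numpy() & jb["mean"].notna().to_numpy()
    # drop constant complete inclusion/exclusion
    const_a = ((ja["min"] == ja["max"]) & ja["min"].isin([0.0, 1.0])).to_numpy()
    const_b = ((jb["min"] == jb["max"]) & jb["min"].isin([0.0, 1.0])).to_numpy()
    ok &= ~const_a & ~const_b
    ok &= ja["sd"].notna().to_numpy() & jb["sd"].notna().to_numpy()
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable orthologous junction pairs")
    ma = logit(np.clip(ja["mean"].to_numpy(float)[ok], eps, 1 - eps))
    mb = logit(np.clip(jb["mean"].to_numpy(float)[ok], eps, 1 - eps))
    cc_mean = float(stats.pearsonr(ma, mb).statistic)
    cc_sd = float(stats.pearsonr(ja["sd"].to_numpy(float)[ok],
                                 jb["sd"].to_numpy(float)[ok]).statistic)
    return cc_mean, cc_sd
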