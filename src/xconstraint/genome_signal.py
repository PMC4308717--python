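"""Binned read-density conservation and normalized metagene chromatin profiles.

Read density is the mean per-nucleotide coverage (length-free and
bedGraph-native).  Conservation of transcription between two genomes is
measured as the Pearson correlation of log10 density over orthologous 100-nt
bins, overall and stratified by annotation class, by distance to the nearest
gene and by sequence-conservation score.  Metagene profiles average
strand-oriented per-nucleotide signal in a 1-kb window around the TSS (or
TTS), normalized to the maximum signal across all genes for each mark.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GeneModel

log = logging.getLogger(__name__)

BIN_WIDTH = 100
DEFAULT_BIN_PSEUDO = 1e-2
DEFAULT_MARK_PSEUDO = 1.0
METAGENE_HALF = 500


# ---------------------------------------------------------------------------
# coverage handling
# ---------------------------------------------------------------------------

def coverage_arrays(bedgraph: pd.DataFrame,
                    chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand a non-overlapping bedGraph into per-base float arrays."""
    out = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    for chrom, sub in bedgraph.groupby("chrom", sort=False):
        if chrom not in out:
            raise ValueError(f"chromosome {chrom} not in chrom_sizes")
        arr = out[chrom]
        for s, e, v in zip(sub["start"].to_numpy(), sub["end"].to_numpy(),
                           sub["value"].to_numpy()):
            if e > len(arr):
                raise ValueError(f"interval {chrom}:{s}-{e} past chromosome end")
            arr[s:e] = v
    return out


def bin_densities(bedgraph: pd.DataFrame, bins: pd.DataFrame,
                  chrom_sizes: dict[str, int],
                  width: int = BIN_WIDTH) -> np.ndarray:
    """Coverage-weighted mean density for each requested bin.

    ``bins`` has chrom/start columns; each bin spans ``width`` nt.  Bins
    extending past the chromosome end are dropped (NaN) with a warning.
    Interval arithmetic, not per-position expansion: each bedGraph interval
    contributes value x overlap to the bins it crosses.
    """
    sums: dict[str, np.ndarray] = {}
    nbins: dict[str, int] = {}
    for chrom, size in chrom_sizes.items():
        nbins[chrom] = size // width + (1 if size % width else 0)
        sums[chrom] = np.zeros(nbins[chrom])
    for chrom, sub in bedgraph.groupby("chrom", sort=False):
        if chrom not in sums:
            raise ValueError(f"chromosome {chrom} not in chrom_sizes")
        acc = sums[chrom]
        for s, e, v in zip(sub["start"].to_numpy(), sub["end"].to_numpy(),
                           sub["value"].to_numpy()):
            b0, b1 = s // width, (e - 1) // width
            if b0 == b1:
                acc[b0] += v * (e - s)
                continue
            acc[b0] += v * ((b0 + 1) * width - s)
            acc[b1] += v * (e - b1 * width)
            if b1 - b0 > 1:
                acc[b0 + 1:b1] += v * width
    out = np.full(len(bins), np.nan)
    dropped = 0
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    for i in range(len(bins)):
        chrom, s = chroms[i], starts[i]
        if chrom not in sums or s + width > chrom_sizes[chrom]:
            dropped += 1
            continue
        if s % width != 0:
            raise ValueError("bins must be aligned to the tiling grid")
        out[i] = sums[chrom][s // width] / width
    if dropped:
        log.warning("%d bins past chromosome end dropped", dropped)
    return out


# ---------------------------------------------------------------------------
# orthologous bin-pair correlation
# ---------------------------------------------------------------------------

@dataclass
class BinPairCorrelation:
    cc: float
    n: int
    by_class: pd.DataFrame
    by_distance: pd.DataFrame
    by_conservation: pd.DataFrame | None = None


def _stratum_cc(x: np.ndarray, y: np.ndarray, labels: pd.Series) -> pd.DataFrame:
    rows = []
    for lab, idx in labels.groupby(labels, observed=True).groups.items():
        xi, yi = x[labels.index.get_indexer(idx)], y[labels.index.get_indexer(idx)]
        if len(xi) < 3 or np.std(xi) == 0 or np.std(yi) == 0:
            rows.append({"stratum": lab, "cc": np.nan, "n": len(xi)})
        else:
            rows.append({"stratum": lab,
                         "cc": float(stats.pearsonr(xi, yi).statistic),
                         "n": len(xi)})
    return pd.DataFrame(rows)


def binpair_correlation(table: pd.DataFrame, pseudo: float = DEFAULT_BIN_PSEUDO,
                        distance_bins: int = 10,
                        conservation_bins: int = 5) -> BinPairCorrelation:
    """Cross-species correlation of log10 bin density, overall and stratified.

    ``table`` columns: density1, density2, region_class, distance_to_gene and
    optionally conservation_score.  ``pseudo`` (> 0) is added before log10.
    """
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    t = table.reset_index(drop=True)
    x = np.log10(t["density1"].to_numpy(float) + pseudo)
    y = np.log10(t["density2"].to_numpy(float) + pseudo)
    cc = float(stats.pearsonr(x, y).statistic)
    by_class = _stratum_cc(x, y, t["region_class"])
    dec = pd.qcut(t["distance_to_gene"], q=distance_bins, duplicates="drop")
    by_distance = _stratum_cc(x, y, dec)
    by_cons = None
    if "conservation_score" in t.columns and t["conservation_score"].notna().any():
        cb = pd.qcut(t["conservation_score"], q=conservation_bins, duplicates="drop")
        by_cons = _stratum_cc(x, y, cb)
    return BinPairCorrelation(cc=cc, n=len(t), by_class=by_class,
                              by_distance=by_distance, by_conservation=by_cons)


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    mark: str
    group: str
    anchor: str
    offsets: np.ndarray = field(repr=False)
    signal: np.ndarray = field(repr=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "signal": self.signal})


def gene_windows(coverage: dict[str, np.ndarray], genes: list[GeneModel],
                 anchor: str = "TSS", half: int = METAGENE_HALF) -> pd.DataFrame:
    """Per-gene strand-oriented signal window around the anchor.

    Rows = genes, columns = offsets -half .. half-1 relative to the anchor in
    the direction of transcription.  Genes whose window leaves the chromosome
    are skipped with a warning.
    """
    if anchor not in {"TSS", "TTS"}:
        raise ValueError("anchor must be TSS or TTS")
    rows = {}
    skipped = 0
    for g in genes:
        if g.chrom not in coverage:
            skipped += 1
            continue
        arr = coverage[g.chrom]
        pos = g.tss if anchor == "TSS" else g.tts
        # '+': [pos-half, pos+half); '-': (pos-half, pos+half] then reversed,
        # so genomic pos -/+ o maps to transcriptional offset +o on both strands
        lo, hi = (pos - half, pos + half) if g.strand == "+" else (pos - half + 1,
                                                                   pos + half + 1)
        if lo < 0 or hi > len(arr):
            skipped += 1
            continue
        win = arr[lo:hi]
        if g.strand == "-":
            win = win[::-1]
        rows[g.gene_id] = win
    if skipped:
        log.warning("%d genes skipped (window beyond chromosome edge)", skipped)
    offsets = np.arange(-half, half)
    return pd.DataFrame.from_dict(rows, orient="index", columns=offsets)


def metagene_profile(coverage_per_sample: list[dict[str, np.ndarray]],
                     genes: list[GeneModel], anchor: str, group_ids,
                     mark: str = "", group: str = "",
                     half: int = METAGENE_HALF) -> MetageneProfile:
    """Group-averaged, mark-normalized metagene profile.

    Per sample, per-gene windows are extracted for *all* genes, normalized to
    the maximum signal across all genes for the mark, averaged over the genes
    of the group, and finally averaged across samples.
    """
    group_ids = set(group_ids)
    profiles = []
    for cov in coverage_per_sample:
        win = gene_windows(cov, genes, anchor=anchor, half=half)
        peak = win.to_numpy().max() if win.size else 0.0
        if peak <= 0:
            profiles.append(np.zeros(2 * half))
            continue
        norm = win / peak
        sel = norm.loc[norm.index.isin(group_ids)]
        profiles.append(sel.to_numpy().mean(axis=0) if len(sel) else np.zeros(2 * half))
    signal = np.mean(profiles, axis=0)
    return MetageneProfile(mark=mark, group=group, anchor=anchor,
                           offsets=np.arange(-half, half), signal=signal)


def mark_divergence(window_mean_sp1: pd.Series, window_mean_sp2: pd.Series,
                    orth, pseudo: float = DEFAULT_MARK_PSEUDO) -> pd.Series:
    """Cross-species divergence of a mark: |log10(s1+pseudo) - log10(s2+pseudo)|
    of the mean window signal per orthologous gene pair; missing genes are
    skipped."""
    pairs = orth.pairs if hasattr(orth, "pairs") else orth
    s1 = window_mean_sp1.reindex(pairs["id1"]).to_numpy(float)
    s2 = window_mean_sp2.reindex(pairs["id2"]).to_numpy(float)
    ok = ~np.isnan(s1) & ~np.isnan(s2)
    if (~ok).sum():
        log.warning("%d orthologue pairs missing mark signal; skipped", int((~ok).sum()))
    d = np.abs(np.log10(s1[ok] + pseudo) - np.log10(s2[ok] + pseudo))
    return pd.Series(d, index=pairs["id1"].to_numpy()[ok], name="abs_dlog_signal")


def divergence_class_test(divergence: pd.Series, classes: pd.Series) -> dict:
    """Compare |dlog signal| between gene classes (two-sided rank-sum)."""
    joined = pd.DataFrame({"d": divergence}).join(classes.rename("class"), how="inner")
    labs = sorted(joined["class"].dropna().unique())
    if len(labs) != 2:
        raise ValueError("need exactly two classes")
    a = joined.loc[joined["class"] == labs[0], "d"]
    b = joined.loc[joined["class"] == labs[1], "d"]
    res = stats.ranksums(a, b)
    return {"classes": labs, "median_" + labs[0]: float(a.median()),
            "median_" + labs[1]: float(b.median()),
            "statistic": float(res.statistic), "pvalue": float(res.pvalue)}
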