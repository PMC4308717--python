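"""Shared data model, standard-format readers/writers, genome partitioning and distances.

Coordinates are 0-based half-open everywhere inside the package; GTF files
(1-based, closed) are converted on read and write.  Missing matrix values are
NA and are distinct from 0 (0 means reproducibly undetected).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Interval = tuple[int, int]

MATRIX_FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# interval helpers
# ---------------------------------------------------------------------------

def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of half-open intervals; overlapping or touching intervals merge."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract_intervals(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Set difference a \\ b for merged, sorted interval lists."""
    out: list[Interval] = []
    b = merge_intervals(b)
    for s, e in merge_intervals(a):
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def complement_intervals(a: list[Interval], size: int) -> list[Interval]:
    return subtract_intervals([(0, size)], a)


def total_length(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene with its merged exon structure on a genome.

    ``exons`` are stored merged (interval union) and sorted; ``exonic_length``
    is therefore the length of the exon union, with overlaps between
    transcripts counted once.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[Interval] = field(default_factory=list)
    transcript_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = merge_intervals(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene span")

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start position (strand aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix (RPKM), NA allowed, negatives rejected."""

    values: pd.DataFrame
    species: str = ""
    replicate_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValueError("duplicated gene ids")
        if v.columns.duplicated().any():
            raise ValueError("duplicated sample ids")
        arr = v.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("negative expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class OrthologyMap:
    """One-to-one identifier pairing between two species."""

    pairs: pd.DataFrame  # columns: id1, id2

    def __post_init__(self) -> None:
        p = self.pairs
        if list(p.columns) != ["id1", "id2"]:
            p = p.iloc[:, :2].set_axis(["id1", "id2"], axis=1)
            self.pairs = p
        for col in ("id1", "id2"):
            if p[col].duplicated().any():
                dup = p.loc[p[col].duplicated(), col].iloc[0]
                raise ValueError(f"orthology not one-to-one: {dup!r} repeated in {col}")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class RegionPartition:
    """Disjoint labelled cover of each chromosome: exonic / intronic / intergenic."""

    intervals: pd.DataFrame  # columns: chrom, start, end, label
    chrom_sizes: dict[str, int]

    LABELS = ("exonic", "intronic", "intergenic")

    def lengths(self) -> pd.Series:
        df = self.intervals
        out = (df["end"] - df["start"]).groupby(df["label"]).sum()
        return out.reindex(self.LABELS, fill_value=0)

    def label_at(self, chrom: str, pos: int) -> str:
        df = self.intervals[self.intervals["chrom"] == chrom]
        hit = df[(df["start"] <= pos) & (pos < df["end"])]
        if hit.empty:
            raise KeyError(f"position {chrom}:{pos} not covered")
        return hit["label"].iloc[0]


# ---------------------------------------------------------------------------
# GTF annotation
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"GTF line {lineno}: malformed attribute {chunk!r}")
        attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


def read_annotation(path) -> list[GeneModel]:
    """Read an Ensembl-dialect GTF into GeneModels (0-based half-open).

    Exons are merged per gene; genes come back ordered by (chrom, start,
    gene_id).  An exon outside the recorded gene span extends the span with a
    warning; a malformed line raises with its line number.
    """
    genes: dict[str, dict] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"GTF line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"GTF line {lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise ValueError(f"GTF line {lineno}: bad coordinates {start1}-{end1}")
            start, end = start1 - 1, end1  # 0-based half-open
            attrs = _parse_gtf_attributes(attr_s, lineno)
            if "gene_id" not in attrs:
                raise ValueError(f"GTF line {lineno}: missing gene_id attribute")
            gid = attrs["gene_id"]
            rec = genes.setdefault(
                gid,
                {"chrom": chrom, "strand": strand, "start": start, "end": end,
                 "exons": [], "transcripts": []},
            )
            if feature == "exon":
                if start < rec["start"] or end > rec["end"]:
                    log.warning(
                        "GTF line %d: exon outside gene span of %s; extending span",
                        lineno, gid,
                    )
                rec["exons"].append((start, end))
            rec["start"] = min(rec["start"], start)
            rec["end"] = max(rec["end"], end)
            tid = attrs.get("transcript_id")
            if tid and tid not in rec["transcripts"]:
                rec["transcripts"].append(tid)
    if n_lines == 0:
        log.warning("annotation file %s is empty", path)
        return []
    out = [
        GeneModel(gene_id=gid, chrom=r["chrom"], start=r["start"], end=r["end"],
                  strand=r["strand"], exons=r["exons"], transcript_ids=sorted(r["transcripts"]))
        for gid, r in genes.items()
    ]
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def write_annotation(genes: list[GeneModel], path) -> None:
    """Write GeneModels as GTF (gene + exon lines, 1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attr = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\txconstraint\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attr}\n"
            )
            tid = g.transcript_ids[0] if g.transcript_ids else g.gene_id + ".t1"
            for s, e in g.exons:
                a = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                fh.write(
                    f"{g.chrom}\txconstraint\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{a}\n"
                )


# ---------------------------------------------------------------------------
# genome partition & distances
# ---------------------------------------------------------------------------

def partition_genome(genes: list[GeneModel], chrom_sizes: dict[str, int]) -> RegionPartition:
    """Label every position exonic (any gene's exon, either strand), else
    intronic (inside a gene span), else intergenic.  Precedence is
    exonic > intronic > intergenic; output intervals are disjoint and cover
    each chromosome exactly."""
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"{g.gene_id}: chromosome {g.chrom} not in chrom_sizes")
        if g.end > chrom_sizes[g.chrom]:
            raise ValueError(f"{g.gene_id}: gene extends past end of {g.chrom}")
    rows = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, size in sorted(chrom_sizes.items()):
        gs = by_chrom.get(chrom, [])
        exonic = merge_intervals([iv for g in gs for iv in g.exons])
        genic = merge_intervals([(g.start, g.end) for g in gs])
        intronic = subtract_intervals(genic, exonic)
        intergenic = complement_intervals(genic, size)
        for label, ivs in (("exonic", exonic), ("intronic", intronic),
                           ("intergenic", intergenic)):
            for s, e in ivs:
                rows.append((chrom, s, e, label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return RegionPartition(intervals=df, chrom_sizes=dict(chrom_sizes))


def distance_to_nearest_gene(bins: pd.DataFrame, genes: list[GeneModel]) -> np.ndarray:
    """Distance (nt) from each bin to the nearest gene span, 0 if overlapping.

    ``bins`` needs columns chrom/start/end.  Bins on chromosomes absent from
    the annotation get NaN (logged)."""
    spans: dict[str, np.ndarray] = {}
    for g in genes:
        spans.setdefault(g.chrom, [])
    tmp: dict[str, list[Interval]] = {}
    for g in genes:
        tmp.setdefault(g.chrom, []).append((g.start, g.end))
    for chrom, ivs in tmp.items():
        spans[chrom] = np.array(merge_intervals(ivs), dtype=float)

    out = np.full(len(bins), np.nan)
    missing: set[str] = set()
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    for i in range(len(bins)):
        chrom = chroms[i]
        if chrom not in spans or len(spans[chrom]) == 0:
            missing.add(chrom)
            continue
        sp = spans[chrom]
        s, e = starts[i], ends[i]
        # overlap test against merged spans
        j = np.searchsorted(sp[:, 0], e, side="left")
        overlap = j > 0 and sp[j - 1, 1] > s
        if overlap:
            out[i] = 0.0
            continue
        cands = []
        if j > 0:
            cands.append(s - sp[j - 1, 1])
        if j < len(sp):
            cands.append(sp[j, 0] - e)
        out[i] = float(max(0, min(cands)))
    for chrom in sorted(missing):
        log.warning("chromosome %s absent from annotation; distances undefined", chrom)
    return out


# ---------------------------------------------------------------------------
# tabular readers / writers
# ---------------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=MATRIX_FLOAT_FORMAT, na_rep="NA",
              index_label="feature")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return df


def write_orthology(orth: OrthologyMap, path) -> None:
    orth.pairs.to_csv(path, sep="\t", index=False)


def read_orthology(path) -> OrthologyMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return OrthologyMap(pairs=df)


def read_bedgraph(path) -> pd.DataFrame:
    """4-column bedGraph -> DataFrame(chrom, start, end, value); intervals must
    be non-overlapping within a chromosome (rejected with the line number)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    df["_line"] = np.arange(1, len(df) + 1)
    if (df["end"] <= df["start"]).any():
        bad = df.loc[df["end"] <= df["start"], "_line"].iloc[0]
        raise ValueError(f"bedGraph line {bad}: empty or inverted interval")
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="mergesort")
        prev_end = sub["end"].to_numpy()[:-1]
        nxt_start = sub["start"].to_numpy()[1:]
        bad = np.nonzero(nxt_start < prev_end)[0]
        if len(bad):
            lineno = int(sub["_line"].to_numpy()[bad[0] + 1])
            raise ValueError(f"bedGraph line {lineno}: overlapping interval on {chrom}")
    return df.drop(columns="_line").reset_index(drop=True)


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format=MATRIX_FLOAT_FORMAT)


JUNCTION_COLUMNS = ["chrom", "start", "end", "strand", "sample", "count"]
BOUNDARY_COLUMNS = ["chrom", "pos", "side", "sample", "count"]


def read_junctions(path) -> pd.DataFrame:
    """Splice-junction split-read counts: chrom, intron start, intron end,
    strand, sample, count (one row per junction per sample)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(JUNCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"junction table missing columns: {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ValueError("negative split-read count")
    key = df[["chrom", "start", "end", "strand", "sample"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise ValueError(f"duplicated (junction, sample) record: {key[key.duplicated()].iloc[0]}")
    return df


def write_junctions(df: pd.DataFrame, path) -> None:
    df[JUNCTION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_boundaries(path) -> pd.DataFrame:
    """Splice-site boundary (exon-intron continuous) read counts."""
    df = pd.read_csv(path, sep="\t")
    missing = set(BOUNDARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"boundary table missing columns: {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ValueError("negative boundary-read count")
    if not df["side"].isin(["donor", "acceptor"]).all():
        raise ValueError("side must be donor or acceptor")
    return df


def write_boundaries(df: pd.DataFrame, path) -> None:
    df[BOUNDARY_COLUMNS].to_csv(path, sep="\t", index=False)
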