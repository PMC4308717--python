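"""Seeded generators for two-species panels with known ground truth.

Every generator is a pure function of (config, seed) and emulates the
statistical structure of a two-species comparative RNA-seq panel:

* orthologous gene panels with a bimodal per-gene expression dynamic range —
  a constrained class whose log10 expression stays inside a window of width
  r < 2 around a shared baseline, and an unconstrained class with Gaussian
  tissue effects wide enough that the range exceeds 2 with high probability;
* replicated measurements with multiplicative noise and signal-dependent
  dropout (feeding the npIDR filter);
* splice-junction panels with binomially sampled split reads around true
  inclusion paths per junction class, plus boundary reads from a stated
  completeness model;
* per-gene isoform abundance tables in expression-driven vs splicing-driven
  regimes;
* orthologous 100-nt bin densities with a stated correlation kernel and
  TSS-anchored chromatin-mark tracks with shared or independent amplitudes.

Default panel sizes are a deliberate scale-down of a consortium panel:
2 species x 20 biosamples x 5,000 orthologues, a 2,000-junction panel.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, GeneModel, OrthologyMap

SPECIES = ("human", "mouse")


@dataclass
class SimConfig:
    # expression panel
    n_genes: int = 5000
    n_samples: int = 20                    # biosamples per species
    frac_constrained: float = 0.45
    constrained_mu_b: float = 1.5          # log10 RPKM baseline mean
    constrained_sd_b: float = 0.75
    constrained_range: float = 1.0         # r: width of the per-sample uniform window (< 2)
    unconstrained_mu_b: float = 1.2
    unconstrained_sd_b: float = 0.9
    tissue_sd: float = 1.0                 # per-sample effect s.d. (unconstrained)
    length_log_mean: float = 3.2           # exonic length ~ 10^N(mean, sd)
    length_log_sd: float = 0.35
    # replicates
    replicate_noise_sd: float = 0.1        # lognormal noise, log10 units
    dropout_midpoint: float = -1.5         # log10 RPKM with 50% dropout
    dropout_slope: float = 2.0
    # junction panel
    n_junctions: int = 2000
    junction_depth: float = 50.0           # Poisson mean split reads per site per sample
    n_junction_samples: int = 30           # per species
    junction_class_fracs: dict = field(default_factory=lambda: {
        "constitutive_high": 0.60, "constitutive_low": 0.05,
        "constrained_intermediate": 0.15, "variable": 0.20})
    variable_beta: tuple = (0.5, 0.5)      # high-variance inclusion process
    theta_low: float = 0.7                 # completeness drawn U(theta_low, theta_high)
    theta_high: float = 0.99
    # isoform panel
    n_isoform_genes: int = 200
    n_isoform_samples: int = 10
    isoform_alpha: float = 0.8             # Dirichlet concentration
    isoform_total_log_sd: float = 0.2      # totals ~ 10^N(1, sd)
    isoform_noise_sd: float = 0.02         # lognormal measurement noise, log10
    frac_splicing_driven: float = 0.5
    # bin panel
    n_bins: int = 10000
    bin_width: int = 100
    bin_log_mean: float = 1.0              # log10 density
    bin_log_sd: float = 0.5
    bin_class_fracs: dict = field(default_factory=lambda: {
        "exonic": 0.3, "intronic": 0.3, "intergenic": 0.4})
    bin_class_rho: dict = field(default_factory=lambda: {
        "exonic": 0.85, "intronic": 0.70, "intergenic": 0.55})
    bin_distance_scale: float | None = 20000.0  # exp decay of rho with distance; None = flat
    bin_max_distance: float = 60000.0
    # chromatin-mark panel
    n_mark_genes: int = 200
    mark_gene_spacing: int = 3000
    mark_gene_length: int = 1000
    mark_amp_log_mean: float = 1.0
    mark_amp_log_sd: float = 0.5
    mark_kernel_sd: float = 150.0
    mark_noise_sd: float = 0.05
    mark_frac_shared: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.frac_constrained <= 1):
            raise ValueError("frac_constrained must be in [0, 1]")
        if self.constrained_range >= 2:
            raise ValueError("constrained range r must be < 2 for a bounded-range truth class")
        if abs(sum(self.junction_class_fracs.values()) - 1) > 1e-9:
            raise ValueError("junction class fractions must sum to 1")


@dataclass
class TruthSet:
    """Everything the generators know: class labels, true paths, analytic summaries."""
    genes: pd.DataFrame | None = None              # gene_1, gene_2, class, baseline
    true_log_expression: dict | None = None        # species -> DataFrame genes x samples
    dnr_true: pd.Series | None = None
    mixture_truth: dict | None = None              # component means/sds + intersection
    junctions: pd.DataFrame | None = None          # junction ids, class, theta_true
    psi_true: dict | None = None                   # species -> DataFrame junctions x samples
    isoform_regime: pd.Series | None = None
    bin_rho: np.ndarray | None = None
    mark_genes: pd.DataFrame | None = None


def dropout_probability(log10_signal, midpoint: float, slope: float):
    """Logistic dropout, decreasing in signal: 0.5 at the midpoint."""
    x = np.asarray(log10_signal, dtype=float)
    return 1.0 / (1.0 + np.exp(slope * (x - midpoint)))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(cfg: SimConfig, seed: int
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix, OrthologyMap, TruthSet]:
    """Two-species orthologous expression panel with a bimodal dynamic range.

    Orthologues share a per-gene log10 baseline across species.  Constrained
    genes add per-sample deviations ~ U(-r/2, r/2), bounding their true
    dynamic range by r < 2; unconstrained genes add Gaussian tissue effects
    (s.d. ``tissue_sd``) whose range across the panel exceeds 2 with high
    probability.  Returned matrices are noise-free biosample-level truth.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_genes
    n_con = int(round(cfg.frac_constrained * n))
    classes = np.array(["constrained"] * n_con + ["unconstrained"] * (n - n_con))
    rng.shuffle(classes)
    is_con = classes == "constrained"

    baseline = np.where(
        is_con,
        rng.normal(cfg.constrained_mu_b, cfg.constrained_sd_b, n),
        rng.normal(cfg.unconstrained_mu_b, cfg.unconstrained_sd_b, n),
    )
    gene_ids = {sp: [f"g{i:05d}_{sp[:1]}" for i in range(n)] for sp in SPECIES}
    true_log = {}
    for sp in SPECIES:
        dev = np.where(
            is_con[:, None],
            rng.uniform(-cfg.constrained_range / 2, cfg.constrained_range / 2,
                        (n, cfg.n_samples)),
            rng.normal(0.0, cfg.tissue_sd, (n, cfg.n_samples)),
        )
        logx = baseline[:, None] + dev
        true_log[sp] = pd.DataFrame(
            logx, index=gene_ids[sp],
            columns=[f"{sp[:1]}s{j:02d}" for j in range(cfg.n_samples)])

    lengths = np.round(10 ** rng.normal(cfg.length_log_mean, cfg.length_log_sd, n)).astype(int)
    genes = pd.DataFrame({
        "gene_1": gene_ids[SPECIES[0]],
        "gene_2": gene_ids[SPECIES[1]],
        "class": classes,
        "baseline": baseline,
        "exonic_length": lengths,
    })
    orth = OrthologyMap(pairs=pd.DataFrame({
        "id1": genes["gene_1"], "id2": genes["gene_2"]}))

    # analytic truth: DNR of the noiseless panel and the two-component summary
    pooled = np.hstack([true_log[sp].to_numpy() for sp in SPECIES])
    dnr_true = pd.Series(pooled.max(axis=1) - pooled.min(axis=1),
                         index=genes["gene_1"].to_numpy(), name="dnr_true")
    mix = {}
    for lab in ("constrained", "unconstrained"):
        vals = dnr_true.to_numpy()[classes == lab]
        mix[lab] = {
            "mean": float(vals.mean()) if len(vals) else float("nan"),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            "weight": float((classes == lab).mean()),
        }
    truth = TruthSet(genes=genes, true_log_expression=true_log, dnr_true=dnr_true,
                     mixture_truth=mix)

    m1 = ExpressionMatrix(values=10 ** true_log[SPECIES[0]], species=SPECIES[0])
    m2 = ExpressionMatrix(values=10 ** true_log[SPECIES[1]], species=SPECIES[1])
    return m1, m2, orth, truth


def simulate_replicates(matrix: ExpressionMatrix, noise_sd: float,
                        dropout_midpoint: float, dropout_slope: float,
                        seed: int) -> ExpressionMatrix:
    """Two replicate measurements per biosample: truth x lognormal noise,
    zeroed with a signal-dependent (logistic, decreasing) dropout probability.

    Returns a matrix with two columns per input biosample (suffix _r1/_r2)
    and ``replicate_of`` set, ready for the npIDR filter.
    """
    rng = np.random.default_rng(seed)
    truth = matrix.values.to_numpy(float)
    with np.errstate(divide="ignore"):
        logx = np.where(truth > 0, np.log10(np.where(truth > 0, truth, 1.0)), -np.inf)
    p_drop = np.where(truth > 0,
                      dropout_probability(logx, dropout_midpoint, dropout_slope), 1.0)
    cols = {}
    rep_of = {}
    for k in (1, 2):
        noise = 10 ** rng.normal(0.0, noise_sd, truth.shape)
        keep = rng.random(truth.shape) >= p_drop
        rep = truth * noise * keep
        for j, sample in enumerate(matrix.sample_ids):
            name = f"{sample}_r{k}"
            cols[name] = rep[:, j]
            rep_of[name] = sample
    order = [f"{s}_r{k}" for s in matrix.sample_ids for k in (1, 2)]
    df = pd.DataFrame(cols, index=matrix.values.index)[order]
    return ExpressionMatrix(values=df, species=matrix.species, replicate_of=rep_of)


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------

def _junction_rows(chrom, start, end, strand, samples, counts):
    return pd.DataFrame({
        "chrom": chrom, "start": start, "end": end, "strand": strand,
        "sample": samples, "count": counts})


def simulate_junctions(cfg: SimConfig, seed: int):
    """Two-species splice-junction panel with known inclusion paths.

    Each panel junction D->A carries a true inclusion path psi*: constant
    > 0.9 (constitutive high), constant < 0.1 (constitutive low), a constant
    intermediate value in (0.15, 0.85) shared across species (constrained),
    or per-sample Beta draws with large variance (variable).  Per sample the
    donor- and acceptor-side totals are Poisson(depth) and the junction's
    split reads Binomial(depth, psi*); the remainders go to one alternative
    acceptor and one alternative donor partner junction, so the pooled psi of
    the panel junction estimates psi* directly.  Boundary reads at the two
    splice sites are Poisson with mean split x (1-theta*)/theta*.

    Returns (junction table sp1, boundary sp1, junction table sp2,
    boundary sp2, OrthologyMap, TruthSet).
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_junctions
    fracs = cfg.junction_class_fracs
    labels = np.concatenate([
        np.repeat(lab, int(round(f * n))) for lab, f in fracs.items()])
    labels = labels[:n] if len(labels) >= n else np.concatenate(
        [labels, np.repeat("variable", n - len(labels))])
    rng.shuffle(labels)

    psi_const = np.empty(n)
    psi_const[labels == "constitutive_high"] = rng.uniform(
        0.92, 0.995, (labels == "constitutive_high").sum())
    psi_const[labels == "constitutive_low"] = rng.uniform(
        0.005, 0.08, (labels == "constitutive_low").sum())
    psi_const[labels == "constrained_intermediate"] = rng.uniform(
        0.2, 0.8, (labels == "constrained_intermediate").sum())
    psi_const[labels == "variable"] = np.nan
    theta_true = rng.uniform(cfg.theta_low, cfg.theta_high, n)

    junction_ids = {}
    tables = {}
    boundaries = {}
    psi_paths = {}
    a, b = cfg.variable_beta
    S = cfg.n_junction_samples
    for sp in SPECIES:
        chrom = f"chrJ_{sp[:1]}"
        base = 1000 * np.arange(n)
        start, end = base + 100, base + 200
        alt_acc_end = base + 300
        alt_don_start = base + 150
        samples = [f"{sp[:1]}j{j:02d}" for j in range(S)]

        psi = np.where(np.isnan(psi_const[:, None]),
                       rng.beta(a, b, (n, S)),
                       np.repeat(psi_const[:, None], S, axis=1))
        depth5 = rng.poisson(cfg.junction_depth, (n, S))
        depth3 = depth5  # matched site totals keep pooled psi unbiased
        n_split = rng.binomial(depth5, psi)

        main, alt1, alt2, brows = [], [], [], []
        for j, sample in enumerate(samples):
            main.append(_junction_rows(chrom, start, end, "+", sample, n_split[:, j]))
            alt1.append(_junction_rows(chrom, start, alt_acc_end, "+", sample,
                                       depth5[:, j] - n_split[:, j]))
            alt2.append(_junction_rows(chrom, alt_don_start, end, "+", sample,
                                       depth3[:, j] - n_split[:, j]))
            split_total = depth5[:, j] + depth3[:, j]
            e_mean = 0.5 * split_total * (1 - theta_true) / theta_true
            eD = rng.poisson(e_mean)
            eA = rng.poisson(e_mean)
            brows.append(pd.DataFrame({
                "chrom": chrom,
                "pos": np.concatenate([start, end, alt_acc_end, alt_don_start]),
                "side": ["donor"] * n + ["acceptor"] * n + ["acceptor"] * n + ["donor"] * n,
                "sample": sample,
                "count": np.concatenate([eD, eA, np.zeros(n, int), np.zeros(n, int)]),
            }))
        tables[sp] = pd.concat(main + alt1 + alt2, ignore_index=True)
        boundaries[sp] = pd.concat(brows, ignore_index=True)
        junction_ids[sp] = [f"{chrom}:{s}-{e}:+" for s, e in zip(start, end)]
        psi_paths[sp] = pd.DataFrame(psi, index=junction_ids[sp], columns=samples)

    orth = OrthologyMap(pairs=pd.DataFrame({
        "id1": junction_ids[SPECIES[0]], "id2": junction_ids[SPECIES[1]]}))
    truth = TruthSet(
        junctions=pd.DataFrame({
            "id1": junction_ids[SPECIES[0]],
            "id2": junction_ids[SPECIES[1]],
            "class": labels, "psi_const": psi_const, "theta_true": theta_true}),
        psi_true=psi_paths)
    return (tables[SPECIES[0]], boundaries[SPECIES[0]],
            tables[SPECIES[1]], boundaries[SPECIES[1]], orth, truth)


# ---------------------------------------------------------------------------
# isoforms
# ---------------------------------------------------------------------------

def simulate_isoforms(cfg: SimConfig, seed: int) -> tuple[dict[str, np.ndarray], pd.Series]:
    """Per-gene isoform abundance tables in two regimes.

    Expression-driven genes keep one Dirichlet proportion vector for every
    sample (variation is total expression only); splicing-driven genes redraw
    proportions per sample.  Totals are lognormal in both regimes; a small
    lognormal measurement noise is applied throughout.  Genes with a single
    transcript (always expression-driven by convention) are included.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_isoform_genes
    S = cfg.n_isoform_samples
    n_split = int(round(cfg.frac_splicing_driven * n))
    regimes = np.array(["splicing_driven"] * n_split + ["expression_driven"] * (n - n_split))
    rng.shuffle(regimes)
    out: dict[str, np.ndarray] = {}
    labels = {}
    for i in range(n):
        gene = f"iso{i:04d}"
        T = int(rng.integers(2, 6))
        if regimes[i] == "expression_driven" and rng.random() < 0.1:
            T = 1
        totals = 10 ** rng.normal(1.0, cfg.isoform_total_log_sd, S)
        if regimes[i] == "expression_driven" or T == 1:
            props = np.repeat(rng.dirichlet(np.full(T, cfg.isoform_alpha))[None, :], S, axis=0)
        else:
            props = rng.dirichlet(np.full(T, cfg.isoform_alpha), size=S)
        noise = 10 ** rng.normal(0.0, cfg.isoform_noise_sd, (S, T))
        out[gene] = totals[:, None] * props * noise
        labels[gene] = regimes[i]
    return out, pd.Series(labels, name="regime")


# ---------------------------------------------------------------------------
# tracks: orthologous bins and chromatin marks
# ---------------------------------------------------------------------------

def simulate_bin_pairs(cfg: SimConfig, seed: int) -> tuple[pd.DataFrame, TruthSet]:
    """Orthologous 100-nt bin densities with a stated correlation kernel.

    Per pair the log10 densities are bivariate normal with correlation
    rho = bin_class_rho[class] x exp(-distance / bin_distance_scale) (flat in
    distance when the scale is None); genic bins sit at distance 0.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_bins
    classes = rng.choice(list(cfg.bin_class_fracs), size=n,
                         p=list(cfg.bin_class_fracs.values()))
    distance = np.where(classes == "intergenic",
                        rng.uniform(0, cfg.bin_max_distance, n), 0.0)
    rho0 = np.array([cfg.bin_class_rho[c] for c in classes])
    if cfg.bin_distance_scale is None:
        rho = rho0
    else:
        rho = rho0 * np.exp(-distance / cfg.bin_distance_scale)
    shared = rng.normal(0, 1, n)
    e1 = rng.normal(0, 1, n)
    e2 = rng.normal(0, 1, n)
    z1 = np.sqrt(rho) * shared + np.sqrt(1 - rho) * e1
    z2 = np.sqrt(rho) * shared + np.sqrt(1 - rho) * e2
    d1 = 10 ** (cfg.bin_log_mean + cfg.bin_log_sd * z1)
    d2 = 10 ** (cfg.bin_log_mean + cfg.bin_log_sd * z2)
    score = np.clip(0.5 + 0.25 * shared + rng.normal(0, 0.15, n), 0, 1)
    table = pd.DataFrame({
        "chrom1": "chrB_h", "start1": cfg.bin_width * np.arange(n),
        "chrom2": "chrB_m", "start2": cfg.bin_width * np.arange(n),
        "density1": d1, "density2": d2,
        "region_class": classes, "distance_to_gene": distance,
        "conservation_score": score,
    })
    return table, TruthSet(bin_rho=rho)


def _gaussian_kernel(half: int, sd: float) -> np.ndarray:
    o = np.arange(-half, half + 1, dtype=float)
    return np.exp(-0.5 * (o / sd) ** 2)


def simulate_mark_tracks(cfg: SimConfig, seed: int):
    """TSS-anchored chromatin-mark coverage for two species.

    Genes sit on one toy chromosome per species at a fixed spacing with
    alternating strand.  Each gene's signal is an amplitude x Gaussian kernel
    centred on its TSS; 'shared' genes use the same amplitude in both species,
    the rest draw independently.  Returns per-species (GeneModel list,
    coverage dict) plus an orthology map and the amplitude truth.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_mark_genes
    spacing, glen = cfg.mark_gene_spacing, cfg.mark_gene_length
    chrom_len = (n + 1) * spacing + 2000
    kernel = _gaussian_kernel(3 * int(cfg.mark_kernel_sd), cfg.mark_kernel_sd)
    khalf = 3 * int(cfg.mark_kernel_sd)

    shared = rng.random(n) < cfg.mark_frac_shared
    amp_shared = 10 ** rng.normal(cfg.mark_amp_log_mean, cfg.mark_amp_log_sd, n)
    out = {}
    ids = {}
    for sp in SPECIES:
        chrom = f"chrT_{sp[:1]}"
        amp = np.where(shared, amp_shared,
                       10 ** rng.normal(cfg.mark_amp_log_mean, cfg.mark_amp_log_sd, n))
        cov = np.zeros(chrom_len)
        genes = []
        gids = []
        for i in range(n):
            start = (i + 1) * spacing
            strand = "+" if i % 2 == 0 else "-"
            g = GeneModel(gene_id=f"mk{i:04d}_{sp[:1]}", chrom=chrom, start=start,
                          end=start + glen, strand=strand,
                          exons=[(start, start + glen)])
            tss = g.tss
            noise = 10 ** rng.normal(0.0, cfg.mark_noise_sd)
            cov[tss - khalf: tss + khalf + 1] += amp[i] * noise * kernel
            genes.append(g)
            gids.append(g.gene_id)
        out[sp] = (genes, {chrom: cov}, amp)
        ids[sp] = gids
    orth = OrthologyMap(pairs=pd.DataFrame({"id1": ids[SPECIES[0]],
                                            "id2": ids[SPECIES[1]]}))
    truth = pd.DataFrame({
        "id1": ids[SPECIES[0]], "id2": ids[SPECIES[1]],
        "shared": shared,
        "amp_1": out[SPECIES[0]][2], "amp_2": out[SPECIES[1]][2],
    })
    return out[SPECIES[0]][:2], out[SPECIES[1]][:2], orth, truth


def simulate_tracks(cfg: SimConfig, seed: int):
    """Bin-pair densities plus chromatin-mark tracks (two sub-generators on
    independent substreams of ``seed``)."""
    ss = np.random.SeedSequence(seed).spawn(2)
    bins, bin_truth = simulate_bin_pairs(cfg, ss[0].generate_state(1)[0] % 2**31)
    marks = simulate_mark_tracks(cfg, ss[1].generate_state(1)[0] % 2**31)
    return bins, bin_truth, marks


def coverage_to_bedgraph(coverage: dict[str, np.ndarray],
                         decimals: int = 6) -> pd.DataFrame:
    """Run-length encode per-base coverage arrays into a bedGraph frame
    (zero runs are kept so the track covers the chromosome)."""
    rows = []
    for chrom in sorted(coverage):
        arr = np.round(coverage[chrom], decimals)
        if len(arr) == 0:
            continue
        change = np.nonzero(np.diff(arr))[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(arr)]])
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e), float(arr[s])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
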