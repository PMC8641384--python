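"""Synthetic cis-eQTL data generator.

Emulates the statistical structure the benchmarking analysis assumes:
diploid dosage genotypes with local LD, one or two populations diverged by a
target Wright's Fst, per-gene expression with a cis-genetic component of
chosen sparsity and heritability, an optional second "tissue" with partially
shared causal effects, and a binary trait mediated by one gene's genetic
expression.

Model choices (deliberately simple and analytically checkable):

* population divergence — Balding-Nichols: per-SNP population frequencies are
  Beta(p(1-F)/F, (1-p)(1-F)/F) draws around the ancestral frequency p;
* local LD — haplotypes are thresholded AR(1) latent Gaussians: adjacent SNPs
  share latent correlation ``ld_rho`` and the threshold is the population
  frequency quantile, so marginal allele frequencies are exact;
* genome layout — each gene sits at the center of its own 2.2 Mb segment
  (one segment per chromosome), so the 1 Mb cis-window rule excises the
  outer flanks non-trivially.

Expression is emitted directly on the normalized (Gaussian) scale that the
prediction models operate on; RNA-seq count noise and normalization are out
of scope.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.optimize import brentq

from .genio import EmptyPanelError, ExpressionPanel, GenotypePanel, extract_cis

SEGMENT_LENGTH = 2_200_000
GENE_LENGTH = 20_000

POPULATIONS = ("popA", "popB")


class SimulationError(ValueError):
    """Invalid simulation parameter."""


@dataclass
class SimConfig:
    """Design knobs of the synthetic cohort.

    Attributes
    ----------
    n_samples
        Samples per population (one entry per population, up to two).  The
        default 373/89 split mirrors a two-ancestry reference cohort.
    n_snps
        SNPs per 2.2 Mb gene segment.
    maf_range
        Ancestral allele frequencies are uniform on this interval (within
        (0, 0.5]).
    ld_rho
        AR(1) latent correlation between adjacent SNPs, in [0, 1).  A tuple
        gives each population its own LD decay.
    fst
        Wright's fixation index for the Balding-Nichols divergence model.
    architecture
        ``"sparse"`` (``n_causal`` effects, large) or ``"polygenic"``
        (every cis SNP contributes).
    h2_cis
        Target cis-heritability of expression, in [0, 1]; a tuple gives one
        value per gene (real genes vary widely).  Enforced exactly in-sample
        for sparse genes, in expectation for polygenic genes.
    tissue_sharing
        ``None`` for a single tissue; otherwise the probability that each
        causal effect is shared with a second tissue (non-shared effects are
        redrawn independently).
    """

    n_samples: tuple[int, ...] = (373, 89)
    n_snps: int = 120
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float | tuple[float, ...] = 0.7
    fst: float = 0.0
    n_genes: int = 10
    architecture: str = "sparse"
    n_causal: int = 2
    h2_cis: float | tuple[float, ...] = 0.2
    tissue_sharing: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_samples, int):
            self.n_samples = (self.n_samples,)
        if not 0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise SimulationError("maf_range must lie within (0, 0.5]")
        if self.fst < 0:
            raise SimulationError("fst must be >= 0")
        if self.fst >= 1:
            raise SimulationError("fst must be < 1")
        h2s = self.h2_cis if isinstance(self.h2_cis, tuple) else (self.h2_cis,)
        if any(not 0.0 <= h <= 1.0 for h in h2s):
            raise SimulationError("h2_cis must lie in [0, 1]")
        if isinstance(self.h2_cis, tuple) and len(self.h2_cis) != self.n_genes:
            raise SimulationError("per-gene h2_cis needs one value per gene")
        if self.architecture not in ("sparse", "polygenic"):
            raise SimulationError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "sparse" and self.n_causal > self.n_snps:
            raise SimulationError("n_causal exceeds n_snps")
        if self.tissue_sharing is not None and not 0.0 <= self.tissue_sharing <= 1.0:
            raise SimulationError("tissue_sharing must lie in [0, 1]")
        rhos = self.ld_rho if isinstance(self.ld_rho, tuple) else (self.ld_rho,)
        for r in rhos:
            if not 0.0 <= r < 1.0:
                raise SimulationError("ld_rho must lie in [0, 1)")

    @property
    def n_populations(self) -> int:
        return len(self.n_samples)

    def ld_rho_for(self, pop_index: int) -> float:
        if isinstance(self.ld_rho, tuple):
            return self.ld_rho[pop_index]
        return self.ld_rho

    def h2_for(self, gene_index: int) -> float:
        if isinstance(self.h2_cis, tuple):
            return self.h2_cis[gene_index]
        return self.h2_cis


@dataclass
class SimTruth:
    """Hidden parameters of a simulated cohort, for recovery tests."""

    causal_indices: dict[str, np.ndarray] = field(default_factory=dict)
    causal_effects: dict[str, np.ndarray] = field(default_factory=dict)
    causal_effects_b: dict[str, np.ndarray] = field(default_factory=dict)
    realized_h2: dict[str, float] = field(default_factory=dict)
    ancestral_freqs: np.ndarray | None = None
    population_freqs: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, idx in self.causal_indices.items():
            eff = self.causal_effects[gene]
            for i, b in zip(idx, eff):
                rows.append((gene, int(i), float(b), self.realized_h2[gene]))
        return pd.DataFrame(rows, columns=["gene", "snp_index", "beta_std", "realized_h2"])


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def draw_population_freqs(ancestral_freqs, fst, seed=None, n_pops=2, rng=None):
    """Balding-Nichols population frequencies around ancestral frequencies.

    Each population's frequency at each SNP is an independent
    Beta(p(1-F)/F, (1-p)(1-F)/F) draw; ``fst = 0`` degenerates to the
    ancestral frequencies.  Output is clipped to (0.001, 0.999).
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise SimulationError("ancestral frequencies must lie strictly in (0, 1)")
    if fst < 0:
        raise SimulationError("fst must be >= 0")
    if fst >= 1:
        raise SimulationError("fst must be < 1")
    if fst == 0:
        return np.tile(p, (n_pops, 1))
    if rng is None:
        rng = np.random.default_rng(seed)
    scale = (1.0 - fst) / fst
    out = rng.beta(p * scale, (1.0 - p) * scale, size=(n_pops, p.size))
    return np.clip(out, 0.001, 0.999)


def _ar1_haplotypes(n_hap: int, freqs: np.ndarray, rho: float, rng) -> np.ndarray:
    """Haplotypes from an AR(1) latent Gaussian thresholded at the frequency
    quantile; P(allele=1 at SNP j) equals ``freqs[j]`` exactly."""
    p = freqs.size
    z = np.empty((n_hap, p))
    z[:, 0] = rng.standard_normal(n_hap)
    if p > 1:
        e = rng.standard_normal((n_hap, p - 1))
        c = np.sqrt(1.0 - rho ** 2)
        for j in range(1, p):
            z[:, j] = rho * z[:, j - 1] + c * e[:, j - 1]
    return (z < ndtri(freqs)).astype(float)


def simulate_genotypes(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Generate a multi-gene, one-or-two-population dosage panel.

    Dosages are sums of two independent AR(1)-latent haplotypes per sample,
    so values are exactly {0, 1, 2}.  SNPs whose realized MAF falls below
    0.01 in any population are removed (the per-population QC the analysis
    would otherwise apply), keeping a single shared SNP set.
    """
    rng = np.random.default_rng(config.seed)
    n_pops = config.n_populations
    blocks, snp_frames = [], []
    anc_all, pop_all = [], []
    for g in range(config.n_genes):
        chrom = f"chr{g + 1}"
        anc = rng.uniform(*config.maf_range, size=config.n_snps)
        pops = draw_population_freqs(anc, config.fst, n_pops=n_pops, rng=rng)
        pos = np.sort(rng.choice(SEGMENT_LENGTH, size=config.n_snps, replace=False)) + 1
        dos = []
        for k, n in enumerate(config.n_samples):
            h1 = _ar1_haplotypes(n, pops[k], config.ld_rho_for(k), rng)
            h2 = _ar1_haplotypes(n, pops[k], config.ld_rho_for(k), rng)
            dos.append(h1 + h2)
        blocks.append(np.vstack(dos))
        snp_frames.append(pd.DataFrame(dict(
            id=[f"g{g}_snp{j}" for j in range(config.n_snps)],
            chrom=chrom, pos=pos, ref="A", alt="B",
        )))
        anc_all.append(anc)
        pop_all.append(pops)
    dosages = np.hstack(blocks)
    snps = pd.concat(snp_frames, ignore_index=True)
    sample_rows = []
    for k, n in enumerate(config.n_samples):
        lab = POPULATIONS[k]
        sample_rows += [(f"{lab}_s{i}", lab) for i in range(n)]
    samples = pd.DataFrame(sample_rows, columns=["id", "population"])
    panel = GenotypePanel(dosages, snps, samples)

    # per-population MAF >= 0.01 in every population
    keep = np.ones(panel.n_snps, dtype=bool)
    offset = 0
    for k, n in enumerate(config.n_samples):
        sub = panel.dosages[offset:offset + n]
        p = sub.mean(axis=0) / 2.0
        keep &= np.minimum(p, 1 - p) >= 0.01
        offset += n
    if not keep.any():
        raise EmptyPanelError("all simulated SNPs failed the MAF filter")
    panel = panel.subset_snps(keep)

    truth = SimTruth(
        ancestral_freqs=np.concatenate(anc_all)[keep],
        population_freqs=np.hstack(pop_all)[:, keep],
    )
    return panel, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> np.ndarray:
    c = X.mean(axis=0)
    s = X.std(axis=0)
    s[s < 1e-12] = 1.0
    return (X - c) / s


def _rescale_to_h2(g: np.ndarray, eps: np.ndarray, h2: float):
    """Scale genetic value and noise so var(g)/(var(g)+var(eps)) = h2 exactly."""
    vg, ve = g.var(), eps.var()
    if h2 == 0.0 or vg < 1e-30:
        return np.zeros_like(g), eps / np.sqrt(ve) if ve > 0 else eps, 0.0
    g = g * np.sqrt(h2 / vg)
    eps = eps * np.sqrt((1.0 - h2) / ve)
    return g, eps, np.sqrt(h2 / vg)


def simulate_expression(panel: GenotypePanel, config: SimConfig, truth: SimTruth | None = None,
                        seed: int | None = None):
    """Simulate per-gene expression ``y = X_std beta + eps`` on the panel.

    Sparse genes draw ``n_causal`` effects N(0, 1) among the gene's
    cis-window SNPs and rescale so the in-sample heritability is exactly
    ``h2_cis``; polygenic genes give every cis SNP an effect N(0, h2/p).
    When ``tissue_sharing`` is set a second tissue's expression is emitted:
    each causal effect is retained with that probability, otherwise replaced
    with an independent draw.

    Returns ``(expr, truth)`` or ``(expr, expr_b, truth)``.
    """
    if panel.n_snps == 0 or panel.n_samples == 0:
        raise EmptyPanelError("cannot simulate expression on an empty panel")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    truth = truth if truth is not None else SimTruth()
    genes = []
    chroms = pd.unique(panel.snps["chrom"])
    start = (SEGMENT_LENGTH - GENE_LENGTH) // 2
    for g, chrom in enumerate(chroms[: config.n_genes]):
        genes.append(dict(id=f"gene{g}", chrom=chrom, start=start, end=start + GENE_LENGTH))
    gene_df = pd.DataFrame(genes)

    Xs_all = _standardize(panel.dosages)
    two_tissues = config.tissue_sharing is not None
    Y = np.empty((panel.n_samples, len(genes)))
    Yb = np.empty_like(Y) if two_tissues else None
    for gi, gene in enumerate(genes):
        h2_gene = config.h2_for(gi)
        cis = extract_cis(panel, gene)
        cis_cols = pd.Index(panel.snp_ids).get_indexer(cis.snp_ids)
        p_cis = len(cis_cols)
        if config.architecture == "sparse":
            nc = min(config.n_causal, p_cis)
            causal = np.sort(rng.choice(cis_cols, size=nc, replace=False))
            beta = rng.standard_normal(nc)
        else:
            causal = np.asarray(cis_cols)
            beta = rng.standard_normal(p_cis) * np.sqrt(h2_gene / p_cis)
        eps = rng.standard_normal(panel.n_samples)
        gval = Xs_all[:, causal] @ beta
        if config.architecture == "sparse":
            gval, eps, scale = _rescale_to_h2(gval, eps, h2_gene)
            beta = beta * scale
            realized = h2_gene if scale > 0 else 0.0
        else:
            eps = eps * np.sqrt(max(1.0 - h2_gene, 0.0))
            vg, ve = gval.var(), eps.var()
            realized = vg / (vg + ve) if vg + ve > 0 else 0.0
        if h2_gene == 0.0:
            beta = np.zeros_like(beta)
            gval = np.zeros_like(gval)
            realized = 0.0
        Y[:, gi] = gval + eps
        truth.causal_indices[gene["id"]] = causal
        truth.causal_effects[gene["id"]] = beta
        truth.realized_h2[gene["id"]] = float(realized)
        if two_tissues:
            shared = rng.random(beta.size) < config.tissue_sharing
            beta_b = np.where(shared, beta, rng.standard_normal(beta.size) * _rms(beta))
            gb = Xs_all[:, causal] @ beta_b
            eb = rng.standard_normal(panel.n_samples)
            if config.architecture == "sparse" and h2_gene > 0:
                gb, eb, sb = _rescale_to_h2(gb, eb, h2_gene)
                beta_b = beta_b * sb
            else:
                eb = eb * np.sqrt(max(1.0 - h2_gene, 0.0))
            Yb[:, gi] = gb + eb
            truth.causal_effects_b[gene["id"]] = beta_b
    expr = ExpressionPanel(Y, gene_df, panel.sample_ids)
    if two_tissues:
        return expr, ExpressionPanel(Yb, gene_df.copy(), panel.sample_ids), truth
    return expr, truth


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x ** 2))) if x.size else 1.0


def simulate_cohort(config: SimConfig):
    """Genotypes + expression (+ second tissue) in one call."""
    panel, truth = simulate_genotypes(config)
    out = simulate_expression(panel, config, truth)
    if config.tissue_sharing is not None:
        expr, expr_b, truth = out
        return panel, expr, expr_b, truth
    expr, truth = out
    return panel, expr, truth


# ---------------------------------------------------------------------------
# binary trait
# ---------------------------------------------------------------------------

def simulate_case_control(panel: GenotypePanel, truth: SimTruth, gene: str,
                          odds_scale: float, prevalence: float, seed: int) -> np.ndarray:
    """Binary trait mediated by one gene's genetic expression component.

    Disease probability is ``expit(c + odds_scale * g)`` with ``g`` the
    standardized genetic value ``X_std beta_true`` of the mediating gene and
    the intercept ``c`` solved so the expected prevalence matches.
    ``odds_scale = 0`` gives a pure-null trait.
    """
    if gene not in truth.causal_indices:
        raise KeyError(f"unknown gene {gene!r} in simulation truth")
    if not 0.0 < prevalence < 1.0:
        raise SimulationError("prevalence must lie in (0, 1)")
    if np.isnan(panel.dosages).any():
        raise SimulationError("panel contains missing dosages; apply qc_filter first")
    rng = np.random.default_rng(seed)
    idx = truth.causal_indices[gene]
    beta = truth.causal_effects[gene]
    g = _standardize(panel.dosages[:, idx]) @ beta if len(idx) else np.zeros(panel.n_samples)
    sd = g.std()
    if sd > 1e-12:
        g = (g - g.mean()) / sd
    eta = odds_scale * g
    c = brentq(lambda c0: expit(c0 + eta).mean() - prevalence, -40, 40)
    return (rng.random(panel.n_samples) < expit(c + eta)).astype(int)


# ---------------------------------------------------------------------------
# estimators on truth (used for calibration checks)
# ---------------------------------------------------------------------------

def hudson_fst(dos_a: np.ndarray, dos_b: np.ndarray) -> float:
    """Hudson's Fst estimator (ratio of averages) from two dosage matrices."""
    n1, n2 = 2 * dos_a.shape[0], 2 * dos_b.shape[0]
    p1 = dos_a.mean(axis=0) / 2.0
    p2 = dos_b.mean(axis=0) / 2.0
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return float(num[ok].sum() / den[ok].sum())
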