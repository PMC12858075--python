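"""Synthetic genotypes, effect sizes, phenotypes, and GWAS statistics.

The generator reproduces the statistical structure the model assumes:

* Genotypes: per block, a latent Gaussian AR(1) process per haplotype is
  thresholded to Hardy-Weinberg allele counts at a drawn minor-allele
  frequency, giving LD within blocks and independence across blocks.
* Effects: a five-part mixture — null for both traits (p0), non-zero for
  only one trait (p1, p2), shared with high correlation r_share1 (p3),
  and shared with a second correlation r_share2 (p4).  Per-class
  variances are ``h1^2 / (M (p1+p3+p4))`` for trait 1 and
  ``h2^2 / (M (p2+p3+p4))`` for trait 2, with cross-covariance
  ``r * h1 h2 / (M sqrt((p1+p3+p4)(p2+p3+p4)))`` in the shared classes.
  Drawn effects are then rescaled so the realized genetic variance on
  the training cohort hits the target heritability exactly.
* Phenotypes: ``Y_t = X_t beta_t + eps_t`` with residual variance
  ``1 - h_t^2``; individuals present in both cohorts (the first ns rows)
  receive jointly drawn residuals with covariance rho_e.
* Summary statistics: per-SNP marginal regression of the phenotype on
  the standardized dosage, so outputs are already on the model's scale.

Defaults follow the simulation design the model targets: M = 30,000
SNPs, 20,000 training individuals per trait, heritabilities 0.15/0.30,
mixture (0.88, 0.02, 0.02, 0.01, 0.07), shared correlations 0.9 and
one of {0.5, 0.7, 0.9}, environmental covariance 0.2 under overlap, 10
replicates, 10,000-individual validation and test sets.  Every piece
accepts overrides so the same machinery serves desk-scale fixtures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .gwas_io import GenotypeMatrix, InputError, SummaryStats, write_genotypes, write_sumstats

logger = logging.getLogger(__name__)

SCENARIOS = ("no_overlap", "partial_overlap", "complete_overlap", "small_n")


@dataclass
class SimulationConfig:
    """Study conditions of the simulation design."""

    m: int = 30_000
    n1: int = 20_000
    n2: int = 20_000
    ns: int = 0
    n_validation: int = 10_000
    n_test: int = 10_000
    n_panel: int = 503
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 100
    #: latent AR(1) coefficient within a block; a (lo, hi) pair draws one
    #: coefficient per block, emulating the strong LD heterogeneity of real
    #: genomes (which the cross-trait LD-score regression relies on)
    ld_decay: float | tuple[float, float] = (0.3, 0.95)
    p: tuple[float, ...] = (0.88, 0.02, 0.02, 0.01, 0.07)
    h1_sq: float = 0.15
    h2_sq: float = 0.30
    r_share1: float = 0.9
    r_share2: float = 0.9          # one of {0.5, 0.7, 0.9} in the study design
    rho_e: float = 0.2
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if len(p) != 5 or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise InputError("mixture proportions must be 5 non-negatives summing to 1")
        for h in (self.h1_sq, self.h2_sq):
            if not 0 < h < 1:
                raise InputError("heritabilities must be in (0, 1)")
        for r in (self.r_share1, self.r_share2):
            if abs(r) > 1:
                raise InputError("|shared correlation| must be <= 1")
        if self.ns > min(self.n1, self.n2):
            raise InputError("ns cannot exceed min(n1, n2)")
        rr = self.rho_e / np.sqrt((1 - self.h1_sq) * (1 - self.h2_sq))
        if not -1 < rr < 1:
            raise InputError(
                f"implied residual correlation {rr:.3f} outside (-1, 1)"
            )

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Genome:
    """Fixed per-SNP properties shared by every simulated cohort."""

    maf: np.ndarray
    thresholds: np.ndarray       # Phi^{-1}(maf), haplotype latent cut
    block_bounds: list[tuple[int, int]]
    decay: np.ndarray            # per-block latent AR(1) coefficient
    snp_ids: np.ndarray
    counted_allele: np.ndarray
    other_allele: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray


@dataclass
class SimulationTruth:
    """Generating effects and labels, plus the phenotypes per cohort."""

    beta1: np.ndarray
    beta2: np.ndarray
    class_label: np.ndarray      # 0..4 per SNP
    genome: Genome
    phenotypes: dict = field(default_factory=dict)


def _make_genome(cfg: SimulationConfig, rng: np.random.Generator) -> Genome:
    maf = rng.uniform(*cfg.maf_range, size=cfg.m)
    bounds = [
        (s, min(s + cfg.ld_block_size, cfg.m))
        for s in range(0, cfg.m, cfg.ld_block_size)
    ]
    if np.isscalar(cfg.ld_decay):
        decay = np.full(len(bounds), float(cfg.ld_decay))
    else:
        lo, hi = cfg.ld_decay
        decay = rng.uniform(lo, hi, size=len(bounds))
    alleles = np.array(["A", "C", "G", "T"])
    a1_idx = rng.integers(0, 4, size=cfg.m)
    # pick a non-ambiguous partner (complement pairs excluded)
    partner = {0: [1, 2], 1: [0, 3], 2: [0, 3], 3: [1, 2]}  # A:C/G, C:A/T, ...
    a2_idx = np.array([rng.choice(partner[int(i)]) for i in a1_idx])
    return Genome(
        maf=maf,
        thresholds=sps.norm.ppf(maf),
        block_bounds=bounds,
        decay=decay,
        snp_ids=np.array([f"snp{j:07d}" for j in range(cfg.m)]),
        counted_allele=alleles[a1_idx],
        other_allele=alleles[a2_idx],
        chrom=np.ones(cfg.m, dtype=int),
        pos=np.arange(1, cfg.m + 1) * 1000,
    )


def _haplotypes(
    genome: Genome, n: int, rng: np.random.Generator
) -> np.ndarray:
    """One haplotype matrix (n x m) of 0/1 alleles with AR(1) latent LD."""
    m = len(genome.maf)
    hap = np.empty((n, m), dtype=np.int8)
    for bi, (s, e) in enumerate(genome.block_bounds):
        phi = genome.decay[bi]
        innov_sd = np.sqrt(1.0 - phi**2)
        L = e - s
        z = np.empty((n, L))
        z[:, 0] = rng.standard_normal(n)
        eps = rng.standard_normal((n, L))
        for i in range(1, L):
            z[:, i] = phi * z[:, i - 1] + innov_sd * eps[:, i]
        hap[:, s:e] = z < genome.thresholds[s:e]
    return hap


def simulate_genotypes(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    n: int | None = None,
    genome: Genome | None = None,
    sample_prefix: str = "ind",
) -> tuple[GenotypeMatrix, Genome]:
    """Simulate an n x m dosage matrix under Hardy-Weinberg equilibrium."""
    if genome is None:
        genome = _make_genome(cfg, rng)
    n = cfg.n1 if n is None else n
    dosages = (
        _haplotypes(genome, n, rng) + _haplotypes(genome, n, rng)
    ).astype(float)
    width = max(6, len(str(n)))
    gm = GenotypeMatrix(
        samples=np.array([f"{sample_prefix}_{i:0{width}d}" for i in range(n)]),
        snp_ids=genome.snp_ids,
        dosages=dosages,
        counted_allele=genome.counted_allele,
        other_allele=genome.other_allele,
        chrom=genome.chrom,
        pos=genome.pos,
    )
    return gm, genome


def latent_to_dosage_correlation(maf_i: float, maf_j: float, phi: float) -> float:
    """Dosage-scale Pearson correlation implied by latent correlation phi.

    The thresholded-Gaussian model attenuates the latent correlation:
    for allele indicators with cuts t_i, t_j,
    corr = (P(z_i < t_i, z_j < t_j) - maf_i maf_j) /
    sqrt(maf_i (1-maf_i) maf_j (1-maf_j)); summing two independent
    haplotypes leaves the correlation unchanged.
    """
    t_i, t_j = sps.norm.ppf(maf_i), sps.norm.ppf(maf_j)
    joint = sps.multivariate_normal(cov=[[1.0, phi], [phi, 1.0]]).cdf([t_i, t_j])
    return (joint - maf_i * maf_j) / np.sqrt(
        maf_i * (1 - maf_i) * maf_j * (1 - maf_j)
    )


def simulate_effects(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-SNP class labels and bivariate effects from the mixture.

    Returns (beta1, beta2, class_label); effects are on the
    standardized-genotype scale and *not yet* rescaled to exact
    heritability (see :func:`rescale_effects`).
    """
    p = np.asarray(cfg.p)
    labels = rng.choice(5, size=cfg.m, p=p)
    causal1 = p[1] + p[3] + p[4]
    causal2 = p[2] + p[3] + p[4]
    v1 = cfg.h1_sq / (cfg.m * causal1)
    v2 = cfg.h2_sq / (cfg.m * causal2)

    beta1 = np.zeros(cfg.m)
    beta2 = np.zeros(cfg.m)
    only1 = labels == 1
    only2 = labels == 2
    beta1[only1] = rng.normal(0.0, np.sqrt(v1), size=only1.sum())
    beta2[only2] = rng.normal(0.0, np.sqrt(v2), size=only2.sum())
    for cls, r in ((3, cfg.r_share1), (4, cfg.r_share2)):
        mask = labels == cls
        cov = np.array(
            [[v1, r * np.sqrt(v1 * v2)], [r * np.sqrt(v1 * v2), v2]]
        )
        draws = rng.multivariate_normal(
            np.zeros(2), cov, size=int(mask.sum()), method="cholesky"
        )
        beta1[mask] = draws[:, 0]
        beta2[mask] = draws[:, 1]
    return beta1, beta2, labels


def rescale_effects(
    X_std: np.ndarray, beta: np.ndarray, h_sq: float
) -> np.ndarray:
    """Scale effects so var(X beta) on this cohort equals h_sq exactly."""
    g = X_std @ beta
    var_g = g.var()
    if var_g == 0:
        raise InputError("no genetic variance to rescale (all effects zero?)")
    return beta * np.sqrt(h_sq / var_g)


def simulate_phenotypes(
    X1_std: np.ndarray,
    X2_std: np.ndarray,
    beta1: np.ndarray,
    beta2: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    ns: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Phenotypes with exact variance decomposition and overlap residuals.

    The first ``ns`` rows of both cohorts are assumed to be the same
    individuals; their residual pairs are drawn jointly with covariance
    rho_e.  Residuals are projected orthogonal to the genetic values and
    rescaled so each trait's realized heritability is exact.
    """
    ns = cfg.ns if ns is None else ns
    n1, n2 = X1_std.shape[0], X2_std.shape[0]
    if ns > min(n1, n2):
        raise InputError("overlap larger than a cohort")

    g1 = X1_std @ beta1
    g2 = X2_std @ beta2

    e1 = np.sqrt(1.0 - cfg.h1_sq) * rng.standard_normal(n1)
    e2 = np.sqrt(1.0 - cfg.h2_sq) * rng.standard_normal(n2)
    if ns > 0:
        cov = np.array(
            [[1.0 - cfg.h1_sq, cfg.rho_e], [cfg.rho_e, 1.0 - cfg.h2_sq]]
        )
        joint = rng.multivariate_normal(np.zeros(2), cov, size=ns, method="cholesky")
        e1[:ns] = joint[:, 0]
        e2[:ns] = joint[:, 1]

    def exactify(e: np.ndarray, g: np.ndarray, target_var: float) -> np.ndarray:
        gc = g - g.mean()
        denom = gc @ gc
        if denom > 0:
            e = e - gc * (gc @ e) / denom
        e = e - e.mean()
        return e * np.sqrt(target_var / e.var())

    e1 = exactify(e1, g1, 1.0 - cfg.h1_sq)
    e2 = exactify(e2, g2, 1.0 - cfg.h2_sq)
    return g1 + e1, g2 + e2


def make_sumstats(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    trait_label: str = "",
    standardized: bool = True,
) -> SummaryStats:
    """Per-SNP marginal regression of the phenotype on each variant.

    With ``standardized=True`` (default) the regressor is the
    standardized dosage and the phenotype is variance-standardized, so
    ``beta_hat`` is the Pearson correlation — the model's native scale.
    With ``standardized=False`` effects are on the allele-count scale
    (for I/O round-trip exercises).
    """
    n = gm.n_samples
    if len(phenotype) != n:
        raise InputError("phenotype length must equal the number of samples")
    y = np.asarray(phenotype, dtype=float)
    y = (y - y.mean()) / y.std() if standardized else y - y.mean()

    X = gm.standardized() if standardized else _centered_dosages(gm)
    denom = (X**2).sum(axis=0)
    mono = denom == 0
    denom[mono] = 1.0
    beta = (X.T @ y) / denom
    resid_ss = (y @ y) - beta**2 * denom
    dof = max(n - 2, 1)
    se = np.sqrt(np.maximum(resid_ss, 1e-300) / dof / denom)
    if mono.any():
        logger.warning("%d monomorphic SNPs: beta set to 0", int(mono.sum()))
        beta[mono] = 0.0
        se[mono] = np.sqrt((y @ y) / dof / n)
    return SummaryStats(
        snp_id=gm.snp_ids,
        effect_allele=gm.counted_allele,
        other_allele=gm.other_allele,
        beta_hat=beta,
        se=se,
        n=np.full(gm.n_snps, float(n)),
        trait_label=trait_label,
    )


def _centered_dosages(gm: GenotypeMatrix) -> np.ndarray:
    X = gm.dosages.astype(float).copy()
    mu = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(mu, np.nonzero(nan_mask)[1])
    return X - X.mean(axis=0)


@dataclass
class ScenarioBundle:
    """Everything one replicate of a scenario produces."""

    cfg: SimulationConfig
    scenario: str
    ss1: SummaryStats
    ss2: SummaryStats
    panel: GenotypeMatrix
    validation: tuple[GenotypeMatrix, np.ndarray, np.ndarray]
    test: tuple[GenotypeMatrix, np.ndarray, np.ndarray]
    truth: SimulationTruth
    manifest: dict


def run_scenario(
    name: str,
    cfg: SimulationConfig | None = None,
    overrides: dict | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> ScenarioBundle:
    """Produce a complete fixture bundle for one overlap scenario.

    ``no_overlap``: independent training cohorts; ``partial_overlap``:
    half of each cohort shared (10,000 at the design scale);
    ``complete_overlap``: one cohort serves both GWAS; ``small_n``:
    independent cohorts at half size.  Training cohorts, an external
    reference panel, and validation/test cohorts are all drawn from the
    same genome.
    """
    if name not in SCENARIOS:
        raise InputError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    cfg = SimulationConfig() if cfg is None else cfg
    if overrides:
        cfg = cfg.replace(**overrides)
    if name == "no_overlap":
        cfg = cfg.replace(ns=0)
    elif name == "partial_overlap":
        cfg = cfg.replace(ns=min(cfg.n1, cfg.n2) // 2 if cfg.ns == 0 else cfg.ns)
    elif name == "complete_overlap":
        cfg = cfg.replace(ns=min(cfg.n1, cfg.n2), n2=cfg.n1)
    elif name == "small_n":
        cfg = cfg.replace(ns=0, n1=cfg.n1 // 2, n2=cfg.n2 // 2)
    if seed is not None:
        cfg = cfg.replace(seed=seed)

    rng = np.random.default_rng(cfg.seed)
    genome = _make_genome(cfg, rng)

    # one pool so overlapping individuals share genotype rows
    n_unique = cfg.n1 + (cfg.n2 - cfg.ns)
    pool, _ = simulate_genotypes(cfg, rng, n=n_unique, genome=genome, sample_prefix="train")
    rows1 = np.arange(cfg.n1)
    rows2 = np.concatenate([np.arange(cfg.ns), np.arange(cfg.n1, n_unique)])
    gm1 = GenotypeMatrix(
        samples=pool.samples[rows1], snp_ids=genome.snp_ids,
        dosages=pool.dosages[rows1], counted_allele=genome.counted_allele,
        other_allele=genome.other_allele, chrom=genome.chrom, pos=genome.pos,
    )
    gm2 = GenotypeMatrix(
        samples=pool.samples[rows2], snp_ids=genome.snp_ids,
        dosages=pool.dosages[rows2], counted_allele=genome.counted_allele,
        other_allele=genome.other_allele, chrom=genome.chrom, pos=genome.pos,
    )

    beta1, beta2, labels = simulate_effects(cfg, rng)
    X1 = gm1.standardized()
    X2 = gm2.standardized()
    beta1 = rescale_effects(X1, beta1, cfg.h1_sq)
    beta2 = rescale_effects(X2, beta2, cfg.h2_sq)
    y1, y2 = simulate_phenotypes(X1, X2, beta1, beta2, cfg, rng)

    ss1 = make_sumstats(gm1, y1, trait_label="trait1")
    ss2 = make_sumstats(gm2, y2, trait_label="trait2")

    panel, _ = simulate_genotypes(cfg, rng, n=cfg.n_panel, genome=genome,
                                  sample_prefix="panel")
    val_gm, _ = simulate_genotypes(cfg, rng, n=cfg.n_validation, genome=genome,
                                   sample_prefix="val")
    test_gm, _ = simulate_genotypes(cfg, rng, n=cfg.n_test, genome=genome,
                                    sample_prefix="test")
    yv1, yv2 = simulate_phenotypes(
        val_gm.standardized(), val_gm.standardized(), beta1, beta2, cfg, rng, ns=0
    )
    yt1, yt2 = simulate_phenotypes(
        test_gm.standardized(), test_gm.standardized(), beta1, beta2, cfg, rng, ns=0
    )

    truth = SimulationTruth(
        beta1=beta1, beta2=beta2, class_label=labels, genome=genome,
        phenotypes={"train1": y1, "train2": y2},
    )
    manifest = {
        "scenario": name,
        "seed": cfg.seed,
        "m": cfg.m,
        "n1": cfg.n1,
        "n2": cfg.n2,
        "ns": cfg.ns,
        "n_replicates": cfg.n_replicates,
        "h1_sq": cfg.h1_sq,
        "h2_sq": cfg.h2_sq,
        "p": list(cfg.p),
        "r_share1": cfg.r_share1,
        "r_share2": cfg.r_share2,
        "rho_e": cfg.rho_e,
    }
    bundle = ScenarioBundle(
        cfg=cfg, scenario=name, ss1=ss1, ss2=ss2, panel=panel,
        validation=(val_gm, yv1, yv2), test=(test_gm, yt1, yt2),
        truth=truth, manifest=manifest,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: ScenarioBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_sumstats(bundle.ss1, outdir / "trait1.sumstats.txt")
    write_sumstats(bundle.ss2, outdir / "trait2.sumstats.txt")
    write_genotypes(bundle.panel, outdir / "panel")
    for tag, (gm, y1, y2) in (("validation", bundle.validation), ("test", bundle.test)):
        write_genotypes(gm, outdir / tag)
        np.savetxt(
            outdir / f"{tag}.pheno.txt",
            np.column_stack([y1, y2]),
            header="trait1\ttrait2", comments="", delimiter="\t",
        )
    truth = bundle.truth
    np.savetxt(
        outdir / "truth.effects.txt",
        np.column_stack([truth.beta1, truth.beta2, truth.class_label]),
        header="beta1\tbeta2\tclass", comments="", delimiter="\t",
    )
    (outdir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))
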