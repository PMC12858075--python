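"""Blocked Gibbs sampler for the bivariate effect-size model.

The stacked per-block statistic (beta_hat_1; beta_hat_2) is modeled as
Normal with mean (I_2 (x) D) beta and covariance Omega (x) A, where
A = D + a*I and Omega is the 2x2 per-SNP sampling matrix from the
overlap model.  The Kronecker structure turns every per-SNP conditional
into a 2x2 problem: given the residuals of all other SNPs, beta_j has a
Gaussian conditional likelihood with precision ``P = q_j * Omega^{-1}``
(``q_j = (D A^{-1} D)_jj``) and natural parameter ``b = Omega^{-1} v_j``.

Each iteration sweeps every block (assignments collapsed over beta_j,
then conjugate redraw of beta_j), then updates all global mixture
parameters from their conjugate conditionals.  Posterior-mean effects
are averaged over post-burn-in, thinned iterations.  Runs are
deterministic given the seed; each (iteration, block) pair gets its own
RNG substream derived from the master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from ._sweep import sweep_block_kernel
from .gwas_io import HarmonizedPair, InputError
from .ld import LDBlock
from .overlap import OverlapModel
from .priors import (
    MixtureParams,
    PriorConfig,
    marginal_logratios,
    sample_invwishart_2x2,
    sample_mixture,
    sample_stick_fractions,
    weights_from_sticks,
)

logger = logging.getLogger(__name__)

#: class sets fitted in each mode; "single1"/"single2" are the
#: single-trait special cases used by the decoupled ablation
MODE_CLASSES = {
    "joint": (0, 1, 2, 3),
    "single1": (0, 1),
    "single2": (0, 2),
}


@dataclass
class MCMCConfig:
    """Sampler protocol: 1,000 iterations with a 200-iteration burn-in."""

    n_iter: int = 1000
    burn_in: int = 200
    thin: int = 1
    seed: int = 0
    a: float = 0.1
    prior: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise InputError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise InputError("thin must be >= 1")


@dataclass
class MCMCState:
    """Current labels, effects, and mixture parameters of the chain."""

    beta: np.ndarray        # (m, 2)
    zc: np.ndarray          # (m,) class in {0, 1, 2, 3}
    zk: np.ndarray          # (m,) component index (0 for the null class)
    mixture: MixtureParams
    overlap: OverlapModel
    iteration: int = 0

    def check_class_invariants(self) -> None:
        if np.any(self.beta[self.zc == 0] != 0):
            raise AssertionError("null-class SNPs must have zero effects")
        if np.any(self.beta[self.zc == 1, 1] != 0):
            raise AssertionError("t1-class SNPs must have beta2 = 0")
        if np.any(self.beta[self.zc == 2, 0] != 0):
            raise AssertionError("t2-class SNPs must have beta1 = 0")


@dataclass
class PosteriorEffects:
    """Posterior summaries on the standardized scale."""

    snp_id: np.ndarray
    counted_allele: np.ndarray
    beta1_mean: np.ndarray
    beta2_mean: np.ndarray
    class_prob: np.ndarray          # (m, 4), rows sum to 1
    diagnostics: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.snp_id,
                "A1": self.counted_allele,
                "BETA1": self.beta1_mean,
                "BETA2": self.beta2_mean,
                "P_NULL": self.class_prob[:, 0],
                "P_TRAIT1": self.class_prob[:, 1],
                "P_TRAIT2": self.class_prob[:, 2],
                "P_SHARED": self.class_prob[:, 3],
            }
        )

    def write(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.8g")


@dataclass
class _BlockData:
    """Per-block precomputations reused by every sweep."""

    start: int
    stop: int
    D: np.ndarray
    H: np.ndarray        # D A^{-1} D
    q: np.ndarray        # diag(H)
    AinvD: np.ndarray    # A^{-1} D
    tv0: np.ndarray      # (2, m_b): D A^{-1} beta_hat_t

    def refresh_stats(self, beta_hat1: np.ndarray, beta_hat2: np.ndarray) -> None:
        """Recompute tv0 for new marginal statistics (full-length arrays)."""
        s, e = self.start, self.stop
        self.tv0 = np.vstack(
            [self.AinvD.T @ beta_hat1[s:e], self.AinvD.T @ beta_hat2[s:e]]
        )


def prepare_blocks(
    blocks: list[LDBlock],
    beta_hat1: np.ndarray,
    beta_hat2: np.ndarray,
) -> list[_BlockData]:
    out = []
    for blk in blocks:
        s, e = blk.start, blk.stop
        cho = cho_factor(blk.A, lower=True)
        AinvD = cho_solve(cho, blk.D)
        H = blk.D @ AinvD
        H = (H + H.T) / 2.0
        bd = _BlockData(
            start=s, stop=e, D=blk.D, H=np.ascontiguousarray(H),
            q=np.ascontiguousarray(np.diag(H)), AinvD=AinvD,
            tv0=np.zeros((2, e - s)),
        )
        bd.refresh_stats(beta_hat1, beta_hat2)
        out.append(bd)
    return out


def simulate_marginal_stats(
    blocks: list[LDBlock],
    beta: np.ndarray,
    overlap: OverlapModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw marginal statistics from the likelihood given true effects.

    Per block, (beta_hat_1; beta_hat_2) ~ N((I_2 (x) D) beta, Omega (x) A).
    This is the generative counterpart of the sampler's likelihood, used
    for posterior-predictive checks and joint-distribution validation.
    """
    m = beta.shape[0]
    bhat1 = np.empty(m)
    bhat2 = np.empty(m)
    cholO = np.linalg.cholesky(overlap.omega)
    for blk in blocks:
        s, e = blk.start, blk.stop
        L = np.linalg.cholesky(blk.A)
        E = cholO @ rng.standard_normal((2, e - s)) @ L.T
        bhat1[s:e] = blk.D @ beta[s:e, 0] + E[0]
        bhat2[s:e] = blk.D @ beta[s:e, 1] + E[1]
    return bhat1, bhat2


def init_state(
    pair: HarmonizedPair,
    blocks: list[LDBlock],
    overlap: OverlapModel,
    cfg: MCMCConfig,
    rng: np.random.Generator | None = None,
) -> MCMCState:
    """All-null starting state with mixture parameters drawn from the prior."""
    if not blocks:
        raise InputError("empty block list")
    total = sum(b.stop - b.start for b in blocks)
    if total != pair.m or blocks[0].start != 0:
        raise InputError(
            f"blocks cover {total} SNPs but the harmonized pair has {pair.m}"
        )
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    m = pair.m
    return MCMCState(
        beta=np.zeros((m, 2)),
        zc=np.zeros(m, dtype=np.int64),
        zk=np.zeros(m, dtype=np.int64),
        mixture=sample_mixture(cfg.prior, rng),
        overlap=overlap,
        iteration=0,
    )


def conditional_moments(
    P: np.ndarray,
    b: np.ndarray,
    class_label: int,
    component: int,
    params: MixtureParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of beta_j's conjugate conditional given z_j.

    ``P`` and ``b`` are the conditional-likelihood precision and natural
    parameter (see module docstring).  Restricted classes return the
    2x2 mean/covariance with zeros on the constrained coordinate.
    """
    mean = np.zeros(2)
    cov = np.zeros((2, 2))
    if class_label == 0:
        return mean, cov
    if class_label == 1:
        prec = P[0, 0] + 1.0 / params.sigma1_sq[component]
        mean[0] = b[0] / prec
        cov[0, 0] = 1.0 / prec
        return mean, cov
    if class_label == 2:
        prec = P[1, 1] + 1.0 / params.sigma2_sq[component]
        mean[1] = b[1] / prec
        cov[1, 1] = 1.0 / prec
        return mean, cov
    Sinv = np.linalg.inv(params.Sigma[component])
    cov = np.linalg.inv(P + Sinv)
    mean = cov @ b
    return mean, cov


def _kernel_args(mixture: MixtureParams, allowed: tuple[int, ...]):
    tiny = 1e-300
    p = mixture.p.copy()
    mask = np.zeros(4, dtype=bool)
    mask[list(allowed)] = True
    p[~mask] = 0.0
    logp = np.log(np.maximum(p, tiny))
    logp[~mask] = -np.inf
    lw1 = logp[1] + np.log(np.maximum(mixture.pi1, tiny))
    lw2 = logp[2] + np.log(np.maximum(mixture.pi2, tiny))
    lw3 = logp[3] + np.log(np.maximum(mixture.pi3, tiny))
    return (
        float(logp[0]),
        lw1, lw2, lw3,
        mixture.sigma1_sq, mixture.sigma2_sq,
        np.ascontiguousarray(mixture.Sigma[:, 0, 0]),
        np.ascontiguousarray(mixture.Sigma[:, 0, 1]),
        np.ascontiguousarray(mixture.Sigma[:, 1, 1]),
    )


def sweep_block(
    bd: _BlockData,
    state: MCMCState,
    seed: int,
    allowed: tuple[int, ...] = (0, 1, 2, 3),
) -> None:
    """Sweep one block in place (assignments + effects + residuals)."""
    s, e = bd.start, bd.stop
    beta_blk = np.ascontiguousarray(state.beta[s:e])
    zc_blk = np.ascontiguousarray(state.zc[s:e])
    zk_blk = np.ascontiguousarray(state.zk[s:e])
    r1 = bd.tv0[0] - bd.H @ beta_blk[:, 0]
    r2 = bd.tv0[1] - bd.H @ beta_blk[:, 1]
    oi = state.overlap.omega_inv
    lp0, lw1, lw2, lw3, s1, s2, S11, S12, S22 = _kernel_args(state.mixture, allowed)
    if not np.isfinite(r1).all() or not np.isfinite(r2).all():
        raise FloatingPointError(f"non-finite residual in block [{s},{e})")
    sweep_block_kernel(
        np.int64(seed), bd.H, bd.q, r1, r2, beta_blk, zc_blk, zk_blk,
        float(oi[0, 0]), float(oi[0, 1]), float(oi[1, 1]),
        lp0, lw1, lw2, lw3, s1, s2, S11, S12, S22,
    )
    state.beta[s:e] = beta_blk
    state.zc[s:e] = zc_blk
    state.zk[s:e] = zk_blk


def update_global(
    state: MCMCState,
    cfg: MCMCConfig,
    rng: np.random.Generator,
    allowed: tuple[int, ...] = (0, 1, 2, 3),
) -> None:
    """Conjugate updates of all mixture parameters given labels and effects."""
    pc = cfg.prior
    K = pc.K
    mix = state.mixture
    zc, zk, beta = state.zc, state.zk, state.beta

    counts = np.bincount(zc, minlength=4).astype(float)
    conc = pc.dirichlet_conc + counts
    p = np.zeros(4)
    idx = list(allowed)
    p[idx] = rng.dirichlet(conc[idx])
    mix.p = p

    def comp_counts(cls: int) -> np.ndarray:
        return np.bincount(zk[zc == cls], minlength=K).astype(float)

    def update_sticks(nk: np.ndarray, alpha: float):
        tail = nk[::-1].cumsum()[::-1] - nk        # sum over m > k
        V = np.empty(K)
        t = np.zeros(K)
        V[: K - 1], t[: K - 1] = sample_stick_fractions(
            1.0 + nk[: K - 1], alpha + tail[: K - 1], K - 1, rng
        )
        V[K - 1] = 1.0
        new_alpha = rng.gamma(
            pc.alpha_shape + (K - 1),
            1.0 / (pc.alpha_rate + t[: K - 1].sum()),
        )
        return V, t, float(new_alpha)

    n1k, n2k, n3k = comp_counts(1), comp_counts(2), comp_counts(3)
    mix.V1, t1, mix.alpha[0] = update_sticks(n1k, mix.alpha[0])
    mix.V2, t2, mix.alpha[1] = update_sticks(n2k, mix.alpha[1])
    mix.V3, t3, mix.alpha[2] = update_sticks(n3k, mix.alpha[2])
    mix.pi1 = weights_from_sticks(mix.V1, t1)
    mix.pi2 = weights_from_sticks(mix.V2, t2)
    mix.pi3 = weights_from_sticks(mix.V3, t3)

    # trait-specific variances: sigma^2 ~ IG(0.5 + n_k/2, hyper + ss_k/2)
    def update_var(cls: int, nk: np.ndarray, col: int, hyper: np.ndarray):
        ss = np.bincount(
            zk[zc == cls], weights=beta[zc == cls, col] ** 2, minlength=K
        )
        shape = pc.ig_shape + nk / 2.0
        rate = hyper + ss / 2.0
        sig = rate / np.maximum(rng.gamma(shape, 1.0), 1e-300)
        return np.maximum(sig, pc.var_floor)

    mix.sigma1_sq = update_var(1, n1k, 0, mix.gamma_k)
    mix.sigma2_sq = update_var(2, n2k, 1, mix.theta_k)
    mix.gamma_k = rng.gamma(
        pc.ig_shape + pc.hyper_gamma_shape,
        1.0 / (pc.hyper_gamma_rate + 1.0 / mix.sigma1_sq),
    )
    mix.theta_k = rng.gamma(
        pc.ig_shape + pc.hyper_gamma_shape,
        1.0 / (pc.hyper_gamma_rate + 1.0 / mix.sigma2_sq),
    )

    # shared covariances: Sigma_k ~ IW(2v+1 + n_k, B_k + S_k)
    shared = zc == 3
    S_11 = np.bincount(zk[shared], weights=beta[shared, 0] ** 2, minlength=K)
    S_22 = np.bincount(zk[shared], weights=beta[shared, 1] ** 2, minlength=K)
    S_12 = np.bincount(
        zk[shared], weights=beta[shared, 0] * beta[shared, 1], minlength=K
    )
    mix.Sigma = sample_invwishart_2x2(
        df=2.0 * pc.v + 1.0 + n3k,
        scale_11=4.0 * pc.v * mix.delta_k + S_11,
        scale_22=4.0 * pc.v * mix.lambda_k + S_22,
        scale_12=S_12,
        rng=rng,
        var_floor=pc.var_floor,
    )
    Sinv_det = (
        mix.Sigma[:, 0, 0] * mix.Sigma[:, 1, 1] - mix.Sigma[:, 0, 1] ** 2
    )
    inv11 = mix.Sigma[:, 1, 1] / Sinv_det
    inv22 = mix.Sigma[:, 0, 0] / Sinv_det
    hshape = pc.hyper_gamma_shape + (2.0 * pc.v + 1.0) / 2.0
    mix.delta_k = rng.gamma(hshape, 1.0 / (pc.hyper_gamma_rate + 2.0 * pc.v * inv11))
    mix.lambda_k = rng.gamma(hshape, 1.0 / (pc.hyper_gamma_rate + 2.0 * pc.v * inv22))

    state.iteration += 1


def run_mcmc(
    pair: HarmonizedPair,
    blocks: list[LDBlock],
    overlap: OverlapModel,
    cfg: MCMCConfig,
    mode: str = "joint",
) -> PosteriorEffects:
    """Fit the model and return posterior-mean effects.

    ``mode`` selects the class structure: "joint" fits the full
    four-class model; "single1"/"single2" fit one trait alone (classes
    {null, that trait}), which is the building block of the decoupled
    ablation used to quantify the benefit of modeling pleiotropy.
    """
    if mode not in MODE_CLASSES:
        raise InputError(f"unknown mode {mode!r}")
    allowed = MODE_CLASSES[mode]
    rng = np.random.default_rng(cfg.seed)
    state = init_state(pair, blocks, overlap, cfg, rng=rng)
    if mode != "joint":
        p = np.zeros(4)
        p[list(allowed)] = 1.0 / len(allowed)
        state.mixture.p = p

    bhat1 = np.zeros(pair.m) if mode == "single2" else pair.beta1
    bhat2 = np.zeros(pair.m) if mode == "single1" else pair.beta2
    block_data = prepare_blocks(blocks, bhat1, bhat2)
    seeds = rng.integers(0, 2**31 - 1, size=(cfg.n_iter, len(block_data)))

    m = pair.m
    beta_sum = np.zeros((m, 2))
    class_count = np.zeros((m, 4))
    n_kept = 0
    diag_counts = np.zeros((cfg.n_iter, 4))
    diag_h2 = np.zeros((cfg.n_iter, 2))

    for it in range(cfg.n_iter):
        for bi, bd in enumerate(block_data):
            sweep_block(bd, state, int(seeds[it, bi]), allowed)
        update_global(state, cfg, rng, allowed)

        diag_counts[it] = np.bincount(state.zc, minlength=4)
        for bd in block_data:
            bb = state.beta[bd.start : bd.stop]
            diag_h2[it, 0] += bb[:, 0] @ bd.D @ bb[:, 0]
            diag_h2[it, 1] += bb[:, 1] @ bd.D @ bb[:, 1]

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            beta_sum += state.beta
            class_count[np.arange(m), state.zc] += 1.0
            n_kept += 1
        if (it + 1) % 50 == 0:
            logger.info(
                "iteration %d/%d: class counts %s, h2 proxy (%.4f, %.4f)",
                it + 1, cfg.n_iter, diag_counts[it].astype(int), *diag_h2[it],
            )

    return PosteriorEffects(
        snp_id=pair.snp_ids,
        counted_allele=pair.ss1.effect_allele,
        beta1_mean=beta_sum[:, 0] / n_kept,
        beta2_mean=beta_sum[:, 1] / n_kept,
        class_prob=class_count / n_kept,
        diagnostics={
            "class_counts": diag_counts,
            "h2_proxy": diag_h2,
            "n_kept": n_kept,
            "mode": mode,
            "seed": cfg.seed,
        },
    )


def run_decoupled(
    pair: HarmonizedPair,
    blocks: list[LDBlock],
    overlap: OverlapModel,
    cfg: MCMCConfig,
) -> PosteriorEffects:
    """Shared-class-disabled ablation: independent single-trait fits.

    With the shared class off and no overlap coupling the bivariate
    model factorizes into two single-trait models; they are run with
    independent RNG substreams spawned from the master seed, so each
    trait's results depend only on its own inputs.
    """
    if overlap.s != 0:
        raise InputError("the decoupled ablation requires s = 0")
    seeds = np.random.SeedSequence(cfg.seed).spawn(2)
    out = []
    for sub, mode in zip(seeds, ("single1", "single2")):
        sub_cfg = MCMCConfig(
            n_iter=cfg.n_iter, burn_in=cfg.burn_in, thin=cfg.thin,
            seed=int(sub.generate_state(1)[0] % (2**31)), a=cfg.a, prior=cfg.prior,
        )
        out.append(run_mcmc(pair, blocks, overlap, sub_cfg, mode=mode))
    fit1, fit2 = out
    class_prob = np.zeros_like(fit1.class_prob)
    # independent fits: combine marginal class frequencies per trait
    class_prob[:, 1] = fit1.class_prob[:, 1]
    class_prob[:, 2] = fit2.class_prob[:, 2]
    class_prob[:, 0] = np.maximum(1.0 - class_prob[:, 1] - class_prob[:, 2], 0.0)
    return PosteriorEffects(
        snp_id=fit1.snp_id,
        counted_allele=fit1.counted_allele,
        beta1_mean=fit1.beta1_mean,
        beta2_mean=fit2.beta2_mean,
        class_prob=class_prob,
        diagnostics={"mode": "decoupled", "seed": cfg.seed,
                     "trait1": fit1.diagnostics, "trait2": fit2.diagnostics},
    )
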