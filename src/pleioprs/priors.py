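"""Four-class stick-breaking mixture prior over bivariate SNP effects.

Per SNP j the bivariate effect (beta_j1, beta_j2) is drawn from one of
four classes: both null, trait-1-specific, trait-2-specific, or shared
with correlation.  Each non-null class is itself a truncated
Dirichlet-process mixture (stick-breaking with concentration alpha_c)
of K components with their own variances/covariances, letting the model
capture region-specific heritability and region-specific genetic
correlation:

* class 1 components: beta_1 ~ N(0, sigma1k^2), beta_2 = 0
* class 2 components: beta_1 = 0, beta_2 ~ N(0, sigma2k^2)
* class 3 components: (beta_1, beta_2) ~ N(0, Sigma_k), full 2x2 Sigma_k

Hyperpriors: class probabilities (p0..p3) ~ Dirichlet(1); stick
concentrations alpha_c ~ Gamma(0.1, 0.1); trait-specific variances get a
hierarchical inverse-gamma (sigma^2 ~ IG(0.5, gamma_k),
gamma_k ~ G(0.5, 0.5)); shared covariances get a hierarchical half-t
construction (Sigma_k ~ IW(2v+1, B_k), B_k = 4v*diag(delta_k, lambda_k),
delta_k, lambda_k ~ G(0.5, 0.5)), which makes the implied marginal
priors on the shared standard deviations half-t with v degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gwas_io import InputError


@dataclass
class PriorConfig:
    """Hyperparameters of the mixture prior.

    K is the truncation level of each non-null class (1,000 by default;
    only a small subset of components ever receives appreciable
    posterior mass, so small K is adequate for small problems).  ``v``
    is the half-t degrees-of-freedom parameter of the shared-covariance
    hyperprior.
    """

    K: int = 1000
    dirichlet_conc: float = 1.0
    alpha_shape: float = 0.1
    alpha_rate: float = 0.1
    ig_shape: float = 0.5
    hyper_gamma_shape: float = 0.5
    hyper_gamma_rate: float = 0.5
    v: float = 2.0
    var_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.K < 1:
            raise InputError("K must be >= 1")
        for name in ("dirichlet_conc", "alpha_shape", "alpha_rate", "ig_shape",
                     "hyper_gamma_shape", "hyper_gamma_rate", "v"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


@dataclass
class MixtureParams:
    """A full realization of the mixture prior's parameters."""

    p: np.ndarray                  # (4,) class probabilities
    V1: np.ndarray                 # (K,) stick fractions, trait-1 class
    V2: np.ndarray
    V3: np.ndarray
    pi1: np.ndarray                # (K,) within-class weights
    pi2: np.ndarray
    pi3: np.ndarray
    sigma1_sq: np.ndarray          # (K,)
    sigma2_sq: np.ndarray
    Sigma: np.ndarray              # (K, 2, 2)
    gamma_k: np.ndarray
    theta_k: np.ndarray
    delta_k: np.ndarray
    lambda_k: np.ndarray
    alpha: np.ndarray              # (3,) stick concentrations

    @property
    def K(self) -> int:
        return len(self.pi1)

    def validate(self) -> None:
        if not np.isclose(self.p.sum(), 1.0) or (self.p < 0).any():
            raise InputError("class probabilities must be a simplex point")
        for pi in (self.pi1, self.pi2, self.pi3):
            if not np.isclose(pi.sum(), 1.0):
                raise InputError("within-class weights must sum to 1")
        dets = (self.Sigma[:, 0, 0] * self.Sigma[:, 1, 1]
                - self.Sigma[:, 0, 1] ** 2)
        if (dets <= 0).any() or (self.Sigma[:, 0, 0] <= 0).any():
            raise InputError("every shared covariance must be positive definite")


def stick_to_weights(V: np.ndarray) -> np.ndarray:
    """Truncated stick-breaking weights with final-stick closure.

    ``pi_k = V_k * prod_{m<k} (1 - V_m)``; the last component absorbs
    the residual mass so the weights sum to exactly 1 (the last entry of
    V is thereby ignored).
    """
    V = np.asarray(V, dtype=float)
    if ((V <= 0) | (V >= 1))[:-1].any():
        raise InputError("stick fractions must lie in (0, 1)")
    remain = np.concatenate([[1.0], np.cumprod(1.0 - V[:-1])])
    w = V * remain
    w[-1] = max(1.0 - w[:-1].sum(), 0.0)
    return w


def sample_stick_fractions(
    a: np.ndarray | float,
    b: np.ndarray | float,
    size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Beta(a, b) stick draws together with exact -log(1 - V).

    Stick concentrations drawn from Gamma(0.1, 0.1) are frequently tiny,
    making 1 - V underflow double precision; the quantity the
    concentration update needs is -log(1 - V), so it is computed in log
    space via the Gamma representation (V = Ga/(Ga+Gb), using the
    small-shape log-gamma identity log Gb = log Gamma(b+1) + log(U)/b).
    Returns (V, t) with t = -log(1 - V) exact even when V rounds to 1.
    """
    a = np.broadcast_to(np.asarray(a, dtype=float), (size,))
    b = np.broadcast_to(np.asarray(b, dtype=float), (size,))
    log_ga = np.log(np.maximum(rng.gamma(a, 1.0), 1e-300))
    log_gb = (
        np.log(np.maximum(rng.gamma(b + 1.0, 1.0), 1e-300))
        + np.log(rng.random(size)) / b
    )
    t = np.logaddexp(log_ga, log_gb) - log_gb
    V = -np.expm1(-t)
    return V, t


def weights_from_sticks(V: np.ndarray, neg_log1m: np.ndarray) -> np.ndarray:
    """Stick-breaking weights computed stably from exact -log(1 - V)."""
    remain = np.exp(-np.concatenate([[0.0], np.cumsum(neg_log1m[:-1])]))
    w = V * remain
    w[-1] = max(1.0 - w[:-1].sum(), 0.0)
    return w


def sample_mixture(cfg: PriorConfig, rng: np.random.Generator) -> MixtureParams:
    """Draw a complete MixtureParams realization from the prior."""
    K = cfg.K
    p = rng.dirichlet(np.full(4, cfg.dirichlet_conc))
    alpha = rng.gamma(cfg.alpha_shape, 1.0 / cfg.alpha_rate, size=3)

    def sticks(a: float) -> tuple[np.ndarray, np.ndarray]:
        return sample_stick_fractions(1.0, a, K, rng)

    (V1, t1), (V2, t2), (V3, t3) = sticks(alpha[0]), sticks(alpha[1]), sticks(alpha[2])

    gamma_k = rng.gamma(cfg.hyper_gamma_shape, 1.0 / cfg.hyper_gamma_rate, size=K)
    theta_k = rng.gamma(cfg.hyper_gamma_shape, 1.0 / cfg.hyper_gamma_rate, size=K)
    delta_k = rng.gamma(cfg.hyper_gamma_shape, 1.0 / cfg.hyper_gamma_rate, size=K)
    lambda_k = rng.gamma(cfg.hyper_gamma_shape, 1.0 / cfg.hyper_gamma_rate, size=K)

    # sigma^2 ~ IG(ig_shape, rate): rate / Gamma(shape)
    sigma1_sq = np.maximum(
        gamma_k / np.maximum(rng.gamma(cfg.ig_shape, 1.0, size=K), 1e-300),
        cfg.var_floor,
    )
    sigma2_sq = np.maximum(
        theta_k / np.maximum(rng.gamma(cfg.ig_shape, 1.0, size=K), 1e-300),
        cfg.var_floor,
    )

    Sigma = sample_invwishart_2x2(
        df=np.full(K, 2.0 * cfg.v + 1.0),
        scale_11=4.0 * cfg.v * delta_k,
        scale_22=4.0 * cfg.v * lambda_k,
        scale_12=np.zeros(K),
        rng=rng,
        var_floor=cfg.var_floor,
    )

    return MixtureParams(
        p=p,
        V1=V1, V2=V2, V3=V3,
        pi1=weights_from_sticks(V1, t1),
        pi2=weights_from_sticks(V2, t2),
        pi3=weights_from_sticks(V3, t3),
        sigma1_sq=sigma1_sq,
        sigma2_sq=sigma2_sq,
        Sigma=Sigma,
        gamma_k=gamma_k,
        theta_k=theta_k,
        delta_k=delta_k,
        lambda_k=lambda_k,
        alpha=alpha,
    )


def sample_invwishart_2x2(
    df: np.ndarray,
    scale_11: np.ndarray,
    scale_22: np.ndarray,
    scale_12: np.ndarray,
    rng: np.random.Generator,
    var_floor: float = 1e-12,
) -> np.ndarray:
    """Vectorized 2x2 inverse-Wishart draws, Sigma ~ IW(df_k, Psi_k).

    Uses the Bartlett decomposition of Wishart(df, Psi^{-1}) and inverts.
    All inputs are length-K arrays; returns (K, 2, 2).
    """
    K = len(df)
    det = scale_11 * scale_22 - scale_12**2
    if (det <= 0).any() or (scale_11 <= 0).any():
        raise InputError("inverse-Wishart scale must be positive definite")
    # chol of Psi^{-1}: Psi^{-1} = [[s22, -s12], [-s12, s11]] / det
    i11 = scale_22 / det
    i12 = -scale_12 / det
    i22 = scale_11 / det
    l11 = np.sqrt(i11)
    l21 = i12 / l11
    l22 = np.sqrt(np.maximum(i22 - l21**2, 1e-300))

    # Bartlett: W = L T T' L' with T lower, T_ii^2 ~ chi2(df - i + 1)
    t11 = np.sqrt(2.0 * rng.gamma(df / 2.0, 1.0, size=K))
    t22 = np.sqrt(2.0 * rng.gamma((df - 1.0) / 2.0, 1.0, size=K))
    t21 = rng.standard_normal(K)

    # C = L @ T (lower triangular), W = C C'
    c11 = l11 * t11
    c21 = l21 * t11 + l22 * t21
    c22 = l22 * t22
    w11 = c11**2
    w12 = c11 * c21
    w22 = c21**2 + c22**2

    wdet = np.maximum(w11 * w22 - w12**2, 1e-300)
    s11 = np.maximum(w22 / wdet, var_floor)
    s22 = np.maximum(w11 / wdet, var_floor)
    s12 = -w12 / wdet
    # keep the implied correlation strictly inside (-1, 1)
    cap = 0.999999 * np.sqrt(s11 * s22)
    s12 = np.clip(s12, -cap, cap)

    Sigma = np.empty((K, 2, 2))
    Sigma[:, 0, 0] = s11
    Sigma[:, 0, 1] = Sigma[:, 1, 0] = s12
    Sigma[:, 1, 1] = s22
    return Sigma


CLASS_NAMES = ("null", "t1", "t2", "shared")


def sample_prior_effect(
    class_label: str | int,
    component: int,
    params: MixtureParams,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw one bivariate effect from a given class/component."""
    if isinstance(class_label, str):
        class_label = CLASS_NAMES.index(class_label)
    if class_label == 0:
        return 0.0, 0.0
    if not 0 <= component < params.K:
        raise IndexError(f"component {component} >= K={params.K}")
    if class_label == 1:
        return float(rng.normal(0.0, np.sqrt(params.sigma1_sq[component]))), 0.0
    if class_label == 2:
        return 0.0, float(rng.normal(0.0, np.sqrt(params.sigma2_sq[component])))
    if class_label == 3:
        S = params.Sigma[component]
        b = rng.multivariate_normal(np.zeros(2), S, method="cholesky")
        return float(b[0]), float(b[1])
    raise InputError(f"unknown class {class_label}")


def sample_prior_assignments(
    params: MixtureParams,
    m: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-SNP classes, components, and effects from the prior.

    Returns (zc, zk, beta) with beta of shape (m, 2); the null class has
    component index 0 and zero effects.
    """
    zc = rng.choice(4, size=m, p=params.p)
    zk = np.zeros(m, dtype=np.int64)
    beta = np.zeros((m, 2))
    for cls, pi in ((1, params.pi1), (2, params.pi2), (3, params.pi3)):
        mask = zc == cls
        if mask.any():
            zk[mask] = rng.choice(params.K, size=int(mask.sum()), p=pi)
    m1 = zc == 1
    beta[m1, 0] = rng.normal(0.0, np.sqrt(params.sigma1_sq[zk[m1]]))
    m2 = zc == 2
    beta[m2, 1] = rng.normal(0.0, np.sqrt(params.sigma2_sq[zk[m2]]))
    for j in np.nonzero(zc == 3)[0]:
        beta[j] = rng.multivariate_normal(
            np.zeros(2), params.Sigma[zk[j]], method="cholesky"
        )
    return zc, zk, beta


def marginal_logratios(
    P: np.ndarray,
    b: np.ndarray,
    params: MixtureParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-component log marginal-likelihood ratios versus the null class.

    The per-SNP conditional likelihood of beta_j given everything else
    is Gaussian with precision ``P`` (2x2) and natural parameter ``b``
    (2-vector), i.e. proportional to exp(-beta'P beta/2 + beta'b).
    Integrating beta against a component's zero-mean Gaussian prior with
    covariance S gives a marginal whose log-ratio to the null point mass
    is ``-log det(I + S P)/2 + b'(I + S P)^{-1} S b / 2``; trait-specific
    components reduce to the 1-D version of the same formula.
    """
    P11, P12, P22 = P[0, 0], P[0, 1], P[1, 1]
    b1, b2 = b[0], b[1]

    m1 = 1.0 + params.sigma1_sq * P11
    lr1 = -0.5 * np.log(m1) + 0.5 * b1 * b1 * params.sigma1_sq / m1
    m2 = 1.0 + params.sigma2_sq * P22
    lr2 = -0.5 * np.log(m2) + 0.5 * b2 * b2 * params.sigma2_sq / m2

    S11 = params.Sigma[:, 0, 0]
    S12 = params.Sigma[:, 0, 1]
    S22 = params.Sigma[:, 1, 1]
    c11 = 1.0 + S11 * P11 + S12 * P12
    c12 = S11 * P12 + S12 * P22
    c21 = S12 * P11 + S22 * P12
    c22 = 1.0 + S12 * P12 + S22 * P22
    detC = c11 * c22 - c12 * c21
    g1 = S11 * b1 + S12 * b2
    g2 = S12 * b1 + S22 * b2
    x1 = (c22 * g1 - c12 * g2) / detC
    x2 = (-c21 * g1 + c11 * g2) / detC
    lr3 = -0.5 * np.log(detC) + 0.5 * (b1 * x1 + b2 * x2)
    return lr1, lr2, lr3


def class_component_marginals(
    stat: np.ndarray,
    noise: np.ndarray,
    params: MixtureParams,
) -> np.ndarray:
    """Log marginal likelihood of a residualized statistic per (class, component).

    ``stat`` is the SNP's residualized bivariate statistic u with
    u | beta ~ N(beta, noise); ``noise`` is its 2x2 sampling covariance.
    Returns an array of shape (1 + 3K,): the null class first, then the
    K components of the trait-1, trait-2, and shared classes, each as a
    log density *relative to the null class* (the null entry is 0), so
    the full categorical posterior just adds log class/component weights.
    """
    noise = np.asarray(noise, dtype=float)
    det = noise[0, 0] * noise[1, 1] - noise[0, 1] ** 2
    if det <= 0 or noise[0, 0] <= 0:
        raise FloatingPointError("noise covariance is not positive definite")
    P = np.array([[noise[1, 1], -noise[0, 1]], [-noise[0, 1], noise[0, 0]]]) / det
    b = P @ np.asarray(stat, dtype=float)
    lr1, lr2, lr3 = marginal_logratios(P, b, params)
    return np.concatenate([[0.0], lr1, lr2, lr3])


def categorical_logweights(params: MixtureParams, lrs: np.ndarray) -> np.ndarray:
    """Unnormalized posterior log weights over the 1 + 3K categories."""
    tiny = 1e-300
    logp = np.log(np.maximum(params.p, tiny))
    return lrs + np.concatenate(
        [
            [logp[0]],
            logp[1] + np.log(np.maximum(params.pi1, tiny)),
            logp[2] + np.log(np.maximum(params.pi2, tiny)),
            logp[3] + np.log(np.maximum(params.pi3, tiny)),
        ]
    )
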