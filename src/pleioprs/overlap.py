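"""Sample-overlap / environmental-covariance adjustment.

When the two GWAS cohorts share Ns individuals, residual (environmental)
covariance rho_e between the traits induces correlated sampling noise in
the marginal effect estimates.  The dimensionless coupling

    s = Ns * rho_e / sqrt(N1 * N2)

is exactly what the cross-trait LD-score-regression intercept estimates
(its environmental part).  Inside the likelihood the cross-covariance of
the two traits' marginal effects is ``(s / sqrt(N1*N2)) * A`` per block:
deriving cov(X1'e1/N1, X2'e2/N2) from the trait model gives
``Ns * rho_e * D / (N1*N2)``, which equals s/sqrt(N1*N2) times D.  The
2x2 per-SNP sampling matrix is therefore

    Omega = [[1/N1, s/sqrt(N1*N2)], [s/sqrt(N1*N2), 1/N2]],

positive definite whenever |s| < 1, which the OverlapModel invariants
(0 <= Ns <= min(N1, N2), |rho_e| <= 1) guarantee.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gwas_io import HarmonizedPair, InputError

logger = logging.getLogger(__name__)


class EstimationError(RuntimeError):
    """Raised when the overlap regression is degenerate."""


def compute_s(ns: float, rho_e: float, n1: float, n2: float) -> float:
    """Dimensionless overlap coupling s = ns * rho_e / sqrt(n1 * n2)."""
    if n1 <= 0 or n2 <= 0:
        raise InputError("sample sizes must be positive")
    if ns < 0 or ns > min(n1, n2):
        raise InputError(f"ns={ns} outside [0, min(n1, n2)]")
    if abs(rho_e) > 1:
        raise InputError("|rho_e| must be <= 1 for unit-variance phenotypes")
    return ns * rho_e / math.sqrt(n1 * n2)


@dataclass
class OverlapModel:
    """Cohort sizes and the derived noise-coupling scalar.

    ``s`` may be supplied directly (e.g. from a cross-trait LDSC fit);
    otherwise it is derived from (ns, rho_e).  Direct (ns, rho_e) input
    wins over an s estimate when both are given.
    """

    n1: float
    n2: float
    ns: float = 0.0
    rho_e: float = 0.0
    s_direct: float | None = None

    def __post_init__(self) -> None:
        if self.ns > 0 and self.rho_e != 0 and self.s_direct is not None:
            logger.info("both (ns, rho_e) and s supplied; (ns, rho_e) wins")
            self.s_direct = None
        if abs(self.s) >= 1.0:
            raise InputError(f"|s|={abs(self.s):.3g} >= 1: invalid overlap model")

    @property
    def s(self) -> float:
        if self.s_direct is not None:
            return float(self.s_direct)
        return compute_s(self.ns, self.rho_e, self.n1, self.n2)

    @property
    def omega(self) -> np.ndarray:
        """Per-SNP 2x2 sampling covariance scale (cross term s/sqrt(N1 N2))."""
        cross = self.s / math.sqrt(self.n1 * self.n2)
        return np.array([[1.0 / self.n1, cross], [cross, 1.0 / self.n2]])

    @property
    def omega_inv(self) -> np.ndarray:
        o = self.omega
        det = o[0, 0] * o[1, 1] - o[0, 1] ** 2
        return np.array([[o[1, 1], -o[0, 1]], [-o[0, 1], o[0, 0]]]) / det


@dataclass
class LdscFit:
    """Cross-trait LD-score regression of z1*z2 on per-SNP LD scores."""

    slope: float
    intercept: float
    intercept_se: float
    s: float
    n_snps: int


def estimate_overlap_term(
    pair: HarmonizedPair,
    ld_scores: np.ndarray,
    n1: float | None = None,
    n2: float | None = None,
    ns: float | None = None,
    weights: np.ndarray | None = None,
) -> LdscFit:
    """Estimate the overlap coupling s from a cross-trait LDSC regression.

    Regresses the product of the two traits' z-scores on LD scores.  The
    intercept estimates ``Ns * rho_pheno / sqrt(N1*N2)`` where rho_pheno
    is the total phenotypic covariance among overlapping individuals;
    the genetic part implied by the slope
    (``slope * M * ns / (n1 * n2)``, since slope = sqrt(N1 N2) * cov_g / M)
    is subtracted when ``ns`` is supplied, leaving the environmental
    coupling s.  Without ``ns`` the raw intercept is returned as s,
    which is only exact when the genetic covariance is negligible.

    Weighted least squares is used when ``weights`` are given (plain OLS
    otherwise).
    """
    ld_scores = np.asarray(ld_scores, dtype=float)
    if len(ld_scores) != pair.m:
        raise InputError("ld_scores not aligned with the harmonized pair")
    if pair.m < 200:
        raise InputError("need at least 200 SNPs for the overlap regression")
    if np.ptp(ld_scores) == 0:
        raise EstimationError("constant LD scores: regression is degenerate")

    n1 = pair.ss1.n_effective if n1 is None else float(n1)
    n2 = pair.ss2.n_effective if n2 is None else float(n2)
    zz = pair.ss1.z * pair.ss2.z

    if weights is None:
        fit = stats.linregress(ld_scores, zz)
        slope, intercept = fit.slope, fit.intercept
        intercept_se = fit.intercept_stderr
    else:
        w = np.asarray(weights, dtype=float)
        W = np.sqrt(w / w.sum())
        Xd = np.column_stack([np.ones_like(ld_scores), ld_scores]) * W[:, None]
        yd = zz * W
        coef, res, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
        intercept, slope = coef
        dof = pair.m - 2
        sigma2 = float(res[0]) / dof if len(res) else float(((yd - Xd @ coef) ** 2).sum()) / dof
        cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
        intercept_se = math.sqrt(cov[0, 0])

    s = float(intercept)
    if ns is not None:
        genetic_part = slope * pair.m * ns / (n1 * n2)
        s -= genetic_part
    else:
        logger.warning(
            "ns not supplied: intercept used as s without genetic correction"
        )
    return LdscFit(
        slope=float(slope),
        intercept=float(intercept),
        intercept_se=float(intercept_se),
        s=s,
        n_snps=pair.m,
    )


def approximate_ns(cohort_contributions) -> float:
    """Overlap approximation: sum over shared cohorts of min(n to trait 1, n to trait 2).

    ``cohort_contributions`` is an iterable of (n_trait1, n_trait2)
    pairs, one per cohort contributing to both GWAS.
    """
    total = 0.0
    for c1, c2 in cohort_contributions:
        if c1 < 0 or c2 < 0:
            raise InputError("cohort contributions must be non-negative")
        total += min(c1, c2)
    return total
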