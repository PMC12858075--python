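"""Polygenic scores from posterior-mean effects, and their evaluation.

Scores are plain weighted allele-count sums, ``score_i = sum_j
dosage_ij * effect_j``, with missing dosages mean-imputed per variant.
Evaluation reports the squared Pearson correlation between score and
phenotype, which equals the R^2 of the simple regression
phenotype ~ score.  When scores for two traits and a validation set are
available, an ordinary-least-squares linear combination of the two
scores can be fitted on the validation individuals and applied to the
test individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import GenotypeMatrix, InputError

logger = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Per-individual polygenic score."""

    sample_id: np.ndarray
    pgs: np.ndarray
    trait_label: str = ""

    def __post_init__(self) -> None:
        if len(self.sample_id) != len(self.pgs):
            raise InputError("sample ids and scores must align")
        if not np.isfinite(self.pgs).all():
            raise InputError("non-finite scores")


@dataclass
class CombinationWeights:
    """OLS coefficients of phenotype on (PGS_trait1, PGS_trait2)."""

    intercept: float
    w1: float
    w2: float

    def apply(self, pgs1: np.ndarray, pgs2: np.ndarray) -> np.ndarray:
        return self.intercept + self.w1 * pgs1 + self.w2 * pgs2


def compute_pgs(
    genotypes: GenotypeMatrix,
    effects: pd.DataFrame,
    snp_col: str = "SNP",
    allele_col: str = "A1",
    effect_col: str = "BETA1",
    trait_label: str = "",
) -> ScoreTable:
    """Aggregate per-SNP effects into per-individual scores.

    Effects whose declared allele is the genotype file's other allele
    are sign-flipped; alleles matching neither are dropped with a
    warning.  Missing dosages are mean-imputed per variant from the
    scored samples.
    """
    idx = {s: j for j, s in enumerate(genotypes.snp_ids)}
    cols, weights = [], []
    n_flip = n_drop = 0
    for snp, allele, eff in zip(
        effects[snp_col], effects[allele_col], effects[effect_col]
    ):
        j = idx.get(snp)
        if j is None:
            continue
        if allele == genotypes.counted_allele[j]:
            cols.append(j)
            weights.append(eff)
        elif allele == genotypes.other_allele[j]:
            cols.append(j)
            weights.append(-eff)
            n_flip += 1
        else:
            n_drop += 1
    if not cols:
        raise InputError("no overlapping SNPs between effects and genotypes")
    if n_flip:
        logger.info("sign-flipped %d effects to the genotype counted allele", n_flip)
    if n_drop:
        logger.warning("dropped %d effects with mismatched alleles", n_drop)

    X = genotypes.dosages[:, cols].astype(float)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        mu = np.nanmean(X, axis=0)
        X[nan_mask] = np.take(mu, np.nonzero(nan_mask)[1])
    scores = X @ np.asarray(weights, dtype=float)
    return ScoreTable(sample_id=genotypes.samples, pgs=scores, trait_label=trait_label)


def fit_combination(
    pgs1: ScoreTable,
    pgs2: ScoreTable,
    phenotype: np.ndarray,
) -> CombinationWeights:
    """OLS of phenotype on the two traits' scores (validation samples).

    Collinear scores degrade gracefully: the second score is dropped
    with a warning and w2 is set to 0.
    """
    if np.array_equal(pgs1.sample_id, pgs2.sample_id):
        common, x1, x2 = pgs1.sample_id, pgs1.pgs, pgs2.pgs
    else:
        common, i1, i2 = np.intersect1d(pgs1.sample_id, pgs2.sample_id,
                                        return_indices=True)
        if len(common) == 0:
            raise InputError("no validation samples shared between the score tables")
        x1 = pgs1.pgs[i1]
        x2 = pgs2.pgs[i2]
    y = np.asarray(phenotype, dtype=float)
    if len(y) != len(common):
        raise InputError("phenotype length must match the shared samples")

    X = np.column_stack([np.ones_like(x1), x1, x2])
    rank = np.linalg.matrix_rank(X)
    if rank < 3:
        logger.warning("collinear scores: dropping the second trait's score")
        coef, *_ = np.linalg.lstsq(X[:, :2], y, rcond=None)
        return CombinationWeights(intercept=coef[0], w1=coef[1], w2=0.0)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return CombinationWeights(intercept=coef[0], w1=coef[1], w2=coef[2])


def evaluate(score: ScoreTable | np.ndarray, phenotype: np.ndarray) -> dict:
    """Predictive accuracy: squared Pearson correlation and regression R^2.

    The two quantities are numerically identical for a single score;
    both are reported.
    """
    s = score.pgs if isinstance(score, ScoreTable) else np.asarray(score, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if len(s) != len(y) or len(s) < 3:
        raise InputError("need >= 3 matched samples")
    if np.std(s) == 0:
        raise InputError("zero-variance score: correlation undefined")
    r = stats.pearsonr(s, y).statistic
    fit = stats.linregress(s, y)
    return {
        "r2_pearson": float(r**2),
        "r2_regression": float(fit.rvalue**2),
        "pearson_r": float(r),
        "n": len(s),
    }
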