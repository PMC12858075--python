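"""Reading, validation, and harmonization of GWAS inputs.

This module handles the two flavours of input the pipeline consumes:

* GWAS summary statistics: whitespace/tab-delimited text with a header,
  one row per variant, carrying either BETA+SE+N or Z+N.  Effects are
  stored internally on the standardized scale (variance-1 genotypes,
  variance-1 phenotype), where ``beta_std = Z / sqrt(N)`` and
  ``se_std = 1 / sqrt(N)``.
* Genotypes: PLINK 1 bed/bim/fam triplets (variant-major bed encoding).
  The codec is implemented here directly; the format is two bits per
  genotype with a three-byte magic header.

Harmonization intersects two traits' summary statistics with a reference
panel, re-signs every effect so it refers to the panel's counted allele,
and optionally drops strand-ambiguous (A/T, C/G) variants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: default recognized header names, lower-cased, for each mandatory field
_DEFAULT_COLUMNS = {
    "snp": ("snp", "snp_id", "rsid", "id", "markername"),
    "a1": ("a1", "effect_allele", "alt", "ea"),
    "a2": ("a2", "other_allele", "ref", "oa", "nea"),
    "beta": ("beta", "b", "effect", "beta_hat"),
    "se": ("se", "stderr", "standard_error"),
    "n": ("n", "nobs", "samplesize", "n_eff"),
    "z": ("z", "zscore", "z_score", "stat"),
}


class InputError(ValueError):
    """Raised when an input file is structurally invalid or empty after QC."""


class ConfigurationError(ValueError):
    """Raised when a required column mapping cannot be resolved."""


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    """One trait's harmonized per-variant marginal effects.

    Effects are on the standardized-genotype, unit-variance-phenotype
    scale.  ``n`` is the per-variant sample size; the likelihood uses a
    single scalar per trait, exposed as :attr:`n_effective` (median of
    per-variant n).
    """

    snp_id: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    beta_hat: np.ndarray
    se: np.ndarray
    n: np.ndarray
    trait_label: str = ""

    def __post_init__(self) -> None:
        m = len(self.snp_id)
        for name in ("effect_allele", "other_allele", "beta_hat", "se", "n"):
            if len(getattr(self, name)) != m:
                raise InputError(f"column {name!r} has length != {m}")
        self.beta_hat = np.asarray(self.beta_hat, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n = np.asarray(self.n, dtype=float)

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def n_effective(self) -> float:
        """Scalar GWAS sample size used by the likelihood (median of per-SNP n)."""
        return float(np.median(self.n))

    @property
    def z(self) -> np.ndarray:
        return self.beta_hat / self.se

    def validate(self) -> None:
        if len(self) == 0:
            raise InputError("summary statistics contain no variants")
        if not np.all(self.n > 0):
            raise InputError("sample sizes must be positive")
        if not np.all(self.se > 0):
            raise InputError("standard errors must be positive")
        for arr in (self.effect_allele, self.other_allele):
            bad = ~np.isin(arr, list(VALID_ALLELES))
            if bad.any():
                raise InputError(f"invalid alleles: {np.unique(arr[bad])}")
        if np.any(self.effect_allele == self.other_allele):
            raise InputError("effect allele equals other allele for some variants")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.snp_id,
                "A1": self.effect_allele,
                "A2": self.other_allele,
                "BETA": self.beta_hat,
                "SE": self.se,
                "N": self.n,
            }
        )


def _resolve_column(columns: list[str], key: str, column_map: dict | None) -> str | None:
    if column_map and key in column_map:
        name = column_map[key]
        if name not in columns:
            raise ConfigurationError(f"mapped column {name!r} for {key!r} not in file")
        return name
    lowered = {c.lower(): c for c in columns}
    for cand in _DEFAULT_COLUMNS[key]:
        if cand in lowered:
            return lowered[cand]
    return None


def read_sumstats(
    path: str | Path,
    column_map: dict | None = None,
    trait_label: str = "",
) -> SummaryStats:
    """Read a whitespace/tab-delimited summary-statistics file.

    Recognized conventions are BETA+SE+N and Z+N; with the latter,
    standardized effects are computed as ``Z/sqrt(N)`` with standard
    error ``1/sqrt(N)``.  Rows with missing or invalid fields (``n <= 0``,
    ``se <= 0``, non-ACGT alleles, identical alleles) are dropped and
    counted in the log.  Duplicate SNP ids keep the first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary statistics file not found: {path}")
    df = pd.read_csv(path, sep=r"\s+", dtype={0: str}, float_precision="round_trip")
    cols = list(df.columns)

    c_snp = _resolve_column(cols, "snp", column_map)
    c_a1 = _resolve_column(cols, "a1", column_map)
    c_a2 = _resolve_column(cols, "a2", column_map)
    c_n = _resolve_column(cols, "n", column_map)
    for key, col in (("snp", c_snp), ("a1", c_a1), ("a2", c_a2), ("n", c_n)):
        if col is None:
            raise ConfigurationError(f"mandatory column for {key!r} missing in {path}")

    c_beta = _resolve_column(cols, "beta", column_map)
    c_se = _resolve_column(cols, "se", column_map)
    c_z = _resolve_column(cols, "z", column_map)

    n = pd.to_numeric(df[c_n], errors="coerce")
    if c_beta is not None and c_se is not None:
        beta = pd.to_numeric(df[c_beta], errors="coerce")
        se = pd.to_numeric(df[c_se], errors="coerce")
    elif c_z is not None:
        z = pd.to_numeric(df[c_z], errors="coerce")
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = z / np.sqrt(n)
            se = 1.0 / np.sqrt(n)
    else:
        raise ConfigurationError(
            f"{path}: need either BETA+SE columns or a Z column alongside N"
        )

    snp = df[c_snp].astype(str)
    a1 = df[c_a1].astype(str).str.upper()
    a2 = df[c_a2].astype(str).str.upper()

    ok = (
        snp.notna()
        & n.notna()
        & (n > 0)
        & beta.notna()
        & se.notna()
        & (se > 0)
        & a1.isin(VALID_ALLELES)
        & a2.isin(VALID_ALLELES)
        & (a1 != a2)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d invalid rows", path.name, n_dropped)

    dup = snp[ok].duplicated()
    if dup.any():
        logger.warning("%s: %d duplicate SNP ids, keeping first", path.name, int(dup.sum()))
        keep_idx = snp[ok].index[~dup.values]
    else:
        keep_idx = snp[ok].index

    if len(keep_idx) == 0:
        raise InputError(f"{path}: no valid rows survive QC")

    return SummaryStats(
        snp_id=snp.loc[keep_idx].to_numpy(),
        effect_allele=a1.loc[keep_idx].to_numpy(),
        other_allele=a2.loc[keep_idx].to_numpy(),
        beta_hat=beta.loc[keep_idx].to_numpy(dtype=float),
        se=se.loc[keep_idx].to_numpy(dtype=float),
        n=n.loc[keep_idx].to_numpy(dtype=float),
        trait_label=trait_label or path.stem,
    )


def write_sumstats(ss: SummaryStats, path: str | Path) -> None:
    """Write summary statistics in the BETA+SE+N dialect (round-trip safe)."""
    ss.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# genotypes (PLINK 1 bed/bim/fam)
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x variants) with per-variant counted allele.

    ``dosages[i, j]`` counts copies of ``counted_allele[j]`` carried by
    individual ``i`` (0, 1, 2, or NaN for missing).
    """

    samples: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray
    counted_allele: np.ndarray
    other_allele: np.ndarray
    chrom: np.ndarray = field(default=None)  # type: ignore[assignment]
    pos: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.samples) != n or len(self.snp_ids) != m:
            raise InputError("dosage matrix shape inconsistent with ids")
        if len(np.unique(self.snp_ids)) != m:
            raise InputError("duplicate SNP ids in genotype matrix")
        if self.chrom is None:
            self.chrom = np.ones(m, dtype=int)
        if self.pos is None:
            self.pos = np.arange(1, m + 1)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def standardized(self) -> np.ndarray:
        """Mean-imputed, column-standardized dosages (monomorphic columns -> 0)."""
        X = self.dosages.astype(float).copy()
        mu = np.nanmean(X, axis=0)
        nan_mask = np.isnan(X)
        if nan_mask.any():
            X[nan_mask] = np.take(mu, np.nonzero(nan_mask)[1])
        X -= mu
        sd = X.std(axis=0)
        mono = sd == 0
        sd[mono] = 1.0
        X /= sd
        X[:, mono] = 0.0
        return X

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=self.samples,
            snp_ids=self.snp_ids[index],
            dosages=self.dosages[:, index],
            counted_allele=self.counted_allele[index],
            other_allele=self.other_allele[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
        )


# 2-bit PLINK codes -> dosage of the bim A1 (counted) allele
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

_DECODE_TABLE = np.empty((256, 4), dtype=float)
for _b in range(256):
    for _i in range(4):
        _DECODE_TABLE[_b, _i] = _CODE_TO_DOSAGE[(_b >> (2 * _i)) & 0x3]


def read_genotypes(bed_prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 bed/bim/fam fileset (variant-major encoding)."""
    prefix = Path(bed_prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise InputError(f"missing PLINK file: {p}")

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    n, m = len(fam), len(bim)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:3]) != _BED_MAGIC:
        raise InputError(f"{bed_path}: not a variant-major PLINK 1 bed file")
    bytes_per_snp = (n + 3) // 4
    payload = raw[3:]
    if len(payload) != m * bytes_per_snp:
        raise InputError(
            f"{bed_path}: payload size {len(payload)} inconsistent with "
            f"{n} samples x {m} variants"
        )
    decoded = _DECODE_TABLE[payload.reshape(m, bytes_per_snp)]
    dosages = decoded.reshape(m, bytes_per_snp * 4)[:, :n].T.copy()

    sample_ids = (fam[0].astype(str) + "_" + fam[1].astype(str)).to_numpy()
    return GenotypeMatrix(
        samples=sample_ids,
        snp_ids=bim["snp"].to_numpy(),
        dosages=dosages,
        counted_allele=bim["a1"].str.upper().to_numpy(),
        other_allele=bim["a2"].str.upper().to_numpy(),
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].to_numpy(),
    )


def write_genotypes(gm: GenotypeMatrix, bed_prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK 1 bed/bim/fam fileset."""
    prefix = Path(bed_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = gm.dosages.shape

    # dosage of counted allele -> 2-bit code
    codes = np.full(gm.dosages.shape, 1, dtype=np.uint8)  # missing
    codes[gm.dosages == 2] = 0
    codes[gm.dosages == 1] = 2
    codes[gm.dosages == 0] = 3

    bytes_per_snp = (n + 3) // 4
    padded = np.ones((m, bytes_per_snp * 4), dtype=np.uint8) * 3  # pad with hom-A2
    padded[:, :n] = codes.T
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        packed.tofile(fh)

    bim = pd.DataFrame(
        {
            "chrom": gm.chrom,
            "snp": gm.snp_ids,
            "cm": 0,
            "pos": gm.pos,
            "a1": gm.counted_allele,
            "a2": gm.other_allele,
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": [s.split("_")[0] for s in gm.samples],
            "iid": [s.split("_", 1)[1] if "_" in s else s for s in gm.samples],
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


@dataclass
class HarmonizedPair:
    """Two traits' summary statistics aligned to a reference panel.

    After harmonization both traits contain exactly the same SNP ids, in
    panel order, and every effect refers to the panel's counted allele.
    """

    ss1: SummaryStats
    ss2: SummaryStats
    panel_index: np.ndarray
    m: int

    @property
    def snp_ids(self) -> np.ndarray:
        return self.ss1.snp_id

    @property
    def beta1(self) -> np.ndarray:
        return self.ss1.beta_hat

    @property
    def beta2(self) -> np.ndarray:
        return self.ss2.beta_hat


def _align_to_panel(
    ss: SummaryStats,
    panel_a1: np.ndarray,
    panel_a2: np.ndarray,
    order: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant sign (+1/-1) aligning effects to the panel counted allele.

    Returns (sign, keep_mask) over the variants in ``order``'s frame.
    Direct match keeps the sign, allele swap flips it; a strand flip of
    either orientation is also accepted; anything else is dropped.
    """
    ea, oa = ss.effect_allele[order], ss.other_allele[order]
    sign = np.zeros(len(order))
    keep = np.zeros(len(order), dtype=bool)

    def comp(arr: np.ndarray) -> np.ndarray:
        return np.vectorize(_COMPLEMENT.get)(arr)

    ea_c, oa_c = comp(ea), comp(oa)
    direct = (ea == panel_a1) & (oa == panel_a2)
    swapped = (ea == panel_a2) & (oa == panel_a1)
    strand = (ea_c == panel_a1) & (oa_c == panel_a2)
    strand_swapped = (ea_c == panel_a2) & (oa_c == panel_a1)

    sign[direct | strand] = 1.0
    sign[(swapped | strand_swapped) & ~(direct | strand)] = -1.0
    keep = direct | swapped | strand | strand_swapped
    return sign, keep


def harmonize(
    ss1: SummaryStats,
    ss2: SummaryStats,
    panel: GenotypeMatrix,
    drop_ambiguous: bool = True,
) -> HarmonizedPair:
    """Intersect two traits with a reference panel and align alleles.

    Effects are re-signed so the effect allele equals the panel's counted
    allele; strand-ambiguous variants (A/T, C/G) are removed when
    ``drop_ambiguous`` is set; variants whose alleles match neither
    directly nor after strand flip are removed.  Output follows panel
    column order.
    """
    ss1.validate()
    ss2.validate()

    idx1 = {s: i for i, s in enumerate(ss1.snp_id)}
    idx2 = {s: i for i, s in enumerate(ss2.snp_id)}

    panel_cols, rows1, rows2 = [], [], []
    for j, snp in enumerate(panel.snp_ids):
        i1 = idx1.get(snp)
        i2 = idx2.get(snp)
        if i1 is not None and i2 is not None:
            panel_cols.append(j)
            rows1.append(i1)
            rows2.append(i2)
    if not panel_cols:
        raise InputError("no SNPs shared among both traits and the panel")

    panel_cols = np.asarray(panel_cols)
    rows1 = np.asarray(rows1)
    rows2 = np.asarray(rows2)
    pa1 = panel.counted_allele[panel_cols]
    pa2 = panel.other_allele[panel_cols]

    keep = np.ones(len(panel_cols), dtype=bool)
    if drop_ambiguous:
        amb = np.array([(a, b) in _AMBIGUOUS_PAIRS for a, b in zip(pa1, pa2)])
        if amb.any():
            logger.info("dropping %d strand-ambiguous variants", int(amb.sum()))
        keep &= ~amb

    sign1, ok1 = _align_to_panel(ss1, pa1, pa2, rows1)
    sign2, ok2 = _align_to_panel(ss2, pa1, pa2, rows2)
    n_mismatch = int((keep & ~(ok1 & ok2)).sum())
    if n_mismatch:
        logger.info("dropping %d variants with irreconcilable alleles", n_mismatch)
    keep &= ok1 & ok2
    if not keep.any():
        raise InputError("no variants survive allele harmonization")

    def take(ss: SummaryStats, rows: np.ndarray, sign: np.ndarray) -> SummaryStats:
        r = rows[keep]
        return SummaryStats(
            snp_id=ss.snp_id[r],
            effect_allele=pa1[keep],
            other_allele=pa2[keep],
            beta_hat=ss.beta_hat[r] * sign[keep],
            se=ss.se[r],
            n=ss.n[r],
            trait_label=ss.trait_label,
        )

    return HarmonizedPair(
        ss1=take(ss1, rows1, sign1),
        ss2=take(ss2, rows2, sign2),
        panel_index=panel_cols[keep],
        m=int(keep.sum()),
    )
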