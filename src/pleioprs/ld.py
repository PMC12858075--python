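"""Reference-panel LD estimation, block partitioning, and regularization.

The likelihood couples SNPs only through the LD correlation matrix D of
each approximately independent block.  Following the shrinkage used by
SDPR-family models, every covariance term uses the regularized matrix
``A = D + a*I`` (default ``a = 0.1``) while the likelihood mean retains
D; the diagonal inflation keeps A positive definite and guards against
mismatch between the GWAS cohort and the reference panel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .gwas_io import GenotypeMatrix, HarmonizedPair, InputError

logger = logging.getLogger(__name__)

DEFAULT_A = 0.1
DEFAULT_R2_THRESHOLD = 0.1
DEFAULT_MAX_BLOCK_SIZE = 500


@dataclass
class LDBlock:
    """A contiguous range of panel columns with its correlation matrix.

    ``D`` is the Pearson correlation of mean-imputed, standardized
    dosages; ``A = D + a*I`` is the regularized form used in all
    covariance algebra.
    """

    start: int
    stop: int
    D: np.ndarray
    a: float = DEFAULT_A

    def __post_init__(self) -> None:
        if self.stop - self.start != self.D.shape[0]:
            raise InputError("block range inconsistent with D dimension")
        if self.D.shape[0] != self.D.shape[1]:
            raise InputError("D must be square")

    @property
    def size(self) -> int:
        return self.stop - self.start

    @property
    def A(self) -> np.ndarray:
        return self.D + self.a * np.eye(self.size)


@dataclass
class BlockPartition:
    """Ordered, contiguous [start, stop) ranges covering all m SNPs."""

    blocks: list[tuple[int, int]]
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    max_block_size: int = DEFAULT_MAX_BLOCK_SIZE

    def __post_init__(self) -> None:
        if not self.blocks:
            raise InputError("empty block list")
        prev = 0
        for start, stop in self.blocks:
            if start != prev or stop <= start:
                raise InputError("block ranges must tile [0, m) contiguously")
            prev = stop
        self.m = prev

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)


def compute_ld(
    panel: GenotypeMatrix,
    start: int = 0,
    stop: int | None = None,
    a: float = DEFAULT_A,
) -> LDBlock:
    """Estimate a block's LD correlation matrix from the reference panel.

    Missing dosages are mean-imputed before correlation.  Monomorphic
    variants keep a unit diagonal with zero correlation to neighbors so
    index alignment is preserved.
    """
    if panel.n_samples < 2:
        raise InputError("need at least 2 panel samples to estimate LD")
    stop = panel.n_snps if stop is None else stop
    if not (0 <= start < stop <= panel.n_snps):
        raise InputError(f"block range [{start}, {stop}) outside panel bounds")

    X = panel.standardized()[:, start:stop]
    mono = (X == 0).all(axis=0)
    if mono.any():
        logger.warning("block [%d,%d): %d monomorphic variants", start, stop, mono.sum())
    D = X.T @ X / panel.n_samples
    D[mono, :] = 0.0
    D[:, mono] = 0.0
    np.fill_diagonal(D, 1.0)
    D = np.clip((D + D.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(D, 1.0)
    return LDBlock(start=start, stop=stop, D=D, a=a)


def partition_blocks(
    panel: GenotypeMatrix,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    max_block_size: int = DEFAULT_MAX_BLOCK_SIZE,
    window: int | None = None,
) -> BlockPartition:
    """Greedy left-to-right scan into approximately independent blocks.

    A boundary is placed between adjacent positions whenever no SNP pair
    spanning it (within ``window`` columns) has squared correlation above
    ``r2_threshold``; a boundary is forced when ``max_block_size`` is
    reached.
    """
    if panel.n_snps == 0:
        raise InputError("empty panel")
    if not 0 < r2_threshold < 1:
        raise InputError("r2_threshold must be in (0, 1)")
    m = panel.n_snps
    window = max_block_size if window is None else window
    X = panel.standardized()
    n = panel.n_samples

    # allowed[i]: a boundary between columns i and i+1 crosses no strong pair
    allowed = np.ones(max(m - 1, 0), dtype=bool)
    for d in range(1, min(window, m - 1) + 1):
        r = np.einsum("ij,ij->j", X[:, :-d], X[:, d:]) / n
        strong = np.nonzero(r * r > r2_threshold)[0]
        for j in strong:
            allowed[j : j + d] = False

    blocks: list[tuple[int, int]] = []
    start = 0
    for i in range(m - 1):
        if allowed[i] or (i + 1 - start) >= max_block_size:
            blocks.append((start, i + 1))
            start = i + 1
    blocks.append((start, m))
    return BlockPartition(blocks=blocks, r2_threshold=r2_threshold, max_block_size=max_block_size)


def load_blocks(
    path: str,
    pair: HarmonizedPair | None = None,
    snp_ids: np.ndarray | None = None,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
) -> BlockPartition:
    """Map a published block-boundary file onto harmonized SNP order.

    Two dialects are auto-detected from the header: chrom/start/stop
    (1-based inclusive positions) or first-SNP/last-SNP ids.  SNPs
    falling in no listed block become singleton blocks (warned).  Pass
    either a :class:`HarmonizedPair` (SNP ids taken from it; supply
    chrom/pos for the coordinate dialect) or explicit arrays.
    """
    if pair is not None:
        snp_ids = pair.snp_ids
    if snp_ids is None:
        raise InputError("need snp_ids (or a HarmonizedPair) to map blocks")
    m = len(snp_ids)
    label = np.full(m, -1, dtype=int)

    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        logger.warning("%s: empty block file; every SNP becomes a singleton", path)
        return BlockPartition(blocks=[(i, i + 1) for i in range(m)])

    header = lines[0].lower().split()
    header_words = {"chr", "chrom", "chromosome", "start", "stop", "end", "bp1",
                    "bp2", "first", "last", "first_snp", "last_snp", "snp1", "snp2"}
    has_header = any(h in header_words for h in header)
    by_position = has_header and any(h in ("start", "stop", "end", "bp1", "bp2") for h in header)
    if not has_header:
        # headerless: coordinate dialect iff columns 2-3 are integers
        toks = lines[0].split()
        by_position = len(toks) >= 3 and _is_number(toks[1]) and _is_number(toks[2])
    body = lines[1:] if has_header else lines

    if by_position:
        if chrom is None or pos is None:
            raise InputError("coordinate block file needs chrom/pos for the SNPs")
        chrom = np.asarray(chrom).astype(str)
        pos = np.asarray(pos).astype(int)
        for bi, ln in enumerate(body):
            toks = ln.split()
            if len(toks) < 3:
                raise InputError(f"{path}: unparseable record {ln!r}")
            try:
                c, lo, hi = toks[0].removeprefix("chr"), int(toks[1]), int(toks[2])
            except ValueError as exc:
                raise InputError(f"{path}: unparseable record {ln!r}") from exc
            hit = (chrom == c) & (pos >= lo) & (pos <= hi)
            label[hit] = bi
    else:
        id_index = {s: i for i, s in enumerate(snp_ids)}
        for bi, ln in enumerate(body):
            toks = ln.split()
            if len(toks) < 2:
                raise InputError(f"{path}: unparseable record {ln!r}")
            lo = id_index.get(toks[0])
            hi = id_index.get(toks[1])
            if lo is None or hi is None:
                continue
            if hi < lo:
                lo, hi = hi, lo
            label[lo : hi + 1] = bi

    n_orphan = int((label == -1).sum())
    if n_orphan:
        logger.warning("%s: %d SNPs outside all blocks become singletons", path, n_orphan)

    blocks: list[tuple[int, int]] = []
    start = 0
    for i in range(1, m):
        if label[i] != label[start] or label[i] == -1:
            blocks.append((start, i))
            start = i
    blocks.append((start, m))
    return BlockPartition(blocks=blocks)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def compute_block_ld(
    panel: GenotypeMatrix,
    partition: BlockPartition,
    a: float = DEFAULT_A,
) -> list[LDBlock]:
    """Estimate D for every block of a partition."""
    return [compute_ld(panel, s, e, a=a) for s, e in partition]


def ld_scores(blocks: list[LDBlock]) -> np.ndarray:
    """Per-SNP LD score: sum of r^2 to all SNPs in the same block.

    Each SNP counts itself, so scores are >= 1 (cross-block correlation
    is treated as zero by construction of the partition).
    """
    out = []
    for blk in blocks:
        out.append((blk.D**2).sum(axis=1))
    return np.concatenate(out)


def save_ld(blocks: list[LDBlock], path: str) -> None:
    """Cache blocks to a single npz container with a JSON manifest."""
    arrays = {f"D_{i}": blk.D for i, blk in enumerate(blocks)}
    manifest = json.dumps(
        {
            "ranges": [[blk.start, blk.stop] for blk in blocks],
            "a": blocks[0].a if blocks else DEFAULT_A,
        }
    )
    np.savez_compressed(path, manifest=np.array(manifest), **arrays)


def load_ld(path: str) -> list[LDBlock]:
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["manifest"]))
        return [
            LDBlock(start=lo, stop=hi, D=data[f"D_{i}"], a=manifest["a"])
            for i, (lo, hi) in enumerate(manifest["ranges"])
        ]
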