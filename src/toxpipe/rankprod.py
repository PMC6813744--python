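"""Rank-product differential expression with permutation-based pfp.

For one exposure condition with n_t treatment and n_c control replicates,
fold changes are computed for all n_t x n_c replicate pairs.  Within each
pairwise comparison genes are ranked (rank 1 = most up-regulated for the
"up" direction, most down-regulated for "down"; ties get average ranks) and
the rank product is the geometric mean of a gene's ranks across comparisons.
A small rank product means consistently extreme regulation.

Significance is the pfp (percentage of false prediction, the method's FDR
analogue): permutations shuffle gene labels independently within every
comparison column, the expected number of permuted rank products at or below
each observed one is divided by the observed rank position, and the result
is monotonized by a cumulative maximum along increasing rank product, then
clipped to [0, 1].  Genes with pfp below the cutoff (default 0.05) in either
direction are the condition's DEGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model_io import ExpressionMatrix, get_logger
from .expression_prep import ExposureCondition, condition_samples

log = get_logger(__name__)

DIRECTIONS = ("up", "down")


def pairwise_fold_changes(expr: ExpressionMatrix,
                          cond: ExposureCondition) -> pd.DataFrame:
    """All treatment x control replicate log2 differences (genes x k)."""
    treat, ctrl = condition_samples(expr, cond)
    values = expr.values
    cols = {}
    for t in treat:
        for c in ctrl:
            cols[f"{t}/{c}"] = values[t] - values[c]
    return pd.DataFrame(cols, index=values.index)


def _ranks(fc: np.ndarray, direction: str) -> np.ndarray:
    """Per-column ranks; rank 1 = most extreme in the requested direction."""
    signed = -fc if direction == "up" else fc
    return np.apply_along_axis(lambda col: rankdata(col, method="average"),
                               0, signed)


@dataclass
class RankProductResult:
    """Per-gene rank products for one direction, optionally with pfp."""

    genes: pd.Index
    direction: str
    rp: np.ndarray
    rank_position: np.ndarray
    pfp: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"rp": self.rp, "rank_position": self.rank_position}
        if self.pfp is not None:
            data["pfp"] = self.pfp
        return pd.DataFrame(data, index=self.genes)


def rank_product(fc_comparisons: pd.DataFrame, direction: str) -> RankProductResult:
    """Geometric mean of per-comparison ranks (no significance yet)."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if len(fc_comparisons) < 2:
        raise ValueError("rank product needs at least 2 genes")
    ranks = _ranks(fc_comparisons.to_numpy(dtype=float), direction)
    rp = np.exp(np.mean(np.log(ranks), axis=1))
    # rank_position: 1-based position when sorted by increasing rp
    order = np.argsort(rp, kind="stable")
    position = np.empty(len(rp), dtype=int)
    position[order] = np.arange(1, len(rp) + 1)
    return RankProductResult(genes=fc_comparisons.index, direction=direction,
                             rp=rp, rank_position=position)


def estimate_pfp(fc_comparisons: pd.DataFrame, direction: str,
                 n_permutations: int = 1000,
                 seed: int | np.random.Generator = 0) -> RankProductResult:
    """Monte-Carlo pfp for every gene in one direction.

    Each permutation reassigns every comparison column's rank multiset to
    genes uniformly at random (equivalent to shuffling gene labels within
    the column), recomputes rank products, and counts how many permuted
    values fall at or below each observed one.  pfp = expected count /
    observed rank position, step-down monotonized and clipped to [0, 1].
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    result = rank_product(fc_comparisons, direction)
    G, k = fc_comparisons.shape
    ranks = _ranks(fc_comparisons.to_numpy(dtype=float), direction)

    # log-domain permuted rank products, collected over all permutations
    log_ranks = np.log(ranks)  # G x k, the fixed per-column rank multisets
    perm_log_rp = np.zeros((n_permutations, G))
    for j in range(k):
        col = np.broadcast_to(log_ranks[:, j], (n_permutations, G))
        perm_log_rp += rng.permuted(col, axis=1)
    perm_rp = np.exp(perm_log_rp / k).ravel()
    perm_rp.sort()

    # expected number of permuted rp values <= observed, per permutation
    counts = np.searchsorted(perm_rp, result.rp * (1 + 1e-12), side="right")
    expected = counts / n_permutations
    pfp = expected / result.rank_position

    # step-down monotonization along increasing rp, then clip
    order = np.argsort(result.rp, kind="stable")
    pfp_sorted = np.maximum.accumulate(pfp[order])
    mono = np.empty_like(pfp)
    mono[order] = pfp_sorted
    result.pfp = np.clip(mono, 0.0, 1.0)
    return result


def call_degs(up_result: RankProductResult, down_result: RankProductResult,
              pfp_cutoff: float = 0.05) -> pd.DataFrame:
    """DEG table (gene, direction, rp, pfp) at strict pfp < cutoff.

    A gene passing in both directions (possible only under pathological
    ties) keeps the direction with the smaller rank product.
    """
    if not up_result.genes.equals(down_result.genes):
        raise ValueError("up and down results cover different gene universes")
    rows = []
    up_pass = set(np.flatnonzero(up_result.pfp < pfp_cutoff))
    down_pass = set(np.flatnonzero(down_result.pfp < pfp_cutoff))
    both = up_pass & down_pass
    if both:
        log.warning("call_degs: %d genes significant in both directions; "
                    "keeping the smaller rank product", len(both))
    for i in sorted(up_pass | down_pass):
        if i in both:
            direction = "up" if up_result.rp[i] <= down_result.rp[i] else "down"
        else:
            direction = "up" if i in up_pass else "down"
        res = up_result if direction == "up" else down_result
        rows.append((res.genes[i], direction, res.rp[i], res.pfp[i]))
    return pd.DataFrame(rows, columns=["gene", "direction", "rp", "pfp"])


def condition_degs(expr: ExpressionMatrix, cond: ExposureCondition,
                   n_permutations: int = 1000, pfp_cutoff: float = 0.05,
                   seed: int = 0) -> pd.DataFrame:
    """End-to-end DEG calling for one exposure condition."""
    fc = pairwise_fold_changes(expr, cond)
    rng = np.random.default_rng(seed)
    up = estimate_pfp(fc, "up", n_permutations, rng)
    down = estimate_pfp(fc, "down", n_permutations, rng)
    return call_degs(up, down, pfp_cutoff)


def study_degs(expr: ExpressionMatrix, conditions=None,
               n_permutations: int = 1000, pfp_cutoff: float = 0.05,
               seed: int = 0) -> dict[str, pd.DataFrame]:
    """DEG tables for every (or the given) non-control condition."""
    from .expression_prep import conditions_of

    if conditions is None:
        conditions = conditions_of(expr)
    out = {}
    for i, cond in enumerate(conditions):
        out[cond.key] = condition_degs(expr, cond, n_permutations,
                                       pfp_cutoff, seed=seed + i)
    return out
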