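"""Hypergeometric over-representation of gene sets per exposure condition.

The universe is the filtered, analyzable gene set of the test system; the
p-value is the upper hypergeometric tail P(X >= n_hit), Benjamini-Hochberg
adjusted across all sets tested for a condition.  A pathway is *reported*
for a condition when it is significant and more than two DEGs map to it,
and the per-chemical summary is a bipartite chemical-pathway edge list
(a pathway linked to a chemical if reported in any of its conditions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model_io import GeneSetCollection


@dataclass
class EnrichmentResult:
    condition: str
    set_id: str
    n_universe: int
    n_set_in_universe: int
    n_deg: int
    n_hit: int
    p_value: float
    p_adjusted: float = float("nan")
    significant: bool = False
    hit_genes: list[str] = field(default_factory=list)


def hypergeom_enrich(degs: set[str], universe: set[str],
                     collection: GeneSetCollection, alpha: float = 0.05,
                     condition: str = "", adjust: str = "fdr_bh",
                     ) -> list[EnrichmentResult]:
    """One-sided over-representation test for every set in the collection."""
    extra = degs - universe
    if extra:
        raise ValueError(f"DEGs outside the universe: {sorted(extra)[:5]}")
    M, N = len(universe), len(degs)
    results = []
    for set_id, members in collection.sets.items():
        in_universe = set(members) & universe
        hits = in_universe & degs
        n, x = len(in_universe), len(hits)
        # upper tail P(X >= x); x = 0 gives p = 1
        p = float(hypergeom.sf(x - 1, M, n, N)) if N > 0 else 1.0
        results.append(EnrichmentResult(
            condition=condition, set_id=set_id, n_universe=M,
            n_set_in_universe=n, n_deg=N, n_hit=x, p_value=min(p, 1.0),
            hit_genes=sorted(hits)))
    if results:
        pvals = [r.p_value for r in results]
        reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method=adjust)
        for r, padj, rej in zip(results, p_adj, reject):
            r.p_adjusted = float(padj)
            r.significant = bool(r.p_adjusted < alpha)
    return results


def filter_reported(results: list[EnrichmentResult],
                    min_hits: int = 3) -> list[EnrichmentResult]:
    """Keep significant results with at least ``min_hits`` mapped DEGs."""
    return [r for r in results if r.significant and r.n_hit >= min_hits]


def chemical_pathway_network(per_condition_results: dict[str, list[EnrichmentResult]],
                             min_hits: int = 3) -> pd.DataFrame:
    """Bipartite (chemical, pathway) edges with a uniqueness flag.

    An edge exists when the pathway is reported (significant, enough hits)
    in at least one condition of the chemical; pathways linked to exactly
    one chemical are flagged ``unique``.
    """
    edges: set[tuple[str, str]] = set()
    for condition_key, results in per_condition_results.items():
        chemical = condition_key.split("|")[0]
        for r in filter_reported(results, min_hits):
            edges.add((chemical, r.set_id))
    df = pd.DataFrame(sorted(edges), columns=["chemical", "set_id"])
    if df.empty:
        df["unique"] = pd.Series(dtype=bool)
        return df
    degree = df.groupby("set_id")["chemical"].transform("nunique")
    df["unique"] = degree == 1
    return df


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.condition, r.set_id, r.n_universe, r.n_set_in_universe, r.n_deg,
          r.n_hit, r.p_value, r.p_adjusted, r.significant,
          ",".join(r.hit_genes)) for r in results],
        columns=["condition", "set_id", "n_universe", "n_set_in_universe",
                 "n_deg", "n_hit", "p_value", "p_adjusted", "significant",
                 "hit_genes"])
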