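"""Cross-system (parallelogram) overlap analysis.

Signals observed in rat in vivo, rat in vitro, and human in vitro assays
are compared after translating human gene IDs to rat IDs; items conserved
in all three systems are inferred to be relevant to humans in vivo.  Per
system, an item (gene, pathway, or predicted metabolite) is *frequent* when
it appears in at least a threshold fraction (default 5%) of the system's
exposure conditions.  The overlap report carries all seven exclusive Venn
regions plus the triple-intersection member list.  Metabolite score
matrices are summarized by Ward/Euclidean hierarchical clustering on both
axes and the dose-level composition of each condition cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .mie import round_half_away
from .model_io import get_logger

log = get_logger(__name__)


def frequent_items(per_condition_items: dict[str, set[str]],
                   threshold_fraction: float = 0.05) -> set[str]:
    """Items present in >= threshold_fraction of the conditions (inclusive)."""
    if not per_condition_items:
        raise ValueError("need at least one condition")
    n = len(per_condition_items)
    counts: dict[str, int] = {}
    for items in per_condition_items.values():
        for item in items:
            counts[item] = counts.get(item, 0) + 1
    return {item for item, c in counts.items() if c / n >= threshold_fraction}


def map_orthologs(human_items: set[str], ortholog: pd.DataFrame,
                  drop_ambiguous: bool = False) -> set[str]:
    """Translate human gene IDs to rat IDs; one-to-many pairs expand.

    With ``drop_ambiguous`` human genes mapping to multiple rat genes are
    dropped instead of expanded.  Unmapped genes are counted in the log.
    """
    by_human = ortholog.groupby("human_gene")["rat_gene"].apply(set).to_dict()
    out: set[str] = set()
    unmapped = 0
    for gene in human_items:
        rats = by_human.get(gene)
        if not rats:
            unmapped += 1
        elif drop_ambiguous and len(rats) > 1:
            log.info("map_orthologs: dropped ambiguous gene %s (%d orthologs)",
                     gene, len(rats))
        else:
            out |= rats
    if unmapped:
        log.info("map_orthologs: %d of %d genes had no ortholog",
                 unmapped, len(human_items))
    return out


@dataclass
class OverlapReport:
    """Three-way set overlap: all seven exclusive Venn regions."""

    labels: tuple[str, str, str]
    regions: dict[str, set[str]]  # keys like "100", "110", "111"

    @property
    def triple_intersection(self) -> set[str]:
        return self.regions["111"]

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def to_json_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "counts": self.counts(),
            "triple_intersection": sorted(self.regions["111"]),
        }


def three_way_overlap(set_a: set[str], set_b: set[str], set_c: set[str],
                      labels: tuple[str, str, str] = ("a", "b", "c"),
                      ) -> OverlapReport:
    """Exclusive Venn regions of three sets over a common ID space."""
    regions: dict[str, set[str]] = {}
    for mask in ("100", "010", "001", "110", "101", "011", "111"):
        ina, inb, inc = (m == "1" for m in mask)
        region = set()
        for item in set_a | set_b | set_c:
            if ((item in set_a) == ina and (item in set_b) == inb
                    and (item in set_c) == inc):
                region.add(item)
        regions[mask] = region
    return OverlapReport(labels=labels, regions=regions)


def cluster_scores(scores: pd.DataFrame, k_metabolite: int = 3,
                   k_condition: int = 3) -> tuple[pd.Series, pd.Series]:
    """Ward/Euclidean hierarchical clustering of a metabolites x conditions
    score matrix, each axis cut independently into k flat clusters.

    Returns (metabolite labels, condition labels), 1-based cluster IDs.
    """
    arr = scores.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("score matrix must be finite")
    if k_metabolite > arr.shape[0] or k_condition > arr.shape[1]:
        raise ValueError("k exceeds axis length")

    def _cut(data: np.ndarray, k: int) -> np.ndarray:
        if k == 1 or data.shape[0] == 1:
            return np.ones(data.shape[0], dtype=int)
        Z = linkage(data, method="ward", metric="euclidean")
        return fcluster(Z, t=k, criterion="maxclust")

    met_labels = pd.Series(_cut(arr, k_metabolite), index=scores.index,
                           name="metabolite_cluster")
    cond_labels = pd.Series(_cut(arr.T, k_condition), index=scores.columns,
                            name="condition_cluster")
    return met_labels, cond_labels


def dose_composition(cluster_assignments: pd.Series,
                     metadata: pd.DataFrame) -> pd.DataFrame:
    """Rounded integer percentage of each dose level within each cluster.

    ``metadata`` must provide a ``dose_level`` per condition key (its index
    aligned with the assignment index).
    """
    missing = [c for c in cluster_assignments.index if c not in metadata.index]
    if missing:
        raise ValueError(f"conditions without dose level: {missing[:5]}")
    rows = []
    for cluster_id in sorted(cluster_assignments.unique()):
        conds = cluster_assignments.index[cluster_assignments == cluster_id]
        doses = metadata.loc[conds, "dose_level"]
        n = len(doses)
        for dose in sorted(doses.unique()):
            pct = round_half_away(100.0 * (doses == dose).sum() / n)
            rows.append((int(cluster_id), dose, pct))
    return pd.DataFrame(rows, columns=["cluster", "dose_level", "pct"])
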