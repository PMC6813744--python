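"""Post-normalization preprocessing of exposure-study expression data.

Input is an already-normalized log2 expression matrix.  The steps here are
non-specific gene filtering (annotation presence + variance), averaging of
replicates within each exposure group, log-ratios of each treatment
condition against its matched control group, and the ternary fold-change
discretization used for reporting heatmaps.

An *exposure condition* is one (chemical, dose level, duration, test system)
cell; the fold-change matrix has one column per non-control condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import ExpressionMatrix, get_logger

log = get_logger(__name__)


class PrepError(ValueError):
    pass


@dataclass(frozen=True)
class ExposureCondition:
    """One (chemical, dose, duration, system) exposure cell."""

    chemical: str
    dose_level: str
    duration: str
    test_system: str

    @property
    def key(self) -> str:
        return f"{self.chemical}|{self.dose_level}|{self.duration}|{self.test_system}"

    @classmethod
    def from_key(cls, key: str) -> "ExposureCondition":
        chemical, dose, duration, system = key.split("|")
        return cls(chemical, dose, duration, system)


def conditions_of(expr: ExpressionMatrix) -> list[ExposureCondition]:
    """Distinct non-control exposure conditions present in the metadata."""
    meta = expr.metadata
    treat = meta[meta["dose_level"] != "control"]
    seen: dict[str, ExposureCondition] = {}
    for _, row in treat.iterrows():
        cond = ExposureCondition(row["chemical"], row["dose_level"],
                                 row["duration"], row["test_system"])
        seen.setdefault(cond.key, cond)
    return list(seen.values())


def condition_samples(expr: ExpressionMatrix,
                      cond: ExposureCondition) -> tuple[list[str], list[str]]:
    """(treatment sample IDs, control sample IDs) for one condition.

    Control samples are matched through the explicit ``control_group``
    column: every treatment sample names its control group, and control
    samples carry the group name they belong to.
    """
    meta = expr.metadata
    mask = (
        (meta["chemical"] == cond.chemical)
        & (meta["dose_level"] == cond.dose_level)
        & (meta["duration"] == cond.duration)
        & (meta["test_system"] == cond.test_system)
    )
    treat = meta.index[mask].tolist()
    if not treat:
        raise PrepError(f"no samples for condition {cond.key}")
    groups = set(meta.loc[treat, "control_group"])
    if len(groups) != 1:
        raise PrepError(
            f"condition {cond.key} maps to multiple control groups: {groups}")
    group = groups.pop()
    ctrl = meta.index[(meta["dose_level"] == "control")
                      & (meta["control_group"] == group)].tolist()
    if not ctrl:
        raise PrepError(f"condition {cond.key}: control group {group!r} empty")
    return treat, ctrl


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def filter_genes(expr: ExpressionMatrix,
                 annotation: dict[str, str | None],
                 variance_quantile: float = 0.25,
                 min_expression_floor: float | None = None) -> ExpressionMatrix:
    """Drop unannotated and low-variance genes.

    A gene survives if (a) ``annotation`` maps it to a non-null external ID
    and (b) its population variance across all samples is at or above the
    ``variance_quantile`` quantile of the variance distribution (computed
    over all genes before any removal).  ``min_expression_floor``, when set,
    additionally drops genes whose maximum sample value is below the floor —
    a stand-in for presence/absence filtering that would need probe-level
    data.
    """
    if not 0 <= variance_quantile < 1:
        raise PrepError("variance_quantile must be in [0, 1)")
    values = expr.values
    annotated = np.array([annotation.get(g) is not None for g in values.index])
    variances = values.var(axis=1, ddof=0)
    threshold = float(np.quantile(variances.to_numpy(), variance_quantile))
    high_var = variances >= threshold
    keep = annotated & high_var.to_numpy()
    if min_expression_floor is not None:
        keep &= (values.max(axis=1) >= min_expression_floor).to_numpy()
    n_anno = int((~annotated).sum())
    n_var = int((annotated & ~high_var.to_numpy()).sum())
    log.info("filter_genes: removed %d unannotated [reason=no_external_id], "
             "%d low-variance [reason=below_q%.2f]; %d of %d genes kept",
             n_anno, n_var, variance_quantile, int(keep.sum()), len(values))
    if not keep.any():
        raise PrepError("all genes removed by filtering")
    return ExpressionMatrix(values=values.loc[keep],
                            metadata=expr.metadata)


def average_replicates(expr: ExpressionMatrix) -> pd.DataFrame:
    """Mean log2 intensity per exposure group (genes x groups).

    Treatment groups are keyed by their condition key; control groups by
    their ``control_group`` name.  Single-replicate groups pass through.
    """
    meta = expr.metadata
    group_keys: dict[str, str] = {}
    for sid, row in meta.iterrows():
        if row["dose_level"] == "control":
            group_keys[sid] = str(row["control_group"])
        else:
            cond = ExposureCondition(row["chemical"], row["dose_level"],
                                     row["duration"], row["test_system"])
            group_keys[sid] = cond.key
    cols = [s for s in expr.samples if s in group_keys]
    keys = [group_keys[s] for s in cols]
    return expr.values[cols].T.groupby(pd.Series(keys, index=cols)).mean().T


def control_pairing(expr: ExpressionMatrix) -> dict[str, str]:
    """Map each non-control condition key to its control group key."""
    pairing: dict[str, str] = {}
    for cond in conditions_of(expr):
        treat, _ = condition_samples(expr, cond)
        pairing[cond.key] = str(expr.metadata.loc[treat[0], "control_group"])
    return pairing


def compute_log_ratios(group_means: pd.DataFrame,
                       pairing: dict[str, str]) -> pd.DataFrame:
    """log2FC(gene, condition) = treatment group mean - control group mean."""
    missing = [c for c in pairing.values() if c not in group_means.columns]
    if missing:
        raise PrepError(f"control groups missing from group means: {missing}")
    absent = [c for c in pairing if c not in group_means.columns]
    if absent:
        raise PrepError(f"treatment conditions missing from group means: {absent}")
    fc = pd.DataFrame(
        {cond: group_means[cond] - group_means[ctrl]
         for cond, ctrl in pairing.items()},
        index=group_means.index,
    )
    fc.columns.name = "condition"
    return fc


def fold_change_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Convenience: average replicates then take paired log-ratios."""
    return compute_log_ratios(average_replicates(expr), control_pairing(expr))


def discretize_fc(fc: pd.DataFrame, cutoff: float = 0.6) -> pd.DataFrame:
    """Ternary up/none/down calls; the closed band [-cutoff, cutoff] is none."""
    if cutoff <= 0:
        raise PrepError("cutoff must be positive")
    arr = fc.to_numpy(dtype=float)
    out = np.full(arr.shape, "none", dtype=object)
    out[arr > cutoff] = "up"
    out[arr < -cutoff] = "down"
    return pd.DataFrame(out, index=fc.index, columns=fc.columns)
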