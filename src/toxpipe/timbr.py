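"""TIMBR: transcriptionally inferred metabolic biomarker response.

Given a stoichiometric model and per-condition DEG log2 fold changes, TIMBR
scores each exchangeable metabolite by comparing the *global network demand*
needed to produce it under control-derived versus treatment-derived reaction
weights.

Pipeline per (condition, metabolite):

1.  Map DEG log2FC values onto reactions through the gene-protein-reaction
    (GPR) rules: AND is the signed minimum of its operands (a complex is
    limited by its most depleted subunit), OR the signed maximum (isozymes
    dominated by the most induced member); genes without a fold change
    contribute 0, and a reaction with no GPR gets 0.
2.  Transform each reaction's fold change Delta into a weight pair
    w_treatment = baseline * 2^(-scale * Delta) and
    w_control   = baseline * 2^(+scale * Delta),
    so up-regulated reactions are cheap in the treatment network and costly
    in the control network (w_t * w_c = baseline^2 always).
3.  Compute v_max, the maximum achievable secretion flux of the metabolite
    (plain flux balance: maximize the exchange flux subject to S v = 0 and
    bounds), once per model/bounds — weights play no role here.
4.  Solve the weighted demand LP: X = min sum_j w_j |v_j| subject to
    S v = 0, bounds, and exchange flux >= opt_fraction * v_max.  The
    absolute value is linearized by splitting every reaction into
    nonnegative forward and backward parts carrying the same weight.
5.  Score X_raw = (X_control - X_treatment) / (X_control + X_treatment),
    z-transform across the condition's exchangeable metabolites (population
    standard deviation), and call increased (z > 0.1), decreased
    (z < -0.1), or unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_io import GPRNode, MetabolicModel, get_logger

log = get_logger(__name__)


class TimbrError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# GPR-level fold-change mapping and weights
# ---------------------------------------------------------------------------


def evaluate_gpr(tree: GPRNode | None, gene_fc: dict[str, float]) -> float:
    """Signed min/max evaluation of a GPR over log2FC values (missing -> 0)."""
    if tree is None:
        return 0.0
    if tree.op == "gene":
        return float(gene_fc.get(tree.gene, 0.0))
    vals = [evaluate_gpr(child, gene_fc) for child in tree.children]
    return min(vals) if tree.op == "and" else max(vals)


def reaction_log2fc(model: MetabolicModel,
                    gene_fc: dict[str, float]) -> dict[str, float]:
    """Per-reaction fold change Delta from the GPR trees."""
    return {rxn.id: evaluate_gpr(rxn.gpr_tree, gene_fc)
            for rxn in model.reactions}


@dataclass
class TIMBRWeights:
    """Paired control/treatment weight vectors over the model's reactions."""

    reaction_ids: list[str]
    delta: np.ndarray
    w_control: np.ndarray
    w_treatment: np.ndarray


def compute_weights(delta: dict[str, float], scale: float = 0.5,
                    baseline: float = 1.0) -> TIMBRWeights:
    """Fold changes -> positive weight pairs with w_t * w_c = baseline^2."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    ids = list(delta)
    d = np.array([delta[r] for r in ids], dtype=float)
    return TIMBRWeights(
        reaction_ids=ids,
        delta=d,
        w_control=baseline * np.power(2.0, scale * d),
        w_treatment=baseline * np.power(2.0, -scale * d),
    )


# ---------------------------------------------------------------------------
# Linear programs
# ---------------------------------------------------------------------------


def apply_bounds_profile(model: MetabolicModel,
                         profile: dict[str, tuple[float, float]]) -> None:
    """Fix exchange-reaction bounds from a named uptake/secretion profile."""
    exchange = set(model.exchange_reactions)
    for rxn_id, (lb, ub) in profile.items():
        if rxn_id not in exchange:
            raise TimbrError(f"bounds profile names non-exchange reaction {rxn_id}")
        rxn = model.reaction(rxn_id)
        rxn.lb, rxn.ub = float(lb), float(ub)
        if rxn.lb > rxn.ub:
            raise TimbrError(f"bounds profile for {rxn_id}: lb > ub")


def max_production(model: MetabolicModel, met_id: str) -> float:
    """Maximum secretion flux of a metabolite (weights play no role)."""
    ex_id = model.exchange_for(met_id)
    met = model.metabolite(met_id)
    if ex_id is None or not met.exchangeable:
        raise TimbrError(f"metabolite {met_id} has no secretion exchange")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    j = model._rxn_index[ex_id]
    c = np.zeros(len(model.reactions))
    c[j] = -1.0  # maximize exchange flux
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        raise TimbrError(f"max_production LP failed for {met_id}: {res.message}")
    return max(float(-res.fun), 0.0)


@dataclass
class DemandResult:
    metabolite: str
    X: float
    v_max: float
    v_opt: float
    flux: np.ndarray


def network_demand(model: MetabolicModel, weights: np.ndarray, met_id: str,
                   opt_fraction: float = 0.9,
                   v_max: float | None = None) -> DemandResult:
    """Minimum weighted total flux while producing the metabolite.

    ``weights`` is one per-reaction vector (pick the control or treatment
    column of :class:`TIMBRWeights`), aligned with ``model.reactions``.
    """
    if not 0 < opt_fraction <= 1:
        raise ValueError("opt_fraction must be in (0, 1]")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(model.reactions),):
        raise ValueError("weights must align with model.reactions")
    if (weights <= 0).any():
        raise ValueError("weights must be positive")
    if v_max is None:
        v_max = max_production(model, met_id)
    if v_max <= 0:
        raise TimbrError(f"metabolite {met_id} is unproducible (v_max = 0)")
    ex_id = model.exchange_for(met_id)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    n = len(model.reactions)
    j = model._rxn_index[ex_id]
    v_opt = opt_fraction * v_max

    # v = f - b with f, b >= 0 carrying the same weight; bounds split so
    # that f - b always stays inside [lb, ub]
    f_lb, f_ub = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
    b_lb, b_ub = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
    c = np.concatenate([weights, weights])
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    A_ineq = np.zeros((1, 2 * n))
    A_ineq[0, j], A_ineq[0, n + j] = -1.0, 1.0  # -(f_j - b_j) <= -v_opt
    bounds = list(zip(f_lb, f_ub)) + list(zip(b_lb, b_ub))
    res = linprog(c, A_ub=A_ineq, b_ub=np.array([-v_opt]), A_eq=A_eq,
                  b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        raise TimbrError(
            f"network demand LP infeasible for metabolite {met_id}: {res.message}")
    flux = res.x[:n] - res.x[n:]
    return DemandResult(metabolite=met_id, X=float(res.fun), v_max=v_max,
                        v_opt=v_opt, flux=flux)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def production_score(x_control: float, x_treatment: float) -> float:
    """Relative production score in [-1, 1]; a 0/0 demand pair scores 0."""
    total = x_control + x_treatment
    if total <= 0:
        log.info("production_score: zero total demand, score defined as 0")
        return 0.0
    return (x_control - x_treatment) / total


def z_scores_and_call(raw: dict[str, float],
                      cutoff: float = 0.1) -> pd.DataFrame:
    """Z-transform raw scores across the condition's metabolites and call.

    Population standard deviation; strict cutoffs (z exactly at the cutoff
    is unchanged).  A degenerate condition (all raw scores equal) yields
    all-unchanged calls.
    """
    if len(raw) < 2:
        raise ValueError("need >= 2 metabolites to z-transform")
    mets = list(raw)
    x = np.array([raw[m] for m in mets], dtype=float)
    mu, sigma = float(np.mean(x)), float(np.std(x, ddof=0))
    if sigma == 0:
        log.info("z_scores_and_call: zero variance, all calls unchanged")
        z = np.zeros_like(x)
    else:
        z = (x - mu) / sigma
    calls = np.where(z > cutoff, "increased",
                     np.where(z < -cutoff, "decreased", "unchanged"))
    return pd.DataFrame({"metabolite": mets, "x_raw": x, "x_s": z,
                         "call": calls})


def exchangeable_targets(model: MetabolicModel,
                         subset: list[str] | None = None) -> list[str]:
    """Scoreable metabolites: exchangeable, with an exchange reaction."""
    mets = [m.id for m in model.metabolites
            if m.exchangeable and model.exchange_for(m.id) is not None]
    if subset is not None:
        keep = set(subset)
        mets = [m for m in mets if m in keep]
    return mets


def condition_scores(model: MetabolicModel, gene_fc: dict[str, float],
                     opt_fraction: float = 0.9, scale: float = 0.5,
                     baseline: float = 1.0, cutoff: float = 0.1,
                     metabolite_subset: list[str] | None = None,
                     ) -> pd.DataFrame:
    """Full TIMBR scoring of one condition's DEG fold changes.

    Returns one row per scoreable metabolite with X_control, X_treatment,
    X_raw, X_s and the increased/unchanged/decreased call.
    """
    delta = reaction_log2fc(model, gene_fc)
    weights = compute_weights(delta, scale=scale, baseline=baseline)
    order = {r: i for i, r in enumerate(weights.reaction_ids)}
    perm = [order[r.id] for r in model.reactions]
    w_ctrl = weights.w_control[perm]
    w_trt = weights.w_treatment[perm]

    rows = {}
    raw: dict[str, float] = {}
    for met_id in exchangeable_targets(model, metabolite_subset):
        v_max = max_production(model, met_id)
        if v_max <= 0:
            log.info("condition_scores: %s unproducible, skipped", met_id)
            continue
        d_ctrl = network_demand(model, w_ctrl, met_id, opt_fraction, v_max)
        d_trt = network_demand(model, w_trt, met_id, opt_fraction, v_max)
        raw[met_id] = production_score(d_ctrl.X, d_trt.X)
        rows[met_id] = (d_ctrl.X, d_trt.X)
    if len(raw) < 2:
        raise TimbrError("fewer than 2 scoreable metabolites")
    scored = z_scores_and_call(raw, cutoff=cutoff)
    scored["x_control"] = [rows[m][0] for m in scored["metabolite"]]
    scored["x_treatment"] = [rows[m][1] for m in scored["metabolite"]]
    return scored[["metabolite", "x_control", "x_treatment", "x_raw", "x_s",
                   "call"]]
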