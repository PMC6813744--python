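"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: multi-condition
expression studies with planted dose-dependent differential expression, a
small mass-balanced metabolic model with gene-protein-reaction rules over
the synthetic gene universe, gene-set collections, TF-target maps, and
ortholog tables with planted cross-system conserved signals.

The expression generator emulates the structure of a multi-chemical
exposure study: per-gene baselines drawn once and shared across all
conditions of a study (gene-specific platform intensity), per-condition
planted shifts for a dose-dependent fraction of genes (more DEGs at higher
dose, not larger fold changes), and i.i.d. Gaussian replicate noise.  All
generators are pure functions of (design, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_io import (
    ExpressionMatrix,
    GeneSetCollection,
    MetabolicModel,
    Metabolite,
    Reaction,
    get_logger,
    write_expression_study,
    write_gmt,
    write_metabolic_model,
    write_orthologs,
    write_tf_targets,
)

log = get_logger(__name__)

DOSE_ORDER = ("low", "medium", "high")


@dataclass
class StudyDesign:
    """Design of one synthetic exposure study (one test system).

    ``deg_fraction_by_dose`` must be monotone non-decreasing with dose;
    planted shift magnitudes spread around ``effect_size`` (normal with
    sd = effect_size/3, folded at zero, so the nominal effect is the
    typical planted effect, not merely the average) with equiprobable
    sign.  ``conserved_genes`` are planted up-regulated in every
    non-control condition (a cross-system conserved signal).
    """

    n_genes: int = 2000
    chemicals: tuple[str, ...] = ("chemA", "chemB")
    dose_levels: tuple[str, ...] = ("low", "medium", "high")
    durations: tuple[str, ...] = ("24h",)
    test_system: str = "rat_in_vivo"
    replicates_per_group: int = 3
    deg_fraction_by_dose: dict[str, float] = field(
        default_factory=lambda: {"low": 0.02, "medium": 0.05, "high": 0.10})
    effect_size: float = 1.5
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0
    gene_prefix: str = "g"
    conserved_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")
        fracs = [self.deg_fraction_by_dose[d] for d in self.dose_levels]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("deg fractions must be in [0, 1]")
        ordered = [self.deg_fraction_by_dose[d] for d in DOSE_ORDER
                   if d in self.dose_levels]
        if any(a > b for a, b in zip(ordered, ordered[1:])):
            raise ValueError("deg fraction must be non-decreasing with dose")
        unknown = set(self.dose_levels) - set(DOSE_ORDER)
        if unknown:
            raise ValueError(f"unknown dose levels: {sorted(unknown)}")

    @property
    def genes(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"{self.gene_prefix}{i:0{width}d}" for i in range(1, self.n_genes + 1)]


def generate_expression_study(design: StudyDesign,
                              ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate one study; returns the matrix and the planted truth table.

    The truth table has one row per planted (condition, gene) with columns
    condition, gene, direction, shift; genes absent for a condition are
    null (no planted effect).
    """
    rng = np.random.default_rng(design.seed)
    genes = design.genes
    gene_index = {g: i for i, g in enumerate(genes)}
    baselines = rng.normal(design.baseline_mean, design.baseline_sd,
                           design.n_genes)
    conserved_idx = np.array(
        [gene_index[g] for g in design.conserved_genes], dtype=int)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    truth_rows = []
    # magnitudes spread around the nominal effect (folded at zero)
    mag_sd = design.effect_size / 3.0

    for chem in design.chemicals:
        for dur in design.durations:
            group = f"{chem}|{dur}|ctrl"
            for rep in range(1, design.replicates_per_group + 1):
                sid = f"{chem}_control_{dur}_r{rep}"
                columns[sid] = baselines + rng.normal(
                    0.0, design.noise_sd, design.n_genes)
                meta_rows.append((sid, chem, "control", dur,
                                  design.test_system, rep, group))
            for dose in design.dose_levels:
                cond_key = f"{chem}|{dose}|{dur}|{design.test_system}"
                frac = design.deg_fraction_by_dose[dose]
                n_deg = int(round(frac * design.n_genes))
                shifts = np.zeros(design.n_genes)
                free = np.setdiff1d(np.arange(design.n_genes), conserved_idx)
                chosen = rng.choice(free, size=min(n_deg, len(free)),
                                    replace=False)
                mags = np.abs(rng.normal(design.effect_size, mag_sd,
                                         len(chosen)))
                signs = rng.choice([-1.0, 1.0], size=len(chosen))
                shifts[chosen] = signs * mags
                if len(conserved_idx):
                    shifts[conserved_idx] = np.abs(rng.normal(
                        design.effect_size, 0.1 * design.effect_size,
                        len(conserved_idx)))
                for idx in np.concatenate([chosen, conserved_idx]).astype(int):
                    truth_rows.append((
                        cond_key, genes[idx],
                        "up" if shifts[idx] > 0 else "down",
                        float(shifts[idx])))
                for rep in range(1, design.replicates_per_group + 1):
                    sid = f"{chem}_{dose}_{dur}_r{rep}"
                    columns[sid] = (baselines + shifts + rng.normal(
                        0.0, design.noise_sd, design.n_genes))
                    meta_rows.append((sid, chem, dose, dur,
                                      design.test_system, rep, group))

    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "chemical", "dose_level", "duration",
                 "test_system", "replicate", "control_group"],
    ).set_index("sample_id")
    truth = pd.DataFrame(
        truth_rows, columns=["condition", "gene", "direction", "shift"])
    return ExpressionMatrix(values=values, metadata=meta), truth


# ---------------------------------------------------------------------------
# Toy metabolic model
# ---------------------------------------------------------------------------


def _random_gpr(rng: np.random.Generator, gene_universe: list[str]) -> str:
    n = int(rng.integers(1, 4))
    picks = list(rng.choice(gene_universe, size=min(n, len(gene_universe)),
                            replace=False))
    if len(picks) == 1:
        return picks[0]
    op = " and " if rng.random() < 0.5 else " or "
    return op.join(picks)


def generate_toy_model(n_internal_metabolites: int, n_exchange: int,
                       gene_universe: list[str], seed: int = 0,
                       max_retries: int = 5) -> MetabolicModel:
    """Small mass-balanced model with one uptake and >= 1 secretion exchange.

    The uptake boundary metabolite ``U`` is the medium nutrient: it feeds
    the network (exchange lb = -10) but is not itself a scored product, so
    it carries ``exchangeable=False`` (net export of the sole imported
    species is impossible under mass balance).  A linear backbone runs from
    U through the internal metabolites to the first secreted metabolite;
    every further exchangeable metabolite branches off a random backbone
    position, plus a few reversible shortcut reactions for variety.  Every
    exchangeable metabolite is producible from the uptake by construction
    (verified with flux balance; regenerated on failure up to
    ``max_retries``).  ``n_exchange`` counts all boundary reactions, the
    uptake included.
    """
    if n_exchange < 2:
        raise ValueError("need n_exchange >= 2 (one uptake, one secretion)")
    if not gene_universe:
        raise ValueError("gene_universe must be nonempty")
    from .timbr import max_production  # deferred: timbr imports model_io only

    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        ex_mets = [f"E{i}" for i in range(1, n_exchange)]
        in_mets = [f"I{i}" for i in range(1, n_internal_metabolites + 1)]
        metabolites = (
            [Metabolite("U", "uptake nutrient", exchangeable=False)]
            + [Metabolite(m, m, exchangeable=True) for m in ex_mets]
            + [Metabolite(m, m, exchangeable=False) for m in in_mets]
        )
        backbone = ["U"] + in_mets
        reactions = []
        reactions.append(Reaction("EX_U", "uptake U", -10.0, 1000.0, "",
                                  {"U": -1.0}))
        for m in ex_mets:
            reactions.append(Reaction(f"EX_{m}", f"secrete {m}", 0.0, 1000.0,
                                      "", {m: -1.0}))
        # backbone conversions
        for a, b in zip(backbone, backbone[1:]):
            reversible = rng.random() < 0.3
            reactions.append(Reaction(
                f"R_{a}_{b}", f"{a} -> {b}",
                -1000.0 if reversible else 0.0, 1000.0,
                _random_gpr(rng, gene_universe), {a: -1.0, b: 1.0}))
        # branches feeding each secreted metabolite from the backbone
        for m in ex_mets:
            src = backbone[int(rng.integers(0, len(backbone)))]
            reactions.append(Reaction(
                f"R_{src}_{m}", f"{src} -> {m}", 0.0, 1000.0,
                _random_gpr(rng, gene_universe), {src: -1.0, m: 1.0}))
        # a couple of reversible shortcuts between distinct backbone nodes
        if len(backbone) > 2:
            for s in range(min(2, len(backbone) - 2)):
                i, j = sorted(rng.choice(len(backbone), size=2, replace=False))
                if i == j:
                    continue
                a, b = backbone[i], backbone[j]
                rid = f"R_sc{s}_{a}_{b}"
                if any(r.id == rid for r in reactions):
                    continue
                reactions.append(Reaction(
                    rid, f"{a} <-> {b}", -1000.0, 1000.0,
                    _random_gpr(rng, gene_universe), {a: -1.0, b: 1.0}))
        model = MetabolicModel(metabolites=metabolites, reactions=reactions)
        try:
            if all(max_production(model, m) > 0 for m in ex_mets):
                return model
        except Exception:  # infeasible draw: retry with a fresh topology
            pass
        log.info("generate_toy_model: attempt %d infeasible, retrying", attempt)
    raise RuntimeError(f"no feasible topology after {max_retries} attempts")


# ---------------------------------------------------------------------------
# Annotations: gene sets, TF targets, orthologs
# ---------------------------------------------------------------------------


def generate_annotations(gene_universe: list[str], n_sets: int = 20,
                         n_tfs: int = 10, seed: int = 0,
                         set_size_range: tuple[int, int] = (10, 50),
                         targets_range: tuple[int, int] = (5, 50),
                         ortholog_fraction: float = 0.9,
                         one_to_many_fraction: float = 0.05,
                         human_prefix: str = "h_",
                         ) -> tuple[GeneSetCollection, pd.DataFrame, pd.DataFrame]:
    """Gene sets, a TF-target map, and a human->rat ortholog table.

    The ortholog table treats ``gene_universe`` as the rat ID space and
    derives human IDs by prefixing; a planted minority of human genes maps
    to two rat genes (one-to-many), the rest one-to-one.
    """
    if not gene_universe:
        raise ValueError("gene_universe must be nonempty")
    rng = np.random.default_rng(seed)
    universe = list(gene_universe)
    G = len(universe)

    sets: dict[str, list[str]] = {}
    for i in range(1, n_sets + 1):
        lo, hi = set_size_range
        size = int(rng.integers(lo, min(hi, G) + 1)) if G > lo else max(1, G)
        size = min(size, G)
        members = list(rng.choice(universe, size=size, replace=False))
        sets[f"P{i:03d}"] = members
    collection = GeneSetCollection(
        sets=sets, descriptions={k: f"synthetic pathway {k}" for k in sets})

    tf_rows = []
    tfs = list(rng.choice(universe, size=min(n_tfs, G), replace=False))
    for tf in tfs:
        lo, hi = targets_range
        size = int(rng.integers(lo, min(hi, G) + 1)) if G > lo else max(1, G)
        targets = rng.choice(universe, size=min(size, G), replace=False)
        for tgt in targets:
            if tgt == tf:
                continue
            mode = rng.choice(["activation", "repression", "unknown"])
            tf_rows.append((tf, tgt, mode))
    tf_map = pd.DataFrame(tf_rows, columns=["tf", "target", "mode"]
                          ).drop_duplicates(subset=["tf", "target"])

    n_mapped = int(round(ortholog_fraction * G))
    mapped = list(rng.choice(universe, size=n_mapped, replace=False))
    orth_rows = [(f"{human_prefix}{g}", g) for g in mapped]
    n_multi = int(round(one_to_many_fraction * n_mapped))
    if n_multi and n_mapped:
        multi = rng.choice(mapped, size=n_multi, replace=False)
        for g in multi:
            extra = universe[int(rng.integers(0, G))]
            if extra != g:
                orth_rows.append((f"{human_prefix}{g}", extra))
    orthologs = pd.DataFrame(orth_rows, columns=["human_gene", "rat_gene"]
                             ).drop_duplicates()
    return collection, tf_map, orthologs


# ---------------------------------------------------------------------------
# Full fixture directory (three test systems + shared annotations)
# ---------------------------------------------------------------------------


def generate_fixture_directory(outdir: str | Path, seed: int = 0,
                               n_genes: int = 2000,
                               n_conserved: int = 8,
                               chemicals: tuple[str, ...] = ("chemA", "chemB"),
                               replicates: int = 3,
                               ortholog_fraction: float = 1.0,
                               ) -> dict[str, Path]:
    """Emit every pipeline input for a three-system parallelogram study.

    Rat in vivo and rat in vitro studies share a rat gene universe; the
    human in vitro study uses prefixed human IDs related to the rat space
    through the generated ortholog table.  ``n_conserved`` genes are
    planted up-regulated in every condition of all three systems — the
    known cross-system conserved signal.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    base = StudyDesign(n_genes=n_genes, chemicals=chemicals,
                       replicates_per_group=replicates, seed=seed)
    rat_genes = base.genes
    conserved = list(rng.choice(rat_genes, size=n_conserved, replace=False))

    collection, tf_map, orthologs = generate_annotations(
        rat_genes, seed=seed + 1, ortholog_fraction=ortholog_fraction)
    # planted conserved genes must survive ortholog translation
    have = set(orthologs["rat_gene"])
    extra = [(f"h_{g}", g) for g in conserved if g not in have]
    if extra:
        orthologs = pd.concat(
            [orthologs, pd.DataFrame(extra, columns=orthologs.columns)],
            ignore_index=True).drop_duplicates()

    paths: dict[str, Path] = {}
    truth_all = {}
    systems = {
        "rat_in_vivo": (rat_genes, "g", tuple(conserved), seed + 10),
        "rat_in_vitro": (rat_genes, "g", tuple(conserved), seed + 20),
        "human_in_vitro": (None, "h_g", tuple(f"h_{g}" for g in conserved),
                           seed + 30),
    }
    for system, (genes_, prefix, cons, sseed) in systems.items():
        design = StudyDesign(
            n_genes=n_genes, chemicals=chemicals,
            replicates_per_group=replicates, test_system=system,
            seed=sseed, gene_prefix=prefix, conserved_genes=cons)
        expr, truth = generate_expression_study(design)
        mpath = outdir / f"{system}_expression.tsv"
        dpath = outdir / f"{system}_metadata.tsv"
        write_expression_study(expr, mpath, dpath)
        paths[f"{system}_expression"] = mpath
        paths[f"{system}_metadata"] = dpath
        truth_all[system] = truth.to_dict(orient="records")

    model = generate_toy_model(6, 4, rat_genes, seed=seed + 2)
    paths["model"] = outdir / "model.json"
    write_metabolic_model(model, paths["model"])
    paths["gene_sets"] = outdir / "gene_sets.gmt"
    write_gmt(collection, paths["gene_sets"])
    paths["tf_targets"] = outdir / "tf_targets.tsv"
    write_tf_targets(tf_map, paths["tf_targets"])
    paths["orthologs"] = outdir / "orthologs.tsv"
    write_orthologs(orthologs, paths["orthologs"])
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump({"conserved_genes": conserved, "per_system": truth_all},
                  fh, indent=1)
    log.info("generate_fixture_directory: wrote %d files to %s",
             len(paths), outdir)
    return paths
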