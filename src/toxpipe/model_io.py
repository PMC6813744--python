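"""Readers and writers for the pipeline's external formats.

Everything the pipeline touches on disk goes through this module:
expression studies (TSV matrix + sample metadata), gene-set collections
(GMT), transcription-factor target tables, ortholog maps, and metabolic
models (JSON).  Loaders validate eagerly — a malformed gene-protein-reaction
(GPR) rule or an inconsistent stoichiometric matrix fails at load time, not
mid-analysis — and every dropped or coerced record is logged with a reason.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

# ---------------------------------------------------------------------------
# Logging
# ---------------------------------------------------------------------------

LOG_FORMAT = "%(asctime)s %(levelname)s %(name)s :: %(message)s"

DOSE_LEVELS = ("control", "low", "medium", "high")
TEST_SYSTEMS = ("rat_in_vivo", "rat_in_vitro", "human_in_vitro")

METADATA_COLUMNS = (
    "sample_id",
    "chemical",
    "dose_level",
    "duration",
    "test_system",
    "replicate",
    "control_group",
)


def get_logger(name: str = "toxpipe", verbose: bool = False,
               logfile: str | Path | None = None) -> logging.Logger:
    """Structured logger writing timestamped lines to stderr (and a file)."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(LOG_FORMAT))
        logger.addHandler(handler)
    if logfile is not None and not any(
        isinstance(h, logging.FileHandler) for h in logger.handlers
    ):
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter(LOG_FORMAT))
        logger.addHandler(fh)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    return logger


log = get_logger(__name__)


class ModelIOError(ValueError):
    """Raised on any validation failure while loading pipeline inputs."""


# ---------------------------------------------------------------------------
# Expression studies
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities plus per-sample metadata.

    ``values`` is a DataFrame indexed by gene ID with one column per sample;
    ``metadata`` is indexed by sample_id with columns chemical, dose_level,
    duration, test_system, replicate, control_group.  For treatment samples
    ``control_group`` names the control group they are compared against;
    for control samples it names the group they belong to (shared controls
    across durations are expressed this way, never inferred).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        validate_expression_matrix(self)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def validate_expression_matrix(expr: ExpressionMatrix) -> None:
    values, meta = expr.values, expr.metadata
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ModelIOError(f"duplicate gene IDs: {dups[:5]}")
    if values.columns.duplicated().any():
        dups = values.columns[values.columns.duplicated()].unique().tolist()
        raise ModelIOError(f"duplicate sample IDs: {dups[:5]}")
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ModelIOError("expression matrix contains non-finite values")
    missing_cols = [c for c in METADATA_COLUMNS if c != "sample_id"
                    and c not in meta.columns]
    if missing_cols:
        raise ModelIOError(f"metadata missing columns: {missing_cols}")
    unknown = [s for s in values.columns if s not in meta.index]
    if unknown:
        raise ModelIOError(
            f"samples present in matrix but absent from metadata: {unknown}"
        )
    bad_dose = set(meta["dose_level"]) - set(DOSE_LEVELS)
    if bad_dose:
        raise ModelIOError(f"unknown dose levels: {sorted(bad_dose)}")
    bad_sys = set(meta["test_system"]) - set(TEST_SYSTEMS)
    if bad_sys:
        raise ModelIOError(f"unknown test systems: {sorted(bad_sys)}")


def read_expression_study(matrix_path: str | Path,
                          metadata_path: str | Path) -> ExpressionMatrix:
    """Load a genes x samples TSV (first column ``gene_id``) and metadata TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.index.name != "gene_id":
        raise ModelIOError(
            f"expression matrix first column must be 'gene_id', "
            f"got {values.index.name!r}"
        )
    values.index = values.index.astype(str)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ModelIOError(f"non-numeric expression values: {exc}") from exc
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ModelIOError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ModelIOError("duplicate sample_id rows in metadata")
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(values=values, metadata=meta)


def write_expression_study(expr: ExpressionMatrix, matrix_path: str | Path,
                           metadata_path: str | Path) -> None:
    values = expr.values.copy()
    values.index.name = "gene_id"
    values.to_csv(matrix_path, sep="\t")
    meta = expr.metadata.reset_index()
    if meta.columns[0] != "sample_id":
        meta = meta.rename(columns={meta.columns[0]: "sample_id"})
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT), TF targets, orthologs
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets; GMT on disk. Members unique within a set."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, members in self.sets.items():
            if not members:
                raise ModelIOError(f"gene set {set_id!r} is empty")
            if len(set(members)) != len(members):
                raise ModelIOError(f"gene set {set_id!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ModelIOError(
                    f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields)}"
                )
            set_id, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ModelIOError(f"{path}:{lineno}: gene set {set_id!r} empty")
            if set_id in sets:
                raise ModelIOError(f"{path}:{lineno}: duplicate set ID {set_id!r}")
            sets[set_id] = members
            descriptions[set_id] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, members in collection.sets.items():
            desc = collection.descriptions.get(set_id, "")
            fh.write("\t".join([set_id, desc, *members]) + "\n")


TF_MODES = ("activation", "repression", "unknown")


def read_tf_targets(path: str | Path) -> pd.DataFrame:
    """TRRUST-like TSV (tf, target, mode) -> deduplicated DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["tf", "target", "mode"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ModelIOError(f"TF-target table missing columns: {missing}")
    bad = set(df["mode"]) - set(TF_MODES)
    if bad:
        raise ModelIOError(f"unknown TF modes: {sorted(bad)}")
    n0 = len(df)
    df = df.drop_duplicates(subset=["tf", "target"]).reset_index(drop=True)
    if len(df) < n0:
        log.info("read_tf_targets: dropped %d duplicate (tf, target) pairs "
                 "[reason=duplicate_pair]", n0 - len(df))
    self_loops = df["tf"] == df["target"]
    if self_loops.any():
        log.warning("read_tf_targets: %d self-loop records retained "
                    "[reason=self_loop]", int(self_loops.sum()))
    return df


def write_tf_targets(df: pd.DataFrame, path: str | Path) -> None:
    df[["tf", "target", "mode"]].to_csv(path, sep="\t", index=False)


def read_orthologs(path: str | Path) -> pd.DataFrame:
    """Ortholog TSV (human_gene, rat_gene); one-to-many pairs preserved."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("human_gene", "rat_gene") if c not in df.columns]
    if missing:
        raise ModelIOError(f"ortholog table missing columns: {missing}")
    n0 = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    if len(df) < n0:
        log.info("read_orthologs: dropped %d duplicate rows "
                 "[reason=duplicate_pair]", n0 - len(df))
    return df


def write_orthologs(df: pd.DataFrame, path: str | Path) -> None:
    df[["human_gene", "rat_gene"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GPR parsing — boolean expression trees over gene IDs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GPRNode:
    """Node of a parsed GPR tree: op in {'gene','and','or'}."""

    op: str
    gene: str | None = None
    children: tuple["GPRNode", ...] = ()

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out


def _tokenize_gpr(rule: str) -> list[str]:
    tokens: list[str] = []
    buf: list[str] = []
    for ch in rule:
        if ch in "()":
            if buf:
                tokens.append("".join(buf))
                buf = []
            tokens.append(ch)
        elif ch.isspace():
            if buf:
                tokens.append("".join(buf))
                buf = []
        else:
            buf.append(ch)
    if buf:
        tokens.append("".join(buf))
    return tokens


def parse_gpr(rule: str) -> GPRNode | None:
    """Parse ``"g1 and (g2 or g3)"`` into a tree; None for an empty rule.

    Grammar: or_expr := and_expr ('or' and_expr)* ;
    and_expr := atom ('and' atom)* ; atom := gene | '(' or_expr ')'.
    AND/OR keywords are case-insensitive.
    """
    tokens = _tokenize_gpr(rule)
    if not tokens:
        return None
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def atom() -> GPRNode:
        tok = peek()
        if tok is None:
            raise ModelIOError(f"GPR {rule!r}: unexpected end of expression")
        if tok == "(":
            take()
            node = or_expr()
            if peek() != ")":
                raise ModelIOError(f"GPR {rule!r}: missing closing parenthesis")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelIOError(f"GPR {rule!r}: unexpected token {tok!r}")
        return GPRNode(op="gene", gene=take())

    def and_expr() -> GPRNode:
        nodes = [atom()]
        while peek() is not None and peek().lower() == "and":  # type: ignore[union-attr]
            take()
            nodes.append(atom())
        return nodes[0] if len(nodes) == 1 else GPRNode(op="and", children=tuple(nodes))

    def or_expr() -> GPRNode:
        nodes = [and_expr()]
        while peek() is not None and peek().lower() == "or":  # type: ignore[union-attr]
            take()
            nodes.append(and_expr())
        return nodes[0] if len(nodes) == 1 else GPRNode(op="or", children=tuple(nodes))

    tree = or_expr()
    if pos != len(tokens):
        raise ModelIOError(f"GPR {rule!r}: trailing tokens {tokens[pos:]}")
    return tree


# ---------------------------------------------------------------------------
# Metabolic model
# ---------------------------------------------------------------------------


@dataclass
class Reaction:
    id: str
    name: str
    lb: float
    ub: float
    gpr: str
    stoich: dict[str, float]
    gpr_tree: GPRNode | None = None

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub


@dataclass
class Metabolite:
    id: str
    name: str
    exchangeable: bool


@dataclass
class MetabolicModel:
    """Stoichiometric model: S (metabolites x reactions), bounds, GPRs.

    Exchange reactions touch exactly one metabolite with coefficient -1
    (positive flux = secretion, negative = uptake).
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ModelIOError("duplicate metabolite IDs")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelIOError("duplicate reaction IDs")
        for rxn in self.reactions:
            if rxn.lb > rxn.ub:
                raise ModelIOError(
                    f"reaction {rxn.id}: lb {rxn.lb} > ub {rxn.ub}")
            unknown = set(rxn.stoich) - set(self._met_index)
            if unknown:
                raise ModelIOError(
                    f"reaction {rxn.id}: unknown metabolites {sorted(unknown)}")
            if rxn.gpr and rxn.gpr_tree is None:
                try:
                    rxn.gpr_tree = parse_gpr(rxn.gpr)
                except ModelIOError as exc:
                    raise ModelIOError(
                        f"reaction {rxn.id}: unparseable GPR: {exc}") from exc
        for ex_id in self.exchange_reactions:
            rxn = self.reaction(ex_id)
            nonzero = {m: c for m, c in rxn.stoich.items() if c != 0}
            if len(nonzero) != 1:
                raise ModelIOError(
                    f"exchange reaction {ex_id} touches {len(nonzero)} metabolites")

    @property
    def exchange_reactions(self) -> list[str]:
        """Reactions with exactly one stoichiometric entry (boundary fluxes)."""
        return [r.id for r in self.reactions
                if len([c for c in r.stoich.values() if c != 0]) == 1]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S, metabolites x reactions."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoich.items():
                S[self._met_index[met_id], j] = coeff
        return S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions], dtype=float)
        ub = np.array([r.ub for r in self.reactions], dtype=float)
        return lb, ub

    def exchange_for(self, met_id: str) -> str | None:
        """The exchange reaction of a metabolite, if one exists."""
        for ex_id in self.exchange_reactions:
            rxn = self.reaction(ex_id)
            if met_id in rxn.stoich and rxn.stoich[met_id] != 0:
                return ex_id
        return None

    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions:
            if rxn.gpr_tree is not None:
                out |= rxn.gpr_tree.genes()
        return out


def read_metabolic_model(path: str | Path) -> MetabolicModel:
    """Load the JSON model document and verify all structural invariants."""
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ModelIOError(f"model JSON missing key {key!r}")
    metabolites = [
        Metabolite(id=m["id"], name=m.get("name", m["id"]),
                   exchangeable=bool(m.get("exchangeable", False)))
        for m in doc["metabolites"]
    ]
    reactions = [
        Reaction(id=r["id"], name=r.get("name", r["id"]),
                 lb=float(r["lb"]), ub=float(r["ub"]),
                 gpr=r.get("gpr", "") or "",
                 stoich={k: float(v) for k, v in r["stoich"].items()})
        for r in doc["reactions"]
    ]
    return MetabolicModel(metabolites=metabolites, reactions=reactions)


def write_metabolic_model(model: MetabolicModel, path: str | Path) -> None:
    doc = {
        "metabolites": [
            {"id": m.id, "name": m.name, "exchangeable": m.exchangeable}
            for m in model.metabolites
        ],
        "reactions": [
            {"id": r.id, "name": r.name, "lb": r.lb, "ub": r.ub,
             "gpr": r.gpr, "stoich": r.stoich}
            for r in model.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "paths": {},
    "prep": {
        "variance_quantile": 0.25,
        "min_expression_floor": None,  # optional MAS5 stand-in, off by default
        "fc_cutoff": 0.6,
    },
    "deg": {
        "n_permutations": 1000,
        "pfp_cutoff": 0.05,
    },
    "enrich": {
        "alpha": 0.05,
        "adjust": "fdr_bh",
        "min_hits": 3,
    },
    "mie": {
        "min_mapped": 10,
        "flag_threshold_pct": 20.0,
    },
    "timbr": {
        "weight_scale": 0.5,
        "baseline_weight": 1.0,
        "opt_fraction": 0.9,
        "call_cutoff": 0.1,
        "deg_only": True,
        "bounds_profile": {},
        "metabolite_subset": None,
    },
    "overlap": {
        "frequency_threshold": 0.05,
        "k_metabolite": 3,
        "k_condition": 3,
        "drop_ambiguous_orthologs": False,
    },
    "simulate": {},
}


def _merge_config(base: dict, override: Mapping, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ModelIOError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and key not in (
                "paths", "bounds_profile", "simulate"):
            if not isinstance(val, Mapping):
                raise ModelIOError(f"config key {here} must be a mapping")
            out[key] = _merge_config(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """YAML config with one block per stage; unknown keys rejected."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_config(DEFAULT_CONFIG, user)
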