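"""Molecular-initiating-event (MIE) activation scoring.

The MIEs of the steatosis adverse outcome pathway are ligand-activated
transcription factors; their activation is read out from the differential
expression of their target genes.  For each chemical the DEG set is the
union over all of its exposure conditions (any dose or duration, either
direction); for each MIE the score is the number of differentially
expressed targets among the targets mapped to the analyzable gene universe,
displayed as a rounded integer percentage and flagged when the unrounded
percentage exceeds 20%.  Only MIEs with more than ``min_mapped`` (default
10) mapped targets are tabulated.
"""

from __future__ import annotations

import math

import pandas as pd

from .model_io import get_logger

log = get_logger(__name__)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def map_targets(tf_map: pd.DataFrame, mies: list[str],
                universe: set[str]) -> tuple[dict[str, set[str]], list[str]]:
    """Targets of each MIE restricted to the universe; plus the unmapped MIEs.

    An MIE is *unmapped* when the TF-target table has no record for it at
    all; an MIE whose recorded targets all fall outside the universe maps to
    an empty set but is not listed as unmapped.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    mapped: dict[str, set[str]] = {}
    unmapped: list[str] = []
    by_tf = tf_map.groupby("tf")["target"].apply(set).to_dict()
    for mie in mies:
        if mie not in by_tf:
            unmapped.append(mie)
            mapped[mie] = set()
        else:
            mapped[mie] = by_tf[mie] & universe
    if unmapped:
        log.info("map_targets: MIEs with no TF-target records: %s", unmapped)
    return mapped, unmapped


def chemical_deg_union(deg_tables: dict[str, pd.DataFrame]) -> dict[str, set[str]]:
    """Union of DEGs over all conditions of each chemical (both directions)."""
    unions: dict[str, set[str]] = {}
    for condition_key, table in deg_tables.items():
        chemical = condition_key.split("|")[0]
        unions.setdefault(chemical, set()).update(table["gene"])
    return unions


def score_mie_activation(deg_tables: dict[str, pd.DataFrame],
                         mapped: dict[str, set[str]],
                         min_mapped: int = 10,
                         flag_threshold_pct: float = 20.0) -> pd.DataFrame:
    """Chemicals x MIEs activation table.

    Columns: chemical, mie, n_de, n_mapped, pct (integer, half away from
    zero), flagged (unrounded percentage strictly above the threshold).
    MIEs with n_mapped <= min_mapped are omitted, matching the "more than
    10 target genes" tabulation convention.
    """
    unions = chemical_deg_union(deg_tables)
    shown = {m: t for m, t in mapped.items() if len(t) > min_mapped}
    rows = []
    for chemical in sorted(unions):
        degs = unions[chemical]
        for mie in sorted(shown):
            targets = shown[mie]
            n_de = len(degs & targets)
            pct_exact = 100.0 * n_de / len(targets)
            rows.append((chemical, mie, n_de, len(targets),
                         round_half_away(pct_exact),
                         pct_exact > flag_threshold_pct))
    return pd.DataFrame(rows, columns=["chemical", "mie", "n_de", "n_mapped",
                                       "pct", "flagged"])
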