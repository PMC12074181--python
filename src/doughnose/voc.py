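"""Presence/absence analysis of GC-MS volatile-compound inventories.

Operates on long tables with one row per (compound, flour, phase) and a
binary ``present`` flag; compound identity is the exact normalized name
(lowercased, whitespace collapsed). Abundances are out of scope — the
reference method reports which compounds appear in each condition, and the
quantities of interest are set-algebra counts: how many compounds the
pre- and post-leavening headspaces share, and which are exclusive to one
phase.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .synthetic import CHEMICAL_CLASSES, FLOURS

VOC_COLUMNS = ["compound", "chemical_class", "phase", "flour", "present"]
VALID_PHASES = ("PRE", "POST")


@dataclass(frozen=True)
class OverlapSummary:
    """Partition of an inventory by phase membership."""

    n_total: int
    n_pre: int
    n_post: int
    n_common: int
    n_pre_only: int
    n_post_only: int

    def __post_init__(self) -> None:
        assert self.n_pre == self.n_common + self.n_pre_only
        assert self.n_post == self.n_common + self.n_post_only
        assert self.n_total == self.n_common + self.n_pre_only + self.n_post_only

    def as_dict(self) -> dict[str, int]:
        return {
            "n_total": self.n_total,
            "n_pre": self.n_pre,
            "n_post": self.n_post,
            "n_common": self.n_common,
            "n_pre_only": self.n_pre_only,
            "n_post_only": self.n_post_only,
        }


@dataclass(frozen=True)
class PhaseExclusives:
    """Compounds detected in only one phase, for one flour and across all."""

    flour: str
    pre_only: list[str]
    post_only: list[str]
    pre_only_all_flours: list[str]
    post_only_all_flours: list[str]


def normalize_compound(name: str) -> str:
    return re.sub(r"\s+", " ", str(name).strip().lower())


def validate_voc_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check columns and values; return a copy with normalized compound
    names and duplicate (compound, flour, phase) rows collapsed by OR."""
    missing = [c for c in VOC_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"VOC table missing column(s): {', '.join(missing)}")
    bad = set(table["phase"].unique()) - set(VALID_PHASES)
    if bad:
        raise ValueError(f"phase values outside {VALID_PHASES}: {sorted(bad)}")
    if table["chemical_class"].isna().any() or (table["chemical_class"] == "").any():
        raise ValueError("chemical_class must be non-empty")
    out = table.copy()
    out["compound"] = out["compound"].map(normalize_compound)
    out["present"] = out["present"].astype(int)
    out = (
        out.groupby(["compound", "chemical_class", "flour", "phase"], as_index=False)[
            "present"
        ].max()
    )
    return out


def _phase_sets(table: pd.DataFrame, flour_scope: str = "pooled"):
    table = validate_voc_table(table)
    if flour_scope != "pooled":
        known = set(table["flour"].unique()) | set(FLOURS)
        if flour_scope not in known:
            raise ValueError(f"unknown flour {flour_scope!r}")
        table = table[table["flour"] == flour_scope]
    present = table[table["present"] == 1]
    pre = set(present.loc[present["phase"] == "PRE", "compound"])
    post = set(present.loc[present["phase"] == "POST", "compound"])
    return pre, post


def overlap_summary(table: pd.DataFrame, flour_scope: str = "pooled") -> OverlapSummary:
    """Count distinct compounds per phase and their overlap partition,
    over one flour or the pooled union of all flours."""
    pre, post = _phase_sets(table, flour_scope)
    common = pre & post
    return OverlapSummary(
        n_total=len(pre | post),
        n_pre=len(pre),
        n_post=len(post),
        n_common=len(common),
        n_pre_only=len(pre - post),
        n_post_only=len(post - pre),
    )


def class_census(table: pd.DataFrame) -> pd.DataFrame:
    """Distinct-compound counts per (flour, phase, chemical_class).

    Classes are ordered by the standard abundance ordering (alkanes first,
    nitriles last), then alphabetically for any class outside it.
    """
    table = validate_voc_table(table)
    present = table[table["present"] == 1]
    counts = (
        present.groupby(["flour", "phase", "chemical_class"])["compound"]
        .nunique()
        .reset_index(name="n_compounds")
    )
    order = {c: i for i, c in enumerate(CHEMICAL_CLASSES)}
    counts["_rank"] = counts["chemical_class"].map(
        lambda c: order.get(c, len(order))
    )
    counts = (
        counts.sort_values(["flour", "phase", "_rank", "chemical_class"])
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return counts


def phase_exclusive_compounds(table: pd.DataFrame, flour: str) -> PhaseExclusives:
    """Compounds detected in only one phase for ``flour``, plus the
    compounds exclusive to one phase in every flour simultaneously."""
    pre_f, post_f = _phase_sets(table, flour)
    flours = sorted(validate_voc_table(table)["flour"].unique())
    pre_all: set[str] | None = None
    post_all: set[str] | None = None
    for f in flours:
        pre, post = _phase_sets(table, f)
        pre_excl = pre - post
        post_excl = post - pre
        pre_all = pre_excl if pre_all is None else pre_all & pre_excl
        post_all = post_excl if post_all is None else post_all & post_excl
    return PhaseExclusives(
        flour=flour,
        pre_only=sorted(pre_f - post_f),
        post_only=sorted(post_f - pre_f),
        pre_only_all_flours=sorted(pre_all or set()),
        post_only_all_flours=sorted(post_all or set()),
    )


def read_voc_table(path) -> pd.DataFrame:
    return validate_voc_table(pd.read_csv(path))


def write_voc_table(table: pd.DataFrame, path) -> None:
    table[VOC_COLUMNS].to_csv(path, index=False)
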