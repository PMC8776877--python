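"""Phage-typing matrices and cross-resistance classification.

Phage typing scores each surviving clone against the full phage panel by
spotting phage on a bacterial lawn: a plaque means the clone is sensitive
(``S``), no plaque means resistant (``R``), ``NT`` marks untested cells.
Relative to the wild-type baseline of its strain, each clone's *acquired*
resistances are the panel phages it newly resists. Because every panel phage
recognises LPS, T4P, or both, an acquired set maps onto receptor groups and
each clone falls into exactly one cross-resistance category:

``none``
    no acquired resistance;
``same_receptor_only``
    acquired resistances confined to receptor group(s) of the applied
    phage(s);
``alternative_receptor_only``
    acquired resistances confined to receptor group(s) *not* targeted by the
    applied phage(s);
``both_groups``
    at least one LPS-targeting and one T4P-targeting phage acquired
    (a dual-receptor phage counts toward both groups).

Phages the wild type already resists are excluded as not evaluable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .panel import PhageDef, panel_by_name, strains_by_name

VALID_CALLS = frozenset({"S", "R", "NT"})
VALID_ORIGINS = frozenset({"biofilm", "planktonic", "control", "wild_type"})

#: Clone metadata columns expected in a typing CSV ahead of the phage columns.
META_COLUMNS = ("clone_id", "strain", "origin", "treatment")

CATEGORIES = ("none", "same_receptor_only", "alternative_receptor_only", "both_groups")


class TypingFormatError(ValueError):
    """Raised when a typing CSV violates the matrix contract."""


@dataclass(frozen=True)
class CrossResistanceCall:
    """Cross-resistance classification of one clone against the panel."""

    clone_id: str
    acquired: frozenset
    not_evaluable: frozenset
    self_resistant_to: frozenset
    category: str

    def __post_init__(self):
        if self.acquired & self.not_evaluable:
            raise ValueError("acquired and not_evaluable must be disjoint")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


class TypingMatrix:
    """Clones x phages sensitivity calls with clone metadata.

    Parameters
    ----------
    panel : sequence of PhageDef
        The phage panel; defines the call columns.
    meta : pandas.DataFrame
        One row per clone, indexed by ``clone_id``, with columns ``strain``,
        ``origin`` (biofilm / planktonic / control / wild_type) and
        ``treatment`` (frozenset of applied phage names; empty for controls
        and wild types).
    calls : pandas.DataFrame
        Clone x phage calls in {S, R, NT}, same index as ``meta``.
    """

    def __init__(self, panel, meta: pd.DataFrame, calls: pd.DataFrame):
        self.panel = tuple(panel)
        self._by_name = panel_by_name(self.panel)
        self.meta = meta
        self.calls = calls
        self._validate()

    # -- construction / validation ------------------------------------

    def _validate(self) -> None:
        panel_names = [p.name for p in self.panel]
        extra = set(self.calls.columns) - set(panel_names)
        if extra:
            raise TypingFormatError(f"unknown phage column(s): {sorted(extra)}")
        missing = set(panel_names) - set(self.calls.columns)
        if missing:
            raise TypingFormatError(f"missing phage column(s): {sorted(missing)}")
        if not self.calls.index.equals(self.meta.index):
            raise TypingFormatError("calls and metadata index mismatch")
        bad = ~self.calls.isin(VALID_CALLS)
        if bad.to_numpy().any():
            r, c = next(zip(*bad.to_numpy().nonzero()))
            raise TypingFormatError(
                f"illegal call {self.calls.iat[r, c]!r} at clone "
                f"{self.calls.index[r]!r}, phage {self.calls.columns[c]!r}"
            )
        bad_origin = set(self.meta["origin"]) - VALID_ORIGINS
        if bad_origin:
            raise TypingFormatError(f"illegal origin value(s): {sorted(bad_origin)}")
        for strain in self.meta["strain"].unique():
            wt = self.meta[
                (self.meta["strain"] == strain) & (self.meta["origin"] == "wild_type")
            ]
            if len(wt) != 1:
                raise TypingFormatError(
                    f"strain {strain!r} needs exactly one wild_type row, found {len(wt)}"
                )
        for origin in ("control", "wild_type"):
            rows = self.meta[self.meta["origin"] == origin]
            nonempty = [cid for cid, t in rows["treatment"].items() if t]
            if nonempty:
                raise TypingFormatError(
                    f"{origin} clone(s) {nonempty} must have empty treatment"
                )

    # -- lookups -------------------------------------------------------

    @property
    def clone_ids(self):
        return list(self.meta.index)

    def wild_type_row(self, strain: str) -> pd.Series:
        sel = self.meta[
            (self.meta["strain"] == strain) & (self.meta["origin"] == "wild_type")
        ]
        return self.calls.loc[sel.index[0]]

    def call(self, clone_id: str, phage: str) -> str:
        return self.calls.at[clone_id, phage]

    def treatment(self, clone_id: str) -> frozenset:
        return self.meta.at[clone_id, "treatment"]

    def treated_clones(self):
        """Clone ids of phage-treated isolates (biofilm or planktonic)."""
        mask = self.meta["origin"].isin(("biofilm", "planktonic"))
        return list(self.meta.index[mask])


def load_typing(path, panel, strains) -> TypingMatrix:
    """Read a typing CSV into a validated :class:`TypingMatrix`.

    The CSV carries the metadata columns ``clone_id, strain, origin,
    treatment`` (treatment as ``;``-joined phage names, empty for controls)
    followed by one column per panel phage with cells in {S, R, NT}.

    A strain's wild-type resistances must show as R or NT in that strain's
    wild_type row; a violation is a format error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise TypingFormatError(f"missing metadata column(s): {missing_meta}")
    if df["clone_id"].duplicated().any():
        dup = df.loc[df["clone_id"].duplicated(), "clone_id"].iloc[0]
        raise TypingFormatError(f"duplicate clone_id {dup!r}")
    df = df.set_index("clone_id")

    by_strain = strains_by_name(strains)
    unknown_strains = set(df["strain"]) - set(by_strain)
    if unknown_strains:
        raise TypingFormatError(f"unknown strain(s): {sorted(unknown_strains)}")

    meta = df[["strain", "origin"]].copy()
    meta["treatment"] = [
        frozenset(t.split(";")) if t else frozenset() for t in df["treatment"]
    ]
    panel_names = {p.name for p in panel}
    for cid, t in meta["treatment"].items():
        if not t <= panel_names:
            raise TypingFormatError(
                f"clone {cid!r}: treatment phage(s) {sorted(t - panel_names)} not in panel"
            )
    calls = df.drop(columns=["strain", "origin", "treatment"])

    matrix = TypingMatrix(panel, meta, calls)

    # wild-type baseline must be consistent with declared WT resistances
    for strain in meta["strain"].unique():
        wt_row = matrix.wild_type_row(strain)
        for phage in by_strain[strain].wt_resistant_phages:
            if wt_row[phage] == "S":
                raise TypingFormatError(
                    f"strain {strain!r}: wild type declared resistant to "
                    f"{phage!r} but typed S"
                )
    return matrix


def _receptor_groups(phages, by_name) -> set:
    """Union of receptor groups targeted by the given phage names."""
    groups: set = set()
    for name in phages:
        groups |= by_name[name].receptors
    return groups


def _categorize(acquired_groups: set, applied_groups: set) -> str:
    if not acquired_groups:
        return "none"
    if {"LPS", "T4P"} <= acquired_groups:
        return "both_groups"
    if acquired_groups <= applied_groups:
        return "same_receptor_only"
    return "alternative_receptor_only"


def classify_clone(matrix: TypingMatrix, clone_id: str) -> CrossResistanceCall:
    """Classify one clone's acquired cross-resistance pattern.

    ``acquired`` holds phages typed R where the strain's wild type is S;
    wild-type-resistant phages are ``not_evaluable``. The category compares
    the receptor groups of the acquired phages with those of the applied
    phage(s); see the module docstring for the four categories.
    """
    if clone_id not in matrix.meta.index:
        raise KeyError(f"clone {clone_id!r} not in matrix")
    if matrix.meta.at[clone_id, "origin"] == "wild_type":
        raise ValueError(f"clone {clone_id!r} is a wild-type row")

    wt = matrix.wild_type_row(matrix.meta.at[clone_id, "strain"])
    row = matrix.calls.loc[clone_id]
    acquired = frozenset(
        p.name for p in matrix.panel if row[p.name] == "R" and wt[p.name] == "S"
    )
    not_evaluable = frozenset(p.name for p in matrix.panel if wt[p.name] != "S")
    treatment = matrix.treatment(clone_id)
    by_name = matrix._by_name
    category = _categorize(
        _receptor_groups(acquired, by_name), _receptor_groups(treatment, by_name)
    )
    return CrossResistanceCall(
        clone_id=clone_id,
        acquired=acquired,
        not_evaluable=not_evaluable,
        self_resistant_to=acquired & treatment,
        category=category,
    )


def unique_patterns(matrix: TypingMatrix) -> pd.DataFrame:
    """Group treated clones of each strain by identical call vectors.

    Returns one row per (strain, pattern) group with the lexicographically
    smallest clone id as representative, the group size, and the member ids.
    """
    clones = matrix.treated_clones()
    if not clones:
        raise ValueError("no treated clones to group")
    rows = []
    sub = matrix.calls.loc[clones]
    strains = matrix.meta.loc[clones, "strain"]
    for (strain, pattern), grp in sub.groupby(
        [strains, sub.apply(lambda r: "".join(r), axis=1)], sort=True
    ):
        members = sorted(grp.index)
        rows.append(
            {
                "strain": strain,
                "pattern": pattern,
                "representative": members[0],
                "n_clones": len(members),
                "members": members,
            }
        )
    return pd.DataFrame(rows)


def summarize_cross_resistance(matrix: TypingMatrix) -> pd.DataFrame:
    """Tabulate cross-resistance categories per strain and treatment arity.

    One row per (strain, arity) where arity is ``monovalent`` (single phage)
    or ``polyvalent`` (cocktail). Counts clones per category, clones
    self-resistant to every applied phage, and clones still sensitive to each
    applied phage; percentages are rounded to one decimal and reported as NA
    for empty arms. NT calls never enter a denominator.
    """
    records = []
    for clone_id in matrix.treated_clones():
        call = classify_clone(matrix, clone_id)
        treatment = matrix.treatment(clone_id)
        records.append(
            {
                "clone_id": clone_id,
                "strain": matrix.meta.at[clone_id, "strain"],
                "arity": "monovalent" if len(treatment) == 1 else "polyvalent",
                "category": call.category,
                "treatment": treatment,
                "self_resistant_all": treatment <= call.acquired,
            }
        )
    df = pd.DataFrame(records)
    rows = []
    for (strain, arity), grp in df.groupby(["strain", "arity"], sort=True):
        n = len(grp)
        row = {"strain": strain, "arity": arity, "n_clones": n}
        for cat in CATEGORIES:
            n_cat = int((grp["category"] == cat).sum())
            row[f"n_{cat}"] = n_cat
            row[f"pct_{cat}"] = round(100.0 * n_cat / n, 1) if n else pd.NA
        row["n_self_resistant_all"] = int(grp["self_resistant_all"].sum())
        still = {}
        applied = sorted(set().union(*grp["treatment"]))
        for phage in applied:
            assessed = [
                cid
                for cid, t in zip(grp["clone_id"], grp["treatment"])
                if phage in t and matrix.call(cid, phage) != "NT"
            ]
            still[phage] = sum(1 for cid in assessed if matrix.call(cid, phage) == "S")
        row["still_sensitive"] = still
        rows.append(row)
    return pd.DataFrame(rows)
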