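"""Phage panel and bacterial strain definitions.

A phage panel is the set of lytic phages used both for selection and for
typing. Each phage recognises one or both of the two surface receptors of
*Pseudomonas aeruginosa* relevant here: lipopolysaccharide (LPS) and type IV
pili (T4P). Strains carry metadata needed downstream: which panel phages the
wild type is already resistant to (those cells are not evaluable for acquired
resistance) and how many intact prophages the wild-type genome carries.

The module ships the seven-phage panel and five-strain set used in the
original selection experiment as ready-made fixtures
(:data:`DEFAULT_PANEL`, :data:`DEFAULT_STRAINS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Receptor classes recognised by the panel phages.
RECEPTORS = frozenset({"LPS", "T4P"})

#: Genome length (bp) above which a phage is considered "jumbo".
JUMBO_GENOME_BP = 200_000


@dataclass(frozen=True)
class PhageDef:
    """A lytic phage: name, recognised receptor(s) and genome size.

    Parameters
    ----------
    name : str
        Phage identifier, used as column name in typing matrices.
    receptors : frozenset of {"LPS", "T4P"}
        Receptor class(es) required for adsorption. Dual-receptor phages
        (e.g. PA5oct) list both.
    genome_length : int
        Genome size in bp; > 200 kbp marks a jumbo phage.
    """

    name: str
    receptors: frozenset
    genome_length: int

    def __post_init__(self):
        object.__setattr__(self, "receptors", frozenset(self.receptors))
        if not self.receptors:
            raise ValueError(f"phage {self.name}: receptors must be nonempty")
        if not self.receptors <= RECEPTORS:
            raise ValueError(
                f"phage {self.name}: unknown receptor(s) {set(self.receptors) - RECEPTORS}"
            )
        if self.genome_length <= 0:
            raise ValueError(f"phage {self.name}: genome_length must be > 0")

    @property
    def is_jumbo(self) -> bool:
        return self.genome_length > JUMBO_GENOME_BP


@dataclass(frozen=True)
class StrainDef:
    """A host strain: wild-type phage resistances and prophage content."""

    name: str
    wt_resistant_phages: frozenset = frozenset()
    prophage_count: int = 0
    intact_prophage_names: tuple = ()

    def __post_init__(self):
        object.__setattr__(
            self, "wt_resistant_phages", frozenset(self.wt_resistant_phages)
        )
        object.__setattr__(
            self, "intact_prophage_names", tuple(self.intact_prophage_names)
        )
        if self.prophage_count < 0:
            raise ValueError(f"strain {self.name}: prophage_count must be >= 0")

    def validate_against_panel(self, panel) -> None:
        names = {p.name for p in panel}
        unknown = self.wt_resistant_phages - names
        if unknown:
            raise ValueError(
                f"strain {self.name}: wild-type resistances {sorted(unknown)} "
                f"not in panel {sorted(names)}"
            )


#: The seven-phage typing panel (receptor specificity and genome size).
DEFAULT_PANEL: tuple = (
    PhageDef("LUZ7", {"LPS"}, 74_901),
    PhageDef("KTN6", {"LPS"}, 65_994),
    PhageDef("KT28", {"LPS"}, 66_381),
    PhageDef("LUZ19", {"T4P"}, 43_548),
    PhageDef("KTN4", {"T4P"}, 279_593),
    PhageDef("phiKZ", {"T4P"}, 280_334),
    PhageDef("PA5oct", {"LPS", "T4P"}, 286_783),
)

#: Canonical column order for carrier-state summary tables.
TABLE_PHAGE_ORDER: tuple = ("LUZ7", "KTN6", "KT28", "LUZ19", "KTN4", "phiKZ", "PA5oct")

#: The five host strains with their wild-type resistances and intact
#: dsDNA prophage counts.
DEFAULT_STRAINS: tuple = (
    StrainDef("PAO1"),
    StrainDef("PAK"),
    StrainDef("CHA", prophage_count=2, intact_prophage_names=("CHA#1", "CHA#2")),
    StrainDef(
        "A5803",
        wt_resistant_phages={"KT28"},
        prophage_count=4,
        intact_prophage_names=("A5803#1", "A5803#3", "A5803#4", "A5803#5"),
    ),
    StrainDef("AA43", wt_resistant_phages={"LUZ19", "KTN4"}),
)


def panel_by_name(panel) -> dict:
    """Index a panel (iterable of PhageDef) by phage name."""
    return {p.name: p for p in panel}


def strains_by_name(strains) -> dict:
    """Index strain definitions by strain name."""
    return {s.name: s for s in strains}
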