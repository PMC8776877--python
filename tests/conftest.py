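"""Shared fixtures: a scaled-down phage panel and a seeded synthetic dataset.

The simulated cohort uses a reduced genome (60 kbp) and a four-phage panel
with small genomes so the whole suite runs in seconds while preserving the
structure the analyses assume (receptor groups, a deletion core, carrier
contigs, triplicate growth curves).
"""

import pandas as pd
import pytest
from hypothesis import settings

from phageres.panel import PhageDef, StrainDef
from phageres.simulate import SimConfig, generate_dataset
from phageres.typing_matrix import TypingMatrix, load_typing

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


SMALL_PANEL = (
    PhageDef("pA", {"LPS"}, 3000),
    PhageDef("pB", {"LPS"}, 3500),
    PhageDef("pC", {"T4P"}, 4000),
    PhageDef("pD", {"LPS", "T4P"}, 5000),
)


@pytest.fixture(scope="session")
def small_panel():
    return SMALL_PANEL


@pytest.fixture(scope="session")
def sim_config(small_panel):
    return SimConfig(
        seed=11,
        genome_length=60_000,
        n_clones_per_treatment=4,
        n_controls=2,
        panel=small_panel,
        treatments=(
            frozenset({"pA"}),
            frozenset({"pC"}),
            frozenset({"pA", "pC"}),
        ),
        deletion_core=(30_000, 33_000),
        deletion_size_range=(10_000, 15_000),
        p_point_mutation=0.35,
        p_deletion=0.4,
        p_carrier=0.5,
        p_no_mechanism=0.1,
        growth_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def dataset(sim_config, tmp_path_factory):
    """Zero-noise synthetic dataset with its planted truth."""
    outdir = tmp_path_factory.mktemp("sim_dataset")
    paths, truth = generate_dataset(sim_config, outdir)
    return paths, truth


@pytest.fixture(scope="session")
def sim_matrix(dataset, sim_config):
    paths, _ = dataset
    return load_typing(
        paths.typing_csv, sim_config.panel, (StrainDef(sim_config.strain_name),)
    )


def make_matrix(panel, clones, strains=("S1",)):
    """Build a TypingMatrix from in-memory clone dicts.

    Each clone dict: clone_id, strain, origin, treatment (set), calls
    (mapping phage -> S/R/NT). A wild-type all-S row is appended per strain
    unless one is supplied.
    """
    rows = list(clones)
    present_wt = {c["strain"] for c in rows if c["origin"] == "wild_type"}
    for strain in strains:
        if strain not in present_wt:
            rows.append(
                {
                    "clone_id": f"{strain}_wt",
                    "strain": strain,
                    "origin": "wild_type",
                    "treatment": set(),
                    "calls": {p.name: "S" for p in panel},
                }
            )
    meta = pd.DataFrame(
        {
            "strain": [c["strain"] for c in rows],
            "origin": [c["origin"] for c in rows],
            "treatment": [frozenset(c["treatment"]) for c in rows],
        },
        index=pd.Index([c["clone_id"] for c in rows], name="clone_id"),
    )
    calls = pd.DataFrame(
        [[c["calls"][p.name] for p in panel] for c in rows],
        index=meta.index,
        columns=[p.name for p in panel],
    )
    return TypingMatrix(panel, meta, calls)
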