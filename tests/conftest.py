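import numpy as np
import pytest

from apisqg import (
    BreedingDesign,
    Pedigree,
    QueenRecord,
    SireGroup,
    compute_kinship,
    generate_pedigree,
)


@pytest.fixture(scope="session")
def super_sister_pedigree() -> Pedigree:
    """Two sisters from one dam and a single-drone sire group (founder DPQ)."""
    return Pedigree(
        [
            QueenRecord("dam"),
            QueenRecord("dpq"),
            QueenRecord("s1", "dam", "g"),
            QueenRecord("s2", "dam", "g"),
        ],
        [SireGroup("g", ("dpq",), n_drones=1)],
    )


@pytest.fixture(scope="session")
def study_sisters_pedigree() -> Pedigree:
    """Sisters from a mating of 12 drones drawn from 12 unrelated founder DPQs."""
    founders = [QueenRecord(f"m{k}") for k in range(12)]
    return Pedigree(
        founders
        + [
            QueenRecord("dam"),
            QueenRecord("s1", "dam", "g"),
            QueenRecord("s2", "dam", "g"),
        ],
        [SireGroup("g", tuple(f"m{k}" for k in range(12)), n_drones=12)],
    )


@pytest.fixture(scope="session")
def small_population():
    """Multi-generation random pedigree (~50 queens) with its exact A."""
    design = BreedingDesign(
        years=(2017, 2018),
        maternal_lines_per_year=(3, 2),
        queens_per_line=(4, 5),
        weeks_per_year=(2, 3),
        dpq_per_year=4,
        drones_per_mating=6,
        shared_ancestor_depth=1,
    )
    ped = generate_pedigree(design, seed=20)
    return design, ped, compute_kinship(ped)
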