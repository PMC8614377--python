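"""Simulation-based parameter-recovery studies.

The headline estimates of a small-population study cannot be checked against
their standard errors alone; what can be checked is that the whole pipeline
— pedigree generator, haplodiploid relationship matrix, REML fit — recovers
a known truth on average.  This module runs that loop: simulate replicate
populations with a chosen true heritability under a study-style breeding
design, fit the animal model to each, and collect the estimates.
"""

from __future__ import annotations

import numpy as np

from .relationship import compute_kinship
from .reml import fit_univariate, heritability
from .simulate import BreedingDesign, generate_pedigree, simulate_phenotypes, single_trait_model

__all__ = ["recovery_design", "heritability_recovery", "diameter_volume_correlation"]


def recovery_design(
    n_lines: int = 25,
    queens_per_line: int = 20,
    n_weeks: int = 15,
    n_dpq: int = 12,
    n_drones: int = 12,
) -> BreedingDesign:
    """Single-season design for recovery runs: 25 maternal lines of 20 queens
    (n = 500), 15 week classes, matings of 12 drones from a 12-DPQ pool."""
    return BreedingDesign(
        years=(2020,),
        maternal_lines_per_year=n_lines,
        queens_per_line=queens_per_line,
        weeks_per_year=n_weeks,
        dpq_per_year=n_dpq,
        drones_per_mating=n_drones,
    )


def heritability_recovery(
    h2_true: float,
    n_replicates: int = 100,
    seed: int = 0,
    design: BreedingDesign | None = None,
    mean: float = 100.0,
    sd: float = 10.0,
    week_effect_sd: float = 0.5,
) -> np.ndarray:
    """REML heritability estimates across replicate synthetic populations.

    Each replicate draws a fresh pedigree and fresh phenotypes (seeds derived
    from ``seed``), computes the exact relationship matrix, and fits the
    univariate week-class animal model.  Returns the ``n_replicates``
    estimates; their mean is the quantity recovery studies report.
    """
    if design is None:
        design = recovery_design()
    rng = np.random.default_rng(seed)
    model = single_trait_model("t", mean, sd, h2=h2_true, week_effect_sd=week_effect_sd)
    out = np.empty(n_replicates)
    for r in range(n_replicates):
        s_ped, s_phe = (int(s) for s in rng.integers(2**31, size=2))
        ped = generate_pedigree(design, seed=s_ped)
        A = compute_kinship(ped)
        pheno = simulate_phenotypes(ped, A, model, design, seed=s_phe)
        out[r] = heritability(fit_univariate(pheno, A, "t"))[0]
    return out


def diameter_volume_correlation(
    n: int = 10_000,
    mean: float = 1.32,
    sd: float = 0.18,
    seed: int = 0,
) -> float:
    """Pearson correlation between Gaussian diameters and sphere volumes.

    Emulates the derivation of spermatheca volume from its recorded
    diameter: draw n diameters, cube them through the sphere formula, and
    correlate.  The analytic value for Gaussian d is
    3(mu^2 + s^2) / sqrt(9 mu^4 + 36 mu^2 s^2 + 15 s^4).
    """
    from .simulate import derive_spermatheca_volume

    rng = np.random.default_rng(seed)
    d = rng.normal(mean, sd, size=n)
    d = np.clip(d, 1e-6, None)
    dbar, vol = derive_spermatheca_volume(d[:, None])
    return float(np.corrcoef(dbar, vol)[0, 1])


def gaussian_cube_correlation(mean: float, sd: float) -> float:
    """Closed-form corr(d, d^3) for d ~ N(mean, sd^2)."""
    m2, s2 = mean * mean, sd * sd
    return 3.0 * (m2 + s2) / np.sqrt(9.0 * m2 * m2 + 36.0 * m2 * s2 + 15.0 * s2 * s2)
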