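"""Synthetic breeding populations with the study's design structure.

The generator emulates a two-season queen-breeding operation: maternal
sister lines sharing common ancestresses, one mating per line dam at an
isolated station where a year-specific pool of drone-producing queens (DPQs)
supplies the drones, and per-queen records of 12 morphological and
reproductive traits harvested across week-of-year classes.

The phenotype model matches the animal model fitted downstream::

    y = mu + week + a + e,   a ~ N(0, G kron A),   e ~ N(0, R per queen)

with week effects drawn once per week class.  Spermatheca volume is not an
independent trait: it is derived from the recorded diameter (mean of three
replicate measurements) by the sphere formula, exactly as in the laboratory
protocol, which is what produces its near-unit phenotypic correlation with
the diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, QueenRecord, SireGroup
from .relationship import RelationshipMatrix, phenotyped_submatrix

__all__ = [
    "TRAIT_TABLE",
    "DEFAULT_DEFECT_RATES",
    "BreedingDesign",
    "TraitModel",
    "default_trait_model",
    "single_trait_model",
    "generate_pedigree",
    "phenotyped_ids",
    "simulate_phenotypes",
    "derive_spermatheca_volume",
    "inject_defect_flags",
]

# (abbreviation, full name, unit, mean, SD, default heritability) for the 12
# queen traits: body/head/thorax/abdomen weight, head/thorax/abdomen width,
# wing length, spermatheca diameter and volume, ovariole count, sperm count.
TRAIT_TABLE: list[tuple[str, str, str, float, float, float]] = [
    ("bw", "body weight", "mg", 195.90, 19.84, 0.54),
    ("hw", "head weight", "mg", 13.22, 1.83, 0.51),
    ("tw", "thorax weight", "mg", 77.93, 8.17, 0.50),
    ("aw", "abdomen weight", "mg", 104.76, 15.28, 0.46),
    ("hwi", "head width", "mm", 3.67, 0.18, 0.26),
    ("twi", "thorax width", "mm", 4.67, 0.26, 0.42),
    ("awi", "abdomen width", "mm", 4.80, 0.21, 0.13),
    ("wl", "wing length", "mm", 10.07, 0.62, 0.30),
    ("sd", "spermatheca diameter", "mm", 1.32, 0.18, 0.17),
    ("sv", "spermatheca volume", "ul", 1.27, 0.53, 0.88),
    ("o", "ovariole count", "n", 141.0, 25.0, 0.70),
    ("sp", "sperm count", "million", 3.6, 2.9, 0.57),
]

DEFAULT_DEFECT_RATES: dict[str, float] = {
    "intestinal_abnormality": 0.16,
    "ovary_melanosis": 0.09,
    "enteroliths": 0.08,
    "ovary_atrophy": 0.027,
    "spermatheca_abnormality": 0.007,
}


def _per_year(value, years: Sequence[int], name: str) -> list[int]:
    if isinstance(value, int):
        return [value] * len(years)
    value = list(value)
    if len(value) != len(years):
        raise ValueError(f"{name} must be an int or one value per year")
    return value


@dataclass
class BreedingDesign:
    """Parameters of the breeding structure the generator reproduces.

    Defaults are the study design: 147 phenotyped queens over two seasons
    (10 lines x 7 queens in 2017, 7 lines x 11 queens in 2018), 15 combined
    week-of-year classes (6 + 9), 12 DPQ colonies per year at the station and
    matings of 12 drones, with the maternal lines sharing a common
    grand-dam generation (``shared_ancestor_depth = 1``).
    """

    years: tuple[int, ...] = (2017, 2018)
    maternal_lines_per_year: tuple[int, ...] | int = (10, 7)
    queens_per_line: tuple[int, ...] | int = (7, 11)
    weeks_per_year: tuple[int, ...] | int = (6, 9)
    dpq_per_year: tuple[int, ...] | int = 12
    drones_per_mating: int = 12
    shared_ancestor_depth: int = 1

    def __post_init__(self) -> None:
        self.years = tuple(self.years)
        if not self.years:
            raise ValueError("design needs at least one year")
        self.maternal_lines_per_year = _per_year(
            self.maternal_lines_per_year, self.years, "maternal_lines_per_year"
        )
        self.queens_per_line = _per_year(self.queens_per_line, self.years, "queens_per_line")
        self.weeks_per_year = _per_year(self.weeks_per_year, self.years, "weeks_per_year")
        self.dpq_per_year = _per_year(self.dpq_per_year, self.years, "dpq_per_year")
        counts = (
            self.maternal_lines_per_year
            + self.queens_per_line
            + self.weeks_per_year
            + self.dpq_per_year
        )
        if any(c < 1 for c in counts) or self.drones_per_mating < 1:
            raise ValueError("all design counts must be positive")
        if self.shared_ancestor_depth < 0:
            raise ValueError("shared_ancestor_depth must be >= 0")

    @property
    def n_phenotyped(self) -> int:
        return sum(
            l * q for l, q in zip(self.maternal_lines_per_year, self.queens_per_line)
        )

    @property
    def week_classes(self) -> list[str]:
        return [
            f"{y}_w{w + 1}"
            for y, nw in zip(self.years, self.weeks_per_year)
            for w in range(nw)
        ]


@dataclass
class TraitModel:
    """Genetic (G) and residual (R) covariances plus fixed-effect structure.

    ``week_effect_sd`` is the week-class effect scale *relative to each
    trait's phenotypic SD* (the traits span four orders of magnitude in their
    units, so an absolute scalar would be meaningless).  When
    ``derive_volume`` is set, G and R cover every trait except ``sv``;
    the volume is computed from the simulated diameter via three replicate
    measurements with noise ``measurement_sd`` (mm) and the sphere formula,
    and the ``sv`` entry of ``means`` is ignored.
    """

    trait_names: tuple[str, ...]
    means: np.ndarray
    G: np.ndarray
    R: np.ndarray
    week_effect_sd: float = 0.5
    measurement_reps: int = 3
    measurement_sd: float = 0.02
    derive_volume: bool = False
    missing_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trait_names = tuple(self.trait_names)
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        k = len(self.sim_trait_names)
        if len(self.means) != len(self.trait_names):
            raise ValueError("means must have one entry per trait")
        if self.G.shape != (k, k) or self.R.shape != (k, k):
            raise ValueError(
                f"G and R must be {k}x{k} (simulated traits"
                f"{' excluding derived sv' if self.derive_volume else ''})"
            )
        for name, M in (("G", self.G), ("R", self.R)):
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M).min() < -1e-8 * max(1.0, np.abs(M).max()):
                raise ValueError(f"{name} is not positive semidefinite")
        if self.week_effect_sd < 0:
            raise ValueError("week_effect_sd must be >= 0")
        if not all(0.0 <= r <= 1.0 for r in self.missing_rates.values()):
            raise ValueError("missing rates must lie in [0, 1]")

    @property
    def sim_trait_names(self) -> tuple[str, ...]:
        if self.derive_volume:
            return tuple(t for t in self.trait_names if t != "sv")
        return self.trait_names

    def phenotypic_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.G) + np.diag(self.R))


def default_trait_model(
    week_effect_sd: float = 0.5,
    genetic_correlation: float = 0.0,
    residual_correlation: float = 0.0,
) -> TraitModel:
    """The 12-trait model at the published means, SDs and heritabilities.

    G and R default to diagonal matrices built from each trait's phenotypic
    SD and heritability; optional uniform correlations can be injected for
    sensitivity runs.  ``sv`` is derived from ``sd``, so its marginal moments
    are a consequence of the cube transform, not free parameters.  ``sp`` is
    missing for 4 of 147 queens on average, mirroring the unequal trait
    counts of real laboratory campaigns.
    """
    names = tuple(t[0] for t in TRAIT_TABLE)
    means = np.array([t[3] for t in TRAIT_TABLE])
    sim = [t for t in TRAIT_TABLE if t[0] != "sv"]
    sds = np.array([t[4] for t in sim])
    h2 = np.array([t[5] for t in sim])
    ga = np.sqrt(h2) * sds
    re = np.sqrt(1.0 - h2) * sds
    k = len(sim)
    cg = np.full((k, k), genetic_correlation) + (1 - genetic_correlation) * np.eye(k)
    cr = np.full((k, k), residual_correlation) + (1 - residual_correlation) * np.eye(k)
    return TraitModel(
        trait_names=names,
        means=means,
        G=cg * np.outer(ga, ga),
        R=cr * np.outer(re, re),
        week_effect_sd=week_effect_sd,
        derive_volume=True,
        missing_rates={"sp": 4.0 / 147.0},
    )


def single_trait_model(
    name: str = "bw",
    mean: float = 195.90,
    sd: float = 19.84,
    h2: float = 0.54,
    week_effect_sd: float = 0.5,
) -> TraitModel:
    """Univariate model with phenotypic variance ``sd**2`` split by ``h2``."""
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    var = sd * sd
    return TraitModel(
        trait_names=(name,),
        means=np.array([mean]),
        G=np.array([[h2 * var]]),
        R=np.array([[(1.0 - h2) * var]]),
        week_effect_sd=week_effect_sd,
    )


def generate_pedigree(design: BreedingDesign, seed: int) -> Pedigree:
    """Build a pedigree realising ``design``; reproducible given ``seed``.

    Structure, bottom-up: phenotyped daughter queens grouped in maternal
    sister lines; one line dam per line, mated once to a sire group of D
    drones drawn from the year's DPQ pool (every mating of a year shares the
    pool, which relates lines paternally within year); line dams descend
    from ``shared_ancestor_depth`` generations of common ancestresses, each
    generation roughly a third the size of the one below, so lines — across
    years too — share maternal ancestors.  Ancestral matings use founder DPQ
    pools of the same size and drone number.  Only the final generation
    carries a ``year`` label, which marks it as phenotyped.
    """
    rng = np.random.default_rng(seed)
    queens: list[QueenRecord] = []
    groups: list[SireGroup] = []

    n_dams_total = sum(design.maternal_lines_per_year)

    # ancestral chain: level 0 = line dams, level depth = founder ancestresses
    counts = [n_dams_total]
    for _ in range(design.shared_ancestor_depth):
        counts.append(max(1, math.ceil(counts[-1] / 3)))
    depth = design.shared_ancestor_depth

    level_ids: list[list[str]] = [[] for _ in counts]
    level_ids[depth] = [f"anc{depth}_{i:03d}" for i in range(counts[depth])]
    queens.extend(QueenRecord(qid) for qid in level_ids[depth])

    n_dpq_anc = design.dpq_per_year[0]
    for level in range(depth - 1, -1, -1):
        # one founder DPQ pool per ancestral generation
        pool = [f"anc{level}_dpq{i:03d}" for i in range(n_dpq_anc)]
        queens.extend(QueenRecord(qid) for qid in pool)
        mothers = level_ids[level + 1]
        assignment = rng.permutation(counts[level]) % len(mothers)
        used: dict[int, str] = {}
        for i in range(counts[level]):
            mi = int(assignment[i])
            if mi not in used:
                gid = f"anc{level}_g{mi:03d}"
                groups.append(
                    SireGroup(gid, tuple(pool), design.drones_per_mating, f"anc{level}")
                )
                used[mi] = gid
            qid = f"anc{level}_{i:03d}"
            level_ids[level].append(qid)
            queens.append(QueenRecord(qid, dam_id=mothers[mi], sire_group_id=used[mi]))

    dams = iter(level_ids[0])
    for yi, year in enumerate(design.years):
        pool = [f"{year}_dpq{i:02d}" for i in range(design.dpq_per_year[yi])]
        queens.extend(QueenRecord(qid) for qid in pool)
        for line in range(design.maternal_lines_per_year[yi]):
            dam = next(dams)
            gid = f"{year}_L{line:02d}_g"
            groups.append(SireGroup(gid, tuple(pool), design.drones_per_mating, str(year)))
            for k in range(design.queens_per_line[yi]):
                queens.append(
                    QueenRecord(
                        f"{year}_L{line:02d}_Q{k:02d}",
                        dam_id=dam,
                        sire_group_id=gid,
                        year=year,
                    )
                )
    return Pedigree(queens, groups)


def phenotyped_ids(ped: Pedigree) -> list[str]:
    """Queens of the final, recorded generation (those with a year label)."""
    return [qid for qid in ped.queen_order if ped.queens[qid].year is not None]


def _chol_psd(M: np.ndarray, what: str) -> np.ndarray:
    jitter = 1e-10 * max(1.0, float(np.trace(M)) / max(1, M.shape[0]))
    for _ in range(3):
        try:
            return np.linalg.cholesky(M + jitter * np.eye(M.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    raise ValueError(f"{what} is not positive semidefinite within jitter tolerance")


def simulate_phenotypes(
    ped: Pedigree,
    A: RelationshipMatrix,
    model: TraitModel,
    design: BreedingDesign,
    seed: int,
    return_effects: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one phenotype record per phenotyped queen.

    Breeding values are drawn as a matrix-normal with row covariance A
    (restricted to phenotyped queens) and column covariance G; residuals are
    iid across queens with covariance R; each queen is assigned a week class
    uniformly within her year, and one effect per week class and trait is
    drawn with SD ``week_effect_sd`` x phenotypic SD.  Returns a data frame
    with ``queen_id, year, week`` and one column per trait (NaN = missing);
    with ``return_effects`` also the latent breeding values per simulated
    trait, for validation against quantitative-genetic theory.
    """
    rng = np.random.default_rng(seed)
    ids = phenotyped_ids(ped)
    if not ids:
        raise ValueError("pedigree has no phenotyped queens (no year labels)")
    Asub = phenotyped_submatrix(A, ids)
    sim_traits = model.sim_trait_names
    k = len(sim_traits)
    n = len(ids)

    La = _chol_psd(Asub.values, "relationship matrix")
    Lg = _chol_psd(model.G, "G")
    Lr = _chol_psd(model.R, "R")
    a = La @ rng.standard_normal((n, k)) @ Lg.T
    e = rng.standard_normal((n, k)) @ Lr.T

    years = np.array([ped.queens[q].year for q in ids])
    week = np.empty(n, dtype=object)
    sigma_p = model.phenotypic_sd()
    week_effects: dict[str, np.ndarray] = {
        wc: model.week_effect_sd * sigma_p * rng.standard_normal(k)
        for wc in design.week_classes
    }
    w = np.zeros((n, k))
    for yi, year in enumerate(design.years):
        classes = [wc for wc in design.week_classes if wc.startswith(f"{year}_")]
        sel = np.flatnonzero(years == year)
        draw = rng.integers(len(classes), size=sel.size)
        for pos, cls in zip(sel, (classes[d] for d in draw)):
            week[pos] = cls
            w[pos] = week_effects[cls]

    mean_map = dict(zip(model.trait_names, model.means))
    mu = np.array([mean_map[t] for t in sim_traits])
    y = mu + w + a + e

    out = pd.DataFrame({"queen_id": ids, "year": years, "week": week})
    for j, t in enumerate(sim_traits):
        out[t] = y[:, j]

    if model.derive_volume and "sv" in model.trait_names:
        if "sd" not in sim_traits:
            raise ValueError("derive_volume requires an 'sd' (diameter) trait")
        reps = out["sd"].to_numpy()[:, None] + model.measurement_sd * rng.standard_normal(
            (n, model.measurement_reps)
        )
        reps = np.clip(reps, 1e-6, None)
        dbar, vol = derive_spermatheca_volume(reps)
        out["sd"] = dbar
        out["sv"] = vol

    out = out[["queen_id", "year", "week", *model.trait_names]]
    for trait, rate in model.missing_rates.items():
        mask = rng.random(n) < rate
        out.loc[mask, trait] = np.nan
    if return_effects:
        effects = pd.DataFrame({"queen_id": ids})
        for j, t in enumerate(sim_traits):
            effects[t] = a[:, j]
        return out, effects
    return out


def derive_spermatheca_volume(diameters) -> tuple[np.ndarray, np.ndarray]:
    """Mean diameter over replicate measurements and the sphere volume.

    The spermatheca is not perfectly spherical, so its diameter is recorded
    as the average d of replicate measurements (conventionally three) and
    the volume as (pi/6) d^3 — mm^3, i.e. microlitres.  ``diameters`` is a
    length-``r`` sequence or an ``(..., r)`` array; returns ``(d_mean,
    volume)`` with the leading shape preserved.
    """
    d = np.asarray(diameters, dtype=float)
    if d.shape[-1] < 1:
        raise ValueError("at least one diameter measurement required")
    if not np.all(np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("diameters must be positive and finite")
    dbar = d.mean(axis=-1)
    return dbar, (np.pi / 6.0) * dbar**3


def inject_defect_flags(
    table: pd.DataFrame,
    rates: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Add independent Bernoulli defect flags (columns ``defect_<name>``).

    Defaults mirror the observed prevalences of the five internal defect
    classes (abnormal intestinal tract 16%, ovary melanosis 9%, enteroliths
    8%, ovary atrophy 2.7%, abnormal spermatheca ~0.7%).
    """
    if rates is None:
        rates = DEFAULT_DEFECT_RATES
    for name, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"defect rate for {name!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = table.copy()
    for name, r in rates.items():
        out[f"defect_{name}"] = rng.random(len(out)) < r
    return out
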