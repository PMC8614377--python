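"""Descriptive statistics and the full genetic-parameter matrix.

Orchestrates the whole analysis: per-trait descriptives (N, mean, SD, CV%),
internal-defect prevalences, one univariate REML fit per trait and one
bivariate fit per trait pair, assembled into the conventional triangular
display — heritabilities on the diagonal, genetic correlations above,
phenotypic correlations below, each with its standard error and a per-cell
status flag.  Reported tables round CV% and prevalences to 1 decimal and
genetic parameters to 2, mirroring how such tables are printed; JSON output
preserves full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .pedigree import Pedigree, load_pedigree
from .relationship import RelationshipMatrix, compute_kinship
from .reml import (
    ModelSpec,
    correlations,
    fit_bivariate,
    fit_univariate,
    heritability,
)
from .simulate import (
    TRAIT_TABLE,
    BreedingDesign,
    default_trait_model,
    generate_pedigree,
    inject_defect_flags,
    simulate_phenotypes,
)

__all__ = [
    "DescriptiveRow",
    "ParameterMatrix",
    "FullAnalysisResult",
    "cv_percent",
    "summarize",
    "defect_prevalence",
    "run_full_analysis",
]

_UNITS = {t[0]: t[2] for t in TRAIT_TABLE}
_META_COLS = {"queen_id", "year", "week"}


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100 * SD / mean (sample SD, n - 1)."""
    if mean == 0:
        return math.nan
    return 100.0 * sd / mean


@dataclass
class DescriptiveRow:
    trait: str
    unit: str
    n: int
    mean: float
    sd: float
    cv_pct: float
    flagged: bool = False  # no usable records


def summarize(
    pheno: pd.DataFrame, units: Mapping[str, str] | None = None
) -> list[DescriptiveRow]:
    """Per-trait N, mean, sample SD and CV%; missing values excluded per trait."""
    if len(pheno) == 0:
        raise ValueError("empty phenotype table")
    units = dict(_UNITS, **(units or {}))
    rows = []
    for col in pheno.columns:
        if col in _META_COLS or col.startswith("defect_"):
            continue
        vals = pd.to_numeric(pheno[col], errors="coerce").dropna()
        if len(vals) == 0:
            rows.append(DescriptiveRow(col, units.get(col, ""), 0, math.nan, math.nan, math.nan, True))
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            DescriptiveRow(col, units.get(col, ""), int(len(vals)), mean, sd, cv_percent(mean, sd))
        )
    return rows


def descriptives_frame(rows: Sequence[DescriptiveRow]) -> pd.DataFrame:
    """Report-style table: CV% at 1 decimal, mean/SD at 2."""
    return pd.DataFrame(
        {
            "trait": [r.trait for r in rows],
            "unit": [r.unit for r in rows],
            "N": [r.n for r in rows],
            "mean": [round(r.mean, 2) for r in rows],
            "SD": [round(r.sd, 2) for r in rows],
            "CV_pct": [round(r.cv_pct, 1) for r in rows],
        }
    )


def defect_prevalence(table: pd.DataFrame) -> dict[str, float]:
    """Percentage of flagged queens per defect class, at 1 decimal."""
    cols = [c for c in table.columns if c.startswith("defect_")]
    if not cols:
        raise ValueError("no defect flag columns (defect_*) present")
    return {
        c.removeprefix("defect_"): round(100.0 * float(table[c].mean()), 1) for c in cols
    }


@dataclass
class ParameterMatrix:
    """Triangular genetic-parameter display over an ordered trait list.

    ``h2``/``h2_se`` along the diagonal; ``rg``/``rg_se`` meaningful above
    the diagonal and ``rp``/``rp_se`` below (both stored as full matrices
    with NaN elsewhere); ``status`` holds a short per-cell flag ("ok",
    "boundary", "not_converged", "undefined", or "failed: ...").
    """

    traits: list[str]
    h2: np.ndarray
    h2_se: np.ndarray
    rg: np.ndarray
    rg_se: np.ndarray
    rp: np.ndarray
    rp_se: np.ndarray
    status: np.ndarray  # (k, k) object array of strings

    def to_dict(self) -> dict:
        def clean(a: np.ndarray) -> list:
            return [
                [None if (isinstance(v, float) and math.isnan(v)) else v for v in row]
                for row in np.asarray(a, dtype=float).tolist()
            ]

        return {
            "traits": list(self.traits),
            "h2": [None if math.isnan(v) else v for v in self.h2.tolist()],
            "h2_se": [None if math.isnan(v) else v for v in self.h2_se.tolist()],
            "rg": clean(self.rg),
            "rg_se": clean(self.rg_se),
            "rp": clean(self.rp),
            "rp_se": clean(self.rp_se),
            "status": [[str(s) for s in row] for row in self.status.tolist()],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterMatrix":
        def arr(x, shape):
            a = np.array(
                [[math.nan if v is None else v for v in row] for row in x], dtype=float
            ) if np.ndim(x) == 2 else np.array(
                [math.nan if v is None else v for v in x], dtype=float
            )
            return a.reshape(shape)

        k = len(d["traits"])
        return cls(
            traits=list(d["traits"]),
            h2=arr(d["h2"], (k,)),
            h2_se=arr(d["h2_se"], (k,)),
            rg=arr(d["rg"], (k, k)),
            rg_se=arr(d["rg_se"], (k, k)),
            rp=arr(d["rp"], (k, k)),
            rp_se=arr(d["rp_se"], (k, k)),
            status=np.array(d["status"], dtype=object),
        )

    @classmethod
    def from_json(cls, s: str) -> "ParameterMatrix":
        return cls.from_dict(json.loads(s))

    def to_frame(self) -> pd.DataFrame:
        """Printed-style table: h2 on the diagonal, r_g above, r_p below,
        each cell ``value (SE)`` at 2 decimals."""
        k = len(self.traits)
        cells = np.empty((k, k), dtype=object)
        for i in range(k):
            for j in range(k):
                if i == j:
                    v, s = self.h2[i], self.h2_se[i]
                elif i < j:
                    v, s = self.rg[i, j], self.rg_se[i, j]
                else:
                    v, s = self.rp[i, j], self.rp_se[i, j]
                if math.isnan(v):
                    cells[i, j] = "--"
                else:
                    se = "NA" if math.isnan(s) else f"{s:.2f}"
                    cells[i, j] = f"{v:.2f} ({se})"
        return pd.DataFrame(cells, index=self.traits, columns=self.traits)


@dataclass
class FullAnalysisResult:
    descriptives: list[DescriptiveRow]
    defects: dict[str, float]
    matrix: ParameterMatrix
    phenotypes: pd.DataFrame
    A: RelationshipMatrix
    log: list[str] = field(default_factory=list)


def _load_config(config) -> dict:
    if config is None:
        return {}
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def run_full_analysis(config=None, out_dir: str | Path | None = None) -> FullAnalysisResult:
    """Run descriptives plus all univariate and pairwise bivariate fits.

    ``config`` is a mapping or YAML path with optional keys:

    * ``seed`` (int, default 0) — drives every stochastic step;
    * ``traits`` — subset of trait abbreviations (default: all 12);
    * ``design`` — ``BreedingDesign`` keyword overrides;
    * ``model`` — ``week_effect_sd``, ``genetic_correlation``,
      ``residual_correlation`` overrides for the default trait model;
    * ``pedigree`` / ``sire_groups`` / ``phenotypes`` — CSV paths; when
      given, data are loaded instead of simulated.

    Any failing fit is recorded in the cell's status flag and the run
    continues.  With ``out_dir`` set, writes ``table1.csv``,
    ``table2_matrix.csv``, ``defects.csv``, ``parameter_matrix.json`` and
    ``run.log``; identical configs and seeds produce byte-identical JSON.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    log: list[str] = [f"seed={seed}"]

    if "phenotypes" in cfg:
        ped = load_pedigree(cfg["pedigree"], cfg["sire_groups"])
        A = compute_kinship(ped)
        pheno = pd.read_csv(cfg["phenotypes"], na_values=["NA"])
        pheno["queen_id"] = pheno["queen_id"].astype(str)
        log.append(f"loaded {len(pheno)} phenotype records from {cfg['phenotypes']}")
    else:
        design = BreedingDesign(**cfg.get("design", {}))
        model = default_trait_model(**cfg.get("model", {}))
        ped = generate_pedigree(design, seed=seed)
        A = compute_kinship(ped)
        pheno = simulate_phenotypes(ped, A, model, design, seed=seed + 1)
        pheno = inject_defect_flags(pheno, seed=seed + 2)
        log.append(f"simulated {len(pheno)} queens under the default breeding design")

    all_traits = [
        c for c in pheno.columns if c not in _META_COLS and not c.startswith("defect_")
    ]
    traits = list(cfg.get("traits", all_traits))
    unknown = set(traits) - set(all_traits)
    if unknown:
        raise ValueError(f"config requests unknown traits: {sorted(unknown)}")
    k = len(traits)

    descriptives = [r for r in summarize(pheno) if r.trait in traits]
    try:
        defects = defect_prevalence(pheno)
    except ValueError:
        defects = {}

    h2 = np.full(k, np.nan)
    h2_se = np.full(k, np.nan)
    rg = np.full((k, k), np.nan)
    rg_se = np.full((k, k), np.nan)
    rp = np.full((k, k), np.nan)
    rp_se = np.full((k, k), np.nan)
    status = np.full((k, k), "", dtype=object)

    uni_fits = {}
    for i, t in enumerate(traits):
        try:
            fit = fit_univariate(pheno, A, t)
            uni_fits[t] = fit
            h2[i], h2_se[i] = heritability(fit)
            status[i, i] = (
                "ok" if fit.converged and not fit.boundary
                else ("boundary" if fit.boundary else "not_converged")
            )
            log.append(
                f"univariate {t}: h2={h2[i]:.3f} se={h2_se[i]:.3f} "
                f"logL={fit.loglik:.3f} status={status[i, i]}"
            )
        except Exception as exc:  # record and continue: partial matrix with flags
            status[i, i] = f"failed: {exc}"
            log.append(f"univariate {t}: FAILED ({exc})")

    for i in range(k):
        for j in range(i + 1, k):
            t1, t2 = traits[i], traits[j]
            try:
                fit = fit_bivariate(pheno, A, (t1, t2))
                cor = correlations(fit)
                rg[i, j], rg_se[i, j] = cor.r_g, cor.se_g
                rp[j, i], rp_se[j, i] = cor.r_p, cor.se_p
                if math.isnan(cor.r_g):
                    cell = "undefined"
                elif not fit.converged:
                    cell = "not_converged"
                elif fit.boundary or cor.r_g_clamped:
                    cell = "boundary"
                else:
                    cell = "ok"
                status[i, j] = status[j, i] = cell
                log.append(
                    f"bivariate {t1}-{t2}: rg={cor.r_g:.3f} rp={cor.r_p:.3f} "
                    f"logL={fit.loglik:.3f} status={cell}"
                )
            except Exception as exc:
                status[i, j] = status[j, i] = f"failed: {exc}"
                log.append(f"bivariate {t1}-{t2}: FAILED ({exc})")

    matrix = ParameterMatrix(traits, h2, h2_se, rg, rg_se, rp, rp_se, status)
    result = FullAnalysisResult(descriptives, defects, matrix, pheno, A, log)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        descriptives_frame(descriptives).to_csv(out / "table1.csv", index=False)
        matrix.to_frame().to_csv(out / "table2_matrix.csv", index_label="trait")
        (out / "parameter_matrix.json").write_text(matrix.to_json())
        pd.DataFrame(
            {"defect": list(defects), "prevalence_pct": list(defects.values())}
        ).to_csv(out / "defects.csv", index=False)
        (out / "run.log").write_text("\n".join(log) + "\n")
    return result
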