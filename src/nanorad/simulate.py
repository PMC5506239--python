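"""Seeded synthetic-data generators for every assay in the pipeline.

The generators reproduce the statistical structure of the study design
— clonogenic plating of gamma-irradiated *D. radiodurans* over 0-8 kGy
in triplicate, OD600 growth curves, and a concentration x incubation
toxicity grid — so the fitting and analysis code can be exercised
end-to-end without external data. Colony counts follow a Poisson law
around the model expectation, multiplied by a lognormal plate factor
representing plating-efficiency variation between plates; growth is
logistic after a lag with multiplicative lognormal noise. Every
generator is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosimetry import ParticleSpec
from .fitting import DoseResponseRecord, SurvivalDataset
from .survival import SurvivalParams, cfu_survival
from .toxicity import CFUToxicityTable, GrowthCurve

__all__ = [
    "AssayDesign",
    "ClonogenicAssay",
    "simulate_clonogenic_assay",
    "simulate_growth_curve",
    "simulate_toxicity_table",
    "reference_scenarios",
]

DEFAULT_DOSES = tuple(np.arange(0.0, 8.5, 0.5))  # kGy; resolves the shoulder


@dataclass(frozen=True)
class AssayDesign:
    """Design of a simulated clonogenic assay.

    ``cells_plated`` is the expected number of viable cells deposited
    on each plate after dilution (so the control expectation is
    ``cells_plated * plating_efficiency`` colonies); triplicate plating
    and ~10% plate-to-plate efficiency variation reflect routine CFU
    practice.
    """

    doses: tuple[float, ...] = DEFAULT_DOSES
    cells_plated: float = 250.0
    plating_efficiency: float = 0.8
    n_replicates: int = 3
    plating_lognormal_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.doses) == 0 or any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-empty and >= 0")
        if self.cells_plated <= 0 or not (0 < self.plating_efficiency <= 1):
            raise ValueError("cells_plated > 0 and plating_efficiency in (0, 1] required")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.plating_lognormal_cv < 0:
            raise ValueError("plating_lognormal_cv must be >= 0")


@dataclass(frozen=True)
class ClonogenicAssay:
    """Raw simulated colony counts plus the derived survival dataset."""

    counts: pd.DataFrame = field(repr=False)  # dose_kGy, replicate, colonies
    dataset: SurvivalDataset


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multiplier with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_clonogenic_assay(
    params: SurvivalParams,
    design: AssayDesign,
    *,
    normalize: str = "per_replicate",
) -> ClonogenicAssay:
    """Simulate colony counts and derive a survival dataset.

    Per dose and replicate the expected colony number is
    ``cells_plated x plating_efficiency x S_cfu(dose)``; a unit-mean
    lognormal plate factor multiplies the expectation and the count is
    Poisson. Survival is the treated count divided by the dose-0 count
    of the same replicate (``normalize="per_replicate"``, the default,
    matching how independent experiments are normalized) or by the
    pooled dose-0 mean (``normalize="pooled"``).
    """
    if normalize not in ("per_replicate", "pooled"):
        raise ValueError(f"unknown normalization {normalize!r}")
    rng = np.random.default_rng(design.seed)
    doses = np.asarray(design.doses, dtype=float)
    if 0.0 not in doses:
        raise ValueError("the dose grid must include 0 for normalization")
    surv = np.atleast_1d(cfu_survival(doses, params))
    expected = design.cells_plated * design.plating_efficiency * surv
    low = doses[expected < 5]
    if len(low):
        warnings.warn(
            f"expected colony count < 5 at doses {low.tolist()}; counting noise dominates",
            stacklevel=2,
        )
    factors = _lognormal_factor(
        rng, design.plating_lognormal_cv, (len(doses), design.n_replicates)
    )
    counts = rng.poisson(expected[:, None] * factors)
    frame = pd.DataFrame(
        {
            "dose_kGy": np.repeat(doses, design.n_replicates),
            "replicate": np.tile(np.arange(1, design.n_replicates + 1), len(doses)),
            "colonies": counts.ravel(),
        }
    )
    i0 = int(np.where(doses == 0.0)[0][0])
    if normalize == "per_replicate":
        denom = counts[i0].astype(float)  # one control plate per replicate
    else:
        denom = np.full(design.n_replicates, counts[i0].mean(), dtype=float)
    if np.any(denom == 0):
        raise ValueError("a dose-0 plate produced zero colonies; increase cells_plated")
    ratios = counts / denom  # (dose, replicate)
    records = []
    for i, d in enumerate(doses):
        mean = float(np.mean(ratios[i]))
        sd = float(np.std(ratios[i], ddof=1)) if design.n_replicates > 1 else None
        records.append(
            DoseResponseRecord(
                dose=float(d),
                survival=min(mean, 1.0),  # shoulder noise can push a ratio above 1
                replicate_sd=sd,
                n_replicates=design.n_replicates,
            )
        )
    dataset = SurvivalDataset(records=tuple(records), label=f"simulated(seed={design.seed})")
    return ClonogenicAssay(counts=frame, dataset=dataset)


def simulate_growth_curve(
    lag: float,
    doubling_time: float,
    carrying_od: float,
    od0: float,
    times,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> GrowthCurve:
    """Logistic growth after a lag, with multiplicative lognormal noise.

    With zero noise and far from the carrying capacity the log2(OD)
    slope equals ``1 / doubling_time``, so the doubling-time estimator
    recovers the input exactly.
    """
    t = np.asarray(times, dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if min(doubling_time, carrying_od, od0) <= 0 or lag < 0:
        raise ValueError("growth parameters must be positive (lag >= 0)")
    rng = np.random.default_rng(seed)
    r = np.log(2.0) / doubling_time
    te = np.clip(t - lag, 0.0, None)
    od = carrying_od / (1.0 + (carrying_od / od0 - 1.0) * np.exp(-r * te))
    od = od * _lognormal_factor(rng, noise_cv, len(t))
    return GrowthCurve(times=t, od600=od)


def simulate_toxicity_table(
    condition_means: dict,
    sds: dict,
    control_count_mean: float = 500.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> CFUToxicityTable:
    """Simulate a concentration x time CFU toxicity grid.

    ``condition_means`` maps ``(concentration, time_h)`` to the mean
    survival ratio relative to control; ``sds`` gives the
    between-replicate SD of that ratio. Control counts are Poisson
    around ``control_count_mean``; treated counts are Poisson around
    the per-replicate ratio (mean plus a normal deviate with the given
    SD, floored at 0) times the control mean.
    """
    for key, m in condition_means.items():
        if not (0.0 <= m <= 1.2):
            raise ValueError(f"mean ratio {m} at {key} outside [0, 1.2]")
    if control_count_mean <= 0:
        raise ValueError("control_count_mean must be > 0")
    if n_replicates == 1:
        warnings.warn("n_replicates=1: replicate SDs will be undefined", stacklevel=2)
    rng = np.random.default_rng(seed)
    times = sorted({t for _, t in condition_means})
    rows = []
    for t in times:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "concentration": 0.0,
                    "time_h": t,
                    "replicate": rep,
                    "cfu_count": rng.poisson(control_count_mean),
                }
            )
    for (conc, t), mean in sorted(condition_means.items()):
        sd = sds.get((conc, t), 0.0)
        for rep in range(1, n_replicates + 1):
            ratio = max(mean + rng.normal(0.0, sd) if sd > 0 else mean, 0.0)
            rows.append(
                {
                    "concentration": conc,
                    "time_h": t,
                    "replicate": rep,
                    "cfu_count": rng.poisson(ratio * control_count_mean),
                }
            )
    return CFUToxicityTable(data=pd.DataFrame(rows))


def reference_scenarios() -> dict:
    """Packaged reference parameter sets for the study system.

    Returns a dict with the fitted survival-model parameter rows for
    unloaded and nanoparticle-loaded *D. radiodurans*, the nanoparticle
    exposure series, the particle and cell geometry used in uptake
    accounting, the toxicity means at the 3x10^6 particles-per-cell
    level, and the growth-curve doubling-time presets.
    """
    return {
        "table1_control": SurvivalParams(alpha=0.290, beta=1.9, delta=0.35, n_units=4),
        "table1_ptnp": SurvivalParams(alpha=0.350, beta=1.9, delta=0.45, n_units=4),
        "particle": ParticleSpec(
            atoms_per_particle=1000, atomic_mass=195.084, diameter=2.0, particle_volume=4.2
        ),
        "cell_volume_nm3": 4.2e9,
        "cell_density_per_ml": 1e7,
        "exposure_series_particles_per_cell": (0.0, 9e5, 1.5e6, 3e6, 6e6),
        "toxicity_means": {(3e6, 3.0): 0.42, (3e6, 12.0): 0.18},
        "toxicity_sds": {(3e6, 3.0): 0.08, (3e6, 12.0): 0.03},
        "doubling_time_control_min": 144.0,
        "doubling_time_loaded_min": 455.0,
        "icpms_total_mass_ug": 1.079,
        "icpms_n_cells": 7e8,
        "icpms_administered_mass_ug": 20.0,
    }
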