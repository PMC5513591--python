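"""Synthetic lactation studies with known ground truth.

Emulates the two-experiment design the pipeline analyses: an intravenous
D2O bolus of 5 g/kg to each dam at time zero with plasma sampled at
3/24/48/72 h and pooled litter urine at 24/48/72/96 h (both measured with
~1 % multiplicative error on top of a 155 ppm natural-abundance
baseline), and daily one-hour weight-suckle-weight sessions on postnatal
days 11-14.  Per-animal kinetic rates and masses are drawn from lognormal
distributions around group medians, so every generated dam carries an
exact ground truth (rates, pools, milk flow) against which fits can be
scored.  Generation is fully reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import StudyBundle
from .model import NATURAL_ABUNDANCE_PPM, Dose, KineticRates, WaterPools, \
    dam_tracer_concentration, litter_tracer_concentration, ppm_to_gpg
from .fitting import DAM_PLASMA, LITTER_URINE

__all__ = ["GroupConfig", "StudyConfig", "generate_study", "fixed_truth_config",
           "inject_suckling_losses"]


def _positive(name, value):
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


def _nonneg(name, value):
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class GroupConfig:
    """Population parameters for one diet group.

    Medians are the centres of lognormal between-animal distributions;
    ``rate_cv`` and ``mass_cv`` their coefficients of variation.  The
    normal-protein (NP) and low-protein (LP) defaults carry the study
    medians for dam mass, body-water fraction and milk-transfer constant;
    environmental loss rates (``k01``/``k02`` centres) are package
    assumptions documented in the methods note.
    """

    name: str
    n_dams: int
    dam_mass_median: float  # g at PND 1
    tbw_fraction: float
    k21_median: float  # 1/h, milk transfer
    k01_median: float = 0.012  # 1/h, dam loss to environment
    k02_median: float = 0.020  # 1/h, litter loss to environment
    rate_cv: float = 0.10
    mass_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.n_dams < 1:
            raise ValueError("n_dams must be at least 1")
        for nm in ("dam_mass_median", "tbw_fraction", "k21_median", "k01_median", "k02_median"):
            _positive(nm, getattr(self, nm))
        if not self.tbw_fraction < 1:
            raise ValueError("tbw_fraction must be below 1")
        _nonneg("rate_cv", self.rate_cv)
        _nonneg("mass_cv", self.mass_cv)


#: Default groups: control (NP) n=4 vs isocaloric low-protein (LP) n=5.
NP_DEFAULT = GroupConfig(name="NP", n_dams=4, dam_mass_median=337.7,
                         tbw_fraction=0.769, k21_median=0.01223)
LP_DEFAULT = GroupConfig(name="LP", n_dams=5, dam_mass_median=308.3,
                         tbw_fraction=0.729, k21_median=0.00980)


@dataclass(frozen=True)
class StudyConfig:
    """Design of a synthetic study (both experiments)."""

    groups: tuple = (NP_DEFAULT, LP_DEFAULT)
    dose_rate_g_per_kg: float = 5.0
    purity: float = 0.999
    plasma_times_h: tuple = (3.0, 24.0, 48.0, 72.0)
    urine_times_h: tuple = (24.0, 48.0, 72.0, 96.0)
    measurement_cv: float = 0.01
    baseline_ppm: float = NATURAL_ABUNDANCE_PPM
    litter_size: int = 8
    pup_mass_median: float = 25.0  # g around PND 11
    pup_mass_cv: float = 0.05
    pup_water_fraction: float = 0.76
    wsw_days: tuple = (11, 12, 13, 14)
    wsw_duration_h: float = 1.0
    wsw_noise_sd: float = 1.5  # g per whole-litter session weighing pair
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        for nm in ("dose_rate_g_per_kg", "pup_mass_median", "pup_water_fraction",
                   "wsw_duration_h"):
            _positive(nm, getattr(self, nm))
        for nm in ("measurement_cv", "baseline_ppm", "pup_mass_cv", "wsw_noise_sd"):
            _nonneg(nm, getattr(self, nm))
        if self.litter_size < 1:
            raise ValueError("litter_size must be at least 1")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must be in (0, 1]")
        for nm in ("plasma_times_h", "urine_times_h"):
            t = getattr(self, nm)
            if list(t) != sorted(t) or any(v < 0 for v in t):
                raise ValueError(f"{nm} must be sorted and non-negative")


def _lognormal(rng: np.random.Generator, median: float, cv: float, size=None):
    """Lognormal draw parameterised by median and coefficient of variation."""
    if cv == 0:
        return median if size is None else np.full(size, median)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(np.log(median), sigma, size=size))


def generate_study(config: StudyConfig | None = None, seed: int | None = None) -> StudyBundle:
    """Generate a complete synthetic study as a :class:`StudyBundle`.

    The bundle holds raw tracer measurements (baseline included, noise
    applied, in g/g), a dose table, WSW sessions and a ground-truth table
    with each dam's true rates, pools and milk flow.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    baseline = ppm_to_gpg(config.baseline_ppm)

    tracer_rows, dose_rows, wsw_rows, truth_rows = [], [], [], []
    for grp in config.groups:
        for i in range(grp.n_dams):
            sid = f"{grp.name}{i + 1:02d}"
            dam_mass = float(_lognormal(rng, grp.dam_mass_median, grp.mass_cv))
            rates = KineticRates(
                k_out_dam=float(_lognormal(rng, grp.k01_median, grp.rate_cv)),
                k_dam_to_litter=float(_lognormal(rng, grp.k21_median, grp.rate_cv)),
                k_out_litter=float(_lognormal(rng, grp.k02_median, grp.rate_cv)),
            )
            pup_masses = _lognormal(rng, config.pup_mass_median, config.pup_mass_cv,
                                    size=config.litter_size)
            litter_mass = float(np.sum(pup_masses))
            pools = WaterPools(
                tbw_dam_mass=grp.tbw_fraction * dam_mass,
                tbw_litter_mass=config.pup_water_fraction * litter_mass,
            )
            dose = Dose(d2o_mass=config.dose_rate_g_per_kg * dam_mass / 1000.0,
                        dam_body_mass=dam_mass, purity=config.purity)
            milk_flow = rates.k_dam_to_litter * pools.tbw_dam_mass

            for compartment, times in ((DAM_PLASMA, config.plasma_times_h),
                                       (LITTER_URINE, config.urine_times_h)):
                t = np.asarray(times, dtype=float)
                clean = (dam_tracer_concentration(t, dose, rates, pools)
                         if compartment == DAM_PLASMA
                         else litter_tracer_concentration(t, dose, rates, pools))
                noise = 1.0 + config.measurement_cv * rng.standard_normal(t.size)
                measured = np.maximum((clean + baseline) * noise, 0.0)
                for tj, cj in zip(t, measured):
                    tracer_rows.append({
                        "subject_id": sid, "group": grp.name, "compartment": compartment,
                        "time_h": float(tj), "concentration": float(cj), "units": "gpg",
                    })

            dose_rows.append({
                "subject_id": sid, "group": grp.name,
                "d2o_mass_g": dose.d2o_mass, "dam_body_mass_g": dam_mass,
                "purity": config.purity, "litter_mass_g": litter_mass,
                "litter_size": config.litter_size,
            })
            pre_weight = litter_mass
            for pnd in config.wsw_days:
                gain = (milk_flow * config.wsw_duration_h
                        + config.wsw_noise_sd * rng.standard_normal())
                wsw_rows.append({
                    "litter_id": sid, "group": grp.name, "pnd": int(pnd),
                    "pre_weight_g": round(pre_weight, 2),
                    "post_weight_g": round(pre_weight + gain, 2),
                    "duration_h": config.wsw_duration_h,
                    "litter_size": config.litter_size,
                })
            truth_rows.append({
                "subject_id": sid, "group": grp.name,
                "k_out_dam": rates.k_out_dam,
                "k_dam_to_litter": rates.k_dam_to_litter,
                "k_out_litter": rates.k_out_litter,
                "tbw_dam_g": pools.tbw_dam_mass,
                "tbw_litter_g": pools.tbw_litter_mass,
                "d2o_mass_g": dose.d2o_mass,
                "milk_flow_g_per_h": milk_flow,
            })

    return StudyBundle(
        tracer=pd.DataFrame(tracer_rows),
        doses=pd.DataFrame(dose_rows),
        wsw=pd.DataFrame(wsw_rows),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def fixed_truth_config(base: GroupConfig = NP_DEFAULT, n_dams: int = 1,
                       measurement_cv: float = 0.01) -> StudyConfig:
    """Design for parameter-recovery simulations: truth pinned at the medians.

    Removes all between-animal variability (rate, dam-mass and pup-mass
    CVs set to zero) so every generated dam carries exactly the group's
    median parameters, leaving measurement noise as the only stochastic
    element.  Used to score estimator bias and precision against a known
    truth under the reference sampling design.
    """
    group = dataclasses.replace(base, n_dams=n_dams, rate_cv=0.0, mass_cv=0.0)
    return StudyConfig(groups=(group,), measurement_cv=measurement_cv, pup_mass_cv=0.0)


def inject_suckling_losses(wsw: pd.DataFrame, loss_rate: float) -> pd.DataFrame:
    """Remove water lost by pups during suckling from WSW weight gains.

    Subtracts ``loss_rate * duration`` grams from each session's post
    weight, reproducing the downward bias of the WSW estimate relative to
    true milk flow (urine, feces and evaporation are invisible to the
    weighing but real water losses).
    """
    if loss_rate < 0:
        raise ValueError("loss_rate must be non-negative")
    out = wsw.copy()
    out["post_weight_g"] = out["post_weight_g"] - loss_rate * out["duration_h"]
    return out
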