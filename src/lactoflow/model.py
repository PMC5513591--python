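"""Two-compartment model of body-water turnover during lactation.

The dam and her litter are each treated as a single well-mixed body-water
pool.  An intravenous bolus of deuterated water (D2O) labels the dam's pool
at time zero; tracer then leaves the dam to the environment (urine, feces,
evaporation) at first-order rate ``k_out_dam`` and to the litter through
milk at rate ``k_dam_to_litter``.  The litter pool in turn loses water to
the environment at ``k_out_litter``.  With tracer masses m1 (dam) and m2
(litter) the system is

    dm1/dt = -(k_out_dam + k_dam_to_litter) * m1
    dm2/dt = k_dam_to_litter * m1 - k_out_litter * m2

whose closed-form solutions are implemented here, along with the
steady-state water flows they imply.  Concentrations are canonically
expressed in g D2O per g body water (1 g/g = 1e6 ppm).

Both animals are assumed to be at (near-)steady state with respect to
total body water over the sampling window, so pool sizes are constants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NATURAL_ABUNDANCE_PPM",
    "KineticRates",
    "WaterPools",
    "Dose",
    "FlowSet",
    "ppm_to_gpg",
    "gpg_to_ppm",
    "dam_tracer_concentration",
    "litter_tracer_concentration",
    "litter_peak_time",
    "steady_state_flows",
]

#: Natural abundance of D2O in body water, in ppm (by mass of water).
NATURAL_ABUNDANCE_PPM = 155.0


def ppm_to_gpg(value_ppm):
    """Convert a concentration in ppm to g D2O per g body water."""
    return np.asarray(value_ppm, dtype=float) / 1e6 if np.ndim(value_ppm) else float(value_ppm) / 1e6


def gpg_to_ppm(value_gpg):
    """Convert a concentration in g/g to ppm."""
    return np.asarray(value_gpg, dtype=float) * 1e6 if np.ndim(value_gpg) else float(value_gpg) * 1e6


def _require_positive_finite(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class KineticRates:
    """First-order rate constants of the two-pool turnover model, in 1/h.

    ``k_out_dam`` is loss from the dam to the environment only; transfer to
    the litter through milk is carried separately by ``k_dam_to_litter``,
    so the dam's total elimination rate is their sum.
    """

    k_out_dam: float
    k_dam_to_litter: float
    k_out_litter: float

    def __post_init__(self) -> None:
        _require_positive_finite("k_out_dam", self.k_out_dam)
        _require_positive_finite("k_dam_to_litter", self.k_dam_to_litter)
        _require_positive_finite("k_out_litter", self.k_out_litter)

    @property
    def dam_elimination_rate(self) -> float:
        """Total first-order disappearance rate of tracer from the dam (1/h)."""
        return self.k_out_dam + self.k_dam_to_litter


@dataclass(frozen=True)
class WaterPools:
    """Total body water of dam and whole litter, in grams."""

    tbw_dam_mass: float
    tbw_litter_mass: float

    def __post_init__(self) -> None:
        _require_positive_finite("tbw_dam_mass", self.tbw_dam_mass)
        _require_positive_finite("tbw_litter_mass", self.tbw_litter_mass)


@dataclass(frozen=True)
class Dose:
    """An intravenous D2O bolus given to the dam.

    ``d2o_mass`` is the injected mass in grams (syringe weighed before and
    after injection); ``purity`` is the mole fraction of D2O in the
    injectate and multiplies the injected mass to give the tracer mass.
    """

    d2o_mass: float
    dam_body_mass: float
    purity: float = 0.999

    def __post_init__(self) -> None:
        _require_positive_finite("d2o_mass", self.d2o_mass)
        _require_positive_finite("dam_body_mass", self.dam_body_mass)
        if not (0 < self.purity <= 1):
            raise ValueError(f"purity must be in (0, 1], got {self.purity!r}")
        rate = self.d2o_mass / self.dam_body_mass
        if not (0.001 <= rate <= 0.05):
            warnings.warn(
                f"dose rate {rate:.4g} g/g outside the typical [0.001, 0.05] range "
                "(5 g/kg is the reference protocol)",
                stacklevel=2,
            )

    @property
    def tracer_mass(self) -> float:
        """Purity-corrected injected D2O mass, in grams."""
        return self.purity * self.d2o_mass


@dataclass(frozen=True)
class FlowSet:
    """Steady-state water flows of the two-pool system, in g/h.

    Dam balance: inflow equals environmental loss plus milk.  Litter
    balance: milk plus non-milk intake equals environmental loss.
    """

    r_in_dam: float
    r_out_dam: float
    r_dam_to_litter: float
    r_in_litter: float
    r_out_litter: float

    def __post_init__(self) -> None:
        if not math.isclose(self.r_in_dam, self.r_out_dam + self.r_dam_to_litter,
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("dam steady-state balance violated: r_in_dam != r_out_dam + r_dam_to_litter")
        if not math.isclose(self.r_in_litter + self.r_dam_to_litter, self.r_out_litter,
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("litter steady-state balance violated")


def _check_times(t) -> np.ndarray:
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    return t_arr


def dam_tracer_concentration(t, dose: Dose, rates: KineticRates, pools: WaterPools):
    """Tracer concentration in the dam's body water at time ``t`` hours.

    A mono-exponential washout from the initial dilution of the dose in the
    dam's pool: C1(t) = (purity * d2o_mass / tbw_dam_mass) * exp(-lam1 * t)
    with lam1 = k_out_dam + k_dam_to_litter.  Returns g D2O per g water.
    """
    t_arr = _check_times(t)
    c0 = dose.tracer_mass / pools.tbw_dam_mass
    out = c0 * np.exp(-rates.dam_elimination_rate * t_arr)
    return out if out.ndim else float(out)


def litter_tracer_concentration(t, dose: Dose, rates: KineticRates, pools: WaterPools):
    """Tracer concentration in the litter's pooled body water at ``t`` hours.

    Solution of dm2/dt = k_dam_to_litter*m1 - k_out_litter*m2 with m2(0)=0,
    divided by the litter pool size:

        C2(t) = D*K21 * (exp(-lam1*t) - exp(-k02*t)) / (TBWl * (k02 - lam1))

    evaluated in a cancellation-safe form; the degenerate case
    k02 == lam1 reduces to D*K21 * t * exp(-lam1*t) / TBWl.  The curve is
    zero at t=0, non-negative, and unimodal.
    """
    t_arr = _check_times(t)
    lam1 = rates.dam_elimination_rate
    k02 = rates.k_out_litter
    d = dose.tracer_mass
    delta = k02 - lam1
    # (exp(-lam1 t) - exp(-k02 t))/delta = exp(-lam1 t) * (-expm1(-delta t))/delta,
    # which tends to t * exp(-lam1 t) as delta -> 0.
    with np.errstate(invalid="ignore", divide="ignore"):
        if delta == 0.0:
            kernel = t_arr * np.exp(-lam1 * t_arr)
        else:
            kernel = np.exp(-lam1 * t_arr) * (-np.expm1(-delta * t_arr)) / delta
    out = d * rates.k_dam_to_litter * kernel / pools.tbw_litter_mass
    return out if out.ndim else float(out)


def litter_peak_time(rates: KineticRates) -> float:
    """Time (h) at which the litter enrichment curve reaches its maximum.

    ln(lam1/k02)/(lam1 - k02) for lam1 != k02, and 1/lam1 at the degenerate
    point; always strictly positive.
    """
    lam1 = rates.dam_elimination_rate
    k02 = rates.k_out_litter
    delta = lam1 - k02
    if delta == 0.0:
        return 1.0 / lam1
    return math.log1p(delta / k02) / delta


def steady_state_flows(rates: KineticRates, pools: WaterPools) -> FlowSet:
    """Absolute water flows (g/h) implied by the rate constants and pools.

    Milk flow is r_dam_to_litter = k_dam_to_litter * tbw_dam_mass.  A
    negative non-milk litter intake (litter excreting more than milk
    supplies) is permitted but flagged, since it implies the litter pool is
    not strictly at steady state.
    """
    r_out_dam = rates.k_out_dam * pools.tbw_dam_mass
    r_milk = rates.k_dam_to_litter * pools.tbw_dam_mass
    r_out_litter = rates.k_out_litter * pools.tbw_litter_mass
    r_in_litter = r_out_litter - r_milk
    if r_in_litter < 0:
        warnings.warn(
            "non-milk litter water intake is negative: litter output is smaller than "
            "milk inflow, implying net water retention (growth) rather than steady state",
            stacklevel=2,
        )
    return FlowSet(
        r_in_dam=r_out_dam + r_milk,
        r_out_dam=r_out_dam,
        r_dam_to_litter=r_milk,
        r_in_litter=r_in_litter,
        r_out_litter=r_out_litter,
    )
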