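"""Weight-suckle-weight (WSW) milk-production estimator and pup growth.

WSW estimates milk intake as the litter's weight gain over a timed
suckling bout: pups are weighed after a separation from the dam, allowed
to suckle for a fixed interval, and weighed again.  The whole litter is
weighed as one unit for better scale precision.  No correction is applied
for water lost by the pups to urine, feces and evaporation during the
bout, so the estimate is biased low by that loss.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SucklingSession", "GrowthRecord", "wsw_dam_production", "relative_mass_gain"]


@dataclass(frozen=True)
class SucklingSession:
    """One timed suckling bout for one litter.

    Weights are whole-litter, in grams; a negative weight change from
    measurement noise is retained as observed, never clipped.
    """

    litter_id: str
    group: str
    pnd: int
    pre_weight: float
    post_weight: float
    duration: float
    litter_size: int

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("suckling duration must be positive")
        if self.litter_size < 1:
            raise ValueError("litter_size must be at least 1")
        if self.pre_weight <= 0 or self.post_weight <= 0:
            raise ValueError("litter weights must be positive")


@dataclass(frozen=True)
class GrowthRecord:
    """Birth weight and daily weights (g) for a pup or whole litter."""

    pup_or_litter_id: str
    birth_weight: float
    daily_weights: tuple  # ordered (pnd, weight_g) pairs

    def __post_init__(self) -> None:
        if self.birth_weight <= 0:
            raise ValueError("birth weight must be positive")
        pnds = [p for p, _ in self.daily_weights]
        if any(b <= a for a, b in zip(pnds, pnds[1:])):
            raise ValueError("postnatal days must be increasing")


def wsw_dam_production(session: SucklingSession) -> float:
    """Dam milk production (g/h) from one WSW session.

    Per-pup intake is the mean weight difference divided by suckling time;
    dam production multiplies it back by litter size, so it reduces to the
    whole-litter weight change per hour and is independent of litter size.
    """
    per_pup = (session.post_weight - session.pre_weight) / session.litter_size / session.duration
    return per_pup * session.litter_size


def relative_mass_gain(record: GrowthRecord, pnd: int) -> float:
    """Weight gained since birth as a fraction of birth weight."""
    weights = dict(record.daily_weights)
    if pnd not in weights:
        raise KeyError(f"{record.pup_or_litter_id}: no weight recorded for PND {pnd}")
    return (weights[pnd] - record.birth_weight) / record.birth_weight
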