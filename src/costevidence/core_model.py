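"""Deterministic forward model of effort allocation.

Cost evidence rises during effort with slope ``Se`` and falls during rest
with slope ``Sr``, between two bounds separated by an amplitude ``A``.
Because the dynamics are linear, the durations of effort and rest epochs
are simply ``Te = A / Se`` and ``Tr = A / Sr``.  Experimental factors
(monetary incentive, actual difficulty, cued difficulty) modulate the
latent parameters either linearly or, for cued difficulty, as a hyperbolic
discounter of the incentive term: ``w * I / (1 + k * Dc)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "FactorLevels",
    "LatentParams",
    "ParamCoefficients",
    "ModelCoefficients",
    "PredictedDurations",
    "Epoch",
    "EpochSequence",
    "InvalidParameterRegion",
    "compute_latent_params",
    "predict_durations",
    "simulate_trial",
]

LATENT_PARAMS = ("A", "Se", "Sr")


class InvalidParameterRegion(ValueError):
    """A latent parameter came out non-positive (durations undefined).

    Fitters treat this region as infinitely penalised rather than clamping,
    which keeps the penalty surface clean for gradient-based optimisation.
    """


@dataclass(frozen=True)
class FactorLevels:
    """Experimental factor levels for one condition.

    incentive: monetary stake in euros (e.g. 0.10, 0.20, 0.50).
    actual_difficulty: target force as a fraction of maximal force, in (0, 1].
    cued_difficulty: announced difficulty level, absent for implicit designs.
    """

    incentive: float
    actual_difficulty: float
    cued_difficulty: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.incentive > 0:
            raise ValueError(f"incentive must be positive, got {self.incentive}")
        if not 0 < self.actual_difficulty <= 1:
            raise ValueError(
                f"actual_difficulty must be in (0, 1], got {self.actual_difficulty}"
            )
        if self.cued_difficulty is not None and not 0 < self.cued_difficulty <= 1:
            raise ValueError(
                f"cued_difficulty must be in (0, 1], got {self.cued_difficulty}"
            )


@dataclass(frozen=True)
class LatentParams:
    """Bound amplitude and slopes, all in cost-evidence units (per second)."""

    A: float
    Se: float
    Sr: float

    def __post_init__(self) -> None:
        for name in LATENT_PARAMS:
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise InvalidParameterRegion(
                    f"latent parameter {name} = {value} is not strictly positive"
                )


@dataclass(frozen=True)
class ParamCoefficients:
    """Coefficients mapping factors to one latent parameter.

    ``mean`` is the baseline value; ``incentive``/``actual``/``cued`` are
    linear weights; ``discount`` is the hyperbolic discount rate k applied to
    the incentive term (hyperbolic family only), giving a contribution
    ``incentive * I / (1 + discount * Dc)``.
    """

    mean: float
    incentive: float = 0.0
    actual: float = 0.0
    cued: float = 0.0
    discount: float = 0.0


@dataclass(frozen=True)
class ModelCoefficients:
    family: str  # "linear" | "hyperbolic"
    A: ParamCoefficients = field(default_factory=lambda: ParamCoefficients(1.0))
    Se: ParamCoefficients = field(default_factory=lambda: ParamCoefficients(1.0))
    Sr: ParamCoefficients = field(default_factory=lambda: ParamCoefficients(1.0))

    def __post_init__(self) -> None:
        if self.family not in ("linear", "hyperbolic"):
            raise ValueError(f"unknown family {self.family!r}")
        for name in LATENT_PARAMS:
            c = getattr(self, name)
            if self.family == "linear" and c.discount != 0.0:
                raise ValueError(
                    f"linear family admits no hyperbolic discount (on {name})"
                )
            if self.family == "hyperbolic" and c.cued != 0.0:
                raise ValueError(
                    "hyperbolic family integrates cued difficulty only through "
                    f"the incentive denominator (additive cued weight on {name})"
                )
            if c.discount != 0.0 and c.incentive == 0.0:
                raise ValueError(
                    f"hyperbolic discount on {name} requires a nonzero incentive "
                    "weight (a null numerator makes the denominator inert)"
                )


@dataclass(frozen=True)
class PredictedDurations:
    """Predicted effort and rest durations in seconds."""

    Te: float
    Tr: float

    def __post_init__(self) -> None:
        if not (self.Te > 0 and self.Tr > 0):
            raise ValueError("durations must be strictly positive")


@dataclass(frozen=True)
class Epoch:
    kind: str  # "effort" | "rest"
    duration: float
    truncated: bool = False


@dataclass(frozen=True)
class EpochSequence:
    """Ordered alternation of effort and rest epochs within one trial."""

    epochs: tuple[Epoch, ...]
    trial_length: float
    factors: Optional[FactorLevels] = None

    def durations(self, kind: str, include_truncated: bool = False) -> list[float]:
        return [
            e.duration
            for e in self.epochs
            if e.kind == kind and (include_truncated or not e.truncated)
        ]

    @property
    def total_duration(self) -> float:
        return sum(e.duration for e in self.epochs)


def _one_param(c: ParamCoefficients, family: str, factors: FactorLevels) -> float:
    dc = factors.cued_difficulty
    if family == "linear":
        value = c.mean + c.incentive * factors.incentive + c.actual * factors.actual_difficulty
        if c.cued != 0.0:
            if dc is None:
                raise ValueError("cued weight present but cued_difficulty absent")
            value += c.cued * dc
        return value
    # hyperbolic: incentive discounted by cued difficulty in the denominator
    denom = 1.0
    if c.discount != 0.0:
        if dc is None:
            raise ValueError("hyperbolic discount present but cued_difficulty absent")
        denom = 1.0 + c.discount * dc
        if denom <= 0:
            raise InvalidParameterRegion(
                f"hyperbolic denominator 1 + k*Dc = {denom} is not positive"
            )
    return c.mean + c.incentive * factors.incentive / denom + c.actual * factors.actual_difficulty


def compute_latent_params(coeffs: ModelCoefficients, factors: FactorLevels) -> LatentParams:
    """Map factor levels to (A, Se, Sr) under the given coefficient set.

    Raises
    ------
    InvalidParameterRegion
        If any latent parameter comes out non-positive.
    """
    return LatentParams(
        A=_one_param(coeffs.A, coeffs.family, factors),
        Se=_one_param(coeffs.Se, coeffs.family, factors),
        Sr=_one_param(coeffs.Sr, coeffs.family, factors),
    )


def predict_durations(latent: LatentParams) -> PredictedDurations:
    """Te = A/Se, Tr = A/Sr -- the ratios of amplitude to slope."""
    return PredictedDurations(Te=latent.A / latent.Se, Tr=latent.A / latent.Sr)


def simulate_trial(
    latent: LatentParams,
    trial_length: float,
    factors: Optional[FactorLevels] = None,
) -> EpochSequence:
    """Alternate effort/rest epochs of durations Te, Tr, ... within a trial.

    The trial starts at the lower bound (cost fully dissipated) with an
    effort epoch; the sequence is truncated exactly at ``trial_length`` and
    the final, cut-short epoch is flagged truncated.
    """
    if not trial_length > 0:
        raise ValueError("trial_length must be positive")
    pred = predict_durations(latent)
    epochs: list[Epoch] = []
    t = 0.0
    kind = "effort"
    while t < trial_length:
        nominal = pred.Te if kind == "effort" else pred.Tr
        remaining = trial_length - t
        if nominal < remaining:
            epochs.append(Epoch(kind, nominal, truncated=False))
            t += nominal
        else:
            epochs.append(Epoch(kind, remaining, truncated=True))
            t = trial_length
        kind = "rest" if kind == "effort" else "effort"
    return EpochSequence(tuple(epochs), trial_length, factors)
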