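"""Enumeration and pruning of modulation-configuration model spaces.

A model is identified by which experimental factors (incentive, actual
difficulty, cued difficulty) are allowed to modulate which latent
parameters (A, Se, Sr).  The full linear space over two factors has
2^6 = 64 configurations and over three factors 2^9 = 512; the hyperbolic
family treats cued difficulty as a discounter in the denominator of the
incentive term, which is inert without the incentive numerator, leaving
6 valid per-parameter combinations (216 overall).

Spaces are pruned by a producibility rule: a configuration is kept only if
some assignment of signed weights can reproduce every observed significant
effect.  A factor can move Te only through A or Se and Tr only through A or
Sr, and opposite-signed effects on Te and Tr require the factor to touch at
least two distinct latent parameters (an A-only pathway moves both
durations in the same direction, since Te and Tr share the numerator A).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from costevidence.core_model import LATENT_PARAMS

__all__ = [
    "FACTORS",
    "ModulationConfig",
    "EffectRequirement",
    "ModelSpace",
    "enumerate_full_space",
    "can_produce",
    "prune_space",
    "pruned_space",
    "winning_config",
    "task_requirements",
    "space_to_frame",
]

FACTORS = ("incentive", "actual", "cued")

# Pathways through which a factor can move each duration.
_TE_PATHWAYS = frozenset({"A", "Se"})
_TR_PATHWAYS = frozenset({"A", "Sr"})


@dataclass(frozen=True)
class ModulationConfig:
    """One model: the set of (latent parameter, factor) modulations allowed.

    For the hyperbolic family the ``cued`` flag on a parameter means the
    incentive term on that parameter is hyperbolically discounted by cued
    difficulty; it therefore requires the ``incentive`` flag on the same
    parameter.
    """

    family: str
    flags: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.family not in ("linear", "hyperbolic"):
            raise ValueError(f"unknown family {self.family!r}")
        for param, factor in self.flags:
            if param not in LATENT_PARAMS or factor not in FACTORS:
                raise ValueError(f"unknown flag ({param}, {factor})")
        if self.family == "hyperbolic":
            for param in LATENT_PARAMS:
                if (param, "cued") in self.flags and (param, "incentive") not in self.flags:
                    raise ValueError(
                        f"hyperbolic cued flag on {param} requires the incentive flag "
                        "(denominator without numerator is inert)"
                    )

    def has(self, param: str, factor: str) -> bool:
        return (param, factor) in self.flags

    def touched_params(self, factor: str) -> frozenset[str]:
        """Latent parameters modulated by ``factor`` through any pathway."""
        return frozenset(p for p in LATENT_PARAMS if (p, factor) in self.flags)

    def label(self) -> str:
        bits = "".join(
            "1" if (p, f) in self.flags else "0" for p in LATENT_PARAMS for f in FACTORS
        )
        return f"{self.family[:3]}:{bits}"


@dataclass(frozen=True)
class EffectRequirement:
    """An observed significant effect the retained models must be able to produce."""

    factor: str
    targets: frozenset[str]  # subset of {"Te", "Tr"}
    sign_pattern: str = "any-sign"  # "same-sign" | "opposite-sign" | "any-sign"

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}")
        if not self.targets or not self.targets <= {"Te", "Tr"}:
            raise ValueError("targets must be a non-empty subset of {'Te', 'Tr'}")
        if self.sign_pattern not in ("same-sign", "opposite-sign", "any-sign"):
            raise ValueError(f"unknown sign pattern {self.sign_pattern!r}")
        if self.sign_pattern != "any-sign" and len(self.targets) != 2:
            raise ValueError("a joint sign pattern needs both Te and Tr as targets")


@dataclass(frozen=True)
class ModelSpace:
    configs: tuple[ModulationConfig, ...]
    provenance: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        if len(set(self.configs)) != len(self.configs):
            raise ValueError("duplicate configurations in model space")

    def __len__(self) -> int:
        return len(self.configs)

    def __iter__(self):
        return iter(self.configs)

    def index_of(self, config: ModulationConfig) -> int:
        return self.configs.index(config)


def _per_param_combos(family: str, factors: Sequence[str]) -> list[frozenset[str]]:
    """All factor subsets one latent parameter may carry, lexicographic order."""
    combos = []
    for bits in itertools.product((0, 1), repeat=len(factors)):
        subset = frozenset(f for f, b in zip(factors, bits) if b)
        if family == "hyperbolic" and "cued" in subset and "incentive" not in subset:
            continue  # denominator without numerator is inert
        combos.append(subset)
    return combos


def enumerate_full_space(family: str, factors: Iterable[str]) -> ModelSpace:
    """Enumerate every modulation configuration for the given factor set.

    Ordering is lexicographic over the (A, Se, Sr) per-parameter factor
    subsets so that model indices are reproducible across runs.
    """
    factors = tuple(factors)
    unknown = set(factors) - set(FACTORS)
    if unknown:
        raise ValueError(f"unknown factors {sorted(unknown)}")
    if family == "hyperbolic" and not {"incentive", "cued"} <= set(factors):
        raise ValueError("hyperbolic family requires both incentive and cued factors")
    combos = _per_param_combos(family, factors)
    configs = []
    for a_set, se_set, sr_set in itertools.product(combos, repeat=3):
        flags = frozenset(
            {("A", f) for f in a_set}
            | {("Se", f) for f in se_set}
            | {("Sr", f) for f in sr_set}
        )
        configs.append(ModulationConfig(family, flags))
    return ModelSpace(tuple(configs), {"family": family, "factors": factors})


def can_produce(config: ModulationConfig, req: EffectRequirement) -> bool:
    """Whether some signed weights under ``config`` yield the required effect.

    The decision rules: a factor affects Te iff it touches A or Se, and Tr
    iff it touches A or Sr; opposite-signed effects on both durations
    additionally require at least two distinct latent-parameter pathways.
    """
    touched = config.touched_params(req.factor)
    if "Te" in req.targets and not touched & _TE_PATHWAYS:
        return False
    if "Tr" in req.targets and not touched & _TR_PATHWAYS:
        return False
    if req.sign_pattern == "opposite-sign" and len(touched) < 2:
        return False
    return True


def prune_space(space: ModelSpace, reqs: Sequence[EffectRequirement]) -> ModelSpace:
    """Retain exactly the configurations able to produce every requirement."""
    kept = tuple(c for c in space if all(can_produce(c, r) for r in reqs))
    provenance = dict(space.provenance)
    provenance["requirements"] = tuple(reqs)
    return ModelSpace(kept, provenance)


def task_requirements(task: str) -> list[EffectRequirement]:
    """The observed significant effects each task's model space must produce.

    implicit: incentive lengthens effort and shortens rest (opposite signs);
    difficulty shortens effort.  explicit: incentive and difficulty each act
    with opposite signs on effort and rest.  dissociation: incentive acts
    with opposite signs; actual difficulty moves effort duration; cued
    difficulty moves rest duration.
    """
    both = frozenset({"Te", "Tr"})
    if task == "implicit":
        return [
            EffectRequirement("incentive", both, "opposite-sign"),
            EffectRequirement("actual", frozenset({"Te"})),
        ]
    if task == "explicit":
        return [
            EffectRequirement("incentive", both, "opposite-sign"),
            EffectRequirement("actual", both, "opposite-sign"),
        ]
    if task in ("dissociation", "explicit_hyperbolic", "dissociation_hyperbolic"):
        return [
            EffectRequirement("incentive", both, "opposite-sign"),
            EffectRequirement("actual", frozenset({"Te"})),
            EffectRequirement("cued", frozenset({"Tr"})),
        ]
    raise ValueError(f"unknown task {task!r}")


_TASK_SPACES = {
    # task -> (family, factors, requirement key)
    "implicit": ("linear", ("incentive", "actual"), "implicit"),
    "explicit": ("linear", ("incentive", "actual"), "explicit"),
    "dissociation": ("linear", ("incentive", "actual", "cued"), "dissociation"),
    "explicit_hyperbolic": ("hyperbolic", ("incentive", "actual", "cued"), "dissociation"),
    "dissociation_hyperbolic": ("hyperbolic", ("incentive", "actual", "cued"), "dissociation"),
}


def pruned_space(task: str) -> ModelSpace:
    """The task's pruned model space (24 / 16 / 144 / 78 configurations).

    The explicit task uses the two-factor linear space because its single
    difficulty factor is both actual and cued; the hyperbolic spaces for the
    explicit and dissociation tasks are identical, with actual difficulty
    bound to the linear pathway and cued difficulty to the hyperbolic one.
    """
    if task not in _TASK_SPACES:
        raise ValueError(f"unknown task {task!r}")
    family, factors, req_key = _TASK_SPACES[task]
    space = enumerate_full_space(family, factors)
    reqs = task_requirements(req_key)
    # For the two-factor explicit space the difficulty requirement is on the
    # single "actual" factor already.
    reqs = [r for r in reqs if r.factor in factors]
    out = prune_space(space, reqs)
    out.provenance["task"] = task
    return out


def winning_config(task: str = "implicit") -> ModulationConfig:
    """The selected configuration: A<-I, Se<-Da, Sr<-I (discounted by Dc).

    Defined for the spaces in which it was selected: the implicit linear
    space and the hyperbolic explicit/dissociation spaces.  In the linear
    explicit and dissociation spaces this configuration has no cued-difficulty
    pathway to rest duration and is pruned away.
    """
    if task == "implicit":
        family = "linear"
        flags = {("A", "incentive"), ("Se", "actual"), ("Sr", "incentive")}
    elif task in ("explicit_hyperbolic", "dissociation_hyperbolic"):
        family = "hyperbolic"
        flags = {
            ("A", "incentive"),
            ("Se", "actual"),
            ("Sr", "incentive"),
            ("Sr", "cued"),
        }
    else:
        raise ValueError(
            f"the winning configuration is not a member of the {task!r} space"
        )
    return ModulationConfig(family, frozenset(flags))


def space_to_frame(space: ModelSpace) -> pd.DataFrame:
    """Flag matrix: one row per model, one 0/1 column per parameter-factor flag."""
    rows = []
    for i, config in enumerate(space):
        row: dict = {"model": i, "family": config.family}
        for p in LATENT_PARAMS:
            for f in FACTORS:
                row[f"{p}_{f}"] = int(config.has(p, f))
        rows.append(row)
    return pd.DataFrame(rows)


def load_space_frame(frame: pd.DataFrame) -> ModelSpace:
    """Inverse of :func:`space_to_frame`."""
    configs = []
    for _, row in frame.iterrows():
        flags = frozenset(
            (p, f)
            for p in LATENT_PARAMS
            for f in FACTORS
            if int(row[f"{p}_{f}"]) == 1
        )
        configs.append(ModulationConfig(str(row["family"]), flags))
    return ModelSpace(tuple(configs))
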