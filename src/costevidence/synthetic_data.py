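"""Ground-truth synthetic behavioural datasets for all seven task variants.

Effort-allocation trials (implicit / explicit / dissociation tasks) are
generated by the bounded cost-evidence model: condition-specific effort and
rest durations from the forward model, per-epoch additive Gaussian noise
truncated at a positive floor, alternation cut at the trial length.
Adaptation tasks (1-3) impose first-effort or rest durations on the
tasks' sampling grids and generate the observed free durations from a
chosen saturation model plus white noise.  The cost-rating task crosses
3 incentives x 7 durations x 7 difficulties (147 cells, one trial each)
and generates ratings from a chosen cost model.  Force traces emulate
grip-force time series for preprocessing round-trips.

All generators are pure functions of (design, truth, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from costevidence.adaptation import SaturationModelSpec
from costevidence.core_model import (
    Epoch,
    EpochSequence,
    FactorLevels,
    ModelCoefficients,
    ParamCoefficients,
    compute_latent_params,
    predict_durations,
)
from costevidence.cost_introspection import CostModelSpec
from costevidence.preprocessing import ForceTrace

__all__ = [
    "Design",
    "NoiseSpec",
    "SubjectDataset",
    "TrialRecord",
    "implicit_design",
    "explicit_design",
    "dissociation_design",
    "adaptation_design",
    "cost_rating_design",
    "design_cells",
    "default_true_coefficients",
    "generate_effort_allocation",
    "generate_adaptation",
    "generate_cost_rating",
    "generate_stop_probabilities",
    "generate_force_trace",
    "task2_rest_durations",
    "to_epoch_table",
    "datasets_from_epoch_table",
]


@dataclass(frozen=True)
class Design:
    task: str
    incentives: tuple = ()
    actual_difficulties: tuple = ()
    cued_difficulties: Optional[tuple] = None
    congruent_cues: bool = False  # explicit task: cue equals actual difficulty
    durations: tuple = ()  # cost-rating imposed effort durations
    n_sessions: int = 8
    trials_per_session: int = 9
    trial_length: float = 30.0
    n_imposed: int = 36
    imposed_range: tuple = (1.0, 10.0)


def implicit_design() -> Design:
    """3 incentives x 3 difficulties, 8 sessions of 9 trials, 30-s trials."""
    return Design(
        task="implicit",
        incentives=(0.10, 0.20, 0.50),
        actual_difficulties=(0.70, 0.80, 0.90),
    )


def explicit_design() -> Design:
    """As implicit, with the difficulty level cued (congruently) at trial start."""
    return replace(implicit_design(), task="explicit", congruent_cues=True)


def dissociation_design() -> Design:
    """2 incentives x 2 actual x 2 cued difficulties; cue valid in half the cells."""
    return Design(
        task="dissociation",
        incentives=(0.10, 0.20),
        actual_difficulties=(0.75, 0.85),
        cued_difficulties=(0.75, 0.85),
        trials_per_session=8,
    )


def adaptation_design(task: int) -> Design:
    """Imposed-duration adaptation tasks 1-3 (8 sessions of 9 trials)."""
    if task not in (1, 2, 3):
        raise ValueError("adaptation task must be 1, 2 or 3")
    rng_range = (1.0, 12.5) if task == 2 else (1.0, 10.0)
    return Design(
        task=f"adaptation{task}",
        n_sessions=8,
        trials_per_session=9,
        imposed_range=rng_range,
    )


def cost_rating_design() -> Design:
    """3 incentives x 7 durations x 7 difficulties: 147 cells, one trial each."""
    return Design(
        task="cost_rating",
        incentives=(0.10, 0.20, 0.50),
        actual_difficulties=tuple(np.round(np.linspace(0.40, 0.60, 7), 6)),
        durations=tuple(np.round(np.linspace(3.0, 7.0, 7), 6)),
        n_sessions=7,
        trials_per_session=21,
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes and the master seed for a generated dataset.

    duration_sd: additive sd on each epoch duration in seconds; None means
    20% of the mean model-predicted duration across design cells.
    rating_sd: additive sd on ratings / stop probabilities (scale units).
    floor: lower truncation of noisy epoch durations, seconds.
    between_subject_sd: coefficient jitter as a fraction of each coefficient.
    """

    duration_sd: Optional[float] = None
    rating_sd: float = 0.05
    seed: int = 0
    floor: float = 0.2
    between_subject_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.duration_sd is not None and self.duration_sd < 0:
            raise ValueError("duration_sd must be >= 0")
        if self.rating_sd < 0 or self.between_subject_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if self.floor <= 0:
            raise ValueError("floor must be > 0")


@dataclass(frozen=True)
class TrialRecord:
    session: int
    trial: int
    sequence: EpochSequence


@dataclass
class SubjectDataset:
    subject: int
    task: str
    trials: Optional[list[TrialRecord]] = None
    table: Optional[pd.DataFrame] = None
    truth: object = None  # generating coefficients/spec, kept for recovery tests
    design: Optional[Design] = None


def design_cells(design: Design) -> list[FactorLevels]:
    """The factorial condition cells of an effort-allocation design."""
    cells = []
    if design.cued_difficulties is not None:
        for inc, da, dc in itertools.product(
            design.incentives, design.actual_difficulties, design.cued_difficulties
        ):
            cells.append(FactorLevels(inc, da, dc))
    else:
        for inc, da in itertools.product(design.incentives, design.actual_difficulties):
            dc = da if design.congruent_cues else None
            cells.append(FactorLevels(inc, da, dc))
    return cells


def default_true_coefficients(task: str = "implicit") -> ModelCoefficients:
    """Generating coefficients of the selected model at realistic magnitudes.

    Amplitude rises with incentive, accumulation slope with actual
    difficulty, dissipation slope with incentive (hyperbolically discounted
    by cued difficulty where cues exist); baseline values chosen to yield
    effort epochs of roughly 5-8 s and rest epochs of 3-5 s in a 30-s
    trial, i.e. a handful of alternations as in the grip task.
    """
    if task == "implicit":
        return ModelCoefficients(
            family="linear",
            A=ParamCoefficients(mean=5.0, incentive=5.0),
            Se=ParamCoefficients(mean=0.2, actual=1.0),
            Sr=ParamCoefficients(mean=1.0, incentive=3.0),
        )
    if task in ("explicit", "dissociation"):
        return ModelCoefficients(
            family="hyperbolic",
            A=ParamCoefficients(mean=5.0, incentive=5.0),
            Se=ParamCoefficients(mean=0.2, actual=1.0),
            Sr=ParamCoefficients(mean=1.0, incentive=3.0, discount=2.0),
        )
    raise ValueError(f"unknown task {task!r}")


def default_rating_truth() -> CostModelSpec:
    """Additive cost-rating truth on the [0, 1] scale.

    Difficulty weighs about twice as much as duration, mirroring the
    asymmetry of rated exhaustion; values keep noiseless ratings well
    inside the scale so clipping stays inert.
    """
    return CostModelSpec(
        include_main_effects=True,
        include_interaction=False,
        include_nonlinearity=False,
        beta0=0.1,
        beta1=0.28,
        beta2=0.14,
    )


def default_stop_truth() -> CostModelSpec:
    """Pure-interaction cost truth behind stop probabilities (logit scale)."""
    return CostModelSpec(
        include_main_effects=False,
        include_interaction=True,
        include_nonlinearity=False,
        beta0=-4.0,
        beta3=4.0,
    )


def _jitter_param(c: ParamCoefficients, rng: np.random.Generator, sd: float) -> ParamCoefficients:
    def j(value: float) -> float:
        return value * (1.0 + rng.normal(scale=sd)) if value != 0.0 else 0.0

    return ParamCoefficients(
        mean=j(c.mean),
        incentive=j(c.incentive),
        actual=j(c.actual),
        cued=j(c.cued),
        discount=j(c.discount),
    )


def _jitter_coefficients(
    coeffs: ModelCoefficients,
    cells: Sequence[FactorLevels],
    rng: np.random.Generator,
    sd: float,
    max_tries: int = 200,
) -> ModelCoefficients:
    if sd == 0:
        return coeffs
    for _ in range(max_tries):
        candidate = ModelCoefficients(
            family=coeffs.family,
            A=_jitter_param(coeffs.A, rng, sd),
            Se=_jitter_param(coeffs.Se, rng, sd),
            Sr=_jitter_param(coeffs.Sr, rng, sd),
        )
        try:
            for cell in cells:
                compute_latent_params(candidate, cell)
        except ValueError:
            continue
        return candidate
    raise RuntimeError("could not draw valid subject coefficients; lower the jitter")


def _session_order(
    cells: Sequence[FactorLevels],
    rng: np.random.Generator,
    avoid_repeated_cues: bool,
    previous_last: Optional[FactorLevels],
    max_tries: int = 500,
) -> list[FactorLevels]:
    """Balanced within-session cell order; the dissociation randomisation
    avoids identical (incentive, cued) pairs in consecutive trials."""
    idx = np.arange(len(cells))
    for _ in range(max_tries):
        order = [cells[i] for i in rng.permutation(idx)]
        if not avoid_repeated_cues:
            return order
        seq = ([previous_last] if previous_last is not None else []) + order
        ok = all(
            (a.incentive, a.cued_difficulty) != (b.incentive, b.cued_difficulty)
            for a, b in zip(seq, seq[1:])
        )
        if ok:
            return order
    raise RuntimeError("could not satisfy the consecutive-cue constraint")


def generate_effort_allocation(
    design: Design,
    true_coeffs: ModelCoefficients,
    noise: NoiseSpec,
    n_subjects: int,
) -> list[SubjectDataset]:
    """Simulate free effort/rest alternation for one cohort.

    Per subject, coefficients are jittered around the group truth; per
    trial, condition-specific Te and Tr come from the forward model and
    each realised epoch duration is perturbed by truncated Gaussian noise
    before the alternation is cut at the trial length.
    """
    cells = design_cells(design)
    if true_coeffs.family == "hyperbolic" and cells[0].cued_difficulty is None:
        raise ValueError("hyperbolic coefficients require a design with cues")
    rng = np.random.default_rng(noise.seed)
    preds = [predict_durations(compute_latent_params(true_coeffs, c)) for c in cells]
    mean_duration = float(np.mean([[p.Te, p.Tr] for p in preds]))
    sd = noise.duration_sd if noise.duration_sd is not None else 0.2 * mean_duration
    avoid_repeats = design.task == "dissociation"

    datasets = []
    for subject in range(n_subjects):
        coeffs = _jitter_coefficients(true_coeffs, cells, rng, noise.between_subject_sd)
        trials: list[TrialRecord] = []
        previous_last: Optional[FactorLevels] = None
        for session in range(design.n_sessions):
            order = _session_order(cells, rng, avoid_repeats, previous_last)
            previous_last = order[-1]
            for trial_idx, factors in enumerate(order):
                pred = predict_durations(compute_latent_params(coeffs, factors))
                epochs: list[Epoch] = []
                t, kind = 0.0, "effort"
                while t < design.trial_length:
                    nominal = pred.Te if kind == "effort" else pred.Tr
                    realised = nominal
                    if sd > 0:
                        realised = max(noise.floor, nominal + rng.normal(scale=sd))
                    remaining = design.trial_length - t
                    if realised < remaining:
                        epochs.append(Epoch(kind, realised, truncated=False))
                        t += realised
                    else:
                        epochs.append(Epoch(kind, remaining, truncated=True))
                        t = design.trial_length
                    kind = "rest" if kind == "effort" else "effort"
                trials.append(
                    TrialRecord(
                        session,
                        trial_idx,
                        EpochSequence(tuple(epochs), design.trial_length, factors),
                    )
                )
        datasets.append(
            SubjectDataset(subject, design.task, trials=trials, truth=coeffs, design=design)
        )
    return datasets


def task2_rest_durations(rng: np.random.Generator, n_points: int = 10_000) -> np.ndarray:
    """The 36 imposed rest durations of the variable-rest adaptation task.

    A two-component Gaussian mixture (75% N(3, 2), 25% N(10, 2)) is
    simulated, truncated below 1 s, split into 37 equal-count bins whose
    means provide candidate durations; the last bin is dropped to avoid
    extreme values, leaving 36 durations that over-sample short rests.
    """
    n_short = int(round(0.75 * n_points))
    draws = np.concatenate(
        [rng.normal(3.0, 2.0, n_short), rng.normal(10.0, 2.0, n_points - n_short)]
    )
    draws = np.sort(draws[draws > 1.0])
    bins = np.array_split(draws, 37)
    values = np.array([b.mean() for b in bins])
    return values[:36]


def _task1_session_indices(rng: np.random.Generator) -> list[np.ndarray]:
    """Session assignment balancing mean imposed duration across sessions:
    every 4th point of a randomised 36-sequence, offsets drawn without
    replacement."""
    order = rng.permutation(36)
    offsets = rng.permutation(4)
    return [order[offset::4] for offset in offsets]


def generate_adaptation(
    design: Design,
    saturation_truth: SaturationModelSpec,
    noise: NoiseSpec,
    n_subjects: int,
    rest_truth: Optional[SaturationModelSpec] = None,
) -> list[SubjectDataset]:
    """Simulate imposed-duration trials and the observed free durations.

    Tasks 1 and 3 impose first-effort durations from 36 points equally
    spaced in [1, 10] s; task 2 imposes rest durations from the truncated
    Gaussian-mixture scheme.  Observed free-effort durations (and, for
    task 3, free-rest durations via ``rest_truth``) follow the given
    saturation model plus white noise.
    """
    if design.task not in ("adaptation1", "adaptation2", "adaptation3"):
        raise ValueError(f"not an adaptation design: {design.task!r}")
    task = int(design.task[-1])
    if task == 3 and rest_truth is None:
        raise ValueError("adaptation task 3 needs a rest_truth saturation model")
    rng = np.random.default_rng(noise.seed)
    sd = noise.duration_sd if noise.duration_sd is not None else saturation_truth.residual_sd

    datasets = []
    for subject in range(n_subjects):
        if task == 2:
            imposed_values = task2_rest_durations(rng)
        else:
            imposed_values = np.linspace(*design.imposed_range, design.n_imposed)
        rows = []
        for hand in ("left", "right"):
            # same randomised order for both hands
            if hand == "left":
                session_indices = _task1_session_indices(rng)
            for s, indices in enumerate(session_indices):
                for trial, i in enumerate(indices):
                    x = float(imposed_values[i])
                    y = float(saturation_truth.predict(x))
                    if sd > 0:
                        y = max(0.1, y + rng.normal(scale=sd))
                    row = {
                        "subject": subject,
                        "hand": hand,
                        "session": s,
                        "trial": trial,
                        "imposed_s": x,
                        "observed_effort_s": y,
                    }
                    if task == 3:
                        r = float(rest_truth.predict(x))
                        rest_sd = sd if noise.duration_sd is not None else rest_truth.residual_sd
                        if rest_sd > 0:
                            r = max(0.1, r + rng.normal(scale=rest_sd))
                        row["observed_rest_s"] = r
                    rows.append(row)
        datasets.append(
            SubjectDataset(
                subject,
                design.task,
                table=pd.DataFrame(rows),
                truth=saturation_truth,
                design=design,
            )
        )
    return datasets


def generate_cost_rating(
    design: Design,
    cost_truth: CostModelSpec,
    noise: NoiseSpec,
    n_subjects: int,
) -> list[SubjectDataset]:
    """One rating per factorial cell: cost model at (d, t) plus noise.

    Sessions are exactly balanced in incentive and difficulty (each of the
    21 incentive x difficulty pairs appears once per session) with the 7
    durations rotated across sessions, mirroring the pseudo-randomisation
    of the task.  Ratings live on a [0, 1] scale and are clipped to it.
    """
    rng = np.random.default_rng(noise.seed)
    d_levels = np.asarray(design.actual_difficulties, dtype=float)
    t_levels = np.asarray(design.durations, dtype=float)
    d_mean, t_mean = d_levels.mean(), t_levels.mean()

    datasets = []
    for subject in range(n_subjects):
        truth = cost_truth
        if noise.between_subject_sd > 0:
            truth = replace(
                cost_truth,
                beta0=cost_truth.beta0 * (1 + rng.normal(scale=noise.between_subject_sd))
                if cost_truth.beta0
                else 0.0,
                beta1=cost_truth.beta1 * (1 + rng.normal(scale=noise.between_subject_sd))
                if cost_truth.beta1
                else 0.0,
                beta2=cost_truth.beta2 * (1 + rng.normal(scale=noise.between_subject_sd))
                if cost_truth.beta2
                else 0.0,
                beta3=cost_truth.beta3 * (1 + rng.normal(scale=noise.between_subject_sd))
                if cost_truth.beta3
                else 0.0,
            )
        rows = []
        for session in range(design.n_sessions):
            for inc in design.incentives:
                for diff in d_levels:
                    rows.append({"session": session, "incentive": inc, "difficulty": diff})
        frame = pd.DataFrame(rows)
        # rotate durations across sessions within each incentive x difficulty pair
        durations = np.empty(len(frame))
        for (inc, diff), group in frame.groupby(["incentive", "difficulty"]):
            durations[group.index] = rng.permutation(t_levels)
        frame["duration"] = durations
        cost = truth.evaluate(frame["difficulty"] / d_mean, frame["duration"] / t_mean)
        rating = cost + (
            rng.normal(scale=noise.rating_sd, size=len(frame)) if noise.rating_sd else 0.0
        )
        frame["rating"] = np.clip(rating, 0.0, 1.0)
        frame["trial"] = frame.groupby("session").cumcount()
        datasets.append(
            SubjectDataset(
                subject, design.task, table=frame, truth=truth, design=design
            )
        )
    return datasets


def generate_stop_probabilities(
    cost_truth: CostModelSpec,
    difficulties: Sequence[float],
    duration_grid: Sequence[float],
    noise: NoiseSpec,
    n_subjects: int,
) -> list[pd.DataFrame]:
    """Noisy stop-probability observations from a sigmoid of modelled cost.

    Emulates the per-difficulty stop curves extracted from free-allocation
    behaviour: p = sigmoid(C(d, t)) plus Gaussian noise, clipped to [0, 1].
    """
    rng = np.random.default_rng(noise.seed)
    d = np.asarray(difficulties, dtype=float)
    t = np.asarray(duration_grid, dtype=float)
    dn = d / d.mean()
    tn = t / t.mean()
    out = []
    for _ in range(n_subjects):
        rows = []
        for i, diff in enumerate(d):
            c = cost_truth.evaluate(np.full_like(tn, dn[i]), tn)
            p = 1.0 / (1.0 + np.exp(-c))
            if noise.rating_sd:
                p = p + rng.normal(scale=noise.rating_sd, size=p.size)
            for j, dur in enumerate(t):
                rows.append(
                    {
                        "difficulty": diff,
                        "duration": dur,
                        "p_stop": float(np.clip(p[j], 0.0, 1.0)),
                    }
                )
        out.append(pd.DataFrame(rows))
    return out


def generate_force_trace(
    epochs: EpochSequence,
    sampling_rate: float = 100.0,
    target_force: float = 0.8,
    trace_noise: float = 0.01,
    ramp_s: float = 0.05,
    seed: int = 0,
) -> ForceTrace:
    """Piecewise grip-force trace realising an epoch sequence.

    Force ramps linearly to the target fraction of maximal force at each
    effort onset (over ``ramp_s`` seconds), holds, and ramps back to zero
    at the offset; rest periods sit near zero.  Additive Gaussian trace
    noise emulates transducer jitter.  Forces are clipped at zero.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    rng = np.random.default_rng(seed)
    total = epochs.total_duration if epochs.epochs else 1.0
    time = np.arange(0.0, total, 1.0 / sampling_rate)
    force = np.zeros_like(time)
    t0 = 0.0
    for epoch in epochs.epochs:
        t1 = t0 + epoch.duration
        if epoch.kind == "effort":
            # rise starts at the onset t0; the fall ramp follows the offset
            # t1, spilling into the first ramp_s of the subsequent rest
            up = np.clip((time - t0) / ramp_s, 0.0, 1.0)
            if epoch.truncated:
                down = np.ones_like(time)
            else:
                down = np.clip((t1 + ramp_s - time) / ramp_s, 0.0, 1.0)
            force = np.maximum(force, target_force * np.minimum(up, down))
        t0 = t1
    if trace_noise > 0:
        force = force + rng.normal(scale=trace_noise, size=force.size)
    return ForceTrace(time, np.clip(force, 0.0, None), sampling_rate)


def to_epoch_table(datasets: Sequence[SubjectDataset]) -> pd.DataFrame:
    """Tidy epoch table: one row per epoch with factor levels."""
    rows = []
    for ds in datasets:
        if ds.trials is None:
            raise ValueError(f"subject {ds.subject} has no trial records")
        for rec in ds.trials:
            f = rec.sequence.factors
            for i, epoch in enumerate(rec.sequence.epochs):
                rows.append(
                    {
                        "subject": ds.subject,
                        "session": rec.session,
                        "trial": rec.trial,
                        "epoch_index": i,
                        "kind": epoch.kind,
                        "duration_s": epoch.duration,
                        "truncated": int(epoch.truncated),
                        "incentive": f.incentive if f else np.nan,
                        "actual_difficulty": f.actual_difficulty if f else np.nan,
                        "cued_difficulty": (
                            f.cued_difficulty
                            if f and f.cued_difficulty is not None
                            else np.nan
                        ),
                    }
                )
    return pd.DataFrame(rows)


def datasets_from_epoch_table(table: pd.DataFrame, task: str = "implicit") -> list[SubjectDataset]:
    """Rebuild per-subject trial records from a tidy epoch table."""
    datasets = []
    for subject, sub in table.groupby("subject"):
        trials = []
        for (session, trial), grp in sub.groupby(["session", "trial"]):
            grp = grp.sort_values("epoch_index")
            first = grp.iloc[0]
            cued = first["cued_difficulty"]
            factors = FactorLevels(
                float(first["incentive"]),
                float(first["actual_difficulty"]),
                None if pd.isna(cued) else float(cued),
            )
            epochs = tuple(
                Epoch(str(r.kind), float(r.duration_s), bool(r.truncated))
                for r in grp.itertuples()
            )
            total = sum(e.duration for e in epochs)
            trials.append(
                TrialRecord(
                    int(session), int(trial), EpochSequence(epochs, total, factors)
                )
            )
        datasets.append(SubjectDataset(int(subject), task, trials=trials))
    return datasets
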