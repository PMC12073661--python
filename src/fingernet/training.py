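"""Error backpropagation and the day/dosage training schedule.

One training step on command ``u`` (force-encoded input) with target EFO:

    E    = -(EFO - FO)
    dO   = FO * (1 - FO)           delta_O  = E * dO
    dWO  = outer(HO, delta_O)
    dHO  = HO * (1 - HO)           delta_H  = (WO @ delta_O) * dHO
    dWH  = outer(u, delta_H)
    WO  <- FM * (WO - eta * dWO)
    WH  <- IM * (WH - eta * dWH)

The hidden derivative is the literal surrogate ``HO * (1 - HO)`` — for
inhibitory neurons (negative HO) this is not the calculus derivative of
``NS * sigmoid``; the surrogate is applied as stated by the model
definition (see docs/methods.md).  Biases are fixed; masks are re-applied
on every update so non-connected weights stay exactly zero.

A phase runs ``n_days`` days; day ``d`` performs ``dosage[d]`` repetitions,
cycling deterministically through the task set (the two single-instructed
commands alternate, the force grid cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_FORCE_GRID, NetworkConfig
from .encoding import ExpectedOutput, expected_outputs
from .network import CommandInput, ForwardTrace, NetworkState, forward_pass
from .metrics import dexterity

__all__ = ["GradientSet", "TrainingSchedule", "TrainingHistory", "DivergenceError",
           "build_task_set", "compute_gradients", "apply_updates", "train_phase"]


class DivergenceError(RuntimeError):
    """Raised when the day-averaged error exceeds the divergence ceiling."""


@dataclass
class GradientSet:
    output_error: np.ndarray        # E, (4,)
    output_derivative: np.ndarray   # dO, (4,)
    output_delta: np.ndarray        # delta_O, (4,)
    output_weight_delta: np.ndarray  # dWO, (n_hidden, 4)
    hidden_derivative: np.ndarray   # dHO, (n_hidden,)
    hidden_delta: np.ndarray        # delta_H, (n_hidden,)
    input_weight_delta: np.ndarray  # dWH, (2, n_hidden)


def build_task_set(forces: Sequence[float] = DEFAULT_FORCE_GRID,
                   commands: Sequence[tuple[int, int]] = ((1, -1), (-1, 1))) -> list[CommandInput]:
    """Default task set: single-instructed commands alternating between the
    two fingers, for each force level of the grid."""
    return [CommandInput(commands=c, force=f) for f in forces for c in commands]


@dataclass
class TrainingSchedule:
    """A training phase: day count, per-day dosage, step size and task set."""

    n_days: int
    dosage: tuple[int, ...]
    learning_rate: float
    task_set: list[CommandInput]
    seed: int = 0
    #: abort if the mean |E| over a full day exceeds this ceiling
    divergence_ceiling: float = 10.0
    #: zero-mean normal noise added to the hidden activation each forward
    #: evaluation (robustness analysis); 0 disables
    hidden_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if len(self.dosage) != self.n_days:
            raise ValueError(f"dosage length {len(self.dosage)} != n_days {self.n_days}")
        if any(d < 0 for d in self.dosage):
            raise ValueError("dosage entries must be >= 0")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not self.task_set:
            raise ValueError("task_set must not be empty")

    @classmethod
    def from_config(cls, config: NetworkConfig,
                    forces: Sequence[float] = DEFAULT_FORCE_GRID,
                    commands: Sequence[tuple[int, int]] = ((1, -1), (-1, 1)),
                    learning_rate: Optional[float] = None,
                    seed: int = 0, **kwargs) -> "TrainingSchedule":
        return cls(
            n_days=config.n_days,
            dosage=tuple(config.dosage),
            learning_rate=config.learning_rate if learning_rate is None else learning_rate,
            task_set=build_task_set(forces, commands),
            seed=seed,
            **kwargs,
        )


@dataclass
class TrainingHistory:
    """End-of-day records of one training phase."""

    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = ["phase", "day", "iteration", "command", "force",
                "fo_cst_f1", "fo_rst_f1", "fo_cst_f2", "fo_rst_f2",
                "individuation", "mean_abs_error", "negative_weight_events"]
        return pd.DataFrame(self.records, columns=cols)

    @property
    def final_day_error(self) -> float:
        """Mean |EFO - FO| over the last day with any training repetitions."""
        days = [r["mean_abs_error"] for r in self.records if not np.isnan(r["mean_abs_error"])]
        return days[-1] if days else float("nan")


def compute_gradients(trace: ForwardTrace, expected: ExpectedOutput,
                      state: NetworkState, cmd: CommandInput) -> GradientSet:
    """Backpropagate one trial's error (pre-update weights throughout)."""
    fo, ho = trace.force_output, trace.hidden_output
    err = -(expected.expected_outputs - fo)
    d_o = fo * (1.0 - fo)
    delta_o = err * d_o
    dwo = np.outer(ho, delta_o)
    d_ho = ho * (1.0 - ho)  # literal surrogate, incl. inhibitory units
    delta_h = (state.output_weights @ delta_o) * d_ho
    dwh = np.outer(trace.input_vector, delta_h)
    grads = GradientSet(
        output_error=err, output_derivative=d_o, output_delta=delta_o,
        output_weight_delta=dwo, hidden_derivative=d_ho,
        hidden_delta=delta_h, input_weight_delta=dwh,
    )
    if not (np.isfinite(dwo).all() and np.isfinite(dwh).all()):
        raise FloatingPointError("non-finite gradient; aborting training step")
    return grads


def apply_updates(state: NetworkState, grads: GradientSet,
                  learning_rate: float) -> NetworkState:
    """Masked gradient-descent update, in place.

    The mask multiplies the whole update, so masked-out weights remain
    exactly zero after arbitrarily many steps.  Weights are not clamped to
    stay positive; sign crossings of connected weights are counted on
    ``state.negative_weight_events``.
    """
    masks = state.masks
    new_wo = masks.output_mask * (state.output_weights - learning_rate * grads.output_weight_delta)
    new_wh = masks.input_mask * (state.input_weights - learning_rate * grads.input_weight_delta)
    crossed = ((np.sign(new_wo) != np.sign(state.output_weights)) & (masks.output_mask > 0)).any() \
        or ((np.sign(new_wh) != np.sign(state.input_weights)) & (masks.input_mask > 0)).any()
    if crossed:
        state.negative_weight_events += 1
    state.output_weights = new_wo
    state.input_weights = new_wh
    return state


def train_phase(state: NetworkState, schedule: TrainingSchedule, *,
                phase: str = "train",
                copy: bool = True) -> tuple[NetworkState, TrainingHistory]:
    """Run one full day/dosage phase of gradient-descent training.

    Tasks are drawn in a fixed round-robin over ``schedule.task_set``; an
    end-of-day summary (clean evaluation of every task plus the day's mean
    absolute error) is recorded.  With ``schedule.hidden_noise_sd`` > 0 the
    per-evaluation noise stream is seeded from ``schedule.seed`` so a rerun
    is bit-identical.
    """
    if copy:
        state = state.copy()
    rng = np.random.default_rng(schedule.seed) if schedule.hidden_noise_sd > 0 else None
    noise_sd = schedule.hidden_noise_sd
    tasks = schedule.task_set
    targets = [expected_outputs(t) for t in tasks]
    history = TrainingHistory()
    eta = schedule.learning_rate
    it = 0
    for day, reps in enumerate(schedule.dosage):
        day_abs_err = 0.0
        for r in range(reps):
            k = it % len(tasks)
            trace = forward_pass(state, tasks[k], hidden_noise_sd=noise_sd, rng=rng)
            grads = compute_gradients(trace, targets[k], state, tasks[k])
            apply_updates(state, grads, eta)
            day_abs_err += float(np.abs(grads.output_error).mean())
            it += 1
        mean_err = day_abs_err / reps if reps else float("nan")
        if reps and mean_err > schedule.divergence_ceiling:
            raise DivergenceError(
                f"day {day}: mean |E| = {mean_err:.3g} exceeds ceiling "
                f"{schedule.divergence_ceiling}"
            )
        for t in tasks:
            tr = forward_pass(state, t, hidden_noise_sd=noise_sd, rng=rng)
            rec = dexterity(tr.force_output)
            history.records.append({
                "phase": phase, "day": day, "iteration": it,
                "command": f"{t.commands[0]:+d}/{t.commands[1]:+d}", "force": t.force,
                "fo_cst_f1": tr.force_output[0], "fo_rst_f1": tr.force_output[1],
                "fo_cst_f2": tr.force_output[2], "fo_rst_f2": tr.force_output[3],
                "individuation": rec.individuation,
                "mean_abs_error": mean_err,
                "negative_weight_events": state.negative_weight_events,
            })
    return state, history
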