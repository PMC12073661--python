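"""End-to-end experiment protocols.

Every protocol runs the same three-phase lifecycle:

1. **pre-stroke** — train a randomly initialised healthy network on the
   task set (single-instructed commands alternating between fingers,
   cycling through a force grid) through the full day/dosage schedule;
2. **acute** — apply the lesion and evaluate *without any weight update*
   (the acute deficit is the untrained response of the injured network);
3. **recovery** — retrain the lesioned network with the same schedule but
   a plasticity-scaled learning rate, then evaluate again.

Convergence of the pre-stroke phase depends on the random initial weights;
:func:`pretrain` therefore retries deterministically-derived seeds until
the final-day error passes a convergence threshold, mirroring the need for
"several trials" to obtain a well-converged healthy network.

Reported per-finger forces are the fine-motor forces (0.75 CST + 0.25 RST),
the quantities the individuation index is built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_FORCE_GRID, NetworkConfig
from .lesion import LesionSpec, apply_lesion, scale_plasticity
from .metrics import (RobustnessCell, SlopeFit, WeightChangeReport, compare_to_reference,
                      dexterity, fit_enslaving_slope, weight_change_report)
from .network import CommandInput, NetworkState, forward_pass, init_state, truncated_normal
from .training import TrainingHistory, TrainingSchedule, train_phase

__all__ = ["LifecycleResult", "pretrain", "evaluate_forces", "run_lifecycle",
           "run_force_sweep", "run_severity_sweep", "run_weight_analysis",
           "run_robustness_grid", "ConvergenceError"]

#: default convergence criterion: mean |EFO - FO| over the final training day
CONVERGENCE_THRESHOLD = 0.15
#: stride between deterministically derived restart seeds
_RESTART_STRIDE = 100003


class ConvergenceError(RuntimeError):
    """Raised when no restart seed yields a converged pre-stroke network."""


def evaluate_forces(state: NetworkState, forces: Sequence[float],
                    commands: tuple[int, int] = (1, -1), *,
                    phase: str = "eval",
                    hidden_noise_sd: float = 0.0,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Clean evaluations of one command at each force level (no learning)."""
    rows = []
    for f in forces:
        cmd = CommandInput(commands=commands, force=f)
        tr = forward_pass(state, cmd, hidden_noise_sd=hidden_noise_sd, rng=rng)
        fo = tr.force_output
        rec = dexterity(fo)
        rows.append({
            "phase": phase, "force": f,
            "fo_cst_f1": fo[0], "fo_rst_f1": fo[1], "fo_cst_f2": fo[2], "fo_rst_f2": fo[3],
            "fine_f1": rec.fine_motor[0], "fine_f2": rec.fine_motor[1],
            "gross_f1": rec.gross_force[0], "gross_f2": rec.gross_force[1],
            "individuation": rec.individuation,
        })
    return pd.DataFrame(rows)


def pretrain(config: NetworkConfig, *, seed: int = 0,
             forces: Sequence[float] = DEFAULT_FORCE_GRID,
             commands: Sequence[tuple[int, int]] = ((1, -1), (-1, 1)),
             convergence_threshold: float = CONVERGENCE_THRESHOLD,
             max_restarts: int = 10,
             hidden_noise_sd: float = 0.0,
             wo_noise_sd: float = 0.0) -> tuple[NetworkState, TrainingHistory, int]:
    """Train a healthy network to convergence, restarting on bad seeds.

    Returns ``(state, history, used_seed)``.  Candidate seeds are derived
    deterministically from ``seed``; a run is accepted when the mean
    absolute output error over the final training day falls below
    ``convergence_threshold``.  ``wo_noise_sd`` perturbs the initial
    hidden-to-output weights (robustness analysis) before training.
    """
    last_err = float("nan")
    for attempt in range(max_restarts):
        s = (seed + _RESTART_STRIDE * attempt) % (2 ** 31)
        state = init_state(config, seed=s)
        if wo_noise_sd > 0.0:
            noise_rng = np.random.default_rng((s + 1) % (2 ** 31))
            noise = noise_rng.normal(0.0, wo_noise_sd, size=state.output_weights.shape)
            state.output_weights = (state.output_weights + noise) * state.masks.output_mask
        schedule = TrainingSchedule.from_config(
            config, forces=forces, commands=commands, seed=s,
            hidden_noise_sd=hidden_noise_sd)
        state, history = train_phase(state, schedule, phase="pre_stroke", copy=False)
        last_err = history.final_day_error
        if not np.isfinite(last_err) or last_err < convergence_threshold:
            return state, history, s
    raise ConvergenceError(
        f"no converged pre-stroke network within {max_restarts} restarts of seed "
        f"{seed} (last final-day error {last_err:.3f})")


@dataclass
class LifecycleResult:
    """Snapshots, histories and evaluations of one pre/acute/recovery run."""

    config: NetworkConfig
    lesion: LesionSpec
    seed: int
    used_seed: int
    recovery_learning_rate: float
    pre_state: NetworkState
    lesioned_state: NetworkState
    recovered_state: NetworkState
    histories: dict[str, TrainingHistory]
    evaluations: pd.DataFrame

    def phase_eval(self, phase: str) -> pd.DataFrame:
        return self.evaluations[self.evaluations["phase"] == phase]

    def summary(self, phase: str, force: float = 1.0) -> dict:
        df = self.phase_eval(phase)
        row = df[np.isclose(df["force"], force)].iloc[0]
        return {"instructed": float(row["fine_f1"]),
                "uninstructed": float(row["fine_f2"]),
                "individuation": float(row["individuation"])}


def run_lifecycle(config: NetworkConfig, lesion: LesionSpec, *,
                  seed: int = 0,
                  train_forces: Sequence[float] = DEFAULT_FORCE_GRID,
                  eval_forces: Optional[Sequence[float]] = None,
                  recovery_commands: Sequence[tuple[int, int]] = ((1, -1), (-1, 1)),
                  pre_state: Optional[NetworkState] = None,
                  pre_history: Optional[TrainingHistory] = None,
                  pre_seed: Optional[int] = None,
                  convergence_threshold: float = CONVERGENCE_THRESHOLD,
                  hidden_noise_sd: float = 0.0,
                  wo_noise_sd: float = 0.0) -> LifecycleResult:
    """Full stroke-and-recovery protocol for one lesion condition.

    An already pre-trained healthy state may be passed in (``pre_state``)
    so several lesion conditions can share one pre-stroke training run.
    """
    if eval_forces is None:
        eval_forces = tuple(train_forces)
    if pre_state is None:
        pre_state, pre_history, used_seed = pretrain(
            config, seed=seed, forces=train_forces,
            convergence_threshold=convergence_threshold,
            hidden_noise_sd=hidden_noise_sd, wo_noise_sd=wo_noise_sd)
    else:
        pre_state = pre_state.copy()
        used_seed = pre_state.seed if pre_seed is None else pre_seed
        if pre_history is None:
            pre_history = TrainingHistory()

    noise_rng = (np.random.default_rng((used_seed + 2) % (2 ** 31))
                 if hidden_noise_sd > 0 else None)
    evals = [evaluate_forces(pre_state, eval_forces, phase="pre_stroke",
                             hidden_noise_sd=hidden_noise_sd, rng=noise_rng)]

    lesioned = apply_lesion(pre_state, lesion)
    evals.append(evaluate_forces(lesioned, eval_forces, phase="acute",
                                 hidden_noise_sd=hidden_noise_sd, rng=noise_rng))

    eta = scale_plasticity(config.learning_rate, lesion, config)
    schedule = TrainingSchedule.from_config(
        config, forces=train_forces, commands=recovery_commands,
        learning_rate=eta, seed=(used_seed + 3) % (2 ** 31),
        hidden_noise_sd=hidden_noise_sd)
    recovered, rec_history = train_phase(lesioned, schedule, phase="recovery")
    evals.append(evaluate_forces(recovered, eval_forces, phase="recovery",
                                 hidden_noise_sd=hidden_noise_sd, rng=noise_rng))

    return LifecycleResult(
        config=config, lesion=lesion, seed=seed, used_seed=used_seed,
        recovery_learning_rate=eta,
        pre_state=pre_state, lesioned_state=lesioned, recovered_state=recovered,
        histories={"pre_stroke": pre_history, "recovery": rec_history},
        evaluations=pd.concat(evals, ignore_index=True),
    )


def run_force_sweep(config: NetworkConfig, lesion: LesionSpec, *,
                    forces: Sequence[float] = DEFAULT_FORCE_GRID,
                    seed: int = 0,
                    pre_state: Optional[NetworkState] = None,
                    convergence_threshold: float = CONVERGENCE_THRESHOLD) -> dict[str, SlopeFit]:
    """Enslaving-slope regression per phase over the force grid.

    For each phase (pre-stroke / acute / recovery) the network is evaluated
    at every force target with Finger 1 instructed; the OLS slope of the
    uninstructed Finger 2 force on the instructed Finger 1 force is the
    enslaving slope of that phase.  Returns the fits plus the underlying
    lifecycle as ``fits["lifecycle"]``-free dict (fits only); use
    :func:`run_lifecycle` directly for the full result.
    """
    if len(forces) < 3:
        raise ValueError("need at least 3 force levels to fit a slope")
    life = run_lifecycle(config, lesion, seed=seed, train_forces=forces,
                         eval_forces=forces, pre_state=pre_state,
                         convergence_threshold=convergence_threshold)
    fits: dict[str, SlopeFit] = {}
    for phase in ("pre_stroke", "acute", "recovery"):
        df = life.phase_eval(phase)
        pts = list(zip(df["fine_f1"], df["fine_f2"]))
        fits[phase] = fit_enslaving_slope(pts)
    return fits


def run_severity_sweep(config: NetworkConfig,
                       severities: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
                       seeds: Sequence[int] = (0,), *,
                       train_forces: Sequence[float] = DEFAULT_FORCE_GRID,
                       eval_force: float = 1.0,
                       lesion_seed_offset: int = 5000,
                       convergence_threshold: float = CONVERGENCE_THRESHOLD) -> pd.DataFrame:
    """Acute and recovered dexterity across combined CS+RS lesion severities.

    Each training seed is pre-trained once; every severity is then applied
    to that same healthy network (fixed per-seed lesion seed), retrained,
    and evaluated.  Returns a tidy frame with one row per
    (seed, severity, phase).
    """
    rows = []
    for seed in seeds:
        pre_state, pre_hist, used = pretrain(config, seed=seed, forces=train_forces,
                                             convergence_threshold=convergence_threshold)
        for sev in severities:
            spec = LesionSpec(severity_cs=sev, severity_rs=sev,
                              seed=(seed + lesion_seed_offset) % (2 ** 31))
            life = run_lifecycle(config, spec, seed=seed, train_forces=train_forces,
                                 eval_forces=(eval_force,), pre_state=pre_state,
                                 pre_history=pre_hist)
            for phase in ("pre_stroke", "acute", "recovery"):
                s = life.summary(phase, force=eval_force)
                rows.append({"seed": seed, "severity": sev, "phase": phase, **s})
    return pd.DataFrame(rows)


def run_weight_analysis(config: NetworkConfig, *, seed: int = 0,
                        severity: float = 0.65, force: float = 1.0,
                        pre_state: Optional[NetworkState] = None,
                        lesion_seed: Optional[int] = None,
                        convergence_threshold: float = CONVERGENCE_THRESHOLD
                        ) -> tuple[WeightChangeReport, LifecycleResult]:
    """Synaptic-weight reorganisation in the representative recovery case.

    Pre-stroke training alternates both fingers; recovery training then
    drives only the Finger-1-instructed command (Finger 2 uninstructed), so
    the two fingers' weight changes become antisymmetric — the situation
    the per-pairing paired t-tests summarise.
    """
    spec = LesionSpec(severity_cs=severity, severity_rs=severity,
                      seed=(seed + 6000) % (2 ** 31) if lesion_seed is None else lesion_seed)
    life = run_lifecycle(config, spec, seed=seed, train_forces=(force,),
                         eval_forces=(force,), recovery_commands=((1, -1),),
                         pre_state=pre_state, convergence_threshold=convergence_threshold)
    report = weight_change_report(life.pre_state, life.recovered_state)
    return report, life


def _history_series(life: LifecycleResult) -> np.ndarray:
    """Concatenated per-day evaluation force outputs of all trained phases."""
    frames = [life.histories[p].to_frame() for p in ("pre_stroke", "recovery")]
    df = pd.concat(frames, ignore_index=True)
    cols = ["fo_cst_f1", "fo_rst_f1", "fo_cst_f2", "fo_rst_f2"]
    return df[cols].to_numpy().ravel()


def run_robustness_grid(config: NetworkConfig,
                        wo_noise_levels: Sequence[float],
                        hidden_noise_levels: Sequence[float], *,
                        seed: int = 0, severity: float = 0.65,
                        train_forces: Sequence[float] = (1.0,)) -> pd.DataFrame:
    """Noise-robustness grid against an unperturbed reference lifecycle.

    For every (WO-init noise SD, hidden-activation noise SD) cell the full
    lifecycle is rerun from the same seed with (1) additive zero-mean
    normal noise on the initial hidden-to-output weights and (2) fresh
    additive noise inside every hidden-activation evaluation; the daily
    force-output series is compared with the noise-free reference via
    RMSE, regression coefficient and VAF.
    """
    spec = LesionSpec(severity_cs=severity, severity_rs=severity,
                      seed=(seed + 6000) % (2 ** 31))

    def one(wo_sd: float, hid_sd: float) -> LifecycleResult:
        # no restarts here: the noisy run must stay comparable to the
        # reference, so the reference seed is reused verbatim
        state = init_state(config, seed=seed)
        if wo_sd > 0.0:
            nr = np.random.default_rng((seed + 1) % (2 ** 31))
            state.output_weights = (state.output_weights +
                                    nr.normal(0.0, wo_sd, size=state.output_weights.shape)
                                    ) * state.masks.output_mask
        sched = TrainingSchedule.from_config(config, forces=train_forces, seed=seed,
                                             hidden_noise_sd=hid_sd)
        state, hist = train_phase(state, sched, phase="pre_stroke", copy=False)
        return run_lifecycle(config, spec, seed=seed, train_forces=train_forces,
                             eval_forces=train_forces, pre_state=state,
                             pre_history=hist, hidden_noise_sd=hid_sd)

    reference = _history_series(one(0.0, 0.0))
    rows = []
    for wo_sd in wo_noise_levels:
        for hid_sd in hidden_noise_levels:
            series = _history_series(one(wo_sd, hid_sd))
            cell = compare_to_reference(series, reference,
                                        noise_wo=wo_sd, noise_hidden=hid_sd)
            rows.append({"noise_wo": wo_sd, "noise_hidden": hid_sd,
                         "rmse": cell.rmse,
                         "regression_coefficient": cell.regression_coefficient,
                         "vaf": cell.vaf})
    return pd.DataFrame(rows)
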