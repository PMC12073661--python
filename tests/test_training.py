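"""Backpropagation correctness, masked updates and the training loop."""

import numpy as np
import pytest

from fingernet import (CommandInput, NetworkConfig, TrainingSchedule, apply_updates,
                       build_task_set, compute_gradients, expected_outputs, forward_pass,
                       init_state, train_phase)
from fingernet.encoding import ExpectedOutput
from fingernet.training import DivergenceError


def small_net(seed=0):
    # 10 hidden neurons: 1+1 focal exc, 1+1 focal inh, 2 shared, 4 RS
    return init_state(NetworkConfig().scaled(10), seed=seed)


def loss(state, cmd, efo):
    fo = forward_pass(state, cmd).force_output
    return 0.5 * float(np.sum((efo - fo) ** 2))


def test_zero_error_is_a_fixed_point(toy_state):
    cmd = CommandInput((1, -1), 1.0)
    trace = forward_pass(toy_state, cmd)
    target = expected_outputs(cmd)
    fake = ExpectedOutput(target.scaled_commands, target.enslaving_commands,
                          target.expected_per_finger, trace.force_output.copy())
    grads = compute_gradients(trace, fake, toy_state, cmd)
    assert np.allclose(grads.output_weight_delta, 0)
    assert np.allclose(grads.input_weight_delta, 0)
    before = toy_state.output_weights.copy()
    apply_updates(toy_state, grads, 0.01)
    assert (toy_state.output_weights == before).all()


@pytest.mark.parametrize("seed", [0, 1])
def test_output_gradient_matches_finite_differences(seed):
    """dL/dWO is exact for every unit type (excitatory and inhibitory)."""
    state = small_net(seed)
    cmd = CommandInput((1, -1), 0.75)
    target = expected_outputs(cmd)
    efo = target.expected_outputs
    trace = forward_pass(state, cmd)
    grads = compute_gradients(trace, target, state, cmd)
    h = 1e-6
    fm = state.masks.output_mask
    for j in range(state.n_hidden):
        for k in range(4):
            if fm[j, k] == 0:
                continue
            s1, s2 = state.copy(), state.copy()
            s1.output_weights[j, k] += h
            s2.output_weights[j, k] -= h
            num = (loss(s1, cmd, efo) - loss(s2, cmd, efo)) / (2 * h)
            assert grads.output_weight_delta[j, k] == pytest.approx(num, rel=1e-5, abs=1e-9)


@pytest.mark.parametrize("seed", [0, 1])
def test_input_gradient_oracle(seed):
    """dL/dWH matches finite differences on excitatory paths; on inhibitory
    units the stated surrogate derivative HO*(1-HO) is verified against an
    independent element-wise evaluation of the update formulas."""
    state = small_net(seed)
    cmd = CommandInput((1, -1), 1.0)
    target = expected_outputs(cmd)
    efo = target.expected_outputs
    trace = forward_pass(state, cmd)
    grads = compute_gradients(trace, target, state, cmd)
    h = 1e-6
    ns = state.masks.neuron_status
    for i in range(2):
        for j in range(state.n_hidden):
            if state.masks.input_mask[i, j] == 0:
                continue
            if ns[j] == 1:
                s1, s2 = state.copy(), state.copy()
                s1.input_weights[i, j] += h
                s2.input_weights[i, j] -= h
                num = (loss(s1, cmd, efo) - loss(s2, cmd, efo)) / (2 * h)
                assert grads.input_weight_delta[i, j] == pytest.approx(num, rel=1e-5,
                                                                       abs=1e-9)
            else:
                fo = trace.force_output
                delta_h = sum((-(efo[k] - fo[k])) * fo[k] * (1 - fo[k])
                              * state.output_weights[j, k] for k in range(4))
                delta_h *= trace.hidden_output[j] * (1 - trace.hidden_output[j])
                expect = trace.input_vector[i] * delta_h
                assert grads.input_weight_delta[i, j] == pytest.approx(expect, rel=1e-12)


def test_dead_neuron_contributes_no_gradient():
    state = small_net(2)
    j = 5
    state.masks.neuron_status[j] = 0.0
    cmd = CommandInput((1, -1), 1.0)
    trace = forward_pass(state, cmd)
    grads = compute_gradients(trace, expected_outputs(cmd), state, cmd)
    assert (grads.output_weight_delta[j] == 0).all()
    assert (grads.input_weight_delta[:, j] == 0).all()


@pytest.mark.parametrize("eta", [1e-3, 1e-2])
def test_single_step_descends(eta):
    state = small_net(3)
    cmd = CommandInput((1, -1), 1.0)
    target = expected_outputs(cmd)
    before = loss(state, cmd, target.expected_outputs)
    trace = forward_pass(state, cmd)
    grads = compute_gradients(trace, target, state, cmd)
    apply_updates(state, grads, eta)
    assert loss(state, cmd, target.expected_outputs) < before


def test_masks_conserved_through_training(toy_config):
    state = init_state(toy_config, seed=1)
    schedule = TrainingSchedule.from_config(toy_config, seed=1)
    trained, _ = train_phase(state, schedule)
    assert (trained.input_weights[trained.masks.input_mask == 0] == 0).all()
    assert (trained.output_weights[trained.masks.output_mask == 0] == 0).all()
    # and training actually moved the connected weights
    assert (trained.output_weights != state.output_weights).any()


def test_zero_dosage_changes_nothing(toy_state):
    cfg = toy_state.config
    schedule = TrainingSchedule(n_days=3, dosage=(0, 0, 0), learning_rate=0.01,
                                task_set=build_task_set((1.0,)))
    trained, history = train_phase(toy_state, schedule)
    assert (trained.input_weights == toy_state.input_weights).all()
    assert (trained.output_weights == toy_state.output_weights).all()
    assert np.isnan(history.final_day_error)


def test_training_is_deterministic(toy_config):
    runs = []
    for _ in range(2):
        state = init_state(toy_config, seed=5)
        schedule = TrainingSchedule.from_config(toy_config, seed=5)
        trained, hist = train_phase(state, schedule)
        runs.append((trained, hist.to_frame()))
    a, b = runs
    assert (a[0].input_weights == b[0].input_weights).all()
    assert (a[0].output_weights == b[0].output_weights).all()
    assert a[1].equals(b[1])


def test_halved_rate_doubled_reps_reaches_same_error(toy_config):
    def run(eta, reps_per_day, days):
        state = init_state(toy_config, seed=2)
        schedule = TrainingSchedule(n_days=days, dosage=(reps_per_day,) * days,
                                    learning_rate=eta, task_set=build_task_set((1.0,)))
        _, hist = train_phase(state, schedule)
        return hist.final_day_error

    assert run(0.01, 100, 4) == pytest.approx(run(0.005, 100, 8), abs=0.02)


def test_error_decreases_over_pretraining(toy_config):
    state = init_state(toy_config, seed=3)
    schedule = TrainingSchedule.from_config(toy_config, seed=3)
    _, hist = train_phase(state, schedule)
    df = hist.to_frame().dropna(subset=["mean_abs_error"])
    per_day = df.groupby("day")["mean_abs_error"].first()
    assert per_day.iloc[-1] < per_day.iloc[0]


def test_divergence_guard(toy_config):
    state = init_state(toy_config, seed=0)
    schedule = TrainingSchedule.from_config(toy_config, divergence_ceiling=1e-9)
    with pytest.raises(DivergenceError):
        train_phase(state, schedule)
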