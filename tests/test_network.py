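"""Structure, masks, initialisation and the forward pass."""

import numpy as np
import pytest
from scipy.special import expit as sigmoid

from fingernet import (CommandInput, ConfigError, NetworkConfig, build_layout_and_masks,
                       forward_pass, init_state, make_toy_state)
from fingernet.network import truncated_normal


@pytest.mark.parametrize("n_hidden,expected", [
    (400, {"focal_exc_f1": 40, "focal_exc_f2": 40, "focal_inh_f1": 40,
           "focal_inh_f2": 40, "shared_cs": 80, "rs": 160}),
    (20, {"focal_exc_f1": 2, "focal_exc_f2": 2, "focal_inh_f1": 2,
          "focal_inh_f2": 2, "shared_cs": 4, "rs": 8}),
])
def test_group_sizes_follow_fractions(n_hidden, expected):
    cfg = NetworkConfig().scaled(n_hidden)
    layout, _ = build_layout_and_masks(cfg)
    assert layout.sizes() == expected
    # contiguous blocks cover every index exactly once
    labels = layout.labels
    assert len(labels) == n_hidden and all(l is not None for l in labels)


def test_input_mask_excludes_cross_finger_inhibition():
    cfg = NetworkConfig()
    layout, masks = build_layout_and_masks(cfg)
    im = masks.input_mask
    inh1, inh2 = layout.indices("focal_inh_f1"), layout.indices("focal_inh_f2")
    # finger-1 command reaches everything except finger-2 inhibitory pool
    assert (im[0, inh2] == 0).all() and im[0].sum() == cfg.n_hidden - len(inh2)
    assert (im[1, inh1] == 0).all() and im[1].sum() == cfg.n_hidden - len(inh1)


def test_output_mask_wiring():
    cfg = NetworkConfig()
    layout, masks = build_layout_and_masks(cfg)
    fm = masks.output_mask
    idx = {g: layout.indices(g) for g in layout.slices}
    # finger-1 CST: own focal excitatory + own inhibitory + shared CS only
    cst1 = np.flatnonzero(fm[:, 0])
    assert set(cst1) == set(np.concatenate([idx["focal_exc_f1"], idx["focal_inh_f1"],
                                            idx["shared_cs"]]))
    # finger-1 RST: own inhibitory + RS pool only
    rst1 = np.flatnonzero(fm[:, 1])
    assert set(rst1) == set(np.concatenate([idx["focal_inh_f1"], idx["rs"]]))
    # mirrored for finger 2
    assert set(np.flatnonzero(fm[:, 2])) == set(
        np.concatenate([idx["focal_exc_f2"], idx["focal_inh_f2"], idx["shared_cs"]]))
    assert set(np.flatnonzero(fm[:, 3])) == set(
        np.concatenate([idx["focal_inh_f2"], idx["rs"]]))


def test_neuron_status_signs():
    cfg = NetworkConfig().scaled(20)
    layout, masks = build_layout_and_masks(cfg)
    ns = masks.neuron_status
    inh = np.concatenate([layout.indices("focal_inh_f1"), layout.indices("focal_inh_f2")])
    assert (ns[inh] == -1).all()
    exc = np.setdiff1d(np.arange(20), inh)
    assert (ns[exc] == 1).all()


def test_init_masks_zero_and_deterministic():
    cfg = NetworkConfig().scaled(40)
    a = init_state(cfg, seed=3)
    b = init_state(cfg, seed=3)
    assert (a.input_weights == b.input_weights).all()
    assert (a.output_weights == b.output_weights).all()
    assert (a.hidden_bias == b.hidden_bias).all()
    # masked-out entries are exactly zero, connected entries strictly inside (0,1)
    assert (a.input_weights[a.masks.input_mask == 0] == 0).all()
    assert (a.output_weights[a.masks.output_mask == 0] == 0).all()
    conn = a.output_weights[a.masks.output_mask == 1]
    assert ((conn > 0) & (conn < 1)).all()
    c = init_state(cfg, seed=4)
    assert (a.input_weights != c.input_weights).any()


def test_truncated_normal_moments(rng):
    from scipy import stats
    draws = truncated_normal(rng, 100_000)
    assert ((draws > 0) & (draws < 1)).all()
    assert abs(draws.mean() - 0.5) < 0.02
    # rejection sampling must match the analytic truncated-normal variance
    sd = np.sqrt(1.0 / 12.0)
    ref = stats.truncnorm((0 - 0.5) / sd, (1 - 0.5) / sd, loc=0.5, scale=sd)
    assert abs(draws.var() - ref.var()) < 0.002


def test_bias_scaling():
    cfg = NetworkConfig().scaled(400)
    s = init_state(cfg, seed=0)
    assert ((s.hidden_bias > -6) & (s.hidden_bias < 0)).all()
    assert ((s.output_bias > -1) & (s.output_bias < 0)).all()


def test_forward_closed_forms(toy_state):
    s = toy_state
    # silence the input weights: every neuron sees only its bias
    s.input_weights[:] = 0.0
    s.hidden_bias[:] = -6.0
    tr = forward_pass(s, CommandInput((1, -1), 1.0))
    exc = s.masks.neuron_status == 1
    assert np.allclose(tr.hidden_output[exc], sigmoid(-6.0))
    assert np.allclose(sigmoid(-6.0), 0.002473, atol=1e-6)
    # inhibitory neuron at zero pre-activation emits exactly -0.5
    inh = np.flatnonzero(s.masks.neuron_status == -1)[0]
    s.hidden_bias[inh] = 0.0
    tr = forward_pass(s, CommandInput((1, -1), 1.0))
    assert tr.hidden_output[inh] == -0.5
    # a dead neuron is silent whatever its input
    s.masks.neuron_status[inh] = 0.0
    tr = forward_pass(s, CommandInput((1, -1), 1.0))
    assert tr.hidden_output[inh] == 0.0


def test_force_outputs_strictly_in_unit_interval(toy_state):
    for commands in [(1, -1), (-1, 1), (1, 1), (-1, -1)]:
        for force in (0.01, 0.4, 1.0):
            fo = forward_pass(toy_state, CommandInput(commands, force)).force_output
            assert fo.shape == (4,)
            assert ((fo > 0) & (fo < 1)).all()


def test_command_validation():
    with pytest.raises(ValueError, match="illegal"):
        CommandInput((1, -1), 0.0)
    with pytest.raises(ValueError):
        CommandInput((1, -1), 1.5)
    with pytest.raises(ValueError):
        CommandInput((1, 0), 1.0)


def test_config_validation_errors():
    with pytest.raises(ConfigError, match="sum to 1.0"):
        NetworkConfig(frac_rs=0.3)
    with pytest.raises(ConfigError, match="even"):
        NetworkConfig().scaled(5)  # focal groups of 1 cannot split across fingers
    with pytest.raises(ConfigError, match="integer group size"):
        NetworkConfig().scaled(42)  # 0.2 * 42 = 8.4
    with pytest.raises(ConfigError, match="dosage length"):
        NetworkConfig(n_days=10)
    with pytest.raises(ConfigError, match="learning_rate"):
        NetworkConfig(learning_rate=0.0)


def test_toy_state_shares_construction_path():
    s = make_toy_state(20, seed=0)
    assert s.layout.sizes()["rs"] == 8
    assert (s.input_weights[s.masks.input_mask == 0] == 0).all()
    assert s.config.n_hidden == 20
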