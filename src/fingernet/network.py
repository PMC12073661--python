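"""Network structure and feedforward pass.

The hidden layer is partitioned into six clusters, laid out as contiguous
index blocks in a fixed order:

========================  ==============================================
group                     role
========================  ==============================================
``focal_exc_f1/_f2``      excitatory CS neurons dedicated to one finger
``focal_inh_f1/_f2``      "inhibitory" CS neurons (pyramidal cells that
                          recruit inhibitory spinal interneurons; their
                          output enters the sum with a negative sign)
``shared_cs``             excitatory CS neurons driving both CST outputs
``rs``                    reticulospinal pool driving both RST outputs
========================  ==============================================

Connectivity is enforced by binary masks: the input mask ``IM`` removes
the connection from each finger's command to the *other* finger's
inhibitory cluster, and the output mask ``FM`` wires finger-k CST to
(focal_exc_k, focal_inh_k, shared_cs) and finger-k RST to (focal_inh_k,
rs).  A per-neuron status ``NS`` is +1 for healthy excitatory, -1 for
healthy inhibitory, and 0 for neurons killed by a lesion.

A forward pass computes, for command input ``u`` (force-encoded, see
:meth:`CommandInput.input_vector`)::

    x_h = u @ WH + BH          HO = NS * sigmoid(x_h)
    x_o = HO @ WO + BO         FO = sigmoid(x_o)

Force outputs ``FO`` are ordered (F1-CST, F1-RST, F2-CST, F2-RST) and lie
strictly in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit as sigmoid

from .config import NetworkConfig

__all__ = [
    "GROUPS",
    "GroupLayout",
    "MaskSet",
    "NetworkState",
    "CommandInput",
    "ForwardTrace",
    "build_layout_and_masks",
    "init_state",
    "forward_pass",
    "make_toy_state",
    "truncated_normal",
]

#: Fixed block order of the hidden-layer clusters.
GROUPS = ("focal_exc_f1", "focal_exc_f2", "focal_inh_f1", "focal_inh_f2", "shared_cs", "rs")

#: Output channel names, index-aligned with FO.
OUTPUTS = ("f1_cst", "f1_rst", "f2_cst", "f2_rst")


@dataclass(frozen=True)
class GroupLayout:
    """Assignment of hidden-neuron indices to clusters (contiguous blocks)."""

    n_hidden: int
    slices: dict[str, slice]

    def indices(self, group: str) -> np.ndarray:
        s = self.slices[group]
        return np.arange(s.start, s.stop)

    @property
    def labels(self) -> np.ndarray:
        out = np.empty(self.n_hidden, dtype=object)
        for g, s in self.slices.items():
            out[s] = g
        return out

    def sizes(self) -> dict[str, int]:
        return {g: s.stop - s.start for g, s in self.slices.items()}

    @property
    def cs_groups(self) -> tuple[str, ...]:
        return GROUPS[:5]

    @property
    def inhibitory_groups(self) -> tuple[str, ...]:
        return ("focal_inh_f1", "focal_inh_f2")


@dataclass
class MaskSet:
    """Binary connectivity masks and the neuron-status vector."""

    input_mask: np.ndarray    # (n_inputs, n_hidden), {0,1}
    output_mask: np.ndarray   # (n_hidden, n_outputs), {0,1}
    neuron_status: np.ndarray  # (n_hidden,), {-1, 0, +1}

    def copy(self) -> "MaskSet":
        return MaskSet(self.input_mask.copy(), self.output_mask.copy(),
                       self.neuron_status.copy())


@dataclass
class NetworkState:
    """Full mutable state of the network: weights, biases, masks, layout."""

    input_weights: np.ndarray   # WH, (n_inputs, n_hidden)
    output_weights: np.ndarray  # WO, (n_hidden, n_outputs)
    hidden_bias: np.ndarray     # BH, (n_hidden,)
    output_bias: np.ndarray     # BO, (n_outputs,)
    masks: MaskSet
    layout: GroupLayout
    config: NetworkConfig
    seed: int
    #: number of update steps in which a connected weight crossed zero
    negative_weight_events: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(
            input_weights=self.input_weights.copy(),
            output_weights=self.output_weights.copy(),
            hidden_bias=self.hidden_bias.copy(),
            output_bias=self.output_bias.copy(),
            masks=self.masks.copy(),
            layout=self.layout,
            config=self.config,
            seed=self.seed,
            negative_weight_events=self.negative_weight_events,
        )

    @property
    def n_hidden(self) -> int:
        return self.layout.n_hidden

    def alive(self) -> np.ndarray:
        """Boolean mask of neurons not killed by a lesion."""
        return self.masks.neuron_status != 0

    def dead_fraction(self) -> float:
        return float(np.mean(~self.alive()))


@dataclass(frozen=True)
class CommandInput:
    """One movement command: per-finger instructed(+1)/uninstructed(-1), plus force.

    ``force`` is the demanded force of the instructed finger(s) as a
    fraction of maximum, in (0, 1]; zero is illegal (no movement can be
    commanded with zero force).  The force is *encoded into the command*:
    the input-layer value of an instructed finger is ``force`` itself,
    while an uninstructed finger contributes -1.
    """

    commands: tuple[int, int]
    force: float = 1.0

    def __post_init__(self) -> None:
        if len(self.commands) != 2 or any(c not in (1, -1) for c in self.commands):
            raise ValueError(f"commands must be a pair of +1/-1, got {self.commands!r}")
        if not (0.0 < self.force <= 1.0):
            raise ValueError(
                f"force must lie in (0, 1]; got {self.force!r} (0 is an illegal value)"
            )

    @property
    def cmd(self) -> np.ndarray:
        """Binary command vector in {+1, -1} (drives the target computation)."""
        return np.asarray(self.commands, dtype=float)

    def input_vector(self) -> np.ndarray:
        """Force-encoded input-layer vector: force where instructed, -1 otherwise."""
        return np.where(self.cmd > 0, self.force, -1.0)


@dataclass
class ForwardTrace:
    """All intermediates of one forward pass (kept for backpropagation)."""

    input_vector: np.ndarray        # u, (n_inputs,)
    hidden_preactivation: np.ndarray  # x_h, (n_hidden,)
    hidden_output: np.ndarray       # HO, (n_hidden,)
    output_preactivation: np.ndarray  # x_o, (n_outputs,)
    force_output: np.ndarray        # FO, (n_outputs,)


def build_layout_and_masks(config: NetworkConfig) -> tuple[GroupLayout, MaskSet]:
    """Partition the hidden layer and build IM/FM/NS.

    Blocks are contiguous in the order ``GROUPS``; any permutation would be
    mathematically equivalent, contiguity is chosen for testability.
    """
    n = config.n_hidden
    sizes = [
        config.n_focal_exc_per_finger,
        config.n_focal_exc_per_finger,
        config.n_focal_inh_per_finger,
        config.n_focal_inh_per_finger,
        config.n_shared_cs,
        config.n_rs,
    ]
    if sum(sizes) != n:
        raise ValueError(
            f"group sizes {sizes} do not sum to n_hidden={n}; check fractions"
        )
    slices: dict[str, slice] = {}
    start = 0
    for g, sz in zip(GROUPS, sizes):
        slices[g] = slice(start, start + sz)
        start += sz
    layout = GroupLayout(n_hidden=n, slices=slices)

    im = np.ones((config.n_inputs, n))
    # a finger's command does not reach the other finger's inhibitory pool
    im[0, slices["focal_inh_f2"]] = 0.0
    im[1, slices["focal_inh_f1"]] = 0.0

    fm = np.zeros((n, config.n_outputs))
    fm[slices["focal_exc_f1"], 0] = 1.0
    fm[slices["focal_inh_f1"], 0] = 1.0
    fm[slices["shared_cs"], 0] = 1.0
    fm[slices["focal_inh_f1"], 1] = 1.0
    fm[slices["rs"], 1] = 1.0
    fm[slices["focal_exc_f2"], 2] = 1.0
    fm[slices["focal_inh_f2"], 2] = 1.0
    fm[slices["shared_cs"], 2] = 1.0
    fm[slices["focal_inh_f2"], 3] = 1.0
    fm[slices["rs"], 3] = 1.0

    ns = np.ones(n)
    ns[slices["focal_inh_f1"]] = -1.0
    ns[slices["focal_inh_f2"]] = -1.0

    return layout, MaskSet(input_mask=im, output_mask=fm, neuron_status=ns)


def truncated_normal(rng: np.random.Generator, shape, mean: float = 0.5,
                     variance: float = 1.0 / 12.0) -> np.ndarray:
    """Sample normal(mean, variance) restricted to the open interval (0, 1).

    Rejection sampling preserves both the stated distribution and the
    stated support exactly.
    """
    sd = float(np.sqrt(variance))
    out = rng.normal(mean, sd, size=shape)
    bad = (out <= 0.0) | (out >= 1.0)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out <= 0.0) | (out >= 1.0)
    return out


def init_state(config: NetworkConfig, layout: Optional[GroupLayout] = None,
               masks: Optional[MaskSet] = None, seed: Optional[int] = None) -> NetworkState:
    """Create a randomly initialised healthy network.

    Weights are truncated-normal(mean, variance) on (0, 1), then multiplied
    elementwise by the connectivity masks (non-connected weights are exactly
    zero).  Per-neuron biases are drawn from the same distribution and scaled
    by the bias constants, so each neuron gets a distinct activation
    threshold in (hidden_bias_value, 0).  The same seed reproduces the state
    bit-for-bit.
    """
    if layout is None or masks is None:
        layout, masks = build_layout_and_masks(config)
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    m, v = config.weight_init_mean, config.weight_init_variance
    wh = truncated_normal(rng, (config.n_inputs, config.n_hidden), m, v) * masks.input_mask
    wo = truncated_normal(rng, (config.n_hidden, config.n_outputs), m, v) * masks.output_mask
    bh = config.hidden_bias_value * truncated_normal(rng, config.n_hidden, m, v)
    bo = config.output_bias_value * truncated_normal(rng, config.n_outputs, m, v)
    return NetworkState(
        input_weights=wh, output_weights=wo, hidden_bias=bh, output_bias=bo,
        masks=masks.copy(), layout=layout, config=config, seed=seed,
    )


def forward_pass(state: NetworkState, cmd: CommandInput, *,
                 hidden_noise_sd: float = 0.0,
                 rng: Optional[np.random.Generator] = None) -> ForwardTrace:
    """Run one feedforward evaluation.

    ``hidden_noise_sd`` > 0 adds zero-mean normal noise to the hidden
    sigmoid output (before the status sign is applied), drawn fresh from
    ``rng`` on every call; used by the robustness analysis.
    """
    u = cmd.input_vector()
    if u.shape[0] != state.input_weights.shape[0]:
        raise ValueError("command dimension does not match network inputs")
    x_h = u @ state.input_weights + state.hidden_bias
    act = sigmoid(x_h)
    if hidden_noise_sd > 0.0:
        if rng is None:
            raise ValueError("hidden_noise_sd > 0 requires an rng")
        act = act + rng.normal(0.0, hidden_noise_sd, size=act.shape)
    ho = state.masks.neuron_status * act
    x_o = ho @ state.output_weights + state.output_bias
    fo = sigmoid(x_o)
    return ForwardTrace(input_vector=u, hidden_preactivation=x_h, hidden_output=ho,
                        output_preactivation=x_o, force_output=fo)


def make_toy_state(n_hidden: int = 20, seed: int = 0, **config_overrides) -> NetworkState:
    """A miniature but fully valid network for fast unit tests.

    Uses the same construction path as :func:`init_state`; ``n_hidden``
    must be compatible with the group fractions (multiples of 10 work for
    the defaults).
    """
    cfg = NetworkConfig(seed=seed).scaled(n_hidden, **config_overrides)
    return init_state(cfg, seed=seed)
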