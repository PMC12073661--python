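"""Simulated stroke lesions and post-lesion plasticity scaling.

A lesion permanently silences a fraction of each hidden-layer cluster by
setting the neuron-status variable to 0 (weights are untouched — the
deficit is expressed purely through the missing activations).  Every CS
cluster (both focal excitatory, both focal inhibitory, shared CS) loses
the same fraction ``severity_cs`` of its neurons; the RS pool loses
``severity_rs``.  Counts are exact per cluster (round half up), with the
dead neurons chosen uniformly at random from the cluster under the lesion
seed, which is independent of any training seed so the lesion geometry can
be held fixed across training replicates.

Post-stroke plasticity is reduced in proportion to the overall lesioned
fraction of the hidden layer; the default rule is linear,
``eta' = eta * (1 - overall_severity)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .config import NetworkConfig
from .network import NetworkState

__all__ = ["LesionSpec", "apply_lesion", "scale_plasticity", "overall_severity",
           "PLASTICITY_RULES"]

CS_GROUPS = ("focal_exc_f1", "focal_exc_f2", "focal_inh_f1", "focal_inh_f2", "shared_cs")


@dataclass(frozen=True)
class LesionSpec:
    """Severity of a simulated stroke in the CS and/or RS regions."""

    severity_cs: float = 0.0
    severity_rs: float = 0.0
    seed: int = 0
    plasticity_rule: str = "linear"

    def __post_init__(self) -> None:
        for name, s in (("severity_cs", self.severity_cs), ("severity_rs", self.severity_rs)):
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {s}")
        if self.plasticity_rule not in PLASTICITY_RULES:
            raise ValueError(f"unknown plasticity rule {self.plasticity_rule!r}; "
                             f"available: {sorted(PLASTICITY_RULES)}")

    @property
    def affected_groups(self) -> tuple[str, ...]:
        groups: tuple[str, ...] = ()
        if self.severity_cs > 0:
            groups += CS_GROUPS
        if self.severity_rs > 0:
            groups += ("rs",)
        return groups


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def apply_lesion(state: NetworkState, spec: LesionSpec) -> NetworkState:
    """Return a lesioned copy of ``state``.

    Within each cluster exactly ``round(severity * cluster size)`` neurons
    are switched to status 0, sampled uniformly without replacement.  A
    request exceeding the number of still-alive neurons in a cluster is
    clipped with a warning (relevant only for repeated lesioning).
    """
    new = state.copy()
    rng = np.random.default_rng(spec.seed)
    ns = new.masks.neuron_status
    for group in ("focal_exc_f1", "focal_exc_f2", "focal_inh_f1", "focal_inh_f2",
                  "shared_cs", "rs"):
        severity = spec.severity_rs if group == "rs" else spec.severity_cs
        idx = new.layout.indices(group)
        k = _round_half_up(severity * len(idx))
        alive = idx[ns[idx] != 0]
        if k > len(alive):
            warnings.warn(
                f"lesion of {group}: requested {k} dead neurons but only "
                f"{len(alive)} alive; clipping", stacklevel=2)
            k = len(alive)
        if k:
            dead = rng.choice(alive, size=k, replace=False)
            ns[dead] = 0.0
    return new


def overall_severity(spec: LesionSpec, config: NetworkConfig) -> float:
    """Lesioned fraction of the whole hidden layer implied by a spec."""
    return spec.severity_cs * config.frac_cs_total + spec.severity_rs * config.frac_rs


def _linear_rule(eta: float, sev: float) -> float:
    return eta * (1.0 - sev)


PLASTICITY_RULES: dict[str, Callable[[float, float], float]] = {
    "linear": _linear_rule,
    "none": lambda eta, sev: eta,
}


def scale_plasticity(learning_rate: float, spec: LesionSpec,
                     config: NetworkConfig) -> float:
    """Post-lesion learning rate under the spec's plasticity rule.

    The model states only that learning capability decreases with lesion
    severity; the functional form is a modelling choice, linear by default
    and pluggable through ``LesionSpec.plasticity_rule``.
    """
    if learning_rate <= 0:
        raise ValueError("learning_rate must be > 0")
    sev = overall_severity(spec, config)
    eta = PLASTICITY_RULES[spec.plasticity_rule](learning_rate, sev)
    return max(eta, 0.0)
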