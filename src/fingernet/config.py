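"""Structural and schedule configuration for the clustered CS/RS network.

The network is a three-layer feedforward model of two-finger control: a
premotor command layer (2 inputs), a hidden layer of corticospinal (CS) and
reticulospinal (RS) neurons, and 4 force outputs (CST and RST per finger).
:class:`NetworkConfig` carries every structural constant (layer sizes,
neuron-group proportions, bias scales) and every training constant
(learning rate, day/dosage schedule, weight-initialisation moments).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import yaml

__all__ = ["NetworkConfig", "ConfigError", "default_dosage", "load_config", "save_config"]

#: Force levels used by default for training and for force-sweep evaluation.
DEFAULT_FORCE_GRID = (0.4, 0.5, 0.75, 1.0)


class ConfigError(ValueError):
    """Raised when a configuration violates a structural invariant."""


def default_dosage(n_days: int = 360) -> tuple[int, ...]:
    """Default daily-repetition schedule: low / high / low / rest.

    The pattern is 50 reps/day, then 200, then 50, then 0, in four equal
    blocks spanning ``n_days``.  Remainder days (when ``n_days`` is not
    divisible by 4) are appended to the final rest block.
    """
    q = n_days // 4
    rest = n_days - 3 * q
    return (50,) * q + (200,) * q + (50,) * q + (0,) * rest


@dataclass(frozen=True)
class NetworkConfig:
    """All structural and schedule parameters of the simulator.

    Parameters
    ----------
    n_hidden
        Number of hidden-layer neurons (CS + RS pools).
    n_inputs, n_outputs
        Fixed at 2 command inputs and 4 force outputs (CST/RST x 2 fingers).
    frac_focal_excitatory, frac_focal_inhibitory
        Fractions of the hidden layer given to focal CS neurons; each is
        split equally between the two fingers.
    frac_shared_cs, frac_rs
        Fractions for the shared excitatory CS pool and the RS pool.
    hidden_bias_value, output_bias_value
        Bias *scale* constants.  Per-neuron biases are drawn like the
        weights (truncated normal on (0, 1)) and multiplied by these
        scales, giving each neuron a distinct activation threshold.
    learning_rate
        Gradient-descent step size (eta).
    n_days, dosage
        Length of a training phase in days and the per-day repetition
        counts.  ``dosage`` must have exactly ``n_days`` entries.
    weight_init_mean, weight_init_variance
        Moments of the truncated-normal weight initialiser on (0, 1).
    seed
        Default seed for weight/bias initialisation.
    """

    n_hidden: int = 400
    n_inputs: int = 2
    n_outputs: int = 4
    frac_focal_excitatory: float = 0.20
    frac_focal_inhibitory: float = 0.20
    frac_shared_cs: float = 0.20
    frac_rs: float = 0.40
    hidden_bias_value: float = -6.0
    output_bias_value: float = -1.0
    learning_rate: float = 0.01
    n_days: int = 360
    dosage: tuple[int, ...] = field(default_factory=default_dosage)
    weight_init_mean: float = 0.5
    weight_init_variance: float = 1.0 / 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # ---- derived sizes -------------------------------------------------
    @property
    def n_focal_exc_per_finger(self) -> int:
        return int(round(self.frac_focal_excitatory * self.n_hidden)) // 2

    @property
    def n_focal_inh_per_finger(self) -> int:
        return int(round(self.frac_focal_inhibitory * self.n_hidden)) // 2

    @property
    def n_shared_cs(self) -> int:
        return int(round(self.frac_shared_cs * self.n_hidden))

    @property
    def n_rs(self) -> int:
        return int(round(self.frac_rs * self.n_hidden))

    @property
    def frac_cs_total(self) -> float:
        """Fraction of hidden neurons belonging to any CS pool."""
        return self.frac_focal_excitatory + self.frac_focal_inhibitory + self.frac_shared_cs

    def validate(self) -> None:
        fracs = {
            "frac_focal_excitatory": self.frac_focal_excitatory,
            "frac_focal_inhibitory": self.frac_focal_inhibitory,
            "frac_shared_cs": self.frac_shared_cs,
            "frac_rs": self.frac_rs,
        }
        total = sum(fracs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"neuron-group fractions must sum to 1.0, got {total!r} from "
                + ", ".join(f"{k}={v}" for k, v in fracs.items())
            )
        if self.n_inputs != 2:
            raise ConfigError(f"n_inputs must be 2 (one command per finger), got {self.n_inputs}")
        if self.n_outputs != 4:
            raise ConfigError(f"n_outputs must be 4 (CST/RST per finger), got {self.n_outputs}")
        if self.n_hidden <= 0:
            raise ConfigError("n_hidden must be positive")
        for name, frac in fracs.items():
            size = frac * self.n_hidden
            if abs(size - round(size)) > 1e-9:
                raise ConfigError(
                    f"{name} x n_hidden = {size} is not an integer group size"
                )
        for name in ("frac_focal_excitatory", "frac_focal_inhibitory"):
            size = round(fracs[name] * self.n_hidden)
            if size % 2:
                raise ConfigError(
                    f"{name} x n_hidden = {size} must be even (split across two fingers)"
                )
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if len(self.dosage) != self.n_days:
            raise ConfigError(
                f"dosage length {len(self.dosage)} != n_days {self.n_days}"
            )
        if any(d < 0 for d in self.dosage):
            raise ConfigError("dosage entries must be >= 0")
        if self.weight_init_variance <= 0:
            raise ConfigError("weight_init_variance must be > 0")

    # ---- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["dosage"] = list(self.dosage)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "dosage" in data and data["dosage"] is not None:
            data["dosage"] = tuple(int(x) for x in data["dosage"])
        return cls(**data)

    def scaled(self, n_hidden: int, **overrides) -> "NetworkConfig":
        """Return a copy with a different hidden-layer size (same fractions)."""
        return replace(self, n_hidden=n_hidden, **overrides)


def load_config(path: str | Path) -> NetworkConfig:
    """Load a :class:`NetworkConfig` from a YAML (or JSON) file.

    Keys mirror the dataclass field names exactly; unknown keys are
    rejected with an explicit error.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return NetworkConfig.from_dict(data)


def save_config(config: NetworkConfig, path: str | Path) -> None:
    """Write a config as YAML; round-trips losslessly through load_config."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
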