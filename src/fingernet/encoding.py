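"""Target (expected-output) encoding of a movement command.

Given the binary command pair CMD in {+1, -1}^2 and force FRC in (0, 1],
the expected per-finger output is

    sCMD = (1 + CMD) / 2                       # {+1 -> 1, -1 -> 0}
    eCMD = max(sCMD) - sCMD                    # enslaving indicator
    EO   = FRC * sCMD + 0.06 * FRC * eCMD + 0.02 * eCMD

so an instructed finger is expected to produce exactly FRC, while an
uninstructed finger is expected to produce the *enslaving* force
0.06*FRC + 0.02 — the small involuntary force healthy hands show when the
other finger presses.  The four-channel target duplicates each finger's EO
onto its CST and RST outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import CommandInput

__all__ = ["ExpectedOutput", "scale_commands", "enslaving_commands", "expected_outputs",
           "ENSLAVING_SLOPE", "ENSLAVING_INTERCEPT"]

ENSLAVING_SLOPE = 0.06
ENSLAVING_INTERCEPT = 0.02


@dataclass(frozen=True)
class ExpectedOutput:
    scaled_commands: np.ndarray      # sCMD, (2,) in {0,1}
    enslaving_commands: np.ndarray   # eCMD, (2,) in {0,1}
    expected_per_finger: np.ndarray  # EO, (2,) in [0,1]
    expected_outputs: np.ndarray     # EFO, (4,) = (EO1, EO1, EO2, EO2)


def scale_commands(cmd: np.ndarray) -> np.ndarray:
    """Map the +1/-1 command pair to {1, 0}: sCMD = (1 + CMD) / 2."""
    cmd = np.asarray(cmd, dtype=float)
    if not np.isin(cmd, (1.0, -1.0)).all():
        raise ValueError(f"command entries must be +1 or -1, got {cmd!r}")
    return (1.0 + cmd) / 2.0


def enslaving_commands(scaled: np.ndarray) -> np.ndarray:
    """eCMD = max(sCMD) - sCMD: 1 exactly for an uninstructed finger while
    the other finger is instructed; 0 everywhere else."""
    scaled = np.asarray(scaled, dtype=float)
    return scaled.max() - scaled


def expected_outputs(cmd: CommandInput) -> ExpectedOutput:
    """Expected per-finger and per-channel outputs for one command."""
    scmd = scale_commands(cmd.cmd)
    ecmd = enslaving_commands(scmd)
    frc = cmd.force
    eo = frc * scmd + ENSLAVING_SLOPE * frc * ecmd + ENSLAVING_INTERCEPT * ecmd
    efo = np.repeat(eo, 2)
    return ExpectedOutput(scaled_commands=scmd, enslaving_commands=ecmd,
                          expected_per_finger=eo, expected_outputs=efo)
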