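"""Lossless network-state snapshots.

A snapshot is a single JSON document holding the config, the group layout,
all weight/bias matrices, masks and neuron status, the originating RNG
seed, and a SHA-256 checksum of the numeric payload.  JSON round-trips
Python floats exactly (shortest-repr), so load(save(state)) reproduces the
state bit-for-bit; a tampered payload fails the checksum and is refused.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .config import NetworkConfig
from .network import GroupLayout, MaskSet, NetworkState, build_layout_and_masks

__all__ = ["save_state", "load_state", "SnapshotError", "FORMAT_VERSION"]

FORMAT_VERSION = 1

_ARRAYS = ("input_weights", "output_weights", "hidden_bias", "output_bias",
           "input_mask", "output_mask", "neuron_status")


class SnapshotError(RuntimeError):
    """Version mismatch or checksum failure on load."""


def _payload(doc: dict) -> str:
    return json.dumps({k: doc[k] for k in _ARRAYS}, sort_keys=True)


def save_state(state: NetworkState, path: str | Path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "config": state.config.to_dict(),
        "seed": state.seed,
        "negative_weight_events": state.negative_weight_events,
        "input_weights": state.input_weights.tolist(),
        "output_weights": state.output_weights.tolist(),
        "hidden_bias": state.hidden_bias.tolist(),
        "output_bias": state.output_bias.tolist(),
        "input_mask": state.masks.input_mask.tolist(),
        "output_mask": state.masks.output_mask.tolist(),
        "neuron_status": state.masks.neuron_status.tolist(),
    }
    doc["checksum"] = hashlib.sha256(_payload(doc).encode()).hexdigest()
    Path(path).write_text(json.dumps(doc))


def load_state(path: str | Path) -> NetworkState:
    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise SnapshotError(f"snapshot format version {version!r} != {FORMAT_VERSION}")
    expect = doc.get("checksum")
    actual = hashlib.sha256(_payload(doc).encode()).hexdigest()
    if expect != actual:
        raise SnapshotError("snapshot checksum mismatch; refusing to load")
    config = NetworkConfig.from_dict(doc["config"])
    layout, _ = build_layout_and_masks(config)
    masks = MaskSet(
        input_mask=np.asarray(doc["input_mask"], dtype=float),
        output_mask=np.asarray(doc["output_mask"], dtype=float),
        neuron_status=np.asarray(doc["neuron_status"], dtype=float),
    )
    return NetworkState(
        input_weights=np.asarray(doc["input_weights"], dtype=float),
        output_weights=np.asarray(doc["output_weights"], dtype=float),
        hidden_bias=np.asarray(doc["hidden_bias"], dtype=float),
        output_bias=np.asarray(doc["output_bias"], dtype=float),
        masks=masks, layout=layout, config=config, seed=int(doc["seed"]),
        negative_weight_events=int(doc.get("negative_weight_events", 0)),
    )
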