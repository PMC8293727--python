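"""Snapshot and resume containers.

Two formats: a human-readable particle CSV (``id,type,mass,x,y,z,radius``)
and a self-describing, versioned HDF5 container that captures the full run
state (particles, both solute fields, clock, RNG stream states and the
parameter set) so a run can be resumed bit-identically.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import yaml

from .biofilm import BiofilmState, RngStreams
from .fields import SoluteFields
from .params import ModelParams, _params_from_dict, _params_to_dict

__all__ = ["save_snapshot", "load_snapshot"]

FORMAT_VERSION = 1


def save_snapshot(path, state: BiofilmState, params: ModelParams) -> None:
    """Write a resumable snapshot of the full simulation state."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "plaquesim-snapshot"
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["t"] = state.t
        f.attrs["next_id"] = state.next_id
        f.attrs["rng"] = json.dumps(state.rng.state_dict())
        f.attrs["params"] = yaml.safe_dump(_params_to_dict(params))
        g = f.create_group("particles")
        g.create_dataset("ids", data=state.ids)
        g.create_dataset("ptype", data=state.ptype)
        g.create_dataset("mass", data=state.mass)
        g.create_dataset("pos", data=state.pos)
        g = f.create_group("fields")
        g.create_dataset("gl", data=state.fields.gl)
        g.create_dataset("acid", data=state.fields.acid)
        g.attrs["spacing"] = state.fields.spacing


def load_snapshot(path) -> tuple[BiofilmState, ModelParams]:
    """Read a snapshot back; returns the state and the embedded parameters."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "plaquesim-snapshot":
            raise ValueError("not a plaquesim snapshot file")
        if int(f.attrs["version"]) > FORMAT_VERSION:
            raise ValueError("snapshot written by a newer format version")
        params = _params_from_dict(yaml.safe_load(f.attrs["params"]))
        fields = SoluteFields(
            gl=f["fields/gl"][()],
            acid=f["fields/acid"][()],
            spacing=float(f["fields"].attrs["spacing"]),
        )
        state = BiofilmState(
            ids=f["particles/ids"][()].astype(np.int64),
            ptype=f["particles/ptype"][()].astype(np.int8),
            mass=f["particles/mass"][()],
            pos=f["particles/pos"][()],
            fields=fields,
            t=float(f.attrs["t"]),
            rng=RngStreams.from_state_dict(json.loads(f.attrs["rng"])),
            next_id=int(f.attrs["next_id"]),
        )
    return state, params
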