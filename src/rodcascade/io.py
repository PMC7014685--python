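"""Trace serialization, run manifests and seed-stream helpers.

Traces are stored in HDF5 (arrays plus JSON-encoded metadata) with a
CSV exporter for trial means; a run manifest captures everything needed
to reproduce a seeded run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .params import CascadeParams, load_params
from .traces import DiscTrace, OuterSegmentActivity, OuterSegmentTrace

__all__ = [
    "SCHEMA_VERSION",
    "RunManifest",
    "seed_streams",
    "write_traces",
    "read_traces",
    "export_trace_csv",
]

SCHEMA_VERSION = 1

_CLASSES = {
    "DiscTrace": DiscTrace,
    "OuterSegmentActivity": OuterSegmentActivity,
    "OuterSegmentTrace": OuterSegmentTrace,
}


def seed_streams(master_seed, n: int) -> list[np.random.Generator]:
    """n independent, reproducible generators derived from a master seed.

    Stream i is derived as (master_seed, i), so trials are reproducible
    and order-independent.
    """
    ss = np.random.SeedSequence(master_seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


@dataclass
class RunManifest:
    """Everything needed to reproduce a seeded run."""

    operation: str
    master_seed: int
    params: dict
    options: dict = field(default_factory=dict)
    seed_rule: str = "numpy SeedSequence(master_seed).spawn(trial_index)"
    schema_version: int = SCHEMA_VERSION

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)

    def resolved_params(self) -> CascadeParams:
        return load_params(self.params)


def _meta_encode(meta: dict) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return {"__ndarray__": o.tolist()}
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"unserializable metadata entry {o!r}")
    return json.dumps(meta, default=default)


def _meta_decode(s: str) -> dict:
    def hook(d):
        if "__ndarray__" in d:
            return np.asarray(d["__ndarray__"])
        return d
    return json.loads(s, object_hook=hook)


def write_traces(path, traces, manifest: RunManifest | None = None) -> None:
    """Write a list of trace objects to an HDF5 container."""
    if isinstance(traces, (DiscTrace, OuterSegmentActivity, OuterSegmentTrace)):
        traces = [traces]
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if manifest is not None:
            f.attrs["manifest"] = _meta_encode(dataclasses.asdict(manifest))
        for i, tr in enumerate(traces):
            g = f.create_group(f"trace_{i:05d}")
            g.attrs["class"] = type(tr).__name__
            for fld in dataclasses.fields(tr):
                v = getattr(tr, fld.name)
                if v is None or fld.name == "meta":
                    continue
                if isinstance(v, np.ndarray):
                    g.create_dataset(fld.name, data=v)
                else:
                    g.attrs[fld.name] = v
            g.attrs["meta"] = _meta_encode(tr.meta)


def read_traces(path):
    """Read back a trace container written by :func:`write_traces`."""
    out = []
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(f"container schema version {version} != "
                             f"supported version {SCHEMA_VERSION}")
        for key in sorted(k for k in f.keys() if k.startswith("trace_")):
            g = f[key]
            cls = _CLASSES[g.attrs["class"]]
            kwargs = {name: np.asarray(g[name]) for name in g.keys()}
            for aname, aval in g.attrs.items():
                if aname in ("class", "meta"):
                    continue
                kwargs[aname] = aval
            kwargs["meta"] = _meta_decode(g.attrs["meta"])
            out.append(cls(**kwargs))
    return out


def export_trace_csv(path, trace: DiscTrace) -> None:
    """Write a disc trace as a plain CSV table."""
    cols = [("time_s", trace.t), ("G_star", trace.G_star), ("E", trace.E),
            ("E_star", trace.E_star), ("E_starstar", trace.E_starstar)]
    if trace.R_star is not None:
        cols.append(("R_star", trace.R_star))
    header = ",".join(name for name, _ in cols)
    data = np.column_stack([v for _, v in cols])
    np.savetxt(path, data, delimiter=",", header=header, comments="")
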