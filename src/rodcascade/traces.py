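"""Lightweight array containers for simulation output."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DiscTrace", "OuterSegmentActivity", "OuterSegmentTrace"]


@dataclass
class DiscTrace:
    """Sampled molecule counts on one disc surface (or a trial mean).

    ``E + E_star + E_starstar`` equals the total PDE complement at every
    sample; counts are continuous for the mass-action engine and integer
    means for the lattice engine.
    """

    t: np.ndarray              # sample times, s (strictly increasing)
    G_star: np.ndarray         # free activated transducin
    E: np.ndarray              # unbound PDE6
    E_star: np.ndarray         # singly bound PDE6
    E_starstar: np.ndarray     # doubly bound (fully active) PDE6
    R_star: np.ndarray | None = None   # number of catalytically active R*
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.t)
        for name in ("G_star", "E", "E_star", "E_starstar"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match time grid")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def E_total_check(self) -> np.ndarray:
        return self.E + self.E_star + self.E_starstar

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class OuterSegmentActivity:
    """Per-compartment E** drive for one outer-segment trial."""

    t: np.ndarray                   # sample times, s
    per_compartment: np.ndarray     # (n_x, n_t) E** molecules per compartment
    meta: dict = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        """Summed E** activity over the whole outer segment."""
        return self.per_compartment.sum(axis=0)


@dataclass
class OuterSegmentTrace:
    """Photocurrent response of the outer segment."""

    t: np.ndarray          # sample times, s
    J: np.ndarray          # circulating current, pA
    J_dark: float          # resting current, pA
    cG: np.ndarray | None = None   # optional per-compartment cGMP snapshots
    Ca: np.ndarray | None = None   # optional per-compartment Ca2+ snapshots
    meta: dict = field(default_factory=dict)

    @property
    def fractional_response(self) -> np.ndarray:
        """r(t) = 1 - J(t)/J_dark (0 in darkness, 1 at full suppression)."""
        return 1.0 - self.J / self.J_dark
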