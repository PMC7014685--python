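"""Model parameters, derived constants, and the dark resting state.

All quantities live in the unit system used throughout the package:
seconds, micrometres (lattice spacing in nm, tick in us), cGMP in uM,
Ca2+ in nM, currents in pA, volumes in pL, and molecule counts per disc
surface. Conversions to molar quantities are isolated here.

The defaults describe a mammalian rod outer segment: a stack of
``N_surfs`` disc membrane surfaces carrying transducin (G protein) and
the phosphodiesterase PDE6, whose doubly-activated form E** (two
transducins bound) hydrolyses cytoplasmic cGMP and thereby closes the
CNG channels that carry the circulating dark current.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.optimize import brentq

__all__ = [
    "N_AV",
    "FARADAY",
    "CascadeParams",
    "DarkState",
    "ParameterError",
    "load_params",
    "solve_dark_state",
    "predicted_beta_estarstar",
    "buffering_power_cgmp",
]

#: Avogadro's number, mol^-1.
N_AV = 6.02214e23
#: Faraday constant, C mol^-1.
FARADAY = 96485.0


class ParameterError(ValueError):
    """Raised when a parameter value violates a model constraint."""


@dataclass
class CascadeParams:
    """Full parameter set of the phototransduction cascade model.

    Defaults are the standard mammalian-rod values; see the package
    methods note for a description of each group.
    """

    # --- geometry and lattice discretization -------------------------------
    d: float = 1.3            # outer-segment / disc diameter, um
    dx: float = 5.0           # lattice grid spacing, nm
    dt: float = 0.5           # lattice time increment, us

    # --- disc membrane densities and diffusion -----------------------------
    C_G: float = 2500.0       # G-protein holomer surface density, um^-2
    K_m_dep: float = 0.14     # saturation constant of G-protein depletion, dimensionless
    C_E: float = 80.0         # PDE6 holomer surface density, um^-2
    D_Rst: float = 1.5        # lateral diffusion coefficient of R*, um^2 s^-1
    D_Gst: float = 2.2        # lateral diffusion coefficient of G*, um^2 s^-1
    D_E: float = 1.2          # lateral diffusion coefficient of PDE (E), um^2 s^-1
    D_Est: float = 1.0        # lateral diffusion coefficient of singly-bound PDE (E*), um^2 s^-1

    # --- stochastic R* shut-off --------------------------------------------
    M: int = 3                # phosphorylation steps before arrestin can bind
    mu: float = 60.0          # common rate of the M+1 shut-off steps, s^-1

    # --- transducin activation and PDE shut-off ----------------------------
    nu_Gst: float = 1250.0    # G* creation rate per fully active R*, s^-1
    k_Est: float = 2.5        # E* -> E shut-off rate constant, s^-1
    k_Estst: float = 5.0      # E** -> E* shut-off rate constant, s^-1
    k_Gst: float = 1.0        # free G* decay rate constant, s^-1

    # --- downstream: resting-state determinants ----------------------------
    beta_dark: float = 4.0    # dark cGMP hydrolysis rate constant, s^-1
    alpha_max: float = 150.0  # maximal guanylyl cyclase rate, uM s^-1
    f_Ca: float = 0.12        # fraction of CNGC current carried by Ca2+
    K_GCAP: float = 80.0      # cyclase Ca2+ half-set point, nM
    m_GCAP: float = 1.5       # cyclase Hill coefficient
    J_cG_max: float = 2000.0  # maximal CNGC current, pA
    n_cG: float = 3.0         # CNGC Hill coefficient
    K_cG: float = 20.0        # CNGC cGMP parameter, uM
    J_ex_max: float = 4.6     # maximal exchanger current, pA
    K_ex: float = 1100.0      # exchanger Ca2+ parameter, nM

    # --- downstream: parameters not affecting the resting state ------------
    beta_Estst: float = 0.017  # cGMP hydrolysis rate per E** molecule, s^-1
    L: float = 22.0            # outer-segment length, um
    N_surfs: int = 1320        # disc surfaces per outer segment
    f_cyto: float = 0.5        # cytoplasmic volume fraction
    V_cyto: float = 0.0146     # cytoplasmic volume, pL
    B_Ca: float = 50.0         # Ca2+ buffering power of the cytoplasm

    # --- longitudinal diffusion (method 3 / spatial downstream) ------------
    D_cG: float = 40.0         # longitudinal diffusion coefficient of cGMP, um^2 s^-1
    D_Ca: float = 2.0          # longitudinal diffusion coefficient of Ca2+, um^2 s^-1
    n_x: int = 100             # longitudinal compartments

    # --- aberrant R* shut-off events ---------------------------------------
    p_aberr: float = 0.002     # probability an R* fails to inactivate normally
    tau_aberr: float = 4.0     # mean aberrant lifetime, s
    a_aberr: float = 0.25      # fractional R* activity in the aberrant state

    # --- biochemical cross-check parameters --------------------------------
    k_cat: float = 2750.0      # catalytic rate of a fully activated PDE**, s^-1
    K_m_pde: float = 10.0      # Michaelis constant of PDE**, uM

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    _POSITIVE = (
        "d", "dx", "dt", "C_G", "K_m_dep", "C_E", "D_Rst", "D_Gst", "D_E",
        "D_Est", "mu", "nu_Gst", "k_Est", "k_Estst", "k_Gst", "beta_dark",
        "alpha_max", "f_Ca", "K_GCAP", "m_GCAP", "J_cG_max", "n_cG", "K_cG",
        "J_ex_max", "K_ex", "beta_Estst", "L", "f_cyto", "V_cyto", "B_Ca",
        "tau_aberr", "a_aberr", "k_cat", "K_m_pde",
    )

    def validate(self) -> None:
        for name in self._POSITIVE:
            if not getattr(self, name) > 0:
                raise ParameterError(f"parameter {name!r} must be strictly positive")
        for name in ("M", "N_surfs", "n_x"):
            v = getattr(self, name)
            if int(v) != v or (v < 0 if name == "M" else v < 1):
                raise ParameterError(f"parameter {name!r} must be a valid integer")
        if not 0.0 <= self.p_aberr <= 1.0:
            raise ParameterError("parameter 'p_aberr' must lie in [0, 1]")
        if not self.a_aberr <= 1.0:
            raise ParameterError("parameter 'a_aberr' must lie in (0, 1]")
        if self.D_cG < 0 or self.D_Ca < 0:
            raise ParameterError("longitudinal diffusion coefficients must be >= 0")

    # -- derived geometric and kinetic constants ----------------------------

    @property
    def disc_area(self) -> float:
        """Area of one disc surface, um^2."""
        return math.pi * (self.d / 2.0) ** 2

    @property
    def E_tot(self) -> int:
        """Number of PDE6 holomers per disc surface."""
        return int(round(self.C_E * self.disc_area))

    @property
    def G0_surface(self) -> int:
        """Number of G-protein holomers per disc surface."""
        return int(round(self.C_G * self.disc_area))

    @property
    def pde_per_os(self) -> int:
        """Total PDE6 holomers per outer segment."""
        return self.N_surfs * self.E_tot

    @property
    def k1(self) -> float:
        """Bimolecular contact rate G* + E, per molecule pair, s^-1."""
        return (self.D_Gst + self.D_E) / self.disc_area

    @property
    def k2(self) -> float:
        """Bimolecular contact rate G* + E*, per molecule pair, s^-1."""
        return (self.D_Gst + self.D_Est) / self.disc_area

    @property
    def mean_rstar_lifetime(self) -> float:
        """Mean normal R* lifetime (M+1)/mu, s."""
        return (self.M + 1) / self.mu

    @property
    def plasma_membrane_area(self) -> float:
        """Lateral plasma-membrane area pi*d*L, um^2."""
        return math.pi * self.d * self.L

    def phi_per_surface(self, Phi: float) -> float:
        """Mean isomerizations per disc surface for a flash of ``Phi`` per OS."""
        return Phi / self.N_surfs

    def equilibration_time(self, Q: int, D: float | None = None) -> float:
        """Spatial homogenization time A/(Q*D) after Q isomerizations, s."""
        if D is None:
            D = self.D_Gst
        return self.disc_area / (Q * D)

    def min_activation_rate(self, Phi_trans: float = 5000.0,
                            T_Rst: float = 0.068) -> float:
        """Minimum G* creation rate (s^-1 per R*) needed to cover every
        PDE6 binding site at the transition intensity.

        Each holomer carries two G* binding sites; covering all of them
        with ``Phi_trans`` isomerizations within a mean R* lifetime
        ``T_Rst`` requires at least this activation rate.
        """
        sites = 2.0 * self.pde_per_os
        return sites / Phi_trans / T_Rst

    # -- plumbing ------------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **overrides) -> "CascadeParams":
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class DarkState:
    """Resting (dark-adapted) state of the downstream model."""

    cG: float      # dark cGMP concentration, uM
    Ca: float      # dark Ca2+ concentration, nM
    alpha: float   # dark cyclase rate, uM s^-1
    J_cG: float    # dark CNGC current, pA
    J_ex: float    # dark exchanger current, pA

    @property
    def J(self) -> float:
        """Total dark circulating current, pA."""
        return self.J_cG + self.J_ex


def load_params(config: Mapping | str | Path | None = None, **overrides) -> CascadeParams:
    """Build a :class:`CascadeParams` from defaults plus overrides.

    ``config`` may be a mapping or a path to a flat key->value YAML
    document; keyword arguments override both. Unknown keys raise
    :class:`ParameterError`.
    """
    values: dict = {}
    if config is not None:
        if isinstance(config, (str, Path)):
            with open(config) as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise ParameterError("config document must be a flat mapping")
            values.update(loaded)
        else:
            values.update(config)
    values.update(overrides)

    valid = {f.name for f in dataclasses.fields(CascadeParams)}
    unknown = set(values) - valid
    if unknown:
        raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
    return CascadeParams(**values)


# ---------------------------------------------------------------------------
# Downstream rate laws (shared with rodcascade.downstream)
# ---------------------------------------------------------------------------

def cyclase_rate(Ca: float, p: CascadeParams):
    """Guanylyl cyclase synthesis rate alpha(Ca), uM s^-1 (GCAP feedback)."""
    return p.alpha_max / (1.0 + (np.asarray(Ca) / p.K_GCAP) ** p.m_GCAP)


def cng_current(cG: float, p: CascadeParams):
    """CNG-channel current J_cG(cG), pA (Hill activation by cGMP)."""
    c = np.asarray(cG) ** p.n_cG
    return p.J_cG_max * c / (c + p.K_cG ** p.n_cG)


def exchanger_current(Ca: float, p: CascadeParams):
    """Na+/Ca2+,K+ exchanger current J_ex(Ca), pA (saturating in Ca2+)."""
    Ca = np.asarray(Ca)
    return p.J_ex_max * Ca / (Ca + p.K_ex)


def _ca_from_cg(cG: float, p: CascadeParams) -> float:
    """Ca2+ (nM) balancing influx f_Ca*J_cG/2 against exchanger efflux."""
    J_in = p.f_Ca * cng_current(cG, p) / 2.0
    x = J_in / p.J_ex_max
    if x >= 1.0:
        raise ParameterError("Ca influx exceeds maximal exchanger capacity")
    return p.K_ex * x / (1.0 - x)


def solve_dark_state(params: CascadeParams) -> DarkState:
    """Solve the dark steady state of the downstream model.

    Simultaneous root of the cyclase/hydrolysis balance
    ``alpha(Ca) = beta_dark * cG`` and the Ca2+ flux balance
    ``f_Ca * J_cG(cG) / 2 = J_ex(Ca)``.
    """
    p = params

    def residual(cG: float) -> float:
        return cyclase_rate(_ca_from_cg(cG, p), p) - p.beta_dark * cG

    # Upper bracket: largest cG for which the exchanger can balance Ca influx.
    hi = p.K_cG
    while True:
        try:
            _ca_from_cg(hi, p)
        except ParameterError:
            hi *= 0.99
            continue
        if residual(hi) < 0:
            break
        hi *= 1.01
        if hi > 100 * p.K_cG:
            raise ParameterError("no dark steady state in this parameter regime")
    lo = 1e-6 * p.K_cG
    if residual(lo) <= 0:
        raise ParameterError("no dark steady state in this parameter regime")
    cG = brentq(residual, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    Ca = _ca_from_cg(cG, p)
    return DarkState(
        cG=cG,
        Ca=Ca,
        alpha=float(cyclase_rate(Ca, p)),
        J_cG=float(cng_current(cG, p)),
        J_ex=float(exchanger_current(Ca, p)),
    )


# ---------------------------------------------------------------------------
# Biochemical cross-checks
# ---------------------------------------------------------------------------

def predicted_beta_estarstar(params: CascadeParams, B_cG: float) -> float:
    """Predicted cGMP hydrolysis rate per E** from biochemical parameters.

    ``k_cat / (K_m * N_Av * V_cyto * B_cG)`` with K_m in uM converted to
    mol/L and V_cyto in pL converted to L; returned in s^-1.
    """
    if B_cG <= 0:
        raise ParameterError("B_cG must be strictly positive")
    km_molar = params.K_m_pde * 1e-6          # uM -> mol/L
    v_litre = params.V_cyto * 1e-12           # pL -> L
    return params.k_cat / (km_molar * N_AV * v_litre * B_cG)


def buffering_power_cgmp(params: CascadeParams, channel_density: float = 400.0,
                         n_sites: int = 3) -> float:
    """Cytoplasmic cGMP buffering power contributed by CNG channels.

    Channels at ``channel_density`` (um^-2) on the plasma membrane each
    carry ``n_sites`` independent cGMP binding sites of dissociation
    constant K_cG; the buffering power is ``1 + N * C_CNGC / K_cG`` with
    C_CNGC the effective channel concentration referenced to V_cyto.
    """
    if channel_density < 0 or n_sites < 0:
        raise ParameterError("channel density and site count must be >= 0")
    n_channels = channel_density * params.plasma_membrane_area
    # molecules / (N_Av * litres) = mol/L; express in uM:
    c_cngc_uM = n_channels / (N_AV * params.V_cyto * 1e-12) * 1e6
    return 1.0 + n_sites * c_cngc_uM / params.K_cG
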