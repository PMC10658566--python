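"""Explicit finite-difference simulation of drug permeation through
microneedle-treated skin.

The model solves Fick's second law,

    dC/dt = D (d²C/dx² + d²C/dy²),

on the half unit cell of one needle: the needle cross-section sits in
the upper-left of a rectangular skin domain, the left column is the
needle symmetry axis, the right column is the midline between adjacent
needles, and the bottom row exchanges drug with a well-mixed receptor
compartment (a Franz-cell receptor solution).  All three side/top
boundaries are no-flux; the scheme is forward-time centred-space (FTCS)
in flux form, so total mass is conserved to floating-point.

Mesh elements fall into five classes by the neighbours they can
exchange with — corner, bottom corner, edge, bottom edge and internal —
which the flux-form update realises implicitly: a missing neighbour
simply contributes no exchange.

The 2D computation is a mass-fraction machine: the fraction of one
needle's load that reaches the receptor multiplies the per-needle load
and the needle count, and the product is normalized by the diffusion
window of the Franz device (1.00 cm² vertical, 1.13 cm² horizontal) to
give cumulative permeation in µg per 1 cm².

Units: lengths µm, time minutes, diffusion coefficient µm²/min,
mass µg.  Dataset-facing time is in hours; conversion happens at the
boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import Needle, rasterize_half_needle

__all__ = [
    "WINDOW_AREA_CM2",
    "SimulationConfig",
    "SimulationState",
    "PermeationCurve",
    "classify_elements",
    "stability_limit",
    "step",
    "run_simulation",
    "cumulative_percentage",
    "slab_release_oracle",
]

#: Diffusion window of the Franz device, cm² (vertical and horizontal cells).
WINDOW_AREA_CM2 = {"vertical": 1.00, "horizontal": 1.13}

#: Range of diffusion coefficients reported for the six permeants, µm²/min.
D_RANGE = (50.0, 1000.0)

ELEMENT_CLASSES = ("corner", "bottom_corner", "edge", "bottom_edge", "internal")


@dataclass
class SimulationConfig:
    """Parameters of one needle–skin–receptor simulation.

    Parameters
    ----------
    D : float
        Diffusion coefficient, µm²/min.  Values outside [50, 1000]
        (the range spanned by the modelled permeants) raise a warning.
    needle : Needle, optional
        Needle geometry; required unless ``needle_mask`` is given.
    load_per_needle : float
        Drug mass assigned to one needle, µg (total load / n_needles).
    n_needles : int
        Needles on the patch; scales receptor mass back to patch level.
    dx, dy : float
        Grid spacing, µm.
    dt : float, optional
        Time step, min.  Clamped to 0.9 × the FTCS stability limit.
    t_end : float
        Final simulated time, min.
    skin_thickness : float
        Skin membrane thickness, µm (default 1 mm).
    unit_cell_width : float
        Half needle spacing (symmetry half cell), µm.
    receptor_mode : {"finite", "sink"}
        Finite well-mixed receptor (equilibrating, produces the
        plateau) or a perfect sink.
    receptor_volume : float
        Receptor solution volume, µL (finite mode).
    mn_type : {"hydrogel", "plastic"}
        Hydrogel: drug loaded inside the needle.  Plastic: skin is
        pre-treated, drug solution fills the needle-shaped cavities and
        a donor layer of height ``donor_layer_height`` above the skin.
    donor_layer_height : float
        Height of the donor solution layer (plastic mode), µm.
    device : {"vertical", "horizontal"}
        Franz device variant; sets the diffusion-window area.
    needle_mask : ndarray, optional
        Pre-rasterized boolean half-needle mask; overrides ``needle``.
    """

    D: float
    load_per_needle: float = 100.0
    n_needles: int = 1
    needle: Optional[Needle] = None
    needle_mask: Optional[np.ndarray] = None
    dx: float = 2.0
    dy: float = 2.0
    dt: Optional[float] = None
    t_end: float = 1440.0
    skin_thickness: float = 1000.0
    unit_cell_width: float = 300.0
    receptor_mode: str = "finite"
    receptor_volume: float = 5000.0
    mn_type: str = "hydrogel"
    donor_layer_height: float = 200.0
    device: str = "vertical"

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("grid spacings must be positive")
        if self.skin_thickness <= 0 or self.unit_cell_width <= 0:
            raise ValueError("domain lengths must be positive")
        if self.D < 0:
            raise ValueError("diffusion coefficient must be non-negative")
        if not (D_RANGE[0] <= self.D <= D_RANGE[1]) and self.D > 0:
            warnings.warn(
                f"D={self.D} µm²/min outside the modelled range "
                f"{D_RANGE[0]}-{D_RANGE[1]}",
                stacklevel=2,
            )
        if self.receptor_mode not in ("finite", "sink", "none"):
            raise ValueError("receptor_mode must be 'finite', 'sink' or 'none'")
        if self.mn_type not in ("hydrogel", "plastic"):
            raise ValueError("mn_type must be 'hydrogel' or 'plastic'")
        if self.device not in WINDOW_AREA_CM2:
            raise ValueError(f"unknown device: {self.device!r}")
        if self.load_per_needle < 0:
            raise ValueError("load_per_needle must be non-negative")

    # -- derived geometry -------------------------------------------------

    @property
    def n_skin_rows(self) -> int:
        return max(int(round(self.skin_thickness / self.dy)), 2)

    @property
    def n_donor_rows(self) -> int:
        if self.mn_type != "plastic":
            return 0
        return max(int(round(self.donor_layer_height / self.dy)), 1)

    @property
    def ncols(self) -> int:
        return max(int(round(self.unit_cell_width / self.dx)), 2)

    def receptor_area_2d(self) -> float:
        """Equivalent 2D receptor area for the half unit cell, µm².

        The needles tile the diffusion window, under which the whole
        receptor volume sits, so the equivalent receptor depth is
        volume / window area — independent of the needle count (which
        keeps the curve invariant to splitting a fixed total load over
        more needles).  The depth multiplies the half-cell width.
        """
        vol_um3 = self.receptor_volume * 1e9  # µL -> µm³
        window_um2 = WINDOW_AREA_CM2[self.device] * 1e8  # cm² -> µm²
        depth = vol_um3 / window_um2
        return depth * self.unit_cell_width


@dataclass
class SimulationState:
    """Concentration field and receptor bookkeeping at one time."""

    conc: np.ndarray  # mass per cell, µg (of one needle's load)
    element_class: np.ndarray  # str codes over ELEMENT_CLASSES
    receptor_mass: float = 0.0  # µg, one needle's contribution
    time: float = 0.0  # min

    def total_mass(self) -> float:
        return float(self.conc.sum()) + self.receptor_mass


@dataclass
class PermeationCurve:
    """Cumulative permeation time series for a whole patch."""

    times: np.ndarray  # min
    cumulative_amount: np.ndarray  # µg per 1 cm² diffusion window
    cumulative_percentage: np.ndarray  # % of loaded drug

    @property
    def times_h(self) -> np.ndarray:
        return self.times / 60.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times_h,
                "amount_ug_per_cm2": self.cumulative_amount,
                "percentage": self.cumulative_percentage,
            }
        )


def classify_elements(nrows: int, ncols: int) -> np.ndarray:
    """Assign each mesh cell its boundary class.

    Classes by available neighbours: ``internal`` (4), ``edge``
    (top-row interior and side-column interior, 3), ``bottom_edge``
    (bottom-row interior, 3), ``corner`` (top-row ends, 2) and
    ``bottom_corner`` (bottom-row ends, 2).
    """
    if nrows < 2 or ncols < 2:
        raise ValueError("grid must be at least 2x2")
    cls = np.full((nrows, ncols), "internal", dtype=object)
    cls[0, 1:-1] = "edge"
    cls[1:-1, 0] = "edge"
    cls[1:-1, -1] = "edge"
    cls[-1, 1:-1] = "bottom_edge"
    cls[0, 0] = cls[0, -1] = "corner"
    cls[-1, 0] = cls[-1, -1] = "bottom_corner"
    return cls


def stability_limit(config: SimulationConfig) -> float:
    """Largest stable FTCS time step, min:
    dx²·dy² / (2·D·(dx²+dy²)); dx²/(4D) on a square grid."""
    if config.D == 0:
        return math.inf
    dx2, dy2 = config.dx**2, config.dy**2
    return dx2 * dy2 / (2.0 * config.D * (dx2 + dy2))


def _effective_dt(config: SimulationConfig) -> float:
    limit = stability_limit(config)
    if config.dt is None:
        return 0.9 * limit if math.isfinite(limit) else config.t_end / 100.0
    return min(config.dt, 0.9 * limit)


def step(state: SimulationState, config: SimulationConfig, dt: Optional[float] = None) -> SimulationState:
    """Advance the field one FTCS step (in place) and return the state.

    The update is in flux form: each interior face exchanges
    α·(C_neighbour − C_cell) with α = D·dt/h²; boundary cells simply
    have fewer faces (the five element classes), which realises the
    no-flux conditions.  The bottom row additionally exchanges with the
    receptor: a perfect sink or a finite well-mixed compartment whose
    equivalent cell concentration is receptor_mass/A_receptor·dx·dy.
    """
    if dt is None:
        dt = _effective_dt(config)
    if dt > stability_limit(config) * (1 + 1e-12):
        raise ValueError(
            f"dt={dt} exceeds the FTCS stability limit "
            f"{stability_limit(config)}; choose a smaller time step"
        )
    c = state.conc
    ax = config.D * dt / config.dx**2
    ay = config.D * dt / config.dy**2

    # horizontal exchanges between columns j and j+1
    dh = c[:, 1:] - c[:, :-1]
    c[:, :-1] += ax * dh
    c[:, 1:] -= ax * dh
    # vertical exchanges between rows i and i+1
    dv = c[1:, :] - c[:-1, :]
    c[:-1, :] += ay * dv
    c[1:, :] -= ay * dv

    # bottom row <-> receptor ("none" keeps the domain closed)
    if config.receptor_mode != "none":
        bottom = c[-1, :]
        if config.receptor_mode == "sink":
            flux = ay * bottom
        else:
            cell_area = config.dx * config.dy
            c_rec = state.receptor_mass / config.receptor_area_2d() * cell_area
            flux = ay * (bottom - c_rec)
        c[-1, :] -= flux
        state.receptor_mass += float(flux.sum())

    if (c < -1e-12 * max(c.max(), 1.0)).any():
        raise ArithmeticError(
            "negative concentrations detected: the scheme is unstable, "
            "reduce dt"
        )
    state.time += dt
    return state


def _initial_state(config: SimulationConfig) -> SimulationState:
    nrows_skin = config.n_skin_rows
    ndonor = config.n_donor_rows
    ncols = config.ncols
    nrows = nrows_skin + ndonor

    if config.needle_mask is not None:
        half_mask = np.asarray(config.needle_mask, dtype=bool)
    elif config.needle is not None:
        half_mask = rasterize_half_needle(
            config.needle, config.dx, config.dy, config.skin_thickness
        )
    else:
        raise ValueError("config must provide a needle or a needle_mask")
    if half_mask.shape[1] > ncols:
        raise ValueError("needle wider than the half unit cell")

    load_mask = np.zeros((nrows, ncols), dtype=bool)
    mr = min(half_mask.shape[0], nrows_skin)
    load_mask[ndonor : ndonor + mr, : half_mask.shape[1]] = half_mask[:mr]
    if config.mn_type == "plastic":
        load_mask[:ndonor, :] = True  # donor solution layer spans the window

    conc = np.zeros((nrows, ncols))
    n_loaded = int(load_mask.sum())
    if n_loaded == 0:
        raise ValueError("no cells carry drug: needle mask is empty")
    conc[load_mask] = config.load_per_needle / n_loaded
    return SimulationState(
        conc=conc,
        element_class=classify_elements(nrows, ncols),
        receptor_mass=0.0,
        time=0.0,
    )


def run_simulation(
    config: SimulationConfig,
    output_times: Optional[Sequence[float]] = None,
) -> PermeationCurve:
    """Run the permeation simulation and sample the cumulative curve.

    Parameters
    ----------
    config : SimulationConfig
    output_times : sequence of float, optional
        Times (min) at which to report the curve; defaults to 50 points
        evenly spaced over (0, t_end].  Values are linearly
        interpolated between the bracketing time steps.

    Returns
    -------
    PermeationCurve
        Cumulative amount (µg per 1 cm² window) and percentage of the
        total load, for the whole patch.
    """
    if config.t_end <= 0:
        raise ValueError("t_end must be positive")
    if output_times is None:
        output_times = np.linspace(0.0, config.t_end, 51)[1:]
    out_t = np.asarray(output_times, dtype=float)
    if (out_t < 0).any() or (out_t > config.t_end * (1 + 1e-9)).any():
        raise ValueError("output times must lie in [0, t_end]")

    m_total = config.load_per_needle * config.n_needles
    window = WINDOW_AREA_CM2[config.device]

    if config.D == 0 or config.load_per_needle == 0:
        zeros = np.zeros_like(out_t)
        return PermeationCurve(out_t.copy(), zeros, zeros.copy())

    state = _initial_state(config)
    dt = _effective_dt(config)
    order = np.argsort(out_t)
    sorted_t = out_t[order]
    fractions = np.empty_like(sorted_t)

    prev_t, prev_f = 0.0, 0.0
    k = 0
    n_out = len(sorted_t)
    while k < n_out and sorted_t[k] <= 0.0:
        fractions[k] = 0.0
        k += 1
    while k < n_out:
        step(state, config, dt)
        cur_f = state.receptor_mass / config.load_per_needle
        while k < n_out and sorted_t[k] <= state.time + 1e-12:
            if state.time == prev_t:
                fractions[k] = cur_f
            else:
                w = (sorted_t[k] - prev_t) / (state.time - prev_t)
                fractions[k] = prev_f + w * (cur_f - prev_f)
            k += 1
        prev_t, prev_f = state.time, cur_f

    frac_out = np.empty_like(fractions)
    frac_out[order] = fractions
    amount = frac_out * m_total / window
    pct = 100.0 * frac_out
    return PermeationCurve(out_t.copy(), amount, pct)


def cumulative_percentage(m_t: float, m_total: float) -> float:
    """Permeation percentage: 100 · m_t / m_total."""
    if m_total <= 0:
        raise ValueError("m_total must be positive")
    if m_t < 0:
        raise ValueError("m_t must be non-negative")
    return 100.0 * m_t / m_total


def slab_release_oracle(D: float, thickness: float, t: float, tol: float = 1e-12) -> float:
    """Analytic fractional release from a uniformly loaded slab.

    One face is impermeable (no flux), the other a perfect sink:

        f(t) = 1 − Σ_{n≥0} 8/((2n+1)²π²) · exp(−D(2n+1)²π²t / (4L²)).

    Serves as an independent closed-form check of the numerical solver
    in its degenerate slab limit.
    """
    if D < 0 or thickness < 0 or t < 0:
        raise ValueError("D, thickness and t must be non-negative")
    if t == 0 or D == 0:
        return 0.0
    if thickness == 0:
        return 1.0
    tau = D * t / (4.0 * thickness**2)
    total = 0.0
    n = 0
    while True:
        k = 2 * n + 1
        term = 8.0 / (k * k * math.pi * math.pi) * math.exp(-(k * k) * math.pi * math.pi * tau)
        total += term
        if term < tol:
            break
        n += 1
        if n > 100000:  # pragma: no cover - safeguard
            break
    return 1.0 - min(total, 1.0)
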