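"""Synthetic permeation datasets generated from the diffusion simulator.

The generator emulates a compiled Franz-cell database: six permeants
spanning molecular weights 64–66,430 Da (a metal ion, four small
molecules, one protein), delivered through hydrogel (frustum) or
plastic (pyramid) microneedle patches with the study's printed needle
lengths (700–1250 µm) and patch surface areas (26.76–36.86 mm²), drug
loadings in 50–70,940 µg, and sampling times on a typical Franz grid
(0.25–48 h).  Cumulative amounts come from the mechanistic simulator;
multiplicative lognormal noise emulates inter-replicate experimental
scatter, and the percentage response is recomputed from the noisy
amount so each row stays internally consistent.

Diffusion coefficients are derived from molecular weight with a
monotone Stokes–Einstein-like map D = c·MW^(−1/3), anchored so a
194 Da small molecule gets 600 µm²/min, clipped to the 50–1000 µm²/min
range spanned by the modelled permeants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dataset import PermeationRecord
from .diffusion import SimulationConfig, WINDOW_AREA_CM2, run_simulation
from .geometry import FrustumNeedle, Needle, PyramidNeedle

__all__ = [
    "DEFAULT_DRUGS",
    "DEFAULT_GEOMETRY_POOL",
    "DEFAULT_TIME_GRID_H",
    "GeneratorConfig",
    "mw_to_diffusion",
    "needle_for",
    "generate_dataset",
    "data_s1_replica",
]

#: The six permeants: (name, molecular weight Da, skin type).
DEFAULT_DRUGS = (
    ("copper", 64.0, "R"),
    ("caffeine", 194.0, "H"),
    ("lidocaine", 234.0, "R"),
    ("ghk", 340.0, "H"),
    ("rhodamine_b", 479.0, "R"),
    ("bsa", 66430.0, "R"),
)

#: Representative patch designs: (mn_type, length µm, patch area mm², n needles).
DEFAULT_GEOMETRY_POOL = (
    ("plastic", 700.0, 36.86, 351),
    ("plastic", 820.0, 32.13, 351),
    ("hydrogel", 875.97, 26.76, 64),
    ("hydrogel", 998.62, 28.54, 64),
    ("hydrogel", 1062.97, 29.97, 64),
    ("hydrogel", 889.0, 32.43, 64),
    ("hydrogel", 1250.0, 34.49, 64),
)

#: Typical Franz-cell sampling grid, hours.
DEFAULT_TIME_GRID_H = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 24.0, 48.0)

#: Anchor of the MW -> D map: a 194 Da small molecule diffuses at
#: 600 µm²/min, so c = 600 · 194^(1/3).
_D_ANCHOR_MW = 194.0
_D_ANCHOR = 600.0
_D_COEFF = _D_ANCHOR * _D_ANCHOR_MW ** (1.0 / 3.0)
_D_MIN, _D_MAX = 50.0, 1000.0

#: Device per MN class: plastic patches ran in the vertical cell
#: (1.00 cm² window), hydrogel patches in the horizontal cell (1.13 cm²).
_DEVICE_BY_TYPE = {"plastic": "vertical", "hydrogel": "horizontal"}


def mw_to_diffusion(mw: float) -> float:
    """Monotone decreasing MW -> diffusion coefficient map, µm²/min.

    D = clip(c · MW^(−1/3), 50, 1000) with c anchored at
    D(194 Da) = 600 µm²/min.
    """
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    return float(np.clip(_D_COEFF * mw ** (-1.0 / 3.0), _D_MIN, _D_MAX))


def needle_for(
    mn_type: str, length: float, patch_area_mm2: float, n_needles: Optional[int] = None
) -> Tuple[Needle, int, str]:
    """Reconstruct a needle design from record-level fields.

    Given the MN class, needle length (µm) and total patch surface area
    (mm²), solve the matching surface-area formula for the free shape
    parameter: the pyramid base edge for plastic needles, or the base
    radius of a frustum with a fixed 1:10 tip:base taper for hydrogel
    needles.  Returns (needle, n_needles, device).
    """
    if n_needles is None:
        n_needles = 351 if mn_type == "plastic" else 64
    s_um2 = patch_area_mm2 * 1e6 / n_needles  # per-needle area, µm²
    if mn_type == "plastic":
        # S = 4x·sqrt(x²+h²), x = a/2  ->  x² = (−h² + sqrt(h⁴ + S²/4)) / 2
        h = length
        x2 = (-h * h + math.sqrt(h**4 + s_um2**2 / 4.0)) / 2.0
        a = 2.0 * math.sqrt(x2)
        needle: Needle = PyramidNeedle(base_edge=a, height=h)
    elif mn_type == "hydrogel":
        # S = πr² + π(R+r)l, r = R/10, l = sqrt((R−r)² + L²); solve for R
        from scipy.optimize import brentq

        L = length

        def area_minus_target(R: float) -> float:
            r = R / 10.0
            l = math.hypot(R - r, L)
            return math.pi * r * r + math.pi * (R + r) * l - s_um2

        upper = max(math.sqrt(s_um2), L) * 10
        R = brentq(area_minus_target, 1e-9, upper)
        r = R / 10.0
        needle = FrustumNeedle(r_top=r, r_base=R, slant=math.hypot(R - r, L), length=L)
    else:
        raise ValueError(f"unknown mn_type: {mn_type!r}")
    return needle, n_needles, _DEVICE_BY_TYPE[mn_type]


@dataclass
class GeneratorConfig:
    """Conditions under which synthetic datasets are generated."""

    seed: int
    drugs: Sequence[Tuple[str, float, str]] = DEFAULT_DRUGS
    geometry_pool: Sequence[Tuple[str, float, float, int]] = DEFAULT_GEOMETRY_POOL
    loading_range: Tuple[float, float] = (50.0, 70940.0)
    loading_range_by_drug: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    time_grid_h: Sequence[float] = DEFAULT_TIME_GRID_H
    noise_sd: float = 0.15  # lognormal sd of inter-replicate scatter
    curves_per_drug: int = 2
    # solver resolution for generation; coarser than the production
    # default so batch generation stays fast
    dx: float = 20.0
    dy: float = 20.0
    skin_thickness: float = 1000.0
    receptor_mode: str = "finite"
    receptor_volume: float = 5000.0

    def __post_init__(self) -> None:
        lo, hi = self.loading_range
        if not (50.0 <= lo <= hi <= 70940.0):
            raise ValueError("loading_range must lie within [50, 70940] µg")
        tg = np.asarray(self.time_grid_h, dtype=float)
        if (tg < 0.0833 - 1e-9).any() or (tg > 48.0 + 1e-9).any():
            raise ValueError("time grid must lie within [0.0833, 48] h")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _simulate_curve(
    cfg: GeneratorConfig,
    mw: float,
    mn_type: str,
    length: float,
    area: float,
    n_needles: int,
    loading: float,
) -> Tuple[np.ndarray, np.ndarray, str]:
    """Noiseless amounts (µg/cm²) and percentages on the time grid."""
    needle, n, device = needle_for(mn_type, length, area, n_needles)
    times_min = np.asarray(cfg.time_grid_h, dtype=float) * 60.0
    # needles longer than the nominal membrane deepen the domain so the
    # tip stays at least two cells above the receptor boundary
    skin = max(cfg.skin_thickness, length + 2.0 * cfg.dy)
    sim = SimulationConfig(
        D=mw_to_diffusion(mw),
        needle=needle,
        n_needles=n,
        load_per_needle=loading / n,
        dx=cfg.dx,
        dy=cfg.dy,
        t_end=float(times_min.max()),
        skin_thickness=skin,
        receptor_mode=cfg.receptor_mode,
        receptor_volume=cfg.receptor_volume,
        mn_type=mn_type,
        device=device,
    )
    curve = run_simulation(sim, output_times=times_min)
    return curve.cumulative_amount, curve.cumulative_percentage, device


def generate_dataset(
    config: GeneratorConfig,
    rows_per_drug: Optional[Dict[str, int]] = None,
) -> Tuple[List[PermeationRecord], List[PermeationRecord]]:
    """Generate (noisy records, noiseless ground-truth records).

    For each drug, ``curves_per_drug`` patch/loading combinations are
    drawn (geometries round-robin from the pool, loadings log-uniform
    over the configured range) and simulated over the time grid.  Noise
    is multiplicative lognormal on the amount; the percentage is
    recomputed from the noisy amount so the two responses stay
    consistent row by row.  When ``rows_per_drug`` is given, each
    drug's rows are generated curve by curve and truncated/extended to
    exactly that count.
    """
    rng = np.random.default_rng(config.seed)
    noisy: List[PermeationRecord] = []
    truth: List[PermeationRecord] = []
    n_times = len(config.time_grid_h)

    for di, (drug, mw, skin) in enumerate(config.drugs):
        if rows_per_drug is not None:
            if drug not in rows_per_drug:
                continue
            want = rows_per_drug[drug]
            n_curves = math.ceil(want / n_times)
        else:
            want = config.curves_per_drug * n_times
            n_curves = config.curves_per_drug
        made = 0
        for ci in range(n_curves):
            mn_type, length, area, n_needles = config.geometry_pool[
                (di + ci) % len(config.geometry_pool)
            ]
            lo, hi = config.loading_range_by_drug.get(drug, config.loading_range)
            loading = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            amounts, _, device = _simulate_curve(
                cfg=config, mw=mw, mn_type=mn_type, length=length,
                area=area, n_needles=n_needles, loading=loading,
            )
            window = WINDOW_AREA_CM2[device]
            factors = (
                np.exp(config.noise_sd * rng.standard_normal(n_times))
                if config.noise_sd > 0
                else np.ones(n_times)
            )
            for ti, t_h in enumerate(config.time_grid_h):
                if made >= want:
                    break
                a_true = float(amounts[ti])
                a_noisy = a_true * float(factors[ti])
                common = dict(
                    drug=drug,
                    skin_type=skin,
                    mn_type=mn_type,
                    mn_length=length,
                    mn_surface_area=area,
                    drug_loading=loading,
                    permeation_time=float(t_h),
                    mw=mw,
                )
                truth.append(
                    PermeationRecord(
                        **common,
                        permeation_amount=a_true,
                        permeation_percentage=100.0 * a_true * window / loading,
                    )
                )
                noisy.append(
                    PermeationRecord(
                        **common,
                        permeation_amount=a_noisy,
                        permeation_percentage=100.0 * a_noisy * window / loading,
                    )
                )
                made += 1
    return noisy, truth


#: Per-drug row counts of the 191-row replica (lidocaine 73 = 38% as in
#: the compiled experimental database; the remainder split across the
#: other five drugs in their approximate reported proportions).
REPLICA_COUNTS = {
    "lidocaine": 73,
    "bsa": 39,
    "ghk": 28,
    "copper": 28,
    "rhodamine_b": 12,
    "caffeine": 11,
}


def data_s1_replica(seed: int, noise_sd: float = 0.15) -> List[PermeationRecord]:
    """A synthetic 191-row stand-in for the compiled experimental
    permeation database: same schema, six drugs, lidocaine carrying
    73 rows (38%).  Entirely simulator-generated; not the original
    experimental data."""
    config = GeneratorConfig(seed=seed, noise_sd=noise_sd)
    noisy, _ = generate_dataset(config, rows_per_drug=REPLICA_COUNTS)
    assert len(noisy) == sum(REPLICA_COUNTS.values()) == 191
    return noisy
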