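"""Model evaluation: RMSE/R² metrics, four-method comparison tables and
leave-one-drug-out validation.

RMSE = sqrt(mean((y - ŷ)²)); R² = 1 − SS_res/SS_tot with SS_tot about
the mean of the observations.  On held-out data R² may be negative and
is reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import PermeationRecord, split_train_test
from .models import (
    TreeModelSpec,
    fit_mlr,
    fit_tree_model,
    predict,
)

__all__ = [
    "MetricReport",
    "rmse",
    "r_squared",
    "fick_predict",
    "compare_methods",
    "leave_one_drug_out",
]


@dataclass
class MetricReport:
    method: str
    target: str  # "amount" or "percentage"
    rmse: float
    r2: float
    n_test: int


def rmse(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Root mean square error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Coefficient of determination, 1 − SS_res/SS_tot."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in observations")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def _observed(records: Sequence[PermeationRecord], target: str) -> np.ndarray:
    attr = "permeation_amount" if target == "amount" else "permeation_percentage"
    vals = [getattr(r, attr) for r in records]
    if any(v is None for v in vals):
        raise ValueError(f"some records lack a {target} response")
    return np.asarray(vals, dtype=float)


def fick_predict(
    records: Sequence[PermeationRecord],
    d_map: Dict[str, float],
    target: str = "amount",
    sim_kwargs: Optional[dict] = None,
) -> np.ndarray:
    """Mechanistic (diffusion) predictions for a set of records.

    Unlike the statistical learners, this route is not trained: each
    record's permeation is simulated from its patch geometry and the
    drug's literature diffusion coefficient (``d_map``, µm²/min per
    drug name).  Records of the same drug/geometry/loading share one
    simulation, evaluated at their time points.
    """
    from . import synthetic_data as _synth
    from .diffusion import SimulationConfig, run_simulation, WINDOW_AREA_CM2

    sim_kwargs = dict(sim_kwargs or {})
    sim_kwargs.setdefault("dx", 20.0)
    sim_kwargs.setdefault("dy", 20.0)
    default_skin = sim_kwargs.pop("skin_thickness", 1000.0)
    preds = np.empty(len(records))
    groups: Dict[tuple, List[int]] = {}
    for i, r in enumerate(records):
        if r.drug not in d_map:
            raise KeyError(f"no diffusion coefficient supplied for {r.drug!r}")
        key = (r.drug, r.mn_type, r.mn_length, r.mn_surface_area, r.drug_loading)
        groups.setdefault(key, []).append(i)

    for (drug, mn_type, length, area, loading), idxs in groups.items():
        times_min = np.array([records[i].permeation_time for i in idxs]) * 60.0
        needle, n_needles, device = _synth.needle_for(mn_type, length, area)
        config = SimulationConfig(
            skin_thickness=max(default_skin, length + 2.0 * sim_kwargs["dy"]),
            D=d_map[drug],
            needle=needle,
            n_needles=n_needles,
            load_per_needle=loading / n_needles,
            t_end=float(times_min.max()),
            mn_type=mn_type,
            device=device,
            **sim_kwargs,
        )
        curve = run_simulation(config, output_times=times_min)
        vals = curve.cumulative_amount if target == "amount" else curve.cumulative_percentage
        for j, i in enumerate(idxs):
            preds[i] = vals[j]
    return preds


def compare_methods(
    records: Sequence[PermeationRecord],
    seed: int = 0,
    targets: Sequence[str] = ("amount", "percentage"),
    d_map: Optional[Dict[str, float]] = None,
    ratio: float = 0.7,
    fick_sim_kwargs: Optional[dict] = None,
) -> pd.DataFrame:
    """Fit MLR/RF/XGBoost on one random 7:3 split and evaluate all
    methods on the held-out rows.

    The diffusion (Fick) method is included only when per-drug
    diffusion coefficients are supplied; it is evaluated on the same
    test rows without any training.  Returns a tidy table of
    method × target × {rmse, r2, n_test}.
    """
    split = split_train_test(records, ratio=ratio, seed=seed)
    reports: List[MetricReport] = []
    for target in targets:
        y = _observed(split.test, target)
        preds = {
            "MLR": predict(fit_mlr(split.train, target), split.test),
            "RF": predict(
                fit_tree_model(split.train, TreeModelSpec("rf", target), seed=seed),
                split.test,
            ),
            "XGBoost": predict(
                fit_tree_model(split.train, TreeModelSpec("xgboost", target), seed=seed),
                split.test,
            ),
        }
        if d_map is not None:
            preds["Fick"] = fick_predict(
                split.test, d_map, target=target, sim_kwargs=fick_sim_kwargs
            )
        for method, yhat in preds.items():
            reports.append(
                MetricReport(
                    method=method,
                    target=target,
                    rmse=rmse(y, yhat),
                    r2=r_squared(y, yhat),
                    n_test=len(split.test),
                )
            )
    return pd.DataFrame([r.__dict__ for r in reports])


def leave_one_drug_out(
    records: Sequence[PermeationRecord],
    drug: str,
    spec: TreeModelSpec,
    seed: int = 0,
):
    """Hold out every row of one drug, train on the rest, and report
    how well the model extrapolates to the unseen compound."""
    held = [r for r in records if r.drug == drug]
    rest = [r for r in records if r.drug != drug]
    if not held:
        raise ValueError(f"drug {drug!r} not present in the dataset")
    if not rest:
        raise ValueError("no training rows left after holding out the drug")
    model = fit_tree_model(rest, spec, seed=seed)
    yhat = predict(model, held)
    y = _observed(held, spec.target)
    report = MetricReport(
        method=f"{spec.family} (LODO {drug})",
        target=spec.target,
        rmse=rmse(y, yhat),
        r2=r_squared(y, yhat),
        n_test=len(held),
    )
    return yhat, report
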