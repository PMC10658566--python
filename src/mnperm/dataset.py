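"""Permeation dataset handling.

A permeation dataset is a CSV with one row per Franz-cell observation:
a drug applied through a microneedle patch to a skin membrane, sampled
at one time point.  Columns (synonyms are mapped at read time):

    drug, skin_type (R/H), mn_type (hydrogel/plastic), mn_length (µm),
    mn_surface_area (mm²), drug_loading (µg), permeation_time (h),
    mw (Da), permeation_amount (µg/cm²), permeation_percentage (%)

The module reads/writes and validates such files, normalizes amounts
to the 1 cm² diffusion window, produces the random 7:3 train/test
split used for model fitting, and summarizes per-drug composition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "PermeationRecord",
    "SplitResult",
    "read_dataset",
    "write_dataset",
    "records_to_frame",
    "frame_to_records",
    "normalize_amount",
    "split_train_test",
    "summarize",
]

COLUMNS = (
    "drug",
    "skin_type",
    "mn_type",
    "mn_length",
    "mn_surface_area",
    "drug_loading",
    "permeation_time",
    "mw",
    "permeation_amount",
    "permeation_percentage",
)

# ranges spanned by the compiled experiments; violations warn, not fail
TIME_RANGE_H = (0.08333, 48.0)
LOADING_RANGE_UG = (50.0, 70940.0)

_SYNONYMS = {
    "drug": "drug",
    "drug name": "drug",
    "compound": "drug",
    "skin type": "skin_type",
    "skin": "skin_type",
    "mn type": "mn_type",
    "needle type": "mn_type",
    "needle_type": "mn_type",
    "mn length": "mn_length",
    "mn length (um)": "mn_length",
    "needle length": "mn_length",
    "mn surface area": "mn_surface_area",
    "mn surface area (mm2)": "mn_surface_area",
    "surface area": "mn_surface_area",
    "drug loading": "drug_loading",
    "drug loading (ug)": "drug_loading",
    "loading": "drug_loading",
    "permeation time": "permeation_time",
    "permeation time (hr)": "permeation_time",
    "time": "permeation_time",
    "time (hr)": "permeation_time",
    "mw": "mw",
    "mw (da)": "mw",
    "molecular weight": "mw",
    "permeation amount": "permeation_amount",
    "cumulative permeation amount": "permeation_amount",
    "amount": "permeation_amount",
    "permeation percentage": "permeation_percentage",
    "cumulative permeation percentage": "permeation_percentage",
    "percentage": "permeation_percentage",
}

_MN_TYPE_MAP = {"hydrogel": "hydrogel", "plastic": "plastic", "solid": "plastic"}
_SKIN_TYPES = ("R", "H")


@dataclass
class PermeationRecord:
    drug: str
    skin_type: str  # "R" rat, "H" human
    mn_type: str  # "hydrogel" or "plastic"
    mn_length: float  # µm
    mn_surface_area: float  # mm², whole patch
    drug_loading: float  # µg
    permeation_time: float  # h
    mw: float  # Da
    permeation_amount: Optional[float] = None  # µg per cm²
    permeation_percentage: Optional[float] = None  # %
    flagged: bool = False  # percentage > 100 or out-of-range inputs

    def __post_init__(self) -> None:
        if self.skin_type not in _SKIN_TYPES:
            raise ValueError(f"skin_type must be one of {_SKIN_TYPES}")
        if self.mn_type not in _MN_TYPE_MAP:
            raise ValueError("mn_type must be 'hydrogel', 'plastic' or 'solid'")
        self.mn_type = _MN_TYPE_MAP[self.mn_type]
        if self.permeation_amount is not None and self.permeation_amount < 0:
            raise ValueError("permeation_amount must be non-negative")
        if self.permeation_percentage is not None and self.permeation_percentage < 0:
            raise ValueError("permeation_percentage must be non-negative")
        if self.permeation_percentage is not None and self.permeation_percentage > 100:
            self.flagged = True
        if not (TIME_RANGE_H[0] <= self.permeation_time <= TIME_RANGE_H[1]):
            warnings.warn(
                f"permeation_time {self.permeation_time} h outside "
                f"{TIME_RANGE_H}", stacklevel=2
            )
        if not (LOADING_RANGE_UG[0] <= self.drug_loading <= LOADING_RANGE_UG[1]):
            warnings.warn(
                f"drug_loading {self.drug_loading} µg outside "
                f"{LOADING_RANGE_UG}", stacklevel=2
            )


@dataclass
class SplitResult:
    train: List[PermeationRecord]
    test: List[PermeationRecord]
    seed: int
    ratio: float


def _canonical_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _SYNONYMS:
            mapping[col] = _SYNONYMS[key]
        elif key in COLUMNS:
            mapping[col] = key
    df = df.rename(columns=mapping)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required column(s): {missing}")
    return df


def frame_to_records(df: pd.DataFrame) -> List[PermeationRecord]:
    df = _canonical_columns(df)
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                PermeationRecord(
                    drug=str(row["drug"]),
                    skin_type=str(row["skin_type"]).strip(),
                    mn_type=str(row["mn_type"]).strip().lower(),
                    mn_length=float(row["mn_length"]),
                    mn_surface_area=float(row["mn_surface_area"]),
                    drug_loading=float(row["drug_loading"]),
                    permeation_time=float(row["permeation_time"]),
                    mw=float(row["mw"]),
                    permeation_amount=(
                        None if pd.isna(row["permeation_amount"])
                        else float(row["permeation_amount"])
                    ),
                    permeation_percentage=(
                        None if pd.isna(row["permeation_percentage"])
                        else float(row["permeation_percentage"])
                    ),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
    return records


def records_to_frame(records: Sequence[PermeationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        d.pop("flagged")
        rows.append(d)
    return pd.DataFrame(rows, columns=list(COLUMNS))


def read_dataset(path) -> List[PermeationRecord]:
    """Read and validate a permeation CSV; row order is preserved."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"dataset {path} contains no rows")
    return frame_to_records(df)


def write_dataset(records: Sequence[PermeationRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def normalize_amount(amount: float, device: str) -> float:
    """Normalize a cumulative amount to µg per 1 cm² of diffusion window.

    The vertical Franz device has a 1.00 cm² window, the horizontal
    device 1.13 cm².
    """
    from .diffusion import WINDOW_AREA_CM2

    if amount < 0:
        raise ValueError("amount must be non-negative")
    if device not in WINDOW_AREA_CM2:
        raise ValueError(f"unknown device: {device!r}")
    return amount / WINDOW_AREA_CM2[device]


def split_train_test(
    records: Sequence[PermeationRecord],
    ratio: float = 0.7,
    seed: int = 0,
) -> SplitResult:
    """Uniform random train/test partition (7:3 by default).

    Train size is round-half-up of ratio·N for reproducibility.
    """
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must be in (0, 1)")
    n_train = int(math.floor(ratio * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = set(perm[:n_train].tolist())
    train = [r for i, r in enumerate(records) if i in train_idx]
    test = [r for i, r in enumerate(records) if i not in train_idx]
    return SplitResult(train=train, test=test, seed=seed, ratio=ratio)


def summarize(records: Sequence[PermeationRecord]) -> Dict[str, Tuple[int, int]]:
    """Per-drug counts and integer percentage shares of the dataset."""
    if not records:
        raise ValueError("no records to summarize")
    n = len(records)
    counts: Dict[str, int] = {}
    for r in records:
        counts[r.drug] = counts.get(r.drug, 0) + 1
    return {
        drug: (c, int(round(100.0 * c / n)))
        for drug, c in sorted(counts.items(), key=lambda kv: -kv[1])
    }
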