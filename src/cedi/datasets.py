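"""Measurement sets of one scalar space-time variable and their scaled frame.

The workflow operates on scattered records ``(b, x1, x2, x3, t)`` — a biomass
value in grams at a position in meters and a time in years.  All fitting is
done in a dimensionless frame where the field is divided by its standard
deviation and the coordinates are centred and divided by theirs:

    B = b / sigma_b,   tau = (t - t_bar) / sigma_t,   xi_i = (x_i - xbar_i) / sigma_i

Population standard deviations (divide by n) are used throughout.  The field
itself is scaled but deliberately not centred, while the coordinates are both
centred and scaled; the asymmetry matters when converting identified
coefficients back to physical units.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementSet",
    "ScalingParams",
    "ScaledDataset",
    "load_measurements",
    "save_measurements",
    "compute_scaling",
    "apply_scaling",
    "invert_scaling",
]

CSV_COLUMNS = ("x1", "x2", "x3", "t", "b")


class ValidationError(ValueError):
    """A measurement set violates an invariant (negative or non-finite values)."""


class FormatError(ValueError):
    """A file does not follow the expected on-disk layout."""


class DegenerateDataError(ValueError):
    """A field needed for scaling is constant (zero standard deviation)."""


@dataclasses.dataclass(frozen=True)
class MeasurementSet:
    """Scattered measurements of a scalar field b(x, t).

    Parameters
    ----------
    b : array of shape (p,)
        Field values (biomass), grams; must be finite and non-negative.
    x : array of shape (p, 3)
        Positions, meters.
    t : array of shape (p,)
        Times, years.
    domain : ((3,2) array, (2,) array), optional
        Spatial bounding box Omega (rows are axes, columns lo/hi) and time
        span.  Defaults to the data bounding box.  The physical boundary
        condition b = 0 on the box boundary is metadata only; nothing
        enforces it.
    label : str
        Free-text provenance tag.
    """

    b: np.ndarray
    x: np.ndarray
    t: np.ndarray
    domain: tuple[np.ndarray, np.ndarray] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        x = np.asarray(self.x, dtype=float)
        t = np.asarray(self.t, dtype=float)
        if b.ndim != 1 or b.size < 1:
            raise ValidationError("measurement set must contain at least one record")
        if x.shape != (b.size, 3) or t.shape != (b.size,):
            raise ValidationError(
                f"shape mismatch: b {b.shape}, x {x.shape}, t {t.shape}"
            )
        bad = ~np.isfinite(b) | ~np.isfinite(t) | ~np.isfinite(x).all(axis=1)
        if bad.any():
            raise ValidationError(
                f"non-finite values in rows {np.flatnonzero(bad).tolist()}"
            )
        neg = b < 0
        if neg.any():
            raise ValidationError(
                f"negative field values in rows {np.flatnonzero(neg).tolist()}"
            )
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "t", t)
        if self.domain is None:
            box = np.column_stack([x.min(axis=0), x.max(axis=0)])
            span = np.array([t.min(), t.max()])
            object.__setattr__(self, "domain", (box, span))
        else:
            box, span = self.domain
            object.__setattr__(
                self, "domain", (np.asarray(box, float), np.asarray(span, float))
            )

    @property
    def p(self) -> int:
        """Number of records."""
        return self.b.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x1": self.x[:, 0],
                "x2": self.x[:, 1],
                "x3": self.x[:, 2],
                "t": self.t,
                "b": self.b,
            }
        )


@dataclasses.dataclass(frozen=True)
class ScalingParams:
    """Means and population standard deviations defining the scaled frame."""

    sigma_b: float
    t_bar: float
    sigma_t: float
    x_bar: np.ndarray
    sigma_x: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_bar", np.asarray(self.x_bar, float))
        object.__setattr__(self, "sigma_x", np.asarray(self.sigma_x, float))
        if not (self.sigma_b > 0 and self.sigma_t > 0 and (self.sigma_x > 0).all()):
            raise DegenerateDataError("all scaling standard deviations must be > 0")

    @classmethod
    def identity(cls) -> "ScalingParams":
        return cls(1.0, 0.0, 1.0, np.zeros(3), np.ones(3))


@dataclasses.dataclass(frozen=True)
class ScaledDataset:
    """A measurement set expressed in the dimensionless (B, xi, tau) frame."""

    B: np.ndarray
    xi: np.ndarray
    tau: np.ndarray
    scaling: ScalingParams

    @property
    def p(self) -> int:
        return self.B.size

    def points(self) -> np.ndarray:
        """Collocation-point array of shape (p, 4): columns xi1, xi2, xi3, tau."""
        return np.column_stack([self.xi, self.tau])


def load_measurements(path: str | Path, format: str | None = None) -> MeasurementSet:
    """Read a measurement set from csv (header x1,x2,x3,t,b) or npz (p x 5 ``data``)."""
    path = Path(path)
    if format is None:
        format = "npz" if path.suffix == ".npz" else "csv"
    if format == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"{path}: empty file") from exc
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        if len(df) == 0:
            raise FormatError(f"{path}: no data rows")
        arr = df[list(CSV_COLUMNS)].to_numpy(dtype=float)
    elif format == "npz":
        with np.load(path) as f:
            if "data" not in f:
                raise FormatError(f"{path}: npz container must hold array 'data'")
            arr = np.asarray(f["data"], dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 5 or arr.shape[0] == 0:
            raise FormatError(f"{path}: 'data' must be a non-empty p x 5 array")
    else:
        raise FormatError(f"unknown format {format!r}")
    return MeasurementSet(
        b=arr[:, 4], x=arr[:, :3], t=arr[:, 3], label=str(path)
    )


def save_measurements(ms: MeasurementSet, path: str | Path, format: str | None = None) -> None:
    """Write a measurement set in the csv dialect or the npz container."""
    path = Path(path)
    if format is None:
        format = "npz" if path.suffix == ".npz" else "csv"
    if format == "csv":
        ms.to_frame().to_csv(path, index=False)
    elif format == "npz":
        data = np.column_stack([ms.x, ms.t, ms.b])
        np.savez(path, data=data)
    else:
        raise FormatError(f"unknown format {format!r}")


def _pop_std(v: np.ndarray) -> float:
    return float(np.std(v))  # numpy default ddof=0: population convention


def compute_scaling(ms: MeasurementSet) -> ScalingParams:
    """Means and population stds of a measurement set; errors on constant fields."""
    if ms.p < 2:
        raise DegenerateDataError("need at least 2 records to compute scaling")
    names = ["b", "x1", "x2", "x3", "t"]
    cols = [ms.b, ms.x[:, 0], ms.x[:, 1], ms.x[:, 2], ms.t]
    for name, col in zip(names, cols):
        if _pop_std(col) == 0.0:
            raise DegenerateDataError(f"field {name!r} is constant; cannot scale")
    return ScalingParams(
        sigma_b=_pop_std(ms.b),
        t_bar=float(ms.t.mean()),
        sigma_t=_pop_std(ms.t),
        x_bar=ms.x.mean(axis=0),
        sigma_x=ms.x.std(axis=0),
    )


def apply_scaling(ms: MeasurementSet, sp: ScalingParams) -> ScaledDataset:
    """Map records into the dimensionless frame: B = b/sigma_b, centred/scaled coords."""
    return ScaledDataset(
        B=ms.b / sp.sigma_b,
        xi=(ms.x - sp.x_bar) / sp.sigma_x,
        tau=(ms.t - sp.t_bar) / sp.sigma_t,
        scaling=sp,
    )


def invert_scaling(sd: ScaledDataset, label: str = "") -> MeasurementSet:
    """Map a scaled dataset back to physical units using its stored scaling."""
    sp = sd.scaling
    return MeasurementSet(
        b=sd.B * sp.sigma_b,
        x=sd.xi * sp.sigma_x + sp.x_bar,
        t=sd.tau * sp.sigma_t + sp.t_bar,
        label=label,
    )
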