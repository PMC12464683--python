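"""Candidate-term catalogues, term libraries, and coefficient scale conversions.

A catalogue is an ordered list of candidate right-hand-side terms for the
sought PDE; the identification step assigns each a weight.  The four default
catalogues express transport either in Cartesian or cylindrical coordinates:

    I   : B, dB/dxi3, Laplacian-sum                 -> rho, v3, d
    II  : B, dB/dxi1, dB/dxi2, dB/dxi3, Laplacian   -> rho, v1, v2, v3, d
    III : B, dB/dr, dB/dxi3, Laplacian              -> rho, vr, v3, d
    IV  : B, dB/dr, (1/r) dB/dtheta, dB/dxi3, Lapl. -> rho, vr, vtheta, v3, d

The identification layer learns raw weights w in  dB/dtau = sum_i w_i term_i.
Reported coefficients follow the advection-reaction-diffusion sign convention
db/dt = rho b - v . grad b + d Lap b, i.e. v = -w for first-derivative terms
and rho = w, d = w otherwise, so a crown rising along +xi3 yields a positive
vertical velocity.

Three coefficient scales coexist and are all carried around:

* ``beta_star``     — on the normalized library (unit-variance columns);
* ``beta_scaled``   — on the dimensionless (B, xi, tau) variables;
* ``beta_physical`` — in physical units (rho [1/y], v [m/y], d [m^2/y]),
  recovered by chain rule from the scaling parameters.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .datasets import ScalingParams
from .differentiation import DerivativeTable

__all__ = [
    "CandidateTerm",
    "Catalogue",
    "TermLibrary",
    "CoefficientSet",
    "standard_catalogue",
    "build_library",
    "normalize_library",
    "denormalize_weights",
    "to_physical_units",
    "make_coefficient_set",
]


class DegenerateTermError(ValueError):
    """A catalogue column has (numerically) zero variance and cannot be normalized."""


class AnisotropicScalingWarning(UserWarning):
    """Spatial scaling sigmas differ enough to distort cylindrical/isotropic terms."""


@dataclasses.dataclass(frozen=True)
class CandidateTerm:
    """One candidate right-hand-side term.

    ``sign`` maps the learned raw weight to the reported coefficient
    (-1 for transport terms, +1 for reaction and diffusion).
    """

    label: str            # weight name: rho, v1, v2, v3, vr, vtheta, d
    term_key: str         # column of the DerivativeTable holding the values
    kind: str             # field | cartesian_derivative | radial_derivative |
                          # angular_derivative | laplacian_sum
    sign: float = 1.0


_TERMS = {
    "rho": CandidateTerm("rho", "B", "field", +1.0),
    "v1": CandidateTerm("v1", "dB_dxi1", "cartesian_derivative", -1.0),
    "v2": CandidateTerm("v2", "dB_dxi2", "cartesian_derivative", -1.0),
    "v3": CandidateTerm("v3", "dB_dxi3", "cartesian_derivative", -1.0),
    "vr": CandidateTerm("vr", "dB_dr", "radial_derivative", -1.0),
    "vtheta": CandidateTerm("vtheta", "dB_dtheta_over_r", "angular_derivative", -1.0),
    "d": CandidateTerm("d", "laplacian", "laplacian_sum", +1.0),
}

_STANDARD = {
    "I": ("rho", "v3", "d"),
    "II": ("rho", "v1", "v2", "v3", "d"),
    "III": ("rho", "vr", "v3", "d"),
    "IV": ("rho", "vr", "vtheta", "v3", "d"),
}
# accept unicode Roman numerals as aliases
_ALIASES = {"Ⅰ": "I", "Ⅱ": "II", "Ⅲ": "III", "Ⅳ": "IV"}


@dataclasses.dataclass(frozen=True)
class Catalogue:
    id: str
    terms: tuple[CandidateTerm, ...]

    def __post_init__(self) -> None:
        labels = [t.label for t in self.terms]
        if len(set(labels)) != len(labels):
            raise ValueError("term labels must be unique within a catalogue")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terms)

    @property
    def n(self) -> int:
        return len(self.terms)

    def needed_keys(self) -> set[str]:
        return {t.term_key for t in self.terms}

    def uses_cylindrical(self) -> bool:
        return any(t.kind in ("radial_derivative", "angular_derivative") for t in self.terms)


def standard_catalogue(id: str) -> Catalogue:
    """One of the four default catalogues, selected by Roman numeral I..IV."""
    key = _ALIASES.get(str(id), str(id)).upper()
    if key not in _STANDARD:
        raise KeyError(f"unknown catalogue {id!r}; choose from I, II, III, IV")
    return Catalogue(id=key, terms=tuple(_TERMS[l] for l in _STANDARD[key]))


def custom_catalogue(labels: Sequence[str]) -> Catalogue:
    """A catalogue from a list of standard weight labels, in the given order."""
    return Catalogue(id="custom", terms=tuple(_TERMS[l] for l in labels))


@dataclasses.dataclass(frozen=True)
class TermLibrary:
    """Matrix of candidate-term values X (q x n) and target Y = dB/dtau (q,).

    ``X_star``/``Y_star`` are the column-normalized copies (each divided by
    its population standard deviation) the identification step trains on.
    Rows masked out by the near-axis rule are already dropped.
    """

    catalogue: Catalogue
    X: np.ndarray
    Y: np.ndarray
    points: np.ndarray
    sigma_X: np.ndarray | None = None
    sigma_Y: float | None = None
    X_star: np.ndarray | None = None
    Y_star: np.ndarray | None = None

    @property
    def q(self) -> int:
        return self.Y.size

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @property
    def normalized(self) -> bool:
        return self.X_star is not None


def build_library(
    table: DerivativeTable, cat: Catalogue, normalize: bool = True
) -> TermLibrary:
    """Assemble the library from a derivative table, in catalogue column order.

    Cylindrical catalogues drop near-axis rows from X, Y and points alike.
    """
    missing = [k for k in cat.needed_keys() if k not in table]
    if missing:
        raise KeyError(f"derivative table lacks terms {missing} needed by catalogue {cat.id}")
    keep = table.axis_mask if cat.uses_cylindrical() else slice(None)
    X = np.column_stack([table[t.term_key][keep] for t in cat.terms])
    lib = TermLibrary(
        catalogue=cat, X=X, Y=table.dB_dtau[keep], points=table.points[keep]
    )
    return normalize_library(lib) if normalize else lib


def normalize_library(lib: TermLibrary) -> TermLibrary:
    """Divide Y and every X column by its population std; originals retained."""
    sigma_Y = float(np.std(lib.Y))
    sigma_X = np.std(lib.X, axis=0)
    scale = np.maximum(1.0, np.abs(lib.X).max(axis=0, initial=0.0))
    for j, (s, sc) in enumerate(zip(sigma_X, scale)):
        if s <= 1e-10 * sc:
            raise DegenerateTermError(
                f"term {lib.catalogue.labels[j]!r} has zero variance; "
                "remove it from the catalogue"
            )
    if sigma_Y == 0.0:
        raise DegenerateTermError("target dB/dtau has zero variance")
    return dataclasses.replace(
        lib,
        sigma_X=sigma_X,
        sigma_Y=sigma_Y,
        X_star=lib.X / sigma_X,
        Y_star=lib.Y / sigma_Y,
    )


def denormalize_weights(beta_star: np.ndarray, lib: TermLibrary) -> np.ndarray:
    """Map weights from the normalized library to the (B, xi, tau) scale:
    beta_scaled_i = beta_star_i * sigma_Y / sigma_X_i."""
    beta_star = np.asarray(beta_star, float)
    if not lib.normalized:
        raise ValueError("library is not normalized")
    if beta_star.shape != (lib.n,):
        raise ValueError("weight vector length does not match the catalogue")
    return beta_star * lib.sigma_Y / lib.sigma_X


def _check_isotropy(sp: ScalingParams, what: str) -> None:
    s = sp.sigma_x
    if s.max() > 1.1 * s.min():
        warnings.warn(
            f"spatial scaling sigmas {s} differ by more than 10%; the physical "
            f"conversion of {what} assumes near-isotropic scaling",
            AnisotropicScalingWarning,
            stacklevel=3,
        )


def to_physical_units(
    beta_scaled: np.ndarray, sp: ScalingParams, cat: Catalogue
) -> np.ndarray:
    """Convert scaled-frame coefficients to physical units by chain rule.

    With b = sigma_b B, t = t_bar + sigma_t tau, x_i = xbar_i + sigma_i xi_i:
    rho_phys = rho_scaled / sigma_t; v_phys,i = v_scaled,i sigma_i / sigma_t;
    d_phys = d_scaled mean(sigma_i^2) / sigma_t.  Radial/angular velocities
    use sigma_1 = sigma_2 (warned if anisotropic); the single isotropic
    Laplacian weight uses the mean squared sigma for the same reason.
    """
    beta_scaled = np.asarray(beta_scaled, float)
    out = np.empty_like(beta_scaled)
    for j, term in enumerate(cat.terms):
        if term.kind == "field":
            out[j] = beta_scaled[j] / sp.sigma_t
        elif term.kind == "cartesian_derivative":
            axis = {"v1": 0, "v2": 1, "v3": 2}[term.label]
            out[j] = beta_scaled[j] * sp.sigma_x[axis] / sp.sigma_t
        elif term.kind in ("radial_derivative", "angular_derivative"):
            _check_isotropy(sp, term.label)
            out[j] = beta_scaled[j] * sp.sigma_x[0] / sp.sigma_t
        elif term.kind == "laplacian_sum":
            _check_isotropy(sp, "the isotropic diffusion weight")
            out[j] = beta_scaled[j] * float(np.mean(sp.sigma_x**2)) / sp.sigma_t
        else:  # pragma: no cover - enumeration is closed
            raise ValueError(f"unknown term kind {term.kind!r}")
    return out


def save_library(lib: TermLibrary, path) -> None:
    """Serialize a term library (with its sigma metadata) to one npz archive."""
    payload = dict(
        X=lib.X,
        Y=lib.Y,
        points=lib.points,
        labels=np.array(lib.catalogue.labels),
        catalogue_id=np.array(lib.catalogue.id),
    )
    if lib.normalized:
        payload.update(sigma_X=lib.sigma_X, sigma_Y=np.array(lib.sigma_Y))
    np.savez(path, **payload)


def load_library(path) -> TermLibrary:
    with np.load(path) as f:
        cid = str(f["catalogue_id"])
        labels = [str(l) for l in f["labels"]]
        cat = (
            standard_catalogue(cid) if cid in _STANDARD else custom_catalogue(labels)
        )
        lib = TermLibrary(catalogue=cat, X=f["X"], Y=f["Y"], points=f["points"])
        if "sigma_X" in f:
            lib = dataclasses.replace(
                lib,
                sigma_X=f["sigma_X"],
                sigma_Y=float(f["sigma_Y"]),
                X_star=f["X"] / f["sigma_X"],
                Y_star=f["Y"] / float(f["sigma_Y"]),
            )
    return lib


@dataclasses.dataclass(frozen=True)
class CoefficientSet:
    """Identified coefficients on all three scales, plus the raw weights.

    The beta arrays carry the ADR sign convention (v = -w); ``w_star`` are
    the raw learned weights on the normalized library.
    """

    labels: tuple[str, ...]
    w_star: np.ndarray
    beta_star: np.ndarray
    beta_scaled: np.ndarray
    beta_physical: np.ndarray

    def as_dict(self, scale: str = "physical") -> dict[str, float]:
        arr = {
            "normalized": self.beta_star,
            "scaled": self.beta_scaled,
            "physical": self.beta_physical,
        }[scale]
        return {l: float(v) for l, v in zip(self.labels, arr)}


def make_coefficient_set(
    w_star: np.ndarray, lib: TermLibrary, sp: ScalingParams
) -> CoefficientSet:
    """Raw normalized-scale weights -> coefficients on all three scales."""
    w_star = np.asarray(w_star, float)
    signs = np.array([t.sign for t in lib.catalogue.terms])
    w_scaled = denormalize_weights(w_star, lib)
    return CoefficientSet(
        labels=lib.catalogue.labels,
        w_star=w_star,
        beta_star=signs * w_star,
        beta_scaled=signs * w_scaled,
        beta_physical=to_physical_units(signs * w_scaled, sp, lib.catalogue),
    )
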