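"""Partial derivatives of the surrogate at collocation points.

Derivatives are taken with respect to the SCALED variables (xi1, xi2, xi3,
tau); conversion to physical units happens only when identified coefficients
are converted (see :mod:`cedi.catalogue`).  Besides the Cartesian pure
derivatives up to second order, the cylindrical pair (dB/dr, (1/r) dB/dtheta)
about the vertical axis through the scaled-frame origin is obtained by chain
rule from the Cartesian gradient — the trees motivating the default
catalogues are roughly axially symmetric about the vertical axis, and scaling
centres the coordinates on the data centroid.

A central finite-difference oracle is included purely for validation of the
exact derivatives.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from .surrogate import CapabilityError, SurrogateModel

__all__ = [
    "TERM_KEYS",
    "DerivativeTable",
    "partial_derivative",
    "cylindrical_derivatives",
    "finite_difference_oracle",
    "build_derivative_table",
]

AXIS_EPS = 1e-8  # points with cylindrical radius below this are masked out

# canonical names for every quantity the default catalogues can request
TERM_KEYS = (
    "B",
    "dB_dxi1",
    "dB_dxi2",
    "dB_dxi3",
    "d2B_dxi1",
    "d2B_dxi2",
    "d2B_dxi3",
    "laplacian",
    "dB_dr",
    "dB_dtheta_over_r",
)

_CARTESIAN = {
    "B": ((0, 0, 0), 0),
    "dB_dxi1": ((1, 0, 0), 0),
    "dB_dxi2": ((0, 1, 0), 0),
    "dB_dxi3": ((0, 0, 1), 0),
    "d2B_dxi1": ((2, 0, 0), 0),
    "d2B_dxi2": ((0, 2, 0), 0),
    "d2B_dxi3": ((0, 0, 2), 0),
}


@dataclasses.dataclass(frozen=True)
class DerivativeTable:
    """Requested derivative arrays at a common set of collocation points.

    ``dB_dtau`` is always present (it is the identification target).
    ``axis_mask`` is True where the point is usable for cylindrical terms
    (radius >= AXIS_EPS); Cartesian terms are valid everywhere.
    """

    points: np.ndarray
    dB_dtau: np.ndarray
    terms: Mapping[str, np.ndarray]
    axis_mask: np.ndarray

    def __getitem__(self, key: str) -> np.ndarray:
        return self.terms[key]

    def __contains__(self, key: str) -> bool:
        return key in self.terms


def _axis_order(gamma: Sequence[int], wrt_time: int) -> tuple[int, int]:
    """Map a multi-index + time flag to (axis, order); rejects mixed derivatives."""
    gamma = tuple(int(g) for g in gamma)
    if len(gamma) != 3 or any(g < 0 for g in gamma) or wrt_time not in (0, 1):
        raise ValueError(f"bad multi-index {gamma} / wrt_time {wrt_time}")
    k = sum(gamma) + wrt_time
    if k == 0:
        return 0, 0
    nonzero = [i for i, g in enumerate(gamma) if g > 0]
    if wrt_time:
        if nonzero:
            raise CapabilityError("mixed space-time derivatives are not supported")
        return 3, 1
    if len(nonzero) != 1:
        raise CapabilityError("mixed spatial derivatives are not supported")
    axis = nonzero[0]
    if gamma[axis] > 2:
        raise CapabilityError("derivative order above 2 is not supported")
    return axis, gamma[axis]


def partial_derivative(
    model: SurrogateModel,
    points: np.ndarray,
    gamma: Sequence[int] = (0, 0, 0),
    wrt_time: int = 0,
) -> np.ndarray:
    """Pure partial derivative of the surrogate at the given scaled points.

    ``gamma`` is the spatial multi-index (gamma1, gamma2, gamma3); ``wrt_time``
    adds one tau-derivative.  Exactness: closed form for the analytic oracle,
    forward-mode exact for the network.
    """
    axis, order = _axis_order(gamma, wrt_time)
    return model.input_derivative(np.atleast_2d(np.asarray(points, float)), axis, order)


def cylindrical_derivatives(
    grad: tuple[np.ndarray, np.ndarray],
    points: np.ndarray,
    axis_offset: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chain-rule map of the in-plane gradient to (dB/dr, (1/r) dB/dtheta).

    The cylindrical axis is vertical through the scaled-frame origin (the
    data centroid); ``axis_offset`` shifts it in the (xi1, xi2) plane for
    off-centre trunks.  With theta = atan2(xi2, xi1) about that axis:

        dB/dr           =  cos(theta) dB/dxi1 + sin(theta) dB/dxi2
        (1/r) dB/dtheta = -sin(theta) dB/dxi1 + cos(theta) dB/dxi2

    Returns ``(dB_dr, dB_dtheta_over_r, mask)`` where ``mask`` is False at
    near-axis points (r < AXIS_EPS); values there are set to NaN and must be
    excluded from any catalogue using cylindrical terms.
    """
    points = np.atleast_2d(np.asarray(points, float))
    g1, g2 = (np.asarray(g, float) for g in grad)
    x1, x2 = points[:, 0] - axis_offset[0], points[:, 1] - axis_offset[1]
    r = np.hypot(x1, x2)
    mask = r >= AXIS_EPS
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(mask, x1 / r, np.nan)
        s = np.where(mask, x2 / r, np.nan)
    return c * g1 + s * g2, -s * g1 + c * g2, mask


def finite_difference_oracle(
    f,
    points: np.ndarray,
    gamma: Sequence[int] = (0, 0, 0),
    wrt_time: int = 0,
    h: float = 1e-4,
) -> np.ndarray:
    """Second-order central-difference estimate of a pure partial derivative.

    ``f`` maps an (n, 4) array of scaled points to (n,) values.  Used as an
    independent check of the exact derivative paths; never used by the
    workflow itself.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    points = np.atleast_2d(np.asarray(points, float))
    axis, order = _axis_order(gamma, wrt_time)
    if order == 0:
        return np.asarray(f(points), float)
    e = np.zeros(4)
    e[axis] = h
    fp = np.asarray(f(points + e), float)
    fm = np.asarray(f(points - e), float)
    if order == 1:
        return (fp - fm) / (2.0 * h)
    f0 = np.asarray(f(points), float)
    return (fp - 2.0 * f0 + fm) / (h * h)


def build_derivative_table(
    model: SurrogateModel,
    points: np.ndarray,
    needed: Iterable[str] = TERM_KEYS,
    axis_offset: tuple[float, float] = (0.0, 0.0),
) -> DerivativeTable:
    """Evaluate every requested term at the collocation points in one pass.

    ``needed`` is a subset of :data:`TERM_KEYS`; the time derivative is always
    computed.  The Laplacian sum is assembled from the three pure second
    derivatives.  Cylindrical terms trigger the near-axis mask.
    """
    points = np.atleast_2d(np.asarray(points, float))
    needed = set(needed)
    unknown = needed - set(TERM_KEYS)
    if unknown:
        raise KeyError(f"unknown derivative terms {sorted(unknown)}")
    n = points.shape[0]
    terms: dict[str, np.ndarray] = {}
    mask = np.ones(n, dtype=bool)
    if n == 0:
        empty = np.empty(0)
        return DerivativeTable(points, empty, {k: empty for k in needed}, mask)

    if "laplacian" in needed:
        needed |= {"d2B_dxi1", "d2B_dxi2", "d2B_dxi3"}
    want_cyl = {"dB_dr", "dB_dtheta_over_r"} & needed
    if want_cyl:
        needed |= {"dB_dxi1", "dB_dxi2"}

    for key in sorted(needed & set(_CARTESIAN)):
        gamma, wt = _CARTESIAN[key]
        terms[key] = partial_derivative(model, points, gamma, wt)
    if "laplacian" in needed:
        terms["laplacian"] = (
            terms["d2B_dxi1"] + terms["d2B_dxi2"] + terms["d2B_dxi3"]
        )
    if want_cyl:
        dr, dth, mask = cylindrical_derivatives(
            (terms["dB_dxi1"], terms["dB_dxi2"]), points, axis_offset
        )
        terms["dB_dr"] = dr
        terms["dB_dtheta_over_r"] = dth
    dB_dtau = partial_derivative(model, points, (0, 0, 0), wrt_time=1)
    return DerivativeTable(points=points, dB_dtau=dB_dtau, terms=terms, axis_mask=mask)
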