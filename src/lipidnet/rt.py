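"""Retention-time prediction from the equivalent carbon number (ECN).

Within one lipid subclass, reversed-phase retention is governed by the
chain composition through ECN = NC - k * DB (NC: total chain carbons, DB:
total chain double bonds).  The classical k = 2 is a poor fit for
polyunsaturated phospholipids, so k is refitted per subclass by grid search:
for each candidate k the calibrants' ECNs are computed and a least-squares
curve tR = f(ECN) is fitted; the k minimizing the residual sum of squares
wins.  Phospholipid subclasses use a straight line; sphingolipid subclasses
select the lowest polynomial degree (1..3) whose R-squared exceeds 0.99,
which lands on a quadratic for typical ceramide-type calibration series.

Predicted tR supports annotation through a relative-error test: an
annotation is tR-consistent when |observed - predicted| / predicted is
within 5% (the default tolerance).

The vinyl-ether double bond of plasmalogens is not a chain unsaturation and
is excluded from DB by construction (chain double-bond counts never include
it); ``ecn`` therefore needs no special casing for ether species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from lipidnet.chem import LipidSpecies, parse_lipid_name

__all__ = ["RTModel", "CalibrationPoint", "ecn", "fit_rt_model",
           "predict_rt", "rt_consistent", "K_GRID", "R2_TOLERANCE"]

K_GRID = np.round(np.arange(0.50, 3.0001, 0.01), 2)
R2_TOLERANCE = 0.99   # lowest polynomial degree with R^2 above this wins
MAX_DEGREE = 3
RT_TOLERANCE = 0.05   # relative tR error accepted when confirming annotations


@dataclass(frozen=True)
class CalibrationPoint:
    """An authentic standard with its observed retention time (minutes)."""

    lipid: LipidSpecies
    rt: float

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError(f"retention time must be positive, got {self.rt}")


@dataclass(frozen=True)
class RTModel:
    """A fitted per-subclass ECN -> tR mapping.

    ``coefficients`` are polynomial coefficients, highest power first
    (numpy.polyval convention); ``degree`` is 1 for phospholipid subclasses.
    """

    subclass: str
    k: float
    family: str                      # "linear" | "polynomial"
    degree: int
    coefficients: tuple[float, ...]
    r_squared: float
    n_calibrants: int

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not (0 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"R^2 out of range: {self.r_squared}")
        if self.family == "linear" and self.degree != 1:
            raise ValueError("linear family implies degree 1")
        if self.degree > MAX_DEGREE:
            raise ValueError(f"degree capped at {MAX_DEGREE}")

    def predict(self, ecn_value: float) -> float:
        return float(np.polyval(self.coefficients, ecn_value))


def ecn(lipid: LipidSpecies | str, k: float) -> float:
    """Equivalent carbon number NC - k * DB.

    NC counts all chain carbons (the sphingoid base included for
    sphingolipids); DB counts chain double bonds only — head groups and the
    plasmalogen vinyl-ether bond are excluded.
    """
    if isinstance(lipid, str):
        lipid = parse_lipid_name(lipid)
    if k <= 0:
        raise ValueError("k must be positive")
    return lipid.nc - k * lipid.db


def _fit_poly(x: np.ndarray, y: np.ndarray, degree: int,
              ) -> tuple[np.ndarray, float, float]:
    """Least-squares polynomial fit; returns (coefficients, ssr, r_squared)."""
    coeffs = np.polyfit(x, y, degree)
    resid = y - np.polyval(coeffs, x)
    ssr = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - ssr / sst)
    return coeffs, ssr, min(r2, 1.0)


def _select_degree(x: np.ndarray, y: np.ndarray, family: str,
                   ) -> tuple[np.ndarray, float, float, int]:
    """Fit at a fixed k: line for phospholipids, parsimonious polynomial
    (lowest degree with R^2 > 0.99, else the best of the allowed) otherwise."""
    if family == "linear":
        coeffs, ssr, r2 = _fit_poly(x, y, 1)
        return coeffs, ssr, r2, 1
    best = None
    for degree in range(1, MAX_DEGREE + 1):
        if len(x) < degree + 2:
            break
        coeffs, ssr, r2 = _fit_poly(x, y, degree)
        if r2 > R2_TOLERANCE:
            return coeffs, ssr, r2, degree
        if best is None or r2 > best[2]:
            best = (coeffs, ssr, r2, degree)
    if best is None:
        raise ValueError("not enough calibrants for any polynomial degree")
    return best


def fit_rt_model(points: Sequence[CalibrationPoint], subclass: str,
                 family: str = "linear",
                 k_grid: np.ndarray | None = None) -> RTModel:
    """Fit the per-subclass retention model by nested grid search over k.

    For each k on the grid the calibrants' ECNs are recomputed and the
    family-appropriate least-squares fit is evaluated; the k with the
    smallest residual sum of squares is kept (ties resolve to the smaller
    k, making the fit deterministic and order-invariant).
    """
    if family not in ("linear", "polynomial"):
        raise ValueError(f"unknown model family {family!r}")
    points = list(points)
    min_points = 3 if family == "linear" else 4
    if len(points) < min_points:
        raise ValueError(
            f"need >= {min_points} calibrants for {family} fit, "
            f"got {len(points)}"
        )
    for p in points:
        if p.lipid.subclass != subclass:
            raise ValueError(
                f"calibrant {p.lipid.name} does not belong to {subclass}"
            )
    # deterministic ordering regardless of input permutation
    points = sorted(points, key=lambda p: (p.lipid.name, p.rt))
    y = np.array([p.rt for p in points])
    nc = np.array([p.lipid.nc for p in points], dtype=float)
    db = np.array([p.lipid.db for p in points], dtype=float)

    grid = K_GRID if k_grid is None else np.asarray(k_grid, dtype=float)
    best: tuple[float, float, np.ndarray, float, int] | None = None
    for k in grid:
        x = nc - k * db
        if np.ptp(x) == 0:
            continue  # degenerate design at this k
        coeffs, ssr, r2, degree = _select_degree(x, y, family)
        if best is None or ssr < best[0] - 1e-12:
            best = (ssr, float(k), coeffs, r2, degree)
    if best is None:
        raise ValueError(
            "degenerate calibration: all ECN values identical for every k"
        )
    ssr, k, coeffs, r2, degree = best
    return RTModel(subclass=subclass, k=k,
                   family=family, degree=degree,
                   coefficients=tuple(float(c) for c in coeffs),
                   r_squared=r2, n_calibrants=len(points))


def predict_rt(model: RTModel, lipid: LipidSpecies | str) -> float:
    """Predicted retention time (minutes) for a lipid of the model's
    subclass."""
    if isinstance(lipid, str):
        lipid = parse_lipid_name(lipid)
    if lipid.subclass != model.subclass:
        raise ValueError(
            f"model fitted for {model.subclass}, got {lipid.subclass}"
        )
    return model.predict(ecn(lipid, model.k))


def rt_consistent(model: RTModel, lipid: LipidSpecies | str,
                  observed_rt: float,
                  tolerance: float = RT_TOLERANCE) -> tuple[bool, float]:
    """Relative-error consistency test between observed and predicted tR.

    Returns ``(flag, relative_error)`` with
    ``relative_error = |observed - predicted| / predicted``.
    """
    predicted = predict_rt(model, lipid)
    if predicted <= 0:
        return False, float("inf")
    relative_error = abs(observed_rt - predicted) / predicted
    return relative_error <= tolerance, relative_error
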