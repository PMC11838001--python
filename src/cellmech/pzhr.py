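"""Permissive-zone-for-hair-regeneration (PZHR) area statistic.

Wound tissue supports hair-follicle neogenesis where its Young's modulus
lies in a permissive band (5-15 kPa).  Site-wise AFM stiffness measurements
along the wound's center-to-periphery axis are fitted with a second-order
polynomial ``E(x) = a x^2 + b x + c`` (x = fraction of center-periphery
distance); the crossing of the 15 kPa ceiling, ``X_15kPa``, bounds the
permissive zone, and its area as a fraction of the wound is ``A = X_15kPa^2``
(1-D fraction squared, treating the wound as geometrically similar along
both axes).  The 5 kPa floor is verified but not used to truncate, because
measured profiles stay above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SITE_FRACTIONS",
    "RigidityProfile",
    "QuadraticFit",
    "encode_sites",
    "fit_quadratic",
    "x_intercept_at",
    "pzhr_area",
    "per_animal_areas",
]

#: Canonical wound measurement sites on the normalized center->periphery axis.
SITE_FRACTIONS = {
    "center": 0.0,
    "inner_third": 0.33,
    "inner_two_thirds": 0.67,
    "periphery": 1.0,
}


@dataclass
class RigidityProfile:
    """Per-site Young's modulus observations (kPa) on the normalized axis."""

    data: pd.DataFrame  # columns: x, E_kPa, animal_id

    def __post_init__(self) -> None:
        required = {"x", "E_kPa"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"profile needs columns {sorted(required)}")
        if "animal_id" not in self.data.columns:
            self.data = self.data.assign(animal_id="pooled")
        x = self.data["x"].to_numpy(dtype=float)
        if np.any((x < 0) | (x > 1)):
            raise ValueError("x must lie in [0, 1]")
        if np.any(self.data["E_kPa"].to_numpy(dtype=float) <= 0):
            raise ValueError("E must be > 0")


@dataclass
class QuadraticFit:
    a: float
    b: float
    c: float
    r_squared: float
    X_15kPa: Optional[float] = None
    pzhr_area: Optional[float] = None

    def evaluate(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * x**2 + self.b * x + self.c


def encode_sites(labels: Iterable[str]) -> np.ndarray:
    """Map site labels to fractions of the center-periphery distance."""
    out = []
    for lab in labels:
        key = str(lab).strip().lower()
        if key not in SITE_FRACTIONS:
            raise ValueError(
                f"unknown site label {lab!r}; expected one of {sorted(SITE_FRACTIONS)}"
            )
        out.append(SITE_FRACTIONS[key])
    return np.asarray(out)


def fit_quadratic(profile: RigidityProfile) -> QuadraticFit:
    """Ordinary least-squares second-order polynomial fit of E(x)."""
    x = profile.data["x"].to_numpy(dtype=float)
    E = profile.data["E_kPa"].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("underdetermined: need >= 3 distinct x values")
    coeffs = np.polyfit(x, E, 2)
    pred = np.polyval(coeffs, x)
    ss_res = float(np.sum((E - pred) ** 2))
    ss_tot = float(np.sum((E - np.mean(E)) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return QuadraticFit(a=float(coeffs[0]), b=float(coeffs[1]), c=float(coeffs[2]),
                        r_squared=min(r2, 1.0))


def x_intercept_at(fit: QuadraticFit, level: float = 15.0) -> float:
    """Smallest x in [0, 1] where the fitted profile crosses ``level`` (kPa).

    Conventions: if the profile already meets the level at the center
    (E(0) >= level) the intercept is 0; if it stays below the level across
    the whole axis the intercept is 1 (entire wound permissive).
    """
    if fit.evaluate(0.0) >= level:
        return 0.0
    # roots of a x^2 + b x + (c - level) = 0
    roots = np.roots([fit.a, fit.b, fit.c - level]) if fit.a != 0 else (
        np.array([(level - fit.c) / fit.b]) if fit.b != 0 else np.array([])
    )
    real = np.sort([r.real for r in np.atleast_1d(roots)
                    if abs(np.imag(r)) < 1e-9 and 0.0 <= r.real <= 1.0])
    if len(real) == 0:
        # continuous quadratic below level at x=0 with no crossing in [0,1]
        assert np.all(fit.evaluate(np.linspace(0, 1, 101)) < level + 1e-9), \
            "quadratic crosses the level without a real root in [0,1]"
        return 1.0
    return float(real[0])


def pzhr_area(
    fit: QuadraticFit, lower_level: float = 5.0, upper_level: float = 15.0
) -> dict:
    """PZHR area fraction ``A = X_upper^2`` with the 5 kPa floor check.

    If the fitted profile dips below ``lower_level`` anywhere inside the
    permissive zone, a warning is raised and a band-restricted area (region
    with lower <= E <= upper) is reported alongside the headline statistic.
    """
    X = x_intercept_at(fit, upper_level)
    area = X**2
    xs = np.linspace(0.0, X, 201) if X > 0 else np.array([0.0])
    below = fit.evaluate(xs) < lower_level
    result = {"X_upper": X, "area": area, "band_area": area,
              "floor_violated": bool(below.any())}
    if below.any():
        warnings.warn(
            f"fitted E drops below {lower_level} kPa inside the permissive zone; "
            "headline area retains the upper-intercept rule"
        )
        in_band = ~below
        frac_in_band = in_band.mean() if X > 0 else 0.0
        result["band_area"] = (X * float(frac_in_band)) ** 2
    fit.X_15kPa = X
    fit.pzhr_area = area
    return result


def per_animal_areas(
    profile: RigidityProfile,
    level: float = 15.0,
    lower_level: float = 5.0,
    pooled: bool = False,
) -> pd.DataFrame:
    """Fit per animal (default) or pooled, returning one row per fit.

    Columns: animal_id, a, b, c, r_squared, X, area.
    """
    groups = (
        [("pooled", profile.data)] if pooled
        else list(profile.data.groupby("animal_id"))
    )
    rows = []
    for animal, sub in groups:
        fit = fit_quadratic(RigidityProfile(sub.reset_index(drop=True)))
        res = pzhr_area(fit, lower_level=lower_level, upper_level=level)
        rows.append({"animal_id": animal, "a": fit.a, "b": fit.b, "c": fit.c,
                     "r_squared": fit.r_squared, "X": res["X_upper"],
                     "area": res["area"]})
    return pd.DataFrame(rows)
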