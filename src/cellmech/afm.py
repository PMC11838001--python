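"""AFM force-curve contact mechanics.

Extraction of Young's modulus from force-distance curves using two elastic
contact models:

* sphere with DMT adhesion — ``P = 4 E sqrt(R) / (3 (1 - nu^2)) * delta^(3/2)
  - 2 pi gamma R``, i.e. the Hertz sphere response minus a constant work-of-
  adhesion term (Derjaguin-Muller-Toporov limit of the Maugis transition);
* cone (Sneddon) — ``P = 2 E tan(theta) / (pi (1 - nu^2)) * delta^2``.

The fit window runs from the contact point (first sustained force elevation
above the pre-contact baseline) to the transition point (where the trigger
force is met and the cantilever retracts).  Indentation is the piezo travel
past contact corrected for cantilever deflection, ``delta = (z - z_c) - P/k``.

All quantities are SI internally (m, N, Pa); readers/writers convert common
AFM units (um, nm, nN, kPa).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ProbeGeometry",
    "ForceCurve",
    "ContactFitResult",
    "ForceMap",
    "eval_sphere_dmt",
    "eval_cone",
    "find_contact_point",
    "compute_indentation",
    "fit_contact_model",
    "fit_force_map",
    "summarize_force_map",
    "QCFlag",
]

#: Maximum acceptable indentation-to-thickness ratio before the measurement
#: is considered contaminated by the rigid support underneath the sample.
MAX_INDENTATION_FRACTION = 0.2


@dataclass(frozen=True)
class ProbeGeometry:
    """AFM probe description.

    Parameters
    ----------
    kind
        ``"sphere"`` (colloidal probe, apex radius ``R``) or ``"cone"``
        (sharp/nanoneedle probe, half angle ``theta``).
    R
        Apex radius in m (sphere only).
    theta
        Half angle in radians (cone only).
    spring_constant
        Cantilever spring constant k in N/m.
    """

    kind: Literal["sphere", "cone"]
    spring_constant: float
    R: Optional[float] = None
    theta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "cone"):
            raise ValueError(
                f"unsupported probe kind {self.kind!r}: supported kinds are "
                "'sphere' and 'cone'"
            )
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if self.kind == "sphere":
            if self.R is None or self.R <= 0:
                raise ValueError("sphere probe requires apex radius R > 0")
            if self.theta is not None:
                raise ValueError("sphere probe must not set theta")
        else:
            if self.theta is None or not (0 < self.theta < math.pi / 2):
                raise ValueError("cone probe requires half angle 0 < theta < pi/2")
            if self.R is not None:
                raise ValueError("cone probe must not set R")


@dataclass
class ForceCurve:
    """A single force-distance curve.

    ``z`` is the piezo position along the approach axis (m), increasing toward
    the sample; ``force`` is the calibrated cantilever load (N).  The retract
    segment is optional and unused by the contact-model fit.
    """

    z: np.ndarray
    force: np.ndarray
    probe: ProbeGeometry
    trigger_force: float
    tip_velocity: Optional[float] = None
    sample_thickness: Optional[float] = None
    site_label: str = ""
    retract_z: Optional[np.ndarray] = None
    retract_force: Optional[np.ndarray] = None
    #: ground-truth parameters when the curve is synthetic
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.z.shape != self.force.shape or self.z.ndim != 1:
            raise ValueError("z and force must be matching 1-D arrays")
        if not (np.all(np.isfinite(self.z)) and np.all(np.isfinite(self.force))):
            raise ValueError("curve samples must be finite")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("approach must be ordered by strictly advancing z")
        if self.trigger_force <= 0:
            raise ValueError("trigger_force must be > 0")


class QCFlag:
    """Reasons a curve/fit may be excluded from summaries."""

    EXCESS_INDENTATION = "indentation exceeds 20% of sample thickness"
    NO_CONTACT = "no contact detected"
    INSUFFICIENT_DATA = "insufficient contact data"


@dataclass
class ContactFitResult:
    """Result of fitting a contact model to one curve."""

    E: float
    gamma: float
    nu: float
    contact_point: float
    transition_point: float
    max_indentation: float
    r_squared: float
    model: Literal["sphere_dmt", "cone"]
    indentation_fraction: Optional[float] = None
    flags: list = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.flags


def eval_sphere_dmt(E: float, R: float, nu: float, gamma: float, delta) -> np.ndarray:
    """Load on a spherical probe with DMT adhesion at indentation ``delta``.

    ``P = 4 E sqrt(R) / (3 (1 - nu^2)) * delta^(3/2) - 2 pi gamma R``
    with E in Pa, R and delta in m, work of adhesion gamma in N/m.
    """
    if nu >= 1:
        raise ValueError("Poisson's ratio must be < 1")
    d = np.asarray(delta, dtype=float)
    if np.any(d < 0):
        raise ValueError("indentation must be >= 0")
    out = 4.0 * E * math.sqrt(R) / (3.0 * (1.0 - nu**2)) * d**1.5 - 2.0 * math.pi * gamma * R
    return out if out.ndim else float(out)


def eval_cone(E: float, theta: float, nu: float, delta) -> np.ndarray:
    """Load on a conical (Sneddon) probe: ``P = 2 E tan(theta) / (pi (1-nu^2)) delta^2``."""
    if nu >= 1:
        raise ValueError("Poisson's ratio must be < 1")
    if not (0 < theta < math.pi / 2):
        raise ValueError("half angle must lie in (0, pi/2)")
    d = np.asarray(delta, dtype=float)
    if np.any(d < 0):
        raise ValueError("indentation must be >= 0")
    out = 2.0 * E * math.tan(theta) / (math.pi * (1.0 - nu**2)) * d**2
    return out if out.ndim else float(out)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad : pad + len(x)]
    return out


def find_contact_point(
    curve: ForceCurve,
    baseline_fraction: float = 0.3,
    n_sigma: float = 3.0,
    sustained: int = 10,
    smooth_window: int = 7,
) -> float:
    """Locate the piezo position where probe-sample contact begins.

    The pre-contact baseline (first ``baseline_fraction`` of the approach) is
    fit with a straight line to remove offset and tilt.  Contact is the first
    sustained excursion of the detrended force beyond ``n_sigma`` baseline
    noise levels (``sustained`` consecutive samples), backtracked along the
    smoothed signal to where the excursion leaves the baseline.  Adhesive
    snap-in produces a negative excursion and is detected the same way.
    """
    z, f = curve.z, curve.force
    n = len(z)
    nb = max(10, int(baseline_fraction * n))
    if nb >= n:
        raise ValueError("curve too short for baseline estimation")
    coeffs = np.polyfit(z[:nb], f[:nb], 1)
    detr = f - np.polyval(coeffs, z)
    sigma = float(np.std(detr[:nb]))
    # noiseless curves: fall back to a tiny floor relative to the signal range
    floor = 1e-6 * max(np.max(np.abs(detr)), 1e-30)
    thr = max(n_sigma * sigma, floor)

    above = np.abs(detr) > thr
    if not np.any(above):
        raise ValueError(QCFlag.NO_CONTACT)
    # first run of `sustained` consecutive exceedances
    run = np.convolve(above.astype(int), np.ones(sustained, dtype=int), mode="valid")
    hits = np.nonzero(run == sustained)[0]
    if len(hits) == 0:
        raise ValueError(QCFlag.NO_CONTACT)
    i0 = int(hits[0])

    sm = _moving_average(detr, smooth_window)
    sign = 1.0 if sm[i0] >= 0 else -1.0
    j = i0
    while j > 0 and sign * sm[j - 1] > 0:
        j -= 1
    # walk forward over samples still indistinguishable from baseline
    while j < i0 and sign * detr[j] <= 0:
        j += 1
    return float(z[j])


def _transition_index(force: np.ndarray, trigger_force: float) -> int:
    """Index of the transition point: first sample reaching the trigger force."""
    idx = np.nonzero(force >= trigger_force * (1 - 1e-9))[0]
    return int(idx[0]) if len(idx) else len(force) - 1


def compute_indentation(
    curve: ForceCurve, contact_point: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indentation/load pairs over the contact-to-transition window.

    ``delta = (z - contact_point) - P/k`` corrects the piezo travel for
    cantilever deflection.  Samples before contact or past the transition
    point are discarded.
    """
    k = curve.probe.spring_constant
    if k <= 0:
        raise ValueError("spring constant must be > 0")
    if not (curve.z[0] <= contact_point <= curve.z[-1]):
        raise ValueError("contact point outside curve range")
    it = _transition_index(curve.force, curve.trigger_force)
    mask = (curve.z >= contact_point) & (np.arange(len(curve.z)) <= it)
    delta = (curve.z[mask] - contact_point) - curve.force[mask] / k
    return delta, curve.force[mask]


def _solve_model(
    delta: np.ndarray, P: np.ndarray, model: str, probe: ProbeGeometry, nu: float
) -> tuple[float, float, np.ndarray]:
    """Linear least squares for (E, gamma) given the indentation origin.

    Both models are linear in their coefficients once delta is fixed:
    sphere: P = A d^1.5 - B with B = 2 pi gamma R >= 0; cone: P = C d^2.
    Returns (E, gamma, predicted P).
    """
    if model == "sphere_dmt":
        X = np.column_stack([delta**1.5, -np.ones_like(delta)])
        coef, *_ = np.linalg.lstsq(X, P, rcond=None)
        A, B = coef
        if B < 0:  # gamma constrained >= 0
            B = 0.0
            A = float(np.dot(delta**1.5, P) / np.dot(delta**1.5, delta**1.5))
        E = 3.0 * A * (1.0 - nu**2) / (4.0 * math.sqrt(probe.R))
        gamma = B / (2.0 * math.pi * probe.R)
        pred = A * delta**1.5 - B
    else:  # cone
        d2 = delta**2
        C = float(np.dot(d2, P) / np.dot(d2, d2))
        E = C * math.pi * (1.0 - nu**2) / (2.0 * math.tan(probe.theta))
        gamma = 0.0
        pred = C * d2
    return E, gamma, pred


def fit_contact_model(
    curve: ForceCurve,
    model: Literal["sphere_dmt", "cone"],
    nu: float = 0.5,
    contact_point: Optional[float] = None,
    refine_contact: bool = True,
    min_samples: int = 10,
) -> ContactFitResult:
    """Least-squares contact-model fit over the contact-to-transition window.

    The contact point is detected (or given), optionally refined by a 1-D
    search minimizing the force residual, and samples with negative
    indentation (snap-in region) are excluded.  For the sphere model the work
    of adhesion gamma is fitted subject to gamma >= 0; the cone model has no
    adhesion term.
    """
    if model == "sphere_dmt" and curve.probe.kind != "sphere":
        raise ValueError("sphere_dmt model requires a sphere probe")
    if model == "cone" and curve.probe.kind != "cone":
        raise ValueError("cone model requires a cone probe")

    zc0 = find_contact_point(curve) if contact_point is None else contact_point

    def sse_at(zc: float) -> float:
        delta, P = compute_indentation(curve, zc)
        keep = delta >= 0
        if keep.sum() < min_samples:
            return np.inf
        d, p = delta[keep], P[keep]
        _, _, pred = _solve_model(d, p, model, curve.probe, nu)
        return float(np.sum((p - pred) ** 2))

    zc = zc0
    if refine_contact:
        span = curve.z[-1] - curve.z[0]
        half = 0.05 * span
        lo = max(curve.z[0], zc0 - half)
        hi = min(curve.z[-1], zc0 + half)
        res = minimize_scalar(sse_at, bounds=(lo, hi), method="bounded",
                              options={"xatol": span * 1e-9})
        if np.isfinite(res.fun):
            zc = float(res.x)

    delta, P = compute_indentation(curve, zc)
    keep = delta >= 0
    if keep.sum() < min_samples:
        raise ValueError(QCFlag.INSUFFICIENT_DATA)
    d, p = delta[keep], P[keep]
    E, gamma, pred = _solve_model(d, p, model, curve.probe, nu)
    ss_res = float(np.sum((p - pred) ** 2))
    ss_tot = float(np.sum((p - np.mean(p)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)

    it = _transition_index(curve.force, curve.trigger_force)
    dmax = float(np.max(d))
    flags: list[str] = []
    frac = None
    if curve.sample_thickness is not None:
        frac = dmax / curve.sample_thickness
        if frac > MAX_INDENTATION_FRACTION:
            flags.append(QCFlag.EXCESS_INDENTATION)

    return ContactFitResult(
        E=E, gamma=gamma, nu=nu, contact_point=zc,
        transition_point=float(curve.z[it]), max_indentation=dmax,
        r_squared=r2, model=model, indentation_fraction=frac, flags=flags,
    )


@dataclass
class ForceMap:
    """Grid of force curves acquired over a region (default 6x6, 25 um extent).

    ``acquisition_time`` tags the map for time-resolved series.
    """

    curves: list  # list of rows, each a list of ForceCurve
    extent: float = 25e-6
    acquisition_time: Optional[float] = None
    results: Optional[list] = None  # parallel grid of ContactFitResult | None

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.curves), len(self.curves[0])


def fit_force_map(fmap: ForceMap, model: str, nu: float = 0.5, **kwargs) -> ForceMap:
    """Fit every cell of a force map; failed fits are stored as None."""
    results = []
    for row in fmap.curves:
        rrow = []
        for c in row:
            try:
                rrow.append(fit_contact_model(c, model, nu=nu, **kwargs))
            except ValueError as exc:
                warnings.warn(f"cell fit failed: {exc}")
                rrow.append(None)
        results.append(rrow)
    fmap.results = results
    return fmap


def summarize_force_map(fmap: ForceMap) -> dict:
    """Per-map E statistics over accepted fits.

    Rejected cells (failed fits or QC-flagged results) are enumerated with
    reasons and excluded from the summary, mirroring standard force-map
    batch analysis where the reported E is the mean of technical replicates.
    """
    if fmap.results is None:
        raise ValueError("map has no fit results; run fit_force_map first")
    accepted, rejected = [], []
    for i, row in enumerate(fmap.results):
        for j, r in enumerate(row):
            if r is None:
                rejected.append(((i, j), "fit failed"))
            elif r.flags:
                rejected.append(((i, j), "; ".join(r.flags)))
            else:
                accepted.append(r.E)
    if not accepted:
        raise ValueError("empty map: zero accepted fits")
    arr = np.asarray(accepted)
    return {
        "n_accepted": len(accepted),
        "n_rejected": len(rejected),
        "rejected": rejected,
        "E_mean": float(np.mean(arr)),
        "E_median": float(np.median(arr)),
        "E_sd": float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0,
        "acquisition_time": fmap.acquisition_time,
    }
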