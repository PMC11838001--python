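"""Nanoneedle AFM: membrane-penetration detection and compartment stiffness.

A high-aspect-ratio (nanoneedle) probe driven at high trigger force pierces
the cell membrane — and, over the nucleus, subsequently the nuclear
envelope.  Each penetration appears on the approach curve as a local force
peak (steep rise as the membrane deforms) followed by an incremental force
decline (rupture), after which indentation of the underlying compartment
resumes.  Curves are accepted only when the number of clearly defined peaks
matches the expectation for the measurement site: two over the nucleus
(cell + nuclear membrane), one elsewhere.  Compartment Young's moduli are
then fitted with the cone (Sneddon) model on the post-penetration segment,
with a free indentation/force offset to account for the material already
traversed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .afm import ForceCurve, _moving_average, _transition_index, find_contact_point

__all__ = [
    "PenetrationEvent",
    "CompartmentMeasurements",
    "SITE_EXPECTED_PEAKS",
    "MAX_PENETRATION_DEPTH",
    "detect_penetration_peaks",
    "qc_curve",
    "fit_post_penetration",
    "compartment_stiffness",
    "stiffness_ratios",
]

SiteClass = Literal["nucleus", "cytoplasm", "junction", "cyto_mid", "cyto_edge"]

#: Expected penetration-peak count per measurement site.
SITE_EXPECTED_PEAKS = {
    "nucleus": 2,
    "cytoplasm": 1,
    "junction": 1,
    "cyto_mid": 1,
    "cyto_edge": 1,
}

#: Penetration depths beyond this are implausible for the needle geometry
#: (probe width stays < 400 nm only below this depth) and are flagged.
MAX_PENETRATION_DEPTH = 2.3e-6


@dataclass
class PenetrationEvent:
    indentation_at_peak: float  # m
    peak_force: float  # N
    force_drop: float  # N
    index: int  # sample index into the contact window

    def __post_init__(self) -> None:
        if self.force_drop <= 0:
            raise ValueError("force_drop must be > 0")


@dataclass
class CompartmentMeasurements:
    """Accepted per-site stiffness values (Pa)."""

    E_by_site: dict  # site class -> list of E (Pa)
    n_rejected: dict = field(default_factory=dict)


def detect_penetration_peaks(
    curve: ForceCurve,
    min_drop: Optional[float] = None,
    smoothing_window: int = 5,
    contact_point: Optional[float] = None,
    min_separation: float = 0.2e-6,
) -> list[PenetrationEvent]:
    """Find membrane-penetration events on the approach segment.

    Events are local maxima of the smoothed force, inside the contact-to-
    transition window, followed by a decline of at least ``min_drop``
    (default 5% of the trigger force) before the force rises back above
    the peak.  Detections closer than ``min_separation`` (m of
    indentation) are merged.  Returned in order of increasing indentation.
    """
    if min_drop is None:
        min_drop = 0.05 * curve.trigger_force
    zc = find_contact_point(curve) if contact_point is None else contact_point
    k = curve.probe.spring_constant
    it = _transition_index(curve.force, curve.trigger_force)
    mask = (curve.z >= zc) & (np.arange(len(curve.z)) <= it)
    z = curve.z[mask]
    P = curve.force[mask]
    if len(P) < smoothing_window + 2:
        raise ValueError("curve lacks a usable contact segment")
    delta = (z - zc) - P / k
    sm = _moving_average(P, smoothing_window)
    candidates, _ = find_peaks(sm)
    events = []
    for p in candidates:
        # decline after the peak, up to where the force rises back above the
        # peak level ("a local maximum followed by an incremental decline");
        # a half-min_drop hysteresis keeps noise from cutting the window short
        rise = np.nonzero(sm[p + 1 :] > sm[p] + 0.5 * min_drop)[0]
        stop = p + 1 + rise[0] if len(rise) else len(sm)
        trough = float(sm[p + 1 : stop].min()) if stop > p + 1 else float(sm[p])
        drop = sm[p] - trough
        if drop < min_drop:
            continue
        events.append(PenetrationEvent(
            indentation_at_peak=float(delta[p]),
            peak_force=float(P[p]),
            force_drop=float(drop),
            index=int(p),
        ))
    events.sort(key=lambda e: e.indentation_at_peak)
    # merge near-duplicate detections of one penetration (noise splitting)
    merged: list[PenetrationEvent] = []
    for e in events:
        if merged and e.indentation_at_peak - merged[-1].indentation_at_peak < min_separation:
            if e.peak_force > merged[-1].peak_force:
                merged[-1] = e
        else:
            merged.append(e)
    return merged


def qc_curve(events: Sequence[PenetrationEvent], site_class: str) -> tuple[bool, str]:
    """Accept or reject a curve from its penetration-event count.

    Nucleus sites require exactly two events (cell then nuclear membrane);
    all other sites exactly one.  Returns (accepted, reason).
    """
    if site_class not in SITE_EXPECTED_PEAKS:
        raise ValueError(f"unknown site class {site_class!r}")
    expected = SITE_EXPECTED_PEAKS[site_class]
    n = len(events)
    if n == expected:
        return True, "ok"
    if n < expected:
        if site_class == "nucleus" and n == 1:
            return False, "incomplete nuclear penetration"
        return False, "too few peaks"
    return False, "too many peaks"


def _offset_cone(delta, C, d0, P0):
    d = np.clip(delta - d0, 0.0, None)
    return P0 + C * d**2


def fit_post_penetration(
    curve: ForceCurve,
    events: Sequence[PenetrationEvent],
    nu: float = 0.5,
    smoothing_window: int = 5,
) -> float:
    """Cone-model E (Pa) fitted on the segment after the last penetration.

    The fit window runs from the recovery after the last peak's force drop
    (local force minimum following the peak, at least one smoothing window
    past it) to the transition point.  The cone law is fitted with free
    indentation and force offsets, ``P = P0 + C (delta - d0)^2``, because
    the needle has already traversed overlying material.
    """
    if curve.probe.kind != "cone":
        raise ValueError("nanoneedle fitting requires a cone probe")
    zc = find_contact_point(curve)
    k = curve.probe.spring_constant
    it = _transition_index(curve.force, curve.trigger_force)
    mask = (curve.z >= zc) & (np.arange(len(curve.z)) <= it)
    z, P = curve.z[mask], curve.force[mask]
    delta = (z - zc) - P / k
    if delta.max() > MAX_PENETRATION_DEPTH:
        import warnings
        warnings.warn("penetration depth exceeds plausible needle range (2.3 um)")

    if events:
        last = max(e.index for e in events)
        tail = _moving_average(P, smoothing_window)[last:]
        start = last + max(int(np.argmin(tail)), smoothing_window)
    else:
        start = 0
    d, p = delta[start:], P[start:]
    if len(d) < 8:
        raise ValueError("insufficient post-penetration data")
    C0 = max((p[-1] - p[0]) / max((d[-1] - d[0]) ** 2, 1e-30), 1.0)
    p0 = (C0, float(d[0]), float(p[0]))
    popt, _ = curve_fit(_offset_cone, d, p, p0=p0, maxfev=10000)
    C = popt[0]
    E = C * np.pi * (1.0 - nu**2) / (2.0 * np.tan(curve.probe.theta))
    return float(E)


def compartment_stiffness(
    curves_by_site: dict,
    nu: float = 0.5,
    min_drop: Optional[float] = None,
    smoothing_window: int = 5,
) -> CompartmentMeasurements:
    """Per-site E lists from QC-passing nanoneedle curves.

    ``curves_by_site`` maps a site class to a sequence of ForceCurve.
    Curves failing the peak-count QC are dropped (counts reported); an
    empty accepted set for a requested site is an error.
    """
    E_by_site: dict = {}
    n_rejected: dict = {}
    for site, curves in curves_by_site.items():
        accepted = []
        rejected = 0
        for c in curves:
            events = detect_penetration_peaks(
                c, min_drop=min_drop, smoothing_window=smoothing_window)
            ok, _ = qc_curve(events, site)
            if not ok:
                rejected += 1
                continue
            accepted.append(fit_post_penetration(
                c, events, nu=nu, smoothing_window=smoothing_window))
        if not accepted:
            raise ValueError(f"no accepted curves for site {site!r}")
        E_by_site[site] = accepted
        n_rejected[site] = rejected
    return CompartmentMeasurements(E_by_site=E_by_site, n_rejected=n_rejected)


def stiffness_ratios(
    m: CompartmentMeasurements,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """Ratios of per-site mean stiffness with bootstrap confidence intervals.

    Reports nucleus/cytoplasm, junction/cytoplasm and edge/mid ratios for
    the pairs whose sites are both present (at least one pair must be);
    cells (curves) are resampled with replacement within each site.
    """
    pairs = {
        "nuc_over_cyto": ("nucleus", "cytoplasm"),
        "junct_over_cyto": ("junction", "cytoplasm"),
        "edge_over_mid": ("cyto_edge", "cyto_mid"),
    }
    rng = np.random.default_rng(seed)
    out = {}
    alpha = (1.0 - ci) / 2.0
    for name, (num, den) in pairs.items():
        if num not in m.E_by_site or den not in m.E_by_site:
            continue
        a = np.asarray(m.E_by_site[num], dtype=float)
        b = np.asarray(m.E_by_site[den], dtype=float)
        if b.mean() == 0:
            raise ValueError("denominator site has zero mean stiffness")
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = (rng.choice(a, size=len(a)).mean()
                        / rng.choice(b, size=len(b)).mean())
        out[name] = {
            "ratio": float(a.mean() / b.mean()),
            "ci_low": float(np.quantile(boots, alpha)),
            "ci_high": float(np.quantile(boots, 1 - alpha)),
        }
    if not out:
        raise ValueError(
            "no computable ratio: measurements lack every required site pair")
    return out
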