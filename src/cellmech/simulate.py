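"""Seeded synthetic-data generators for every analysis stage.

Each generator forward-simulates the data model its downstream estimator
assumes — contact-mechanics force curves, nanoneedle curves with planted
membrane-penetration peaks, quadratic spatial rigidity profiles, balanced
traction fields with their exact elastic displacement (and optionally
rendered bead images), nucleus localization clouds with planted dense
nanodomains, and leader/follower cell-track populations — and returns the
ground-truth parameters alongside the data so recovery can be tested.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call: identical arguments (including the seed) give bitwise-identical
output.  Noise is additive Gaussian unless stated otherwise.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .afm import ForceCurve, ProbeGeometry, eval_cone, eval_sphere_dmt
from .chromatin import LocalizationSet
from .pzhr import RigidityProfile
from .tfm import DisplacementField, TractionField, forward_displacement
from .tracks import TrackTable

__all__ = [
    "gen_force_curve",
    "gen_nanoneedle_curve",
    "gen_rigidity_profile",
    "gen_traction_scene",
    "gen_nucleus_localizations",
    "gen_tracks",
    "render_beads",
]


def gen_force_curve(
    E_true: float,
    probe: ProbeGeometry,
    adhesion_work: float = 0.0,
    max_force: float = 2e-9,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 1000,
    nu: float = 0.5,
    contact_z: float = 5e-6,
    baseline_fraction: float = 0.33,
    sample_thickness: Optional[float] = None,
    site_label: str = "",
) -> ForceCurve:
    """Forward-simulate a contact-model approach curve.

    The in-contact branch follows the probe's contact law exactly before
    noise — sphere with DMT adhesion, or cone (``adhesion_work`` must be 0
    for cones) — sampled uniformly in indentation from the post-snap-in
    equilibrium up to the transition point where the load first reaches
    ``max_force`` (the trigger).  Piezo position follows from
    ``z = z_c + delta + P/k``.  A flat pre-contact baseline precedes
    contact; Gaussian force noise of ``noise_sd`` is added throughout.
    """
    if E_true <= 0 or max_force <= 0:
        raise ValueError("E_true and max_force must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    k = probe.spring_constant

    if probe.kind == "sphere":
        B = 2.0 * math.pi * adhesion_work * probe.R
        model = lambda d: eval_sphere_dmt(E_true, probe.R, nu, adhesion_work, d)
        A = 4.0 * E_true * math.sqrt(probe.R) / (3.0 * (1.0 - nu**2))
        delta_max = ((max_force + B) / A) ** (2.0 / 3.0)
        if B > 0:
            # post-snap-in equilibrium: k d0 = B - A d0^1.5
            delta0 = brentq(lambda d: k * d + A * d**1.5 - B, 0.0, B / k)
        else:
            delta0 = 0.0
    elif probe.kind == "cone":
        if adhesion_work != 0:
            raise ValueError("adhesion is only modeled for sphere probes")
        model = lambda d: eval_cone(E_true, probe.theta, nu, d)
        C = 2.0 * E_true * math.tan(probe.theta) / (math.pi * (1.0 - nu**2))
        delta_max = math.sqrt(max_force / C)
        delta0 = 0.0
    else:  # pragma: no cover - ProbeGeometry already validates
        raise ValueError(f"unsupported probe kind {probe.kind!r}")

    n_base = max(10, int(baseline_fraction * n_samples))
    n_contact = n_samples - n_base
    delta = np.linspace(delta0, delta_max, n_contact)
    P = np.asarray(model(delta), dtype=float)
    z_contact = contact_z + delta + P / k

    base_extent = max(0.5 * (z_contact[-1] - contact_z), 2e-7)
    z_base = np.linspace(contact_z - base_extent, contact_z, n_base, endpoint=False)
    z = np.concatenate([z_base, z_contact])
    force = np.concatenate([np.zeros(n_base), P])
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=len(force))

    return ForceCurve(
        z=z, force=force, probe=probe, trigger_force=max_force,
        sample_thickness=sample_thickness, site_label=site_label,
        truth={"E": E_true, "gamma": adhesion_work, "contact_z": contact_z,
               "nu": nu, "delta_max": delta_max},
    )


def gen_nanoneedle_curve(
    base_E: float,
    peaks: Sequence[tuple[float, float]],
    seed: int = 0,
    trigger_force: float = 10e-9,
    theta: float = math.radians(3.9),
    spring_constant: float = 0.05,
    nu: float = 0.5,
    noise_sd: float = 0.0,
    n_samples: int = 1500,
    drop_width: float = 0.15e-6,
    rise_width: float = 0.1e-6,
    segment_E: Optional[Sequence[float]] = None,
    contact_z: float = 2e-6,
    site_label: str = "",
) -> ForceCurve:
    """Nanoneedle approach curve with planted membrane-penetration peaks.

    The underlying indentation response is piecewise cone-law (Sneddon),
    one segment per compartment with its own indentation origin so the
    post-penetration branch obeys ``P = P0 + C (delta - d0)^2`` exactly.
    Each planted peak adds a membrane-loading bump on top: the force rises
    steeply by the requested drop over ``rise_width`` before the peak
    (membrane deforming), then declines incrementally back to the
    underlying curve over ``drop_width`` (rupture) — the penetration
    signature.  ``peaks`` is a list of (indentation_at_peak m, force_drop
    N) with strictly increasing indentations; 0, 1, or 2 peaks cover
    cytoplasmic vs nuclear sites.  ``segment_E`` optionally sets a Young's
    modulus per compartment (len(peaks)+1 values); by default every
    segment uses ``base_E``.
    """
    if base_E <= 0:
        raise ValueError("base_E must be > 0")
    rng = np.random.default_rng(seed)
    probe = ProbeGeometry(kind="cone", theta=theta, spring_constant=spring_constant)
    n_seg = len(peaks) + 1
    seg_E = list(segment_E) if segment_E is not None else [base_E] * n_seg
    if len(seg_E) != n_seg:
        raise ValueError("segment_E must have len(peaks)+1 entries")
    indents = [p[0] for p in peaks]
    if any(b - a <= drop_width + rise_width for a, b in zip(indents, indents[1:])):
        raise ValueError("peaks too close: drop/rise regions overlap")
    if indents and indents[0] <= rise_width:
        raise ValueError("first peak too close to the contact point")

    def cone_C(E: float) -> float:
        return 2.0 * E * math.tan(theta) / (math.pi * (1.0 - nu**2))

    # underlying piecewise-cone response (continuous, monotone)
    bounds = [0.0] + [d + drop_width for d, _ in peaks]
    Cs = [cone_C(E) for E in seg_E]
    P_off = [0.0]
    for i in range(1, n_seg):
        P_off.append(P_off[i - 1] + Cs[i - 1] * (bounds[i] - bounds[i - 1]) ** 2)

    def underlying(d: np.ndarray) -> np.ndarray:
        out = np.empty_like(d)
        for i in range(n_seg):
            hi = bounds[i + 1] if i + 1 < n_seg else np.inf
            sel = (d >= bounds[i]) & (d < hi) if i + 1 < n_seg else d >= bounds[i]
            out[sel] = P_off[i] + Cs[i] * (d[sel] - bounds[i]) ** 2
        return out

    for i, (d_peak, drop) in enumerate(peaks):
        if float(underlying(np.array([d_peak]))[0]) + drop >= trigger_force:
            raise ValueError("planted peak lies beyond the trigger-force depth")
    d_trans = bounds[-1] + math.sqrt((trigger_force - P_off[-1]) / Cs[-1])

    def smoothstep(t: np.ndarray) -> np.ndarray:
        t = np.clip(t, 0.0, 1.0)
        return 3 * t**2 - 2 * t**3

    n_base = max(10, int(0.33 * n_samples))
    n_contact = n_samples - n_base
    delta = np.linspace(0.0, d_trans, n_contact)
    P = underlying(delta)
    for d_peak, drop in peaks:
        # amplitude compensates the underlying rise across the decline so the
        # observed force drop matches the requested one
        dU = float(underlying(np.array([d_peak + drop_width]))[0]
                   - underlying(np.array([d_peak]))[0])
        amp = drop + dU
        bump = amp * smoothstep((delta - d_peak + rise_width) / rise_width)
        bump *= 1.0 - smoothstep((delta - d_peak) / drop_width)
        P = P + bump
    z_contact = contact_z + delta + P / spring_constant
    base_extent = max(0.3 * (z_contact[-1] - contact_z), 2e-7)
    z_base = np.linspace(contact_z - base_extent, contact_z, n_base, endpoint=False)
    z = np.concatenate([z_base, z_contact])
    force = np.concatenate([np.zeros(n_base), P])
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=len(force))
    return ForceCurve(
        z=z, force=force, probe=probe, trigger_force=trigger_force,
        site_label=site_label,
        truth={"peaks": list(peaks), "segment_E": seg_E, "contact_z": contact_z,
               "transition_indentation": d_trans},
    )


def gen_rigidity_profile(
    coeffs: tuple[float, float, float],
    sites: Sequence[float] = (0.0, 0.33, 0.67, 1.0),
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    floor: float = 0.1,
    n_animals: int = 1,
) -> RigidityProfile:
    """Per-site stiffness replicates around a quadratic spatial profile.

    ``E(x) = a x^2 + b x + c`` (kPa) evaluated at the given site fractions,
    plus Gaussian noise, truncated below at ``floor`` (> 0) to keep moduli
    physical.  Replicates are drawn per site per animal.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    sites = np.asarray(sites, dtype=float)
    if np.any((sites < 0) | (sites > 1)):
        raise ValueError("sites must lie in [0, 1]")
    a, b, c = coeffs
    rng = np.random.default_rng(seed)
    rows = []
    for animal in range(n_animals):
        for x in sites:
            mean = a * x**2 + b * x + c
            vals = mean + rng.normal(0.0, noise_sd, size=replicates) \
                if noise_sd > 0 else np.full(replicates, mean)
            vals = np.maximum(vals, floor)
            for v in vals:
                rows.append({"x": x, "E_kPa": float(v),
                             "animal_id": f"animal{animal}"})
    profile = RigidityProfile(pd.DataFrame(rows))
    profile.truth = {"coeffs": (a, b, c), "floor": floor}
    return profile


def gen_traction_scene(
    traction: str = "spots",
    substrate_E: float = 12e3,
    nu: float = 0.5,
    n: int = 64,
    spacing: float = 1e-6,
    amplitude: float = 100.0,
    wavelength: Optional[float] = None,
    n_spots: int = 4,
    spot_sigma: float = 4e-6,
    render: bool = False,
    image_size: int = 256,
    n_beads: int = 1200,
    bead_sigma_px: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """Balanced synthetic traction field with its exact elastic displacement.

    ``traction="mode"`` builds a single Fourier mode ``T = A cos(2 pi x /
    wavelength) x_hat`` (zero-mean by construction); ``"spots"`` scatters
    Gaussian traction spots with alternating directions and subtracts the
    mean to balance forces.  The displacement is the forward Boussinesq
    solution on the same grid — the exact inverse target for FTTC.  With
    ``render=True`` a bead image pair (reference, deformed) is rendered:
    Gaussian spots advected by the displacement field scaled to pixels.
    Gaussian ``noise_sd`` (in Pa) perturbs the traction before the forward
    solve when nonzero.
    """
    if n & (n - 1) != 0:
        raise ValueError("grid size n must be a power of two")
    rng = np.random.default_rng(seed)
    x = np.arange(n) * spacing
    X, Y = np.meshgrid(x, x)
    T = np.zeros((n, n, 2))
    if traction == "mode":
        if wavelength is None:
            wavelength = n * spacing / 4
        # snap to an integer number of periods so the mode is exactly
        # periodic (and zero-mean) on the grid
        m = max(1, round(n * spacing / wavelength))
        wavelength = n * spacing / m
        kx = 2 * np.pi / wavelength
        T[:, :, 0] = amplitude * np.cos(kx * X)
        T[:, :, 0] -= T[:, :, 0].mean()
    elif traction == "spots":
        for _ in range(n_spots):
            cx, cy = rng.uniform(0.2, 0.8, size=2) * n * spacing
            ang = rng.uniform(0, 2 * np.pi)
            g = np.exp(-(((X - cx) ** 2 + (Y - cy) ** 2) / (2 * spot_sigma**2)))
            T[:, :, 0] += amplitude * np.cos(ang) * g
            T[:, :, 1] += amplitude * np.sin(ang) * g
        T -= T.mean(axis=(0, 1))
    else:
        raise ValueError(f"unknown traction spec {traction!r}")
    if noise_sd > 0:
        T = T + rng.normal(0.0, noise_sd, size=T.shape)
        T -= T.mean(axis=(0, 1))

    total = np.abs(T.sum(axis=(0, 1)))
    if np.any(total > 1e-9 * np.abs(T).sum()) and np.abs(T).sum() > 0:
        raise ValueError("unbalanced force")

    tfield = TractionField(T=T, spacing=spacing, substrate_E=substrate_E, nu=nu)
    ufield = forward_displacement(tfield)
    out = {"traction": tfield, "displacement": ufield,
           "truth": {"amplitude": amplitude, "wavelength": wavelength}}
    if render:
        px = n * spacing / image_size  # m per pixel
        beads = rng.uniform(0, n * spacing, size=(n_beads, 2))
        ref = render_beads(beads / px, (image_size, image_size), bead_sigma_px)
        # sample displacement at bead positions (nearest node)
        idx = np.clip((beads / spacing).astype(int), 0, n - 1)
        disp = ufield.u[idx[:, 1], idx[:, 0]]  # (ux, uy)
        moved = (beads + disp) / px
        warped = render_beads(moved, (image_size, image_size), bead_sigma_px)
        out["images"] = (ref, warped)
        out["pixel_size"] = px
    return out


def render_beads(
    positions_px: np.ndarray,
    shape: tuple[int, int],
    sigma: float = 1.5,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Render sub-resolution beads as Gaussian spots at pixel positions."""
    img = np.zeros(shape)
    half = int(np.ceil(4 * sigma))
    for x, y in np.asarray(positions_px, dtype=float):
        ix, iy = int(round(x)), int(round(y))
        x0, x1 = max(ix - half, 0), min(ix + half + 1, shape[1])
        y0, y1 = max(iy - half, 0), min(iy + half + 1, shape[0])
        if x0 >= x1 or y0 >= y1:
            continue
        gx, gy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((gx - x) ** 2 + (gy - y) ** 2) / (2 * sigma**2))
    return img


def gen_nucleus_localizations(
    n_background: int = 3000,
    domains: Sequence[tuple] = (),
    nucleus_radius_nm: float = 4000.0,
    peripheral_fraction: float = 0.0,
    jitter_sd: float = 15.0,
    seed: int = 0,
    nucleus_id: str = "",
    condition: str = "",
) -> LocalizationSet:
    """Nucleus localization cloud with planted dense nanodomains.

    Background points are uniform in the nucleus disk; each domain is
    ``(center | None, radius_nm, n_points)`` with points uniform in its
    disk.  Domains with ``center=None`` are placed randomly: with
    probability ``peripheral_fraction`` within the 0.15 R peripheral band
    (emulating peripherally enriched dense chromatin), otherwise well
    inside the interior.  Isotropic Gaussian jitter of ``jitter_sd`` nm
    (typical SMLM localization precision) is added to every point.
    Ground-truth labels (-1 background, domain index otherwise) and planted
    parameters are retained on the returned set.
    """
    if not (0.0 <= peripheral_fraction <= 1.0):
        raise ValueError("peripheral_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    Rn = nucleus_radius_nm

    def uniform_disk(npts: int, center, radius: float) -> np.ndarray:
        r = radius * np.sqrt(rng.uniform(size=npts))
        th = rng.uniform(0, 2 * np.pi, size=npts)
        return np.column_stack([center[0] + r * np.cos(th),
                                center[1] + r * np.sin(th)])

    pts = [uniform_disk(n_background, (0.0, 0.0), Rn)]
    labels = [np.full(n_background, -1)]
    placed = []
    band = 0.15 * Rn
    for i, (center, rad, npts) in enumerate(domains):
        if rad <= 0:
            raise ValueError("domain radius must be > 0")
        if center is None:
            if rng.uniform() < peripheral_fraction:
                lo, hi = Rn - band + rad, Rn - rad
                rc = rng.uniform(lo, hi) if lo < hi else Rn - band / 2
            else:
                # keep interior domains a clear margin outside the band
                rc = rng.uniform(0, max(Rn - band - 2 * rad, rad))
            th = rng.uniform(0, 2 * np.pi)
            center = (rc * np.cos(th), rc * np.sin(th))
        if np.hypot(*center) > Rn:
            raise ValueError("domain center outside the nucleus disk")
        pts.append(uniform_disk(npts, center, rad))
        labels.append(np.full(npts, i))
        dist_to_boundary = Rn - float(np.hypot(*center)) - rad
        placed.append({"center": tuple(center), "radius": rad, "n": npts,
                       "peripheral": dist_to_boundary < band})
    points = np.vstack(pts)
    if jitter_sd > 0:
        points = points + rng.normal(0.0, jitter_sd, size=points.shape)
    locs = LocalizationSet(points=points, nucleus_id=nucleus_id,
                           condition=condition,
                           truth_labels=np.concatenate(labels))
    locs.truth = {"nucleus_radius": Rn, "domains": placed,
                  "peripheral_band": band}
    return locs


def gen_tracks(
    n_leaders: int = 25,
    n_followers: int = 475,
    leader_speed: float = 20.0,
    follower_speed: float = 2.0,
    drift_axis: Sequence[float] = (0.0, 1.0),
    duration: float = 10.0,
    dt: float = 0.5,
    field_size: float = 500.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> TrackTable:
    """Leader/follower track populations for durotaxis summaries.

    Leaders drift along ``drift_axis`` at ``leader_speed`` (um/h) with
    isotropic Gaussian positional noise; followers perform an unbiased
    Gaussian random walk whose mean step length is ``follower_speed * dt``
    (Rayleigh-distributed step lengths, as for 2-D diffusion).  Leaders start in
    a thin strip just beyond the follower field along the gradient axis, so
    they form (and carry) the monolayer's leading edge.  Ground-truth class
    labels are kept in the ``leader`` column.
    """
    n_steps = round(duration / dt)
    if abs(n_steps * dt - duration) > 1e-9 * max(duration, 1.0):
        raise ValueError("dt must divide duration")
    rng = np.random.default_rng(seed)
    axis = np.asarray(drift_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    perp = np.array([-axis[1], axis[0]])
    rows = []
    tid = 0
    for cls, count, speed in (("leader", n_leaders, leader_speed),
                              ("follower", n_followers, follower_speed)):
        for _ in range(count):
            if cls == "leader":  # seed leaders on the advancing edge strip
                pos = (perp * rng.uniform(0, field_size)
                       + axis * field_size * rng.uniform(1.0, 1.05))
            else:
                pos = (perp * rng.uniform(0, field_size)
                       + axis * rng.uniform(0, field_size))
            for step in range(n_steps + 1):
                rows.append({"track_id": tid, "frame": step, "t_h": step * dt,
                             "x_um": pos[0], "y_um": pos[1], "leader": cls == "leader"})
                if cls == "leader":
                    move = axis * speed * dt + rng.normal(0, noise_sd, 2)
                else:
                    # isotropic Gaussian step; mean length = speed * dt
                    sigma = speed * dt / math.sqrt(math.pi / 2.0)
                    move = rng.normal(0.0, sigma, 2)
                pos = pos + move
            tid += 1
    table = TrackTable(pd.DataFrame(rows), gradient_axis=axis, frame_interval=dt)
    table.truth = {"n_leaders": n_leaders, "n_followers": n_followers,
                   "leader_speed": leader_speed, "follower_speed": follower_speed}
    return table
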