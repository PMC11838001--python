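"""Traction force microscopy: drift correction, PIV, FTTC, strain energy.

Substrate tractions are recovered from gel-bead displacement fields by
Fourier-transform traction cytometry (FTTC): in Fourier space the elastic
half-space (Boussinesq) problem diagonalizes per wavevector into a 2x2
linear system ``u_hat(k) = G(k) T_hat(k)`` with the Green's tensor

    G(k) = 2 (1 + nu) / (E k^3) *
           [[(1 - nu) k^2 + nu ky^2,  -nu kx ky],
            [-nu kx ky,               (1 - nu) k^2 + nu kx^2]]

Inversion is either direct (nonregularized, used for large colonies) or
zeroth-order Tikhonov ``T_hat = (G^T G + lam_abs^2 I)^-1 G^T u_hat``
(regularized, used for single cells).  The regularization factor is
dimensionless: it is scaled by the largest singular value of G on the grid,
so its effect does not depend on grid size, spacing or substrate stiffness.

The strain energy transferred to the substrate is ``U = 1/2 integral T . u``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "DisplacementField",
    "TractionField",
    "StrainEnergyResult",
    "greens_tensor",
    "forward_displacement",
    "fttc_traction",
    "strain_energy",
    "drift_correct",
    "piv_displacement",
]


@dataclass
class DisplacementField:
    """Node-centered 2-D displacement field; ``u[iy, ix, :] = (ux, uy)`` in m."""

    u: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3 or self.u.shape[2] != 2:
            raise ValueError("u must have shape (ny, nx, 2)")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape[:2]


@dataclass
class TractionField:
    """Traction vectors per grid node (Pa) with substrate elastic constants."""

    T: np.ndarray
    spacing: float
    substrate_E: float
    nu: float = 0.5
    lam: float = 0.0

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if self.T.ndim != 3 or self.T.shape[2] != 2:
            raise ValueError("T must have shape (ny, nx, 2)")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.substrate_E <= 0:
            raise ValueError("substrate_E must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.T.shape[:2]


@dataclass
class StrainEnergyResult:
    U: float  # J
    density: np.ndarray  # J/m^2 per node


def _wavevectors(shape: tuple[int, int], spacing: float):
    ny, nx = shape
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=spacing)
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=spacing)
    KX, KY = np.meshgrid(kx, ky)
    K = np.hypot(KX, KY)
    return KX, KY, K


def greens_tensor(shape: tuple[int, int], spacing: float, E: float, nu: float):
    """Boussinesq half-space Green's tensor per wavevector.

    Returns (Gxx, Gxy, Gyy, K); the k=0 entries are set to 0 and must be
    handled by the caller (the zero mode carries no elastic information).
    """
    KX, KY, K = _wavevectors(shape, spacing)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * K**3)
        Gxx = pref * ((1.0 - nu) * K**2 + nu * KY**2)
        Gyy = pref * ((1.0 - nu) * K**2 + nu * KX**2)
        Gxy = pref * (-nu * KX * KY)
    Gxx[0, 0] = Gxy[0, 0] = Gyy[0, 0] = 0.0
    return Gxx, Gxy, Gyy, K


def _check_zero_mean(T: np.ndarray) -> None:
    total = np.abs(T.sum(axis=(0, 1)))
    scale = np.abs(T).sum()
    if scale > 0 and np.any(total > 1e-9 * scale):
        raise ValueError("unbalanced force: traction field must be zero-mean")


def forward_displacement(T: TractionField) -> DisplacementField:
    """Displacement produced by a balanced traction field on a periodic grid.

    Spectral application of the Green's tensor; the exact inverse of the
    nonregularized FTTC inversion, used as the built-in oracle.
    """
    _check_zero_mean(T.T)
    Gxx, Gxy, Gyy, _ = greens_tensor(T.shape, T.spacing, T.substrate_E, T.nu)
    Tx = np.fft.fft2(T.T[:, :, 0])
    Ty = np.fft.fft2(T.T[:, :, 1])
    ux = np.fft.ifft2(Gxx * Tx + Gxy * Ty).real
    uy = np.fft.ifft2(Gxy * Tx + Gyy * Ty).real
    return DisplacementField(u=np.stack([ux, uy], axis=-1), spacing=T.spacing)


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def fttc_traction(
    u: DisplacementField,
    substrate_E: float,
    nu: float = 0.5,
    lam: float = 1e-7,
    regularized: bool = True,
    taper: bool = False,
) -> TractionField:
    """Recover tractions from a displacement field by FTTC.

    Parameters
    ----------
    lam
        Dimensionless Tikhonov factor, relative to the largest singular value
        of the Green's tensor on this grid.  Ignored when ``regularized`` is
        False (direct per-wavevector inversion, colony mode).
    taper
        Mean-subtract and Hann-window the field before the FFT to suppress
        periodicity artifacts on non-periodic experimental fields.  Leave off
        for periodic synthetic fields (oracle mode).
    """
    if substrate_E <= 0:
        raise ValueError("substrate_E must be > 0")
    arr = u.u
    if not np.all(np.isfinite(arr)):
        raise ValueError("displacement field contains NaN/inf")
    if taper:
        w = _hann2d(u.shape)[..., None]
        arr = (arr - arr.mean(axis=(0, 1))) * w

    Gxx, Gxy, Gyy, _ = greens_tensor(u.shape, u.spacing, substrate_E, nu)
    ux = np.fft.fft2(arr[:, :, 0])
    uy = np.fft.fft2(arr[:, :, 1])

    # G is symmetric positive definite for k != 0: invert (with optional
    # Tikhonov filtering) through its eigendecomposition, one mode at a time
    tr = Gxx + Gyy
    disc = np.sqrt((Gxx - Gyy) ** 2 + 4 * Gxy**2)
    s1 = 0.5 * (tr + disc)
    s2 = 0.5 * (tr - disc)
    smax = float(np.max(s1))
    lam_abs = lam * smax if (regularized and lam > 0) else 0.0

    # eigenvector for s1; the s2 eigenvector is its perpendicular
    offdiag = np.abs(Gxy) > 1e-30 * smax
    v1x = np.where(offdiag, Gxy, np.where(Gxx >= Gyy, 1.0, 0.0))
    v1y = np.where(offdiag, s1 - Gxx, np.where(Gxx >= Gyy, 0.0, 1.0))
    vn = np.hypot(v1x, v1y)
    vn[vn == 0] = 1.0
    v1x, v1y = v1x / vn, v1y / vn
    v2x, v2y = -v1y, v1x

    def flt(s: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = s / (s**2 + lam_abs**2) if lam_abs > 0 else 1.0 / s
        phi[~np.isfinite(phi)] = 0.0
        return phi

    c1 = flt(s1) * (v1x * ux + v1y * uy)
    c2 = flt(s2) * (v2x * ux + v2y * uy)
    Tx = c1 * v1x + c2 * v2x
    Ty = c1 * v1y + c2 * v2y
    Tx[0, 0] = Ty[0, 0] = 0.0  # zero mode removed (force balance)
    T = np.stack([np.fft.ifft2(Tx).real, np.fft.ifft2(Ty).real], axis=-1)
    return TractionField(T=T, spacing=u.spacing, substrate_E=substrate_E,
                         nu=nu, lam=lam if regularized else 0.0)


def strain_energy(T: TractionField, u: DisplacementField) -> StrainEnergyResult:
    """Strain energy ``U = 1/2 sum (T . u) * cell_area`` and its density map."""
    if T.shape != u.shape or not np.isclose(T.spacing, u.spacing):
        raise ValueError("traction and displacement grids do not match")
    density = 0.5 * np.einsum("ijk,ijk->ij", T.T, u.u)
    U = float(density.sum() * T.spacing**2)
    return StrainEnergyResult(U=U, density=density)


def drift_correct(
    stack: np.ndarray, upsample_factor: int = 20, min_quality: float = 0.2
) -> tuple[np.ndarray, np.ndarray, list[bool]]:
    """Align a frame stack to its first frame by normalized cross-correlation.

    Returns (aligned stack, per-frame (dy, dx) shifts, low-quality flags).
    A frame whose aligned Pearson correlation with the reference falls below
    ``min_quality`` is flagged (likely featureless or pure noise).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of >= 2 frames")
    ref = stack[0]
    aligned = [ref.copy()]
    shifts = [np.zeros(2)]
    flags = [False]
    for frame in stack[1:]:
        if frame.shape != ref.shape:
            raise ValueError("frame size mismatch")
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None
        )
        moved = ndimage.shift(frame, shift, order=1, mode="nearest")
        r = np.corrcoef(ref.ravel(), moved.ravel())[0, 1]
        low = not np.isfinite(r) or r < min_quality
        if low:
            warnings.warn("low correlation peak: drift estimate unreliable")
        aligned.append(moved)
        shifts.append(np.asarray(shift, dtype=float))
        flags.append(bool(low))
    return np.stack(aligned), np.stack(shifts), flags


def _gaussian_subpixel(c: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """3-point Gaussian peak interpolation along each axis.

    The correlation background (median level) is removed first: a constant
    pedestal under the peak breaks the log-Gaussian model and shrinks the
    estimated subpixel offset.  Points driven non-positive fall back to a
    parabolic fit.
    """
    c = c - np.median(c)

    def offset(m1: float, c0: float, p1: float) -> float:
        if c0 <= 0 or c0 <= m1 or c0 <= p1:
            return 0.0
        if m1 > 0 and p1 > 0:
            denom = 2.0 * (np.log(m1) + np.log(p1) - 2.0 * np.log(c0))
            if denom < 0:
                return float((np.log(m1) - np.log(p1)) / denom)
        denom = 2.0 * (m1 + p1 - 2.0 * c0)
        if denom >= 0:
            return 0.0
        return float((m1 - p1) / denom)

    ny, nx = c.shape
    dy = offset(c[(iy - 1) % ny, ix], c[iy, ix], c[(iy + 1) % ny, ix])
    dx = offset(c[iy, (ix - 1) % nx], c[iy, ix], c[iy, (ix + 1) % nx])
    return dy, dx


def _window_correlate(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Circular FFT cross-correlation of two interrogation windows.

    Windows are mean-subtracted and Hann-weighted: edge truncation of bead
    images otherwise biases the correlation peak toward zero displacement.
    Returns (dy, dx, peak_ratio): displacement of b relative to a and the
    ratio of the primary correlation peak to the second-highest peak.
    """
    taper = _hann2d(a.shape)
    a = (a - a.mean()) * taper
    b = (b - b.mean()) * taper
    C = np.fft.ifft2(np.conj(np.fft.fft2(a)) * np.fft.fft2(b)).real
    iy, ix = np.unravel_index(np.argmax(C), C.shape)
    peak = C[iy, ix]
    # second peak outside the 3x3 neighborhood of the primary
    mask = np.ones_like(C, dtype=bool)
    for oy in (-1, 0, 1):
        for ox in (-1, 0, 1):
            mask[(iy + oy) % C.shape[0], (ix + ox) % C.shape[1]] = False
    second = C[mask].max()
    ratio = peak / second if second > 0 else np.inf
    dy, dx = _gaussian_subpixel(C, iy, ix)
    sy = iy if iy <= C.shape[0] // 2 else iy - C.shape[0]
    sx = ix if ix <= C.shape[1] // 2 else ix - C.shape[1]
    return sy + dy, sx + dx, float(ratio)


def piv_displacement(
    ref: np.ndarray,
    deformed: np.ndarray,
    windows: Sequence[int] = (64, 32, 16),
    overlap: float = 0.5,
    peak_ratio_min: float = 1.2,
    pixel_size: float = 1.0,
) -> DisplacementField:
    """Multi-pass window cross-correlation PIV.

    Each pass refines the previous pass's field at a smaller interrogation
    window: the deformed window is pre-shifted by the rounded predictor
    before correlating, so only the residual displacement must fit within
    the window.  Subpixel peaks use a 3-point Gaussian fit; vectors with a
    correlation peak ratio below ``peak_ratio_min`` are replaced by the
    local median.  Output displacements and grid spacing are multiplied by
    ``pixel_size`` (m/px); with the default 1.0 they stay in pixels.
    """
    ref = np.asarray(ref, dtype=float)
    deformed = np.asarray(deformed, dtype=float)
    if ref.shape != deformed.shape:
        raise ValueError("images must have the same shape")
    if any(w2 > w1 for w1, w2 in zip(windows, windows[1:])):
        raise ValueError("windows must be descending (repeats allowed for refinement)")
    if windows[0] > min(ref.shape):
        raise ValueError("window larger than image")

    H, W = ref.shape
    prev_field = None  # (ys, xs, U, V)
    for w in windows:
        step = max(1, int(w * overlap))
        ys = np.arange(0, H - w + 1, step)
        xs = np.arange(0, W - w + 1, step)
        U = np.zeros((len(ys), len(xs)))
        V = np.zeros((len(ys), len(xs)))
        bad = np.zeros((len(ys), len(xs)), dtype=bool)
        for i, y0 in enumerate(ys):
            for j, x0 in enumerate(xs):
                cy, cx = y0 + w / 2, x0 + w / 2
                py = px = 0
                if prev_field is not None:
                    py = int(round(_interp_field(prev_field, cy, cx, 1)))
                    px = int(round(_interp_field(prev_field, cy, cx, 0)))
                yb = min(max(y0 + py, 0), H - w)
                xb = min(max(x0 + px, 0), W - w)
                a = ref[y0 : y0 + w, x0 : x0 + w]
                b = deformed[yb : yb + w, xb : xb + w]
                dy, dx, ratio = _window_correlate(a, b)
                V[i, j] = (yb - y0) + dy
                U[i, j] = (xb - x0) + dx
                bad[i, j] = ratio < peak_ratio_min
        if bad.any() and not bad.all():
            medU = ndimage.median_filter(U, size=3, mode="nearest")
            medV = ndimage.median_filter(V, size=3, mode="nearest")
            U[bad] = medU[bad]
            V[bad] = medV[bad]
        prev_field = (ys + w / 2, xs + w / 2, U, V)

    ys, xs, U, V = prev_field
    u = np.stack([U, V], axis=-1) * pixel_size
    spacing = float((xs[1] - xs[0]) if len(xs) > 1 else windows[-1] * overlap)
    return DisplacementField(u=u, spacing=spacing * pixel_size)


def _interp_field(field, y: float, x: float, comp: int) -> float:
    """Bilinear lookup into a previous-pass PIV field (edge-clamped)."""
    ys, xs, U, V = field
    arr = U if comp == 0 else V

    def locate(grid, v):
        i0 = int(np.clip(np.searchsorted(grid, v) - 1, 0, len(grid) - 2)) \
            if len(grid) > 1 else 0
        if len(grid) == 1:
            return 0, 0, 0.0
        t = (v - grid[i0]) / (grid[i0 + 1] - grid[i0])
        return i0, i0 + 1, float(np.clip(t, 0.0, 1.0))

    iy0, iy1, ty = locate(ys, y)
    ix0, ix1, tx = locate(xs, x)
    top = (1 - tx) * arr[iy0, ix0] + tx * arr[iy0, ix1]
    bot = (1 - tx) * arr[iy1, ix0] + tx * arr[iy1, ix1]
    return float((1 - ty) * top + ty * bot)
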