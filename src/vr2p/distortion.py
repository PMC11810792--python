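"""Brown--Conrady radial distortion model for head-mounted display optics.

The projection optics of a compact head-mounted display introduce radial
distortion that is corrected in software by pre-warping the rendered image
with the inverse of the lens distortion.  The model used here is the purely
radial Brown--Conrady polynomial

    x_d = x_u * (1 + K1 r^2 + K2 r^4 + K3 r^6)
    y_d = y_u * (1 + K1 r^2 + K2 r^4 + K3 r^6)

where ``(x_u, y_u)`` are undistorted and ``(x_d, y_d)`` distorted
coordinates and ``r`` is the distance from the distortion center in units of
``norm_radius``.  The sign pattern of the coefficients distinguishes the
classical distortion types: all negative -> barrel, all positive ->
pincushion, mixed -> mustache.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "DistortionModel",
    "apply_distortion",
    "invert_distortion",
    "estimate_coefficients",
    "classify_distortion",
]


@dataclass(frozen=True)
class DistortionModel:
    """Radial distortion coefficients plus the normalization convention.

    Parameters
    ----------
    k1, k2, k3 : float
        Dimensionless radial coefficients of r^2, r^4 and r^6.
    center : tuple of float
        Distortion center in normalized image coordinates.
    norm_radius : float
        Distance from the center that maps to r = 1.  By convention we use
        half the image diagonal; rescaling this rescales the coefficients.
    """

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    norm_radius: float = 1.0

    def __post_init__(self) -> None:
        if not self.norm_radius > 0:
            raise ValueError(f"norm_radius must be > 0, got {self.norm_radius}")

    def radial_factor(self, r: np.ndarray) -> np.ndarray:
        """1 + K1 r^2 + K2 r^4 + K3 r^6 evaluated at normalized radius r."""
        r2 = np.asarray(r, dtype=float) ** 2
        return 1.0 + self.k1 * r2 + self.k2 * r2**2 + self.k3 * r2**3

    def _monotone_on(self, r_max: float, n_check: int = 512) -> bool:
        # d/dr [r * factor(r)] = 1 + 3 K1 r^2 + 5 K2 r^4 + 7 K3 r^6
        r2 = np.linspace(0.0, r_max, n_check) ** 2
        deriv = 1.0 + 3 * self.k1 * r2 + 5 * self.k2 * r2**2 + 7 * self.k3 * r2**3
        return bool(np.all(deriv > 0))


def _split(points: np.ndarray, model: DistortionModel) -> tuple[np.ndarray, np.ndarray]:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[-1] != 2:
        raise ValueError(f"points must have shape (n, 2), got {pts.shape}")
    rel = pts - np.asarray(model.center)
    r = np.hypot(rel[:, 0], rel[:, 1]) / model.norm_radius
    return rel, r


def apply_distortion(points: np.ndarray, model: DistortionModel) -> np.ndarray:
    """Map undistorted points to distorted ones through the radial polynomial.

    Raises
    ------
    ValueError
        If the radial mapping r -> r*(1 + K1 r^2 + ...) is not strictly
        increasing on the radial range covered by ``points`` (the inverse
        would then be ill-defined).
    """
    rel, r = _split(points, model)
    r_max = float(r.max()) if r.size else 0.0
    if r_max > 0 and not model._monotone_on(r_max):
        raise ValueError(
            f"radial polynomial is not monotone on [0, {r_max:.4g}]; "
            "distortion is not invertible on the requested domain"
        )
    out = rel * model.radial_factor(r)[:, None] + np.asarray(model.center)
    return out


def invert_distortion(
    points: np.ndarray,
    model: DistortionModel,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> np.ndarray:
    """Numerically invert the radial distortion.

    Works on the radius: given the distorted radius ``r_d``, solve
    ``r_u * g(r_u) = r_d`` by fixed-point iteration ``r_u <- r_d / g(r_u)``
    with a Newton fallback, then rescale the coordinates.  Guarantees
    ``|apply(invert(p)) - p| <= tol`` or raises.
    """
    rel, r_d = _split(points, model)
    r_u = r_d.copy()
    converged = np.zeros_like(r_d, dtype=bool)
    for _ in range(max_iter):
        g = model.radial_factor(r_u)
        resid = r_u * g - r_d
        converged = np.abs(resid) <= tol
        if converged.all():
            break
        # Newton step on h(r) = r*g(r) - r_d; fall back to fixed point where
        # the derivative is tiny.
        r2 = r_u**2
        dh = 1.0 + 3 * model.k1 * r2 + 5 * model.k2 * r2**2 + 7 * model.k3 * r2**3
        step = np.where(np.abs(dh) > 1e-12, resid / np.where(dh == 0, 1.0, dh), 0.0)
        newton = r_u - step
        fixed = np.where(g > 0, r_d / np.where(g == 0, 1.0, g), r_u)
        r_next = np.where(np.abs(dh) > 1e-12, newton, fixed)
        r_u = np.maximum(r_next, 0.0)
    else:
        worst = float(np.max(np.abs(r_u * model.radial_factor(r_u) - r_d)))
        raise RuntimeError(
            f"invert_distortion did not converge in {max_iter} iterations; "
            f"worst radial residual {worst:.3e}"
        )
    scale = np.where(r_d > 0, r_u / np.where(r_d == 0, 1.0, r_d), 1.0)
    return rel * scale[:, None] + np.asarray(model.center)


def estimate_coefficients(
    undistorted: np.ndarray,
    distorted: np.ndarray,
    center: tuple[float, float] = (0.0, 0.0),
    norm_radius: float = 1.0,
) -> tuple[DistortionModel, float]:
    """Fit (K1, K2, K3) from calibration point correspondences.

    Damped nonlinear least squares (Levenberg--Marquardt) on the
    reprojection residuals of the forward model.  Requires at least 6 pairs
    spanning several radii; a single-radius configuration leaves the three
    coefficients unidentifiable and raises.

    Returns
    -------
    (model, rms_residual)
    """
    und = np.atleast_2d(np.asarray(undistorted, dtype=float))
    dist = np.atleast_2d(np.asarray(distorted, dtype=float))
    if und.shape != dist.shape or und.shape[-1] != 2:
        raise ValueError("undistorted and distorted must be matching (n, 2) arrays")
    if und.shape[0] < 6:
        raise ValueError(f"need >= 6 point pairs, got {und.shape[0]}")
    rel = und - np.asarray(center)
    r = np.hypot(rel[:, 0], rel[:, 1]) / norm_radius
    # Identifiability: the design in (K1,K2,K3) is Vandermonde-like in r^2;
    # fewer than 3 distinct nonzero radii is rank deficient.
    design = np.column_stack([r**2, r**4, r**6]) * np.hypot(rel[:, 0], rel[:, 1])[:, None]
    if np.linalg.matrix_rank(design, tol=1e-10 * max(1.0, np.abs(design).max())) < 3:
        raise ValueError(
            "calibration points are rank deficient (too few distinct radii) "
            "for estimating three radial coefficients"
        )

    def residuals(k: np.ndarray) -> np.ndarray:
        model = DistortionModel(*k, center=center, norm_radius=norm_radius)
        pred = rel * model.radial_factor(r)[:, None] + np.asarray(center)
        return (pred - dist).ravel()

    sol = optimize.least_squares(residuals, x0=np.zeros(3), method="lm")
    model = DistortionModel(*sol.x, center=center, norm_radius=norm_radius)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return model, rms


def classify_distortion(model: DistortionModel, tol: float = 1e-12) -> str:
    """Classify the distortion type from the coefficient sign pattern.

    Negative coefficients indicate barrel distortion, positive pincushion,
    and a mix of signs mustache distortion.  All coefficients at zero means
    no distortion.
    """
    ks = np.array([model.k1, model.k2, model.k3])
    nonzero = ks[np.abs(ks) > tol]
    if nonzero.size == 0:
        return "none"
    if np.all(nonzero > 0):
        return "pincushion"
    if np.all(nonzero < 0):
        return "barrel"
    return "mustache"
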