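"""Hertz-model elasticity from AFM force-indentation curves.

A sharp indenter pressed into an (assumed) linear-elastic, incompressible
half-space produces a force

    F = C(geometry) * E / (1 - nu^2) * (delta - delta0)^2

where ``E`` is the Young's modulus, ``nu`` the Poisson ratio (0.5 for live
cells), ``delta`` the indentation depth and ``delta0`` the contact point.
The geometry factor is ``(2/pi)*tan(alpha)`` for a cone of half-angle
``alpha`` (Sneddon) and ``0.7453*tan(alpha)`` for a four-sided pyramid of
face angle ``alpha`` (Bilodeau).

Units throughout: indentation in nm, force in nN, modulus in Pa.  The fit
window is capped at 0.5 nN by default, matching the low loading forces used
for live-cell elasticity mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ForceCurve",
    "HertzFit",
    "ElasticityMap",
    "hertz_force",
    "geometry_factor",
    "detect_contact_point",
    "fit_hertz",
    "map_elasticity",
]

_BILODEAU = 0.7453  # four-sided pyramid prefactor


class ContactPointError(RuntimeError):
    """No usable contact point could be located on the curve."""


def geometry_factor(geometry: str, alpha_deg: float) -> float:
    """Dimensionless prefactor C of the Hertz force law for a sharp tip."""
    tan_a = np.tan(np.deg2rad(alpha_deg))
    if geometry == "cone":
        return (2.0 / np.pi) * tan_a
    if geometry == "pyramid":
        return _BILODEAU * tan_a
    raise ValueError(f"unknown tip geometry {geometry!r}")


def hertz_force(
    indentation_nm: np.ndarray | float,
    E_pa: float,
    geometry: str = "cone",
    alpha_deg: float = 35.0,
    nu: float = 0.5,
) -> np.ndarray:
    """Forward Hertz model: force (nN) at the given indentation depth (nm).

    Negative indentations (tip above the surface) give zero force.
    """
    delta = np.clip(np.asarray(indentation_nm, dtype=float), 0.0, None)
    C = geometry_factor(geometry, alpha_deg)
    # E[Pa] * (delta[nm] * 1e-9 m)^2 -> N; 1e9 nN/N leaves a net 1e-9
    return C * E_pa / (1.0 - nu**2) * delta**2 * 1e-9


@dataclass
class ForceCurve:
    """Approach segment of a force-distance curve.

    ``position_nm`` is the tip-sample axis (piezo extension mapped so that
    larger values indent deeper); ``force_nN`` the measured load.  Before
    the contact point the force is a flat baseline; after it the Hertz ramp.
    """

    position_nm: np.ndarray
    force_nN: np.ndarray

    def __post_init__(self) -> None:
        self.position_nm = np.asarray(self.position_nm, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.position_nm.shape != self.force_nN.shape:
            raise ValueError("position and force must have equal length")
        if not np.all(np.isfinite(self.force_nN)):
            raise ValueError("force values must be finite")
        if np.any(np.diff(self.position_nm) < 0):
            raise ValueError("approach segment must have non-decreasing position")

    @classmethod
    def from_z_deflection(
        cls,
        z_nm: np.ndarray,
        deflection_nm: np.ndarray,
        k_spring: float,
    ) -> "ForceCurve":
        """Convert raw (piezo z, cantilever deflection) to force vs position.

        ``k_spring`` is in N/m, so force in nN is simply ``k * deflection``
        with the deflection in nm; the sample position is ``z - deflection``
        (cantilever bending subtracts from the indentation).
        """
        z = np.asarray(z_nm, dtype=float)
        d = np.asarray(deflection_nm, dtype=float)
        return cls(position_nm=z - d, force_nN=k_spring * d)

    @classmethod
    def from_text(cls, path: str | Path, k_spring: float | None = None) -> "ForceCurve":
        """Read a two-column text/CSV curve.

        Columns are (position_nm, force_nN), or (z_nm, deflection_nm) when a
        spring constant is supplied.
        """
        data = np.loadtxt(path, delimiter=None if k_spring is None else None)
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns")
        a, b = data[:, 0], data[:, 1]
        if k_spring is not None:
            return cls.from_z_deflection(a, b, k_spring)
        return cls(position_nm=a, force_nN=b)

    def __len__(self) -> int:
        return len(self.position_nm)


@dataclass
class HertzFit:
    """Result of a Hertz fit on one curve."""

    E_pa: float
    contact_point_nm: float
    baseline_nN: float
    residual_rms_nN: float
    geometry: str
    alpha_deg: float
    nu: float
    n_points: int


def detect_contact_point(
    curve: ForceCurve,
    min_baseline_points: int = 5,
    min_contact_points: int = 10,
) -> tuple[float, float]:
    """Locate the contact point and force baseline of an approach curve.

    Grid search over candidate contact samples: each candidate splits the
    curve into a flat pre-contact baseline and a quadratic (Hertz-shaped)
    post-contact ramp, fitted by least squares; the split with the smallest
    total squared residual wins.

    Returns ``(delta0_nm, baseline_nN)``.  Raises :class:`ContactPointError`
    when the curve has no baseline region or no detectable contact (flat
    noise).
    """
    z = curve.position_nm
    F = curve.force_nN
    n = len(z)
    if n < min_baseline_points + min_contact_points:
        raise ContactPointError("curve too short for contact detection")

    best = (np.inf, None, None)
    for i in range(min_baseline_points, n - min_contact_points + 1):
        b = F[:i].mean()
        x2 = (z[i:] - z[i]) ** 2
        denom = float(np.dot(x2, x2))
        if denom == 0:
            continue
        a = float(np.dot(x2, F[i:] - b)) / denom
        ssr = float(np.sum((F[:i] - b) ** 2)) + float(
            np.sum((F[i:] - b - a * x2) ** 2)
        )
        if ssr < best[0]:
            best = (ssr, i, (a, b))
    if best[1] is None:
        raise ContactPointError("no candidate contact point")
    i = best[1]
    a, b = best[2]
    # Flat-noise guard: the post-contact rise must clear the baseline scatter.
    baseline_sd = float(F[:i].std()) if i > 1 else 0.0
    rise = float(F[-min(5, n):].mean() - b)
    if a <= 0 or rise <= 3.0 * baseline_sd:
        raise ContactPointError("no contact detected (flat curve)")
    return float(z[i]), float(b)


def fit_hertz(
    curve: ForceCurve,
    geometry: str = "cone",
    alpha_deg: float = 35.0,
    nu: float = 0.5,
    max_force_nN: float = 0.5,
    contact: tuple[float, float] | None = None,
) -> HertzFit:
    """Fit the Young's modulus of one approach curve.

    The contact point and baseline are grid-searched first (unless given),
    then (E, delta0, baseline) are refined jointly by nonlinear least
    squares on the window of post-contact samples with net force at most
    ``max_force_nN``.
    """
    if contact is None:
        contact = detect_contact_point(curve)
    delta0, baseline = contact
    C = geometry_factor(geometry, alpha_deg)
    k = C / (1.0 - nu**2) * 1e-9  # F_nN = k * E_pa * delta_nm^2

    z = curve.position_nm
    F = curve.force_nN

    def model(zz: np.ndarray, E: float, d0: float, b: float) -> np.ndarray:
        return b + k * E * np.clip(zz - d0, 0.0, None) ** 2

    # Initial linear estimate of E on the post-contact samples.
    post = z >= delta0
    x2 = (z[post] - delta0) ** 2
    denom = float(np.dot(x2, x2))
    E0 = max(float(np.dot(x2, F[post] - baseline)) / denom / k, 1.0) if denom else 1.0

    # Two passes: the force cap is applied to the model prediction (capping
    # on the noisy measured force would preferentially discard upward noise
    # near the cap and bias E low).  The pre-contact baseline samples stay
    # in the fit; they anchor the baseline and contact point.
    popt = np.array([E0, delta0, baseline])
    try:
        for _ in range(2):
            window = ~post | (model(z, *popt) - popt[2] <= max_force_nN)
            if (window & post).sum() < 10:
                raise ValueError(
                    "fewer than 10 post-contact samples in the fit window"
                )
            popt, _ = curve_fit(
                model, z[window], F[window], p0=popt, maxfev=20000
            )
    except RuntimeError as exc:  # pragma: no cover - rare
        raise RuntimeError(f"Hertz fit did not converge: {exc}") from exc
    E_hat, d0_hat, b_hat = popt
    zw, Fw = z[window], F[window]
    if E_hat <= 0:
        raise ValueError("fitted modulus is non-positive")
    resid = Fw - model(zw, *popt)
    return HertzFit(
        E_pa=float(E_hat),
        contact_point_nm=float(d0_hat),
        baseline_nN=float(b_hat),
        residual_rms_nN=float(np.sqrt(np.mean(resid**2))),
        geometry=geometry,
        alpha_deg=alpha_deg,
        nu=nu,
        n_points=int(window.sum()),
    )


@dataclass
class ElasticityMap:
    """Spatial Young's-modulus map plus its probability histogram.

    ``modulus_pa`` holds NaN where the per-curve fit failed; failed cells
    are excluded from the histogram, whose probabilities sum to 1.
    """

    modulus_pa: np.ndarray
    grid_pitch_nm: float
    histogram_edges_pa: np.ndarray = field(default=None)  # type: ignore[assignment]
    histogram_probability: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_failed: int = 0

    def __post_init__(self) -> None:
        self.modulus_pa = np.asarray(self.modulus_pa, dtype=float)
        if self.histogram_edges_pa is None:
            self.recompute_histogram()

    def recompute_histogram(self, bins: int = 30) -> None:
        values = self.modulus_pa[np.isfinite(self.modulus_pa)]
        if values.size == 0:
            raise ValueError("no successful fits in the map")
        counts, edges = np.histogram(values, bins=bins)
        self.histogram_edges_pa = edges
        self.histogram_probability = counts / counts.sum()


def map_elasticity(
    curves: Sequence[Sequence[ForceCurve | None]],
    grid_pitch_nm: float = 100.0,
    geometry: str = "cone",
    alpha_deg: float = 35.0,
    nu: float = 0.5,
    max_force_nN: float = 0.5,
) -> ElasticityMap:
    """Fit every curve of a rectangular scan grid into an elasticity map.

    ``curves[r][c]`` may be None for a missing cell.  Cells whose fit fails
    are recorded as NaN and excluded from the probability histogram.
    """
    n_rows = len(curves)
    n_cols = len(curves[0])
    E = np.full((n_rows, n_cols), np.nan)
    n_failed = 0
    for r in range(n_rows):
        for c in range(n_cols):
            curve = curves[r][c]
            if curve is None:
                n_failed += 1
                continue
            try:
                E[r, c] = fit_hertz(
                    curve,
                    geometry=geometry,
                    alpha_deg=alpha_deg,
                    nu=nu,
                    max_force_nN=max_force_nN,
                ).E_pa
            except (ValueError, RuntimeError, ContactPointError):
                n_failed += 1
    if not np.any(np.isfinite(E)):
        raise RuntimeError("all Hertz fits failed")
    return ElasticityMap(modulus_pa=E, grid_pitch_nm=grid_pitch_nm, n_failed=n_failed)
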