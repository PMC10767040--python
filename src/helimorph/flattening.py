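"""Elliptical flattening of round tube models at fixed perimeter.

Tubes embedded in thin vitreous ice are often compressed into an elliptical
cross-section.  Because the tube wall is a (locally rigid) 2D crystal, the
deformation conserves the cross-section perimeter: the round circumference C
becomes an ellipse with semi-major axis a = scale * r (scale 1.00-1.09,
i.e. 0-9 % flattening) whose semi-minor axis b is solved numerically so the
elliptical perimeter equals C.  Each subunit keeps its arc-length position
along the cross-section and its axial position, and is re-oriented so its
outward reference vector follows the local ellipse normal (a rotation about
the vertical axis through its center of gravity).

Perimeters and arc lengths use the complete/incomplete elliptic integrals
of the second kind (machine precision); the minor axis and arc-length
inversions use bracketed scalar root finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import ellipe, ellipeinc

from .tube import SubunitPlacement, TubeModel, _rot_z

__all__ = [
    "EllipseSpec",
    "ellipse_perimeter",
    "minor_axis_for_perimeter",
    "point_at_arc_length",
    "flatten",
]


@dataclass(frozen=True)
class EllipseSpec:
    """A perimeter-preserving elliptical cross-section.

    ``scale`` relates the semi-major axis to the round radius r = C/(2π):
    semi_major = scale * r, so scale 1.05 means 5 % flattening.
    """

    semi_major: float
    semi_minor: float
    perimeter: float
    scale: float


def ellipse_perimeter(semi_major: float, semi_minor: float) -> float:
    """Perimeter of an ellipse with the given semi-axes (Å).

    Uses the complete elliptic integral of the second kind:
    P = 4 a E(m), m = 1 - (b/a)^2 with a the larger semi-axis.  Relative
    accuracy is far better than 1e-9; a circle returns exactly 2*pi*a.
    """
    if not (semi_major > 0 and semi_minor > 0):
        raise ValueError("ellipse semi-axes must be positive")
    a, b = max(semi_major, semi_minor), min(semi_major, semi_minor)
    m = 1.0 - (b / a) ** 2
    return float(4.0 * a * ellipe(m))


def minor_axis_for_perimeter(circumference: float, scale: float) -> EllipseSpec:
    """Solve the semi-minor axis so the ellipse perimeter equals ``circumference``.

    ``scale`` >= 1 multiplies the round radius r = C/(2π) to give the
    semi-major axis.  The root is bracketed in [0.4 r, r] and refined until
    the perimeter residual satisfies |ΔC|/C <= 1e-8.
    """
    if not circumference > 0:
        raise ValueError("circumference must be positive")
    if scale < 1.0:
        raise ValueError("flattening scale must be >= 1")
    r = circumference / (2.0 * math.pi)
    if scale == 1.0:
        return EllipseSpec(r, r, circumference, 1.0)
    a = scale * r

    def residual(b: float) -> float:
        return ellipse_perimeter(a, b) - circumference

    lo, hi = 0.4 * r, r
    if residual(lo) > 0:
        raise ValueError(
            f"flattening scale {scale} too large: no perimeter-preserving "
            "minor axis in the bracket [0.4 r, r]"
        )
    b = brentq(residual, lo, hi, xtol=1e-12 * r, rtol=8.9e-16)
    spec = EllipseSpec(a, float(b), circumference, scale)
    if abs(ellipse_perimeter(a, b) - circumference) / circumference > 1e-8:
        raise RuntimeError("perimeter solver did not converge to 1e-8 relative")
    return spec


def _arc_length(spec: EllipseSpec, t: float) -> float:
    """Arc length from (a, 0) counterclockwise to parameter angle t.

    Parameterization (x, y) = (a cos t, b sin t); the integrand
    sqrt(a² sin²u + b² cos²u) reduces to the incomplete elliptic integral
    E(φ, m) with m = 1 - (b/a)².
    """
    a, b = spec.semi_major, spec.semi_minor
    m = 1.0 - (b / a) ** 2
    return float(a * (ellipe(m) - ellipeinc(0.5 * math.pi - t, m)))


def point_at_arc_length(spec: EllipseSpec, s: float) -> tuple[float, float, np.ndarray]:
    """Point and outward normal at arc length ``s`` from (semi_major, 0).

    ``s`` is taken modulo the perimeter and measured counterclockwise.
    Returns (x, y, normal) with the exact unit outward normal
    ∝ (cos t / a, sin t / b).
    """
    P = spec.perimeter
    s = s % P

    def f(t: float) -> float:
        return _arc_length(spec, t) - s

    # L(t) is strictly monotone on [0, 2π] with L(0)=0, L(2π)=P; guard the
    # endpoints against rounding of s % P near 0 or P
    two_pi = 2.0 * math.pi
    if f(0.0) >= 0.0:
        t = 0.0
    elif f(two_pi) <= 0.0:
        t = two_pi
    else:
        t = brentq(f, 0.0, two_pi, xtol=1e-13, rtol=8.9e-16)
    a, b = spec.semi_major, spec.semi_minor
    x, y = a * math.cos(t), b * math.sin(t)
    n = np.array([math.cos(t) / a, math.sin(t) / b])
    n /= np.linalg.norm(n)
    return float(x), float(y), n


def flatten(tube: TubeModel, scale: float, phase_deg: float = 0.0) -> TubeModel:
    """Deform a round tube to an elliptical cross-section of equal perimeter.

    Each subunit's circular arc coordinate s = r * azimuth maps to the point
    at the same arc length on the ellipse (z unchanged), and the subunit is
    rotated about the vertical axis through its center of gravity so its
    outward reference direction aligns with the ellipse normal.

    ``phase_deg`` offsets the registration between azimuth zero and the
    flattening (major) axis; the default puts azimuth 0 on the major axis.
    Only round tubes can be flattened; compose different scales from the
    round model rather than re-flattening.
    """
    if tube.flattening_scale != 1.0:
        raise ValueError("input tube is already flattened; start from the round model")
    if scale == 1.0:
        return TubeModel(
            unit=tube.unit,
            placements=list(tube.placements),
            symmetry=tube.symmetry,
            lattice=tube.lattice,
            flattening_scale=1.0,
            ellipse=minor_axis_for_perimeter(tube.symmetry.circumference, 1.0),
        )
    spec = minor_axis_for_perimeter(tube.symmetry.circumference, scale)
    r = tube.symmetry.radius
    com_u = tube.unit.center_of_mass
    new_placements: list[SubunitPlacement] = []
    for p in tube.placements:
        com = p.rotation @ com_u + p.translation
        theta = math.atan2(com[1], com[0])
        s = r * (theta + math.radians(phase_deg))
        x, y, n = point_at_arc_length(spec, s)
        delta = math.degrees(math.atan2(n[1], n[0])) - math.degrees(theta)
        Rz = _rot_z(delta)
        new_R = Rz @ p.rotation
        new_com = np.array([x, y, com[2]])
        # affine: x -> RzΔ (R x + t - com) + new_com
        new_t = Rz @ (p.translation - com) + new_com
        new_placements.append(SubunitPlacement(new_R, new_t, p.lattice_coords))
    return TubeModel(
        unit=tube.unit,
        placements=new_placements,
        symmetry=tube.symmetry,
        lattice=tube.lattice,
        flattening_scale=scale,
        ellipse=spec,
    )
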