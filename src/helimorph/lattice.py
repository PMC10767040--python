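"""Helical symmetry from a wrapped 2D crystal lattice.

A tubular protein crystal can be described by rolling a planar 2D lattice
onto a cylinder.  The roll is specified by a *wrapping vector*

    w = n1*a + n2*b

where ``a`` and ``b`` are the lattice basis vectors (in Å, expressed in a
plane whose x axis is the equatorial/arc direction of a chosen reference
wrapping and whose y axis is the helix axis).  The wrapping vector lies in
the equator of the resulting tube and its length is the tube circumference.
Each integer pair ``(n1, n2)`` therefore defines a distinct helical
polymorph built from the *same* local packing.

This module turns a lattice plus a wrapping index into a full helical
symmetry description (circumference, radius, per-basis-vector twists and
rises, rotational order, and a canonical one-start screw operator) and can
enumerate all candidate polymorphs within a circumference range.

All lengths are in Å and all angles in degrees unless noted otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "Lattice2D",
    "WrappingIndex",
    "HelicalSymmetry",
    "VP39_LATTICE",
    "wrapping_vector",
    "rotational_order",
    "helix_from_wrapping",
    "enumerate_wrappings",
    "default_sector",
    "spin_angle",
]


@dataclass(frozen=True)
class Lattice2D:
    """Basis vectors of the 2D crystal lattice.

    Components are ``(arc, axial)`` in Å: the first component runs along the
    equator of the reference wrapping, the second along the helix axis.
    """

    a: tuple[float, float]
    b: tuple[float, float]

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != (2,) or b.shape != (2,):
            raise ValueError("lattice basis vectors must be 2-vectors")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("lattice basis vectors must be finite")
        if abs(float(a[0] * b[1] - a[1] * b[0])) <= 1e-9 * (np.linalg.norm(a) * np.linalg.norm(b) + 1.0):
            raise ValueError("lattice basis vectors are collinear (degenerate lattice)")
        object.__setattr__(self, "a", (float(a[0]), float(a[1])))
        object.__setattr__(self, "b", (float(b[0]), float(b[1])))

    @property
    def a_vec(self) -> np.ndarray:
        return np.array(self.a, dtype=float)

    @property
    def b_vec(self) -> np.ndarray:
        return np.array(self.b, dtype=float)

    @property
    def det(self) -> float:
        """Signed unit-cell area (Å²)."""
        a, b = self.a_vec, self.b_vec
        return float(a[0] * b[1] - a[1] * b[0])

    def scaled(self, factor: float) -> "Lattice2D":
        return Lattice2D(tuple(factor * self.a_vec), tuple(factor * self.b_vec))


#: The 2D crystal lattice of the VP39 nucleocapsid wall, as determined from
#: the C14 helical reconstruction (arc, axial components in Å).
VP39_LATTICE = Lattice2D(a=(27.91, -43.86), b=(72.31, 43.86))


@dataclass(frozen=True)
class WrappingIndex:
    """Integer wrapping index (n1, n2); (0, 0) is not a valid wrapping."""

    n1: int
    n2: int

    def __post_init__(self) -> None:
        if int(self.n1) != self.n1 or int(self.n2) != self.n2:
            raise ValueError("wrapping index components must be integers")
        object.__setattr__(self, "n1", int(self.n1))
        object.__setattr__(self, "n2", int(self.n2))
        if self.n1 == 0 and self.n2 == 0:
            raise ValueError("wrapping index (0, 0) does not define a tube")

    def __iter__(self):
        return iter((self.n1, self.n2))


def _as_index(idx) -> WrappingIndex:
    if isinstance(idx, WrappingIndex):
        return idx
    n1, n2 = idx
    return WrappingIndex(int(n1), int(n2))


@dataclass(frozen=True)
class HelicalSymmetry:
    """Complete helical description of one wrapping of a 2D lattice.

    ``x1, y1`` (``x2, y2``) are the arc and axial components of basis vector
    ``a`` (``b``) in the frame of this wrapping; ``twist1``/``twist2`` are the
    corresponding azimuthal rotations (360°·x/C).  ``order`` is the
    rotational symmetry order Cn.  The canonical one-start operator has
    positive rise by convention; the sign of its twist encodes handedness.
    """

    index: WrappingIndex
    circumference: float
    radius: float
    diameter: float
    x1: float
    y1: float
    x2: float
    y2: float
    twist1: float
    twist2: float
    order: int
    one_start_twist: float
    one_start_rise: float


def wrapping_vector(lattice: Lattice2D, idx) -> np.ndarray:
    """Return w = n1*a + n2*b (Å); its length is the tube circumference."""
    idx = _as_index(idx)
    return idx.n1 * lattice.a_vec + idx.n2 * lattice.b_vec


def rotational_order(idx) -> int:
    """Rotational symmetry order of the wrapped tube, gcd(|n1|, |n2|).

    A Cn rotation maps the rolled lattice onto itself exactly when n divides
    both wrapping components; the largest such n is the gcd.  For example
    (14, 14) gives C14 while (6, 13) gives C1 (no rotational symmetry).
    """
    idx = _as_index(idx)
    return math.gcd(abs(idx.n1), abs(idx.n2))


def _egcd(p: int, q: int) -> tuple[int, int, int]:
    """Extended gcd: returns (g, s, t) with s*p + t*q = g = gcd(p, q) >= 0."""
    old_r, r = p, q
    old_s, s = 1, 0
    old_t, t = 0, 1
    while r != 0:
        quo = old_r // r
        old_r, r = r, old_r - quo * r
        old_s, s = s, old_s - quo * s
        old_t, t = t, old_t - quo * t
    if old_r < 0:
        old_r, old_s, old_t = -old_r, -old_s, -old_t
    return old_r, old_s, old_t


def helix_from_wrapping(lattice: Lattice2D, idx) -> HelicalSymmetry:
    """Derive the full helical symmetry of wrapping ``idx`` of ``lattice``.

    Decomposes each basis vector into components along the wrapping
    direction (arc) and perpendicular to it (axial), converts arcs to
    azimuthal twists, and constructs the canonical one-start screw operator:
    the lattice translation with the smallest positive rise, its twist
    reduced modulo 360°/order to the smallest absolute value.
    """
    idx = _as_index(idx)
    w = wrapping_vector(lattice, idx)
    circ = float(np.linalg.norm(w))
    radius = circ / (2.0 * math.pi)
    w_hat = w / circ
    axial_hat = np.array([-w_hat[1], w_hat[0]])  # 90° CCW: right-handed (arc, axial)

    a, b = lattice.a_vec, lattice.b_vec
    x1, y1 = float(a @ w_hat), float(a @ axial_hat)
    x2, y2 = float(b @ w_hat), float(b @ axial_hat)
    twist1 = 360.0 * x1 / circ
    twist2 = 360.0 * x2 / circ

    order = rotational_order(idx)

    # Axial rises of lattice translations form the set t*g*Z with
    # t = det(a,b)/C, so the minimal positive rise is |t|*g.  Find one
    # lattice point achieving it via the extended gcd and reduce its twist
    # modulo the Cn rotation (period 360/order) to the smallest magnitude.
    t_unit = lattice.det / circ
    g0, s, t = _egcd(idx.n1, idx.n2)
    assert g0 == order
    k_target = order if t_unit > 0 else -order
    m = k_target // g0
    u2, u1 = s * m, -t * m  # n1*u2 - n2*u1 = k_target
    rise = abs(t_unit) * order
    arc = u1 * x1 + u2 * x2
    twist = 360.0 * arc / circ
    period = 360.0 / order
    twist -= period * math.floor(twist / period + 0.5)

    return HelicalSymmetry(
        index=idx,
        circumference=circ,
        radius=radius,
        diameter=2.0 * radius,
        x1=x1, y1=y1, x2=x2, y2=y2,
        twist1=twist1, twist2=twist2,
        order=order,
        one_start_twist=twist,
        one_start_rise=rise,
    )


def default_sector(
    lattice: Lattice2D, pitch_limit_deg: float = 20.0
) -> Callable[[WrappingIndex, HelicalSymmetry], bool]:
    """Default sector predicate for polymorph enumeration.

    Accepts wrappings whose pitch angle |atan2(w_axial, w_arc)| (components
    taken in the reference lattice frame) does not exceed
    ``pitch_limit_deg`` and whose index satisfies n1 + n2 > 0 (sign
    canonicalization: (n1, n2) and (−n1, −n2) describe the same tube).
    """

    def predicate(idx: WrappingIndex, sym: HelicalSymmetry) -> bool:
        if idx.n1 + idx.n2 <= 0:
            return False
        w = wrapping_vector(lattice, idx)
        pitch = math.degrees(math.atan2(abs(float(w[1])), abs(float(w[0]))))
        return pitch <= pitch_limit_deg

    return predicate


def enumerate_wrappings(
    lattice: Lattice2D,
    c_min: float,
    c_max: float,
    sector: Callable[[WrappingIndex, HelicalSymmetry], bool] | None = None,
    pitch_limit_deg: float = 20.0,
) -> list[WrappingIndex]:
    """Enumerate wrapping indices with circumference in [c_min, c_max].

    Candidates are deduplicated under (n1, n2) ↔ (−n1, −n2) and filtered by
    a sector predicate.  The default sector keeps wrappings whose pitch
    angle |atan2(w_axial, w_arc)| (in the reference lattice frame) is at
    most ``pitch_limit_deg`` and canonicalizes signs with n1 + n2 > 0.
    Results are ordered by ascending circumference, then n1, then n2.
    """
    if not (0 < c_min < c_max):
        raise ValueError("require 0 < c_min < c_max")
    basis = np.column_stack([lattice.a_vec, lattice.b_vec])
    sigma_min = float(np.linalg.svd(basis, compute_uv=False)[-1])
    n_max = int(math.ceil(c_max / sigma_min)) + 1

    found: dict[tuple[int, int], float] = {}
    for n1 in range(-n_max, n_max + 1):
        for n2 in range(-n_max, n_max + 1):
            if n1 == 0 and n2 == 0:
                continue
            idx = WrappingIndex(n1, n2)
            w = wrapping_vector(lattice, idx)
            circ = float(np.linalg.norm(w))
            if not (c_min <= circ <= c_max):
                continue
            if sector is None:
                if n1 + n2 <= 0 or (n1 + n2 == 0 and n1 <= 0):
                    continue
                pitch = math.degrees(math.atan2(abs(w[1]), abs(w[0])))
                if pitch > pitch_limit_deg:
                    continue
            else:
                sym = helix_from_wrapping(lattice, idx)
                if not sector(idx, sym):
                    continue
            key = (n1, n2)
            mirror = (-n1, -n2)
            if mirror in found:
                continue
            found[key] = circ

    ordered = sorted(found.items(), key=lambda kv: (kv[1], kv[0][0], kv[0][1]))
    return [WrappingIndex(*k) for k, _ in ordered]


def spin_angle(lattice: Lattice2D, idx, reference_idx=(14, 14)) -> float:
    """Signed angle (degrees) from the reference wrapping direction to ŵ.

    This is the in-plane rotation of the 2D lattice between two wrappings:
    a subunit oriented for the reference wrapping must be spun by this angle
    about its radial vector (see :mod:`helimorph.tube`) to sit correctly on
    the new tube.  Positive spin tilts the wrapping vector toward +axial.
    """
    w = wrapping_vector(lattice, _as_index(idx))
    w_ref = wrapping_vector(lattice, _as_index(reference_idx))
    cross = float(w_ref[0] * w[1] - w_ref[1] * w[0])
    dot = float(w_ref @ w)
    return math.degrees(math.atan2(cross, dot))
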