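"""Build 3D tube models by placing a rigid subunit on a wrapped lattice.

The asymmetric unit (for the baculovirus nucleocapsid, the VP39 dimer) is
first translated radially so its center of mass sits on the tube surface,
then symmetry-expanded: each lattice point maps to a placement obtained by
rotating about the helix axis to the point's azimuth, translating to its
axial position, and spinning the subunit about its radial vector to account
for the in-plane rotation of the 2D lattice between wrappings.

Conventions
-----------
* Helix axis = +z; azimuth measured from +x toward +y (right handed).
* The radialized unit sits with its center of mass at (r, 0, 0) and its
  outward direction along +x; its tangential direction is +y and axial +z.
* Positive spin appears counterclockwise when viewed from outside the tube
  looking inward along −radial; internally this is a rotation by −spin
  about the +x axis of the radialized frame.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .lattice import (
    HelicalSymmetry,
    Lattice2D,
    WrappingIndex,
    _as_index,
    helix_from_wrapping,
    spin_angle,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "AsymmetricUnit",
    "SubunitPlacement",
    "LatticeSite",
    "TubeModel",
    "NeighborContact",
    "radialize",
    "lattice_points_in_window",
    "build_tube",
    "neighbor_pairs",
    "write_model",
    "read_unit",
]

# Scattering weights (≈ atomic number) used for the center of mass and for
# density rendering; unknown elements fall back to a generic carbon-like
# scatterer.
_ELEMENT_WEIGHTS = {
    "H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0, "P": 15.0, "S": 16.0,
    "MG": 12.0, "ZN": 30.0, "FE": 26.0, "CA": 20.0, "MN": 25.0,
    "NA": 11.0, "K": 19.0, "CL": 17.0,
}
_DEFAULT_WEIGHT = 6.0


@dataclass
class AtomRecord:
    """One atom (or pseudo-atom blob) of the asymmetric unit."""

    element: str
    position: np.ndarray  # (3,) Å
    name: str = "C"
    occupancy: float = 1.0
    b_factor: float = 20.0
    chain: str = "A"
    res_name: str = "ALA"
    res_seq: int = 1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")

    @property
    def weight(self) -> float:
        return _ELEMENT_WEIGHTS.get(self.element.upper(), _DEFAULT_WEIGHT)


@dataclass
class AsymmetricUnit:
    """A rigid subunit: atoms plus a defined outward (radial) direction."""

    atoms: list[AtomRecord]
    radial_reference: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("asymmetric unit needs at least one atom")
        v = np.asarray(self.radial_reference, dtype=float).reshape(3)
        n = np.linalg.norm(v)
        if n == 0 or not np.all(np.isfinite(v)):
            raise ValueError("radial_reference must be a nonzero finite vector")
        self.radial_reference = v / n

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([a.weight for a in self.atoms], dtype=float)

    @property
    def center_of_mass(self) -> np.ndarray:
        w = self.weights
        return (self.positions * w[:, None]).sum(axis=0) / w.sum()

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AsymmetricUnit":
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_atoms = [
            replace(a, position=rotation @ a.position + translation) for a in self.atoms
        ]
        return AsymmetricUnit(new_atoms, rotation @ self.radial_reference)


@dataclass(frozen=True)
class LatticeSite:
    """One subunit location on the rolled-out tube surface."""

    u1: int
    u2: int
    azimuth_deg: float
    z: float
    spin_deg: float


@dataclass(frozen=True)
class SubunitPlacement:
    """Rigid placement x -> R x + t applied to the radialized unit."""

    rotation: np.ndarray  # (3, 3), proper rotation
    translation: np.ndarray  # (3,) Å
    lattice_coords: tuple[int, int]

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) \
                or not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be a proper orthonormal 3x3 matrix")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))


@dataclass
class TubeModel:
    """A polymorph model: radialized unit + placements + symmetry."""

    unit: AsymmetricUnit
    placements: list[SubunitPlacement]
    symmetry: HelicalSymmetry
    lattice: Lattice2D
    flattening_scale: float = 1.0
    ellipse: object | None = None  # EllipseSpec when flattened

    def atom_positions(self) -> np.ndarray:
        """All atom coordinates, shape (n_placements * n_atoms, 3)."""
        base = self.unit.positions
        out = np.empty((len(self.placements), base.shape[0], 3))
        for i, p in enumerate(self.placements):
            out[i] = base @ p.rotation.T + p.translation
        return out.reshape(-1, 3)

    def atom_weights(self) -> np.ndarray:
        return np.tile(self.unit.weights, len(self.placements))

    def com_positions(self) -> np.ndarray:
        com = self.unit.center_of_mass
        return np.array([p.rotation @ com + p.translation for p in self.placements])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def radialize(unit: AsymmetricUnit, radius: float) -> AsymmetricUnit:
    """Move the unit so its center of mass sits at (radius, 0, 0).

    If the unit's ``radial_reference`` is not already +x, the unit is first
    rotated (minimal rotation) so that it is; a unit already in the
    radialized frame is only translated.  Idempotent for a fixed radius.
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    x_hat = np.array([1.0, 0.0, 0.0])
    v = unit.radial_reference
    if np.allclose(v, x_hat, atol=1e-12):
        rotated = unit
    else:
        axis = np.cross(v, x_hat)
        s = np.linalg.norm(axis)
        c = float(v @ x_hat)
        if s < 1e-12:  # anti-parallel: flip about z
            R = np.diag([-1.0, -1.0, 1.0])
        else:
            axis = axis / s
            K = np.array([
                [0.0, -axis[2], axis[1]],
                [axis[2], 0.0, -axis[0]],
                [-axis[1], axis[0], 0.0],
            ])
            ang = np.arctan2(s, c)  # Rodrigues rotation v -> +x
            R = np.eye(3) + np.sin(ang) * K + (1.0 - np.cos(ang)) * (K @ K)
        rotated = unit.transformed(R, np.zeros(3))
    shift = np.array([radius, 0.0, 0.0]) - rotated.center_of_mass
    out = rotated.transformed(np.eye(3), shift)
    out.radial_reference = x_hat.copy()
    return out


def lattice_points_in_window(
    lattice: Lattice2D,
    idx,
    z_min: float,
    z_max: float,
    reference_idx=(14, 14),
) -> list[LatticeSite]:
    """Lattice points of wrapping ``idx`` with axial position in [z_min, z_max).

    Each returned site carries its azimuth (degrees, in [0, 360)), axial
    position z (Å) and the constant spin angle of this wrapping relative to
    ``reference_idx``.  Lattice points congruent modulo the wrapping vector
    (n1, n2) collapse to a single site (seamlessness): exactly one
    representative with arc coordinate in [0, C) is kept per equivalence
    class.
    """
    if not z_min < z_max:
        raise ValueError("require z_min < z_max")
    idx = _as_index(idx)
    sym = helix_from_wrapping(lattice, idx)
    spin = spin_angle(lattice, idx, reference_idx)

    # (arc, z) of lattice point (u1, u2) is M @ (u1, u2) with columns the
    # basis vectors in this wrapping's frame; invert to bound the search box.
    M = np.array([[sym.x1, sym.x2], [sym.y1, sym.y2]])
    Minv = np.linalg.inv(M)
    corners = np.array([
        [0.0, z_min], [0.0, z_max],
        [sym.circumference, z_min], [sym.circumference, z_max],
    ])
    uv = corners @ Minv.T
    u1_lo, u2_lo = np.floor(uv.min(axis=0)).astype(int) - 2
    u1_hi, u2_hi = np.ceil(uv.max(axis=0)).astype(int) + 2

    sites: list[LatticeSite] = []
    eps = 1e-9 * max(1.0, abs(z_min), abs(z_max))
    for u1 in range(u1_lo, u1_hi + 1):
        for u2 in range(u2_lo, u2_hi + 1):
            arc = u1 * sym.x1 + u2 * sym.x2
            z = u1 * sym.y1 + u2 * sym.y2
            if not (-eps <= arc < sym.circumference - eps):
                continue
            if not (z_min - eps <= z < z_max - eps):
                continue
            azimuth = 360.0 * arc / sym.circumference
            sites.append(LatticeSite(u1, u2, azimuth % 360.0, z, spin))
    sites.sort(key=lambda s: (round(s.z, 6), round(s.azimuth_deg, 6)))
    return sites


def build_tube(
    unit: AsymmetricUnit,
    lattice: Lattice2D,
    idx,
    z_min: float,
    z_max: float,
    reference_idx=(14, 14),
) -> TubeModel:
    """Symmetry-expand ``unit`` into a full tube model for wrapping ``idx``.

    The unit is assumed to be supplied in the frame of ``reference_idx``
    (default (14, 14)); it is radialized to this wrapping's radius and each
    placement applies Rz(azimuth) · Rradial(spin) plus the axial translation
    of its lattice point.
    """
    idx = _as_index(idx)
    sym = helix_from_wrapping(lattice, idx)
    runit = radialize(unit, sym.radius)
    sites = lattice_points_in_window(lattice, idx, z_min, z_max, reference_idx)
    if not sites:
        warnings.warn("z window contains no lattice point; tube model is empty")
    placements = []
    for s in sites:
        # positive spin = CCW seen from outside along -radial = Rx(-spin)
        R = _rot_z(s.azimuth_deg) @ _rot_x(-s.spin_deg)
        t = np.array([0.0, 0.0, s.z])
        placements.append(SubunitPlacement(R, t, (s.u1, s.u2)))
    return TubeModel(unit=runit, placements=placements, symmetry=sym, lattice=lattice)


@dataclass(frozen=True)
class NeighborContact:
    i: int
    j: int
    distance: float
    atom_i: int
    atom_j: int


def neighbor_pairs(tube: TubeModel, cutoff: float) -> list[NeighborContact]:
    """All pairs of placements with any inter-atom distance <= cutoff.

    Returns one contact per placement pair (i < j) with the minimizing atom
    pair.  Atom indices refer to positions within the asymmetric unit.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    n_atoms = len(tube.unit.atoms)
    pos = tube.atom_positions()
    tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    best: dict[tuple[int, int], tuple[float, int, int]] = {}
    if len(pairs):
        pi = pairs // n_atoms
        ai = pairs % n_atoms
        d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
        for (p0, p1), (a0, a1), dist in zip(pi, ai, d):
            if p0 == p1:
                continue
            if p0 > p1:
                p0, p1, a0, a1 = p1, p0, a1, a0
            key = (int(p0), int(p1))
            if key not in best or dist < best[key][0]:
                best[key] = (float(dist), int(a0), int(a1))
    return [
        NeighborContact(i, j, dist, a0, a1)
        for (i, j), (dist, a0, a1) in sorted(best.items())
    ]


# ---------------------------------------------------------------------------
# model I/O (gemmi-backed)

_PDB_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def _tube_to_structure(tube: TubeModel, pdb_chains: bool, chain_overflow: str):
    import gemmi

    st = gemmi.Structure()
    st.name = "tube"
    model = gemmi.Model("1")
    n = len(tube.placements)
    if pdb_chains and n > len(_PDB_CHAIN_IDS) and chain_overflow == "error":
        raise ValueError(
            f"{n} subunits exceed the {len(_PDB_CHAIN_IDS)} single-character "
            "PDB chain ids; write mmCIF or pass chain_overflow='wrap'"
        )
    base = tube.unit.positions
    for i, p in enumerate(tube.placements):
        if pdb_chains:
            cname = _PDB_CHAIN_IDS[i % len(_PDB_CHAIN_IDS)]
        else:
            u1, u2 = p.lattice_coords
            cname = f"u{u1}.{u2}"
        chain = gemmi.Chain(cname)
        coords = base @ p.rotation.T + p.translation
        res = None
        last_key = None
        for a, xyz in zip(tube.unit.atoms, coords):
            key = (a.res_seq, a.res_name)
            if key != last_key:
                res = gemmi.Residue()
                res.name = a.res_name
                res.seqid = gemmi.SeqId(a.res_seq, " ")
                chain.add_residue(res)
                last_key = key
                res = chain[-1]
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*xyz)
            atom.occ = a.occupancy
            atom.b_iso = a.b_factor
            res.add_atom(atom)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_model(tube: TubeModel, path, fmt: str | None = None, chain_overflow: str = "error") -> None:
    """Write a tube model as PDB or mmCIF (inferred from the suffix).

    mmCIF is preferred for large tubes: chains are labeled by their (u1, u2)
    lattice coordinates.  PDB files use single-character chain ids and, with
    ``chain_overflow='error'`` (default), refuse tubes with more than 62
    subunits; ``'wrap'`` recycles ids instead.
    """
    path = str(path)
    if fmt is None:
        fmt = "pdb" if path.lower().endswith(".pdb") else "mmcif"
    fmt = fmt.lower()
    if fmt not in ("pdb", "mmcif", "cif"):
        raise ValueError(f"unsupported format: {fmt}")
    pdb = fmt == "pdb"
    st = _tube_to_structure(tube, pdb_chains=pdb, chain_overflow=chain_overflow)
    if pdb:
        with open(path, "w") as fh:
            fh.write(st.make_pdb_string())
    else:
        with open(path, "w") as fh:
            fh.write(st.make_mmcif_document().as_string())


def read_unit(path, radial_reference=(1.0, 0.0, 0.0)) -> AsymmetricUnit:
    """Read an asymmetric unit from a PDB or mmCIF file.

    All atoms of all chains are loaded.  A missing element column is
    inferred from the atom name (logged as a warning).
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse model file {path}: {exc}") from exc
    atoms: list[AtomRecord] = []
    inferred = 0
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    el = at.element.name
                    if not el or el == "X":
                        el = "".join(c for c in at.name if c.isalpha())[:1] or "C"
                        inferred += 1
                    atoms.append(AtomRecord(
                        element=el,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        name=at.name,
                        occupancy=at.occ,
                        b_factor=at.b_iso,
                        chain=chain.name,
                        res_name=res.name,
                        res_seq=res.seqid.num,
                    ))
        break  # first model only
    if inferred:
        logger.warning("inferred element for %d atoms from atom names", inferred)
    if not atoms:
        raise ValueError(f"no atoms found in {path}")
    return AsymmetricUnit(atoms, np.asarray(radial_reference, dtype=float))
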