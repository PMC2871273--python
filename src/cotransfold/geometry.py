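"""Backbone representation and internal-coordinate (torsion) geometry.

A protein chain is modelled by its backbone heavy atoms (N, CA, C, O) plus an
optional geometrically placed pseudo-CB.  Chains are built from per-residue
(phi, psi, omega) torsion triples with ideal covalent geometry, so that
construction is deterministic and exactly invertible on interior angles.

Conventions
-----------
* Angles are in degrees, normalised to (-180, 180].
* ``phi(i)   = dihedral(C(i-1), N(i), CA(i), C(i))``   — undefined for i = 1
* ``psi(i)   = dihedral(N(i), CA(i), C(i), N(i+1))``   — undefined for i = n
* ``omega(i) = dihedral(CA(i), C(i), N(i+1), CA(i+1))`` — undefined for i = n
* Undefined terminal angles are reported as ``math.nan``.
* The fully extended conformation is (phi, psi, omega) = (-150, 150, 180),
  the state in which every newly extruded segment is appended.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import InvalidInputError, MalformedStructureError

__all__ = [
    "TorsionTriple",
    "EXTENDED",
    "UNDEFINED",
    "BackboneGeometry",
    "IDEAL_GEOMETRY",
    "SYMMETRIC_GEOMETRY",
    "Residue",
    "Structure",
    "dihedral",
    "build_from_torsions",
    "extract_torsions",
    "extend_chain",
    "pseudo_cb",
    "read_pdb",
    "write_pdb",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Sentinel for dihedrals that do not exist at chain termini.
UNDEFINED = math.nan


class TorsionTriple(NamedTuple):
    """One residue's backbone dihedrals, in degrees."""

    phi: float
    psi: float
    omega: float


#: Fully extended conformation used for every freshly extruded segment.
EXTENDED = TorsionTriple(-150.0, 150.0, 180.0)


@dataclass(frozen=True)
class BackboneGeometry:
    """Ideal covalent bond lengths (Angstrom) and angles (degrees).

    Defaults follow standard Engh--Huber-style values.  ``SYMMETRIC_GEOMETRY``
    equalises the N-CA / CA-C bond lengths and the two peptide-bond angles so
    that a chain read C-to-N is congruent to one built N-to-C; it exists for
    mirror-equivalence checks, not for production folding.
    """

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8


IDEAL_GEOMETRY = BackboneGeometry()
SYMMETRIC_GEOMETRY = BackboneGeometry(
    n_ca=1.49, ca_c=1.49, ang_ca_c_n=119.0, ang_c_n_ca=119.0
)


@dataclass
class Residue:
    """One residue: 1-based index, one-letter code, backbone atom coordinates."""

    index: int
    aa: str
    atoms: dict  # atom name -> np.ndarray shape (3,)

    def coord(self, name: str) -> np.ndarray:
        return self.atoms[name]


@dataclass
class Structure:
    """An ordered single-chain backbone model.

    Residue indices are contiguous and 1-based; original file numbering, the
    producing algorithm, seeds etc. live in ``meta``.
    """

    residues: list
    chain_id: str = "A"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise InvalidInputError("a Structure needs at least one residue")
        for k, r in enumerate(self.residues, start=1):
            if r.index != k:
                raise InvalidInputError(
                    f"residue indices must be contiguous from 1; got {r.index} at {k}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atoms["CA"] for r in self.residues])

    def atom_coords(self, names: Sequence[str] = BACKBONE_ATOMS) -> np.ndarray:
        return np.array([r.atoms[n] for r in self.residues for n in names])

    def copy(self) -> "Structure":
        residues = [
            Residue(r.index, r.aa, {n: c.copy() for n, c in r.atoms.items()})
            for r in self.residues
        ]
        return Structure(residues, self.chain_id, dict(self.meta))


def _norm_angle(a: float) -> float:
    """Map an angle in degrees to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return _norm_angle(math.degrees(math.atan2(y, x)))


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: the point d with |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = dihedral."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(chi),
            -bond * math.sin(theta) * math.sin(chi),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d2


def _check_sequence(sequence: str) -> None:
    if len(sequence) < 1:
        raise InvalidInputError("empty sequence")
    if not sequence.isalpha():
        raise InvalidInputError(f"sequence must be one-letter codes: {sequence!r}")


def _place_oxygen(n, ca, c, psi: float, geom: BackboneGeometry) -> np.ndarray:
    # carbonyl O sits in the peptide plane, anti to the next N
    psi_eff = 150.0 if math.isnan(psi) else psi
    return place_atom(n, ca, c, geom.c_o, geom.ang_ca_c_o, _norm_angle(psi_eff + 180.0))


def build_from_torsions(
    sequence: str,
    torsions: Sequence[TorsionTriple],
    geometry: BackboneGeometry = IDEAL_GEOMETRY,
) -> Structure:
    """Build backbone coordinates from per-residue (phi, psi, omega) triples.

    phi of the first residue and psi/omega of the last are geometrically
    irrelevant; they may be NaN.  All other angles must be finite.
    """
    _check_sequence(sequence)
    if len(torsions) != len(sequence):
        raise InvalidInputError(
            f"{len(torsions)} torsion triples for {len(sequence)} residues"
        )
    n_res = len(sequence)
    for i, t in enumerate(torsions):
        needed = []
        if i > 0:
            needed.append(t[0])
        if i < n_res - 1:
            needed.extend([t[1], t[2]])
        if any(not math.isfinite(v) for v in needed):
            raise InvalidInputError(f"non-finite torsion at residue {i + 1}")

    g = geometry
    coords = {}  # (i, name) -> np.ndarray, i is 0-based
    coords[(0, "N")] = np.zeros(3)
    coords[(0, "CA")] = np.array([g.n_ca, 0.0, 0.0])
    th = math.radians(g.ang_n_ca_c)
    coords[(0, "C")] = coords[(0, "CA")] + g.ca_c * np.array(
        [-math.cos(th), math.sin(th), 0.0]
    )
    for i in range(n_res - 1):
        psi, omega = torsions[i].psi, torsions[i].omega
        phi_next = torsions[i + 1].phi
        n_i, ca_i, c_i = coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")]
        n_next = place_atom(n_i, ca_i, c_i, g.c_n, g.ang_ca_c_n, psi)
        ca_next = place_atom(ca_i, c_i, n_next, g.n_ca, g.ang_c_n_ca, omega)
        c_next = place_atom(c_i, n_next, ca_next, g.ca_c, g.ang_n_ca_c, phi_next)
        coords[(i + 1, "N")] = n_next
        coords[(i + 1, "CA")] = ca_next
        coords[(i + 1, "C")] = c_next

    residues = []
    for i, aa in enumerate(sequence):
        n_i, ca_i, c_i = coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")]
        o_i = _place_oxygen(n_i, ca_i, c_i, torsions[i].psi, g)
        residues.append(Residue(i + 1, aa, {"N": n_i, "CA": ca_i, "C": c_i, "O": o_i}))
    return Structure(residues, meta={"geometry": g})


def extract_torsions(s: Structure) -> list:
    """Per-residue (phi, psi, omega); terminal undefined angles are NaN.

    Inverse of :func:`build_from_torsions` on interior angles.
    """
    if len(s) < 2:
        raise InvalidInputError("torsions are undefined for a single-residue chain")
    out = []
    rs = s.residues
    for i in range(len(rs)):
        phi = psi = omega = UNDEFINED
        if i > 0:
            phi = dihedral(
                rs[i - 1].atoms["C"], rs[i].atoms["N"], rs[i].atoms["CA"], rs[i].atoms["C"]
            )
        if i < len(rs) - 1:
            psi = dihedral(
                rs[i].atoms["N"], rs[i].atoms["CA"], rs[i].atoms["C"], rs[i + 1].atoms["N"]
            )
            omega = dihedral(
                rs[i].atoms["CA"], rs[i].atoms["C"], rs[i + 1].atoms["N"], rs[i + 1].atoms["CA"]
            )
        out.append(TorsionTriple(phi, psi, omega))
    return out


def extend_chain(
    s: Structure,
    n_new: int,
    terminus: str,
    sequence: str | None = None,
    triple: TorsionTriple = EXTENDED,
    geometry: BackboneGeometry | None = None,
) -> Structure:
    """Append ``n_new`` residues in extended conformation at the N or C terminus.

    Existing atoms are never moved, so the old chain's internal coordinates are
    preserved exactly; junction psi/omega (C growth) or phi (N growth) take the
    extended values.  ``sequence`` supplies one-letter codes for the new block
    (defaults to alanine).
    """
    if n_new < 1:
        raise InvalidInputError("n_new must be >= 1")
    if terminus not in ("N", "C"):
        raise InvalidInputError(f"terminus must be 'N' or 'C', got {terminus!r}")
    seq_new = sequence if sequence is not None else "A" * n_new
    if len(seq_new) != n_new:
        raise InvalidInputError("sequence length must equal n_new")
    g = geometry or s.meta.get("geometry") or IDEAL_GEOMETRY
    s = s.copy()
    rs = s.residues

    if terminus == "C":
        for k, aa in enumerate(seq_new):
            last = rs[-1]
            n_p, ca_p, c_p = last.atoms["N"], last.atoms["CA"], last.atoms["C"]
            n_new_at = place_atom(n_p, ca_p, c_p, g.c_n, g.ang_ca_c_n, triple.psi)
            ca_new = place_atom(ca_p, c_p, n_new_at, g.n_ca, g.ang_c_n_ca, triple.omega)
            c_new = place_atom(c_p, n_new_at, ca_new, g.ca_c, g.ang_n_ca_c, triple.phi)
            o_new = _place_oxygen(n_new_at, ca_new, c_new, triple.psi, g)
            rs.append(
                Residue(
                    last.index + 1,
                    aa,
                    {"N": n_new_at, "CA": ca_new, "C": c_new, "O": o_new},
                )
            )
    else:
        block = []
        for aa in reversed(seq_new):
            first = block[0] if block else rs[0]
            n_f, ca_f, c_f = first.atoms["N"], first.atoms["CA"], first.atoms["C"]
            # reverse NeRF: dihedral(a,b,c,d) == dihedral(d,c,b,a)
            c_new = place_atom(c_f, ca_f, n_f, g.c_n, g.ang_c_n_ca, triple.phi)
            ca_new = place_atom(ca_f, n_f, c_new, g.ca_c, g.ang_ca_c_n, triple.omega)
            n_new_at = place_atom(n_f, c_new, ca_new, g.n_ca, g.ang_n_ca_c, triple.psi)
            o_new = _place_oxygen(n_new_at, ca_new, c_new, triple.psi, g)
            block.insert(
                0, Residue(0, aa, {"N": n_new_at, "CA": ca_new, "C": c_new, "O": o_new})
            )
        rs[:0] = block
        for k, r in enumerate(rs, start=1):
            r.index = k
    s.meta["geometry"] = g
    return Structure(rs, s.chain_id, s.meta)


# CB placement: ideal tetrahedral pseudo-CB from the backbone frame.
_CB_BOND = 1.53
_CB_ANGLE = 110.1  # N-CA-CB
_CB_DIHEDRAL = 122.5  # C-N-CA-CB


def pseudo_cb(res: Residue) -> np.ndarray:
    """Geometrically reconstructed CB position from the N, CA, C frame."""
    return place_atom(
        res.atoms["C"], res.atoms["N"], res.atoms["CA"], _CB_BOND, _CB_ANGLE, _CB_DIHEDRAL
    )


# ---------------------------------------------------------------------------
# PDB I/O (single chain, backbone atoms), via gemmi
# ---------------------------------------------------------------------------

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
_ONE = {v: k for k, v in _THREE.items()}


def read_pdb(path, chain_id: str | None = None) -> Structure:
    """Read one chain's backbone from a PDB file.

    Residues are renumbered 1..N internally; the original author numbering is
    kept in ``meta['orig_numbering']``.  Altlocs other than blank/'A' are
    ignored.  A residue missing any of N, CA, C, O raises
    :class:`MalformedStructureError`.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    st = gemmi.read_structure(str(path))
    if len(st) == 0 or len(st[0]) == 0:
        raise MalformedStructureError(f"{path}: no chains found")
    model = st[0]
    chain = None
    for ch in model:
        if chain_id is None or ch.name == chain_id:
            chain = ch
            break
    if chain is None:
        raise MalformedStructureError(f"{path}: chain {chain_id!r} not found")

    residues = []
    orig = []
    idx = 0
    for res in chain:
        atoms = {}
        for at in res:
            if at.name in BACKBONE_ATOMS and at.altloc in ("", "A", "\x00"):
                if at.name not in atoms:
                    atoms[at.name] = np.array([at.pos.x, at.pos.y, at.pos.z])
        if not atoms:
            continue  # waters / het groups without backbone
        missing = [n for n in BACKBONE_ATOMS if n not in atoms]
        if missing:
            raise MalformedStructureError(
                f"{path}: residue {res.seqid.num} ({res.name}) missing {','.join(missing)}"
            )
        idx += 1
        aa = _ONE.get(res.name.strip(), "X")
        residues.append(Residue(idx, aa, atoms))
        orig.append(res.seqid.num)
    if not residues:
        raise MalformedStructureError(f"{path}: no complete backbone residues")
    return Structure(
        residues, chain.name if chain.name else "A", meta={"orig_numbering": orig}
    )


def write_pdb(s: Structure, path) -> None:
    """Write the backbone to a single-chain PDB file (fixed-width, 3 d.p.)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "cotransfold"
    model = gemmi.Model("1")
    chain = gemmi.Chain(s.chain_id or "A")
    for r in s.residues:
        res = gemmi.Residue()
        res.name = _THREE.get(r.aa.upper(), "UNK")
        res.seqid = gemmi.SeqId(r.index, " ")
        for name in BACKBONE_ATOMS:
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(name[0])
            x, y, z = (float(v) for v in r.atoms[name])
            at.pos = gemmi.Position(x, y, z)
            at.occ = 1.0
            at.b_iso = 0.0
            res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
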