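"""Three-state secondary-structure assignment from backbone coordinates.

Helix and strand are detected from backbone hydrogen bonds using the
Kabsch--Sander electrostatic criterion (amide H reconstructed geometrically,
bond when the dipole interaction energy is below -0.5 kcal/mol).  Helices are
runs covered by consecutive i -> i+4 (or i+3) turns; strands are residues in
parallel or antiparallel bridge ladders.  Everything else is coil.  Eight-state
labels read from external files are collapsed as {H,G,I} -> H, {E,B} -> E,
else C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .geometry import Structure

__all__ = [
    "SSAssignment",
    "SSElement",
    "hbond_matrix",
    "assign_ss",
    "parse_ss_labels",
    "read_ss_labels",
    "find_elements",
]

_Q1Q2_F = 0.084 * 332.0  # Kabsch-Sander dipole coupling constant, kcal/mol*A
HBOND_CUTOFF = -0.5  # kcal/mol

_COLLAPSE = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", "-": "C", " ": "C", ".": "C", "P": "C",
}


@dataclass
class SSAssignment:
    """Per-residue H/E/C labels."""

    labels: str
    source: str = "computed"  # computed | external

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SSElement:
    """A maximal helix or strand run of at least four residues (1-based, inclusive)."""

    kind: str  # 'H' or 'E'
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("H", "E"):
            raise InvalidInputError("element kind must be 'H' or 'E'")
        if self.end - self.start + 1 < 4:
            raise InvalidInputError("an element spans at least four residues")


def _amide_hydrogens(s: Structure) -> np.ndarray:
    """Reconstructed amide H positions (NaN row for the N-terminal residue)."""
    n = len(s)
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        ni = s.residues[i].atoms["N"]
        d1 = ni - s.residues[i - 1].atoms["C"]
        d2 = ni - s.residues[i].atoms["CA"]
        d1 = d1 / np.linalg.norm(d1)
        d2 = d2 / np.linalg.norm(d2)
        u = d1 + d2
        H[i] = ni + u / np.linalg.norm(u)
    return H


def hbond_matrix(s: Structure) -> np.ndarray:
    """Kabsch--Sander H-bond energies: entry [d, a] couples donor NH of
    residue d with acceptor CO of residue a (kcal/mol; +inf where undefined).

    Donor and acceptor must be distinct residues and not sequence neighbours.
    """
    n = len(s)
    H = _amide_hydrogens(s)
    N = np.array([r.atoms["N"] for r in s.residues])
    O = np.array([r.atoms["O"] for r in s.residues])
    C = np.array([r.atoms["C"] for r in s.residues])

    def pd(a, b):  # pairwise distances, [donor, acceptor]
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)

    r_on = pd(N, O)
    r_ch = pd(H, C)
    r_oh = pd(H, O)
    r_cn = pd(N, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        E = _Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
    # steric overlap counts as bonded in K-S
    too_close = np.minimum(np.minimum(r_on, r_ch), np.minimum(r_oh, r_cn)) < 0.5
    E = np.where(too_close, -9.9, E)
    d_idx, a_idx = np.indices((n, n))
    E[np.abs(d_idx - a_idx) < 2] = np.inf
    E[0, :] = np.inf  # residue 0 has no amide H
    E[np.isnan(E)] = np.inf
    return E


def count_backbone_hbonds(s: Structure) -> int:
    """Number of (donor, acceptor) pairs below the Kabsch--Sander cutoff."""
    if len(s) < 3:
        return 0
    return int((hbond_matrix(s) < HBOND_CUTOFF).sum())


def assign_ss(s: Structure) -> SSAssignment:
    """Assign H/E/C per residue from coordinates.

    Chains shorter than five residues cannot form any element; they come back
    all-coil with a warning.
    """
    n = len(s)
    if n < 5:
        warnings.warn("chain too short for secondary structure; assigning all coil")
        return SSAssignment("C" * n, source="computed")

    hb = hbond_matrix(s) < HBOND_CUTOFF

    def bond(acceptor: int, donor: int) -> bool:
        # Kabsch-Sander Hbond(i, j): CO of i accepts the NH of j
        if 0 <= donor < n and 0 <= acceptor < n:
            return bool(hb[donor, acceptor])
        return False

    labels = ["C"] * n

    # helix: two consecutive n-turns (alpha 4-turns; 3-10 turns collapse to H)
    for turn in (4, 3):
        turn_at = [bond(i, i + turn) for i in range(n)]
        for i in range(n - 1):
            if turn_at[i] and i + 1 < n and turn_at[i + 1]:
                for j in range(i + 1, min(i + turn + 1, n)):
                    labels[j] = "H"

    # bridges: parallel / antiparallel beta partners
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = (bond(i - 1, j) and bond(j, i + 1)) or (
                bond(j - 1, i) and bond(i, j + 1)
            )
            anti = (bond(i, j) and bond(j, i)) or (
                bond(i - 1, j + 1) and bond(j - 1, i + 1)
            )
            if parallel or anti:
                if labels[i] != "H":
                    labels[i] = "E"
                if labels[j] != "H":
                    labels[j] = "E"
    return SSAssignment("".join(labels), source="computed")


def parse_ss_labels(text: str) -> str:
    """Collapse an 8-state label string to 3 states, validating characters."""
    collapsed = []
    bad = []
    for k, ch in enumerate(text, start=1):
        c = _COLLAPSE.get(ch.upper())
        if c is None:
            bad.append((k, ch))
        else:
            collapsed.append(c)
    if bad:
        where = ", ".join(f"{ch!r} at position {k}" for k, ch in bad)
        raise InvalidInputError(f"unknown secondary-structure labels: {where}")
    return "".join(collapsed)


def read_ss_labels(path) -> SSAssignment:
    """Read labels from a plain string file, a per-residue table, or classic
    DSSP output; 8-state labels are collapsed to H/E/C."""
    with open(path) as fh:
        content = fh.read()
    lines = [ln for ln in content.splitlines() if ln.strip()]
    if not lines:
        raise InvalidInputError(f"{path}: empty label file")

    # classic DSSP: per-residue records follow a '#  RESIDUE AA STRUCTURE' header
    header_idx = next(
        (k for k, ln in enumerate(lines) if ln.lstrip().startswith("#  RESIDUE")), None
    )
    if header_idx is not None:
        chars = []
        for ln in lines[header_idx + 1 :]:
            if len(ln) > 16 and ln[13] != "!":
                chars.append(ln[16] if ln[16] != " " else "C")
        return SSAssignment(parse_ss_labels("".join(chars)), source="external")

    if len(lines) == 1:
        return SSAssignment(parse_ss_labels(lines[0].strip()), source="external")

    # per-residue table: use the last whitespace-separated field of each line
    chars = [ln.split()[-1] for ln in lines]
    if any(len(c) != 1 for c in chars):
        raise InvalidInputError(f"{path}: per-residue table must end in one-letter labels")
    return SSAssignment(parse_ss_labels("".join(chars)), source="external")


def find_elements(a: SSAssignment) -> list:
    """Maximal runs of >= 4 identical H or E labels, in chain order."""
    out = []
    labels = a.labels
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] in ("H", "E") and j - i >= 4:
            out.append(SSElement(labels[i], i + 1, j))
        i = j
    return out
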