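"""Torsion-fragment libraries for insertion moves.

The folding engine replaces chain segments with short torsion fragments
(9-mers by default, matching the extrusion unit; 3-mers for refinement).
Without an external fragment database, candidates are drawn from idealized
secondary-structure motifs with Gaussian torsion noise, weighted by a simple
per-residue conformational propensity table.  An optional harvester pulls
real torsion windows from PDB structures instead.

Omega is held at exactly 180 degrees (trans peptide) by default; cis
peptides and omega jitter are outside the model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EmptyLibraryError, InvalidInputError
from .geometry import Structure, TorsionTriple, extract_torsions, read_pdb

logger = logging.getLogger(__name__)

__all__ = [
    "TorsionFragment",
    "FragmentLibrary",
    "MOTIFS",
    "make_idealized_library",
    "harvest_library",
    "mirror_library",
    "save_library",
    "load_library",
]

ALLOWED_LENGTHS = (3, 9)

#: Canonical (phi, psi) motifs sampled by the idealized generator.
MOTIFS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 130.0),
    "polyproline": (-75.0, 145.0),
    "extended": (-150.0, 150.0),
}

# Relative motif propensities per residue (helix, strand, polyproline,
# extended).  Coarse single-residue preferences: helix formers favour the
# helix motif, beta-branched/aromatic residues the strand motifs, G/P the
# open ones.  Values are unnormalised weights.
_DEFAULT_PROPENSITY = (1.0, 1.0, 0.5, 0.5)
_PROPENSITY = {
    "A": (1.6, 0.8, 0.5, 0.4),
    "E": (1.5, 0.8, 0.5, 0.4),
    "L": (1.4, 1.0, 0.4, 0.4),
    "M": (1.4, 1.0, 0.4, 0.4),
    "Q": (1.3, 0.9, 0.5, 0.4),
    "K": (1.2, 0.9, 0.5, 0.4),
    "R": (1.2, 0.9, 0.5, 0.4),
    "H": (1.0, 1.0, 0.5, 0.4),
    "V": (0.7, 1.8, 0.4, 0.5),
    "I": (0.8, 1.7, 0.4, 0.5),
    "Y": (0.8, 1.4, 0.5, 0.5),
    "W": (0.9, 1.3, 0.5, 0.5),
    "F": (0.8, 1.4, 0.5, 0.5),
    "T": (0.7, 1.3, 0.6, 0.5),
    "C": (0.8, 1.2, 0.5, 0.5),
    "S": (0.8, 0.9, 0.7, 0.6),
    "N": (0.9, 0.7, 0.7, 0.6),
    "D": (1.0, 0.6, 0.7, 0.6),
    "G": (0.5, 0.6, 0.9, 1.2),
    "P": (0.3, 0.4, 1.8, 0.6),
}


@dataclass(frozen=True)
class TorsionFragment:
    """A window of consecutive (phi, psi, omega) triples."""

    length: int
    triples: tuple
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.length not in ALLOWED_LENGTHS:
            raise InvalidInputError(f"fragment length must be in {ALLOWED_LENGTHS}")
        if len(self.triples) != self.length:
            raise InvalidInputError("triples must match the declared length")


@dataclass
class FragmentLibrary:
    """Candidate fragments keyed by 1-based window start position."""

    by_position: dict  # position -> list[TorsionFragment]
    fragment_length: int
    chain_length: int

    def __post_init__(self) -> None:
        n_pos = self.chain_length - self.fragment_length + 1
        for p in range(1, n_pos + 1):
            if not self.by_position.get(p):
                raise InvalidInputError(f"no candidate fragments at position {p}")
        for p, frags in self.by_position.items():
            if p < 1 or p + self.fragment_length - 1 > self.chain_length:
                raise InvalidInputError(f"window at {p} extends past the chain")
            for f in frags:
                if f.length != self.fragment_length:
                    raise InvalidInputError("mixed fragment lengths in library")

    @property
    def positions(self) -> range:
        return range(1, self.chain_length - self.fragment_length + 2)


def make_idealized_library(
    sequence: str,
    fragment_length: int = 9,
    per_position: int = 25,
    noise_deg: float = 20.0,
    seed: int = 0,
) -> FragmentLibrary:
    """Generate motif-based fragments for every window of the target sequence.

    For each window, ``per_position`` candidates are drawn: per residue a
    motif is chosen with probability proportional to that residue's
    propensity weights, and Gaussian noise of standard deviation
    ``noise_deg`` is added to phi and psi.  Omega stays at 180.  Deterministic
    for a given seed.
    """
    if fragment_length not in ALLOWED_LENGTHS:
        raise InvalidInputError(f"fragment length must be in {ALLOWED_LENGTHS}")
    if per_position < 1:
        raise InvalidInputError("per_position must be >= 1")
    if noise_deg < 0:
        raise InvalidInputError("noise_deg must be >= 0")
    if len(sequence) < fragment_length:
        raise InvalidInputError("sequence shorter than the fragment length")

    rng = np.random.default_rng(seed)
    motif_names = list(MOTIFS)
    by_position = {}
    for pos in range(1, len(sequence) - fragment_length + 2):
        window = sequence[pos - 1 : pos - 1 + fragment_length]
        frags = []
        for k in range(per_position):
            triples = []
            # one motif per candidate fragment keeps windows internally
            # coherent (a fragment is a motif, not a residue salad); the
            # motif is drawn from the mean propensity of the window
            weights = np.mean(
                [_PROPENSITY.get(aa, _DEFAULT_PROPENSITY) for aa in window], axis=0
            )
            weights = weights / weights.sum()
            motif = motif_names[rng.choice(len(motif_names), p=weights)]
            phi0, psi0 = MOTIFS[motif]
            for _ in range(fragment_length):
                dphi, dpsi = (
                    rng.normal(0.0, noise_deg, size=2) if noise_deg > 0 else (0.0, 0.0)
                )
                triples.append(TorsionTriple(phi0 + dphi, psi0 + dpsi, 180.0))
            frags.append(
                TorsionFragment(fragment_length, tuple(triples), f"{motif}:{pos}.{k}")
            )
        by_position[pos] = frags
    return FragmentLibrary(by_position, fragment_length, len(sequence))


# BLOSUM62-style scoring for the harvester, via Biopython's matrices.
def _window_score(a: str, b: str) -> float:
    from Bio.Align import substitution_matrices

    mat = _window_score._cache
    if mat is None:
        mat = substitution_matrices.load("BLOSUM62")
        _window_score._cache = mat
    score = 0.0
    for x, y in zip(a.upper(), b.upper()):
        try:
            score += mat[x, y]
        except (KeyError, IndexError):
            score += 0.0
    return score


_window_score._cache = None


def harvest_library(
    pdb_paths: Sequence,
    sequence: str,
    fragment_length: int = 9,
    per_position: int = 25,
    exclude_paths: Sequence = (),
) -> FragmentLibrary:
    """Harvest real torsion windows from PDB structures.

    Every contiguous window of each source structure is a candidate; for each
    target position the ``per_position`` highest-scoring windows (substitution
    matrix sum against the target window, ties broken by source order) are
    kept.  ``exclude_paths`` drops sources (e.g. the target's own experimental
    structure) before harvesting.
    """
    if fragment_length not in ALLOWED_LENGTHS:
        raise InvalidInputError(f"fragment length must be in {ALLOWED_LENGTHS}")
    excluded = {str(p) for p in exclude_paths}
    pool = []  # (source order, window seq, triples, label)
    order = 0
    for path in pdb_paths:
        if str(path) in excluded:
            continue
        s = read_pdb(path)
        if len(s) < fragment_length:
            continue
        torsions = extract_torsions(s)
        seq = s.sequence
        for start in range(len(s) - fragment_length + 1):
            triples = torsions[start : start + fragment_length]
            # windows touching the termini carry undefined angles
            if any(
                not all(map(math.isfinite, t)) for t in triples
            ):
                continue
            pool.append(
                (
                    order,
                    seq[start : start + fragment_length],
                    tuple(TorsionTriple(*t) for t in triples),
                    f"{path}+{start + 1}",
                )
            )
            order += 1
    if not pool:
        raise EmptyLibraryError("no valid torsion windows in the source structures")

    by_position = {}
    for pos in range(1, len(sequence) - fragment_length + 2):
        target = sequence[pos - 1 : pos - 1 + fragment_length]
        ranked = sorted(
            pool, key=lambda w: (-_window_score(target, w[1]), w[0])
        )
        if per_position > len(ranked):
            logger.warning(
                "position %d: only %d windows available (%d requested)",
                pos,
                len(ranked),
                per_position,
            )
        by_position[pos] = [
            TorsionFragment(fragment_length, w[2], w[3]) for w in ranked[:per_position]
        ]
    return FragmentLibrary(by_position, fragment_length, len(sequence))


def mirror_library(lib: FragmentLibrary) -> FragmentLibrary:
    """The library seen by a chain read C-to-N.

    Window start q maps to start L - q - k + 2; fragment triples are reversed
    with phi and psi exchanged.  Used as the oracle counterpart of reverse
    folding: folding sequence S in reverse with library ``lib`` corresponds to
    folding reversed(S) forwards with ``mirror_library(lib)``.  Valid only for
    trans-only libraries (omega = 180 throughout).
    """
    k = lib.fragment_length
    L = lib.chain_length
    by_position = {}
    for q, frags in lib.by_position.items():
        mirrored = []
        for f in frags:
            trip = tuple(
                TorsionTriple(t.psi, t.phi, t.omega) for t in reversed(f.triples)
            )
            mirrored.append(TorsionFragment(k, trip, f"mirror({f.source_label})"))
        by_position[L - q - k + 2] = mirrored
    return FragmentLibrary(by_position, k, L)


def save_library(lib: FragmentLibrary, path) -> None:
    """Serialize as TSV: position, rank, k x (phi, psi, omega), source label."""
    with open(path, "w") as fh:
        for pos in lib.positions:
            for rank, f in enumerate(lib.by_position[pos]):
                angles = "\t".join(
                    f"{v:.4f}" for t in f.triples for v in (t.phi, t.psi, t.omega)
                )
                fh.write(f"{pos}\t{rank}\t{angles}\t{f.source_label}\n")


def load_library(path, chain_length: int) -> FragmentLibrary:
    by_position = {}
    frag_len = None
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            pos = int(parts[0])
            label = parts[-1]
            vals = [float(v) for v in parts[2:-1]]
            if len(vals) % 3:
                raise InvalidInputError(f"malformed library line: {line!r}")
            k = len(vals) // 3
            frag_len = frag_len or k
            triples = tuple(
                TorsionTriple(*vals[3 * i : 3 * i + 3]) for i in range(k)
            )
            by_position.setdefault(pos, []).append(TorsionFragment(k, triples, label))
    if frag_len is None:
        raise EmptyLibraryError(f"{path}: empty library file")
    return FragmentLibrary(by_position, frag_len, chain_length)
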