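"""Monte Carlo fragment-assembly folding in three senses.

Three modes share one Metropolis annealer:

* **forward** (the sense of translation): the chain is extruded nine residues
  at a time from the N-terminus, each new segment appended in fully extended
  conformation, and the chain folds after every extrusion;
* **reverse**: identical, but the chain grows from the C-terminus toward the
  N-terminus;
* **nonsequential**: the full-length chain starts fully extended and folds in
  a single stage.

All modes spend the same total number of cycles t = round(b * l / 100) for a
base cycle count b and chain length l; sequential modes split t evenly over
the ceil(l / 9) extrusions, with the remainder going to the final stage.  A
cycle is one attempted fragment insertion.

The score is a coarse surrogate built from four terms: soft-sphere backbone
repulsion, a radius-of-gyration compactness term, a backbone hydrogen-bond
reward (Kabsch--Sander criterion) and a torsion-propensity penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, NoMoveError
from .fragments import FragmentLibrary
from .geometry import (
    EXTENDED,
    IDEAL_GEOMETRY,
    BackboneGeometry,
    Structure,
    TorsionTriple,
    build_from_torsions,
    extend_chain,
    extract_torsions,
    pseudo_cb,
)
from .ss import hbond_matrix, HBOND_CUTOFF

__all__ = [
    "FoldingSchedule",
    "EnergyWeights",
    "FoldingResult",
    "allocate_cycles",
    "energy",
    "fold_stage",
    "fold_sequential",
    "fold_nonsequential",
    "generate_decoys",
]

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52}


@dataclass(frozen=True)
class FoldingSchedule:
    """Cycle-allocation bookkeeping for one chain length.

    t = round(b*l/100) total cycles, e = ceil(l/9) extrusions, n = floor(t/e)
    cycles for each of the first e-1 extrusions and last = t - n(e-1) for the
    final one.  Extrusion sizes are nine except possibly the last.
    """

    b: int
    l: int
    t: int
    e: int
    n: int
    last: int
    extrusion_sizes: tuple

    def __post_init__(self) -> None:
        assert self.t == round(self.b * self.l / 100)
        assert self.e == math.ceil(self.l / 9)
        assert self.n == self.t // self.e
        assert self.last == self.t - self.n * (self.e - 1)
        assert self.last >= self.n
        assert sum(self.extrusion_sizes) == self.l
        assert all(sz == 9 for sz in self.extrusion_sizes[:-1])
        assert 1 <= self.extrusion_sizes[-1] <= 9

    @property
    def stage_cycles(self) -> tuple:
        return tuple([self.n] * (self.e - 1) + [self.last])


def allocate_cycles(b: int, l: int) -> FoldingSchedule:
    """Distribute b*(l/100) cycles over ceil(l/9) extrusion stages."""
    if b < 1 or l < 1:
        raise InvalidInputError("base cycles and length must be positive")
    t = round(b * l / 100)
    e = math.ceil(l / 9)
    n = t // e
    last = t - n * (e - 1)
    sizes = [9] * (e - 1)
    sizes.append(l - 9 * (e - 1))
    return FoldingSchedule(b, l, t, e, n, last, tuple(sizes))


@dataclass(frozen=True)
class EnergyWeights:
    """Weights of the surrogate score terms (all dimensionless, >= 0)."""

    w_clash: float = 1.0
    w_rg: float = 0.5
    w_hbond: float = 2.0
    w_rama: float = 0.2
    ca_only: bool = False  # score the CA trace only (uniform radii)

    def __post_init__(self) -> None:
        if min(self.w_clash, self.w_rg, self.w_hbond, self.w_rama) < 0:
            raise InvalidInputError("energy weights must be >= 0")
        if max(self.w_clash, self.w_rg, self.w_hbond, self.w_rama) == 0:
            raise InvalidInputError("at least one energy weight must be positive")


@dataclass
class FoldingResult:
    """One folding run: final model, per-stage intermediates and bookkeeping."""

    final: Structure
    intermediates: list
    trajectory_energies: list
    seed: int
    mode: str  # forward | reverse | nonsequential
    n_trials: int = 0
    meta: dict = field(default_factory=dict)


def _score_atoms(s: Structure, ca_only: bool):
    """(coords, radii, residue index) arrays for the repulsion term."""
    coords, radii, res_idx, names = [], [], [], []
    for i, r in enumerate(s.residues):
        if ca_only:
            coords.append(r.atoms["CA"])
            radii.append(VDW_RADII["C"])
            res_idx.append(i)
            names.append("CA")
            continue
        for name in ("N", "CA", "C", "O"):
            coords.append(r.atoms[name])
            radii.append(VDW_RADII[name[0]])
            res_idx.append(i)
            names.append(name)
        if r.aa != "G":
            coords.append(pseudo_cb(r))
            radii.append(VDW_RADII["C"])
            res_idx.append(i)
            names.append("CB")
    return np.array(coords), np.array(radii), np.array(res_idx), names


def energy(s: Structure, w: EnergyWeights, torsions=None) -> float:
    """Surrogate folding score; lower is better.

    clash: sum of squared soft-sphere overlaps between atoms of residues at
    least two apart in sequence.  rg: CA radius of gyration (strictly larger
    for an expanded chain).  hbond: -1 per backbone hydrogen bond.  rama: +1
    per non-glycine residue with positive phi.  ``torsions`` may be supplied
    when the caller already knows them, skipping re-extraction.
    """
    coords, radii, res_idx, _ = _score_atoms(s, w.ca_only)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    rsum = radii[:, None] + radii[None, :]
    sep = np.abs(res_idx[:, None] - res_idx[None, :])
    overlap = np.where(sep >= 2, np.maximum(rsum - d, 0.0), 0.0)
    clash = float(np.triu(overlap ** 2, 1).sum())

    ca = s.ca_coords()
    rg = float(np.sqrt(((ca - ca.mean(axis=0)) ** 2).sum(axis=1).mean()))

    nhb = 0
    if w.w_hbond > 0 and len(s) >= 3:
        nhb = int((hbond_matrix(s) < HBOND_CUTOFF).sum())

    nbad = 0
    if w.w_rama > 0:
        if torsions is None:
            torsions = extract_torsions(s) if len(s) >= 2 else []
        for r, t in zip(s.residues, torsions):
            if r.aa != "G" and math.isfinite(t.phi) and t.phi > 0:
                nbad += 1

    return (
        w.w_clash * clash + w.w_rg * rg - w.w_hbond * nhb + w.w_rama * nbad
    )


def _temperature(i: int, cycles: int, t_range) -> float:
    t_hi, t_lo = t_range
    if cycles <= 1:
        return t_hi
    return t_hi * (t_lo / t_hi) ** (i / (cycles - 1))


def fold_stage(
    s: Structure,
    lib: FragmentLibrary,
    cycles: int,
    active_range: tuple,
    w: EnergyWeights,
    t_range: tuple = (2.0, 0.25),
    rng: np.random.Generator | None = None,
    lib_offset: int = 0,
    position_order: str = "asc",
    geometry: BackboneGeometry = IDEAL_GEOMETRY,
    stats: dict | None = None,
) -> Structure:
    """Run ``cycles`` Metropolis fragment-insertion trials on one chain.

    Each trial picks a window start uniformly among windows fully inside
    ``active_range`` (1-based, inclusive), overwrites its torsions with a
    uniformly chosen candidate fragment, rebuilds the chain and accepts if
    the score does not rise or with Boltzmann probability exp(-dE/T)
    otherwise.  The lowest-energy accepted conformation is returned.

    ``lib_offset`` maps chain positions to library positions (the reverse
    sense renumbers the chain as it grows from the C-terminus); with
    ``position_order='desc'`` eligible windows are enumerated from the
    C-terminal end, which makes move indices line up with the mirrored
    forward problem.  One uniform variate is consumed per trial regardless of
    the branch taken, so trajectories are reproducible and comparable.
    """
    if cycles < 0:
        raise InvalidInputError("cycles must be >= 0")
    lo, hi = active_range
    if lo < 1 or hi > len(s) or lo > hi:
        raise InvalidInputError(f"active range {active_range} outside chain 1..{len(s)}")
    if cycles == 0:
        return s.copy()
    rng = rng if rng is not None else np.random.default_rng(0)
    k = lib.fragment_length
    eligible = [
        p
        for p in range(lo, hi - k + 2)
        if lib.by_position.get(p + lib_offset)
    ]
    if position_order == "desc":
        eligible = eligible[::-1]
    if not eligible:
        raise NoMoveError(
            f"no eligible insertion window inside {active_range} (fragments of {k})"
        )

    seq = s.sequence
    current = [TorsionTriple(*t) for t in extract_torsions(s)]
    cur_struct = build_from_torsions(seq, current, geometry)
    cur_e = energy(cur_struct, w, current)
    best_struct, best_e = cur_struct, cur_e
    energies = [cur_e]

    for i in range(cycles):
        pos = eligible[int(rng.integers(len(eligible)))]
        candidates = lib.by_position[pos + lib_offset]
        frag = candidates[int(rng.integers(len(candidates)))]
        trial = list(current)
        trial[pos - 1 : pos - 1 + k] = list(frag.triples)
        trial_struct = build_from_torsions(seq, trial, geometry)
        trial_e = energy(trial_struct, w, trial)
        de = trial_e - cur_e
        temp = _temperature(i, cycles, t_range)
        u = float(rng.random())  # always consumed: keeps streams aligned
        if de <= 0 or u < math.exp(-de / temp):
            current, cur_struct, cur_e = trial, trial_struct, trial_e
            energies.append(cur_e)
            if cur_e < best_e:
                best_struct, best_e = cur_struct, cur_e
        if stats is not None:
            stats["trials"] = stats.get("trials", 0) + 1
    if stats is not None:
        stats.setdefault("energies", []).extend(energies)
    out = best_struct.copy()
    out.meta.update(s.meta)
    out.meta["stage_energy"] = best_e
    return out


def _block_bounds(l: int, sizes, stage: int, sense: str) -> tuple:
    """Full-sequence slice (0-based, half-open) of the block extruded at ``stage``."""
    done = sum(sizes[:stage])
    size = sizes[stage]
    if sense == "forward":
        return done, done + size
    return l - done - size, l - done


def fold_sequential(
    sequence: str,
    lib: FragmentLibrary,
    schedule: FoldingSchedule,
    sense: str,
    w: EnergyWeights,
    seed: int,
    t_range: tuple = (2.0, 0.25),
    geometry: BackboneGeometry = IDEAL_GEOMETRY,
    extended_triple: TorsionTriple = EXTENDED,
) -> FoldingResult:
    """Cotranslational folding: extrude a block, fold, repeat.

    ``sense='forward'`` grows at the C-terminus starting from the N-terminal
    block (the sense of translation); ``sense='reverse'`` grows at the
    N-terminus starting from the C-terminal block.  Stage k runs the
    schedule's per-stage cycle budget over the whole currently extruded
    chain.  Intermediates (one per stage, after folding) are recorded.
    """
    if sense not in ("forward", "reverse"):
        raise InvalidInputError(f"sense must be forward or reverse, got {sense!r}")
    if len(sequence) != schedule.l:
        raise InvalidInputError(
            f"sequence length {len(sequence)} != schedule length {schedule.l}"
        )
    rng = np.random.default_rng(seed)
    sizes = schedule.extrusion_sizes
    l = schedule.l
    stats: dict = {"trials": 0}
    intermediates = []
    stage_energies = []
    current: Structure | None = None

    for stage in range(schedule.e):
        a, b = _block_bounds(l, sizes, stage, sense)
        block_seq = sequence[a:b]
        if current is None:
            current = build_from_torsions(
                block_seq, [extended_triple] * len(block_seq), geometry
            )
        elif sense == "forward":
            current = extend_chain(
                current, len(block_seq), "C", block_seq, extended_triple, geometry
            )
        else:
            current = extend_chain(
                current, len(block_seq), "N", block_seq, extended_triple, geometry
            )
        m = len(current)
        offset = 0 if sense == "forward" else l - m
        current = fold_stage(
            current,
            lib,
            schedule.stage_cycles[stage],
            (1, m),
            w,
            t_range,
            rng,
            lib_offset=offset,
            position_order="asc" if sense == "forward" else "desc",
            geometry=geometry,
            stats=stats,
        )
        stage_energies.append(current.meta.get("stage_energy", math.nan))
        snap = current.copy()
        snap.meta["stage"] = stage + 1
        intermediates.append(snap)

    final = current.copy()
    final.meta.update({"mode": sense, "seed": seed})
    return FoldingResult(
        final=final,
        intermediates=intermediates,
        trajectory_energies=stage_energies,
        seed=seed,
        mode=sense,
        n_trials=stats["trials"],
        meta={"schedule": schedule},
    )


def fold_nonsequential(
    sequence: str,
    lib: FragmentLibrary,
    total_cycles: int,
    w: EnergyWeights,
    seed: int,
    t_range: tuple = (2.0, 0.25),
    geometry: BackboneGeometry = IDEAL_GEOMETRY,
) -> FoldingResult:
    """Fold the full-length chain from the fully extended state in one stage."""
    if total_cycles < 0:
        raise InvalidInputError("total_cycles must be >= 0")
    rng = np.random.default_rng(seed)
    stats: dict = {"trials": 0}
    start = build_from_torsions(sequence, [EXTENDED] * len(sequence), geometry)
    if total_cycles == 0:
        final = start
        e_final = math.nan
    else:
        final = fold_stage(
            start,
            lib,
            total_cycles,
            (1, len(sequence)),
            w,
            t_range,
            rng,
            geometry=geometry,
            stats=stats,
        )
        e_final = final.meta.get("stage_energy", math.nan)
    final = final.copy()
    final.meta.update({"mode": "nonsequential", "seed": seed})
    return FoldingResult(
        final=final,
        intermediates=[],
        trajectory_energies=[e_final],
        seed=seed,
        mode="nonsequential",
        n_trials=stats["trials"],
    )


def generate_decoys(
    mode: str,
    sequence: str,
    lib: FragmentLibrary,
    b: int,
    n_decoys: int,
    w: EnergyWeights,
    base_seed: int,
    t_range: tuple = (2.0, 0.25),
    geometry: BackboneGeometry = IDEAL_GEOMETRY,
) -> list:
    """Independent folding runs; decoy i uses seed base_seed + i."""
    if n_decoys < 1:
        raise InvalidInputError("n_decoys must be >= 1")
    schedule = allocate_cycles(b, len(sequence))
    out = []
    for i in range(n_decoys):
        seed = base_seed + i
        if mode in ("forward", "reverse"):
            res = fold_sequential(
                sequence, lib, schedule, mode, w, seed, t_range, geometry
            )
        elif mode in ("nonsequential", "none"):
            res = fold_nonsequential(
                sequence, lib, schedule.t, w, seed, t_range, geometry
            )
        else:
            raise InvalidInputError(f"unknown mode {mode!r}")
        res.meta["decoy_index"] = i
        out.append(res)
    return out
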