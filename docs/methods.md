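# Methods

## The model

`cotransfold` predicts protein backbone structure by Monte Carlo fragment
assembly and asks a single question of the result: does following the sense
of translation matter?  Proteins are synthesized N-terminus first, and the
nascent chain can begin folding while it is being extruded.  The sequential
("cotranslational") mode imitates this: the chain grows by nine-residue
segments, each appended in the fully extended conformation
(phi = -150&deg;, psi = 150&deg;, omega = 180&deg;), and after every
extrusion the currently exposed chain relaxes by fragment insertion.  The
reverse mode is identical except that the chain grows from the C-terminus
toward the N-terminus, and the non-sequential mode folds the full-length
extended chain in one stage.  Comparing forward and reverse runs on the same
targets, schedules and seeds is a paired design: any systematic difference
isolates the direction of growth.

### Chain representation

A chain is an ordered list of residues, each holding the four backbone heavy
atoms (N, CA, C, O).  Coordinates are built from per-residue
(phi, psi, omega) torsion triples by sequential natural-extension (NeRF)
placement with ideal covalent geometry (N-CA 1.458, CA-C 1.525, C-N 1.329,
C=O 1.231 &Aring;; angles N-CA-C 111.2&deg;, CA-C-N 116.2&deg;, C-N-CA
121.7&deg;).  Construction and torsion extraction are exact inverses on
interior angles (round-trip < 0.5&deg;, property-tested), and chain
extension at either terminus never moves an existing atom: N-terminal
growth places the new block by reverse NeRF off the old first residue's
frame.  A pseudo-CB is reconstructed geometrically (1.53 &Aring;, N-CA-CB
110.1&deg;, dihedral C-N-CA-CB +122.5&deg;, validated against ideal
L-residue coordinates) for steric terms; side chains are otherwise absent.
Glycine carries no CB.  Cis peptide bonds, non-standard residues and
multi-chain assemblies are out of scope.

### Fragment libraries

Insertion moves draw from a per-position candidate list of 9-mer (optionally
3-mer) torsion fragments.  Without an external fragment database, candidates
are idealized motifs — helix (-57, -47), strand (-120, 130), polyproline II
(-75, 145), extended (-150, 150) — with Gaussian noise on phi/psi
(default sigma 20&deg;) and omega pinned to 180&deg;, weighted by a coarse
per-residue propensity table (helix formers prefer the helix motif,
beta-branched residues the strand motifs, G/P the open ones).  A harvester
can instead rank real torsion windows from supplied PDB files by a BLOSUM62
window score; excluding the target's own structure from the source list is
the caller's responsibility and is exposed as an explicit `exclude_paths`
argument, so homology leakage is off by default.

### Folding schedule

For base cycle count `b` and chain length `l`, the total number of cycles is
`t = round(b*l/100)` — longer chains get proportionally more search, the way
longer proteins spend more time on the ribosome.  A cycle is one attempted
fragment insertion.  Sequential modes split `t` over `e = ceil(l/9)`
extrusions: `n = floor(t/e)` cycles for each of the first `e-1` stages and
`t - n(e-1)` for the last, so that all three modes spend exactly the same
total search effort (asserted by a trial counter in every test run).  The
rounding of `t` for lengths that are not multiples of 100 is nearest-integer.

### The surrogate score

The score the annealer minimizes has four terms with non-negative weights:

| term    | default weight | form |
|---------|---------------|------|
| clash   | 1.0 | sum of squared soft-sphere overlaps, atoms of residues >= 2 apart (radii C 1.70, N 1.55, O 1.52 &Aring;) |
| rg      | 0.5 | CA radius of gyration, &Aring; |
| hbond   | 2.0 | -1 per backbone hydrogen bond (Kabsch–Sander criterion, below) |
| rama    | 0.2 | +1 per non-glycine residue with phi > 0 |

This is a deliberately coarse stand-in for a full knowledge-based force
field: it rewards compact, hydrogen-bonded, sterically clean, mostly
left-half-Ramachandran conformations and nothing more.  Absolute accuracies
obtained with it are not comparable to production fragment-assembly
pipelines, which is why the package's benchmark statistics ship as packaged
tables rather than being re-derived by folding (see "What the toys do and do
not show").

### The annealer

Each stage runs Metropolis trials over a geometric temperature ladder
(default 2.0 -> 0.25 across the stage).  A trial picks an insertion window
uniformly among windows inside the active region, overwrites its torsions
with a uniformly chosen candidate fragment, rebuilds coordinates and accepts
if the score does not rise, or with probability exp(-dE/T) otherwise.  One
uniform variate is consumed per trial whether or not the Boltzmann branch is
reached, so random streams stay aligned between runs that should be
comparable.  The conformation carried to the next extrusion is the
lowest-energy accepted one (best-so-far), not the last accepted — the
alternative is a one-line change but best-so-far makes stage-to-stage
progress monotone and testable.  Insertion positions are uniform over the
extruded region; a growth-terminus-skewed distribution is a plausible
refinement but is not implemented.

## Evaluation metrics

**GDT_TS.**  For cutoffs 1, 2, 4, 8 &Aring;, `N_c` is the largest number of
residues a rigid superposition places within `c` of their native CA
positions; `GDT_TS = 100 (N1+N2+N4+N8)/(4N)`.  The non-cumulative weights
follow from the telescoping identity `4M1 + 3M2 + 2M4 + M8 = sum N_c`, which
is what "more heavily weighting closer pairs" means operationally.  The
superposition search is deterministic seed-and-refine: every contiguous CA
segment of lengths 4, 8, 16 and the whole chain seeds a least-squares fit,
each fit is refined by alternately superposing on its inlier set and
recounting, every visited rotation is also tried with the n translations
that place each residue exactly on its native position, and a sorted-prefix
sweep re-fits on the s best residues for every s.  Chains of <= 16 residues
additionally seed from all contiguous segments of every length and restart
refinement from more inclusive inlier sets.  The search provably never
misses the naive whole-chain count (the whole chain is a seed); empirically
it dominates a dense-rotation-grid brute force and agrees with exhaustive
subset-enumeration on structured cases, trailing enumeration by at most one
residue at the 1–2 &Aring; cutoffs on adversarial random perturbations.
Tests bound it between those two oracles rather than pinning one of them.

**Local window quality.**  Every full 11-residue window of a decoy is
independently superposed onto the matching native window; the mean CA-CA
deviation is assigned to the centre residue (defined for residues 6..N-5).
The sense-difference statistic averages these values over natively helical
(resp. strand) residues, per decoy, then over each decoy set, and reports
reverse-mean minus forward-mean per class: positive means the forward sense
is more accurate.  Targets with no strand residues yield NaN for the strand
class and are excluded by callers.

**Terminus trimming.**  Secondary-structure elements are maximal runs of at
least four identical H or E labels in the native assignment.  Trimming
removes residues before the first element and after the last, provided the
inclusive span from the first element's last residue to the last element's
first residue covers at least five residues; otherwise the model is returned
untrimmed with a logged skip.  The span rule is this package's resolution of
an ambiguous textual constraint; it is the only reading we found consistent
with both worked examples in the original protocol description.

**Clashscore.**  Overlaps greater than 0.4 &Aring; between van-der-Waals
spheres (C 1.70, N 1.55, O 1.52 &Aring;) per 1000 atoms, over backbone +
pseudo-CB.  Pairs within four covalent bonds are excluded: through the 1-5
level, interatomic distances are dictated by covalent geometry and the
sampled torsions themselves — a fully extended chain holds O(i) about
2.5 &Aring; from CB(i+1) by construction — whereas the statistic is meant to
count nonlocal packing violations.  This simplified score is not comparable
to full-chemistry, hydrogen-added clashscores in absolute terms; the
extension-delta protocol (clashscore change upon appending nine extended
residues at the growing terminus, averaged over intermediates of lengths 18,
36, 54, 72, 90) uses only differences, which the simplification preserves.

**Secondary structure.**  A three-state Kabsch–Sander-style assigner: the
amide H is reconstructed on the backbone bisector, the electrostatic dipole
energy `0.084 * 332 (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)` defines a hydrogen
bond below -0.5 kcal/mol, helices are runs covered by two consecutive
i -> i+4 (or i+3) turns, strands are residues in parallel/antiparallel
bridge patterns, and everything else is coil.  Externally computed 8-state
labels can be read instead and are collapsed {H,G,I} -> H, {E,B} -> E,
else C.  Bulges, bends and pi-helix edge cases are not reproduced.

**ALR.**  The previous-contact statistic: a contact is a CA pair within
8 &Aring; at sequence separation >= 5; for residue i, `p_i` counts contacts
to earlier residues and `s_i` to later ones, and
`ALR = mean over {i : p_i + s_i > 0} of log2((p_i + 1/2)/(s_i + 1/2))`.
The pseudo-count, log base, cutoff and separation are this package's
concrete choices for a statistic whose published definition is not restated
in full anywhere we could verify; ALR values computed here are therefore
internally consistent (exactly antisymmetric under chain reversal, zero with
a flag when no residue has a long-range contact) but not guaranteed to match
published per-protein values such as 0.2762 for 1qc7A.  The packaged
benchmark tables carry the published ALR values verbatim.

## Packaged benchmark tables

The per-protein results of the original directionality study (34 proteins
with ALR >= 0.15, 34 with ALR <= -0.15; mean and maximum GDT_TS over 1000
decoys for the sequential, reverse-sequential and non-sequential
algorithms, plus terminus-trimmed maxima) are shipped as TSV fixtures with
SHA-256 integrity checks.  Re-deriving them would require the original
fragment-assembly engine, its fragment database and cluster-scale decoy
generation; they are inputs here, and every statistic quoted from them
(win/loss/tie counts, sign-test p-values, mean-of-means, extreme
differences, satisfactory-prediction counts, the 94% directionality
headline) is recomputed from the tables at run time.  The trimmed
positive-set table has 33 rows as published: one chain was skipped by the
element-separation rule.  Pairwise comparisons use the printed two-decimal
values, with ties defined as exact equality at that precision; the
significance stars come from an exact two-sided binomial sign test excluding
ties (***, **, * at 0.001, 0.01, 0.05).  Recomputing from printed values
reproduces almost every quoted number exactly; the handful of one-off
discrepancies between the tables and the running text (e.g. a mean that
re-averages to 19.74 where the text says 19.72) are reported as computed
from the tables.

## Synthetic toys and the desk-scale experiment

`make_toy_native` builds clash-free toy natives from hand-tuned torsion
recipes: an ideal helix; a 14-residue antiparallel hairpin core with four
cross-strand hydrogen-bond rungs (found by direct search over strand and
turn torsions, then verified with the Kabsch–Sander assigner and the
clashscore); a two-helix bundle; and a mixed helix + hairpin fold.  Optional
Gaussian torsion noise perturbs each recipe, with clash-free retries that
remain a pure function of the spec.  Decoy sets for metric testing perturb
the native in torsion space — never Cartesian, so every decoy is a valid
chain — with the noise magnitude bisected per decoy until the superposed CA
RMSD is within 5% of the requested value.

The directional experiment folds five toy targets (18–27 residues, all four
topologies, natives lightly perturbed at sigma = 3&deg;) forwards and in
reverse: 20 decoys per sense, base 200 cycles, shared schedules, library and
per-decoy seeds, GDT_TS against the toy native, and an exact sign test over
targets.  These sizes keep the full pipeline — generator, library, both
folding senses, GDT, paired statistics — exercised end to end in a few
minutes on one core.  **What passing does and does not show:** the toys
demonstrate that the machinery is correct, deterministic and paired; they do
not reproduce the published 94% directionality rate, and no such claim is
made.  Real targets are two to twenty times longer, have evolved sequences
rather than motif-coloured ones, and were folded with a full knowledge-based
score and fragment database; with the surrogate score on near-trivial
topologies, forward and reverse folding perform similarly and the observed
win counts simply are what they are.

## Numerical choices and degenerate inputs

* Angles live in (-180, 180]; terminal dihedrals that do not exist are NaN
  sentinels, never fabricated values.
* `allocate_cycles` tolerates t < e (stages with zero trials are legal and
  count zero towards the trial conservation assertion).
* Ties in "highest-GDT decoy" selection break by lowest decoy index; ties in
  extreme-difference rows break by first occurrence.
* Chains shorter than five residues get an all-coil assignment with a
  warning; single-residue chains have no dihedrals and torsion extraction
  refuses them.
* The Metropolis comparison draws its uniform variate unconditionally so
  that floating-point ties in dE cannot desynchronize paired runs.
* `SYMMETRIC_GEOMETRY` (equalized bond lengths and peptide angles) exists so
  that reverse folding can be checked, exactly, against forward folding of
  the mirrored problem; production runs always use the asymmetric ideal
  geometry.

## Known limitations

* The surrogate score has no solvation, no pairwise statistical potentials
  and no side chains beyond pseudo-CB; absolute GDT_TS values from this
  engine are not comparable to the packaged benchmark numbers.
* The GDT search is a bounded heuristic (see above); scores are
  deterministic and mutually comparable, which is what the paired design
  needs, but are not certified maxima.
* The idealized fragment generator knows four motifs; it cannot propose
  irregular loops beyond what noise provides.
* Ribosome-tunnel confinement, variable translation speed and variable
  extrusion sizes are not modelled.
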