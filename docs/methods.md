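# Methods and numerical conventions

This note records the modelling assumptions, parameter defaults, and
numerical choices behind each analysis stage, and what the synthetic
generators do and do not emulate.

## Units and coordinate conventions

Lengths are Angstrom, masses amu, times ps, energies kBT at the run
temperature. Nanometres appear only at the presentation layer:
cluster–cluster distances are *reported* in nm because the functional
window (1.1–1.4 nm, i.e. 11–14 Å) and the sampling windows are
conventionally quoted that way. All residue positions and consensus
offsets are 1-based inclusive.

## Superposition

`kabsch_superpose` minimizes the mass-weighted RMSD via the SVD of the
weighted covariance, with the determinant sign fixed so the result is
always a proper rotation (reflections excluded). Collinear point sets
(fewer than two significant singular values) raise
`DegenerateGeometryError` rather than returning an arbitrary rotation.
`quaternion_superpose_rmsd` implements the independent Kearsley
quaternion-eigenvalue method and is used purely as a cross-check oracle;
the two agree to better than 1e-8 Å on random instances.

## SASA (Shrake–Rupley)

Deterministic golden-spiral point set (default 960 points per atom),
probe radius 1.4 Å (water-sized), Bondi-type van der Waals radii.
Iron's radius is overridden to zero by default: in FeS clusters the
metal is buried by its ligands and should contribute no surface.
Zero-radius atoms neither expose surface nor occlude others — probe
inflation is suppressed for them. An isolated sphere reproduces the
closed form 4π(r+p)² exactly because every point is accessible; pairs
are validated against the spherical-cap closed form. The point lattice
does not rotate with the molecule, so per-atom areas vary slightly
(sub-percent in total) under rigid motion.

## Compactness ratio

R = SASA(whole) / (SASA(bare F) + SASA(bare H)), where each "bare"
domain is evaluated with every other atom removed. Non-overlapping
domains give R = 1; occlusion lowers R; residues outside F and H (a
short C-terminal tail) can push R slightly above 1. A conformation is
classified compact iff R ≤ 0.95, boundary inclusive.

## Radial distribution function

Orthorhombic minimum-image convention when the trajectory carries a
box; each bin normalized by its shell volume 4πr²dr and by the mean
partner density so an ideal gas gives g → 1. `r_max` may not exceed
half the smallest box edge. Without a box the density is taken from
the r_max sphere itself ("local" mode) and a warning is emitted.
Self-pairs are excluded.

## RMSF by principal components

Frames are superposed mass-weighted onto their mean (two passes: align
to the first frame, then to the resulting mean), the 3N × 3N positional
covariance is diagonalized, and per-atom fluctuations are rebuilt from
the top modes (default 4). With the full spectrum this equals the
direct per-atom variance to machine precision; truncation can only
lower it — for spatially uncorrelated jitter the top few modes capture
only a small share, which is the expected behaviour, not an error.
Superposition absorbs a little genuine fluctuation (about 1 % at
mid-structure atoms for the toy systems), which is why planted-recovery
checks probe a mid-structure atom.

## Water orientation at the distal iron

A shell event is a frame/water pair whose oxygen lies within 4 Å of
the iron; the event is H-inward when the nearer hydrogen is closer to
the iron than the oxygen. With zero events the probability is undefined
(`None`), deliberately distinct from zero.

## Salt bridges

Charged-group atoms by convention: Cδ(Glu), Cγ(Asp) and the C-terminal
carboxyl carbon versus Nζ(Lys), Nη(Arg) and the N-terminal nitrogen;
contact iff distance ≤ 4 Å (inclusive).

## Sequence fingerprints

Motif scanning is ungapped Hamming matching over short cores; gapped
alignment belongs to external aligners. `X` always counts as a mismatch
and never satisfies an anchor. Anchored positions (e.g. the cysteine at
offset 4 of `TSCCPGW`) must match exactly regardless of the mismatch
budget. Cysteine spacing is summarized with gap counts:
positions [21, 72, 75, 78] → `Cx50Cx2Cx2C`. Domain segmentation prefers
explicit curated boundaries; the heuristic fallback places the H-domain
start 134 residues before and its end 307 residues after the best P1
hit.

## Chimeric grafting

The donor range is rigidly placed by a mass-weighted superposition of
the shared heavy atoms of a single junction residue (at least 3
required), then host atoms are overwritten name-by-name within each
positionally aligned residue. Host atoms with no donor partner are
retained untouched and listed in the report. Cluster ligation checks
the minimum Sγ–Fe distance per cysteine against a 2.6 Å covalent-bond
upper bound; a missing Sγ yields an error entry without aborting the
report.

## Metadynamics engine

Overdamped Euler–Maruyama Langevin dynamics (`q += F dt + sqrt(2 dt) ξ`)
stands in for the molecular integrator; harmonic walls (k = 200) keep
walkers on the CV grid. Well-tempered deposition adds a Gaussian of
width σ (default 0.1) every `deposit_interval` steps with height
`w0 · exp(−V(s)/kBΔT)`; the bias lives on a grid with spacing σ/4 and
forces come from linear interpolation of its gradient. Multiple-walker
sharing is "altruistic" by default — each walker deposits into a private
copy, merged into the shared sum every `exchange_interval` steps (the
merge is exact because deposits are additive) — or strictly "shared".
Every kernel is logged (center, height, width, walker, step), so the
final bias is exactly reproducible from the log.

Free-energy conventions: `negative-bias` gives F = −V;
`well-tempered-rescaled` gives F = −(T+ΔT)/ΔT · V, the standard
converged-bias estimator for this deposition rule. In the literature
the same estimator is often written −γ/(γ−1) · V with the bias factor
defined as γ = (T+ΔT)/T; both notations describe the same rescaling.
Basin free-energy differences come from ΔF = −ln(Z_right/Z_left) with
Z the trapezoidal integral of exp(−F) over each basin.

### Toy schedule

The recovery studies use T = 300 K with ΔT = 2700 K (bias factor
(T+ΔT)/ΔT = 10/9), 8 walkers, 250 000 steps each (2×10⁶ total),
w0 = 0.5 kBT, σ = 0.1. ΔT is a property of the toy study, not of any
production system: with the quartic well's barrier of a few kBT, a
strong tempering keeps deposition decaying fast enough to converge
within the step budget, while the physical-scale ΔT = 20 K (bias factor
16 in the γ = (T+ΔT)/T convention) would temper far too weakly for a
desk-scale run. Recovery of the double-well ΔF is accurate to about
±0.15 kBT across seeds at this schedule, against a 0.3 kBT tolerance.

## Synthetic generators

All generators are deterministic under `(seed, params)` and return a
`SyntheticTruth` with the planted parameters and expected downstream
values. What they emulate — and what they do not:

- **Toy proteins** are idealized helical sticks (1.5 Å rise, 100°
  twist, five atoms per residue); real domains pack side chains and
  cofactors. They exist to give SASA/compactness/grafting a geometry
  with known overlap structure.
- **Harmonic trajectories** are uncorrelated Gaussian jitter around a
  reference; real MD is time-correlated. Expected RMSF is std·√3
  isotropically, std along a restricted axis.
- **Hydration shells** fix rigid water geometry with only the
  orientation statistics controlled; the planted inward hydrogen is
  placed exactly at its target Fe distance, letting the O–H bond absorb
  the ~0.04 Å difference from the rigid 0.957 Å length.
- **Sequences** use a cysteine-free background alphabet so Cys
  positions are exactly the planted ones (plus any C inside a planted
  motif).
- **Double wells** U(s) = b(s²−1)² + a(s+1)/2 store their quadrature
  ΔF (basins split at the numerically located barrier top) as truth.

## Limitations

- The PDB codec covers fixed-column v3.3 coordinate records
  (ATOM/HETATM/MODEL/ENDMDL) with defined policies — altlocs resolved
  to highest occupancy (first on ties), first MODEL for structures —
  not the full format; insertion codes and hybrid-36 serials are out of
  scope.
- SASA accuracy is bounded by the point count (default 960); per-atom
  areas are orientation-dependent at the sub-percent level.
- The metadynamics engine targets bookkeeping fidelity (tempering,
  sharing, logging, reconstruction) on 1D toy CVs, not molecular force
  fields; error bars on recovered ΔF come from seed variation, not from
  block analysis.
- Truncated-mode RMSF underestimates fluctuations of high-rank motion
  by construction; use the full spectrum when the motion is not
  low-dimensional.
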