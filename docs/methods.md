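# Methods

## Model

The analysis treats a set of receptor-frame-aligned snapshots of probe
molecules as draws from the equilibrium distribution of the
probe–receptor system.  Space is partitioned into cubic voxels
(isotropic spacing, default 0.5 Å; half-open intervals so every point
belongs to exactly one voxel).  For a tracked group (a chemotype's
atoms, or the molecular centre of mass) the per-voxel binding free
energy is the Boltzmann inversion of the occupancy ratio

    ΔG(v) = −k_B T ln(N_v / N_0),       k_B = 1.987204e-3 kcal/(mol·K)

with `N_0` the occupancy expected if the receptor exerted no influence.
`N_0` is computed from the bulk probe number density ρ (molecules/Å³):
`N_0 = ρ · h³ · F · m`, with `h` the voxel edge, `F` the number of
frames and `m` the multiplicity (number of equivalent atoms pooled
into the map).  ρ can be supplied (known v/v concentration; exact for
synthetic systems) or estimated as the mean per-voxel count over a
user-designated bulk region.  Replicas are concatenated and pooled
with equal weight; no per-replica normalisation or density smoothing
is applied.

## Atomic repartition

Raw per-atom maps conflate an atom's intrinsic affinity with the pull
of the rest of its molecule.  The repartition subtracts the expected
contribution of the rest of the molecule, using the molecular map
`ΔG^M` (from the CoM density) and per-atom surface fractions
`α_i = SASA_i / SASA_M`:

    ΔG_i^corr(v) = ΔG_i(v) − (1 − α_i) · ΔG^M(u)

Because the CoM explores a range of positions while atom *i* sits in
voxel *v*, `ΔG^M` is evaluated at the CoM voxel `u` of each individual
observation (the accumulator records an (atom voxel, CoM voxel) pair
per observation) and the corrected value is the mean over the `N_v`
observations in *v*.  Observations whose CoM left the grid are skipped
and tallied; when atomic and molecular maps come from the same
snapshots a CoM observation guarantees the CoM voxel is defined, so the
undefined-CoM tally is zero by construction (asserted in tests).

The α entering the correction is the **per-atom** fraction of the
observed atom.  For a chemotype of symmetry-equivalent atoms (the two
isopropanol methyls, the six ring carbons) all members share one α, and
the pooled map uses that common value — not the sum over members: each
observation is a single atom, and the expected contribution of "the
rest of the molecule" excludes only that atom.  Using the summed α
would make the correction vanish for a fully symmetric probe, which
contradicts both the per-atom physical limit and the size-invariance
property the correction exists to deliver.

## SASA and α fractions

Shrake–Rupley with a deterministic golden-angle-spiral point set
(default 960 points per atom), solvent probe radius 1.4 Å, heavy atoms
with Bondi radii.  For flexible molecules α is the population-weighted
ratio of conformer SASAs; the shipped small probes are treated as one
rigid conformer.  α may also be supplied directly in the probe
topology, which is preferred when symmetry dictates the exact value
(1/6 for six identical ring atoms): the spiral point set is
quasi-uniform but not symmetric under the molecular point group, so a
computed α deviates from the symmetric value by ~0.5%, a bias a
−6 kcal/mol well would translate into ~0.01 kcal/mol on corrected
values.  Increasing 960 → 3840 points moves any shipped-probe α by
less than 0.01.

## Centre of mass

Mass-weighted over the topology's (heavy) atoms by default; a proxy
atom (the central carbon of isopropanol) can stand in for the CoM,
matching common practice.  Hydrogens are ignored for counting, CoM and
SASA throughout; they carry little mass, are rarely written to
snapshot files, and their surface is largely subsumed by heavy-atom
radii.

## Synthetic generator

The generator emulates the equilibrium statistics the method assumes,
not the dynamics: each probe instance, independently per frame, is
bound to discrete site *s* with probability
`p_s = w_s / (1 + Σ_t w_t)`, `w_s = (V_site/V_box) exp(−U_s/kT)`
(`V_site` = one analysis voxel), otherwise uniform in the box with
random orientation.  The site-voxel/bulk-voxel density ratio is then
exactly `exp(−U_s/kT)` and inversion recovers the well depth to within
binomial noise (`se(ΔG) ≈ kT·sqrt((1−p_s)/(n·p_s))`).  Instances are
ideal (non-interacting) and may co-occupy a site; enforcing single
occupancy would introduce Langmuir saturation and the closed form
would no longer be exact for deep wells.

Bound placement is rigid.  Two modes per site: a **fixed pose**
(anchor + constant offsets), in which each atom's density equals the
molecular density, so raw atomic maps show the full well depth and
corrected maps show exactly `α_i·U` — the regime with exact point-value
ground truth; and a **random orientation** about an anchor atom,
modelling a group that binds while the rest of the molecule swings
freely (the polar-only scenario).  In the latter the swinging atoms
spread over shells, their raw maps carry the depth minus an
orientational-entropy term, and ground truth is qualitative rather
than point-valued.

Fixed-pose systems are analysed with a **single representative atom**
per chemotype (multiplicity 1).  With a rigid pose each equivalent atom
is pinned to its own voxel, so pooling all of them against a
multiplicity-scaled `N_0` would add a spurious symmetry-number offset
`+kT ln m` to site values.  Pooling with multiplicity-scaled `N_0`
remains the default for real, rotationally averaged simulations, where
every equivalent atom visits the site voxel and the offset cancels.

Default study conditions: 20 Å cubic box, 50 instances (bulk density
≈ 6e-3 Å⁻³, comparable to a ~20% v/v cosolvent mix), 2×10⁴ frames
(10⁶ instance-frames — enough to resolve a −6 kcal/mol well voxel to
±0.001 kcal/mol and bulk voxels to ±0.2), temperature 300 K, analysis
grid 12 Å cube at 0.5 Å spacing around the site.  Seeds are explicit
everywhere; a run is bit-reproducible from (config, seed).

What the generator does **not** emulate: solvent–solvent interactions,
receptor flexibility (and hence cryptic-pocket opening), finite probe
diffusion/autocorrelation between frames, anisotropic or partially
occluded sites, and conformational flexibility of the probe.  Passing
tests therefore demonstrate the correctness of the estimator chain on
Boltzmann-exact input, not the convergence behaviour of real MD.

## Numerical choices

- Voxel assignment: `floor((x − origin)/h)`, half-open boxes; points on
  the upper face of the last voxel are out of bounds.  Out-of-bounds
  observations are tallied and reported, never silently dropped.
- Zero-count voxels: masked as undefined by default (`ΔG = +∞` has no
  finite representation the correction stage could consume); an
  optional pseudocount policy caps them at the `N=1` sampling floor.
- OpenDX export: z-fastest (C) data order, three values per line;
  undefined voxels written as a configurable sentinel (default 999.0)
  because DX has no portable NaN convention.  Read-back re-masks the
  sentinel.  Only orthogonal isotropic lattices are accepted.
- Hotspots: 26-connectivity so thin diagonal features are not split;
  representative point is the minimum-value voxel centre (ties broken
  to the lexicographically lowest index), with an unweighted-centroid
  option.  Default thresholds −1.5 kcal/mol (raw) and −0.7 to −1.0
  (corrected) maps.
- Coincident equal-radius spheres are rejected in SASA (undefined
  surface partition); conformer weights are normalised internally and
  a zero-weight conformer's SASA is never evaluated.
- Uncertainties: per-voxel `se(ΔG) = kT/√N_v` (Poisson counts),
  exposed by `BindingFreeEnergyResults.std_error`.

## Open design choices

- Grid origin/extent are free parameters; nothing forces the grid to
  cover the whole box, and `N_0` from a supplied density keeps partial
  grids unbiased.
- Multi-model PDB is the one required snapshot dialect (read through
  biotite); other trajectory formats can be adapted behind the
  `SnapshotSet` contract.
- Per-atom α values are computed individually and averaged within a
  chemotype for the pooled map; chemotype-level pooling of SASA before
  the ratio would give the same number for symmetric groups.

## Known limitations

- The correction is first-order: it removes the mean drag of the rest
  of the molecule but cannot assign exactly zero to a non-binding
  group whose bound-state positional entropy is finite (the residual
  is an orientational-entropy term, visible in the polar-only
  synthetic case as corrected values near but not exactly zero).
- Corrected voxels inherit the raw map's mask; no extrapolation into
  unsampled space.
- No enthalpy/entropy decomposition, no inhomogeneous-solvation-theory
  terms, no receptor-side per-residue decomposition.
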