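# Methods

This note records the models implemented, the defaults and why they were
chosen, the numerical choices that affect results, and what the synthetic
fixtures do and do not establish about real data.

## Trajectory statistics

**Hydrogen-bond criterion.** A bond X–H···Y is counted when
*d*(H···Y) < 2.2 Å **and** the deviation from linearity,
180° − ∠(X–H···Y), is < 90°; both inequalities strict. The second clause is
the "complementary angle" reading: it admits any geometry with
∠(X–H···Y) > 90° and rejects folded arrangements in which the acceptor sits
back toward the donor heavy atom, which an "angle < 90°" reading would
absurdly accept. The occurrence percentage is frame-level: a frame with two
simultaneous H-bonds counts once; per-pair percentages are reported
alongside for diagnostics.

**Host frame.** The cavity center is the unweighted mean of the host
heavy-atom coordinates (hydrogens excluded; "geometric center", not center
of mass). The cavity axis is the unit vector from the narrow-rim centroid
to the wide-rim centroid; rim selections are user configuration because no
single atom-name convention covers modified hosts.

**Depth metrics d1/d2/d3.** Signed projections of selection centroids
(whole guest, and two moieties) onto the cavity axis, measured from the
host center, positive toward the wide rim. A signed projection — not a 3-D
center-to-center distance — is the only reading under which slightly
negative values (a guest centroid just below the cavity midplane) are
meaningful; reported per-frame, summarised as mean ± sd.

**RMSD and residence.** Each frame is least-squares superposed on a
reference using the host atoms only (Kabsch with uniform weights and the
proper-rotation determinant correction, via
`scipy.spatial.transform.Rotation.align_vectors`), then the RMSD is taken
over the guest selection. The bound state is RMSD < 5 Å (strict); residence
occupancy is the bound-frame percentage and dwell times are maximal
contiguous bound runs × frame interval, reported in ns. Frame spacing is
explicit caller metadata (default 20 ps): trajectory files do not carry it,
and treating it as data avoids baking one sampling convention into the
format layer.

Assumptions: inputs are imaged (no periodic-boundary handling) and
water-mediated H-bond bridges are out of scope.

## MM-PB/SA interaction enthalpy

Single-trajectory approximation: receptor and ligand are cut from the
complex geometry without relaxation, so ΔE_Valence ≡ 0 and the
decomposition is an *interaction* enthalpy, not a binding free energy.

* **Coulomb**: exact inter-selection pairwise sum with
  k_e = 332.0637 kcal·Å/(mol·e²) (the Amber convention). No cutoff — systems
  at this scale are finite and exactness is cheap.
* **Lennard-Jones**: 12-6 form ε[(r_min/r)¹² − 2(r_min/r)⁶] with
  Lorentz–Berthelot combination (r_min additive in the half-radii, ε
  geometric). No cutoff.
* **Polar solvation (PB)**: finite-difference linearized Poisson–Boltzmann.
  The dielectric map is sharp and two-valued — ε_in = 1 inside the union of
  atom spheres at their PB radii, ε_out = 80 outside; no reentrant/molecular
  surface. Zero ionic strength by default (a Debye–Hückel-screened path
  exists but is not exercised by the shipped analyses). These are common
  MM-PB/SA defaults adopted because nothing in the workflow constrains
  them. Numerics: 7-point symmetric stencil; on edges crossing the
  dielectric interface the face coefficient is the harmonic mean of the two
  dielectrics weighted by the in-solute fraction of the edge (computed from
  a signed-distance field), the standard flux-continuity treatment — the
  *map* stays two-valued, only the discrete face coefficient is averaged;
  trilinear charge spreading; Dirichlet boundary from the (screened)
  Coulomb monopole sum; Jacobi-preconditioned conjugate gradients to a 1e-6
  relative residual, with a hard iteration cap that raises an error
  reporting the residual. The reaction-field energy is ½Σqφ from the
  two-dielectric solve minus the same quantity from a uniform-ε_in solve on
  the identical grid, which cancels the divergent grid self-energy of point
  charges. Defaults: 0.5 Å spacing, 8 Å padding. Validation: Born ion
  (q = 1 e, a = 2 Å) errors of 3.8 / 0.8 / 0.2 % at 1.0 / 0.5 / 0.25 Å —
  monotone in refinement and insensitive to whether the ion sits on a grid
  node.
* **Nonpolar solvation**: γ·ΔSASA + b with γ = 0.0072 kcal/(mol·Å²), b = 0
  (Amber-style defaults, overridable). SASA is Shrake–Rupley with a
  deterministic Fibonacci-spiral point set (960 points/atom, probe 1.4 Å);
  doubling the point density moves 10-atom-cluster totals by < 0.5%.
  Degenerate tie-break: a test point exactly on a neighbour's inflated
  sphere is assigned to the lower-indexed atom, so coincident identical
  spheres report the area of one sphere rather than two or zero.

Trajectory averaging applies the decomposition per frame and averages
components; the shipped pipeline strides to ~10 frames because the PB solve
dominates cost and component means converge quickly on the toy systems.

## RRHO thermochemistry

Standard ideal-gas rigid-rotor/harmonic-oscillator expressions at
T = 298.15 K and P = 1 atm by default (the quantum-chemistry toolchain
convention; a stated "298 K" is treated as this standard state, and both
are overridable). Translation uses Sackur–Tetrode with V = k_BT/P; rotation
the classical rigid rotor with symmetry number, linear vs nonlinear decided
from the principal moments of inertia (threshold 1e-8 relative); vibration
a product over real modes with the bottom-of-well convention and the ZPE
carried separately into H; electronic contribution is the spin multiplicity
only. H = E_elec + ZPE + thermal corrections + RT and G = H − TS, so
G ≡ H − TS holds to machine precision by construction. A transition state
must carry exactly one imaginary mode (stored as a negative wavenumber) and
that mode is excluded from every thermal function; a declared minimum with
fewer than 3N−6 (3N−5 linear) real modes is rejected.

No frequency scaling and no quasi-harmonic floor for low modes are applied:
low-frequency torsions therefore contribute large, probably overestimated
entropies, and conformational entropy over multiple minima is ignored —
absolute entropies are underestimates. Activation decompositions are
differences, so much of this cancels, but the reactant-reference choice
does not: a pre-reactive supermolecule complex and a sum of separated
species give very different ΔH‡/−TΔS‡ splits. Both are supported and the
choice is recorded in the output; the supermolecule is the default since
the decomposition targets the *in-cavity* reaction step.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the analyses consume,
not the physics that produces it: per-frame Bernoulli H-bond formation
(geometry placed exactly at d = 1.9 Å, 10° deviation in the final jittered
frame, so detection tests are decoupled from noise), Gaussian binding depth
along the axis, a two-state Markov chain for guest residence
(P(transition) = 1 − exp(−k·Δt); no diffusive pathway, no intermediate
poses), and 0.1 Å isotropic coordinate jitter. Defaults are study-scale for
the methylated-host system: 3000 frames at 100 ps (300 ns), p_hbond =
0.0067, stationary occupancy k_on/(k_on+k_off) ≈ 0.349 with k_off =
0.1 ns⁻¹ (10 ns mean dwell, so ~60 ns maxima are observable in one run),
depth 2.05 ± 0.73 Å. Passing recovery tests therefore shows the estimators
are unbiased and correctly normalised under the generative model — it says
nothing about force-field accuracy, sampling convergence, or the realism of
any MD ensemble. Real-data features deliberately absent: solvent, PBC
imaging artifacts, correlated H-bond/depth fluctuations, multiple binding
poses, host flexibility.

The unbound pose of the hopping guest is ≥ 10 Å from the cavity and its
bound pose is fixed (plus jitter), so RMSD-based classification against the
noise-free bound reference is exact by construction; this is intentional —
the classification *rule* is under test, not a clustering procedure.

Thermochemistry fixtures carry closed-form answers (Sackur–Tetrode;
harmonic-mode entropy; a reactant/TS pair whose activation entropy is
exactly one deleted 50 cm⁻¹ mode's contribution). The Born-ion fixture
carries −(k_e q²/2a)(1 − 1/ε_out).

## Problem sizes and tolerances in the shipped checks

The test suite and acceptance script run 20 independently seeded 3000-frame
trajectories (~12 s), one Born-ion PB refinement series down to 0.25 Å
(~2 s, ~275k unknowns), and 100-atom pairwise oracles. Statistical
recoveries are asserted within 3 standard errors (binomial for occupancies,
with the two-state chain's autocorrelation inflation (1+λ)/(1−λ),
λ = exp(−(k_on+k_off)Δt), for residence); table identities within 0.01
kcal/mol where printed rounding permits and 0.015 where five printed
addends accumulate; closed-form entropies within 0.01 cal/(mol·K).

## Known limitations

* The PB dielectric map has no reentrant surface, so deep crevices between
  close atoms read as solvent; adequate for toy systems and Born-type
  validation, not for production electrostatics of real hosts.
* MM-PB/SA here yields interaction enthalpies under the single-trajectory
  approximation; no entropy term, no strain, no parameter derivation.
* The format layer reads PDB and multi-model XYZ only; binary MD formats
  and electronic-structure logs are out of scope by design — frequency
  datasets use a documented YAML dialect.
* Reported reference tables are consumed as shipped fixtures; the package
  checks their internal arithmetic, it cannot re-derive them from first
  principles.
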