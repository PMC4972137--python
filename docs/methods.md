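# Methods

## Activities and permeability ratios

Effective activities are α = γ·[X] with γ from the extended
Debye–Hückel equation, log₁₀γ = −A z²√I/(1 + B å√I), using A = 0.509
M^-1/2 and B = 0.328 Å⁻¹M^-1/2 (water, 25 °C) and Kielland ion-size
parameters å (Na 4.0, K 3.0, Li 6.0, Rb/Cs 2.5, Mg 8.0, Ca 6.0, Sr/Ba
5.0 Å), overridable per species. Ionic strength is computed from the
declared test salt alone (X-Cl at c gives I = c; X-Cl₂ gives I = 3c);
buffer species contribute under 10 mM in the saline recipes this
models and are ignored. With these defaults the 150 mM monovalent bath
gives γ_Na = 0.74 and γ_K = 0.72 (two decimals). For other species the
same defaults land within 0.02 of commonly tabulated values (e.g. Ca²⁺
0.28 at I = 0.33 M); all size parameters are arguments, not constants.

The monovalent ratio uses the bi-ionic GHK reduction
P_X/P_Na = (α_Na,e/α_X,e)·exp(ΔE_rev F/RT) with
ΔE_rev = E_rev,X − E_rev,Na; this orientation is pinned by a test
(14 mV vs 37 mV with the γ above must give 0.4 to one decimal). The
divalent relation is Lewis-type; because the grouping of its two
exponential factors is ambiguous in parts of the literature, both
readings are implemented and selectable:

- `product` (default, the Fatt–Ginsborg form):
  α_Na,i·e^x·(e^x+1)/(4α_X,e)
- `quotient`: α_Na,i·e^x/((e^x+1)·4α_X,e), which saturates at
  α_Na,i/(4α_X,e) and is therefore not invertible above that bound.

Neither grouping is asserted against published divalent ratios: applied
naively to the printed mutant Ca²⁺ condition (E_rev = 16 mV, 110 mM
bath, 30 mM internal Na) the product form gives ≈0.94 and the quotient
form ≈0.11, suggesting unreported per-condition junction corrections or
a different internal activity convention in the source analyses. The
forward (generator) direction and the analysis direction use the same
implementation, so round-trip tests are exact.

Temperature defaults to 295 K (RT/F ≈ 25.4 mV); recording temperature
is rarely reported for room-temperature whole-cell work, and every
equation takes the temperature through the `Environment` object.
Junction potentials are subtracted from measured E_rev only when a
per-condition value is supplied (convention: corrected = measured − JP,
pinned by tests). Conditions with apparent E_rev ≤ −4 mV (inclusive)
carry no activatable current and only bound the ratio: the result is
clamped to a configurable detection floor (default 0.1) and flagged as
an upper bound.

## I–V analysis

Peak currents per step are fit with I(V) = g_max·(V − V_rev)/{1 +
exp[(V − V_1/2)/k]} by Levenberg–Marquardt least squares. The printed
form of this expression is dimensionally a voltage; the amplitude
g_max (pA/mV) makes it a current. The sign of k selects the gate
orientation: k < 0 opens the gate with depolarisation (the
physiological case for these channels). Initialisation: V_rev from the
zero crossing interpolated on the depolarised side of the inward-current
peak (falling back to an open-limb extrapolation), V_1/2 from the
half-maximal inward current on the closed-gate limb, k = ±8 mV with the
sign inferred from where the crossing sits, g_max from the open-limb
slope; a deterministic restart schedule jitters and sign-flips k, and
the best-residual convergent attempt wins. Non-convergence raises an
error carrying per-attempt diagnostics.

P/4 leak subtraction removes 4× the averaged quarter-amplitude
sub-sweep response, which cancels any strictly linear component
exactly (property-tested over random leak conductances). Rundown is an
ordinary least-squares line through the control-period current,
exposed as an extrapolating model; percent block is
(I_metal − I_control)/I_control × 100 against the rundown-extrapolated
control at the measurement time.

## Structure analysis

PDB files are parsed with gemmi; alternate locations resolve to the
highest-occupancy conformer. Crystal-symmetry operators from CRYST1
are converted to orthogonal-frame rigid transforms, and
`apply_symmetry` appends transformed chain copies under fresh labels,
so entries deposited as half-tetramers can be completed before
analysis. Superposition pairs atoms by chain/residue-number/atom-name
(a `chain_map` renames across tetramers); the optimal rotation is the
Kabsch solution (via SVD), cross-checked in tests against an
independent SVD oracle and a random-rotation optimality property.
Pairing by atom name means side-chain atoms absent from one model —
e.g. beyond Cγ at a mutated filter position — drop out automatically.
"All-atom" RMSDs are over non-hydrogen protein atoms (deposited
structures carry no hydrogens); the selectivity-filter selection
defaults to residues 176–181 (the TLESWS motif) and is overridable,
since the exact atom set behind published filter-only RMSDs is not
enumerated anywhere.

Sodium sites are detected as Na HETATM records, ordered by descending
axial coordinate after aligning the pore axis with z — the axis is the
principal axis whose covariance eigenvalue is most separated from the
other two (the in-plane pair is nearly degenerate for a ~4-fold
tetramer) — and labelled Na_I, Na_II, … from the extracellular side.
The geometry report lists consecutive inter-site distances, each
site's nearest protein atom, the count of protein atoms within a
coordination cutoff (default 3.5 Å, the outer limit of a sodium
coordination sphere) and waters within the same cutoff.

## Electrostatics

The linearized Poisson–Boltzmann equation ∇·(ε∇φ) − κ̄²φ = −ρ/ε₀ is
discretised on a uniform cubic grid with a 7-point stencil,
harmonic-mean face dielectrics, trilinear charge spreading and
Dirichlet boundary values from the Debye-screened Coulomb potential in
bulk solvent. The symmetric positive-definite system is solved by
Jacobi-preconditioned conjugate gradients to a relative residual of
1e-6 by default (1e-8 in energy calculations); the solve is
deterministic given its inputs. The potential is carried in thermal
units u = eφ/kT and energies are ½Σqᵢu(rᵢ) in kT.

Geometry: grid cells inside any atom inflated by the water probe
radius (1.4 Å) take the protein dielectric; cells in the membrane slab
and outside the protein take the membrane dielectric; mobile-ion
screening is zeroed inside atoms inflated by the mobile-ion radius
(2.0 Å) and across the slab span. Defaults mirror the standard
implicit-membrane protocol for this channel class: 300 Å box, 97³
points, slab z ∈ [−25, 15] Å, ε 2/2/80 for protein/membrane/water,
100 mM monovalent salt. An optional cylindrical exclusion radius keeps
an aqueous channel through the slab around the pore axis, the usual
way an open pore is represented in slab models.

Insertion energies use a three-state cycle on one identical grid,
ΔG = E[protein+probe] − E[protein] − E[probe in bulk water], with the
bulk reference at the same fractional grid offset so the probe's grid
self-energy cancels exactly (a uniform water box therefore yields a
numerically flat zero profile). The probe is a point charge whose Born
radius carves its cavity (Na⁺ 1.68, K⁺ 2.2, Li⁺ 1.39, Ca²⁺ 1.73 Å).
Published profile figures are not reproduced value-for-value — the
solver is validated by properties instead: Coulomb/Yukawa analytic
agreement within 5% over 10–40 Å, exact linearity in the fixed
charges, q² scaling of the reaction-field component within 2%, mirror
symmetry on symmetric fixtures, and an exact quadratic
linear-response decomposition that predicts a fifth charge state from
four others.

Size selectivity in this model needs partial hydration: at a narrow
aqueous channel through the slab (exclusion radius 2.6 Å, grid spacing
0.6 Å) a Na⁺-sized probe threads the pore with part of its hydration
annulus intact while a K⁺-sized cavity occludes it, giving barriers
ordered Li⁺ < Na⁺ < K⁺. In a fully occluding constriction continuum
theory instead favours the larger ion (smaller Born penalty); the
tests encode the partially hydrated regime, which is the mechanism the
hydrated-ion filter architecture implies. Standard protonation is
assumed for consumed PQR charges; charge/radius assignment itself is
out of scope (PQR files are inputs).

## Synthetic data

The I–V generator emulates whole-cell families: reversal potentials
come from the GHK voltage equation over the declared saline
compositions (divalent conditions invert the Lewis-type relation), the
gate is a Boltzmann with defaults V_1/2 = −100 mV, k = −8 mV, g_max =
2 pA/mV, leak 0.5 pA/mV, rundown 3 %/min, noise σ = 5 pA on peak
currents, steps −180…+60 mV in 10 mV increments. Rundown multiplies
the gated component (conductance loss), so the peak current decays
linearly in time while the reversal potential is untouched — an
additive drift would bias the zero crossing, which no recorded
rundown does. P/4 sub-sweeps carry only the linear leak, emulating
delivery from a hyperpolarised holding potential. Internal saline
defaults to 30 mM Na + 90 mM NMDG (NMDG impermeant). Generators are
bit-reproducible under a fixed seed. What the generator does not
emulate: trace-level kinetics (only peak currents), capacitance
transients, series-resistance error, endogenous background currents
beyond the detection-floor convention — so passing round-trip tests
demonstrates the correctness of the analysis chain, not robustness to
every artefact of real recordings.

Toy pores are exactly n-fold-symmetric rings of partial charges
(carboxylate-like −0.76 e, carbonyl-like −0.51 e oxygens) about the z
axis with axial sodium ions and waters, emitted as matched PDB and PQR
fixtures; atoms closer than 0.5 Å are rejected.

## Problem sizes and numerical choices in the test suite

Electrostatics tests run on 33³–81³ grids over 40–120 Å boxes, chosen
so each solve completes in seconds while staying in the regime where
the analytic oracles hold; grid-refinement stability is checked
between 0.86 Å and 0.6 Å spacings (within 10%; cavity-boundary
staircasing makes convergence non-monotone at coarser spacings).
Round-trip permeability recovery uses 20 seeds per true ratio and
asserts the median within ±0.05. The deposited-coordinate geometry
check requires the wild-type and mutant entries cached under
`scratch/pdb/` and reports distances and RMSDs at the tolerances
stated in the tests; every other test is self-contained.

## Known limitations

- Linearized (not nonlinear) PB, single uniform grid, no focusing:
  adequate for qualitative barrier/well shapes, not for absolute
  energies of highly charged systems.
- The divalent-ratio groupings do not reproduce published mutant
  divalent ratios from the printed inputs alone (see above); results
  for divalents should be read comparatively, not absolutely.
- Published Li⁺ ratios are similarly not reproduced exactly by the
  monovalent equation applied to printed reversal potentials (0.8
  computed vs 0.7 published for the mutant), consistent with
  unreported per-solution junction corrections; no test asserts them.
- The filter-only RMSD depends on the residue selection (default
  176–181); published filter RMSDs are matched only within ±0.1 Å.
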