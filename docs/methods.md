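# Methods

This note documents the model implemented in `siepka`, its assumptions,
the numerical choices behind the solvers, what the synthetic fixtures do
and do not emulate, and known limitations.

## Physical model and assumptions

The pKa of a titratable side chain reflects the free-energy difference
between its protonated and unprotonated forms. The model assumes this
difference is dominated by electrostatics: the context-dependent part of
the free energy is taken proportional to the electrostatic interaction
energy difference ΔE^inter computed with fixed partial charges and a
two-dielectric continuum, while all context-independent terms (internal
energies, the hydronium free energy) are absorbed into a single intercept
C per residue type. Non-electrostatic terms (van der Waals, torsions) are
used only to filter and relax side-chain placements, never as free-energy
contributions.

The linear model is

    pKa = C − (α / RT·ln10) · ΔE^inter,
    ΔE^inter = min E(protonated micro-states) − min E(unprotonated ones),

so a negative ΔE (protonated form better stabilized) raises the pKa. The
conversion factor α < 1 absorbs entropy–enthalpy compensation; the
calibrated magnitudes are α ≈ 0.29 for His and 0.21 for Asp, in line with
the SIE binding-affinity scaling (α ≈ 0.2). `RT·ln10` defaults to
1.3643 kcal/mol (standard temperature); because α is calibrated jointly
with this constant, the choice of 298.15 K vs 300 K is absorbed by the
fit and does not affect predictions.

Background protonation policy: all titratable residues other than the
target and its coupled histidine neighbours are fixed in their predominant
pH-7.4 states (Asp/Glu ionized, Lys/Arg protonated). Non-target histidines
are neutral, with the HID/HIE tautomer chosen by a local screened-Coulomb
hydrogen-bond score; this geometric scorer is a stand-in for a full
preparation pipeline and is the weakest link of the background model.
Residues coordinating metals or ligands are outside the model's domain.

### Intercept anchoring

The published slope magnitudes are reproducible but the intercepts of the
original regressions are not; the bundled defaults therefore anchor C so
that an unperturbed, fully solvent-exposed reference side chain on the
bundled helix fixture predicts the nominal solution pKa (6.5 for His, 3.8
for Asp) at default solver settings: C = pKa_nominal + (α/RT·ln10)·ΔE_ref
with ΔE_ref = −13.216 (His) and +4.577 kcal/mol (Asp), both computed by
the pipeline itself. Re-calibration against experimental data via
`fit_params` replaces these defaults and is the intended workflow when a
calibration set is available.

## Energy machinery

**Coulomb term.** `k q_i q_j/(ε_in r_ij)` with k = 332.0637 kcal·Å/(mol·e²)
fixed for bit-reproducibility, ε_in = 2.25, 1-2/1-3 pairs excluded and 1-4
pairs scaled by 5/6 (the Amber convention; the bonded topology comes from
bundled residue templates plus peptide bonds, and the classification is by
breadth-first search over that graph). The Coulomb dielectric matching the
interior value 2.25 is a homogeneous-interior approximation, exposed in
the solver settings.

**Solvent-excluded surface.** Scaled spheres (vdW × 1.1) rolled by a 1.4 Å
probe. On a grid, the probe-accessible region A is where the distance to
the sphere union is ≥ the probe radius; the SES interior is the set of
points ≥ probe radius from A. The signed distance combines the exact
sphere-union distance on convex patches with a probe-erosion estimate in
reentrant regions; the erosion estimate (a Euclidean distance transform to
the accessible *node set*) systematically overestimates by about half a
grid step and is debiased by 0.5·h before the two are merged. Surface
triangulation is marching cubes at 0.5 Å spacing; each triangle is owned
by the atom whose scaled sphere is nearest its centroid, which partitions
the total area exactly. Hydrogens carry no surface. A residue's SESA is
the summed area owned by its side-chain atoms (Cβ and beyond), PSESA the
subset owned by the polar atoms (His ring N, Asp carboxylate O); both are
taken from the winning *unprotonated* variant (which variant to use is
not uniquely determined by the model; the choice is config-exposed).

**Reaction field.** Finite-difference Poisson on a node-centred grid:
ε_in inside the SES, ε_out = 78.5 outside, zero ionic strength. Edge
dielectrics use the fraction of each edge inside the solute (from the
linear zero crossing of the signed distance) combined harmonically — the
series combination of the two media; an abrupt per-edge assignment is
available as a config option. Charges spread trilinearly; red-black SOR
(Numba) with ω = 2/(1 + π/n); one focusing level: a coarse grid (4× the
fine spacing, 8 Å margin) with analytic screened-Coulomb boundary values
(Σ qᵢ/(ε_out·r)) feeds interpolated Dirichlet values to a fine grid
(0.4 Å, 4 Å margin) around the solute. The reaction-field energy is
½·k·Σ qᵢ[φ_het(rᵢ) − φ_hom(rᵢ)], where φ_hom solves the same discrete
problem with ε_in everywhere — the grid self-energy of the spread point
charges cancels exactly in the difference. Validation: the solver is
within 0.7% of the Born closed form (|q| = 1, cavity radii 1.5–3 Å) and
0.4% of the L=30 Kirkwood series for an off-centre charge pair, at
default settings; the test-suite bounds are 2% and 3%. Energy differences
between protonation states converge faster than absolute energies under
grid refinement (< 0.1 kcal/mol change when the spacing is halved).

## Conformational sampling

Only the target side chain moves; the backbone and all other heavy atoms
stay at their experimental positions ("no other forms of conformational
sampling"). The bundled backbone-independent library holds 8 His and 6 Asp
χ₁/χ₂ modes in a swappable TSV. Each library rotamer is relaxed per-χ by
golden-section search within ±5° (two sweeps) on a soft-core clash
objective over the *moving* atoms (Cγ and beyond — Cβ is part of the fixed
stem and its covalent contacts with adjacent backbone are not clashes);
clash-free rotamers stay exactly at their canonical χ. Hard filter: any
moving heavy atom closer than 0.7 × (sum of vdW radii) to another
residue's heavy atom removes the rotamer. "Isosteric" is operationalized
(the term has no published definition) as: every moving heavy atom within
1.5 Å of some native side-chain heavy-atom position, or clash-free at a
stricter 0.8 factor; both constants are config-exposed. The native
conformation is always retained.

Protonation micro-states: His — HID, HIE, HIP and their 180° ring flips
(implemented as an exact exchange of the Nδ1/Cδ2 and Cε1/Nε2 coordinates,
with charges riding atom names); Asp — ionized ASP plus neutral ASH with
syn (0°) or anti (180°) carboxyl proton and their Oδ1/Oδ2 flips; the flip
of the symmetric ionized form is geometrically degenerate and collapsed,
giving exactly 6 and 5 states. Protons are built from ideal internal
coordinates (bundled templates); ring and amide N–H lie in-plane along
the bisector of the heavy-atom substituents.

Hydrogen-bond network: rotatable polar hydrogens (Ser/Thr/Tyr/Cys
hydroxyls, Lys ammonium as a rigid group) on a 30° torsion grid and
Asn/Gln amide flips, for residues within 6 Å of the target side chain.
The objective is the screened Coulomb energy of all pairs touching the
moved atoms (with a 0.5 Å distance floor; torsion-circle geometry already
prevents collapse). Up to three degrees of freedom are searched
exhaustively; beyond that, two greedy sweeps in fixed order. The input
configuration is always a candidate, so optimization never worsens the
objective, and everything is deterministic.

## Burial correction

Buried histidines are systematically over-predicted by the electrostatic
model alone — plausibly the lost His(N)–water hydrogen bonding that
perturbs the tautomeric equilibrium, an effect a continuum model cannot
see, and one that buried Asp does not show. The correction is a
two-threshold abrupt step: −2.0 pH iff SESA < 20 Å² and PSESA < 8 Å²,
His only. All three constants are config-exposed. Being a step function,
predictions for residues near the thresholds are the least certain.

## Coupled histidines

Histidines with side-chain heavy atoms within 6 Å (any model) form
maximal connected clusters. For each member, conditional pKa values are
computed with every combination of the other members fixed protonated
(HIP) or neutral (the lower-scoring of HID/HIE); clusters above 4 members
are refused (2^(n−1) enumeration). Effective values solve the
self-consistent system

    pKa_eff(A) = Σ_s w(s at pH = pKa_eff(A)) · pKa(A|s),

with w(s) the product over neighbours of their protonated fraction
f_H = 1/(1+10^(pH−pKa_eff)) or its complement. The solver is a damped
(λ = 0.5) fixed-point iteration from the all-neutral conditional values,
tol 1e-4 pH, max 100 iterations, cross-checked against an independent
nested-bisection solution of the same equations. The system is a
mean-field approximation and becomes *bistable* once conditional shifts
approach ~1 pH unit each (near-degenerate pairs break symmetry first):
several valid fixed points exist and the initialization selects the
branch continuously connected to the all-neutral state. The iteration map
is a provable contraction — hence the fixed point unique — when each
member's coupling shift stays below 2/ln10 ≈ 0.87 pH; the oracle
comparison in the test suite draws repulsive shifts ≤ 0.8 pH from that
regime;
a separate property test verifies that under arbitrary coupling the
returned value is still an exact root. Aspartate targets are never
clustered (Asp–Asp/Glu coupling would require Glu predictions, which are
out of scope).

## Calibration

(C, α) are fitted per residue type by Nelder–Mead simplex (start
(6.5, 0.2), xatol 1e-6) minimizing the RMSE of the full pipeline —
burial correction included, decoupling recomputed each step for records
carrying conditional data. On uncoupled, uncorrected records the fit
agrees with closed-form least squares to 1e-4. Confidence intervals are
2.5/97.5 percentiles over bootstrap resamples (records resampled with
replacement, refit each cycle; > 10% failed refits aborts). Records with
only bounded experimental values ("< 5") are excluded from fitting;
redundant measurements of the same residue across structures are averaged
first. The estimator surface (`SIEPkaRegressor`) follows the
scikit-learn contract so the calibration composes with sklearn model
selection.

## Parameter tables

The bundled charge/radius set is this package's own: polar hydrogens are
explicit, nonpolar-hydrogen charges are folded into their parent carbon,
polar-group dipoles follow the magnitudes of the Amber fixed-charge
family, and each residue label sums *exactly* to its formal charge (the
residual is absorbed by a designated sink atom, usually Cβ). Radii are
Amber-like vdW values by element (C 1.908, N 1.824, O 1.661, S 2.0 Å;
polar H 0.6 Å, no surface contribution). Chain termini use mid-chain
(neutral blocked) charge sets; OXT and terminal protons are dropped. The
tables are plain TSV and user-extendable — whitelisted HET groups (kept
cofactors, fixture pseudo-atoms) require a user-supplied charge/radius
table row per atom.

## Synthetic fixtures

The test structures are generated, not stored: a Born sphere (single
pseudo-atom with an exactly known reaction-field energy), a free
His/Asp residue, a 9-residue ideal poly-Ala α-helix with the target at
position 5 (χ chosen for maximal solvent exposure), the same helix with a
±1 e probe at a set distance from the ring centroid, two His tripeptides
on rigid scaffolds at a controlled side-chain gap, and a His sealed in a
Fibonacci shell of neutral atoms (SESA exactly 0). They probe the
electrostatics, sampling, clustering and burial logic against closed
forms and constructions. What they do not emulate: real packing
heterogeneity, crystallographic noise, missing atoms, multiple
interacting titratable groups of mixed type, cofactors, or conformational
response to ionization — passing them validates the machinery, not
field accuracy on real proteins, which is what the optional 3BE1
benchmark and a PKAD-scale calibration would measure.

Problem sizes used by the test suite and the acceptance script are
desk-scale by design: ≤ 9-residue fixtures, 100 random decoupling
matrices, calibration sets of n = 90 with 100 bootstrap cycles × 100
meta-replicates.

## Degenerate inputs and tie-breaks

Alternate locations resolve to highest occupancy, ties by altloc letter.
Missing side-chain atoms on acyclic residues are rebuilt from ideal
internal coordinates (trans growth); ring-containing residues with
missing ring atoms, and any residue missing backbone atoms, are flagged
unusable (a target in that state, or within the coupling cutoff of one,
is refused). Grid discretization ties in the network search resolve to
the first-encountered minimum in fixed candidate order. Waters are always
removed; hetero groups are removed unless whitelisted.

## Known limitations

* No backbone or neighbour side-chain relaxation; ionization-induced
  conformational change is invisible to the model.
* The background H-bond scorer is local and electrostatic only.
* ε_in is global; no residue-specific or depth-dependent dielectric.
* The burial step is abrupt; near-threshold residues carry ~2 pH of
  correction uncertainty.
* Strongly coupled clusters (> ~1.5 pH mutual shifts) are bistable in the
  mean-field decoupling; the reported branch is the all-neutral
  continuation.
* Glu/Lys/Tyr/Cys are background-only, never prediction targets; metal-
  or ligand-coordinated histidines are out of the model's domain.
* mmCIF input, symmetry-mate generation and automatic PDB retrieval are
  not implemented.
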