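# Methods

This note records the models, conventions and numerical choices behind
`polyqlab`, and what its synthetic test conditions do and do not show
about real conformer ensembles.

## Data model and I/O

A `Conformer` is one chain of residues with named heavy atoms in
ångströms; an `Ensemble` is an ordered list of conformers, optionally a
strictly time-ordered trajectory (timestamps in ps). PDB I/O goes
through biotite; only the first chain is read, altloc `A` wins, and
hydrogens are dropped (the secondary-structure assigner places its own
amide H). Residue indices are 0-based in memory and 1-based in every
file and report. RMSD between equal-length conformers uses the
closed-form (SVD) Kabsch superposition with reflections disallowed.

## Synthetic conformers

The generators supply ensembles with the statistical features the
analysis assumes, in place of biased-sampling trajectories:

- **Ideal motifs** are built from internal coordinates (NeRF) with
  standard backbone geometry. Helices use φ = −57°, ψ = −47°; extended
  chains are all-trans; the hairpin joins two β-strands
  (φ = −139°, ψ = 135°) with a type II′-like two-residue turn
  (60°, −120°)/(−80°, 0°), chosen because it yields fully cross-strand
  hydrogen-bonded hairpins under this package's own assigner.
- **Self-avoiding coils** grow with a fixed 3.8 Å CA bond and reject
  any step bringing non-bonded CAs closer than 4.0 Å.
- **Planted knots** resample standard parametric curves (trefoil
  `(sin t + 2 sin 2t, cos t − 2 cos 2t, −sin 3t)`, figure-eight and
  cinquefoil torus forms; the three-twist 5₂ as the closure of the
  braid word σ₁³σ₂σ₁⁻¹σ₂ realized as a polyline) at exactly 3.8 Å chord
  spacing. The closed curve is cut at its outermost point — so the
  straight radial tails leave through empty space instead of piercing
  the knot — and two ground truths are recorded: the non-tail span, and
  a `planted_core` defined geometrically as the median span of vertices
  participating in diagram self-crossings over 30 random projections.
  The second is the honest oracle for core localization: end arcs of a
  loose open knot beyond all crossings are isotopically removable, so a
  trimming-based core is expected to match the crossing span (observed
  within ±3 residues), not the full parametric span.
- **Sieve fixtures** emit time-ordered frames realizing a planted plan
  of (start, end, SS%) bursts; frames within one burst are 0.2 Å
  perturbations of a per-burst base coil so the structural-independence
  stage also recovers the plan.

Synthetic conformers carry backbone heavy atoms only; no side chains
are synthesized (rotamer building is out of proportion to its test
value). Consequently contact maps of synthetic chains run in a
documented backbone-only mode and coordination numbers are lower than
for real side-chain-bearing structures — tests exercised on these
fixtures validate the operators' contracts, not absolute descriptor
scales of real proteins. All generators are pure functions of their
seeds.

## Descriptors

- **Contacts**: residues i, j with |i−j| ≥ 3 are in contact iff any
  heavy-atom pair overlaps after enlarging Tsai/Taylor/Chothia-style
  van der Waals radii (C sp³ 1.88, C sp² 1.76, carbonyl C 1.61, N 1.64,
  O 1.42, S 1.77 Å) by the factor 1.24 — the established companion of
  this radii set in structure-based models. |i−j| = 2 pairs are
  excluded because they are dominated by covalent geometry in Cα
  models.
- **R_g** is the root-mean-square CA distance from the CA centroid.
- **Shape parameter** w = Π(λᵢ − λ̄)/λ̄³ over gyration-tensor
  eigenvalues — the normalized prolateness. Closed forms fix the scale:
  a thin rod has λ = (L²/12, 0, 0) giving w = 2; a thin disk
  λ = (R²/4, R²/4, 0) giving w = −0.25; a sphere gives 0. The sign
  convention (elongated +, flattened −) is the binding contract; the
  normalization is this package's choice.
- **Secondary structure** is a deliberately minimal Kabsch–Sander
  assigner: amide H is placed 1.0 Å from N anti to the preceding
  carbonyl; the electrostatic bond energy uses the classic 0.084·332
  prefactor with the −0.5 kcal/mol cutoff; helices need two consecutive
  4-turns (only H counts as α — no 3₁₀/π subclasses), β is E+B from
  parallel/antiparallel bridge patterns, T marks 3/4/5-turn interiors.
  Percentages are rounded to 0.1% before summing into ss_total.
- **⟨z⟩** counts peptide-bond neighbours (1 for chain ends, 2
  otherwise) plus contacts; **CO** = (Σₖ Sₖ)/(L·N_contacts).
- **Rigidity**: constraint counting N·z/2 ≥ 3N − 6 gives the
  finite-size threshold z* = 6 − 12/N (bulk limit 6). A conformer with
  ⟨z⟩ < z* is volatile; exactly at threshold counts as stiff.

## Independence sieve

SS filtering is strict (> 30%). Time clusters split when the gap
between successive structured frames exceeds 50 ps; the representative
is the highest-SS member, earliest member on ties. Structural
independence is greedy leader clustering in temporal order with a 2 Å
superposed-RMSD criterion — a deterministic extension of comparing
consecutive representatives, since only consecutive comparisons are
otherwise specified. All three thresholds are recorded in the result
and overridable. Accumulation kinetics of independent structures is fit
by ordinary least squares (short trajectories are linear).

## Coarse-grained mechanics

The structure-based Cα model assigns, from a reference conformer and
its contact map:

- harmonic bonds, k_bond = 100 ε/Å², at native lengths;
- per native contact, V(r) = ε[(r₀/r)¹² − 2(r₀/r)⁶] with minimum −ε
  exactly at the native CA–CA distance r₀;
- a harmonic chirality term ½κ(Cᵢ − Cᵢⁿᵃᵗ)², κ = 1 ε, on each
  quadruplet, with Cᵢ = [(vᵢ₋₁×vᵢ)·vᵢ₊₁]/d₀³;
- purely repulsive (WCA-style, shifted and truncated at its minimum)
  pairs for all non-bonded non-contact pairs with
  σᵢⱼ = min(4.0 Å, native distance) — capping σ at the native
  separation keeps the native-state energy exactly −ε·n_contacts.

Reduced units: energy ε, length Å, time τ (≈ 1 ns physically), forces
in ε/Å with 1 ε/Å = 110 pN. Defaults: T = 0.3 ε/k_B, damping γ = 2/τ,
timestep 0.005 τ, pulling speed 5·10⁻³ Å/τ, tether springs 0.12 ε/Å².
Integration is BAOAB Langevin (an exact Ornstein–Uhlenbeck kick between
velocity-Verlet halves), which reduces to symplectic velocity Verlet at
γ = T = 0 — the energy-conservation tests run in that limit (windowed
drift < 10⁻⁴ ε over 10⁵ steps from a 0.02 Å-perturbed start) and
equipartition holds within 10% at the default temperature.

Pulling tethers the first CA to a fixed harmonic anchor and the last to
an anchor moving along the initial end-to-end axis. The spring force
projected on that axis, boxcar-averaged over 1 Å of displacement, is
the force-extension curve. The run stops when the end-to-end distance
reaches 95% of contour length, with an anchor-travel budget that
accounts for the initial end-to-end distance and the compliance of the
two soft tethers. Peaks are local maxima with height **and** prominence
above the 0.1 ε/Å thermal noise level, excluding the terminal monotone
rise; peak heights are absolute forces, not heights above a local
baseline. F_max is the largest peak height and defined as zero when no
peak exists; models without contacts report F_max = 0 without
simulation (they cannot articulate a peak). Contact ruptures record the
displacement of the **last** upward crossing of 1.5× the native
distance; never-broken contacts are flagged unbroken.

## Knots

Open chains are simplified by KMT triangle elimination (a vertex is
removable when no other segment crosses its triangle; exactly colinear
spikes are always removable since their retraction sweeps no area).
Closure extends both termini radially to a sphere of 10× the trace
gyration radius and joins them through a random sphere point; 64
closures vote, ties report "other". Each closed curve is projected
along a random direction (re-drawn until the diagram is generic) and
the Alexander matrix of the diagram is evaluated exactly (fraction-free
elimination) at t = −1 and t = −2. |Δ(−1)| and the odd part of
|Δ(−2)| — the odd part removes the ±2^m unit ambiguity — separate the
types in scope: (1,1) → 0₁, 3 → 3₁, (5,11) → 4₁, (5,31) → 5₁, 7 → 5₂,
anything else → "other". The core is localized by trimming residues
from the N terminus while the voted type is preserved, then from the C
terminus; Δk = k₊ − k₋ + 1. Untying under stretch pulls the model once
per seed and classifies the final frame only (transient mid-pull
untying does not count).

## Life span

t_R is the last sampled time with RMSD (to frame 0, superposed) at or
below 2 Å; a trajectory still inside the threshold at its end is
censored at the run length. P_e(t) is the fraction of all conformers
(censored included in the denominator) with non-censored t_R < t,
evaluated as a step function on the union of event times. The
statistics operators accept any externally produced RMSD series; the
free-dynamics runs shipped here use the coarse-grained model, which
relaxes faster than all-atom dynamics — the qualitative stiff/volatile
ordering is the claim being tested, not absolute times.

## Ensemble statistics

F_max per conformer is the median over n_seeds pulls (default 5; the
analysis drivers and the acceptance script use 1 pull per conformer to
keep the runs desk-sized — problem sizes: 7-conformer ensembles at
n = 16–32, one 16-residue mixed set of 6 in the acceptance script).
Zero-peak and knotted fractions carry bootstrap standard errors (2000
resamples, seeded). The F_max histogram uses 0.2 ε/Å bins on [0, 3];
conformers without peaks are excluded from the bins but included in the
normalization, so zero_peak_fraction plus the positive-bin mass is
exactly 1. Length scans fit χ_F(n) = a·ln(n/b) and F_max^M(n) = c·n^d
by least squares; the independence screen compares the joint CDF of two
descriptors against the product of marginals on the sample grid, and
the OLS screen reports R², slope, its standard error and p-value.

Tract scanning reports maximal runs of identical residues (≥ 5 by
default) with the uniform-composition null probability (1/20)^L for an
L-residue tract at a given position.

## Known limitations

- Backbone-only synthetic conformers underestimate contact counts and
  ⟨z⟩ relative to side-chain-bearing structures.
- The minimal secondary-structure assigner omits 3₁₀/π helices and
  bends; percentages can differ from full DSSP on real structures.
- Knot classification covers prime knots up to five crossings; anything
  else (including composites and slipknots) reports "other".
- Coarse-grained free dynamics compresses time scales; residence times
  are comparable within the model, not across to all-atom runs.
- The braid-closure 5₂ polyline is a topological, not geometric, model
  of a three-twist knot; after chord resampling its local geometry is
  angular rather than smooth.
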