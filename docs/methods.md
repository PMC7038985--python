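# Methods

## Scope and model

`dnastretch` analyses torsionally constrained overstretching of short DNA
duplexes.  It deliberately replaces the molecular-dynamics engine with a
deterministic, seeded geometric generator: the package's claims are about
the *analysis* — interaction detection, aggregation, bubble and motif
statistics, force bookkeeping — not about reproducing nanosecond-scale
forcefield dynamics.  Published per-sequence force magnitudes (tens of pN)
and melting-onset extensions emerge from MD energetics and are outside what
a geometric generator can reproduce; the synthetic runs instead provide
ground-truth-controlled inputs for validating every analysis stage.

## Idealized duplex geometry

Bases are planar heavy-atom templates in the standard base reference frame
(x toward the major groove, z along the helical axis).  Base pair *i*
(1-based) is the standard pair frame rotated by (i−1)·twist₀ about z and
translated to z = (i−1)·rise₀; the complementary base is placed by the 180°
rotation about x.  Defaults are canonical B-DNA values:

| parameter | default | unit | rationale |
|---|---|---|---|
| twist₀ | 36.0 | deg/step | canonical B-DNA, 10 bp/turn |
| rise₀ | 3.3 | Å/step | makes 30 Å over 23 steps ≈ 39.5 % extension |
| Lk₀ | (n_bp−1)·twist₀/360 | turns | summed relaxed step twist; configurable |

Polar hydrogens sit 1.0 Å from their donor nitrogen along idealized sp²
directions (ring N–H on the exterior bisector; amino N–H₂ at ±60° from the
C–N bond).  With this geometry the default detection criteria report
exactly 2 canonical H-bonds per A·T and 3 per G·C pair, and zero
non-canonical bonds, on every undeformed duplex — a structural invariant the
tests assert exactly.

The backbone is a simplified 11-atom sugar-phosphate set per nucleotide at
plausible B-DNA radii (successive-residue P···P ≈ 7 Å).  It provides
realistic atom inventories for stacking sums, PDB output and the terminal
force selection; covalent connectivity between residues is not modelled
because no bonded energy terms are computed anywhere.

Sequence-dependent fine structure (propeller, sugar pucker, groove-width
variation) is out of scope by design.

## Supercoiling

σ = (Lk − Lk₀)/Lk₀; σ < 0 is under-twisted.  `impose_supercoiling` rotates
the terminal base pair by σ·Lk₀·360° about z and distributes the added
twist uniformly over all steps, standing in for torsional relaxation.
Because the rotation per unit σ depends on the Lk₀ convention, Lk₀ is an
explicit, overridable argument.  Calls compose: +σ then −σ restores
coordinates to < 1e−9 Å, and the σ inferred from summed measured step
twists round-trips to < 1e−6.

Step parameters are measured directly from coordinates: twist as the signed
angle about z between successive C1′–C1′ pair axes, rise as axial
centre-to-centre displacement, inclination as the mean angle between base
normals and the axis.  This is a simplified step-parameter measure, not a
full helicoidal analysis (no local-axis refinement); on the idealized
geometry it inverts the generator exactly, which is the property the
pipeline needs.

## Synthetic trajectories

The stretching schedule mirrors the umbrella-window protocol: window *w*
displaces one terminal base pair by w·step (1 Å default) along z; interior
base pairs interpolate linearly in z; both terminal pairs are treated as
rigidly trapped (noise-free, constant within a window).  Window duration
(500 ps), stretch rate (2 Å/ns) and trap constant (500 kcal/mol/Å²) are
carried as metadata only — there is no integrator, thermostat or
equilibration stage.  Thermal motion is i.i.d. Gaussian jitter per atom
coordinate, default 0.15 Å, chosen so ideal WC bonds survive per-frame
detection with probability > 0.99.

Structural events are injected, not emergent:

* **Melting bubbles**: both bases of each affected pair swing in-plane
  about vertical axes through their C1′ atoms, in opposite directions, by
  severity × 60°.  At severity 1 the WC edges separate by ~5 Å and the pair
  reports zero canonical bonds; the response is monotone in severity.
* **Non-canonical H-bond motifs**: the strand-1 base shifts 2.8 Å in-plane
  across the helix, past its partner, into a register where its donors and
  acceptors meet the partner's non-WC atoms.  Canonical bonds are replaced
  by ~1 non-canonical bond per affected pair, for all four study sequences.
* **Non-canonical stacking motifs**: a smaller 1.5 Å in-plane shift that
  keeps WC bonds intact while deepening the inter-strand diagonal
  (cross-stacking) vdW contacts by ~6–7 kcal/mol per pair.

Both motif shifts stay within the base's own pair plane, which is what
keeps the Lennard-Jones sums finite: out-of-plane tilts were evaluated and
rejected because they drive ring atoms into the neighbouring base planes.
Salt is a label; an optional documented hook scales bubble severity per
salt label, but no electrostatics are computed, consistent with treating
ionic strength as a reported condition rather than a modelled force.

Seeding: one master seed; per-run seeds derive from CRC32 of
"sequence|σ|salt" XOR the master seed, kept below 2³¹.  Identical inputs
give bitwise-identical trajectories.

## Interaction analysis

**Hydrogen bonds.**  A bond is reported iff donor-heavy-atom to
acceptor-heavy-atom distance ≤ 3.5 Å *and* donor–H···acceptor angle ≥ 120°,
both boundaries inclusive — the common trajectory-analysis convention.
Canonical bonds are the WC atom pairs (A·T: N6–O4, N1–N3; G·C: O6–N4,
N1–N3, N2–O2) between WC-paired residues; every other base–base bond is
non-canonical, and each bond is assigned to the base pair of its donor
residue.  Only base-moiety donors/acceptors enter detection, so
backbone-only bonds are excluded by construction.

**Stacking.**  Pair energies are 12-6 Lennard-Jones sums over inter-residue
atom pairs with a 5-class parameter table (C, N, O, P, H; geometric-mean ε,
arithmetic Rmin), values representative of standard biomolecular
forcefields and shipped as editable configuration.  Absolute energies are
therefore approximations — they omit electrostatics and implicit-solvent
contributions — so every downstream energy threshold is configurable.  The
canonical channel is intra-strand successive neighbours; self and the WC
partner are excluded from both channels; everything else (including the
inter-strand diagonal) is non-canonical.  The three sets plus {self,
partner} partition all residue pairs exactly, a property the tests assert.
An alternative reading of "non-neighbour" would leave the WC partner in the
non-canonical channel; we exclude it so that pair-internal clashes during
injected deformations cannot contaminate the stacking statistics.

No distance cutoff is applied within a frame (24-bp systems are small); a
cutoff hook exists for larger inputs.  Per-bp stacking values are the sum
over the pair's two nucleotides, each residue-pair energy being credited to
both participants.

## Aggregation, bubbles, motifs

Channels are averaged arithmetically per window per bp.  Two bp per end are
trimmed before analysis (24 bp → rows 3–22), and bubbles are detected on
the trimmed matrix; an untrimmed analysis is available by setting
`n_trim=0`.  A melting bubble is a maximal run of ≥ 2 consecutive bp with
mean canonical bonds strictly < 1.0 (a value of exactly 1.0 does not melt).
The bubble time series sums bubble sizes per window.

Motif classification evaluates named rule schemes per (bp, window) cell,
first match wins, unmatched cells are `background`.  "Loss"/"gain"
quantities are computed against the first window by default.  The shipped
schemes encode the published per-sequence colouring criteria (AA-red:
> 2 non-canonical bonds; AA-blue: < 2 and negative non-canonical stacking;
AT-red/blue; CC-green: canonical loss ≥ 1; CG-yellow: loss ≈ 2 bonds, gain
≈ 1 bond, |Δ non-canonical stacking| ≈ 20 kcal/mol with ±0.5-bond and
±5-kcal/mol tolerance bands), plus the alternative explicit-solvent
figure thresholds (> 1 bond/bp; < −10 kcal/mol) as separate named schemes.
Note that the AT-blue criterion is satisfied by intact B-DNA cells; the
schemes are faithful to their source and are colouring rules, not
structure-discovery tests.

## Force estimation

Per frame, the axial (z) force is averaged over a named backbone-atom set
on the terminal base pairs — default {P, OP1, OP2, O5′, C5′, C4′, C3′, O3′,
O4′}, nine atoms per terminal residue, configurable because the published
protocol does not enumerate them.  F_avg is the pulling-run mean minus the
restraint-free control-run mean; the SEM pools the two runs' per-frame
variances, treating frames as uncorrelated (a block-averaging option exists
for correlated inputs).  The synthetic force fixture loads terminal
backbone atoms with spring_k × extension pN of axial force plus Gaussian
noise, giving a closed-form ground truth: the estimator recovers it within
3·SEM per run, with SEM ∝ 1/√n, and with bias far below the statistical
error over a 100-seed ensemble.

## Numerical choices and problem sizes

* All geometry in float64; LJ energies via a squared-distance matrix
  (scipy `cdist`) and residue-indicator matrix products; agreement with a
  naive double loop to < 1e−10 kcal/mol.
* Measured twist uses atan2 of projected pair axes; degenerate (missing
  template atoms) steps are flagged unmeasurable, never silently skipped.
* Default test/acceptance problem sizes: 24 bp, 30 windows, 5–10 frames per
  window for end-to-end runs, 50 frames for per-window statistics, 10⁴
  random rows for the bubble oracle, 100 seeds for force ensembles, and the
  full 72-run design matrix at 10 frames/window.  These sizes were chosen as
  the smallest at which every statistical assertion is stable across seeds.

## What passing tests do and do not show

The generator emulates the *protocol and bookkeeping* of a stretching study
(window structure, rigid traps, percent extension, design matrix) and the
*signatures* of its structural events (bubbles, motif classes) with exact
ground truth.  It does not emulate forcefield energetics, kinetics,
salt-dependent electrostatics, or P-DNA/S-DNA transitions; passing tests
therefore certify the correctness of the analysis pipeline on controlled
inputs, not the biophysical accuracy of any particular MD study.

## Known limitations

* Idealized geometry only; no minimisation, so injected deformations are
  rigid motions with hand-chosen magnitudes.
* Lennard-Jones absolute values are forcefield-flavoured approximations;
  only energy *differences* within a run are meaningful, and thresholds
  that reference them are configurable.
* The multi-model PDB reader restores window structure from a JSON sidecar;
  foreign trajectories without one are treated as one window per frame.
* Binary MD trajectory formats are an extension point, not implemented.
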