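# Methods

## The question the pipeline answers

A protein–dsDNA complex fixes the conformation of the bound duplex.  If
that conformation is A-like, an RNA/DNA heteroduplex — which is
constrained to near-A geometry by its ribose 2'-hydroxyls — could in
principle be bound the same way, provided the extra O2' atoms fit into
the complex without serious steric conflict.  The pipeline quantifies
both conditions: the conformational one through base-pair step geometry,
and the steric one through explicit hydroxyl grafting and van-der-Waals
overlap scoring.

## Geometry engine

**Base frames.**  Idealized planar base templates (G, A, C, T, U) are
expressed in the standard nucleic-acid reference frame: pair plane z = 0,
+x into the major groove, pair pseudo-dyad along x, C1' anchored at
x = −2.476 Å.  A frame is fitted to an observed base by least-squares
superposition (Kabsch, proper rotations only) over the ring atoms.
Base-pair frames average the two base frames after rotating the
complementary-strand frame by 180° about x.

**Step parameters.**  Shift/slide/rise/tilt/roll/twist follow the CEHS
mid-step convention: the two pair frames are rotated by ± half the
"roll–tilt" hinge angle onto a common z, twist is the remaining in-plane
rotation, and the translation is expressed in the mid-frame.
`compose_step` implements the exact algebraic inverse
(T = Rz(τ/2−φ)·Ry(Γ)·Rz(τ/2+φ)), which is what the synthetic generator
uses; analyze(compose(p)) = p to machine precision is enforced by
property tests.

**Helical parameters and Zp.**  Each step transform is decomposed into
its screw axis; helical twist and rise are the rotation about and advance
along that axis, x-displacement/inclination/tip locate the pair frame
relative to it.  Zp is the mean z coordinate of the two step phosphates
(P of the 3'-side nucleotide on each strand) in the mid-step helical
frame, with each strand's phosphate measured along its own 5'→3' advance.
On the idealized fibers this convention yields Zp ≈ +5.2 Å (A-form) and
−0.38 Å (B-form); the B value matches the classical fiber result, while
the A value is larger than the mid-step-frame variant some programs
report.  Classification thresholds (defaults, configurable): A-like if
Zp ≥ 1.5 Å, B-like if Zp ≤ 0.5 Å, otherwise intermediate.  Both ideal
forms classify correctly for all ten dinucleotide step types with wide
margins.

**Sugar puckers.**  Altona–Sundaralingam pseudorotation from the five
endocyclic torsions; conformers are named by 36° wedge (C3'-endo for
P ∈ [0°, 36°), C2'-endo for P ∈ [144°, 180°), ...).  Near-planar rings
(amplitude < ~0.001°) are reported as undefined rather than assigned.

## Operational definitions fixed by calibration

Two quantities in the analysis have no unique textbook definition; both
are implemented as explicit operational definitions whose free choices
were fixed **once**, by calibrating against idealized fiber duplexes, and
are persisted in every report.

**Base-pair displacement from the helix axis** (`c1c1_midpoint`): the
perpendicular distance from the global helix axis (mean of the per-step
screw axes) to the C1'–C1' midpoint of each pair, averaged over interior
pairs.  Candidate landmarks considered: pair-frame origin, glycosidic-N
midpoint, C1'–C1' midpoint, and |helical x-displacement|.  The C1'
midpoint minimizes total deviation from the reference values 6.9 Å
(ideal A) and 1.9 Å (ideal B): the A-form build gives 6.87 Å; the B-form
build gives 2.27 Å, a known residual of ~0.4 Å that no candidate landmark
removes without moving the generator's B-form x-displacement away from
the fiber-survey value (+0.2 Å).

**Groove depths** (`cross_rim_v1`): the reference depth values
(minor 18.5/11.7 Å, major 15.2/17.2 Å for ideal A/B) are
across-the-helix quantities, larger than any local rim-to-floor
construction, so the definition measures across the duplex:

* minor depth at level i = the largest distance from the major-side rim
  line (P_I(i) to the closest cross-strand P on the major-groove side) to
  any minor-groove-edge base atom within ±3 levels;
* major depth at level i = the largest distance from the midpoint of the
  fixed-offset minor rim pair (P_I(i), P_II(i−2), El Hassan–Calladine
  style indexing) to any phosphorus within ±1 levels.

Both are evaluated from each strand's perspective and averaged, making
palindromic profiles exactly symmetric; levels where the construction
does not fit are flagged undefined and excluded from summaries.
Calibration on the generated fibers gives minor 16.1 (A) / 11.8 (B) and
major 15.1 (A) / 17.2 (B): three of the four references are reproduced
within 0.3 Å, while the A-form minor depth falls ~2.4 Å short of the
18.5 Å reference — no rule in the searched family (rim choice × floor
atom set × window, spans and point/line variants) reaches that value on
true fiber geometry, so the total-deviation minimizer was frozen and the
residual is reported rather than absorbed.  Groove widths are
conventional: closest cross-strand P–P distance on each side minus 5.8 Å.

## Synthetic structures

The generator emulates idealized fiber duplexes, not crystal structures.
Per-form sugar-phosphate backbone templates were derived by restrained
least squares under each form's helical symmetry operation (a small
linked-atom fiber refinement): standard bond lengths/angles, ring pucker
restrained to C3'-endo (P = 18°, A) or C2'-endo (P = 155°, B), canonical
backbone-torsion priors, glycosidic χ = −157° (A) / −98° (B), and exact
O3'(i)–P(i+1) connectivity.  The B-form solve is additionally anchored to
the classical fiber phosphorus position (r 8.91 Å, φ 95.2°, z −2.08 Å) to
resolve directions the restraints leave flat; both solves reproduce the
classic direct groove widths of their forms.  Helical defaults: A-form
twist 32.7°, rise 2.548 Å, x-displacement −4.4 Å, inclination +19°;
B-form twist 36.0°, rise 3.375 Å, x-displacement +0.2 Å, inclination −6°.

Three things real data have that the generator does not: sequence-
dependent conformational variation, thermal/crystallographic noise, and a
protein environment (probes stand in for the latter as single atoms).
Passing the synthetic tests therefore demonstrates correctness of the
geometry, grafting and scoring machinery — not robustness to disordered
or distorted experimental coordinates, which is exercised only when real
structures are analyzed.

Probe atoms are placed on the outward C2'→O2' ray at distance
r_O2' + r_probe − intended_clash from the would-be O2' position, so the
protein-partner clash of a graft is known exactly by construction; they
are emitted as a separate pseudo-protein chain so the protein/nucleic
split is exercised.  Placement refuses configurations that would corrupt
the oracle (a previous probe already clashing with the O2' site, or a
probe buried inside an existing atom).  Probe oracles require A-form
geometry: in B-form the O2' ray runs into the 3'-neighbouring nucleotide
— which is precisely the steric reason B-form RNA does not exist.

## Grafting and clash scoring

O2' placement completes the tetrahedron at C2' given C1' and C3'
(bond 1.413 Å, angles ≈ 110.7°), with the face chosen by the D-ribose
signed volume; an independent chirality witness at C3' rejects
mirror-imaged sugars.  No existing atom moves, so puckers are unchanged
identically.  The hydroxyl hydrogen is not placed: its rotameric freedom
is unconstrained and only the heavy atom is scored.  Grafts are evaluated
one at a time — each graft is scored against the ungrafted model — so no
artificial O2'–O2' cross-strand conflicts arise.

Scoring excludes atoms within two covalent bonds of O2' in its own
nucleotide, all hydrogens, waters and monoatomic ions (bonded geometry is
not a steric conflict; solvent and ions are displaceable).  "Cumulative"
sums overlaps per partner atom.  The neighbour-search cutoff
(2·r_max + expected clash, 4.8 Å default) affects speed only; exact
equivalence with an all-pairs scan is asserted by tests on randomized
5000-atom models, with sorted accumulation so sums are independent of
search order.

## Statistics and prediction

Enzyme-level score: maximum per-graft clash over recognition-site
nucleotides, both strands, before strand averaging; the
`exclude_outermost` variant drops the first and last site pair first
(separating flank-driven conflicts from core ones).  Ensembles are
standardized with the sample (n−1) standard deviation — conservative for
the small ensembles typical here — and converted to lower-tail and
two-sided normal probabilities; empirical ranks r/(n+1) are reported
alongside because "one-sided test" is equally readable as a rank
statistic.  The cleavage-competence rule is the conjunction of A-like
site binding (fraction of A-classified site steps ≥ 0.5) and
accommodable hydroxyls (site score ≤ 1.1 Å); both knobs are exposed, and
false positives of the rule are reported, never suppressed.

## Surface metrics

SASA is Shrake–Rupley sampling with a deterministic golden-spiral point
set (default 960 points/atom, probe 1.4 Å); buried interface area is
SASA(A) + SASA(B) − SASA(AB) over non-hydrogen, non-water atoms, with the
total over both partners as the headline number.  Because the point set
is fixed in the laboratory frame, SASA is rotation-invariant only to
sampling resolution (~0.1% at 960 points); doubling the point count
changes results by < 0.5%.

## Problem sizes and determinism

All synthetic analyses run on 8–22-mer duplexes (a few hundred atoms);
the full test suite and the acceptance script each complete in about a
minute on one CPU.  Every code path is deterministic: the generator is a
pure function of its inputs, the sphere point set contains no randomness,
and randomized tests use fixed seeds.

## Known limitations

* Conformer handling keeps the highest-occupancy alternate location per
  atom at parse time; analyses of multi-conformer crystal structures that
  require conformer averaging must parse the conformers separately and
  average downstream.
* The step-parameter sign conventions match the generator's own
  composition algebra; absolute agreement with other analysis programs
  was only verified for the quantities listed above (helical parameters,
  Zp of the B fiber, classic groove widths).
* The groove-depth and displacement definitions are operational
  calibrations with documented residuals, not community standards; the
  `definition_id` travels with every report so downstream comparisons
  stay within one convention.
* The cleavage prediction is a structural necessary-condition test;
  enzymes can fail to cleave RNA/DNA for non-steric reasons.
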