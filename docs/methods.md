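# Methods

This note documents the model, its calibration, the numerical choices, and
the limits of what the shipped tests demonstrate.

## Model structure

### Receptor layer (exact kinetic scheme)

The receptor module is a 19-species, 37-reaction mass-action ODE system in
nM and hours.  The BCR arm binds extracellular ANTIGEN to surface BCR
(synthesis 4.93 nM/h, turnover 1.43/h), and the engaged receptor ABCR
activates the CBM adapter complex; the CD40 arm forms CD40L·CD40R
complexes that switch TRAF6 on and deplete TRAF3.  Both arms converge on a
TAK1 activation cycle driving the IKK cycle
(IKK_off → IKK2 → IKK3 → IIKK → IKK_off), and TRAF3 loss releases NIK,
whose degradation is gated by a Hill term
`φ37·NIK·TRAF3²/(TRAF3² + 0.5²)`.  Ligand-facing bimolecular terms carry
the medium-to-cell volume factor `c_c2m = 0.01`.  All rate constants are
the tabulated standard set, exposed in
`src/bcellfate/data/receptor_rates.csv`; the test-suite checks the
right-hand side against a brute-force stoichiometric re-assembly of that
table to 1e-12.

Two readings of the printed scheme required a decision, both recorded in
code comments: TRAF3 synthesis is implemented as zeroth-order (10 nM/h) —
the alternative first-order reading diverges — and the IKK-activating
catalyst of the cycle is the *active* TAK1 species, without which
stimulation could not raise IKK2 above its basal level.

Pool sizes of the closed cycles (CBM, TAK1, TRAF6, IKK) are not
identifiable from the calibration data and are configuration: CBM, TAK1
and IKK pools default to 1 (fraction convention), while the TRAF6 pool
defaults to 100 nM because the CD40→TRAF6→TAK1 flux must exceed the basal
TAK1 activation rate (249/h) for CD40 to signal at all; with a unit pool
it contributes <4%.

### NF-κB module (reduced surrogate)

The published multi-dimer NF-κB network is intentionally out of scope; a
9-state surrogate stands in behind the same interface.  Canonical kinase
activity (IKK2+IKK3, expressed as fold over the resting reference
3.57e-5 nM) gates nuclear import of RelA:p50 and cRel:p50 through steep
Hill functions (h ≈ 5–6, half-activation near twofold-over-basal), IκBα is
NF-κB-inducible and IKK-degradable (adaptation), the IκBδ brake assembles
from p100 and is released by NIK, NIK processes p100 to p52 (read out as
nuclear cRel:p52, slow and non-saturating in dose), and total cRel is
boosted by autoinduction.  All downstream couplings consume *fold-changes*
over each cell's own resting state, so absolute receptor-layer scales
cancel.

The free gains and gate constants were fitted (bounded least squares in
log space; `calibrate_surrogate`) so that population means over
heterogeneous cells reproduce the fold-change anchors — nuclear RelA 10×
(30 nM CD40L) and 5× (6 nM), nuclear cRel 13× and 4×, all at 7 h — while
preserving the qualitative dose structure: canonical peaks saturate
between 12 and 30 nM (RelA:p50 within ~5%, cRel:p50 within ~16%), nuclear
cRel:p52 keeps rising, cRel declines more steeply than RelA from 7 h to
24 h, and BCR costimulation synergizes strongly only on the sub-saturating
low CD40 dose.

### Fate modules (reduced surrogates)

**Apoptosis.**  Pre-caspase-8 (resting pool 19 000 nM) undergoes slow
basal processing that switches on at culture onset — a minimal stand-in
for survival-factor withdrawal, giving unstimulated cultures their
intrinsic decline — plus the engagement-driven term
`φ_C8,AICD·[PC8]·[ABCR]` with `φ_C8,AICD = 2.1e-4 nM⁻¹h⁻¹` applied
verbatim (moved from PC8 to C8, conserving their sum).  Caspase-8
activates Bax with a softly saturating flux (half-saturation 15.5 nM C8;
a finite effector pool keeps an engagement burst from outrunning
protection indefinitely); NF-κB induces Bcl-xL through a weighted nuclear
drive (weights 0.3 RelA : 0.45 cRel:p50 group : 2.8 cRel:p52, normalized
so the resting drive is 1 — the slow non-canonical arm is what
distinguishes sustained CD40 help from a transient BCR pulse); Bcl-xL
neutralizes activated Bax one-to-one.  MOMP latches when activated Bax
exceeds 4 nM; cleaved PARP then accumulates and its crossing of 1 nM marks
death.  The thresholds and gains are release-calibration constants fixed
against three observations: the ~30-percentage-point reduction of 24 h
survival by AICD under high costimulation, the monotone CD40 and
non-monotone BCR survival dose-responses, and the sequential-stimulation
window (below).

**Cell cycle.**  A cMyc-like commitment integrator accumulates under
saturating NF-κB drive and latches (autocatalytic gate); committed cells
inactivate Rb at a rate graded by the sustained drive; below the Rb
restriction threshold, cyclin B accumulates and flips Cdh1 off — each
downward crossing of Cdh1 through 0.2 is a division.  Division requires a
minimum cell mass (0.8 of the founder mass); mass grows with the drive and
halves at division, so lineages stop dividing when their integrated
mitogenic signal is spent ("division destiny").  The CD40 tuning operation
multiplies Rb decay by 0.1 and CycB synthesis by 1.8, exactly; with it the
release reproduces mean first-division times of ~63 h (30 nM) and ~73 h
(6 nM), later inter-division intervals of ~6 h, and divider fractions of
~46% / ~32% (30 / 12 nM), versus ~45 h / ~8.5 h / ~77% untuned.

### Population layer

Each virtual cell samples its synthesis, degradation, association and
dissociation rates from truncated normals with CV 11.2% around the
standard set (catalytic rates shared), equilibrates ligand-free (capped at
800 h), then runs the stimulated time course.  Signaling and the apoptosis
branch form one 33-state ODE per cell; the cell-cycle branch is driven by
the stored NF-κB readouts and does not feed back, and daughters inherit
parameters and signaling state unchanged with only cyclin B, Cdh1 and mass
reset.  A lineage therefore shares one signaling trajectory and one death
time, and is simulated as a single division chain with multiplicity 2^g —
an exact consequence of the inheritance rules, not an approximation.
Generation counts above 6 are binned as "6+" for comparison with
dye-dilution data.

## Stimulation protocols and dose mapping

Ligands are piecewise constant: doses are added to the free-ligand species
at onsets and washed (set to zero) at offsets; free antibody decays at
0.05/h throughout.  Experimental antibody doses map to model ligand
concentrations through the fixed table anti-CD40
{0→0, 1→6, 3.3→12, 10→30 nM} and anti-BCR {0→0, 1→0.005, 10→0.25 nM}
(linear interpolation otherwise, with a warning).  The sequential scenario
is a 1 h washed antigen pulse followed by an open-ended CD40L step after a
1–8 h gap.

## Evaluation metrics

`rmsd_generation` is the root-sum-square of generation-composition
fraction differences over the five post-onset timepoints and generations
0–6+ (no division by the number of terms).  `rmsd_population` sums two
root terms over expansion-ratio deviations — one normalized to the 0 h
population over five timepoints, one to the 24 h population over four —
each divided inside the root by (number of timepoints × the maximum
experimental expansion ratio).  The ratio reading of that maximum is the
default because a raw-count maximum would collapse the score toward zero
for experiment-sized populations, incompatible with the 0.3–1.6 range the
metric is meant to resolve; the count reading remains available
(`max_mode="count"`).  Both metrics are scale-free in the table counts,
and "total RMSD" is their sum.

## Synthetic data generator

The Cyton-style generator emulates the *shape* of dye-dilution data:
founders divide with probability F0, first divisions at
N+(Tdiv0, sd) and later ones at N+(Tdiv1+, sd) intervals, every cell
racing an exponential death hazard.  Presets carry the measured per-dose
Tdiv0/Tdiv1+/F0 values; dispersions (Tdiv0 sd 10 h, Tdiv1+ sd 1–6 h) and
hazards (0.005–0.02/h) are generator choices giving realistic count
scales.  What it does *not* emulate: dye-intensity noise and
generation-misassignment, correlated fates within families, time-varying
hazards, and mechanical early cell loss — so tests that pass against
synthetic tables demonstrate correctness of the evaluation machinery, not
fidelity to any real measurement.

## Numerical choices

* Integrator: LSODA (Adams/BDF switching) with the stated defaults
  atol 1e-5, rtol 1e-3.  The kinase cycles relax at up to 2.6e5/h, which
  makes the system stiff; an explicit 4/5-order pair cannot step a 96 h
  horizon.  Halving the tolerances moves the 96 h endpoint by ≲5e-3
  relative (slowest species).
* Integration is split at protocol events and once at MOMP, so the latch
  and post-MOMP cParp accumulation are exact; threshold crossings
  (division, death) are located by the solvers' event machinery and linear
  interpolation.
* Steady states are found by ligand-free integration in chunks with a
  relative-derivative criterion (1e-7/h), capped at 800 h with a
  non-convergence warning rather than an error.
* Per-cell pre-equilibration starts from the base-parameter steady state,
  which cuts the equilibration cost several-fold.
* The LOESS surface is a hand-rolled 2-D tricube-weighted local linear
  regression on log10(dose + ε) axes (ε = half the smallest nonzero dose;
  span 0.75 of the design points), since no installed package provides
  two-dimensional LOESS.
* Kaplan–Meier estimation uses lifelines; simulated non-deaths are
  censored at the horizon.

## Problem sizes

Shipped defaults keep everything desk-scale: the acceptance script uses
120 cells per condition for the fold-change anchors, 300 founders per dose
for division timing, and 200-founder pairs for the AICD effect; the
test-suite uses 40–200 founders per condition with fixed seeds, sized so
Monte-Carlo error is small against each stated tolerance.  All entry
points accept larger counts.

## Known limitations

* The NF-κB, apoptosis and cell-cycle layers are reduced surrogates
  calibrated to the fold-change and timing observations above; their
  internal species are not quantitative predictions.
* Daughters inherit the full signaling and apoptosis state, so lineage
  fates are perfectly correlated (a lineage dies as a unit).  Real sibling
  fates decorrelate; generation-resolved counts are the intended readout.
* Absolute population expansion depends on the division-destiny
  calibration and is reproduced at the ~2–3-fold scale for CD40-only
  stimulation, but the model is calibrated to timing and fraction
  statistics, not to absolute cell yields.
* The cRel:p50 peak saturation between the medium and high CD40 dose lands
  at ~16% rather than below 10%; nuclear RelA:p50 saturates within ~5%.
* In the reduced cell-cycle, commitment and oscillator parameters carry
  much of the first-division-time sensitivity, so the scan ranks Rb decay
  among the influential Tdiv0 knobs rather than strictly first; the
  directional effects motivating the CD40 tuning (slower Rb decay → later
  first division, faster CycB synthesis → shorter cycles) hold and are
  tested.
* Unstimulated-culture death is modeled as a basal caspase-8 processing
  switch at culture onset; it is a phenomenological stand-in for
  survival-factor withdrawal, not a mechanism.
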