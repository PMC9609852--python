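# Methods

`dcmkit` analyses dissolution experiments run in a segmented-lumen in vitro
model of the human proximal colon: ten hydraulically actuated segments
(2.8 cm, 8.9 mL each) plus an 11 mL hepatic-flexure compartment, holding
100 mL of viscous medium with an extended-release tablet inserted at the
caecal end (segment 1).  This note records the models implemented, the
parameter choices that matter, and the limits of what the synthetic-data
tests can show.

## Actuator calibration

Wall motion is commanded through syringes; wall parameters relate linearly to
actuator commands over the calibrated ranges (SD 0–28 mm, SS 0–50 mm/s):

| transform | form | coefficients |
|---|---|---|
| membrane displacement | MD = a·SD + b | a = 0.3425, b = 0.7246 mm |
| occlusion degree | OD = a·SD + b | a = 5.797 %/mm, b = −44.03 % |
| occlusion velocity | OV = a·SS + b | a = 0.3172, b = 0.9221 mm/s |

Occlusion degree is defined from luminal cross-sectional areas at the haustral
apex, OD = 100·(1 − A_x/A_N).  Inversions are exact; out-of-range commands
warn rather than raise because the library is not hardware-bound.  Note one
documented inconsistency: inverting the OV calibration at 36 mm/s gives a
syringe speed of 110.60 mm/s, while the source protocol quotes 109.63 mm/s
(consistent with a rounded slope); `invert_calibration` always uses the exact
inverse.

## Motility patterns and indices

A pattern is a schedule of contraction events over a 120 s cycle.  Each
event's contraction phase lasts (membrane displacement)/(occlusion velocity);
walls relax 0.26× slower than they contract for propagating/stimulated events
and 0.91× for baseline isolated contractions.  Propagating waves are encoded
from their published per-wave parameters; the inter-segment stagger is
derived from the published wave velocity via
time = distance/velocity = (n−1)·stagger + last contraction duration.

Event start times within the cycle are not published as numbers.  The packaged
schedules were reconstructed to be consistent with (a) the published
narrative of each pattern (baseline: a propagating wave S2→S4 plus isolated
contractions at S3, S6, S5, S8 in that order; the PEG pattern's waves avoid
S2 while its isolated contractions sit there; the maltose pattern's waves
involve S2), (b) the published wave sizes and velocities, and (c) the
published motility-index values.

Indices over one cycle split into K = 6 sub-intervals of t_iv = 20 s:

- MI = Σ_k t_iv·N_seg,k, where N_seg,k counts events whose contraction phase
  overlaps sub-interval k with positive measure; a contraction spanning a
  boundary counts in both intervals (this is what lets the slow baseline
  events reach MI = 180).
- MI_DCM = (1/(ω·L))·Σ_k (v·N_seg)_k with v the occlusion velocity in mm/s.
  The normalisation defaults are ω = 12 s⁻¹ and L = 280 mm (the tube length),
  i.e. ω·L = 3360 mm/s — the pair under which the published stimulated-pattern
  values are recovered (PEG 0.0850, maltose 0.0734, printed 0.085/0.073).
  Both constants are exposed in `MotilityIndexConfig`.

**Known discrepancy.**  Under this single counting convention the package
computes MI_DCM = 0.0042 for baseline and 0.0321 for the full-tube waves,
whereas the published table prints 0.0033 and 0.016.  No convention we found
reproduces all four published values simultaneously, so the stimulated pair
(which the normalisation is anchored to) is reproduced and the discrepancy is
reported rather than force-fitted.  The published ordering
static < baseline < CPPW < maltose < PEG is preserved.

## Release reconstruction

At each scheduled time t (0.25, 0.5, 1, 2, 3, 4, 6, 8, 10, 12, 16, 24 h),
V_r = 1 mL is withdrawn from ports at segments 1, 3, 5, 7 and 10 and replaced
with blank medium.  With measured port concentrations C_S(t):

1. withdrawn mass m_S(t) = V_r·C_S(t), summed over the five ports and
   accumulated over timepoints ≤ T gives m_removed(T);
2. unsampled segments (2, 4, 6, 8, 9) take piecewise-linear interpolation of
   concentration against segment-centre position; the flexure takes the most
   distal measured value (linear extrapolation could go negative);
3. resident mass m_L(t) = Σ_S V_S·C_S(t) + V_HF·C_HF(t) over post-sampling
   volumes — by default the exact proportional redistribution of the
   remaining 95 mL (V_S = 8.455 mL, V_HF = 10.45 mL), since the commonly
   quoted rounded V_S = 8.5 mL breaks the volume balance
   (10·8.5 + 10.45 = 95.45 mL);
4. cumulative release M_t = m_L(t) + m_removed(t), reported as % of the
   200 mg dose.

Replicates are reconstructed independently and aggregated as mean ± sd on the
released fraction; raw concentrations are never pooled.  M_t is not forced
monotone — decreases under noise are counted and reported — and fractions
above 110% raise a mass-balance warning.  The interpolation scheme is a
documented choice (the source protocol does not state one); it is exact for
constant and linear fields and overestimates convex decaying profiles, which
is why a sharply localised (static) lumen reconstructs a few percent high.

## Similarity and kinetics

- f1 = 100·Σ|R_t − T_t|/ΣR_t (asymmetric; reference in the denominator).
- f2 = 50·log₁₀(100/√(1 + Σ(ΔQ)²/n)), base-10 log (the standard regulatory
  formulation).  The 15 < Q < 85% validity window is applied to f2 only, with
  strict inequalities decided on the first (reference) profile; `similarity`
  reports how many points survived.  Anchors: identical profiles give exactly
  f1 = 0 and f2 = 100; a uniform 10-point gap gives 49.89.
- Release kinetics: fraction(%) = K·t^m fitted by unweighted nonlinear least
  squares (t = 0 excluded; the schedule starts at 0.25 h).  Start values are
  K from the first usable point at m = 0.8; the basin is flat enough that any
  start in [0.1, 100] × [0.1, 2] recovers exact data to 1e−6.  95% CIs come
  from the parameter covariance with Student-t quantiles (n − 2 dof);
  RMSE = √(SSE/(n−2)); R² is adjusted.

## Synthetic lumen simulator

The generator produces datasets with the structure the reconstruction
assumes, plus ground truth.  It is a discrete-event/ODE hybrid over 11
compartments (10 segments + flexure):

- **Source.** The tablet (fixed in segment 1, matching the observed static/
  baseline tablet position) releases at the derivative of a power-law curve,
  default (K, m) = (5.85 %/h^m, 0.90) — the steepest fitted study profile,
  i.e. near-complete release in 24 h when transport does not limit it.
  Release throttles linearly to zero over the top 10% below the 5.5 mg/mL
  aqueous solubility of theophylline, emulating solubility-limited plateaus.
- **Background mixing.** Nearest-neighbour diffusive exchange at
  `exchange_base` = 0.2 mL/h, advanced exactly between events via cached
  matrix exponentials of the graph-Laplacian generator (stable at any rate,
  including the well-mixed limit used in tests).
- **Event-driven mixing.** Each contraction instantaneously swaps
  `exchange_per_event`·(OD/100)·(OV/12.98) mL (default 0.5 mL at full
  strength) with its neighbours — the same OD·OV quantity MI_DCM aggregates.
  For wave members, 60% of the swap (`retrograde_bias`) goes against the
  propagation direction, mirroring the observed dominance of backflow.
- **Sampling operator.** At each schedule time the five ports lose 1 mL of
  fluid at their current concentration (recorded as truth) and are
  replenished with blank medium; measurements multiply the true concentration
  by mean-one lognormal noise, cv defaulting to 0.07 (the order of the
  published replicate error bars, e.g. 0.21/3.07).

Mass conservation (tablet + dissolved + removed = dose) holds to < 1e−9·dose
by construction.  Runs are deterministic given the config; the seed only
drives measurement noise, which does not feed back into the dynamics, so
replicate datasets are generated by redrawing noise from one truth trajectory
with per-replicate seed offsets.

The motility→mixing coupling constants are fictional calibration knobs: they
reproduce the qualitative, monotone ordering of distal transport with MI_DCM
(static < baseline < CPPW < maltose < PEG at segment 10 after 24 h), not any
measured flow field.  The simulator has no fluid dynamics, no shear-stress
fields, no tablet migration, and its release law is imposed rather than
emergent — so passing tests demonstrate that the *analysis pipeline* is
correct and unbiased under the stated assumptions, not that the simulator
predicts real dissolution data.

## Numerical choices and problem sizes

- Integration substeps are capped at 5 s so the saturation throttle tracks
  the local concentration; the release source is applied before the mixing
  propagator within a substep so freshly released drug is mixed before any
  sampling at the boundary.
- Ties: events scheduled exactly at a sampling time execute before the
  sampling; contraction phases touching an interval boundary at a single
  point do not double-count.
- Event swaps are capped at 45% of either compartment volume to keep masses
  positive.
- A 24 h, 720-cycle simulation of the densest pattern integrates ~17k
  event-bounded steps and runs in well under a second, so the test suite
  simulates every pattern outright and the 100-replicate noise studies reuse
  the deterministic truth trajectory.

## Limitations

- The MI_DCM normalisation constants are anchored to the stimulated patterns;
  the published baseline/CPPW index values are not reproduced (see above).
- Interpolation bias makes reconstructed release overshoot by a few percent
  when the true axial profile is strongly convex (static/baseline lumens);
  the bias is reported, and alternative interpolants can be plugged in at
  `interpolate_lumen_profile`.
- The simulator's coupling constants are not estimates; only orderings and
  conservation properties, not absolute release magnitudes, should be read
  from it.
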