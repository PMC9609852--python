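# dcmkit

Analysis toolkit for dissolution experiments in segmented-lumen in vitro
models of the human proximal colon — the kind of rig that replicates colonic
peristalsis with a chain of hydraulically actuated haustral segments.  It is
aimed at biopharmaceutics researchers who need to go from sparse segmental
concentration measurements to defensible cumulative-release profiles, and to
quantify how colonic motility shapes drug release from extended-release
matrices.

The package covers four things:

1. **Motility encoding and indices.**  Colonic motor patterns (isolated
   contractions and antegrade/retrograde propagating waves) are encoded as
   per-segment contraction events over a 120 s cycle, with linear
   calibrations between wall parameters and actuator commands
   (MD = 0.3425·SD + 0.7246; OD = 5.797·SD − 44.03; OV = 0.3172·SS + 0.9221).
   Contractile intensity is scored by the motility index
   MI = Σₖ t_iv·N_seg,k and its dimensionless, velocity-weighted variant
   MI_DCM = (1/ωL)·Σₖ (v·N_seg)ₖ.  Six study patterns ship ready-built:
   `static`, `baseline`, `cppw_antegrade`, `cppw_retrograde`, `peg`,
   `maltose`.
2. **Mass-balance release reconstruction.**  A 100 mL lumen (ten 8.9 mL
   segments + 11 mL hepatic flexure) is sampled with 1 mL withdrawals at five
   ports, replenished with blank medium.  Cumulative release is
   M_t = m_L(t) + m_removed(t): resident mass from axially interpolated
   segment concentrations over post-sampling volumes, plus the running total
   of withdrawn mass.
3. **Profile statistics.**  Regulatory similarity factors f1/f2 (with the
   15–85% validity window) and Korsmeyer–Peppas power-law fits
   (fraction = K·tᵐ) with 95% confidence intervals.
4. **A synthetic lumen simulator** that generates segmental datasets with
   ground truth — power-law tablet source with solubility throttling,
   motility-driven inter-compartment mixing, the five-port sampling operator
   and lognormal measurement noise — used to validate the reconstruction.

## Worked example

Score the packaged motility patterns (`python examples/motility_indices.py`):

```
pattern           MI [seg*s]    MI_DCM
static                     0    0.0000
baseline                 180    0.0042
cppw_antegrade           200    0.0321
cppw_retrograde          200    0.0321
peg                      440    0.0850
maltose                  380    0.0734

antegrade full-tube wave: 10 segments, 28.0 cm in 7.53 s -> 3.72 cm/s
```

MI counts contracting-segment seconds per cycle; MI_DCM additionally weights
each contraction by its wall velocity, so the stimulated patterns (many fast,
deep contractions) score an order of magnitude above baseline.

Simulate a maltose-stimulated run and reconstruct release from the sampled
concentrations (`python examples/reconstruct_release.py`, abridged):

```
 t [h]   true %  recon %     m_L  m_removed
  0.25     1.68     2.38     4.4       0.35
  4.00    20.37    21.44    34.9       7.98
 12.00    54.75    56.30    86.9      25.67
 24.00   100.00   104.04   165.8      42.32

Without the m_removed correction the 24 h release would read 82.9%
instead of 104.0%.
```

The sampling correction matters: eleven replenished 5 mL withdrawals turn
over 55% of the medium, and ignoring the withdrawn drug would bias the 24 h
release down by ~21 percentage points here.  The small overshoot above truth
is the (reported) axial-interpolation bias plus measurement noise.

Fit kinetics and compare profiles (`python examples/fit_and_compare.py`):

```
maltose    K =  6.41 (6.06, 6.77)  m = 0.88 (0.86, 0.90)  adj R^2 = 0.9994

baseline vs maltose: f1 = 21.7%  f2 = 42.5 (n = 9 timepoints in the 15-85% window)
-> the profiles are different: stimulated motility releases markedly more drug
```

A thin CLI mirrors the library: `dcmkit mi peg`, `dcmkit simulate`,
`dcmkit reconstruct`, `dcmkit fit`, `dcmkit compare`, `dcmkit run`,
`dcmkit export-pattern`.

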