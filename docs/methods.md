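# Methods

## Scope and model assumptions

`mrseqopt` predicts relative steady-state signals for four pulse sequences
— fast spin echo (FSE), fluid-attenuated inversion recovery (FLAIR),
spoiled gradient echo (GRE) and 3D MP-RAGE — and drives a CNR-maximizing
grid search over their scanning parameters.  The signal model is the
standard closed-form steady-state description under ideal conditions:

- every RF pulse delivers exactly its nominal flip angle, instantaneously
  and uniformly across the slice;
- all transverse magnetization decays or is spoiled before the next TR;
- stimulated echoes, B1 and B0 inhomogeneity, slice-profile and
  off-resonance effects are ignored;
- acquisition is Cartesian without undersampling.

These are deliberate simplifications: the whole point of the validation
workflow is to find out *which* parameters survive them.  Susceptibility-
and chemical-shift-driven effects are exactly where an in-vivo experiment
overrides the simulation (the `overrides` mechanism in
`stepwise_optimize`), so disagreement with a scanner measurement on, say,
an echo-spacing or GRE flip-angle optimum is expected behavior, not a bug.

## Signal conventions

Signals are **signed** (in units of M0).  Inversion-recovery sequences
produce negative longitudinal magnetization below the null point; keeping
the sign makes CNR maximization well defined on a single orientation
(bright tissue minus dark tissue).  A **magnitude** mode (`abs` of the
signal) is available for image rendering and for sweeps meant to emulate
magnitude-reconstruction measurements.

FSE/FLAIR use a first-order longitudinal model: recovery happens over
`TD = TR − ETL·ESP`, and transverse decay is applied at the effective echo
time of the center echo, `TE_eff = ESP·ceil((ETL+1)/2)` (linear phase-
encode ordering; the center echo fills the k-space center).  This
convention reproduces the printed 59.2 ms effective TE of the 15-echo
T2-weighted protocol; the single printed 14.6 ms FLAIR entry differs from
the convention's 14.8 ms and is treated as a vendor rounding.

### MP-RAGE steady state

The MP-RAGE cycle is: 180° inversion — recovery TI — N readout pulses of
angle θ, each followed by one echo-spacing recovery — delay TD — next
inversion, with the timing identity `TR = TI + N·ESP + TD` enforced to
1e−6 ms.  Propagating Mz through one cycle and solving the fixed point
gives (δ = e^(−ESP/T1), μ = δcosθ, γ = e^(−TI/T1), φ = e^(−TD/T1)):

    Meq/M0 = [1 − φ + φ(1−δ)(1−μ^N)/(1−μ) + φμ^N(1−γ)] / (1 + γφμ^N)
    M_n/M0 = (1−δ)(1−μ^{n−1})/(1−μ) + μ^{n−1}[(1−γ) − γ·Meq/M0]

Published forms of this steady state vary in whether the last readout is
followed by an echo-spacing recovery before TD; we use the self-consistent
convention above (recovery after every readout, which makes the
denominator equal `1 + e^(−TR/T1)·cos^N θ` under the timing identity) and
validate it against an explicit cycle simulation to 1e−6 over random
parameter grids.  The reported readout defaults to the center of the train
(`n = ceil(N/2)`); TD defaults to 0.  The quoted TE enters only the T2*
factor and may exceed the derived ESP — vendor protocols quote the two
independently, and the study's printed MP-RAGE timing (TR 1983 ms,
TI 1700 ms, N 128, TE 2.3 ms) implies exactly that.  For TI sweeps the
timing follows a scanner-style minimum-TR rule: ESP stays at
(1983 − 1700)/128 ms and TR is derived per grid point.

## Acquisition model

    SNR ∝ FOVx · FOVy · Δz · S · [NSA/(BW·N_FE·N_PE)]^p,   CNR = SNR₁ − SNR₂

The exponent `p` defaults to 1, with `p = 0.5` (the physical
root-bandwidth reading) available via `SnrConfig` or `--nsa-exponent`.
The default reproduces the study's T1-weighted FSE TR/NSA optimum
(TR 500 ms at 3 averages); the square-root reading shifts that optimum to
700 ms.  Bandwidth units are opaque — only ratios ever enter a result.
Within a sweep that holds geometry, NSA and BW fixed, the winning grid
point is independent of `p` and of all geometric prefactors (tested by
randomizing them).

Scan time is `TR · ceil(N_PE/ETL) · NSA` for 2D Cartesian multi-slice
acquisitions (ETL = 1 for GRE) and `TR · Nz · NSA` for the 3D MP-RAGE,
computed in exact rational arithmetic; display strings round to the
nearest second.  This model reproduces the printed protocol durations
(FLAIR 9:36, T1w FSE 4:48, GRE 4:24, T2* mapping 4:16) except the
T2-weighted FSE's printed 4:12, which no integer shot count yields
(the model gives 273 s); we attribute that entry to scanner-side rounding
and do not reproduce it.  `max_nsa_under_budget` takes the largest integer
NSA within a budget and raises on infeasibility.

The echo-spacing → bandwidth coupling is an explicit lookup table with no
interpolation.  Anchored entries are 5.4→100, 7.4→50, 13.4→20 and
17.4→13.5; the remaining default-table values (6→75, 9.4→33, 11.4→25,
15.4→16) are plausible stepped scanner settings chosen by this package —
they affect only the simulated ESP winner, which the validation workflow
overrides with the in-vivo value in any case.

## Sweeps, objectives and tie-breaking

A sweep varies one parameter over an explicit grid with optional linked
rules (ESP→BW table, TR→ETL schedule, NSA budget).  The objective is a
signed CNR for an ordered tissue pair, or a single tissue's SNR.  Pair
orientation in the shipped presets puts the brighter tissue first
(pre-contrast T1w: parenchyma − tumor; post-contrast T1w: tumor −
parenchyma; T2w: tumor − parenchyma; FLAIR: parenchyma − CSF), so signed
maximization selects the contrast optimum.  Ties are broken by smaller
scan time, then smaller parameter value — deterministic and
reproducibility-friendly.  Stages chain by pinning each winner (or a user
override) into subsequent stages; `compare_parameters` issues exact
per-parameter verdicts against a reference set, and mismatched parameters
are precisely those to pin and re-run.

Curve agreement uses Kendall's tau-a over all pairs (ties contribute
zero); the study's curves are tie-free in practice, where tau-a and tau-b
coincide.

## Tissue catalog and cohort sampling

The catalog stores the 7 T cohort means and between-mouse SDs of T1/T2/T2*
for brain parenchyma, CSF and tumor, pre- and post-contrast.  White and
gray matter converge in relaxation at high field, so the contralateral
hemisphere is one tissue.  The cohort sampler draws independent
truncated-normal marginals per field (no covariance is published), seeded;
zero SD is the identity.  Both cohort-mean and single-animal (user-
supplied CSV) inputs are supported, because published optimization curves
are typically shown for a representative animal: with cohort means the
FLAIR TI optimum lands one 200 ms grid step from the representative
animal's 1700 ms, which is the expected resolution of that comparison.

## Relaxometry

The fitters mirror the mapping protocols: saturation-recovery T1 on the
7-point variable-TR grid (278–7000 ms), mono-exponential T2 on the 5-point
multi-echo grid (8.5–76.5 ms) and T2* on 15 gradient echoes (2.4 + 4k ms).
The T1 model is 2-parameter `A(1 − e^(−TR/T1))` — the readout's constant
TE factor is absorbed into A; a 3-parameter variant with free efficiency
`A(1 − b·e^(−TR/T1))` is available behind a flag, without any claimed
match to the vendor tool.  Fitting is Levenberg–Marquardt (via
`scipy.optimize.curve_fit`) with non-negative bounds, initialized at
A = max signal and T = abscissa median (recovery) or span/3 (decay);
non-convergence is reported, not raised.  Fixture noise is additive
Gaussian: the fitted quantities are ROI means over many voxels, where the
Rician magnitude bias of single voxels averages toward Gaussian behavior.

## Digital phantom

The phantom is a stack of identical slices (a cylinder through the head):
an 8×6 mm parenchyma ellipse, a 2 mm-radius tumor centered 2 mm lateral
(mimicking the implantation site) and two small CSF pockets, all
dimensions configurable.  Voxels take the magnitude of their tissue's
analytic signal; noise is Gaussian or Rician (magnitude reconstruction of
two independent Gaussian channels), seeded.  The ROI pipeline computes
per-slice means/SDs and slice-averaged CNR with its cross-slice CV,
mirroring the image-based measurement.  With zero noise the image CNR
equals the analytic CNR divided by the geometric SNR prefactor — the
image-domain oracle for the analytic model.  ROI sizes and placements are
package fixtures; the in-vivo ones are unpublished.

What the phantom does **not** emulate: k-space acquisition, partial
volume, motion/chemical-shift/susceptibility artifacts, coil profiles.
Passing phantom tests therefore validates the bookkeeping between the
analytic and image domains, not robustness to real-scanner artifacts.

## Numerical choices and problem sizes

- Timing validation tolerances: 1e−6 ms on the MP-RAGE identity; the FLAIR
  null-TI closed form is exact (its substitution test uses 1e−9 on M/M0).
- The MP-RAGE closed-form/oracle agreement is tested at 1e−6 absolute on
  100 random parameter sets; the cycle oracle iterates to 1e−12.
- Monte-Carlo test sizes (200 fit replicates, 100 phantom seeds, 1000
  cohort draws) are chosen so each check runs in well under a minute while
  keeping sampling error far below the asserted tolerances.
- Degenerate inputs: μ → 1 in the MP-RAGE geometric sum is handled by its
  limit N; zero-radius phantom regions paint nothing; zero-mean summaries
  and empty ROIs raise informative errors.

## Known limitations

- The first-order FSE/FLAIR longitudinal model ignores recovery during the
  echo train; it is accurate to O(ETL·ESP/T1) (≤ ~2% for the protocols
  here, verified against an exact ideal-pulse recovery simulation).
- The GRE model carries no susceptibility physics beyond the monoexponential
  T2* factor; its flip-angle and TR optima are the workflow's canonical
  override case.
- The SNR expression omits coil loading and electronic noise entirely;
  simulated CNR values are proportional to, not equal to, scanner CNR, so
  only argmax locations and curve shapes are comparable across domains.
- FLAIR's signal at fixed TI *decreases* with TR in this model (the
  pre-inversion recovery term shrinks), while the parenchyma−CSF CNR
  increases with TR; in vivo, refocusing-train imperfections at high ETL
  reverse that trend above TR ≈ 9000 ms — another override case.
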