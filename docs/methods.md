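# Methods

## Physical setting and observables

A dilute suspension of swimming ciliates fills a cylindrical well 12 mm in
diameter and 1 mm deep, open to air.  Bright-field z-stacks are acquired
every Δz = 50 µm from the glass bottom (z = 0) to the free surface,
J = 21 slices per stack, one stack every 30 s for 10 min (21 snapshots).
The camera's square field of view (6.75 mm per side) is clipped by the image
circle, so the imaged volume is the inscribed cylinder
6.75² × 1.0 × π/4 mm³ ≈ 0.0358 mL.

With a low-NA objective the focal depth is ≈ 90 µm; adding a ≈ 50 µm cell
body gives a detectable depth of ≈ 140 µm, i.e. one cell is seen in-focus in
about three consecutive slices.  Raw totals are therefore inflated by a
multiple-counting factor whose modal value is 3, and one slice effectively
samples ≈ 150 µm of the column.  Concentration is estimated as
(raw detections summed over the stack) / 3 / imaged volume.  Probability
profiles (per-slice mass normalised to 1) are unaffected by the factor.

## The boundary-modified diffusion model

Bulk cells move up or down along z with equal probability; departure from
the boundary layers is rescaled by exodus coefficients m_solid (site 1) and
m_air (site J), with m < 1 meaning cells linger (accumulate).  The discrete
population equation is

    dc_1/dt = D (m_2 c_2 − m_1 c_1)/Δz²
    dc_j/dt = D (m_{j+1} c_{j+1} − 2 m_j c_j + m_{j−1} c_{j−1})/Δz²   (interior)
    dc_J/dt = D (m_{J−1} c_{J−1} − m_J c_J)/Δz²

The generator's columns sum to zero (exact mass conservation) and flux
balance at stationarity forces m_j c_j = const, hence

    c_steady ∝ [1/m_solid, 1, …, 1, 1/m_air].

The boundary-to-bulk occupancy ratio is therefore α = 1/m, linking the
transport model directly to the measured accumulation coefficients.
Three independent routes to the stationary state are implemented and tested
against each other: the closed form, the numerical null space of the
generator, and long-time forward simulation.

Numerical choices: explicit forward Euler (the simplest scheme consistent
with the discrete equation), with a stability guard
D·max(m)·Δt/Δz² ≤ 1/2 enforced at construction.  The reference step sizes
are D = 0.001, Δz = 0.05, Δt = 0.005 on a unit-depth domain with J = 21
(matching the experimental 1 mm / 50 µm grid).  "Steady" means the per-step
L1 change falls below 10⁻¹²; `simulate_to_steady` applies the same Euler
chain in blocks of 1024 steps through a precomputed propagator for speed.
At the reference step sizes the slowest relaxation mode has a decay rate of
about 9×10⁻³ per unit time, so a horizon of T = 300 from a generic random
start still leaves an L1 residual of order 10⁻³–10⁻²; convergence statements
are therefore made at per-step stationarity, not at a fixed horizon.

## Detection convolution and the two α estimators

Because each cell is counted in ~3 neighbouring slices, the measured
("apparent") profile is the physical one convolved with a detection kernel.
Two kernels are provided: a boxcar [1, 1, 1] truncated at the stack edges
(the nearest-neighbour summation view), and the exact per-site observation
matrix of the "nearest-3-clipped-inward" rule, in which the 3-slice window
of a boundary cell is shifted inward so interface cells are still counted
three times.  Apparent profiles are re-normalised before comparison with
measured probability profiles.

Estimator A (peak ratio): α = raw interface peak / (bulk mean / 3).  The
asymmetry is deliberate — a stationary interface cell appears exactly once
in the peak slice, while bulk slices are inflated threefold.  The bulk mean
excludes 3 slices on each side of each peak (the ≈ 150 µm detection spill);
this exclusion zone is a configurable interpretation, recorded in output
metadata.  The raw peak, however, also collects spill *into* the peak slice
from the first bulk layers, so estimator A overestimates α by up to a few
bulk units for broad peaks; this bias is intrinsic to the estimator, is
reported rather than hidden, and is covered by tests.  An alternative
3-slice-sum/3 peak estimator is exposed for broad peaks.

Estimator B (kernel-aware least squares): minimise
‖normalise(K·steady(m)) − p_obs‖₂ over (m_solid, m_air) in log space.  With
the kernel matching the acquisition this removes the spill bias; noiseless
round trips recover m to 10⁻⁶ and seeded noisy benchmarks recover α within
a few percent.  Both estimates are always reported side by side; their
discrepancy is a diagnostic, not something the code resolves silently.

Peak location: bottom peak = argmax over the lowest 4 slices, top peak =
argmax over the highest 5 (wider to absorb the downward drift of the surface
under evaporation).  A window whose maximum does not exceed the interior
mean is flagged "no distinct peak".  Uncertainties on α are the sample
standard deviation over the 21 snapshots (the dispersion convention of the
time-resolved analysis); the standard error of the mean is reported
alongside.

## The synthetic twin

`swimstack.synthetic` generates data with the statistical structure the
analysis assumes:

- **Agent chain.** Independent walkers on the J sites; per-direction move
  probability r·m_j·dt (boundary sites have a single exit).  Detailed
  balance gives the stationary law π ∝ 1/m exactly — the same law as the
  population model — so estimator recovery can be tested against exact
  ground truth.  The default hop-rate scale r = 0.1 /s lets a cell explore a
  few slices between snapshots, consistent with continuously swimming cells;
  no measured value exists for this rate and results at stationarity do not
  depend on it.
- **Observation model.** Each cell is detected in k consecutive slices,
  k = 3 deterministically by default (a categorical law on {1..6} models the
  looser bulk multiplicities), window clipped inward at the edges.  With
  deterministic k = 3, total raw detections are exactly 3 × n_cells.
- **Benchmark generator.** Requested (α_solid, α_air, concentration) are
  realised by m = 1/α and n_cells = concentration × imaged volume; cells
  start in the stationary law and evolve through the 21 × 30 s schedule, so
  snapshots carry realistic temporal correlation.  Optional evaporation
  lowers the surface by a fixed rate per snapshot; cells stranded above the
  falling surface are re-injected at the new top site (a mass-conserving
  modelling choice; no measured rule exists) and the air-interface
  coefficient follows the surface.
- **Image rendering.** Cells are dark Gaussian blobs on a bright background;
  contrast decays as 1/(1 + (d/90 µm)²) with defocus d and width grows
  correspondingly, so with the default threshold a cell is detectable over
  ≈ 140 µm — three slices.  Detection is deterministic thresholding +
  connected components + area filter; multiplicities are estimated by greedy
  nearest-centroid linking across adjacent slices.  This stands in for the
  machine-learning segmentation used on real images: the scientific content
  is the counting statistics, not the classifier.

What the twin does *not* emulate: hydrodynamic cell–wall and cell–cell
interactions, the x–y structure of real images (clustering, background
inhomogeneity beyond a smooth gradient), curvature of the image plane, and
concentration-dependent behaviour.  Passing tests therefore demonstrate that
the estimators are correct for data obeying the stated model, not that the
model captures every feature of real suspensions.

## Problem sizes and defaults

Tests and the acceptance script run on the experiment-scale geometry
(J = 21, 21 snapshots) with ~10⁴ cells per benchmark (3×10⁵ cells/mL in the
0.036 mL imaged volume) — the dilute regime of the measurements — and
10⁵ pooled cell-snapshots for stationary-law checks.  Image fixtures use
128–512 px frames; real acquisitions (2048 px) differ only in scale.  All
randomness flows through explicit integer seeds; identical seeds give
byte-identical pipeline summaries.

## Known limitations

- The diffusion coefficient D is not estimable from stationary profiles (it
  cancels at steady state) and no relaxation-based estimator is provided.
- Estimator A's spill bias is documented, not corrected; use estimator B
  when the detection kernel is known.
- The evaporation re-injection rule and the bulk exclusion zone are
  modelling interpretations; both are configurable.
- The boundary layer is treated as one imaging slice; sub-slice interface
  structure is unresolved by construction.
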