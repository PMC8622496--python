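# swimstack

Quantifies how swimming microorganisms (ciliates such as *Tetrahymena
pyriformis*) distribute along the depth of a shallow open chamber, and in
particular how strongly they accumulate at the solid bottom and at the free
water surface.

The experimental observable is a z-stack count table N(z, t): in-focus cell
detections per 50 µm imaging slice, for a series of time snapshots of a
1 mm deep well.  Because the depth of focus spans roughly three slices, each
physical cell is detected about three times (the *multiple-counting factor*),
which matters both for absolute concentrations and for the shape of the
measured profile.  The package is aimed at microscopists and active-matter
researchers who want to turn such tables (real or simulated) into
interpretable accumulation coefficients.

## The model

Accumulation at the two interfaces is summarised by two coefficients

    α_solid = N_solid / N_bulk,        α_air = N_air / N_bulk

the ratios of the interface peak cell numbers to the (factor-corrected) bulk
cell number.  On a grid of J slices the population obeys a 1D diffusion
equation with boundary-modified exodus rates m_j (m = 1 in the bulk):

    dc_j/dt = D (m_{j+1} c_{j+1} − 2 m_j c_j + m_{j−1} c_{j−1}) / Δz²

with one-sided versions at j = 1 and j = J.  Its stationary state is

    c_steady ∝ [1/m_solid, 1, …, 1, 1/m_air]

so boundary occupancy relative to bulk is exactly α = 1/m: the accumulation
coefficients *are* the steady state of the transport model.  The package
implements the closed-form steady state, a generator null-space cross-check,
explicit-Euler forward simulation, the detection-kernel convolution that maps
the physical profile onto the apparent (measured) one, and two estimators of
α from data: the direct peak-over-bulk ratio and a kernel-aware least-squares
fit that undoes the detection smearing.

A fully tested synthetic twin (independent random walkers whose departure
rate from site j is proportional to m_j, plus the 3-slice observation model)
generates benchmark tables with exact ground truth.

## Worked example

```python
from swimstack.synthetic import make_benchmark_dataset
from swimstack import InterfaceAccumulation

counts, truth = make_benchmark_dataset(
    alpha_solid=4.0, alpha_air=2.0, concentration=3.0e5, seed=1)
results = InterfaceAccumulation(counts).fit()
print(results.summary())
```

```
Interface Accumulation Results
==============================================
snapshots:   21   slices:   21   counting factor: 3
concentration: 3.000e+05 +/- 6.0e-11 cells/mL
----------------------------------------------
peak-ratio estimator (per-snapshot mean +/- sd):
  alpha_solid =   6.912 +/- 0.102  (se 0.022)
  alpha_air   =   4.960 +/- 0.083  (se 0.018)
profile least-squares fit (kernel-aware):
  alpha_solid =   3.954   m_solid = 0.2529
  alpha_air   =   1.980   m_air   = 0.5050
  residual L2 = 1.489e-03
==============================================
```

The generator planted α = (4, 2) at a concentration of 3×10⁵ cells/mL.  The
concentration estimate (raw totals / 3 / imaged volume) recovers the input
exactly.  The peak-ratio estimator reads the raw interface peak over the
factor-corrected bulk and *overestimates* (6.9, 5.0), because the peak slice
also collects detections spilling over from the first bulk layers — a known
property of that estimator for broad peaks.  The kernel-aware least-squares
fit models the spill explicitly and recovers (3.95, 1.98), within sampling
error of the truth.  `results.plot()` overlays the measured and fitted
apparent profiles.

The same analysis runs from the shell on any counts CSV
(`snapshot_index,time_s,slice_z_um,raw_count`):

```
swimstack pipeline --outdir run --seed 1     # synthetic end-to-end run
swimstack alpha counts.csv --out alpha.json  # analyse a measured table
```

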