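# Methods

## The coupled-equilibrium (modulated-receptor) model

Availability follows a two-state Boltzmann in voltage,
`h(V) = A / (1 + exp((V - V_1/2)/k))` with `k > 0`, so curves decrease with
depolarization.  A drug with dissociation constants `K_r` (resting) and
`K_i` (inactivated) shifts the midpoint by
`dV = -k ln[(1 + D/K_i)/(1 + D/K_r)]` and scales the hyperpolarized plateau
by the resting block `b = 1/(1 + D/K_r)`.  The model assumes a single
common slope factor for control and drug conditions; accordingly the
inference chain uses the **control-fit slope** in the shift inversion (the
drug-fit slope differs slightly in real data because it absorbs noise and
secondary gating effects).  `K_r` may be infinite, representing no
measurable resting-state binding; `infer_kd_rest` returns that sentinel
when the resting block is exactly 1.

The apparent affinity at intermediate voltages is the harmonic
interpolation `1/K_app = h/K_r + (1-h)/K_i`, valid when gating is fast
relative to binding — which holds by orders of magnitude under the default
calibration (gating relaxes in milliseconds, binding in tens of seconds).

## Six-state kinetic scheme

States: R (resting/closed), IF (fast-inactivated), IS (slow-inactivated)
and drug-bound RD, IFD, ISD.  Slow inactivation is entered only through IF
(no direct R–IS edge): entry into slowly recovering states at modestly
depolarized voltages proceeds through fast-inactivated channels, and a
minimal topology suffices for every protocol the package simulates.

Voltage dependence lives on the R–IF edge in single-barrier exponential
form: `alpha(V) = a0 exp(delta x)`, `beta(V) = a0 exp(-(1-delta) x)` with
`x = (V - V_1/2)/k`, so the equilibrium reproduces the target Boltzmann
exactly for any barrier partitioning `delta`.  Both `a0` and `delta` are
solved from two relaxation-time anchors; a fixed symmetric partitioning
cannot satisfy two independent anchors, so `delta` is treated as derived
(the defaults give `delta ≈ 0.364`).

Default calibration (units ms, mV, nM):

| quantity | value | rationale |
| --- | --- | --- |
| control Boltzmann | V_1/2 = -75.2, k = 7.9 | representative steady-state availability fit |
| tau_h at -40 mV | 3 ms | fast-inactivation entry time constant |
| recovery tau at -100 mV | 2 ms | drug-free recovery from fast inactivation |
| IF→IS rate | 5e-4 ms⁻¹ | 2-s slow-inactivation entry at -40 mV |
| IS→IF rate | 0.05 ms⁻¹ | keeps the IS/IF equilibrium ratio at 0.01, so the 5-s steady-state curve stays within 0.005 of the generating Boltzmann |
| K_r | 360 nM | resting affinity consistent with the observed hyperpolarized block |
| K_i | 50 nM | inactivated-state affinity (IS shares K_i: the drug stays bound through slow inactivation) |
| k_on | 5e-8 nM⁻¹ms⁻¹ (0.05 µM⁻¹s⁻¹), all states | sets the slow onset of block: at 300 nM the relaxation rate k_on(D + K_app) gives tau ≈ 54 s at -70 mV, so two minutes of application produces strong but still sub-steady-state block (relative current ≈ 0.28) and full equilibration takes ~10 minutes |
| bound-gating factor | 1 | drug-bound channels gate at unchanged speed |

Off-rates are `k_on * K_state`.  The drug-bound gating rates are then
*solved from detailed balance*, one dependent rate per cycle:
`IFD→RD = beta(V) K_i/K_r` (the bound R/IF equilibrium is shifted by
`K_r/K_i`, which is exactly how the modulated-receptor shift arises
kinetically) and `IFD↔ISD` equals `IF↔IS` (equal affinities).  Scheme
validation checks the Kolmogorov cycle criterion on every basis cycle of
the rate graph (networkx `cycle_basis`) to 1e-8 relative and raises naming
the offending cycle.

Propagation over piecewise-constant voltage protocols is exact per epoch
via `expm(Q t)`; integration error is therefore limited to the matrix
exponential itself (verified against a tight-tolerance Runge–Kutta
integration to 1e-6 in the tests).  Availability readouts count the R
occupancy only: **drug-bound resting channels do not conduct** in the
default readout, which is how resting-state binding produces block at
hyperpolarized potentials.  `slowly_recovering_fraction` is defined
absolutely — one minus availability after a 100-ms recovery criterion at
-100 mV — so with zero conditioning it reduces to the baseline unavailable
fraction at the holding potential.

## Fitting

Both curve fits use scipy's trust-region-reflective least squares with
bounds (slope in 0.5–30 mV, Hill coefficient in 0.2–5) and tight
tolerances (1e-14 on relative objective/step, max 500 evaluations).
Boltzmann initialization takes the midpoint from the interpolated
half-maximum crossing, slope 8 mV, amplitude from the curve maximum; the
Hill fit works on log10(IC50) (well conditioned across concentration
decades) initialized from the log-linear 50%-crossing.  Accepted
trust-region steps only ever reduce the cost, and the recorded
per-iteration objective trace is asserted non-increasing in the tests.
Degenerate inputs (flat curves, all-zero inhibition, slope pinned at a
bound) are flagged `converged=False`, never silently returned.  Parameter
uncertainties come from the Gauss–Newton covariance `(J'J)^{-1} * 2 cost/dof`.

Multi-cell aggregation follows the averaged-shift convention: shifts are
computed per cell and averaged, then drift-corrected by exact subtraction
of the average control drift; the package operates on those averages
rather than pooling points across cells.

## Synthetic data

Generators emulate the *structure* of patch-clamp data, not its full
physics: additive Gaussian noise on normalized current (error bars on
availability curves are roughly uniform across voltage), default sd 0.02,
clipped at zero; a single global seed expands into per-curve substreams via
`default_rng([seed, stream])`, so identical seeds are bit-identical and
changing the seed changes only the noise.  The paired-curve generator is
the exact forward model of the inference chain (shifted, plateau-scaled
Boltzmann plus the resting block), which gives the adjoint property used
throughout the tests: every generator's parameters are recovered exactly by
its inference operation in the noiseless limit.  What passing these tests
does **not** show: robustness to multiplicative or correlated noise,
series-resistance voltage errors, rundown that is not a pure midpoint
drift, or cell-to-cell parameter heterogeneity beyond what the noise sd
captures.

Structural fixtures are constructed stand-ins (labelled synthetic in their
sources): a donor–acceptor triad at 2.8 Å/170°, a decoy pair at 4.5 Å,
parallel rings at 4.0 Å centroid separation, and a 12-atom chain with a
planted 30° rotation for superposition round trips.

## Structural annotation choices

Deposited cryo-EM models carry no hydrogens, so hydrogen bonds use a
heavy-atom criterion: N/O pairs within 3.5 Å plus an angle check at the
donor computed from its bonded heavy neighbors (covalent cutoff 1.8 Å),
accepting geometries ≥ 120°; when the donor has no resolved neighbor the
detection is distance-only and flagged (`angle=None`).  Contacts use a
4.5 Å heavy-atom cutoff; aromatic stacking uses ring centroids ≤ 5.5 Å and
interplanar angle ≤ 30° with ring planes from an SVD fit (protein ring
templates for Phe/Tyr/Trp/His; ligand rings supplied by atom-name list;
rings with fewer than five resolved atoms are skipped).  All cutoffs are
conventional defaults exposed as arguments — interaction calls in
structure figures are typically qualitative, so no single numeric criterion
is canonical.  Superposition is least-squares with a proper rotation
(Kabsch via scipy's `align_vectors`), pairing atoms by (chain, residue
number, atom name) with Cα as the default representative; residue
numbering is taken from the input model unchanged.

## Problem sizes

Defaults used by the tests and the acceptance script: 23-point voltage
grids (-130 to -20 mV in 5-mV steps), the five-point dose grid
{0.3, 1, 3, 10, 30 µM}, 120-s applications simulated as one matrix
exponential, 100 randomly calibrated schemes for the conservation/detailed
balance suite, and 200 replicate noisy pairs (sd 0.02) for the recovery
simulation study.  The whole suite runs in a few seconds.

## Known limitations

- A single well-mixed aqueous drug pool: membrane partitioning and access
  kinetics are not modeled.  Real lipophilic drugs load the membrane
  slowly and then bind fast from the lipid phase; a single on-rate cannot
  reproduce both a minutes-long onset at the holding potential and rapid
  binding to fast-inactivated states within tens of milliseconds.  The
  default calibration prioritizes the slow onset; consequently the drug
  branch of the slow-recovery readout reflects standing block plus
  redistribution of already-bound channels rather than fresh binding
  during a 20-ms step.
- No conductance or current-waveform modeling: availability is an
  occupancy readout, with no series-resistance or capacitance artifacts.
- Temperature is not modeled; datasets recorded at different temperatures
  are treated as separate calibrations.
- Slow inactivation is deliberately shallow under the default calibration
  (equilibrium ratio 0.01, relevant only above ~-40 mV for seconds); the
  IS states exist chiefly to carry drug-bound occupancy and the scheme
  topology, not to reproduce deep slow inactivation at strongly
  depolarized voltages.
- Statistical comparison between conditions (t-tests, F-tests on fits) is
  out of scope; the package stops at point estimates and fit covariances.
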