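# Methods

`rloopflank` quantifies the conformational state of duplex DNA flanking an
R-loop from three kinds of measurements: permanganate/piperidine footprinting
gels, molecular-dynamics trajectory frames, and UV melting curves. This note
records the models behind each estimator, the simulators used to validate
them, the numerical choices, and the limits of what the tests demonstrate.

## Footprinting model

Permanganate oxidizes thymines whose C5=C6 double bond is approachable —
melted, flipped-out, or helically distorted DNA — and piperidine then cleaves
the backbone at each oxidized thymine. On a denaturing gel only the labeled
fragment of each molecule is visible, and it ends at the oxidized thymine
*closest to the labeled end*. A lane is therefore a censored observation:
band `i` counts molecules whose first (label-proximal-most) oxidation is at
thymine `i`, and the full-length band counts unoxidized molecules.

Assuming oxidation events at different thymines are independent, the
probability that thymine `i` was oxidized is the conditional frequency

    p_i = v_i / Σ_{j ≥ i} v_j

— out of all molecules for which cleavage at `i` would have been observable
(fragments at or above band `i`, full-length included), the fraction actually
cleaved there. This estimator is exact under independence, and is unaffected
by any bands below `i`, which is why lanes whose shortest fragments ran off
the bottom of the gel remain usable (the missing bands are flagged, not
imputed). Independence is an approximation: clustered thymines can enhance
one another's oxidation, so `p_i` is an estimate, not a measurement.

With a uniform oxidation hazard over the permanganate exposure (quenched at
time `t`, in minutes), `p_i = 1 − exp(−k_i t)` defines the per-thymine rate
constant

    k_i = ln(1/(1 − p_i)) / t.

As `p_i → 1` the transform's slope diverges, so `p_i ≥ 0.99` (configurable)
sets a `saturated` flag and `p_i = 1` is reported missing rather than
infinite. `p_i = 0` is informative (no signal above background) and yields
`k_i = 0`, not a missing value.

### Cross-replicate normalization, PRI, FO

Each replicate set uses a freshly prepared permanganate solution whose
oxidation activity varies multiplicatively. A reference thymine whose
conformation is unaffected by R-loop formation (by convention the thymine
10 nt from the 5′-labeled end, present in all substrates) calibrates this
out: per replicate set the reference rate is averaged across lanes
(`k̄_ref`, unweighted), the grand mean of those set means (`μ_ref`,
unweighted) is taken as the reference thymine's true rate, and every rate in
set `r` is corrected by `k_i,corr = (μ_ref / k̄_ref,r) · k_i`. Unweighted
averaging is a deliberate choice; volume-weighted alternatives were not
adopted because phosphorimager volumes are arbitrary units that differ
between lanes for reasons unrelated to precision.

The **Permanganate Reactivity Index** is the corrected rate normalized to a
fully single-stranded thymine:

    PRI_i = k_i,corr / kss_corr,   kss_corr = 0.79 min⁻¹ by default,

so PRI = 1 means "as reactive as unpaired DNA" and PRI is linear in the
corrected rate (a PRI 0.4 thymine was oxidized twice as fast as a PRI 0.2
thymine). The corrected oxidation probability is
`p_i,corr = 1 − exp(−k_i,corr t)`.

The **Fraction Oxidized** of a substrate's R-loop flank (RLF) — the flank
thymines on both strands, each with an explicit strand assignment — is

    FO = 1 − Π_{a∈RLF} (1 − p_a,corr) = 1 − exp(−Σ_{a∈RLF} k_a,corr t),

combining the two strand labelings under the assumption that oxidation on
the two strands of one molecule is independent. The two closed forms are
algebraically identical; the implementation accumulates `log1p(−p)` so they
agree to better than 1e−12 relative, which the tests assert. Replicates are
summarized as mean ± sample SD (n−1); a single replicate reports its mean
with the SD flagged unavailable rather than zero.

## Synthetic gel experiments

The simulator draws each molecule's oxidation pattern independently per
thymine with `q_i = 1 − exp(−k_i a_r t)`, where `a_r` is the replicate set's
activity factor (drawn lognormal(0, σ) when not given; σ = 0.4 emulates the
observed prep-to-prep variation the reference correction exists to remove).
The recorded band is the label-proximal-most oxidized thymine. Without
optional artifacts this collapses to a multinomial over bands with

    P(band i) = q_i · Π_{j<i} (1 − q_j),

which is also computed exactly by a brute-force enumeration over all `2^m`
oxidation patterns (`enumerate_expected_lane`, refused above m = 20). The
enumeration is the sampling-free oracle: the estimator applied to an
enumerated lane must return `q` to machine precision, and Monte-Carlo lanes
must agree with enumeration within binomial error.

Optional stress features, off by default:

* **Chain reactions.** Oxidation breaks the base's planarity and can
  unstack its neighbour, exposing it to further oxidation. The simulated
  chain propagates from a primary oxidation site recursively *toward the
  labeled end* with probability `c` per step (a geometric chain length).
  This direction is the one that is observable on a gel: the detected
  cleavage is the label-proximal-most oxidation, so only chains running
  toward the label can move it, piling volume into the low-index bands.
  Whether real chains would run in one or both directions along the strand
  is unknown; the simulator makes no mechanistic claim.
* **Background** is added as a uniform pseudocount fraction of total lane
  signal, emulating diffuse phosphorimager background.
* **Truncation** deletes bands below a configurable index and flags the
  lane, emulating short fragments run off the gel; the estimator's
  truncation invariance (no `p_j` changes for surviving bands) is tested.

Default study conditions used throughout validation: quench time 2 min,
10⁶ molecules per lane, 3 replicate sets, activity σ = 0.4, 9 probed
thymines spanning true oxidation probabilities ~0.02–0.6, chain reactions
off. Parameter-recovery tests propagate uncertainty by the delta method;
because the multinomial likelihood factorizes into independent conditional
binomials, `Var(k_i) = p_i /((1−p_i)·tail_i·t²)` and the corrected rate's
variance follows from the chain rule through `μ_ref/k̄_ref`. The recovery
check (≥95% of thymines within 3 propagated SE over 200 seeded runs) passes
with calibrated z-scores (SD ≈ 0.97).

What the simulator does **not** emulate: gel physics (band shapes, smiling,
compression), sequence-dependent oxidation chemistry (cytosine/purine side
reactions — though annotated non-thymine bands can be excluded from
denominators via a toggle), mutual oxidation enhancement other than the
one-directional chain model, and non-uniform background. Passing tests
demonstrate correctness of the estimators under the stated generative model,
not the model's fidelity to every gel artifact.

## Envelope surface area (ESA)

ESA is the solvent-exposed surface area of two nucleobases considered
jointly — the RNA-terminal base of the hybrid and the DNA base stacked on it
from the displaced strand. Stacked faces bury each other, so low ESA means
stacked, high ESA means unstacked; the trace over trajectory frames reports
coaxial-stacking dynamics.

The surface is computed Shrake–Rupley style: each atomic sphere (element
radii C 1.70, N 1.55, O 1.52, P 1.80, H 1.10, S 1.80 Å, overridable) is
inflated by the probe radius (default 1.4 Å, water) and covered with a
deterministic Fibonacci lattice (default 960 points); a point is exposed if
it lies outside all other inflated spheres, and each atom contributes
`4πR² · exposed/total`. "Solvent-exposed" is read as the probe-inflated
(solvent-accessible) surface; a probe-contact (molecular) surface would be a
different, unimplemented convention.

Two numerical choices matter:

* **Canonical orientation.** The lattice is oriented in the principal-axes
  frame of each connected cluster of overlapping spheres, with eigenvector
  signs fixed by the third moment of the projections. ESA is then *exactly*
  invariant under rigid-body motion, and non-overlapping groups of atoms are
  *exactly* additive. Degenerate clusters (near-equal eigenvalues or
  vanishing skewness, e.g. two identical spheres) fall back to the lab
  frame, where invariance is only statistical — still within the sampling
  tolerance.
* **Sampling tolerance.** At 960 points the two-sphere spherical-cap closed
  form is reproduced within 1% (documented tolerance); the error shrinks
  with the point count and an isolated sphere is exact at any count. An
  independent Shrake–Rupley implementation (biotite) agrees within 2% on
  multi-atom fixtures.

Hydrogens are included by default (they were present in the simulated
models); the default nucleobase selection keeps ring and exocyclic atoms and
drops sugar (primed names) and phosphate atoms, overridable per residue.
Frames are read from multi-model PDB (selection by chain and residue number)
or plain xyz (no residue metadata, whole frame used) at a nominal 1 frame/ps;
smoothing is a centered moving average over a 1000 ps (1 ns) window,
truncated at the edges. Stacked/intermediate/unstacked classification
thresholds are this artifact's plumbing — the underlying measurement is a
continuous trace — and must be chosen explicitly by the user.

The analyzed trajectories themselves (MD engine, force field, thermostat)
are out of scope; validation uses analytic sphere configurations and
synthetic frames.

## Melting curves

Refolding curves (A260 while cooling 95 → 2 °C at 1 °C/min, one reading per
0.5 °C, 187 points) are fit to a two-state model with linear baselines,

    A(T) = B_f(T) + (B_u(T) − B_f(T)) · s(T),   s = 1/(1 + e^{−(T−Tm)/w}),

by least squares on internally normalized absorbance (making the fit
invariant to affine rescaling and to temperature ordering). The two-state
form is justified by the unimolecular, concentration-independent constructs;
`w` is reported as a width, not interpreted as a van't Hoff enthalpy.
Initialization: Tm from the extremum of a 5-point-smoothed derivative,
baselines from the outer ~15% of points, `log w` parameterization keeps the
width positive. A curve whose detrended residual is below 0.1% of its range,
or whose fitted transition amplitude is within 3× the residual SD, raises a
"no transition" error. If the optimizer fails, the smoothed-derivative
extremum is returned, tagged `derivative`.

Noiseless fixtures are recovered to <0.01 °C across Tm 10–90 °C and widths
1–8 °C. With 2% amplitude Gaussian noise on the 187-point grid the fit
attains the Cramér–Rao bound (SE ≈ 0.15 °C at width 4 °C); the stochastic
recovery study therefore asserts aggregate accuracy (RMSE and mean |error|
≤ 0.3 °C over 100 seeds) — per-seed guarantees tighter than the information
bound are not possible for any estimator. `compare_tm` reports a difference
of replicate means with root-sum-square propagated SD, flagging the
uncertainty unavailable when either side lacks replicate scatter.

## Interfaces and determinism

Lane tables and results are TSV; substrate definitions and run configuration
are YAML; positions are 1-based along the labeled strand counted from the
labeled end (so 5′- and 3′-labeled lanes share one code path, the reader
having put bands in label-proximal order). Quench times are accepted in
seconds or minutes and normalized to minutes. All randomness flows from
explicit seeds (`simulate` refuses to run without one); identical inputs and
seeds give byte-identical outputs, and result files carry a metadata header
(`kss_corr`, `μ_ref`, version). Readers reject malformed input with row or
field coordinates rather than repairing it.

## Known limitations

* The independence assumptions (between thymines, and between the two
  strands for FO) are inherited from the estimator definitions; the chain
  simulator can probe the first but the estimators do not correct for it.
* The reference-thymine correction removes only multiplicative activity
  variation; additive or thymine-specific batch effects pass through.
* ESA thresholds for stacking classes have no principled default here.
* Tm extraction assumes a single two-state transition; multiphasic curves
  will fit poorly and should be inspected via the derivative trace.
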