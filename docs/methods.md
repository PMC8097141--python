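# Methods

## Cell model and integration

Cells follow the two-regime quadratic adaptive (hybrid) model: a
quadratic membrane equation with piecewise scaling `k_low`/`k_high`
switching at the instantaneous threshold `v_t`, a slow linear recovery
variable `u`, and a discrete reset (`V ← c`, `u ← u + d`) when `V`
reaches the cutoff `v_peak`.  `(v_r, u = 0)` is an exact fixed point of
the flow at zero input, and is the initial state of every protocol that
"starts from rest".

Integration is fixed-step forward Euler with `dt = 0.04 ms` by default.
The scheme choice is guarded rather than assumed: the test suite checks
that spike counts are invariant under halving `dt`, that first-spike
times agree within 1 ms with the same scheme at `dt/16`, and an
independent adaptive integrator (`scipy.solve_ivp` at tolerance 1e-10)
was used during development to confirm near-rheobase spike times to
sub-millisecond accuracy.  The `k` regime is selected from the voltage
at the start of each step; the reset is applied at most once per step,
and the spike timestamp is the end of the step on which the cutoff was
reached (no sub-step interpolation — PRC shifts are normalized by
periods several thousand times larger than `dt`).

## Feature protocols

* **Rheobase** — constant currents −25…25 pA in 0.5 pA increments,
  ascending, each from rest; the first current with a spike in the first
  500 ms is the rheobase.
* **PIR** — 1 s hyperpolarizing steps 0…−25 pA in 0.5 pA increments,
  each from rest, released to zero current; the first step whose release
  elicits a spike (with none at the previous step) is the PIR value.
  The rebound-detection window after release is 500 ms (config-exposed;
  the protocol definition leaves it open).
* **SFA** — 1 s steps 0…98 pA in 2 pA increments; per step the initial
  frequency is the inverse first interspike interval and the final
  frequency the inverse last one; one least-squares line is fitted to
  each frequency-vs-current relation and SFA is the slope difference
  (initial − final).  Only steps with ≥ 3 spikes contribute (with
  exactly two spikes the two intervals coincide and carry no adaptation
  contrast); both lines use the same qualifying set so the slopes are
  comparable.

For the default cell these protocols yield SFA = 0.463 Hz/pA and
PIR = −5.0 pA.  The rheobase quantifies to **3.5 pA**.  This value sits
on a knife edge of the protocol: the time to first spike diverges as
the current approaches the dynamic threshold (≈3.25 pA), jumping from
≈313 ms at 3.3 pA to never-spiking at 3.2 pA, and it is extremely
sensitive to the initial recovery variable — starting with `u₀` as
small as 0.5 pA (instead of the exact fixed-point value 0) moves the
quantified rheobase to 4.0 pA.  We keep the exact fixed-point
initialization because it is the only principled choice; the
sensitivity is documented here rather than hidden by tuning.  Because no
current in the sweep has a first-spike time between 313 and 500 ms, the
result is insensitive to the detection-window length anywhere in that
range.

## Model database and bands

The database sweeps the four parameters that control excitability and
adaptation — `a`, `b`, `d`, `k_low` — over a Cartesian grid with all
other parameters fixed.  The reference grid uses 10 values per
parameter (10,000 models): `a` and `k_low` log-spaced over
0.0004–0.004 ms⁻¹ and 0.05–0.2 nS/mV (they act multiplicatively),
`b` and `d` linear over 1–5 nS and 2–20 pA, with the default value
snapped onto each list.  The grid is config-first: these ranges bracket
the default cell roughly ±50–130% and are a reference fixture, not a
claim about any particular published database.

Low/Medium/High bands are the tertile split (1/3 and 2/3 quantiles,
linear interpolation) of each feature's defined values; Narrow/Broad
bands are symmetric intervals about the base values (0.46, 4.0, −5.0)
covering 20% and 60% of the observed range (both fractions
config-exposed — the partition itself is a convention, only its
structure matters: L/M/H disjoint and ordered, Narrow ⊂ Broad).
Populations are drawn uniformly **with replacement** from qualifying
rows, so a handful of distinct models can populate thousands of network
cells; draws are seeded and reproducible.

Which band the base model lands in depends on the grid: on the 3⁴ test
grid it falls in M/M/M, and nothing in the pipeline assumes a
particular assignment.

## Networks

Reference architecture: 10,000 PYR + 500 fast-firing PV⁺ cells.
Connection probabilities: PYR→PYR 0.009 (sparse, <1%), PYR→PV 0.02,
PV→PYR 0.30, PV→PV 0.12 — the PV→PYR > PYR→PV asymmetry is enforced at
reference scale.  Synapses are conductance-based single exponentials
(instantaneous rise): excitatory `τ = 3 ms`, `E_rev = −15 mV`;
inhibitory `τ = 8 ms`, `E_rev = −85 mV` (reversal values as used with
Izhikevich-type cells in this modelling lineage).  One conductance
channel per sign per cell, so all projections of the same sign must
share a decay constant.

**Scaling rule.**  `scale_network` multiplies cell counts by a factor
and preserves the product (presynaptic count × connection probability ×
weight) per projection by holding the probability and dividing the
weight, keeping the expected summed input conductance per cell
invariant.

**Drive.**  Each cell receives an independent noisy current: mean plus
zero-mean Gaussian fluctuations held piecewise-constant over 1 ms, with
SD = fluctuation/6 so the typical peak-to-peak excursion approximates
the configured fluctuation amplitude (an Ornstein–Uhlenbeck option with
matched stationary SD is available).  The PYR preset is mean 25 pA,
fluctuation 30 pA; the mean matches the ≈20–30 pA net excitatory input
a PYR cell sees in the full circuit.  A zero-mean drive of this
fluctuation class cannot ignite the scaled network at all: the membrane
time constant near rest is `C_m/(k_low·(v_t−v_r)) ≈ 240 ms`, which
averages 1-ms noise down to <1 pA effective drive, below rheobase.

**Presets are calibration, not measurement.**  Synaptic weights
(PYR→PYR 0.15, PYR→PV 0.5, PV→PYR 1.0, PV→PV 0.3 nS at reference
scale) were chosen once to place the circuit in its documented
operating regime and then frozen: at 0.1 scale the E-only network
bursts at ≈3.4 Hz with dense participation (≈0.7 of cells per cycle,
mean rate above the burst frequency), and the matched E-I network
produces a strong ≈8.3 Hz theta rhythm with sparse participation
(≈0.34, mean PYR rate ≈2.9 Hz, well below the rhythm frequency).  These
regimes are stable across seeds; the property tests assert the regime
structure (theta-band peak; E-I strictly sparser than E-only), not the
specific frequencies.

## Rhythm quantification

The PYR population rate (1 ms bins, Hz per cell, first 500 ms discarded
as transient) is mean-subtracted and analyzed with Welch's method
(Hann windows of 2048 ms, 50% overlap).  The rhythm frequency is the
argmax of spectral density within the 3–12 Hz search band and the power
is that density.  A run is classified rhythmic when the band peak is at
least 5× the band's median density and the mean rate exceeds
0.05 Hz/cell (near-silent rasters are never "rhythmic").  Both
thresholds are conventions, config-exposed, and validated on synthetic
ground truth: sinusoidally modulated inhomogeneous-Poisson rasters
(thinning construction) at 4/7/10/15 Hz are recovered at the modulation
frequency, detected power grows monotonically with modulation depth,
and unmodulated rasters classify as non-rhythmic.

Burst participation is the mean fraction of distinct cells firing per
window of one rhythm period — a deliberately simple measure that needs
no burst-boundary detection.

## Phase response curves

A tonic current (20:2:30 pA sweep) is applied from rest; the period λ
is the 9th-to-10th interspike interval, by which point the slow
recovery variable has settled (asserted: the 8th-to-9th interval agrees
within 1%).  For each phase i/100, an independent re-initialized
simulation delivers a −500 pA, 1 ms pulse at i·λ/100 after the 10th
spike, and the perturbed period λₚ is the 10th-to-11th interval.

One numerical refinement: the shift is computed as (λ_ref − λₚ)/λ where
λ_ref is the *unperturbed* 10th-to-11th interval — the very interval
the pulse perturbs — rather than λ itself.  λ and λ_ref agree to ≈3·10⁻⁴
relative (residual adaptation drift), so the two definitions are
numerically indistinguishable for real perturbations, but the refined
baseline makes the zero-amplitude-pulse PRC *exactly* zero instead of
inheriting the drift.  λ keeps its role as phase ruler, normalizer and
frequency readout (intrinsic frequency = 1/λ).

Negative shifts are phase delays, positive shifts advances; a
depolarizing mid-cycle pulse advances the next spike of the default
cell (sign-convention check), while for this rebound-capable cell an
*inhibitory* pulse early in the cycle also advances it.  If the pulse
suppresses the following spike entirely within the simulation window
(4λ past the pulse), that phase is recorded as NaN and excluded from
population means with a warning.

Population mean PRCs average one PRC per **distinct** model, unweighted
(an abundance-weighted mode is available, since a drawn population may
contain the same model many times).  The two extracted features are the
mean shift at phase 0.3 and the sample variance (ddof = 1) of the
forward difference quotients computed at all but the last phase (99
quotients over 100 points).

## Problem sizes and determinism

Default workflow scale is 0.1 (1,000 PYR + 50 PV⁺) with 6–10 s
simulated time per network — sizes chosen so a full L/M/H triangle
sweep and the test suite run comfortably on a single laptop core; the
reference scale is available behind the `scale` argument.  The test
database uses a 3⁴ grid (81 models, ≈3 s to phenotype).  Every
stochastic stage (connectivity, drive noise, population draws) derives
from a single integer seed via `numpy.random.default_rng`; identical
config + seed reproduces rasters, databases and selections
bit-identically.  PRC phases are evaluated in independent
re-initialized runs, so shifts are invariant to evaluation order.

## Known limitations

* Output is spike times only — no field-potential proxy; comparisons to
  experimental LFP frequency/power are therefore structural, not
  quantitative.
* Single-compartment hybrid neurons: no dendrites, no conductance-based
  ion channels (PIR here is a recovery-variable effect, not an
  h-current model).
* Two cell classes only; no other interneuron types, no gap junctions.
* The synthetic drive is statistically stationary and spatially
  independent across cells; real afferent input is neither.
* Reduced-scale networks conserve expected synaptic input but have
  lumpier input statistics (fewer, stronger synapses), so quantitative
  frequencies/powers at 0.1 scale are not claims about the full-scale
  circuit; only the qualitative regime structure is asserted.
* The rheobase protocol's knife-edge sensitivity near threshold (see
  above) means its absolute value carries an intrinsic ±0.5 pA
  (one grid step) ambiguity across reasonable initialization
  conventions.
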