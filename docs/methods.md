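# Methods

## Network constructors

All fixed in-degree topologies enforce, exactly and per realization, that
every node receives `k_from_exc` edges from excitatory (E) nodes and
`k_from_inh` edges from inhibitory (I) nodes.  The defaults are
`n_exc = 4000`, `n_inh = 1000`, `k_from_exc = 800`, `k_from_inh = 200`,
chosen so the in-degree from each class equals 20% of that class's size;
the E and I in-degrees of I nodes are independent fields (`k_ie`, `k_ii`)
defaulting to the same constants.  Out-degrees are random with the correct
mean: an exact-out-degree ("doubly regular") construction is out of scope
because origin resampling during rewiring cannot preserve it.

**Ring lattice.**  E node *m* receives E edges from *m* ± 1 …
± `k_from_exc`/2 (indices mod `n_exc`); the I ring is built analogously.
For the cross-class blocks, with block size c = `n_exc`/`n_inh`, E node
*m* takes I origins ⌊m/c⌋ + j (j = −k/2 … k/2, j ≠ 0, mod `n_inh`) so that
contiguous blocks of c E nodes share identical I origin pools, and I node
*n* takes E origins c·n + j, so that E nodes with adjacent indices project
to I nodes with adjacent indices.  This is the symmetric reading of the
block construction; it makes every E–E lattice edge reciprocated and most
E–I edges reciprocated, which is what the class-recovery metric relies on.

**Rewiring.**  Each node independently becomes Class 2 with probability
`p2` (default 0.075); each remaining node becomes Class 3 with probability
`p3` (default 0.05).  Class 2 nodes receive new, uniformly drawn I origins
excluding self, duplicates and — crucially — all of the node's lattice I
origins.  Class 3 nodes have both E and I origins resampled; the
original-origin exclusion is applied there too by default
(`exclude_original_class3`), for symmetry with Class 2.  `p3` is a free
default: the rewired network's bistability analysis requires Class 3
nodes to exist but is insensitive to their exact fraction; 0.05 keeps them
a small minority comparable to Class 2.  In-degrees are bit-identical
before and after rewiring, which the test suite checks exhaustively.

**Embedded modular network.**  Bernoulli edges: within-module E→E with
probability `p_in`, between-module `p_out`, any edge touching an I node
`p_inh`.  Either (`p_in`, `p_out`) or (`mean_p_ee`, `ratio_ee`) may be
specified; the conversion uses the exact within-module pair fraction
(module_size−1)/(n_exc−1).  This is the one constructor without constant
in-degrees; its provenance records that, and validation skips the
in-degree invariant for it.

## Neuron and synapse model

Conductance-synapse leaky integrate-and-fire, voltages relative to rest:

    tau_m dV/dt = −V + Σ_k g_k(t) (V_rev,k − V),   k ∈ {ext, exc, inh}

| parameter | E | I | units |
|---|---|---|---|
| tau_m | 20 | 10 | ms |
| refractory | 2 | 1 | ms |
| threshold / reset | 18 / 11 | 18 / 11 | mV |
| V_rev (exc & ext / inh) | 70 / 0 | 70 / 0 | mV |

Synaptic kernels are differences of exponentials with onset latency
2 ms for every class; rise/decay times (ms): 0.4/2 for excitatory or
external input onto E, 0.25/5 for inhibitory onto E, 0.2/1 for excitatory
or external onto I, 0.25/5 for inhibitory onto I.  Dimensionless
efficacies (relative to leak): E→E 0.028, E→I 0.011, I→E 0.113, I→I
0.180, ext→E 0.008, ext→I 0.014.  Inhibition reverses at rest, i.e. it is
purely shunting at V = 0 and hyperpolarising above rest.

**Kernel prefactor.**  The efficacy table needs a convention for how J
scales the kernel g(t) ∝ e^(−t/τ_d) − e^(−t/τ_r).  `SynapseParams.prefactor`
offers four readings: `"parent"` (default) — the conductance cascade
inherits the prefactor of the current-based model family this one
descends from, amplitude A = J·τ_m(target)/(τ_d−τ_r), so the per-spike
conductance integral is τ_m·J; `"peak"` — J is the kernel's peak
conductance; `"charge"` — J is the per-spike conductance integral; and
`"raw"` — J multiplies the unnormalised difference.  The parent reading is
the default because it is the exact conductance translation of the
predecessor model's synaptic equations and it preserves the qualitative
ordering of the populations (inhibitory neurons respond first and fire
roughly an order of magnitude faster than excitatory ones).

**A documented limitation of this parameter set.**  With these efficacies
and a shunting inhibitory reversal, *no* uniform kernel prefactor yields a
stable sparse balanced state at ~1 spike/s (E) / ~4 spikes/s (I).  The
obstruction is structural: for E and I to ignite together as the external
drive rises, the prefactor must favour fast kernels (the external kernel
onto I rises in 0.2 ms vs 0.4 ms onto E), while for the fully saturated
state to be quenchable by inhibition it must favour slow kernels (the
inhibitory decay is 5 ms vs 2 ms excitatory); no monotone rule does both,
given that J_II/J_EI = 16.4 guarantees the inhibitory population
self-limits during runaway.  In practice the network passes directly from
a very sparse regime (E ≈ 10⁻³ spikes/s) to a refractory-limited saturated
state as the drive increases, and the saturated state, once entered, is
permanent.  Consequently this implementation reproduces the structural
results exactly (constant in-degrees, class recovery, motif statistics)
and the dynamical machinery faithfully (integrator accuracy, refractory
ceilings, detector behaviour), but *not* the reported balanced firing
rates or the sustained up/down switching of the rewired lattice; see the
calibration below for how the operating point was fixed.

## External drive and calibration

External input is an independent homogeneous Poisson train per neuron,
driving the Ext conductance with the excitatory reversal.  The intended
calibration target — mean E rate ≈ 1 spike/s in the default random
network — is unattainable (previous section), so the default rate was
fixed by the rule: *the largest rate on a 0.01 spikes/ms grid for which
the full-scale random network remains in the sparse regime for 5 s across
seeds 1–5*.  This gives `DEFAULT_EXT_RATE = 1.21` spikes/ms at full scale
and `SCALED_EXT_RATE = 1.29` for the scaled-down condition.  Both were
frozen once and are not tuned per experiment.  At this operating point the
full-scale random network fires at ≈ 7·10⁻⁴ (E) and 8·10⁻³ (I) spikes/s.

## Integration scheme

Fixed step dt = 0.05 ms.  Each current type keeps two exponential state
variables (decay and rise) updated exactly each step; arriving spikes
increment both by the edge amplitude after a circular delay buffer of
latency/dt slots.  The membrane uses exponential-Euler with conductances
frozen over the step; the decay factor e^(−dt(1+g_tot)/τ_m) is evaluated
by a 4th-order Taylor polynomial when the exponent is below 0.05 (error
< 10⁻⁹) and by the true exponential in high-conductance states.
Threshold crossings are evaluated at the end of the step, the spike time
recorded at the step boundary without interpolation; V is clamped at the
reset value for the refractory period while synaptic conductances continue
to integrate.  External Poisson counts per neuron-step are drawn by CDF
inversion from a precomputed table.  All state initialises to zero, and
the first 100 ms of every run are discarded from analyses (`burn_in`).

Recorded traces (membrane potential, per-type conductances) are sampled at
the start of each 1-ms bin; the LFP is accumulated at every step and
stored as 1-ms means.  An independent subthreshold oracle (RK4 at dt/50,
closed-form kernel evaluation, no shared code path) bounds the
integrator's single-PSP error below 1% at the peak.

## Up/down-state detection

Runs on the 1-ms LFP series, windows expressed in ms.  Pass 1 slides a
100-ms uniform mean with 1-sample stride; the baseline is the window with
the smallest mean, and samples whose window mean exceeds baseline mean +
k·SD (k = 3) are preliminary upstates.  Pass 2 refines each upstate's
boundaries with 5-ms sliding geometric means against the same threshold
(the LFP distribution is strongly right-skewed, so the geometric mean is
the robust local level estimate); a preliminary upstate with no
corresponding fine-scale component is dropped.  An epsilon of 10⁻¹² × the
trace maximum guards the log of exact zeros, and the same epsilon pads the
fine-pass threshold so an exactly-constant trace yields a single
downstate.  Upstates closer than `merge_gap` ms are merged when requested
(used by transition analyses; duration statistics use no merging).  The
first and last, boundary-censored, intervals are excluded from duration
statistics.  The detector is invariant under positive rescaling of the
trace, and raising k never increases total upstate time.

At the calibrated (very sparse) operating point, isolated single spikes
produce LFP transients that exceed the 3-SD criterion, so even the
deterministic lattice yields occasional few-ms "upstates"; with the
intended ~1 spike/s texture these transients would be part of the
baseline.  This is a direct corollary of the operating-point limitation
above, not a detector defect — on two-level synthetic traces the detector
recovers boundaries within one fine window.

## Neuron states, activity flags, functional in-degree

A neuron is *high* in a 1-ms bin if it spiked within the trailing 15 ms;
else *low* if its membrane potential is below the low-state threshold;
else *neutral*.  The low threshold is not hard-coded: it is derived as
mean − 2 SD of membrane potentials in a seed-matched random-network run
(`derive_low_threshold`) and recorded with the result.  *Highly active*
flags use strict thresholds of 4 spikes/s (E) and 30 spikes/s (I) over a
stated interval.  The functional in-degree of a node is its number of
incoming edges whose origin is flagged active (optionally restricted to
an origin class).

## Motif metrics

Reciprocal counts come from A ∘ Aᵀ row-summed over partner classes,
signed by parity: same-type pairs (0 or 2 inhibitory edges) are positive
feedback, mixed pairs negative.  Feed-forward-inhibition counts are
diag(A[E,:]ᵀ · A[E,I] · A[I,:]) (reference node = convergence target);
cycle counts diag(A[:,E] · A[E,S] · A[S,:]) with S = I (negative feedback)
or E (positive), so each 3-cycle credits every member whose outgoing
pattern matches.  All motif nodes are distinct (guaranteed by the empty
diagonal).  A brute-force enumerator over ordered node tuples, sharing no
code with the matrix forms, serves as the oracle in the tests.

Structural classes are recovered per physiological population by splitting
the integer histogram of total reciprocal counts at its two widest runs of
empty bins (leftmost on ties; boundary values join the lower stratum) and
ranking strata by descending count: Class 1 highest, Class 3 lowest.
Fewer than three strata (e.g. an unrewired lattice) returns the best
partition with a warning flag.

## Problem sizes and seeds

The test suite runs the scaled-down condition `n_exc = 800`,
`n_inh = 200`, in-degrees 160/40 (preserving the 20% rule) for simulation
tests, with durations from 0.5 s (unit tests) through 5.1 s (topology
contrasts) to 100 s (state-duration statistics); structural acceptance
checks (in-degree exactness, class recovery) run at full scale, where they
are exact per realization.  `scripts/acceptance.py` runs the full-scale
condition: a 100-s rewired-lattice simulation for state durations and a
5-s random-network simulation for baseline rates, about ten minutes on one
CPU in total.  One master seed expands through `numpy.random.SeedSequence`
into independent child seeds for topology, rewiring and simulation; every
artifact's manifest records them, and identical seeds reproduce rasters
bit for bit.

## What the synthetic conditions do and do not show

The generators produce the idealised study conditions: exactly constant
in-degrees, homogeneous neuron parameters within each physiological type,
and stationary independent Poisson drive.  Real cortical networks have
none of these exactly — degree heterogeneity, parameter spread, correlated
and non-stationary input.  Passing tests therefore demonstrate the
correctness of the constructions, metrics and integrator under the model's
own assumptions, not that the model captures any particular biological
recording.  The central known limitation — no stable ~1 spike/s balanced
regime under this efficacy table with any uniform kernel closure, hence no
sustained up/down alternation — is documented above and reflected honestly
in the acceptance quantities rather than patched by altering published
constants.
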