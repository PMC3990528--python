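# rewirenet

Tools for studying how *structurally-defined neuron classes* — groups of
neurons that differ only in their connectivity, not in their physiology —
shape balanced excitation and inhibition in spiking cortical network
models.

The package builds directed excitatory/inhibitory networks in which every
neuron has exactly the same number of incoming excitatory and inhibitory
synapses, simulates them as conductance-synapse leaky integrate-and-fire
(LIF) neurons, and analyses the resulting population dynamics and
connectivity structure:

* **Topologies** (`rewirenet.topology`) — a null-hypothesis random network
  with constant in-degrees; a deterministic forwards–backwards ring
  lattice; a *rewired* ring lattice in which randomly chosen nodes have
  the origins of their incoming inhibitory edges (Class 2) or all incoming
  edges (Class 3) resampled, leaving in-degrees untouched; and an embedded
  modular network with clustered excitatory modules.  Networks serialize
  to Matrix Market + TSV node tables.
* **Dynamics** (`rewirenet.dynamics`) — conductance LIF with
  difference-of-exponentials synaptic kernels, a global 2-ms onset
  latency, class-specific refractory periods and independent per-neuron
  Poisson external drive, integrated by exact exponential updates of the
  synaptic states and exponential-Euler for the membrane (dt = 0.05 ms,
  numba-accelerated).
* **Balance analysis** (`rewirenet.balance`) — a model LFP (sum of
  absolute synaptic currents into excitatory neurons), a two-pass
  up/downstate detector (100-ms coarse mean pass, 5-ms geometric-mean
  boundary refinement, baseline + 3 SD criterion), per-neuron
  high/neutral/low state classification, highly-active flags and
  *functional in-degrees* (in-degrees restricted to currently active
  origins).
* **Motifs** (`rewirenet.motifs`) — per-node signed participation counts
  for reciprocal pairs, feed-forward inhibition (E→x, E→I, I→x) and
  directed 3-cycles (x→E→I→x, x→E→E→x) via products of class-restricted
  sub-adjacency matrices, validated against a brute-force enumeration
  oracle, plus recovery of the structural classes from reciprocal-count
  histograms alone.
* **Experiments** (`rewirenet.experiments`) — seeded end-to-end runs with
  full provenance manifests, rewiring-probability sweeps and a fixture
  catalogue.

## The model

Each neuron's membrane potential V (mV relative to rest) follows

    tau_m dV/dt = -V + g_ext (V_E - V) + g_exc (V_E - V) + g_inh (V_I - V)

with V_E = 70 mV, V_I = 0 mV (inhibition is shunting at rest), threshold
18 mV, reset 11 mV, tau_m = 20 ms (E) / 10 ms (I) and refractory periods
2 ms (E) / 1 ms (I).  Each afferent spike, after a 2-ms latency, adds a
conductance transient A (e^(-t/tau_d) - e^(-t/tau_r)) with class-specific
rise/decay constants and amplitude A set by the edge-class efficacy (see
`docs/methods.md` for the kernel-normalisation choices and the calibration
of the external drive).  The model LFP is

    LFP(t) = sum over E neurons of |I_ext| + |I_exc| + |I_inh|.

## Worked example

```python
import numpy as np
from rewirenet import (SCALED_DOWN, RewireConfig, build_ring_lattice,
                       rewire_lattice, identify_structural_classes)
from rewirenet.motifs import ffi_counts, reciprocal_counts

lattice = build_ring_lattice(SCALED_DOWN)          # 800 E + 200 I neurons
net = rewire_lattice(lattice, RewireConfig(p2=0.075, p3=0.05, seed=7))

names = net.class_names()
print({c: int((names == c).sum()) for c in np.unique(names)})

same, diff = reciprocal_counts(net)
ffi = ffi_counts(net)
for c in ("E1", "E2", "E3"):
    m = names == c
    print(f"{c}: median reciprocal={int(np.median(same[m] + diff[m]))}, "
          f"median FFI={int(np.median(ffi[m]))}")

labels, ok = identify_structural_classes(net)
print("three strata found:", ok,
      "| recovery errors:", int((labels != net.struct_class).sum()))
```

prints

```
{'E1': 711, 'E2': 59, 'E3': 30, 'I1': 171, 'I2': 22, 'I3': 7}
E1: median reciprocal=192, median FFI=4546
E2: median reciprocal=154, median FFI=475
E3: median reciprocal=1, median FFI=1482
three strata found: True | recovery errors: 0
```

Reading the numbers: rewiring touched ~7.5% of nodes (Class 2) and ~5% of
the rest (Class 3).  Class 2 neurons keep their local excitatory
neighbourhood (high reciprocal counts, close to Class 1) but participate
in an order of magnitude fewer feed-forward-inhibition motifs — they are
excited locally yet receive only non-local inhibition.  The
reciprocal-count strata are cleanly separated, so the structural classes
are recovered from the adjacency matrix alone with zero errors.

A command-line interface mirrors the library:

```bash
rewirenet net-build --topology rewired --seed 7 --out net
rewirenet simulate --network net --seed 1 --duration 5100 --out run/
rewirenet analyze --lfp run/lfp.tsv --out run/
rewirenet motifs --network net --identify --out run/
```

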