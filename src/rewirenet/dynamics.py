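"""Conductance-synapse leaky integrate-and-fire network simulation.

The membrane potential of neuron *i* (measured relative to rest, so rest is
0 mV) obeys

    tau_m dV_i/dt = -V_i + I_ext,i(t) + I_exc,i(t) + I_inh,i(t)

with each current of type k given by a conductance times the driving force,
``I_k = g_k(t) (V_rev,k - V_i)``, where the dimensionless conductance
``g_k`` is a sum of difference-of-exponentials kernels triggered by
afferent spikes after a fixed onset latency (the kernel prefactor is a
configurable modelling choice; see :data:`PREFACTOR_MODES`).  When V crosses
threshold from below the neuron spikes, V is set to the reset value and
clamped there for the class refractory period (synaptic conductances keep
integrating during the clamp), and the spike is delivered to all
out-neighbours after the latency.  External input is an independent
homogeneous Poisson spike train per neuron, driving the Ext conductance
with the excitatory reversal potential.

Integration uses exact exponential updates of the two synaptic state
variables per current type and exponential-Euler for the membrane, both on
a fixed grid (default dt = 0.05 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numba
import numpy as np

from .topology import ConfigurationError, DirectedNetwork, E

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "SimConfig",
    "RecordConfig",
    "SimulationResult",
    "synaptic_kernel",
    "kernel_peak_time",
    "generate_external_spikes",
    "simulate",
    "subthreshold_oracle",
    "DEFAULT_EXT_RATE",
]


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters (mV relative to rest, ms)."""

    tau_m_exc: float = 20.0
    tau_m_inh: float = 10.0
    v_rev_exc: float = 70.0   # excitatory / external reversal
    v_rev_inh: float = 0.0    # inhibitory reversal (shunting at rest)
    refrac_exc: float = 2.0
    refrac_inh: float = 1.0
    v_thresh: float = 18.0
    v_reset: float = 11.0

    def validate(self) -> None:
        if not (self.v_reset < self.v_thresh < self.v_rev_exc):
            raise ConfigurationError("need v_reset < v_thresh < v_rev_exc")
        if min(self.refrac_exc, self.refrac_inh) <= 0:
            raise ConfigurationError("refractory times must be positive")
        if min(self.tau_m_exc, self.tau_m_inh) <= 0:
            raise ConfigurationError("membrane time constants must be positive")


#: How Table efficacies scale the difference-of-exponentials conductance
#: kernel.  The exact prefactor of the kernel is a modelling choice (see
#: docs/methods.md):
#:
#: * ``"parent"`` (default): the conductance inherits the parent
#:   current-based cascade's prefactor, g(t) = J tau_m/(tau_d - tau_r)
#:   (exp(-t/tau_d) - exp(-t/tau_r)), so the per-spike conductance
#:   integral is tau_m x J (tau_m of the target neuron).
#: * ``"peak"``: J is the peak conductance of the peak-normalised kernel.
#: * ``"charge"``: J is the per-spike conductance integral.
#: * ``"raw"``: J multiplies the unnormalised difference of exponentials.
PREFACTOR_MODES = ("parent", "peak", "charge", "raw")


@dataclass(frozen=True)
class SynapseParams:
    """Synaptic kernel parameters per edge class (ms; efficacies relative to leak).

    Rise/decay constants are shared by external and recurrent excitatory
    input onto a given target type.  ``prefactor`` selects the kernel
    normalisation the efficacies scale (see :data:`PREFACTOR_MODES`).
    """

    latency: float = 2.0
    prefactor: str = "parent"
    rise_exc_onto_e: float = 0.4
    rise_inh_onto_e: float = 0.25
    rise_exc_onto_i: float = 0.2
    rise_inh_onto_i: float = 0.25
    decay_exc_onto_e: float = 2.0
    decay_inh_onto_e: float = 5.0
    decay_exc_onto_i: float = 1.0
    decay_inh_onto_i: float = 5.0
    j_e2e: float = 0.028
    j_e2i: float = 0.011
    j_i2e: float = 0.113
    j_i2i: float = 0.180
    j_x2e: float = 0.008
    j_x2i: float = 0.014

    def validate(self) -> None:
        for tgt in ("e", "i"):
            for cur in ("exc", "inh"):
                r = getattr(self, f"rise_{cur}_onto_{tgt}")
                d = getattr(self, f"decay_{cur}_onto_{tgt}")
                if not 0.0 < r < d:
                    raise ConfigurationError(
                        f"need 0 < rise < decay for {cur}->{tgt} (got {r}, {d})")
        if self.latency < 0:
            raise ConfigurationError("latency must be >= 0")
        if min(self.j_e2e, self.j_e2i, self.j_i2e, self.j_i2i,
               self.j_x2e, self.j_x2i) < 0:
            raise ConfigurationError("efficacies must be >= 0")
        if self.prefactor not in PREFACTOR_MODES:
            raise ConfigurationError(
                f"prefactor must be one of {PREFACTOR_MODES}")

    def tau(self, current: str, target_is_exc: bool) -> tuple[float, float]:
        tgt = "e" if target_is_exc else "i"
        cur = "exc" if current in ("exc", "ext") else "inh"
        return (getattr(self, f"rise_{cur}_onto_{tgt}"),
                getattr(self, f"decay_{cur}_onto_{tgt}"))


#: Default external Poisson rate (spikes/ms per neuron), calibrated once on
#: the full-scale random network as the strongest drive that keeps it in
#: the sparse balanced regime across seeds; see docs/methods.md.
DEFAULT_EXT_RATE = 1.21

#: Calibrated external rate for the scaled-down condition (n_exc=800,
#: n_inh=200, in-degrees 160/40), obtained with the same rule.
SCALED_EXT_RATE = 1.29


@dataclass(frozen=True)
class RecordConfig:
    """What to record besides the spike raster and the 1-ms LFP series."""

    v_traces: bool = False
    conductance_traces: bool = False
    sample_dt: float = 1.0  # ms between trace samples

    def stride(self, dt: float) -> int:
        s = int(round(self.sample_dt / dt))
        if s < 1 or abs(s * dt - self.sample_dt) > 1e-9:
            raise ConfigurationError("sample_dt must be a multiple of dt")
        return s


@dataclass(frozen=True)
class SimConfig:
    """Simulation grid, duration and external drive."""

    dt: float = 0.05          # ms
    duration: float = 5100.0  # ms
    burn_in: float = 100.0    # ms discarded from analyses
    ext_rate: float = DEFAULT_EXT_RATE  # spikes/ms per neuron
    seed: int = 0
    record: RecordConfig = field(default_factory=RecordConfig)

    def validate(self, latency: float) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        steps = latency / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ConfigurationError("latency must be an integer multiple of dt")
        if not (self.duration > self.burn_in >= 0):
            raise ConfigurationError("need duration > burn_in >= 0")
        if self.ext_rate < 0:
            raise ConfigurationError("ext_rate must be >= 0")


class NumericalError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass
class SimulationResult:
    """Raster, optional traces and run metadata from one simulation.

    ``spike_times``/``spike_ids`` hold the raster in ms, sorted by time.
    ``lfp`` is the 1-ms sampled population signal (sum over E neurons of
    absolute synaptic currents, averaged within each ms).  Optional traces
    are sampled every ``trace_dt`` ms with shape ``(n_samples, n_nodes)``.
    """

    spike_times: np.ndarray
    spike_ids: np.ndarray
    lfp: np.ndarray
    lfp_dt: float
    trace_dt: Optional[float] = None
    trace_t: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None
    g_ext: Optional[np.ndarray] = None
    g_exc: Optional[np.ndarray] = None
    g_inh: Optional[np.ndarray] = None
    current_traces: Optional[dict] = None  # overrides derived currents if set
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.meta["n_nodes"]

    @property
    def duration(self) -> float:
        return self.meta["duration"]

    def spike_counts(self, t_start: float = None, t_stop: float = None) -> np.ndarray:
        """Per-node spike counts within [t_start, t_stop) (defaults: post burn-in)."""
        if t_start is None:
            t_start = self.meta.get("burn_in", 0.0)
        if t_stop is None:
            t_stop = self.duration
        sel = (self.spike_times >= t_start) & (self.spike_times < t_stop)
        return np.bincount(self.spike_ids[sel], minlength=self.n_nodes)

    def rates(self, t_start: float = None, t_stop: float = None) -> np.ndarray:
        """Per-node firing rates in spikes/s within the interval."""
        if t_start is None:
            t_start = self.meta.get("burn_in", 0.0)
        if t_stop is None:
            t_stop = self.duration
        if t_stop <= t_start:
            raise ValueError("zero-length interval")
        return self.spike_counts(t_start, t_stop) * 1000.0 / (t_stop - t_start)

    def currents(self) -> dict:
        """Per-node current traces {ext, exc, inh} derived from g and V."""
        if self.current_traces is not None:
            return self.current_traces
        if self.v is None or self.g_ext is None:
            raise ConfigurationError(
                "current traces unavailable: enable v_traces and "
                "conductance_traces recording")
        vre = self.meta.get("v_rev_exc", 70.0)
        vri = self.meta.get("v_rev_inh", 0.0)
        return {"ext": self.g_ext * (vre - self.v),
                "exc": self.g_exc * (vre - self.v),
                "inh": self.g_inh * (vri - self.v)}


# ---------------------------------------------------------------------------
# synaptic kernel
# ---------------------------------------------------------------------------

def kernel_peak_time(rise: float, decay: float, latency: float = 0.0) -> float:
    """Time of the kernel maximum: latency + rise*decay/(decay-rise)*ln(decay/rise)."""
    return latency + rise * decay / (decay - rise) * math.log(decay / rise)


def _kernel_norm(rise: float, decay: float) -> float:
    tp = kernel_peak_time(rise, decay)
    return math.exp(-tp / decay) - math.exp(-tp / rise)


def kernel_amplitude(j: float, rise: float, decay: float, tau_m: float,
                     mode: str) -> float:
    """Amplitude multiplying (exp(-t/tau_d) - exp(-t/tau_r)) for efficacy j."""
    if mode == "parent":
        return j * tau_m / (decay - rise)
    if mode == "peak":
        return j / _kernel_norm(rise, decay)
    if mode == "charge":
        return j / (decay - rise)
    if mode == "raw":
        return j
    raise ConfigurationError(f"unknown prefactor mode {mode!r}")


def synaptic_kernel(t, rise: float, decay: float, latency: float = 2.0):
    """Peak-normalised difference-of-exponentials conductance kernel.

    Zero for ``t <= latency``; for later times
    ``(exp(-(t-latency)/decay) - exp(-(t-latency)/rise)) / norm`` with the
    normalisation chosen so the maximum over t equals 1.
    """
    if not 0.0 < rise < decay:
        raise ConfigurationError("need 0 < rise < decay")
    t = np.asarray(t, dtype=float)
    s = t - latency
    out = np.where(s > 0,
                   np.exp(-np.maximum(s, 0.0) / decay)
                   - np.exp(-np.maximum(s, 0.0) / rise), 0.0)
    out = out / _kernel_norm(rise, decay)
    return out if out.shape else float(out)


def generate_external_spikes(config: SimConfig, n_nodes: int) -> list[np.ndarray]:
    """Independent homogeneous Poisson spike-time lists per node (ms)."""
    if config.ext_rate < 0:
        raise ConfigurationError("ext_rate must be >= 0")
    rng = np.random.default_rng(config.seed)
    out = []
    for _ in range(n_nodes):
        n = rng.poisson(config.ext_rate * config.duration)
        out.append(np.sort(rng.random(n) * config.duration))
    return out


# ---------------------------------------------------------------------------
# main integrator (numba)
# ---------------------------------------------------------------------------

@numba.njit(cache=True, fastmath=True)
def _run_kernel(n_steps, dt, n, is_exc,
                indptr, indices, w_edge, edge_is_inh,
                dec_d_ext, dec_r_ext, dec_d_exc, dec_r_exc,
                dec_d_inh, dec_r_inh,
                w_ext, tau_m, refrac_steps,
                v_thresh, v_reset, v_rev_exc,
                delay_steps, ext_cdf, seed,
                lfp_stride, lfp_out,
                rec_stride, v_out, gx_out, ge_out, gi_out, v_init):
    """Fixed-step network integration; returns (spike_steps, spike_ids)."""
    np.random.seed(seed)
    v = v_init.copy()
    ed_ext = np.zeros(n)
    er_ext = np.zeros(n)
    ed_exc = np.zeros(n)
    er_exc = np.zeros(n)
    ed_inh = np.zeros(n)
    er_inh = np.zeros(n)
    refrac_until = np.full(n, -1, np.int64)

    nslots = delay_steps + 1
    pend_exc = np.zeros((nslots, n))
    pend_inh = np.zeros((nslots, n))

    cap = 1 << 16
    sp_step = np.empty(cap, np.int64)
    sp_id = np.empty(cap, np.int64)
    nsp = 0

    ncdf = ext_cdf.shape[0]
    record = rec_stride > 0

    for s in range(n_steps):
        slot = s % nslots
        lfp_bin = s // lfp_stride
        lfp_acc = 0.0
        for i in range(n):
            # record state as of the start of this step (t = s*dt)
            if record and s % rec_stride == 0:
                r = s // rec_stride
                if v_out.shape[0] > 0:
                    v_out[r, i] = v[i]
                if gx_out.shape[0] > 0:
                    gx_out[r, i] = ed_ext[i] - er_ext[i]
                    ge_out[r, i] = ed_exc[i] - er_exc[i]
                    gi_out[r, i] = ed_inh[i] - er_inh[i]
            # external Poisson arrivals this step (inversion on fixed CDF)
            u = np.random.random()
            k = 0
            while k < ncdf and u > ext_cdf[k]:
                k += 1
            if k > 0:
                inc = w_ext[i] * k
                ed_ext[i] += inc
                er_ext[i] += inc
            # delayed recurrent arrivals
            pe = pend_exc[slot, i]
            if pe != 0.0:
                ed_exc[i] += pe
                er_exc[i] += pe
                pend_exc[slot, i] = 0.0
            pi = pend_inh[slot, i]
            if pi != 0.0:
                ed_inh[i] += pi
                er_inh[i] += pi
                pend_inh[slot, i] = 0.0
            # exact exponential decay of synaptic states
            ed_ext[i] *= dec_d_ext[i]
            er_ext[i] *= dec_r_ext[i]
            ed_exc[i] *= dec_d_exc[i]
            er_exc[i] *= dec_r_exc[i]
            ed_inh[i] *= dec_d_inh[i]
            er_inh[i] *= dec_r_inh[i]
            g_ext = ed_ext[i] - er_ext[i]
            g_exc = ed_exc[i] - er_exc[i]
            g_inh = ed_inh[i] - er_inh[i]

            if s < refrac_until[i]:
                v[i] = v_reset
            else:
                g_tot = g_ext + g_exc + g_inh
                denom = 1.0 + g_tot
                v_inf = (g_ext + g_exc) * v_rev_exc / denom
                # exponential-Euler factor; 4th-order Taylor where it is
                # accurate to <1e-9, true exp in high-conductance states
                x = dt * denom / tau_m[i]
                if x < 0.05:
                    f = 1.0 - x * (1.0 - 0.5 * x * (1.0 - x / 3.0 * (1.0 - 0.25 * x)))
                else:
                    f = np.exp(-x)
                vi = v_inf + (v[i] - v_inf) * f
                if vi >= v_thresh:
                    # spike: reset, clamp, deliver after the latency
                    v[i] = v_reset
                    refrac_until[i] = s + 1 + refrac_steps[i]
                    if nsp >= cap:
                        cap *= 2
                        tmp1 = np.empty(cap, np.int64)
                        tmp1[:nsp] = sp_step
                        sp_step = tmp1
                        tmp2 = np.empty(cap, np.int64)
                        tmp2[:nsp] = sp_id
                        sp_id = tmp2
                    sp_step[nsp] = s
                    sp_id[nsp] = i
                    nsp += 1
                    dslot = (s + delay_steps) % nslots
                    if edge_is_inh[i]:
                        for e in range(indptr[i], indptr[i + 1]):
                            pend_inh[dslot, indices[e]] += w_edge[e]
                    else:
                        for e in range(indptr[i], indptr[i + 1]):
                            pend_exc[dslot, indices[e]] += w_edge[e]
                else:
                    v[i] = vi

            if is_exc[i]:
                cur = (g_ext + g_exc) * (v_rev_exc - v[i])
                if cur < 0.0:
                    cur = -cur
                ci = g_inh * v[i]
                if ci < 0.0:
                    ci = -ci
                lfp_acc += cur + ci

        lfp_out[lfp_bin] += lfp_acc / lfp_stride
        if not np.isfinite(lfp_acc):
            return sp_step[:nsp], sp_id[:nsp], s, 1
    return sp_step[:nsp], sp_id[:nsp], n_steps, 0


def _poisson_cdf(mean: float) -> np.ndarray:
    """CDF of spike counts per step; entry k = P(N <= k)."""
    if mean <= 0:
        return np.array([1.0])
    kmax = max(8, int(mean + 10.0 * math.sqrt(mean) + 10))
    pmf = np.empty(kmax + 1)
    pmf[0] = math.exp(-mean)
    for k in range(1, kmax + 1):
        pmf[k] = pmf[k - 1] * mean / k
    return np.minimum(np.cumsum(pmf), 1.0)


def simulate(net: DirectedNetwork, npar: NeuronParams = None,
             spar: SynapseParams = None, sc: SimConfig = None,
             _v_init: Optional[np.ndarray] = None) -> SimulationResult:
    """Simulate the conductance LIF network; see the module docstring.

    All state is initialised to zero.  Returns the raster, the 1-ms LFP
    series and any requested traces.
    """
    npar = npar or NeuronParams()
    spar = spar or SynapseParams()
    sc = sc or SimConfig()
    npar.validate()
    spar.validate()
    sc.validate(spar.latency)

    n = net.n_nodes
    is_exc = net.exc_mask
    dt = sc.dt
    n_steps = int(round(sc.duration / dt))
    delay_steps = int(round(spar.latency / dt))

    # per-edge kernel amplitude for the edge class (depends on efficacy,
    # kernel time constants and, in the parent mode, the target's tau_m)
    out_csr = net.adjacency.tocsr()
    indptr = out_csr.indptr.astype(np.int64)
    indices = out_csr.indices.astype(np.int64)
    j_tab = np.array([[spar.j_e2e, spar.j_e2i], [spar.j_i2e, spar.j_i2i]])
    tau_m_of = (npar.tau_m_exc, npar.tau_m_inh)
    amp_tab = np.empty((2, 2))
    for src in (0, 1):
        for tgt in (0, 1):
            r, d = spar.tau("exc" if src == 0 else "inh", tgt == 0)
            amp_tab[src, tgt] = kernel_amplitude(
                j_tab[src, tgt], r, d, tau_m_of[tgt], spar.prefactor)
    src_of_edge = np.repeat(np.arange(n), np.diff(indptr))
    src_ei = net.ei_label[src_of_edge].astype(np.int64)
    tgt_ei = net.ei_label[indices].astype(np.int64)
    w_edge = amp_tab[src_ei, tgt_ei]

    ei = net.ei_label.astype(np.int64)
    w_ext = np.array([
        kernel_amplitude(spar.j_x2e, *spar.tau("ext", True),
                         npar.tau_m_exc, spar.prefactor),
        kernel_amplitude(spar.j_x2i, *spar.tau("ext", False),
                         npar.tau_m_inh, spar.prefactor)])[ei]

    def _dec(cur, tau_attr):
        taus = np.array([spar.tau(cur, True), spar.tau(cur, False)])
        idx = 0 if tau_attr == "rise" else 1
        return np.exp(-dt / taus[ei, idx])

    dec_r_ext = _dec("ext", "rise")
    dec_d_ext = _dec("ext", "decay")
    dec_r_inh = _dec("inh", "rise")
    dec_d_inh = _dec("inh", "decay")

    tau_m = np.where(is_exc, npar.tau_m_exc, npar.tau_m_inh).astype(float)
    refrac_steps = np.where(is_exc,
                            int(round(npar.refrac_exc / dt)),
                            int(round(npar.refrac_inh / dt))).astype(np.int64)

    lfp_stride = max(1, int(round(1.0 / dt)))
    n_lfp = -(-n_steps // lfp_stride)
    lfp_out = np.zeros(n_lfp)

    rec = sc.record
    rec_stride = rec.stride(dt) if (rec.v_traces or rec.conductance_traces) else 0
    n_rec = -(-n_steps // rec_stride) if rec_stride else 0
    v_out = np.zeros((n_rec if rec.v_traces else 0, n))
    gx_out = np.zeros((n_rec if rec.conductance_traces else 0, n))
    ge_out = np.zeros_like(gx_out)
    gi_out = np.zeros_like(gx_out)

    ext_cdf = _poisson_cdf(sc.ext_rate * dt)
    seed = int(sc.seed) % (2 ** 31)

    sp_step, sp_id, stop_step, bad = _run_kernel(
        n_steps, dt, n, is_exc.astype(np.uint8),
        indptr, indices, w_edge, (ei == 1).astype(np.uint8),
        dec_d_ext, dec_r_ext, dec_d_ext.copy(), dec_r_ext.copy(),
        dec_d_inh, dec_r_inh,
        w_ext, tau_m, refrac_steps,
        npar.v_thresh, npar.v_reset, npar.v_rev_exc,
        delay_steps, ext_cdf, seed,
        lfp_stride, lfp_out,
        rec_stride, v_out, gx_out, ge_out, gi_out,
        np.zeros(n) if _v_init is None else np.asarray(_v_init, dtype=float))
    if bad:
        raise NumericalError(f"non-finite state at t = {stop_step * dt:.3f} ms")

    meta = {"n_nodes": n, "dt": dt, "duration": sc.duration,
            "burn_in": sc.burn_in, "ext_rate": sc.ext_rate, "seed": sc.seed,
            "v_rev_exc": npar.v_rev_exc, "v_rev_inh": npar.v_rev_inh,
            "topology": net.provenance.get("topology", "unknown")}
    trace_t = np.arange(n_rec) * rec.sample_dt if rec_stride else None
    return SimulationResult(
        spike_times=sp_step * dt, spike_ids=sp_id.astype(np.int64),
        lfp=lfp_out, lfp_dt=lfp_stride * dt,
        trace_dt=rec.sample_dt if rec_stride else None, trace_t=trace_t,
        v=v_out if rec.v_traces else None,
        g_ext=gx_out if rec.conductance_traces else None,
        g_exc=ge_out if rec.conductance_traces else None,
        g_inh=gi_out if rec.conductance_traces else None,
        meta=meta)


# ---------------------------------------------------------------------------
# independent fine-step oracle for subthreshold dynamics
# ---------------------------------------------------------------------------

def subthreshold_oracle(npar: NeuronParams, input_spikes, edge_class: str,
                        duration: float, dt: float = 0.05, v0: float = 0.0,
                        spar: SynapseParams = None, refine: int = 50,
                        freeze_v: Optional[float] = None) -> np.ndarray:
    """Integrate one neuron's subthreshold response with RK4 at ``dt/refine``.

    ``edge_class`` is one of 'e2e', 'i2e', 'e2i', 'i2i', 'x2e', 'x2i';
    ``input_spikes`` are presynaptic spike times (ms).  The conductance is
    evaluated in closed form from the kernel, so this integrator shares no
    code path with the main simulator.  With ``freeze_v`` set, the driving
    force is held at that voltage (linearity checks).  Returns V at the
    coarse grid times ``0, dt, ..., duration``.
    """
    spar = spar or SynapseParams()
    src, tgt = edge_class.split("2")
    target_is_exc = tgt == "e"
    rise, decay = spar.tau("exc" if src in "ex" else "inh", target_is_exc)
    j = getattr(spar, f"j_{edge_class}")
    v_rev = npar.v_rev_exc if src in "ex" else npar.v_rev_inh
    tau = npar.tau_m_exc if target_is_exc else npar.tau_m_inh
    amp = kernel_amplitude(j, rise, decay, tau, spar.prefactor)
    spikes = np.asarray(input_spikes, dtype=float)

    def g(t):
        s = t - spikes - spar.latency
        s = s[s > 0]
        if not s.size:
            return 0.0
        return amp * np.sum(np.exp(-s / decay) - np.exp(-s / rise))

    def dv(t, v):
        drive = (v_rev - (freeze_v if freeze_v is not None else v))
        return (-v + g(t) * drive) / tau

    h = dt / refine
    n_coarse = int(round(duration / dt))
    out = np.empty(n_coarse + 1)
    v = v0
    out[0] = v
    t = 0.0
    for c in range(n_coarse):
        for _ in range(refine):
            k1 = dv(t, v)
            k2 = dv(t + h / 2, v + h / 2 * k1)
            k3 = dv(t + h / 2, v + h / 2 * k2)
            k4 = dv(t + h, v + h * k3)
            v = v + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[c + 1] = v
    return out
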