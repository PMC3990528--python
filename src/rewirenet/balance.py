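"""Balance analysis: model LFP, network up/down states, per-neuron states.

The population signal ("LFP") is the sum over excitatory neurons of the
absolute values of their synaptic currents (external, recurrent excitatory
and inhibitory), up to a proportionality constant.  Network-level balance
is assessed by a two-pass detector that segments the LFP into *upstates*
(epochs of elevated population activity) and *downstates*; neuron-level
balance by classifying each neuron at each time point as *high* (spiked
within a trailing window), *low* (membrane potential below a threshold) or
*neutral*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .topology import ConfigurationError, DirectedNetwork
from .dynamics import SimulationResult

__all__ = [
    "LfpTrace",
    "StateIntervals",
    "NeuronStateSeries",
    "ActivityThresholds",
    "compute_lfp",
    "detect_up_down_states",
    "classify_neuron_states",
    "derive_low_threshold",
    "classify_highly_active",
    "functional_in_degree",
    "class_rate_and_conductance_summary",
]

HIGH, NEUTRAL, LOW = 2, 1, 0  # neuron-state codes


@dataclass
class LfpTrace:
    """Nonnegative population signal sampled every ``dt_sample`` ms."""

    values: np.ndarray
    dt_sample: float
    constant: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ConfigurationError("LFP must be a 1-D series")
        if (self.values < 0).any():
            raise ConfigurationError("LFP values must be nonnegative")

    @property
    def duration(self) -> float:
        return len(self.values) * self.dt_sample

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(len(self.values)) * self.dt_sample
        return pd.DataFrame({"time_ms": t, "lfp": self.values})


@dataclass
class StateIntervals:
    """Alternating up/down intervals tiling the analysed window.

    ``intervals`` has columns state ('up'/'down'), start_ms, end_ms,
    duration_ms, geo_mean and censored (True for the first/last partial
    intervals, which are excluded from duration statistics).
    """

    intervals: pd.DataFrame
    threshold: float
    baseline_mean: float
    baseline_sd: float

    def _full(self, state: str) -> pd.DataFrame:
        df = self.intervals
        return df[(df["state"] == state) & ~df["censored"]]

    @property
    def n_switches(self) -> int:
        """Number of up<->down transitions in the analysed window."""
        return max(len(self.intervals) - 1, 0)

    def durations(self, state: str) -> np.ndarray:
        return self._full(state)["duration_ms"].to_numpy()

    def mean_duration(self, state: str) -> float:
        d = self.durations(state)
        return float(d.mean()) if d.size else float("nan")

    def summary(self) -> pd.DataFrame:
        rows = []
        for state in ("down", "up"):
            d = self.durations(state)
            rows.append({
                "state": state, "n": len(d),
                "mean_duration_ms": d.mean() if d.size else np.nan,
                "max_duration_ms": d.max() if d.size else np.nan,
                "mean_geo_lfp": self._full(state)["geo_mean"].mean()
                if len(self._full(state)) else np.nan,
            })
        return pd.DataFrame(rows)


@dataclass
class NeuronStateSeries:
    """Per-node, per-bin high/neutral/low labels.

    ``labels`` has shape ``(n_bins, n_nodes)`` with codes HIGH/NEUTRAL/LOW;
    bins are ``dt_bin`` ms wide starting at ``t_start``.
    """

    labels: np.ndarray
    dt_bin: float
    t_start: float
    low_v_threshold: float
    high_window: float

    def occupancy(self, node_mask: Optional[np.ndarray] = None) -> dict:
        lab = self.labels if node_mask is None else self.labels[:, node_mask]
        n = lab.size or 1
        return {"high": float((lab == HIGH).sum()) / n,
                "neutral": float((lab == NEUTRAL).sum()) / n,
                "low": float((lab == LOW).sum()) / n}


@dataclass(frozen=True)
class ActivityThresholds:
    """Rates (spikes/s) above which a neuron counts as highly active."""

    highly_active_exc: float = 4.0
    highly_active_inh: float = 30.0

    def __post_init__(self):
        if min(self.highly_active_exc, self.highly_active_inh) <= 0:
            raise ConfigurationError("activity thresholds must be positive")


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def compute_lfp(result: SimulationResult, exc_mask: Optional[np.ndarray] = None,
                constant: float = 1.0) -> LfpTrace:
    """Population LFP: constant x sum over E neurons of |I_ext|+|I_exc|+|I_inh|.

    If per-neuron current traces are available (recorded, or injected via
    ``result.current_traces``) they are summed directly, restricted to
    ``exc_mask`` when given.  Otherwise the simulator's internally
    accumulated 1-ms LFP series is used.
    """
    have_traces = result.current_traces is not None or (
        result.v is not None and result.g_ext is not None)
    if have_traces:
        cur = result.currents()
        total = sum(np.abs(cur[k]) for k in ("ext", "exc", "inh"))
        if exc_mask is not None:
            total = total[:, np.asarray(exc_mask, bool)]
        return LfpTrace(constant * total.sum(axis=1),
                        result.trace_dt or result.lfp_dt, constant)
    if result.lfp is not None and len(result.lfp):
        return LfpTrace(constant * result.lfp, result.lfp_dt, constant)
    raise ConfigurationError(
        "no current traces recorded and no accumulated LFP available")


# ---------------------------------------------------------------------------
# Method 1: network up/down states from the LFP
# ---------------------------------------------------------------------------

def _sliding_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Means of all length-w windows (length len(x)-w+1)."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[w:] - c[:-w]) / w


def detect_up_down_states(lfp: LfpTrace, coarse_window: float = 100.0,
                          fine_window: float = 5.0, k_sd: float = 3.0,
                          t_start: float = 0.0,
                          merge_gap: Optional[float] = None) -> StateIntervals:
    """Two-pass up/down-state detection on a nonnegative LFP series.

    Pass 1: the series is smoothed with a sliding ``coarse_window``-ms
    uniform kernel; the window with the smallest mean defines the baseline,
    and samples whose window mean exceeds ``baseline mean + k_sd x baseline
    SD`` form preliminary upstates.  Pass 2 refines each upstate's
    boundaries with a ``fine_window``-ms sliding *geometric* mean compared
    against the same criterion (the LFP distribution is strongly positively
    skewed).  Upstates separated by less than ``merge_gap`` ms are merged
    when it is given.  Emits alternating intervals with durations and the
    geometric-mean LFP of each interval; the censored first/last intervals
    are excluded from duration statistics.
    """
    x = lfp.values[int(round(t_start / lfp.dt_sample)):]
    dt = lfp.dt_sample
    wc = max(int(round(coarse_window / dt)), 1)
    wf = max(int(round(fine_window / dt)), 1)
    n = len(x)
    if n <= wc:
        raise ConfigurationError("trace must be longer than the coarse window")

    coarse = _sliding_mean(x, wc)
    b0 = int(np.argmin(coarse))
    base = x[b0:b0 + wc]
    mu, sd = float(base.mean()), float(base.std())
    thr = mu + k_sd * sd

    # center window means on samples; edges take the nearest valid window
    half = wc // 2
    idx = np.clip(np.arange(n) - half, 0, n - wc)
    prelim = coarse[idx] > thr

    # pass 2: sliding geometric means (epsilon guards exact zeros)
    eps = 1e-12 * max(float(x.max()), 1.0)
    geo = np.exp(_sliding_mean(np.log(x + eps), wf))
    halff = wf // 2
    idxf = np.clip(np.arange(n) - halff, 0, n - wf)
    # the epsilon keeps an exactly-constant baseline (sd = 0) subthreshold
    fine_up = geo[idxf] > thr + 2 * eps

    up = np.zeros(n, dtype=bool)
    for s, e in _runs(prelim):
        # refine boundaries: the fine-scale component overlapping [s, e)
        comp = _overlapping_run(fine_up, s, e)
        if comp is not None:
            up[comp[0]:comp[1]] = True

    if merge_gap is not None:
        gap = int(round(merge_gap / dt))
        runs = _runs(up)
        for (s1, e1), (s2, e2) in zip(runs[:-1], runs[1:]):
            if s2 - e1 < gap:
                up[e1:s2] = True

    rows = []
    bounds = [0]
    flips = np.flatnonzero(np.diff(up.astype(np.int8))) + 1
    bounds.extend(flips.tolist())
    bounds.append(n)
    for i, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
        seg = x[s:e]
        rows.append({
            "state": "up" if up[s] else "down",
            "start_ms": t_start + s * dt, "end_ms": t_start + e * dt,
            "duration_ms": (e - s) * dt,
            "geo_mean": float(np.exp(np.log(seg + eps).mean())),
            "censored": i == 0 or e == n,
        })
    df = pd.DataFrame(rows)
    return StateIntervals(df, threshold=thr, baseline_mean=mu, baseline_sd=sd)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [len(mask)]])
    return list(zip(starts.tolist(), ends.tolist()))


def _overlapping_run(mask: np.ndarray, s: int, e: int):
    """The True run in ``mask`` overlapping [s, e), spanning all such runs."""
    best = None
    for rs, re in _runs(mask):
        if rs < e and re > s:
            best = (rs, re) if best is None else (min(best[0], rs),
                                                  max(best[1], re))
    return best


# ---------------------------------------------------------------------------
# Method 2: per-neuron high / neutral / low states
# ---------------------------------------------------------------------------

def derive_low_threshold(result: SimulationResult, n_sd: float = 2.0) -> float:
    """Low-state voltage threshold: mean - n_sd x SD of membrane potentials.

    Intended to be measured on a seed-matched random-network run, following
    the definition of the low state as a membrane potential significantly
    below what a random network exhibits.
    """
    if result.v is None:
        raise ConfigurationError("membrane traces not recorded")
    t0 = int(round(result.meta.get("burn_in", 0.0) / result.trace_dt))
    v = result.v[t0:]
    return float(v.mean() - n_sd * v.std())


def classify_neuron_states(result: SimulationResult, low_v_threshold: float,
                           high_window: float = 15.0,
                           t_start: Optional[float] = None) -> NeuronStateSeries:
    """Label each neuron per bin: high > low > neutral precedence.

    A neuron is *high* in a bin if it spiked at least once within the
    trailing ``high_window`` ms, else *low* if its membrane potential is
    below ``low_v_threshold``, else *neutral*.  Bins are the membrane-trace
    samples.
    """
    if result.v is None:
        raise ConfigurationError("membrane traces not recorded")
    dt = result.trace_dt
    if t_start is None:
        t_start = result.meta.get("burn_in", 0.0)
    s0 = int(round(t_start / dt))
    v = result.v[s0:]
    n_bins, n_nodes = v.shape

    labels = np.full((n_bins, n_nodes), NEUTRAL, dtype=np.int8)
    labels[v < low_v_threshold] = LOW

    # trailing-window spike indicator: bin spikes, then a windowed
    # difference of cumulative counts per node
    times = result.spike_times
    ids = result.spike_ids
    w = int(round(high_window / dt))
    sel = (times > t_start - high_window) & (times <= t_start + (n_bins - 1) * dt)
    # spike at time t affects bins with t in (t_bin - window, t_bin]
    b_idx = np.ceil((times[sel] - t_start) / dt).astype(np.int64)
    counts = np.zeros((n_bins + w + 1, n_nodes), dtype=np.int32)
    np.add.at(counts, (np.clip(b_idx, -w, n_bins - 1) + w, ids[sel]), 1)
    cum = np.cumsum(counts, axis=0)
    # bin b (offset w in cum coords): spikes in bins (b-w, b]
    recent = cum[w:w + n_bins] - cum[:n_bins]
    labels[recent > 0] = HIGH
    return NeuronStateSeries(labels, dt, t_start, low_v_threshold, high_window)


# ---------------------------------------------------------------------------
# highly active neurons and functional in-degree
# ---------------------------------------------------------------------------

def classify_highly_active(result: SimulationResult, interval: tuple[float, float],
                           ei_label: np.ndarray,
                           thresholds: ActivityThresholds = ActivityThresholds(),
                           ) -> np.ndarray:
    """Flag neurons whose rate in ``interval`` strictly exceeds the class threshold."""
    t0, t1 = interval
    if t1 <= t0:
        raise ConfigurationError("zero-length interval")
    rates = result.rates(t0, t1)
    thr = np.where(np.asarray(ei_label) == 0,
                   thresholds.highly_active_exc, thresholds.highly_active_inh)
    return rates > thr


def functional_in_degree(net: DirectedNetwork, active_flags: np.ndarray,
                         origin_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Per node, incoming edges whose origin is active (and in ``origin_mask``).

    ``origin_mask`` restricts origins to a class of interest (e.g. the
    ground-truth Class E2 nodes); by default all active origins count.
    """
    flags = np.asarray(active_flags, dtype=bool)
    if flags.shape != (net.n_nodes,):
        raise ConfigurationError("active_flags length mismatch")
    sel = flags if origin_mask is None else flags & np.asarray(origin_mask, bool)
    return net.in_degrees(origin_mask=sel)


def class_rate_and_conductance_summary(result: SimulationResult,
                                       net: DirectedNetwork,
                                       interval: Optional[tuple[float, float]] = None,
                                       states: Optional[NeuronStateSeries] = None,
                                       ) -> pd.DataFrame:
    """Per structural class: mean rate, mean conductances, state occupancy.

    Rows cover the populated classes among E1..I3 over ``interval``
    (default: burn-in to end).  Conductance columns are present only when
    conductance traces were recorded; occupancy columns only when a
    ``NeuronStateSeries`` is supplied.
    """
    if interval is None:
        interval = (result.meta.get("burn_in", 0.0), result.duration)
    t0, t1 = interval
    rates = result.rates(t0, t1)
    names = net.class_names()
    rows = []
    for cname in ("E1", "E2", "E3", "I1", "I2", "I3"):
        mask = names == cname
        if not mask.any():
            continue
        row = {"class": cname, "n": int(mask.sum()),
               "mean_rate": float(rates[mask].mean())}
        if result.g_exc is not None:
            s0 = int(round(t0 / result.trace_dt))
            s1 = int(round(t1 / result.trace_dt))
            row["mean_g_exc"] = float(result.g_exc[s0:s1, mask].mean())
            row["mean_g_inh"] = float(result.g_inh[s0:s1, mask].mean())
        if states is not None:
            occ = states.occupancy(mask)
            row.update({f"frac_{k}": v for k, v in occ.items()})
        rows.append(row)
    return pd.DataFrame(rows)
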