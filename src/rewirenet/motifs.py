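"""Per-node signed motif participation counts and structural-class recovery.

Counts of small connectivity patterns (2-3 nodes) in which each node
participates, computed from products of class-restricted sub-adjacency
matrices, with a brute-force enumeration oracle for validation.  Motifs are
signed by feedback parity: a pattern with an even number of inhibitory
edges (including none) is positive feedback, an odd number negative.

The reciprocal-count histograms recover the structural classes created by
lattice rewiring: Class 2 nodes lose the reciprocity of their incoming
inhibitory edges and Class 3 of all incoming edges, so the per-population
histograms separate into distinct strata.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .topology import DirectedNetwork, E, I

__all__ = [
    "MotifSpec",
    "MotifCounts",
    "reciprocal_counts",
    "ffi_counts",
    "cycle_counts",
    "brute_force_motif_counts",
    "identify_structural_classes",
    "FFI_SPEC",
    "CYCLE_EEI_SPEC",
    "CYCLE_EEE_SPEC",
    "counts_frame",
]


@dataclass(frozen=True)
class MotifSpec:
    """A small directed pattern with a distinguished reference role 'x'.

    ``edges`` are (origin_role, target_role) pairs; ``classes`` maps each
    non-reference role to 0 (E) or 1 (I); the reference node may be any
    class unless listed.  The feedback sign of a match is the parity of
    its edges that originate at inhibitory nodes.
    """

    name: str
    edges: tuple[tuple[str, str], ...]
    classes: dict  # role -> 0/1, may omit 'x'

    @property
    def roles(self) -> tuple[str, ...]:
        rs = []
        for a, b in self.edges:
            for r in (a, b):
                if r not in rs:
                    rs.append(r)
        return tuple(rs)


#: Feed-forward inhibition converging on x: E->x, E->I, I->x.
FFI_SPEC = MotifSpec("ffi", (("a", "x"), ("a", "b"), ("b", "x")),
                     {"a": E, "b": I})
#: Negative-feedback 3-cycle from x: x->E->I->x.
CYCLE_EEI_SPEC = MotifSpec("cycle_eei", (("x", "a"), ("a", "b"), ("b", "x")),
                           {"a": E, "b": I})
#: All-excitatory positive-feedback 3-cycle: x->E->E->x.
CYCLE_EEE_SPEC = MotifSpec("cycle_eee", (("x", "a"), ("a", "b"), ("b", "x")),
                           {"a": E, "b": E})


@dataclass
class MotifCounts:
    """Per-node participation counts for the standard motif families."""

    reciprocal_positive: np.ndarray
    reciprocal_negative: np.ndarray
    ffi: np.ndarray
    cycle_eei: np.ndarray
    cycle_eee: np.ndarray

    def to_frame(self, net: DirectedNetwork) -> pd.DataFrame:
        return counts_frame(net, {
            "reciprocal_positive": self.reciprocal_positive,
            "reciprocal_negative": self.reciprocal_negative,
            "ffi": self.ffi,
            "cycle_eei": self.cycle_eei,
            "cycle_eee": self.cycle_eee,
        })


def counts_frame(net: DirectedNetwork, families: dict) -> pd.DataFrame:
    """Long-form node_id / ei_label / family / count table."""
    ei = np.array(["E", "I"])[net.ei_label]
    frames = [pd.DataFrame({"node_id": np.arange(net.n_nodes), "ei_label": ei,
                            "family": name, "count": counts})
              for name, counts in families.items()]
    return pd.concat(frames, ignore_index=True)


def all_motif_counts(net: DirectedNetwork) -> MotifCounts:
    rp, rn = reciprocal_counts(net)
    return MotifCounts(rp, rn, ffi_counts(net),
                       cycle_counts(net, "eei"), cycle_counts(net, "eee"))


# ---------------------------------------------------------------------------
# matrix-product counts
# ---------------------------------------------------------------------------

def reciprocal_counts(net: DirectedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-node reciprocal-partner counts, split by feedback sign.

    A reciprocal pair x<->y is positive feedback when x and y are of the
    same physiological type (zero or two inhibitory edges) and negative
    when they differ (exactly one).  Computed from the elementwise product
    of the adjacency with its transpose, row-summed over partner classes.
    """
    a = net.adjacency.astype(np.int8)
    recip = a.multiply(a.T).tocsr()
    same = np.zeros(net.n_nodes, dtype=np.int64)
    diff = np.zeros(net.n_nodes, dtype=np.int64)
    partners_e = np.asarray(recip[:, net.exc_mask].sum(axis=1)).ravel()
    partners_i = np.asarray(recip[:, net.inh_mask].sum(axis=1)).ravel()
    is_e = net.exc_mask
    same[is_e] = partners_e[is_e]
    same[~is_e] = partners_i[~is_e]
    diff[is_e] = partners_i[is_e]
    diff[~is_e] = partners_e[~is_e]
    return same, diff


def _sub(net: DirectedNetwork, rows: np.ndarray, cols: np.ndarray) -> sp.csr_matrix:
    return net.adjacency[rows][:, cols].astype(np.int64).tocsr()


def ffi_counts(net: DirectedNetwork) -> np.ndarray:
    """Feed-forward inhibition motifs converging on each node.

    Node x participates once per (E, I) pair with E->x, I->x and E->I: the
    excitatory source both excites x directly and inhibits it disynaptically.
    Count vector = diag(A[E,:]^T A[E,I] A[I,:]).
    """
    e, i = net.exc_mask, net.inh_mask
    a_e_all = _sub(net, e, np.ones(net.n_nodes, bool))   # E origins -> all
    a_ei = _sub(net, e, i)                               # E -> I
    a_i_all = _sub(net, i, np.ones(net.n_nodes, bool))   # I origins -> all
    # diag(A_e_all^T @ (A_ei @ A_i_all)) without forming the dense product
    m = (a_ei @ a_i_all).tocsc()
    return np.asarray(a_e_all.multiply(m).sum(axis=0)).ravel()


def cycle_counts(net: DirectedNetwork, family: str) -> np.ndarray:
    """Directed 3-cycles through each node: x->E->I->x (eei) or x->E->E->x (eee).

    Each cycle is attributed once to every node from which the remaining
    two nodes match the stated class pattern.
    """
    e, i = net.exc_mask, net.inh_mask
    second = {"eei": i, "eee": e}[family]
    a_x_e = _sub(net, np.ones(net.n_nodes, bool), e)   # x -> E
    a_e_s = _sub(net, e, second)                       # E -> E/I
    a_s_x = _sub(net, second, np.ones(net.n_nodes, bool))
    m = (a_e_s @ a_s_x).tocsr()                        # E -> x paths
    # diag(A_x_e @ m): row x of A_x_e dotted with column x of m
    return np.asarray(a_x_e.multiply(m.T).sum(axis=1)).ravel()


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_motif_counts(net: DirectedNetwork, spec: MotifSpec) -> np.ndarray:
    """Exhaustive enumeration over ordered tuples of distinct nodes.

    Counts, for each node in the reference role, the assignments of the
    remaining roles to distinct other nodes satisfying the class
    constraints and all edges.  Intended for small networks; shares no code
    with the matrix-product implementations.
    """
    n = net.n_nodes
    adj = net.adjacency.toarray()
    ei = net.ei_label
    roles = [r for r in spec.roles if r != "x"]
    counts = np.zeros(n, dtype=np.int64)
    pools = [np.flatnonzero(ei == spec.classes[r]) if r in spec.classes
             else np.arange(n) for r in roles]
    for x in range(n):
        if "x" in spec.classes and ei[x] != spec.classes["x"]:
            continue
        c = 0
        for assign in _assignments(pools, x):
            node_of = {"x": x, **dict(zip(roles, assign))}
            if all(adj[node_of[a], node_of[b]] for a, b in spec.edges):
                c += 1
        counts[x] = c
    return counts


def _assignments(pools, x):
    """Ordered choices of distinct nodes (and distinct from x) per pool."""
    if len(pools) == 1:
        for a in pools[0]:
            if a != x:
                yield (a,)
    else:
        for a in pools[0]:
            if a == x:
                continue
            for rest in _assignments(pools[1:], x):
                if a not in rest:
                    yield (a, *rest)


def reciprocal_counts_brute(net: DirectedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Enumeration oracle for the signed reciprocal-pair counts."""
    n = net.n_nodes
    adj = net.adjacency.toarray()
    ei = net.ei_label
    same = np.zeros(n, dtype=np.int64)
    diff = np.zeros(n, dtype=np.int64)
    for x in range(n):
        for y in range(n):
            if y != x and adj[x, y] and adj[y, x]:
                if ei[x] == ei[y]:
                    same[x] += 1
                else:
                    diff[x] += 1
    return same, diff


# ---------------------------------------------------------------------------
# structural-class identification
# ---------------------------------------------------------------------------

def identify_structural_classes(net: DirectedNetwork,
                                ) -> tuple[np.ndarray, bool]:
    """Recover Class 1/2/3 labels from reciprocal counts alone.

    Within each physiological population the total reciprocal count
    histogram (integer resolution) is split at its two widest runs of
    empty bins; strata are mapped to classes by descending count (Class 1
    highest).  Returns ``(labels, ok)`` where ``ok`` is False when fewer
    than three separated strata were found in either population (labels
    then cover the strata actually present, in descending order 1, 2, 3).
    """
    same, diff = reciprocal_counts(net)
    total = same + diff
    labels = np.ones(net.n_nodes, dtype=np.int8)
    ok = True
    for mask in (net.exc_mask, net.inh_mask):
        if not mask.any():
            continue
        vals = total[mask]
        strata = _split_by_gaps(vals, n_strata=3)
        ok &= len(strata) == 3
        # order strata by descending representative count
        order = np.argsort([-vals[s].mean() for s in strata])
        sub = np.empty(len(vals), dtype=np.int8)
        for rank, si in enumerate(order):
            sub[strata[si]] = rank + 1
        labels[mask] = sub
    return labels, ok


def _split_by_gaps(vals: np.ndarray, n_strata: int = 3) -> list[np.ndarray]:
    """Index groups split at the widest empty integer gaps.

    Gaps are runs of unoccupied integer bins between min and max; the
    ``n_strata - 1`` widest (leftmost on ties, boundary values joining the
    lower stratum) define the cut points.
    """
    lo, hi = int(vals.min()), int(vals.max())
    if lo == hi:
        return [np.arange(len(vals))]
    occupied = np.zeros(hi - lo + 1, dtype=bool)
    occupied[np.asarray(vals, dtype=np.int64) - lo] = True
    gaps = []  # (width, start_bin)
    run = 0
    for b in range(len(occupied)):
        if not occupied[b]:
            run += 1
        else:
            if run:
                gaps.append((run, b - run))
            run = 0
    gaps.sort(key=lambda g: (-g[0], g[1]))
    cuts = sorted(lo + g[1] for g in gaps[:n_strata - 1])
    edges = [lo - 1] + cuts + [hi + 1]
    groups = []
    for a, b in zip(edges[:-1], edges[1:]):
        idx = np.flatnonzero((vals >= a) & (vals < b))
        if idx.size:
            groups.append(idx)
    return groups
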