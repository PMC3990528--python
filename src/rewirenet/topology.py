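"""Network topologies with exactly constant class-pair in-degrees.

Four directed network constructors over an excitatory (E) and an inhibitory (I)
population:

* a null-hypothesis random network in which every node receives exactly
  ``k_from_exc`` excitatory and ``k_from_inh`` inhibitory edges,
* a deterministic forwards-backwards ring lattice with the same constant
  in-degrees,
* a rewired ring lattice in which randomly chosen nodes have the origins of
  some or all of their incoming edges resampled, defining structural
  neuron classes (Class 1: untouched, Class 2: inhibitory origins resampled,
  Class 3: all origins resampled),
* an embedded modular network with Bernoulli edges and clustered E modules
  (the one constructor that does *not* enforce constant in-degrees).

Nodes are 0-based; E nodes occupy indices ``0 .. n_exc-1``, I nodes follow.
Adjacency is boolean with rows = origin and columns = target, so
``adj[j, i]`` means an edge j -> i.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "TopologyConfig",
    "RewireConfig",
    "ModularConfig",
    "DirectedNetwork",
    "build_random_fixed_indegree",
    "build_ring_lattice",
    "rewire_lattice",
    "build_embedded_modular",
    "in_degree_profile",
    "write_network",
    "read_network",
    "FULL_SCALE",
    "SCALED_DOWN",
]

E, I = 0, 1  # integer E/I labels used internally
_EI_NAMES = np.array(["E", "I"])


class ConfigurationError(ValueError):
    """Raised when a topology/simulation configuration is inconsistent."""


class FormatError(ValueError):
    """Raised when an on-disk artifact fails validation."""


@dataclass(frozen=True)
class TopologyConfig:
    """Sizes and constant in-degrees for the fixed in-degree constructors.

    ``k_from_exc`` / ``k_from_inh`` are the number of incoming E / I edges
    of *every* node (E and I targets alike).  ``k_ie`` and ``k_ii`` allow the
    E and I in-degrees of I nodes to differ from those of E nodes; they
    default to the same constants.
    """

    n_exc: int = 4000
    n_inh: int = 1000
    k_from_exc: int = 800
    k_from_inh: int = 200
    seed: int = 0
    k_ie: Optional[int] = None  # E in-degree of I nodes (default: k_from_exc)
    k_ii: Optional[int] = None  # I in-degree of I nodes (default: k_from_inh)

    @property
    def kee(self) -> int:
        return self.k_from_exc

    @property
    def kei(self) -> int:
        """I in-degree of E nodes."""
        return self.k_from_inh

    @property
    def kie(self) -> int:
        return self.k_from_exc if self.k_ie is None else self.k_ie

    @property
    def kii(self) -> int:
        return self.k_from_inh if self.k_ii is None else self.k_ii

    @property
    def n_nodes(self) -> int:
        return self.n_exc + self.n_inh

    def validate(self, lattice: bool = False) -> None:
        for name, k in (("k_from_exc", self.kee), ("k_from_inh", self.kei),
                        ("k_ie", self.kie), ("k_ii", self.kii)):
            if k <= 0 or k % 2:
                raise ConfigurationError(f"{name}={k} must be even and positive")
        if self.kee >= self.n_exc or self.kie >= self.n_exc:
            raise ConfigurationError("excitatory in-degree must be < n_exc")
        if self.kei >= self.n_inh or self.kii >= self.n_inh:
            raise ConfigurationError("inhibitory in-degree must be < n_inh")
        if lattice and self.n_exc % self.n_inh:
            raise ConfigurationError(
                "ring lattice needs n_exc to be an integer multiple of n_inh")


#: Full-scale default condition: in-degrees are 20% of each class size.
FULL_SCALE = TopologyConfig(n_exc=4000, n_inh=1000, k_from_exc=800, k_from_inh=200)

#: Scaled-down condition preserving the 20% in-degree rule, used by the
#: test suite and sweeps.
SCALED_DOWN = TopologyConfig(n_exc=800, n_inh=200, k_from_exc=160, k_from_inh=40)


@dataclass(frozen=True)
class RewireConfig:
    """Probabilities of the two node-level rewiring events.

    A node becomes Class 2 with probability ``p2`` (all incoming inhibitory
    edges re-originated), otherwise Class 3 with probability ``p3`` (all
    incoming edges re-originated).  ``exclude_original_class3`` extends the
    Class-2 rule that new origins must not duplicate lattice origins to the
    Class-3 resampling as well.
    """

    p2: float = 0.075
    p3: float = 0.05
    seed: int = 0
    exclude_original_class3: bool = True

    def validate(self) -> None:
        if not (0.0 <= self.p2 <= 1.0 and 0.0 <= self.p3 <= 1.0):
            raise ConfigurationError("rewiring probabilities must be in [0, 1]")


@dataclass(frozen=True)
class ModularConfig:
    """Embedded modular network: clustered Bernoulli E->E connectivity.

    Within-module E->E edges appear with probability ``p_in``, between-module
    with ``p_out``; any edge class involving an I node with ``p_inh``.
    Either (``p_in``, ``p_out``) or (``mean_p_ee``, ``ratio_ee``) may be
    given; the other pair is derived from the identity
    ``mean_p_ee = f*p_in + (1-f)*p_out`` with ``f`` the within-module
    fraction of ordered E pairs and ``ratio_ee = p_in/p_out``.
    """

    n_exc: int = 800
    n_inh: int = 200
    module_size: int = 100
    p_inh: float = 0.2
    mean_p_ee: Optional[float] = 0.2
    ratio_ee: Optional[float] = 2.5
    p_in: Optional[float] = None
    p_out: Optional[float] = None
    seed: int = 0

    def resolve(self) -> tuple[float, float]:
        """Return ``(p_in, p_out)``, deriving them if needed."""
        if self.n_exc % self.module_size:
            raise ConfigurationError("module_size must divide n_exc")
        if self.p_in is not None and self.p_out is not None:
            p_in, p_out = self.p_in, self.p_out
        elif self.mean_p_ee is not None and self.ratio_ee is not None:
            if self.ratio_ee < 1.0:
                raise ConfigurationError("ratio_ee must be >= 1")
            m = self.n_exc // self.module_size
            # fraction of ordered E pairs (excluding self) inside a module
            f = (self.module_size - 1) / (self.n_exc - 1) if m > 0 else 1.0
            p_out = self.mean_p_ee / (f * self.ratio_ee + (1.0 - f))
            p_in = self.ratio_ee * p_out
        else:
            raise ConfigurationError(
                "give either (p_in, p_out) or (mean_p_ee, ratio_ee)")
        for name, p in (("p_in", p_in), ("p_out", p_out), ("p_inh", self.p_inh)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p:.4f} outside [0, 1]")
        if p_in < p_out:
            raise ConfigurationError("p_in must be >= p_out")
        return p_in, p_out


class DirectedNetwork:
    """Boolean directed network with E/I labels and structural classes.

    Parameters
    ----------
    adjacency
        ``(n, n)`` sparse boolean matrix, ``adjacency[j, i]`` true for an
        edge j -> i.
    ei_label
        Per-node 0 (E) / 1 (I) integer array.
    struct_class
        Per-node label in {1, 2, 3} (1 everywhere before rewiring).
    provenance
        Topology name and the parameters it was built from.  A
        ``"constant_indegree": False`` entry flags the Bernoulli modular
        topology, which is exempt from the in-degree invariant.
    """

    def __init__(self, adjacency, ei_label, struct_class=None, provenance=None):
        adjacency = sp.csr_matrix(adjacency, dtype=bool)
        n = adjacency.shape[0]
        if adjacency.shape != (n, n):
            raise FormatError("adjacency must be square")
        self.adjacency = adjacency
        self.ei_label = np.asarray(ei_label, dtype=np.int8)
        if self.ei_label.shape != (n,):
            raise FormatError("ei_label length mismatch")
        if struct_class is None:
            struct_class = np.ones(n, dtype=np.int8)
        self.struct_class = np.asarray(struct_class, dtype=np.int8)
        if self.struct_class.shape != (n,):
            raise FormatError("struct_class length mismatch")
        self.provenance = dict(provenance or {})

    # -- basic views ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def exc_mask(self) -> np.ndarray:
        return self.ei_label == E

    @property
    def inh_mask(self) -> np.ndarray:
        return self.ei_label == I

    @property
    def n_exc(self) -> int:
        return int(self.exc_mask.sum())

    @property
    def n_inh(self) -> int:
        return int(self.inh_mask.sum())

    def class_name(self, node: int) -> str:
        return f"{_EI_NAMES[self.ei_label[node]]}{self.struct_class[node]}"

    def class_names(self) -> np.ndarray:
        """Per-node combined labels 'E1' .. 'I3'."""
        return np.char.add(_EI_NAMES[self.ei_label],
                           self.struct_class.astype("U1"))

    def in_degrees(self, origin_mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-node count of incoming edges, optionally from a node subset."""
        a = self.adjacency
        if origin_mask is not None:
            a = a[origin_mask, :]
        return np.asarray(a.sum(axis=0)).ravel().astype(np.int64)

    def out_degrees(self, target_mask: Optional[np.ndarray] = None) -> np.ndarray:
        a = self.adjacency
        if target_mask is not None:
            a = a[:, target_mask]
        return np.asarray(a.sum(axis=1)).ravel().astype(np.int64)

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise ``FormatError`` on failure."""
        if self.adjacency.diagonal().any():
            raise FormatError("self-edges present")
        if not np.isin(self.ei_label, [E, I]).all():
            raise FormatError("ei_label outside {0, 1}")
        if not np.isin(self.struct_class, [1, 2, 3]).all():
            raise FormatError("struct_class outside {1, 2, 3}")
        if self.provenance.get("constant_indegree", True):
            kin_e = self.in_degrees(self.exc_mask)
            kin_i = self.in_degrees(self.inh_mask)
            if np.ptp(kin_e) or np.ptp(kin_i):
                raise FormatError("in-degrees are not constant across nodes")

    def copy(self) -> "DirectedNetwork":
        return DirectedNetwork(self.adjacency.copy(), self.ei_label.copy(),
                               self.struct_class.copy(), dict(self.provenance))


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def _assemble(n_exc, n_inh, origin_lists, provenance, struct_class=None):
    """Build a DirectedNetwork from per-target origin index arrays."""
    n = n_exc + n_inh
    targets = np.concatenate(
        [np.full(len(orig), t, dtype=np.int64) for t, orig in origin_lists])
    origins = np.concatenate([orig for _, orig in origin_lists])
    adj = sp.csr_matrix(
        (np.ones(len(origins), dtype=bool), (origins, targets)), shape=(n, n))
    ei = np.concatenate([np.zeros(n_exc, np.int8), np.ones(n_inh, np.int8)])
    return DirectedNetwork(adj, ei, struct_class, provenance)


def build_random_fixed_indegree(config: TopologyConfig) -> DirectedNetwork:
    """Null-hypothesis random network with exactly constant in-degrees.

    Every node receives exactly ``k_from_exc`` edges from E nodes and
    ``k_from_inh`` edges from I nodes (``k_ie`` / ``k_ii`` for I targets),
    origins drawn uniformly without replacement from the class, excluding
    the target itself.  Out-degrees are random with the correct mean.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ne, ni = config.n_exc, config.n_inh
    e_ids = np.arange(ne)
    i_ids = np.arange(ne, ne + ni)
    pairs = []
    for t in range(ne + ni):
        ke = config.kee if t < ne else config.kie
        ki = config.kei if t < ne else config.kii
        e_pool = e_ids[e_ids != t]
        i_pool = i_ids[i_ids != t]
        pairs.append((t, np.concatenate([
            rng.choice(e_pool, size=ke, replace=False),
            rng.choice(i_pool, size=ki, replace=False)])))
    prov = {"topology": "random_fixed_indegree", "seed": config.seed,
            "n_exc": ne, "n_inh": ni, "k_from_exc": config.kee,
            "k_from_inh": config.kei, "k_ie": config.kie, "k_ii": config.kii}
    return _assemble(ne, ni, pairs, prov)


def _window(offsets_center: int, half: int, mod: int) -> np.ndarray:
    """Symmetric window center+-1..half (center excluded), modulo ``mod``."""
    j = np.concatenate([np.arange(-half, 0), np.arange(1, half + 1)])
    return (offsets_center + j) % mod


def build_ring_lattice(config: TopologyConfig) -> DirectedNetwork:
    """Deterministic forwards-backwards ring lattice.

    E node ``m`` receives E edges from ``m +- 1 .. m +- kee/2`` on the E
    ring; I node ``n`` receives I edges analogously on the I ring.  The
    cross-class blocks mirror the lattice structure: each contiguous block
    of ``c = n_exc/n_inh`` E nodes shares the same symmetric window of I
    origins centred at ``floor(m/c)``, and I node ``n`` receives E edges
    from the window centred at ``c*n``, so that E nodes with adjacent
    indices receive input from the same I nodes and project to I nodes
    with adjacent indices.
    """
    config.validate(lattice=True)
    ne, ni = config.n_exc, config.n_inh
    c = ne // ni
    pairs = []
    for m in range(ne):
        ee = _window(m, config.kee // 2, ne)
        ie = ne + _window(m // c, config.kei // 2, ni)
        pairs.append((m, np.concatenate([ee, ie])))
    for n in range(ni):
        ii = ne + _window(n, config.kii // 2, ni)
        ei = _window(c * n, config.kie // 2, ne)
        pairs.append((ne + n, np.concatenate([ei, ii])))
    prov = {"topology": "ring_lattice", "seed": config.seed,
            "n_exc": ne, "n_inh": ni, "k_from_exc": config.kee,
            "k_from_inh": config.kei, "k_ie": config.kie, "k_ii": config.kii}
    return _assemble(ne, ni, pairs, prov)


def rewire_lattice(lattice: DirectedNetwork, rc: RewireConfig) -> DirectedNetwork:
    """Rewire incoming-edge origins of randomly selected lattice nodes.

    Each node independently becomes Class 2 with probability ``p2``; each
    remaining node becomes Class 3 with probability ``p3``.  Class 2 nodes
    keep their incoming E edges but every incoming I edge is given a new
    origin sampled uniformly, without duplication, from I nodes that did
    not project to the node in the lattice.  Class 3 nodes have all
    incoming origins resampled uniformly within the origin's E/I class
    (excluding self; by default also excluding lattice origins).
    In-degrees per origin class are identical before and after.
    """
    rc.validate()
    if (lattice.struct_class != 1).any():
        raise ConfigurationError("input must be an unrewired (all Class 1) network")
    rng = np.random.default_rng(rc.seed)
    n = lattice.n_nodes
    ne = lattice.n_exc
    ni = lattice.n_inh
    e_ids = np.arange(ne)
    i_ids = np.arange(ne, n)

    u = rng.random(n)
    is2 = u < rc.p2
    is3 = ~is2 & (rng.random(n) < rc.p3)
    struct = np.ones(n, dtype=np.int8)
    struct[is2] = 2
    struct[is3] = 3

    csc = lattice.adjacency.tocsc()
    ei = lattice.ei_label

    def _resample(target, origins, pool, exclude_original):
        """New origins for ``target``: same count, uniform, no duplicates."""
        banned = {target}
        if exclude_original:
            banned.update(origins.tolist())
        eligible = pool[~np.isin(pool, list(banned))]
        if len(eligible) < len(origins):
            raise ConfigurationError(
                f"eligible origin pool ({len(eligible)}) smaller than "
                f"required in-degree ({len(origins)}) for node {target}")
        return rng.choice(eligible, size=len(origins), replace=False)

    pairs = []
    for t in range(n):
        origins = csc.indices[csc.indptr[t]:csc.indptr[t + 1]]
        e_orig = origins[ei[origins] == E]
        i_orig = origins[ei[origins] == I]
        if struct[t] == 2:
            i_orig = _resample(t, i_orig, i_ids, exclude_original=True)
        elif struct[t] == 3:
            e_orig = _resample(t, e_orig, e_ids, rc.exclude_original_class3)
            i_orig = _resample(t, i_orig, i_ids, rc.exclude_original_class3)
        pairs.append((t, np.concatenate([e_orig, i_orig])))

    prov = dict(lattice.provenance)
    prov.update({"topology": "rewired_lattice", "p2": rc.p2, "p3": rc.p3,
                 "rewire_seed": rc.seed,
                 "exclude_original_class3": rc.exclude_original_class3})
    return _assemble(ne, ni, pairs, prov, struct_class=struct)


def build_embedded_modular(mc: ModularConfig) -> DirectedNetwork:
    """Embedded modular network (Bernoulli edges, clustered E modules).

    E nodes are partitioned into equal, non-overlapping modules of
    ``module_size``; within-module E->E edges exist independently with
    probability ``p_in``, between-module with ``p_out``, and any edge class
    involving an I node with ``p_inh``.  In-degrees are *not* constant;
    the provenance records ``constant_indegree: False``.
    """
    p_in, p_out = mc.resolve()
    rng = np.random.default_rng(mc.seed)
    ne, ni = mc.n_exc, mc.n_inh
    n = ne + ni
    module = np.arange(ne) // mc.module_size

    probs = np.full((n, n), mc.p_inh)
    same = module[:, None] == module[None, :]
    probs[:ne, :ne] = np.where(same, p_in, p_out)
    mask = rng.random((n, n)) < probs
    np.fill_diagonal(mask, False)

    ei = np.concatenate([np.zeros(ne, np.int8), np.ones(ni, np.int8)])
    prov = {"topology": "embedded_modular", "seed": mc.seed,
            "n_exc": ne, "n_inh": ni, "module_size": mc.module_size,
            "p_in": p_in, "p_out": p_out, "p_inh": mc.p_inh,
            "constant_indegree": False}
    return DirectedNetwork(sp.csr_matrix(mask), ei, provenance=prov)


# ---------------------------------------------------------------------------
# degree bookkeeping and serialization
# ---------------------------------------------------------------------------

def in_degree_profile(net: DirectedNetwork) -> pd.DataFrame:
    """Per class-pair in/out-degree summaries (min, max, mean).

    Rows cover every ordered pair of node groups at two granularities:
    the E/I split and the combined structural classes (E1..I3).  For a row
    ``(origin_group, target_group)``, ``in_*`` summarise, over nodes of the
    target group, the number of incoming edges from the origin group, and
    ``out_*`` summarise, over nodes of the origin group, the number of
    outgoing edges to the target group.
    """
    groups: dict[str, np.ndarray] = {
        "E": net.exc_mask, "I": net.inh_mask}
    names = net.class_names()
    for cname in np.unique(names):
        groups[str(cname)] = names == cname
    rows = []
    for oname, omask in groups.items():
        # mixing granularities is redundant; keep pairs within a granularity
        for tname, tmask in groups.items():
            if (len(oname) == 1) != (len(tname) == 1):
                continue
            kin = net.in_degrees(omask)[tmask]
            kout = net.out_degrees(tmask)[omask]
            rows.append({
                "origin": oname, "target": tname,
                "n_origin": int(omask.sum()), "n_target": int(tmask.sum()),
                "in_min": int(kin.min()) if kin.size else 0,
                "in_max": int(kin.max()) if kin.size else 0,
                "in_mean": float(kin.mean()) if kin.size else 0.0,
                "out_min": int(kout.min()) if kout.size else 0,
                "out_max": int(kout.max()) if kout.size else 0,
                "out_mean": float(kout.mean()) if kout.size else 0.0,
            })
    return pd.DataFrame(rows)


def _paths(path) -> tuple[Path, Path]:
    """Adjacency (.mtx) and node-table (.nodes.tsv) paths for a base path."""
    base = Path(path)
    if base.suffix == ".mtx":
        base = base.with_suffix("")
    return base.with_suffix(".mtx"), base.with_name(base.name + ".nodes.tsv")


def write_network(net: DirectedNetwork, path) -> None:
    """Write adjacency as Matrix Market pattern + node metadata TSV.

    ``path`` is a base path; ``<base>.mtx`` holds the 1-based coordinate
    pattern matrix (rows = origins) and ``<base>.nodes.tsv`` the per-node
    ``node_id / ei_label / struct_class`` table, with the provenance stored
    as a ``# provenance=`` header comment.
    """
    mtx_path, nodes_path = _paths(path)
    scipy.io.mmwrite(str(mtx_path), net.adjacency.tocoo(), field="pattern")
    with open(nodes_path, "w") as fh:
        fh.write("# provenance=" + json.dumps(net.provenance, sort_keys=True) + "\n")
        pd.DataFrame({
            "node_id": np.arange(net.n_nodes),
            "ei_label": _EI_NAMES[net.ei_label],
            "struct_class": net.struct_class,
        }).to_csv(fh, sep="\t", index=False)


def read_network(path) -> DirectedNetwork:
    """Read a network written by :func:`write_network` and validate it."""
    mtx_path, nodes_path = _paths(path)
    try:
        adj = sp.csr_matrix(scipy.io.mmread(str(mtx_path)), dtype=bool)
    except Exception as exc:  # malformed MTX
        raise FormatError(f"cannot read adjacency from {mtx_path}: {exc}") from exc
    provenance = {}
    text = Path(nodes_path).read_text()
    body = []
    for line in text.splitlines():
        if line.startswith("# provenance="):
            provenance = json.loads(line.split("=", 1)[1])
        elif line and not line.startswith("#"):
            body.append(line)
    table = pd.read_csv(io.StringIO("\n".join(body)), sep="\t")
    for col in ("node_id", "ei_label", "struct_class"):
        if col not in table.columns:
            raise FormatError(f"node table missing column {col!r}")
    if len(table) != adj.shape[0]:
        raise FormatError("node table length does not match adjacency dimension")
    if not table["ei_label"].isin(["E", "I"]).all():
        raise FormatError("unknown ei_label in node table")
    if not table["struct_class"].isin([1, 2, 3]).all():
        raise FormatError("unknown struct_class in node table")
    order = np.argsort(table["node_id"].to_numpy())
    ei = (table["ei_label"].to_numpy()[order] == "I").astype(np.int8)
    struct = table["struct_class"].to_numpy()[order].astype(np.int8)
    net = DirectedNetwork(adj, ei, struct, provenance)
    net.validate()
    return net
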