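"""Group difference networks, weighted graph properties and clinical association.

Edge-wise group contrasts follow the retention rule "keep directed edges
whose weights differ at p < alpha between groups" (uncorrected by default;
a Benjamini-Hochberg mode is available behind a flag).  Graph summaries
use the canonical weighted definitions: Onnela clustering (geometric-mean
triangle intensity), shortest paths on edge lengths 1/w, characteristic
path length over connected pairs, Latora-Marchiori global and local
efficiency.  By default metrics are computed on the symmetrized matrix
(w + w')/2 with the diagonal zeroed; a directed variant (Fagiolo
clustering, directed Dijkstra) can be switched on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import dijkstra

from .adtf import TimeVaryingNetwork
from .errors import ParameterError, StatisticsError
from .erp import fdr_correct

PROPERTY_NAMES = ("C", "L", "Ge", "Le")


class EdgeResult(NamedTuple):
    source: str
    sink: str
    t_value: float
    p_value: float
    direction: str               # "A>B" | "B>A"


@dataclass
class DifferenceNetwork:
    time_ms: float
    edges: list
    alpha: float
    channel_labels: tuple

    def edge_set(self):
        return {(e.source, e.sink) for e in self.edges}

    def to_records(self):
        return [{"time_ms": self.time_ms, "source": e.source, "sink": e.sink,
                 "t": e.t_value, "p": e.p_value, "direction": e.direction}
                for e in self.edges]


@dataclass
class NetworkProperties:
    C: float
    L: float
    Ge: float
    Le: float
    subject_id: Optional[str] = None
    averaging_window_ms: Optional[tuple] = None

    def as_dict(self):
        return {"C": self.C, "L": self.L, "Ge": self.Ge, "Le": self.Le}


@dataclass
class AssociationResult:
    property: str
    r: float
    p: float
    n: int
    note: Optional[str] = None


def _prepare_weights(w: np.ndarray, directed_handling: str) -> tuple:
    w = np.asarray(w, dtype=float).copy()
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ParameterError("weight matrix must be square")
    if w.shape[0] < 2:
        raise ParameterError("graph metrics need at least 2 nodes")
    if np.any(w < 0):
        raise ParameterError("weights must be nonnegative")
    np.fill_diagonal(w, 0.0)
    if directed_handling == "symmetrize":
        return (w + w.T) / 2.0, False
    if directed_handling == "directed":
        return w, True
    raise ParameterError(f"unknown directed_handling {directed_handling!r}")


def _clustering(w: np.ndarray, directed: bool) -> float:
    """Mean weighted clustering from geometric-mean triangle intensities.

    Weights are used as given (ADTF networks are already normalized to
    [0, 1]); no per-graph rescaling is applied, so the coefficient stays
    comparable across subjects.  The directed form follows Fagiolo's
    generalization.
    """
    W3 = np.cbrt(w)
    n = w.shape[0]
    if not directed:
        tri = np.diagonal(W3 @ W3 @ W3)                  # 2 * triangle intensity
        k = (w > 0).sum(axis=1)
        denom = k * (k - 1)
        with np.errstate(invalid="ignore"):
            c = np.where(denom > 0, tri / denom, 0.0)
        return float(c.mean())
    S = W3 + W3.T
    tri = np.diagonal(S @ S @ S)
    a = (w > 0).astype(int)
    d_tot = a.sum(axis=0) + a.sum(axis=1)
    d_bi = (a * a.T).sum(axis=1)
    denom = 2.0 * (d_tot * (d_tot - 1) - 2 * d_bi)
    with np.errstate(invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return float(c.mean())


def _distances(w: np.ndarray, directed: bool) -> np.ndarray:
    lengths = np.zeros_like(w)
    np.divide(1.0, w, out=lengths, where=w > 0)
    return dijkstra(sparse.csr_matrix(lengths), directed=directed)


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].mean())


def graph_properties(w: np.ndarray, directed_handling: str = "symmetrize",
                     subject_id: Optional[str] = None) -> NetworkProperties:
    """Weighted C, L, Ge, Le of one adjacency matrix.

    L averages shortest-path lengths over connected ordered pairs only and
    is +inf for an empty graph; disconnected pairs contribute 0 to Ge.
    Le is the mean over nodes of the global efficiency of each node's
    neighborhood subgraph (nodes with < 2 neighbors contribute 0).
    """
    W, directed = _prepare_weights(w, directed_handling)
    C = _clustering(W, directed)
    d = _distances(W, directed)
    n = W.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    L = float(d[finite].mean()) if finite.any() else float("inf")
    Ge = _efficiency_from_distances(d)
    Le = 0.0
    neigh_adj = W if not directed else np.maximum(W, W.T)
    for i in range(n):
        nb = np.flatnonzero(neigh_adj[i] > 0)
        if nb.size >= 2:
            sub = W[np.ix_(nb, nb)]
            Le += _efficiency_from_distances(_distances(sub, directed))
    Le /= n
    return NetworkProperties(C=C, L=L, Ge=Ge, Le=Le, subject_id=subject_id)


def edge_group_test(groupA: Sequence[TimeVaryingNetwork],
                    groupB: Sequence[TimeVaryingNetwork],
                    time_ms: float, alpha: float = 0.05,
                    fdr: bool = False) -> DifferenceNetwork:
    """Welch two-tailed t-test per directed off-diagonal edge at a latency.

    Subject networks are sampled at the nearest grid latency; edges with
    p < alpha are retained with a direction label from the sign of the
    group mean difference.  Retention is uncorrected unless ``fdr`` is set.
    """
    if len(groupA) < 2 or len(groupB) < 2:
        raise StatisticsError("edge test needs >= 2 subjects per group")
    ref = groupA[0]
    labels = ref.channel_labels or tuple(str(i) for i in range(ref.n_channels))
    A = np.stack([net.at_time(time_ms) for net in groupA])
    B = np.stack([net.at_time(time_ms) for net in groupB])
    grid_time = float(ref.times_ms[np.argmin(np.abs(ref.times_ms - time_ms))])
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=False)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    n = A.shape[1]
    off = ~np.eye(n, dtype=bool)
    if fdr:
        keep = fdr_correct(np.where(off, p, 1.0), q=alpha) & off
    else:
        keep = (p < alpha) & off
    diff = A.mean(axis=0) - B.mean(axis=0)
    edges = []
    for i, j in zip(*np.nonzero(keep)):      # sink i <- source j
        edges.append(EdgeResult(source=labels[j], sink=labels[i],
                                t_value=float(t[i, j]), p_value=float(p[i, j]),
                                direction="A>B" if diff[i, j] > 0 else "B>A"))
    return DifferenceNetwork(time_ms=grid_time, edges=edges, alpha=alpha,
                             channel_labels=tuple(labels))


def snapshot_series(groupA, groupB,
                    times_ms: Sequence[float] = (100.0, 200.0, 300.0, 600.0, 1000.0),
                    alpha: float = 0.05, fdr: bool = False):
    """Difference networks at a series of snapshot latencies."""
    return [edge_group_test(groupA, groupB, t, alpha=alpha, fdr=fdr)
            for t in times_ms]


def subject_properties(net: TimeVaryingNetwork,
                       window_ms: Sequence[float] = (0.0, 1000.0),
                       directed_handling: str = "symmetrize",
                       mode: str = "average_first",
                       subject_id: Optional[str] = None) -> NetworkProperties:
    """Graph properties of a subject's network over a time window.

    ``average_first`` (default) averages the weight matrix over the window
    and computes metrics once; ``metrics_then_average`` computes metrics
    per time point and averages them.
    """
    lo, hi = window_ms
    sel = (net.times_ms >= lo - 1e-9) & (net.times_ms <= hi + 1e-9)
    if not sel.any():
        raise ParameterError(f"window {window_ms} contains no network time points")
    if mode == "average_first":
        props = graph_properties(net.w[sel].mean(axis=0), directed_handling)
    elif mode == "metrics_then_average":
        per = [graph_properties(net.w[i], directed_handling)
               for i in np.flatnonzero(sel)]
        props = NetworkProperties(
            C=float(np.mean([q.C for q in per])),
            L=float(np.mean([q.L for q in per])),
            Ge=float(np.mean([q.Ge for q in per])),
            Le=float(np.mean([q.Le for q in per])),
        )
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    props.subject_id = subject_id
    props.averaging_window_ms = tuple(window_ms)
    return props


def pearson_association(props: Sequence[NetworkProperties],
                        scores: Sequence[float]):
    """Pearson r (and two-tailed p, t-transform with n-2 df) between each
    network property and the clinical scores, over matched subjects."""
    if len(props) != len(scores):
        raise StatisticsError("one score per subject required")
    n = len(props)
    if n < 3:
        raise StatisticsError("association needs at least 3 subjects")
    scores = np.asarray(scores, dtype=float)
    out = []
    for name in PROPERTY_NAMES:
        x = np.asarray([getattr(q, name) for q in props], dtype=float)
        if np.ptp(x) == 0 or np.ptp(scores) == 0:
            out.append(AssociationResult(name, float("nan"), float("nan"), n,
                                         note="zero variance"))
            continue
        r, p = stats.pearsonr(x, scores)
        out.append(AssociationResult(name, float(r), float(p), n))
    return out
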