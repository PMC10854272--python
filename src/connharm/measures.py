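"""Streamline-count-invariant graph measures with their matrix-weighting mapping.

Measure-to-weighting mapping:

* **modularity** — streamline-count matrices (raw counts; scale-invariant);
* **global efficiency** — per-subject max-normalized streamline-count matrices,
  with connection length 1/weight and weighted shortest paths;
* **average betweenness centrality** — mean-streamline-length matrices, entries
  used directly as connection lengths.

All measures zero the diagonal first: self-connections are artifacts of the
triangle vectorization including the diagonal, not graph edges.

Modularity uses a fully deterministic Newman leading-eigenvector bisection with
Kernighan-Lin style fine-tuning (node-index tie-breaking), so repeated runs and
regression tests get bit-identical partitions — stochastic Louvain-type solvers
are deliberately avoided.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

from connharm.io import (
    MEAN_LENGTH,
    STREAMLINE_COUNT,
    CohortManifest,
    ConnectivityMatrix,
)

MEASURES = ("modularity", "global_efficiency", "avg_betweenness")

#: gain below this is treated as zero when deciding whether a split improves Q
_Q_TOL = 1e-10


class DegenerateMatrixError(ValueError):
    """Raised when a measure is undefined for the input (e.g. all-zero matrix)."""


def _zero_diagonal(values: np.ndarray) -> np.ndarray:
    w = values.copy()
    np.fill_diagonal(w, 0.0)
    return w


def normalize_counts(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Divide every entry by the matrix maximum, mapping weights into [0, 1]."""
    if m.weighting != STREAMLINE_COUNT:
        raise ValueError("normalize_counts applies to streamline_count matrices")
    mx = float(m.values.max())
    if mx <= 0:
        raise DegenerateMatrixError("all-zero matrix cannot be normalized")
    return ConnectivityMatrix(m.subject_id, m.weighting, m.values / mx)


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector sign: largest-|.| component (lowest index on ties) > 0."""
    k = int(np.argmax(np.abs(vec) - 1e-15 * np.arange(len(vec))))
    return -vec if vec[k] < 0 else vec


def _kl_refine(b_hat: np.ndarray, s: np.ndarray, max_passes: int = 100) -> np.ndarray:
    """Kernighan-Lin style fine-tuning of a bisection vector s in {-1, +1}.

    Repeated passes: each pass moves every node exactly once, greedily by the
    change in s^T B s, then keeps the best prefix of moves. A pass is accepted
    only if the recomputed quality genuinely improves (B is expected in
    per-total-weight units, so the tolerance is in natural modularity units).
    """
    n = len(s)
    diag = np.diag(b_hat).copy()
    q_cur = float(s @ b_hat @ s)
    for _ in range(max_passes):
        s_pass = s.copy()
        bs = b_hat @ s_pass
        moved = np.zeros(n, dtype=bool)
        gains = np.empty(n)
        order = np.empty(n, dtype=int)
        total = 0.0
        for step in range(n):
            delta = -4.0 * s_pass * bs + 4.0 * diag
            delta[moved] = -np.inf
            i = int(np.argmax(delta))  # ties -> lowest index
            total += delta[i]
            gains[step] = total
            order[step] = i
            # flip node i and update bs incrementally
            bs = bs - 2.0 * s_pass[i] * b_hat[:, i]
            s_pass[i] = -s_pass[i]
            moved[i] = True
        best = int(np.argmax(gains))
        s_new = s.copy()
        s_new[order[: best + 1]] *= -1
        q_new = float(s_new @ b_hat @ s_new)
        if q_new <= q_cur + _Q_TOL:
            return s
        s, q_cur = s_new, q_new
    return s


def _bisect(b_hat: np.ndarray) -> np.ndarray | None:
    """One spectral bisection of a (generalized) modularity matrix.

    Returns a sign vector in {-1, +1}, or None if the group is indivisible
    (no split with positive modularity gain exists along this route).
    """
    vals, vecs = scipy.linalg.eigh(b_hat)
    leading = _fix_sign(vecs[:, -1])
    s = np.where(leading >= 0, 1.0, -1.0)
    s = _kl_refine(b_hat, s)
    if np.all(s == s[0]):
        return None
    if float(s @ b_hat @ s) <= _Q_TOL:
        return None
    return s


def _communities(w: np.ndarray) -> np.ndarray:
    """Community labels by recursive spectral bisection with fine-tuning."""
    n = w.shape[0]
    k = w.sum(axis=1)
    m2 = float(k.sum())
    # per-total-weight units: s^T B_hat s gains are in natural modularity units
    b = (w - np.outer(k, k) / m2) / m2
    labels = np.zeros(n, dtype=int)
    stack = [np.arange(n)]
    next_label = 1
    while stack:
        group = stack.pop()
        if len(group) < 2:
            continue
        bg = b[np.ix_(group, group)]
        b_hat = bg - np.diag(bg.sum(axis=1))
        s = _bisect(b_hat)
        if s is None:
            continue
        right = group[s < 0]
        left = group[s > 0]
        labels[right] = next_label
        next_label += 1
        stack.append(left)
        stack.append(right)
    return labels


def modularity_partition(m: ConnectivityMatrix) -> np.ndarray:
    """Community labels for a streamline-count matrix (deterministic)."""
    if m.weighting != STREAMLINE_COUNT:
        raise ValueError("modularity applies to streamline_count matrices")
    w = _zero_diagonal(m.values)
    if w.sum() <= 0:
        raise DegenerateMatrixError("all-zero matrix has no modular structure")
    return _communities(w)


def partition_quality(w: np.ndarray, labels: np.ndarray) -> float:
    """Newman-Girvan modularity Q = sum_c (e_cc - a_c^2) of a labelled partition."""
    w = _zero_diagonal(np.asarray(w, dtype=float))
    m2 = w.sum()
    if m2 <= 0:
        raise DegenerateMatrixError("all-zero matrix")
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_cc = w[np.ix_(mask, mask)].sum() / m2
        a_c = w[mask].sum() / m2
        q += e_cc - a_c**2
    return float(q)


def modularity(m: ConnectivityMatrix) -> float:
    """Modularity Q of the partition found by deterministic spectral optimization.

    Undirected weighted, resolution 1. A network with no divisible structure
    (e.g. a complete graph) yields the single-community partition, Q = 0.
    """
    labels = modularity_partition(m)
    return partition_quality(m.values, labels)


def global_efficiency(m: ConnectivityMatrix) -> float:
    """Average inverse weighted shortest-path length over ordered node pairs.

    Connection lengths are 1/weight for positive weights (no edge otherwise);
    disconnected pairs contribute 0 (1/inf). Expects a max-normalized
    streamline-count matrix, so a complete unit-weight graph scores 1.
    """
    w = _zero_diagonal(m.values)
    n = w.shape[0]
    if n < 2:
        raise DegenerateMatrixError("global efficiency needs n >= 2")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    graph = scipy.sparse.csr_matrix(lengths)
    d = scipy.sparse.csgraph.shortest_path(graph, method="D", directed=False)
    np.fill_diagonal(d, np.inf)  # exclude i == j
    inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv.sum() / (n * (n - 1)))


def avg_betweenness(m: ConnectivityMatrix) -> float:
    """Mean over nodes of unnormalized betweenness centrality, ordered-pair convention.

    Entries of a mean-streamline-length matrix are used directly as connection
    lengths (0 = no edge). Shortest-path ties share credit fractionally
    (Brandes accumulation). Ordered (s, t) pairs are counted, so a path and its
    reverse both contribute; a star center on n nodes scores (n-1)(n-2).
    """
    if m.weighting != MEAN_LENGTH:
        raise ValueError("avg_betweenness applies to mean_length matrices")
    w = _zero_diagonal(m.values)
    n = w.shape[0]
    if n < 3:
        raise DegenerateMatrixError("betweenness needs n >= 3")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(w))
    g.add_weighted_edges_from(
        ((int(i), int(j), float(w[i, j])) for i, j in zip(ii, jj)), weight="length"
    )
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    # networkx counts unordered pairs on undirected graphs; double for ordered pairs
    return float(2.0 * np.mean([bc[i] for i in range(n)]))


def compute_all(
    matrices: Sequence[ConnectivityMatrix], manifest: CohortManifest
) -> pd.DataFrame:
    """Graph-measure table: one row per subject per measure.

    ``matrices`` must contain, for every manifest subject, one streamline_count
    and one mean_length matrix. Returns a DataFrame with columns
    (subject_id, site, measure, value).
    """
    by_key = {(m.subject_id, m.weighting): m for m in matrices}
    rows = []
    for _, rec in manifest.table.iterrows():
        sid, site = rec["subject_id"], rec["site"]
        for weighting in (STREAMLINE_COUNT, MEAN_LENGTH):
            if (sid, weighting) not in by_key:
                raise ValueError(f"subject {sid!r} is missing its {weighting} matrix")
        counts = by_key[(sid, STREAMLINE_COUNT)]
        lengths = by_key[(sid, MEAN_LENGTH)]
        rows.append((sid, site, "modularity", modularity(counts)))
        rows.append((sid, site, "global_efficiency", global_efficiency(normalize_counts(counts))))
        rows.append((sid, site, "avg_betweenness", avg_betweenness(lengths)))
    return pd.DataFrame(rows, columns=["subject_id", "site", "measure", "value"])
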