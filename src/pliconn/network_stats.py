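"""Network-based permutation statistics over connectivity matrices.

The procedure controls family-wise error at the level of connected
components ("networks") of supra-threshold edges:

1. an edge-wise repeated-measures F statistic contrasts conditions
   (two levels: F = t^2 of the paired t; three levels: one-way
   repeated-measures ANOVA F);
2. edges with F > K form a graph whose connected components are the
   candidate networks, sized by their edge count;
3. the null distribution of the *largest* component size is built by
   re-randomising condition labels independently per participant
   (sign flips of paired differences for two levels, label shuffles for
   three) and re-running steps 1–2;
4. a component is significant when its size falls in the highest 5% of
   that null distribution, i.e. p_fwe < 0.05 with
   p_fwe = (1 + #{null >= observed}) / (1 + n_perm);
5. the threshold K itself is searched over a grid (default 3..10, step
   0.1): the final K is the largest grid value that still yields at
   least one significant component.

Post-hoc stages rank the component edges by mean condition difference,
keep the top ``k`` (default 32) that survive an uncorrected two-tailed
paired t at alpha, split them by direction, and — for three ordered
conditions — flag edges whose condition means change strictly
monotonically with at least one significant adjacent pairwise step.

Data enter as arrays of per-participant edge vectors (see
:mod:`pliconn.edgeops`), one (n_participants, n_edges) array per
condition.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .edgeops import edge_pairs, to_vector

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass
class Component:
    """A connected set of supra-threshold edges."""

    edges: list[tuple[int, int]]
    nodes: set[int]

    @property
    def size(self) -> int:
        """Network size = number of edges."""
        return len(self.edges)


@dataclass
class EdgeTest:
    """Post-hoc result for one edge."""

    edge: tuple[int, int]
    mean_diff: float
    t: float
    p: float
    direction: str  # "A>B" or "B>A"


@dataclass
class NetworkResult:
    threshold: float | None
    components: list[Component]
    p_fwe: list[float]
    n_permutations: int
    significant: list[bool]
    f_values: np.ndarray | None = None
    null_max_sizes: np.ndarray | None = None
    top_edges: list[EdgeTest] = field(default_factory=list)

    @property
    def any_significant(self) -> bool:
        return any(self.significant)

    def significant_components(self) -> list[Component]:
        return [c for c, s in zip(self.components, self.significant) if s]


@dataclass
class TrendEdge:
    edge: tuple[int, int]
    means: tuple[float, float, float]
    monotonic: str  # "increasing", "decreasing", or "none"
    adjacent_p: tuple[float, float]


@dataclass
class TrendResult:
    network: NetworkResult
    edges: list[TrendEdge]

    def monotonic_edges(self) -> list[TrendEdge]:
        return [e for e in self.edges if e.monotonic != "none"]


# ---------------------------------------------------------------------------
# edge-wise statistics


def _as_edge_array(mats) -> np.ndarray:
    """Accept (n, E) arrays, lists of edge vectors, or lists of matrices."""
    if isinstance(mats, np.ndarray) and mats.ndim == 2:
        first_square = mats.shape[0] == mats.shape[1]
        if not first_square:
            return np.asarray(mats, dtype=float)
    arrs = []
    for m in mats:
        m = np.asarray(getattr(m, "values", m), dtype=float)
        arrs.append(to_vector(m) if m.ndim == 2 else m)
    return np.asarray(arrs)


def average_conditions(
    data: dict[str, np.ndarray], groups: dict[str, list[str]]
) -> dict[str, np.ndarray]:
    """Per-participant element-wise mean across grouped conditions.

    E.g. ``groups={"softer": ["-10", "-5"], "equal": ["0"]}`` collapses
    the two softer-distractor conditions into one matrix per
    participant. Every participant must be present in every grouped
    condition (equal row counts).
    """
    out = {}
    for name, conds in groups.items():
        arrs = [np.asarray(data[c], dtype=float) for c in conds]
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise ValueError(
                f"group {name!r}: participant sets differ across {conds} ({shapes})"
            )
        out[name] = np.mean(arrs, axis=0)
    return out


def edgewise_f(mat_a, mat_b) -> np.ndarray:
    """Two-level repeated-measures F per edge: the squared paired t,
    df (1, n-1). Edges with zero difference variance get F = +inf when
    the mean difference is nonzero, else 0."""
    a = _as_edge_array(mat_a)
    b = _as_edge_array(mat_b)
    if a.shape != b.shape:
        raise ValueError("condition arrays must be paired with equal shapes")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    d = a - b
    return _paired_f_from_diffs(d)


def _paired_f_from_diffs(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    mean = d.mean(axis=0)
    var = d.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = n * mean**2 / var
    f = np.where(var == 0, np.where(mean == 0, 0.0, np.inf), f)
    return f


def rm_anova_f(data: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """One-way repeated-measures ANOVA F per edge from sums of squares.

    ``data`` is (n_participants, n_levels, n_edges). Returns the F
    vector and its (df1, df2) = (a-1, (a-1)(n-1)).
    """
    n, a, _ = data.shape
    grand = data.mean(axis=(0, 1))
    m_cond = data.mean(axis=0)  # (a, E)
    m_subj = data.mean(axis=1)  # (n, E)
    ss_cond = n * ((m_cond - grand) ** 2).sum(axis=0)
    resid = data - m_cond[None, :, :] - m_subj[:, None, :] + grand[None, None, :]
    ss_err = (resid**2).sum(axis=(0, 1))
    df1, df2 = a - 1, (a - 1) * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_cond / df1) / (ss_err / df2)
    f = np.where(ss_err == 0, np.where(ss_cond == 0, 0.0, np.inf), f)
    return f, (df1, df2)


# ---------------------------------------------------------------------------
# components


class _UnionFind:
    __slots__ = ("parent", "edge_count")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.edge_count = [0] * n

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def add_edge(self, i: int, j: int) -> int:
        """Union by attaching; returns the edge count of the merged component."""
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            self.edge_count[ri] += 1
            return self.edge_count[ri]
        self.parent[rj] = ri
        self.edge_count[ri] += self.edge_count[rj] + 1
        return self.edge_count[ri]


def suprathreshold_components(
    f_values: np.ndarray, threshold: float, n_regions: int | None = None
) -> list[Component]:
    """Connected components of the graph of edges with F > threshold.

    ``f_values`` is an edge vector or a symmetric matrix. Components are
    returned sorted by decreasing size, ties broken by smallest node.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    f = np.asarray(f_values, dtype=float)
    if f.ndim == 2:
        n_regions = f.shape[0]
        f = to_vector(f)
    if n_regions is None:
        # invert E = n(n-1)/2
        n_regions = int((1 + np.sqrt(1 + 8 * len(f))) / 2)
    pairs = edge_pairs(n_regions)
    supra = f > threshold
    members: dict[int, list[tuple[int, int]]] = {}
    uf = _UnionFind(n_regions)
    for (i, j) in pairs[supra]:
        uf.add_edge(int(i), int(j))
    for (i, j) in pairs[supra]:
        members.setdefault(uf.find(int(i)), []).append((int(i), int(j)))
    comps = [
        Component(edges=sorted(es), nodes={v for e in es for v in e})
        for es in members.values()
    ]
    comps.sort(key=lambda c: (-c.size, min(c.nodes)))
    return comps


def _null_max_size_curves(
    f_perm: np.ndarray, pairs: np.ndarray, thresholds: np.ndarray
) -> np.ndarray:
    """Largest-component edge count per permutation per threshold.

    Single Kruskal-style pass per permutation: insert edges in
    decreasing F order into a union-find, tracking the running maximum
    component edge count; the value after inserting all edges with
    F > K is the null max size at K. Returns (n_perm, n_thresholds).
    """
    n_perm, n_edges_ = f_perm.shape
    n_nodes = int(pairs.max()) + 1 if len(pairs) else 0
    out = np.zeros((n_perm, len(thresholds)), dtype=int)
    # descending thresholds => prefix counts are monotone
    order_thr = np.argsort(-thresholds)
    thr_sorted = thresholds[order_thr]
    for p in range(n_perm):
        f = f_perm[p]
        order = np.argsort(-f)
        f_sorted = f[order]
        # cumulative max component size after each insertion
        uf = _UnionFind(n_nodes)
        run_max = 0
        cummax = np.empty(n_edges_, dtype=int)
        pi = pairs[order]
        for idx in range(n_edges_):
            i, j = pi[idx]
            size = uf.add_edge(int(i), int(j))
            if size > run_max:
                run_max = size
            cummax[idx] = run_max
        # edges with F > K: count via searchsorted on descending f_sorted
        counts = np.searchsorted(-f_sorted, -thr_sorted, side="right")
        vals = np.where(counts > 0, cummax[np.maximum(counts - 1, 0)], 0)
        out[p, order_thr] = vals
    return out


# ---------------------------------------------------------------------------
# permutation machinery


def _two_level_perm_f(
    d: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, int, bool]:
    """Null F matrices by per-participant sign flips of paired differences.

    Returns (F_perm (P, E), P, exhaustive). Falls back to exhaustive
    enumeration of all 2^n sign patterns when that is fewer than
    ``n_perm``, with a warning.
    """
    n, _ = d.shape
    if 2**n < n_perm:
        warnings.warn(
            f"only 2^{n} = {2**n} distinct sign patterns; enumerating exhaustively"
        )
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        exhaustive = True
    else:
        signs = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
        exhaustive = False
    q = (d**2).sum(axis=0)  # invariant under sign flips
    m = signs @ d / n  # (P, E)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (n - 1) * n * m**2 / (q - n * m**2)
    f = np.nan_to_num(f, nan=0.0, posinf=np.inf)
    f[f < 0] = np.inf  # numerical q - n m^2 < 0 means zero residual variance
    return f, signs.shape[0], exhaustive


def _three_level_perm_f(
    data: np.ndarray, n_perm: int, rng: np.random.Generator, chunk: int = 50
) -> tuple[np.ndarray, int, bool]:
    """Null F by per-participant random permutation of the 3 condition labels."""
    n, a, ne = data.shape
    perms_per_subject = np.array(list(itertools.permutations(range(a))))
    total = len(perms_per_subject) ** n
    if total < n_perm:
        warnings.warn(
            f"only {total} distinct label patterns; enumerating exhaustively"
        )
        choice_iter = itertools.product(range(len(perms_per_subject)), repeat=n)
        choices = np.array(list(choice_iter))
        exhaustive = True
    else:
        choices = rng.integers(0, len(perms_per_subject), size=(n_perm, n))
        exhaustive = False
    n_total = choices.shape[0]

    # RM ANOVA terms that are invariant under within-participant label
    # permutation: total SS, participant means, grand mean
    grand = data.mean(axis=(0, 1))
    m_subj = data.mean(axis=1)
    ss_within_rows = ((data - m_subj[:, None, :]) ** 2).sum(axis=(0, 1))
    df1, df2 = a - 1, (a - 1) * (n - 1)

    f_out = np.empty((n_total, ne))
    for lo in range(0, n_total, chunk):
        hi = min(lo + chunk, n_total)
        idx = perms_per_subject[choices[lo:hi]]  # (chunk, n, a)
        permuted = np.take_along_axis(
            data[None, :, :, :], idx[:, :, :, None], axis=2
        )  # (chunk, n, a, E)
        m_cond = permuted.mean(axis=1)  # (chunk, a, E)
        ss_cond = n * ((m_cond - grand[None, None, :]) ** 2).sum(axis=1)
        ss_err = ss_within_rows[None, :] - ss_cond
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_cond / df1) / (np.maximum(ss_err, 0.0) / df2)
        f_out[lo:hi] = np.nan_to_num(f, nan=0.0, posinf=np.inf)
    return f_out, n_total, exhaustive


def _p_fwe(observed_size: int, null_max: np.ndarray, exhaustive: bool) -> float:
    c = int(np.sum(null_max >= observed_size))
    if exhaustive:
        return c / len(null_max)
    return (1 + c) / (1 + len(null_max))


def permutation_fwe(
    mat_a,
    mat_b,
    threshold: float,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> NetworkResult:
    """Two-condition network test at one fixed supra-threshold K."""
    a = _as_edge_array(mat_a)
    b = _as_edge_array(mat_b)
    if a.shape != b.shape:
        raise ValueError("condition arrays must be paired with equal shapes")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = a - b
    f_obs = _paired_f_from_diffs(d)
    f_perm, n_total, exhaustive = _two_level_perm_f(d, n_perm, rng)
    return _result_at_thresholds(
        f_obs, f_perm, np.array([threshold]), n_total, exhaustive, alpha
    )[0]


def _result_at_thresholds(
    f_obs: np.ndarray,
    f_perm: np.ndarray,
    thresholds: np.ndarray,
    n_total: int,
    exhaustive: bool,
    alpha: float,
) -> list[NetworkResult]:
    ne = len(f_obs)
    n_regions = int((1 + np.sqrt(1 + 8 * ne)) / 2)
    pairs = edge_pairs(n_regions)
    null_curves = _null_max_size_curves(f_perm, pairs, thresholds)
    results = []
    for t_idx, k in enumerate(thresholds):
        comps = suprathreshold_components(f_obs, float(k), n_regions)
        null_max = null_curves[:, t_idx]
        p_vals = [_p_fwe(c.size, null_max, exhaustive) for c in comps]
        sig = [p < alpha for p in p_vals]
        results.append(
            NetworkResult(
                threshold=float(k), components=comps, p_fwe=p_vals,
                n_permutations=n_total, significant=sig,
                f_values=f_obs, null_max_sizes=null_max,
            )
        )
    return results


def threshold_search(
    mat_a,
    mat_b,
    f_range: tuple[float, float] = (3.0, 10.0),
    step: float = 0.1,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    statistic: str = "two_level",
    data_three=None,
) -> NetworkResult:
    """Scan F thresholds and return the result at the largest K that
    still yields at least one significant component.

    One set of permutations is shared across the whole grid. When no
    grid value yields a significant network the returned result has
    ``threshold=None`` and no components.
    """
    lo, hi = f_range
    if not (hi >= lo):
        raise ValueError("empty threshold range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = np.round(np.arange(lo, hi + step / 2, step), 10)

    if statistic == "two_level":
        a = _as_edge_array(mat_a)
        b = _as_edge_array(mat_b)
        d = a - b
        f_obs = _paired_f_from_diffs(d)
        f_perm, n_total, exhaustive = _two_level_perm_f(d, n_perm, rng)
    elif statistic == "three_level":
        f_obs, _ = rm_anova_f(data_three)
        f_perm, n_total, exhaustive = _three_level_perm_f(data_three, n_perm, rng)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    results = _result_at_thresholds(f_obs, f_perm, grid, n_total, exhaustive, alpha)
    for res in reversed(results):  # largest K first
        if res.any_significant:
            return res
    return NetworkResult(
        threshold=None, components=[], p_fwe=[], n_permutations=n_total,
        significant=[], f_values=f_obs,
    )


# ---------------------------------------------------------------------------
# post-hoc stages


def select_top_edges(
    network: NetworkResult,
    mat_a,
    mat_b,
    k: int = 32,
    alpha: float = 0.05,
) -> list[EdgeTest]:
    """Rank significant-component edges by |mean difference|, test the
    top ``k`` with uncorrected two-tailed paired t, keep survivors,
    split by direction ("A>B" vs "B>A")."""
    comps = network.significant_components()
    if not comps:
        return []
    a = _as_edge_array(mat_a)
    b = _as_edge_array(mat_b)
    d = a - b  # (n, E)
    n_regions = int((1 + np.sqrt(1 + 8 * d.shape[1])) / 2)
    edges = sorted({e for c in comps for e in c.edges})
    from .edgeops import edge_index

    idx = np.array([edge_index(i, j, n_regions) for i, j in edges])
    mean_diff = d[:, idx].mean(axis=0)
    # deterministic ordering: |diff| descending, then region indices
    order = sorted(
        range(len(edges)), key=lambda q: (-abs(mean_diff[q]), edges[q])
    )
    order = order[: min(k, len(order))]
    out = []
    for q in order:
        col = d[:, idx[q]]
        t, p = stats.ttest_1samp(col, 0.0)
        if np.isnan(p):
            continue
        if p < alpha and mean_diff[q] != 0:
            out.append(
                EdgeTest(
                    edge=edges[q], mean_diff=float(mean_diff[q]),
                    t=float(t), p=float(p),
                    direction="A>B" if mean_diff[q] > 0 else "B>A",
                )
            )
    network.top_edges = out
    return out


def monotonic_trend(
    data: dict[str, np.ndarray],
    ordered_conditions: tuple[str, str, str],
    f_range: tuple[float, float] = (3.0, 10.0),
    step: float = 0.1,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    network: NetworkResult | None = None,
) -> TrendResult:
    """Three-condition trend analysis.

    Runs (or reuses) a three-level NBS threshold search, then flags an
    edge of a significant component as monotonic when its three
    condition means are strictly ordered AND at least one adjacent
    pairwise paired t is significant at ``alpha``. Ties in means flag
    "none".
    """
    if len(ordered_conditions) != 3:
        raise ValueError("exactly three ordered conditions required")
    cube = np.stack(
        [_as_edge_array(data[c]) for c in ordered_conditions], axis=1
    )  # (n, 3, E)
    if network is None:
        network = threshold_search(
            None, None, f_range=f_range, step=step, n_perm=n_perm,
            seed=seed, alpha=alpha, statistic="three_level", data_three=cube,
        )
    comps = network.significant_components()
    n_regions = int((1 + np.sqrt(1 + 8 * cube.shape[2])) / 2)
    from .edgeops import edge_index

    trend_edges = []
    for comp in comps:
        for (i, j) in comp.edges:
            col = cube[:, :, edge_index(i, j, n_regions)]  # (n, 3)
            m1, m2, m3 = col.mean(axis=0)
            _, p12 = stats.ttest_rel(col[:, 0], col[:, 1])
            _, p23 = stats.ttest_rel(col[:, 1], col[:, 2])
            sig_adjacent = (p12 < alpha) or (p23 < alpha)
            if m1 < m2 < m3 and sig_adjacent:
                flag = "increasing"
            elif m1 > m2 > m3 and sig_adjacent:
                flag = "decreasing"
            else:
                flag = "none"
            trend_edges.append(
                TrendEdge(
                    edge=(i, j), means=(float(m1), float(m2), float(m3)),
                    monotonic=flag, adjacent_p=(float(p12), float(p23)),
                )
            )
    return TrendResult(network=network, edges=trend_edges)
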