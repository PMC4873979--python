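"""Subpopulation gating, quantification and rare-event detection on viSNE maps.

Subpopulations are polygonal gates drawn in map coordinates (stored
geometrically so that expert categorization is reproducible), each map
point is labeled by the gate containing it or "uncategorized", and
per-sample counts/fractions are tabulated. Small detached map clusters —
candidate rare events such as microplastic particles — are found by
density-connected component analysis, and fluorescence sort gates are
derived from the events of a detected cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.sparse.csgraph import connected_components
from shapely.geometry import Polygon
from sklearn.neighbors import radius_neighbors_graph

from .errors import GateOverlapError
from .fcio import ARCSINH, EventTable
from .embedding import ViSNEMap, compute_visne
from .preprocess import subsample_equal

UNCATEGORIZED = "uncategorized"

#: Sorter-wavelength aliases to analyzer channel names.
SORT_CHANNEL_ALIASES = {
    "448": "FL448", "576": "FL575", "620": "FL620", "695": "FL695", "722": "FL725",
}


@dataclass(frozen=True)
class Gate:
    """A named, closed, non-self-intersecting polygon in map coordinates."""

    name: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise ValueError(f"gate {self.name}: need >= 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"gate {self.name}: polygon is invalid or degenerate")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class GateSet:
    """Ordered gates; pairwise overlap above 0.1% of either area is rejected."""

    gates: tuple[Gate, ...]
    overlap_tolerance: float = 1e-3

    def __post_init__(self):
        names = [g.name for g in self.gates]
        if len(set(names)) != len(names):
            raise ValueError("gate names must be unique")
        polys = [g.polygon for g in self.gates]
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                inter = polys[i].intersection(polys[j]).area
                if inter > self.overlap_tolerance * min(polys[i].area, polys[j].area):
                    raise GateOverlapError(
                        f"gates {names[i]!r} and {names[j]!r} overlap by "
                        f"{inter:.4g} map-units^2")

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.gates]

    def save(self, path: str | Path) -> Path:
        """Plain structured text: one block per gate, 'x y' vertex lines."""
        lines = []
        for g in self.gates:
            lines.append(f"[{g.name}]")
            lines += [f"{x:.10g} {y:.10g}" for x, y in g.vertices]
            lines.append("")
        Path(path).write_text("\n".join(lines))
        return Path(path)

    @classmethod
    def load(cls, path: str | Path) -> "GateSet":
        gates, name, verts = [], None, []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                if name is not None:
                    gates.append(Gate(name, tuple(verts)))
                name, verts = line[1:-1], []
            else:
                x, y = line.split()
                verts.append((float(x), float(y)))
        if name is not None:
            gates.append(Gate(name, tuple(verts)))
        return cls(tuple(gates))


def assign_gates(vmap: ViSNEMap, gates: GateSet) -> np.ndarray:
    """Label each map point by the gate containing it (boundary inclusive).

    Points outside every gate are labeled "uncategorized". Deterministic and
    independent of point order; with a valid (non-overlapping) gate set at
    most one gate can contain a point, earlier gates win on shared borders.
    """
    labels = np.full(vmap.n_points, UNCATEGORIZED, dtype=object)
    unassigned = np.ones(vmap.n_points, dtype=bool)
    x, y = vmap.coords[:, 0], vmap.coords[:, 1]
    for gate in gates.gates:
        if not unassigned.any():
            break
        ix = np.flatnonzero(unassigned)
        # intersects == inside or on the boundary (closed polygon)
        hit = shapely.intersects_xy(gate.polygon, x[ix], y[ix])
        labels[ix[hit]] = gate.name
        unassigned[ix[hit]] = False
    return labels


def auto_gates(vmap: ViSNEMap, labels: np.ndarray | None = None,
               core_quantile: float = 0.95, min_points: int = 30,
               overlap_tolerance: float = 1e-3) -> GateSet:
    """Derive polygon gates from labeled map points (reproducible "expert" gating).

    For each label, the gate is the convex hull of the points within the
    ``core_quantile`` radius around the label's map medoid; trimming the
    radial tail keeps hulls of well-separated clusters disjoint and leaves a
    small uncategorized fringe, as manual gating does. If two hulls still
    overlap beyond the tolerance (adjacent phenotypes such as consecutive
    decay stages), the offending hulls are shrunk stepwise until they
    separate — mirroring how an expert draws tighter gates around touching
    clusters.
    """
    lab = labels if labels is not None else vmap.labels
    if lab is None:
        raise ValueError("need per-point labels to derive gates")
    lab = np.asarray(lab, dtype=object)
    points: dict[str, np.ndarray] = {}
    for name in pd.unique(lab):
        pts = vmap.coords[lab == name]
        if pts.shape[0] >= min_points:
            points[str(name)] = pts

    def hull_of(pts: np.ndarray, q: float) -> Polygon | None:
        center = np.median(pts, axis=0)
        r = np.linalg.norm(pts - center, axis=1)
        core = pts[r <= np.quantile(r, q)]
        hull = shapely.convex_hull(shapely.multipoints(core))
        return hull if hull.geom_type == "Polygon" and hull.area > 0 else None

    quantile = {name: core_quantile for name in points}
    hulls = {name: hull_of(pts, core_quantile) for name, pts in points.items()}
    hulls = {n: h for n, h in hulls.items() if h is not None}
    for _ in range(100):
        worst, worst_ratio = None, overlap_tolerance
        names = list(hulls)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = hulls[names[i]], hulls[names[j]]
                inter = a.intersection(b).area
                if inter > overlap_tolerance * min(a.area, b.area):
                    ratio = inter / min(a.area, b.area)
                    if ratio > worst_ratio or worst is None:
                        worst_ratio = ratio
                        # shrink whichever hull the intersection occupies more of
                        worst = names[i] if inter / a.area >= inter / b.area \
                            else names[j]
        if worst is None:
            break
        quantile[worst] = max(quantile[worst] - 0.03, 0.5)
        new = hull_of(points[worst], quantile[worst])
        if new is None or quantile[worst] <= 0.5:
            hulls.pop(worst, None)
        else:
            hulls[worst] = new
    gates = tuple(
        Gate(name, tuple(np.asarray(h.exterior.coords)[:-1]))
        for name, h in hulls.items())
    return GateSet(gates, overlap_tolerance)


@dataclass
class SubpopulationTable:
    """Per-sample subpopulation counts and fractions (rows sum to 1)."""

    counts: pd.DataFrame     # samples x (subpopulations + uncategorized)
    fractions: pd.DataFrame
    pooled_fractions: pd.Series

    def __post_init__(self):
        if not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("fraction rows must sum to 1")


def quantify(labels: Sequence, origin: Sequence) -> SubpopulationTable:
    """Tabulate per-sample and pooled subpopulation counts and fractions."""
    labels = np.asarray(labels, dtype=object)
    origin = np.asarray(origin, dtype=object)
    if labels.shape[0] != origin.shape[0]:
        raise ValueError("labels and origin must be aligned")
    counts = pd.crosstab(pd.Series(origin, name="sample"),
                         pd.Series(labels, name="subpopulation"))
    # stable sample order: first appearance in origin
    counts = counts.reindex(index=pd.unique(origin))
    fractions = counts.div(counts.sum(axis=1), axis=0)
    pooled = counts.sum(axis=0) / counts.to_numpy().sum()
    return SubpopulationTable(counts, fractions, pooled)


# ---------------------------------------------------------------------------
# Rare-cluster detection
# ---------------------------------------------------------------------------

def _default_eps(coords: np.ndarray) -> float:
    """Connectivity radius from the map's own nearest-neighbour scale.

    Twice the 99th percentile of nearest-neighbour distances among unique
    map positions: nearly every point reaches its neighbour well within
    eps, so visually contiguous regions stay connected, while detached
    clusters (gaps of several within-cluster spacings) stay separate.
    """
    from sklearn.neighbors import NearestNeighbors

    uniq = np.unique(coords, axis=0)
    if uniq.shape[0] < 2:
        return 1.0
    d, _ = NearestNeighbors(n_neighbors=2).fit(uniq).kneighbors(uniq)
    return float(2.0 * np.quantile(d[:, 1], 0.99))


def detect_small_clusters(vmap: ViSNEMap, min_points: int = 20,
                          max_fraction: float = 0.02,
                          density_eps: float | None = None
                          ) -> list[dict]:
    """Find small detached map clusters (candidate rare populations).

    Clusters are the eps-connected components of the 2-D map (points closer
    than ``density_eps`` are connected); components with at least
    ``min_points`` members and at most ``max_fraction`` of all points are
    reported, sorted by size ascending. Components are by construction
    separated from each other by more than ``density_eps``. The default eps
    is 1/40 of the map bounding-box diagonal.

    Returns dicts with ``indices``, ``centroid`` and ``incidence`` (per-sample
    point counts).
    """
    coords = vmap.coords
    eps = density_eps if density_eps is not None else _default_eps(coords)
    if eps <= 0:
        raise ValueError("density_eps must be positive")
    # landmark-engine maps repeat coordinates heavily: cluster unique points
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    graph = radius_neighbors_graph(uniq, radius=eps, mode="connectivity",
                                   include_self=False)
    n_comp, comp_of_uniq = connected_components(graph, directed=False)
    comp = comp_of_uniq[inverse]
    n_total = coords.shape[0]
    out = []
    for c in range(n_comp):
        idx = np.flatnonzero(comp == c)
        if idx.size < min_points or idx.size > max_fraction * n_total:
            continue
        incidence = pd.Series(vmap.origin[idx]).value_counts().to_dict()
        out.append({
            "indices": idx,
            "centroid": coords[idx].mean(axis=0),
            "incidence": incidence,
        })
    out.sort(key=lambda d: d["indices"].size)
    return out


def derive_sort_gates(cluster_events: EventTable, channels: Sequence[str],
                      coverage: float = 0.99,
                      cofactor: float = 150.0) -> pd.DataFrame:
    """Per-channel raw-intensity intervals covering a cluster's events.

    For each requested channel (sorter wavelengths like "576" are aliased to
    analyzer names like "FL575"), the central quantile interval
    ``[(1-c)/2, (1+c)/2]`` containing at least ``coverage`` of the cluster
    is returned in raw units — directly usable as sorter gate bounds.
    """
    if cluster_events.n_events < 10:
        raise ValueError("need >= 10 cluster events to derive sort gates")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    values = cluster_events.values
    if cluster_events.space == ARCSINH:
        values = np.sinh(values) * cofactor
    n = values.shape[0]
    n_trim = n - int(np.ceil(coverage * n))  # interval keeps >= coverage * n
    lo_trim = n_trim // 2
    hi_trim = n_trim - lo_trim
    rows = []
    for ch in channels:
        name = SORT_CHANNEL_ALIASES.get(str(ch), str(ch))
        col = np.sort(values[:, cluster_events.panel.index(name)])
        rows.append({"channel": name, "lo": float(col[lo_trim]),
                     "hi": float(col[n - 1 - hi_trim])})
    return pd.DataFrame(rows)


def apply_sort_gates(events: EventTable, gates: pd.DataFrame,
                     cofactor: float = 150.0) -> np.ndarray:
    """Boolean mask of events inside every sort-gate interval (raw units)."""
    values = events.values
    if events.space == ARCSINH:
        values = np.sinh(values) * cofactor
    mask = np.ones(events.n_events, dtype=bool)
    for _, row in gates.iterrows():
        col = values[:, events.panel.index(row["channel"])]
        mask &= (col >= row["lo"]) & (col <= row["hi"])
    return mask


# ---------------------------------------------------------------------------
# Detection-limit scan
# ---------------------------------------------------------------------------

def detection_limit_scan(samples: Sequence, rare_label: str,
                         sizes: Sequence[int], seeds: Sequence[int],
                         min_points: int = 20, max_fraction: float = 0.02,
                         density_eps: float | None = None,
                         purity_threshold: float = 0.8,
                         perplexity: float = 30.0, n_iter: int = 1000,
                         engine: str = "auto",
                         max_landmarks: int = 5_000,
                         crowd_limit: int = 150_000,
                         ) -> tuple[pd.DataFrame, int | None]:
    """Rare-population detection limit over decreasing pooled sample sizes.

    For each total pooled size and seed: equal per-sample subsampling, map
    embedding, small-cluster detection; detection is declared when some
    small cluster consists of at least ``purity_threshold`` rare-labeled
    events. Samples must be in arcsinh space with ``event_labels`` marking
    the rare events.

    Returns the scan table (size, seed, detected, recovered_fraction,
    purity) and the smallest size detected under every seed (None if none).
    """
    n_samples = len(samples)
    for size in sizes:
        if size > crowd_limit or size % n_samples:
            raise ValueError(f"invalid pooled size {size}: must be <= "
                             f"{crowd_limit} and divisible by {n_samples}")
    rows = []
    for size in sizes:
        per_sample_n = size // n_samples
        for seed in seeds:
            pool = subsample_equal(samples, per_sample_n, seed)
            n_rare = int((pool.labels == rare_label).sum())
            vmap = compute_visne(pool, perplexity=perplexity, n_iter=n_iter,
                                 seed=seed, engine=engine,
                                 max_landmarks=max_landmarks)
            clusters = detect_small_clusters(vmap, min_points, max_fraction,
                                             density_eps)
            best_purity, recovered = 0.0, 0.0
            for cl in clusters:
                in_cl = pool.labels[cl["indices"]] == rare_label
                purity = float(in_cl.mean())
                if purity > best_purity:
                    best_purity = purity
                    recovered = float(in_cl.sum() / n_rare) if n_rare else 0.0
            rows.append({"size": size, "seed": seed,
                         "n_rare_in_pool": n_rare,
                         "detected": best_purity >= purity_threshold,
                         "purity": best_purity,
                         "recovered_fraction": recovered})
    table = pd.DataFrame(rows)
    smallest = None
    for size in sorted(sizes):
        if table.loc[table["size"] == size, "detected"].all():
            smallest = int(size)
            break
    return table, smallest
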