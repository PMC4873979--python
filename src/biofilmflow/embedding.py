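"""viSNE map construction and nearest-neighbour projection.

The map is a 2-D Barnes-Hut t-SNE embedding of arcsinh-space events, the
standard viSNE visualization of single-cell cytometry: points are placed by
gradient descent on the Kullback-Leibler divergence between high- and
low-dimensional neighbourhood distributions.

Engines
-------
``bh``        scikit-learn Barnes-Hut t-SNE on every pooled event.
``landmark``  Barnes-Hut t-SNE on a seeded uniform subsample of at most
              ``max_landmarks`` events; every remaining event is placed at
              the map coordinates of its Euclidean-nearest landmark in the
              12-D input space. Scales to the 150,000-event crowd limit at
              desk runtimes while preserving cluster-level geometry.
``auto``      ``bh`` up to ``max_landmarks`` events, ``landmark`` beyond.

Map coordinates have no physical units and are engine-dependent; analyses
built on them (gating, density, MMD, small-cluster detection) must not
depend on a specific engine's coordinate values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.distance import cdist
from sklearn.manifold import TSNE

from .errors import CrowdLimitError
from .fcio import ARCSINH, EventTable
from .preprocess import CROWD_LIMIT, PooledEvents

DEFAULT_MAX_LANDMARKS = 5_000


@dataclass
class ViSNEMap:
    """2-D map coordinates aligned 1:1 with their arcsinh-space source events."""

    coords: np.ndarray            # n x 2
    source: EventTable            # n x 12, arcsinh space
    origin: np.ndarray            # per-point sample id
    rng_seed: int
    perplexity: float
    labels: np.ndarray | None = None
    engine: str = "bh"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.shape != (self.source.n_events, 2):
            raise ValueError("coords must be n x 2 aligned with source events")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite map coordinates")
        if self.source.n_events > CROWD_LIMIT:
            raise CrowdLimitError(f"map has {self.source.n_events} points")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def save(self, directory: str | Path) -> Path:
        """Serialize as a directory: coords CSV, source CSV, metadata YAML."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        import pandas as pd
        coords = pd.DataFrame(self.coords, columns=["tsne1", "tsne2"])
        coords["origin"] = self.origin
        if self.labels is not None:
            coords["label"] = self.labels
        coords.to_csv(directory / "coords.csv", index=False)
        self.source.to_frame().to_csv(directory / "source.csv", index=False)
        meta = {"rng_seed": int(self.rng_seed), "perplexity": float(self.perplexity),
                "engine": self.engine, "n_points": int(self.n_points),
                "channels": self.source.panel.names}
        (directory / "map.yaml").write_text(yaml.safe_dump(meta))
        return directory

    @classmethod
    def load(cls, directory: str | Path, panel) -> "ViSNEMap":
        import pandas as pd
        directory = Path(directory)
        meta = yaml.safe_load((directory / "map.yaml").read_text())
        coords = pd.read_csv(directory / "coords.csv")
        source = pd.read_csv(directory / "source.csv")
        return cls(
            coords[["tsne1", "tsne2"]].to_numpy(),
            EventTable(source[panel.names].to_numpy(), panel, ARCSINH),
            coords["origin"].to_numpy(),
            int(meta["rng_seed"]), float(meta["perplexity"]),
            coords["label"].to_numpy() if "label" in coords else None,
            str(meta.get("engine", "bh")),
        )


def _bh_tsne(values: np.ndarray, perplexity: float, n_iter: int, seed: int) -> np.ndarray:
    tsne = TSNE(n_components=2, method="barnes_hut", perplexity=perplexity,
                max_iter=max(n_iter, 250), random_state=seed, init="pca",
                learning_rate="auto")
    return tsne.fit_transform(values)


def _nearest_source_index(source: np.ndarray, queries: np.ndarray,
                          chunk: int = 2048) -> np.ndarray:
    """Index of the Euclidean-nearest source row per query; ties -> lowest index."""
    out = np.empty(queries.shape[0], dtype=np.int64)
    for start in range(0, queries.shape[0], chunk):
        block = queries[start:start + chunk]
        d = cdist(block, source)
        out[start:start + chunk] = np.argmin(d, axis=1)  # argmin: first minimum
    return out


def compute_visne(pool: PooledEvents, perplexity: float = 30.0,
                  n_iter: int = 1000, seed: int = 0, engine: str = "auto",
                  max_landmarks: int = DEFAULT_MAX_LANDMARKS) -> ViSNEMap:
    """Embed a pooled event set into a 2-D viSNE map (seeded, deterministic)."""
    n = pool.n_events
    if n > CROWD_LIMIT:
        raise CrowdLimitError(f"pool of {n} events exceeds {CROWD_LIMIT}")
    if 3 * perplexity >= n:
        raise ValueError(f"perplexity {perplexity} too large for n={n}")
    if engine == "auto":
        engine = "bh" if n <= max_landmarks else "landmark"
    values = pool.events.values
    if engine == "bh":
        coords = _bh_tsne(values, perplexity, n_iter, seed)
    elif engine == "landmark":
        rng = np.random.default_rng(seed)
        k = min(max_landmarks, n)
        landmark_ix = np.sort(rng.choice(n, size=k, replace=False))
        lm_coords = _bh_tsne(values[landmark_ix], perplexity, n_iter, seed)
        coords = np.empty((n, 2))
        coords[landmark_ix] = lm_coords
        rest = np.setdiff1d(np.arange(n), landmark_ix)
        if rest.size:
            nearest = _nearest_source_index(values[landmark_ix], values[rest])
            coords[rest] = lm_coords[nearest]
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return ViSNEMap(coords, pool.events, pool.origin, seed, perplexity,
                    pool.labels, engine)


def project_onto_map(vmap: ViSNEMap, new_events: EventTable) -> np.ndarray:
    """Place held-out events at the coordinates of their nearest map point.

    Distance is Euclidean in the 12-D arcsinh space the map was built from;
    each projected point receives an existing map coordinate (no
    interpolation), with ties broken by the lowest source index.
    """
    if new_events.panel != vmap.source.panel:
        raise ValueError("panel mismatch between map source and new events")
    if new_events.space != ARCSINH:
        raise ValueError("new events must be in arcsinh space")
    if new_events.n_events == 0:
        return np.empty((0, 2))
    nearest = _nearest_source_index(vmap.source.values, new_events.values)
    return vmap.coords[nearest]


def map_density(vmap: ViSNEMap, sample_id: str, grid: int = 64) -> np.ndarray:
    """2-D histogram of one sample's points over the full map extent.

    Cells sum to the sample's point count; higher values mark denser
    submap regions.
    """
    if grid < 32:
        raise ValueError("grid must be >= 32")
    mask = vmap.origin == sample_id
    if not mask.any() and sample_id not in set(vmap.origin):
        raise ValueError(f"unknown sample id {sample_id!r}")
    x, y = vmap.coords[:, 0], vmap.coords[:, 1]
    xedges = np.linspace(x.min(), x.max() + 1e-9, grid + 1)
    yedges = np.linspace(y.min(), y.max() + 1e-9, grid + 1)
    hist, _, _ = np.histogram2d(x[mask], y[mask], bins=(xedges, yedges))
    return hist
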