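"""Map construction, projection and density: contracts and oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

import biofilmflow as bf
from biofilmflow.errors import CrowdLimitError
from biofilmflow.fcio import EventTable, Sample
from biofilmflow.preprocess import PooledEvents, transform_sample


def _pool_from_values(panel, values, labels=None):
    return PooledEvents(EventTable(values, panel, "arcsinh"),
                        np.repeat("s0", len(values)), len(values),
                        None if labels is None else np.asarray(labels))


def _agreement(labels_a, labels_b):
    """Best-of-two-relabelings agreement for binary partitions."""
    a = np.asarray(labels_a).astype(int)
    b = np.asarray(labels_b).astype(int)
    return max((a == b).mean(), (a == 1 - b).mean())


def test_two_components_recovered_by_kmeans(two_component_map):
    """Well-separated 12-D mixture stays separated on the 2-D map."""
    truth = (two_component_map.labels == "microplastic").astype(int)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(
        two_component_map.coords)
    assert _agreement(truth, km.labels_) >= 0.99


def test_same_seed_identical_coords(panel):
    rng = np.random.default_rng(0)
    pool = _pool_from_values(panel, rng.normal(2, 1, (600, 12)))
    a = bf.compute_visne(pool, seed=9, engine="bh", n_iter=500)
    b = bf.compute_visne(pool, seed=9, engine="bh", n_iter=500)
    np.testing.assert_array_equal(a.coords, b.coords)


def test_duplicate_points_are_mutual_neighbours(panel):
    rng = np.random.default_rng(1)
    values = rng.normal(2, 1, (400, 12))
    values[250] = values[50]  # exact duplicate
    pool = _pool_from_values(panel, values)
    vmap = bf.compute_visne(pool, seed=2, engine="bh", n_iter=500)
    d = cdist(vmap.coords[[50]], vmap.coords)[0]
    d[50] = np.inf
    assert np.argmin(d) == 250


def test_crowd_limit_and_perplexity_guards(panel):
    rng = np.random.default_rng(2)
    pool = _pool_from_values(panel, rng.normal(0, 1, (100, 12)).clip(0))
    with pytest.raises(ValueError):
        bf.compute_visne(pool, perplexity=40)  # 3*40 >= 100
    over = _pool_from_values(panel, np.zeros((150_001, 12)))
    with pytest.raises(CrowdLimitError):
        bf.compute_visne(over, seed=0)


def test_landmark_engine_covers_all_points(panel, profiles):
    spec = bf.CommunitySpec(((profiles["green_algae"], 0.5),
                             (profiles["sediment"], 0.5)))
    sample, _ = bf.simulate_community(spec, 3_000, seed=5, panel=panel)
    sample = transform_sample(sample)
    pool = bf.subsample_equal([sample], 3_000, seed=0)
    vmap = bf.compute_visne(pool, seed=1, engine="landmark", max_landmarks=800)
    assert vmap.coords.shape == (3_000, 2)
    # every non-landmark coordinate equals some landmark coordinate
    uniq = np.unique(vmap.coords, axis=0)
    assert uniq.shape[0] <= 800
    truth = (pool.labels == "sediment").astype(int)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(vmap.coords)
    assert _agreement(truth, km.labels_) >= 0.99


def test_projection_matches_brute_force(two_component_map, panel, profiles):
    """Projection equals an exhaustive nearest-neighbour scan (m=200)."""
    spec = bf.CommunitySpec(((profiles["green_algae"], 0.5),
                             (profiles["microplastic"], 0.5)))
    new, _ = bf.simulate_community(spec, 200, seed=77, panel=panel)
    new = transform_sample(new)
    got = bf.project_onto_map(two_component_map, new.events)
    d = cdist(new.events.values, two_component_map.source.values)
    expected = two_component_map.coords[np.argmin(d, axis=1)]
    np.testing.assert_array_equal(got, expected)
    # no interpolation: every projected point is an existing map coordinate
    map_rows = {tuple(r) for r in two_component_map.coords}
    assert all(tuple(r) in map_rows for r in got)


def test_projection_of_source_returns_own_coords(two_component_map):
    got = bf.project_onto_map(two_component_map, two_component_map.source)
    np.testing.assert_array_equal(got, two_component_map.coords)


def test_projection_rejects_raw_space(two_component_map, panel):
    raw = EventTable(np.zeros((1, 12)), panel, "raw")
    with pytest.raises(ValueError):
        bf.project_onto_map(two_component_map, raw)


def test_three_components_silhouette(panel, profiles):
    spec = bf.CommunitySpec(((profiles["green_algae"], 0.4),
                             (profiles["sediment"], 0.3),
                             (profiles["microplastic"], 0.3)))
    sample, _ = bf.simulate_community(spec, 5_000, seed=6, panel=panel)
    sample = transform_sample(sample)
    pool = bf.subsample_equal([sample], 5_000, seed=0)
    vmap = bf.compute_visne(pool, seed=4, engine="bh")
    assert silhouette_score(vmap.coords, pool.labels) > 0.5


def test_channel_permutation_invariance(panel, profiles):
    """Permuting input channel order leaves cluster structure intact."""
    spec = bf.CommunitySpec(((profiles["green_algae"], 0.5),
                             (profiles["microplastic"], 0.5)))
    sample, _ = bf.simulate_community(spec, 1_000, seed=8, panel=panel)
    sample = transform_sample(sample)
    pool = bf.subsample_equal([sample], 1_000, seed=0)
    truth = (pool.labels == "microplastic").astype(int)

    perm = np.random.default_rng(0).permutation(12)
    permuted_panel = bf.ChannelPanel(tuple(panel.channels[i] for i in perm))
    pool_perm = PooledEvents(
        EventTable(pool.events.values[:, perm], permuted_panel, "arcsinh"),
        pool.origin, pool.per_sample_n, pool.labels)

    for p in (pool, pool_perm):
        vmap = bf.compute_visne(p, seed=3, engine="bh", n_iter=500)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(vmap.coords)
        assert _agreement(truth, km.labels_) >= 0.99


def test_map_density_conservation(two_component_map):
    hist = bf.map_density(two_component_map, "2comp", grid=40)
    assert hist.shape == (40, 40)
    assert hist.sum() == two_component_map.n_points
    with pytest.raises(ValueError):
        bf.map_density(two_component_map, "nope")


def test_map_save_load_round_trip(tmp_path, two_component_map, panel):
    d = two_component_map.save(tmp_path / "map")
    back = bf.ViSNEMap.load(d, panel)
    np.testing.assert_allclose(back.coords, two_component_map.coords, atol=1e-9)
    np.testing.assert_allclose(back.source.values,
                               two_component_map.source.values, atol=1e-9)
    assert back.perplexity == two_component_map.perplexity
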