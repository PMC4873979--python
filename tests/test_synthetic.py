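"""Generator correctness: determinism, distributional targets, structure."""

import numpy as np
import pandas as pd
import pytest

import biofilmflow as bf
from biofilmflow.synthetic import RED_CHANNELS


def test_default_panel_layout(panel):
    assert len(panel) == 12
    assert sum(c.is_fluorescence for c in panel.channels) == 10
    assert len(set(panel.names)) == 12
    assert (panel.saturation_limits > 0).all()


def test_sample_events_deterministic(profiles):
    a = bf.sample_events(profiles["diatom"], 500, seed=42)
    b = bf.sample_events(profiles["diatom"], 500, seed=42)
    np.testing.assert_array_equal(a.values, b.values)
    c = bf.sample_events(profiles["diatom"], 500, seed=43)
    assert not np.array_equal(a.values, c.values)


def test_sample_events_rejects_empty(profiles):
    with pytest.raises(ValueError):
        bf.sample_events(profiles["diatom"], 0, seed=0)


def test_sample_events_mean_matches_location(panel, profiles):
    """Channel-wise arcsinh-space sample mean -> location +- 3 scale/sqrt(n)."""
    prof = profiles["green_algae"]
    n = 10_000
    events = bf.sample_events(prof, n, seed=1, panel=panel)
    y = np.arcsinh(events.values / 150.0)
    tol = 3 * prof.scale / np.sqrt(n)
    # clamping at raw 0 truncates only far-negative tails; locations here are
    # comfortably positive so the Gaussian mean law applies
    np.testing.assert_array_less(np.abs(y.mean(axis=0) - prof.location), tol + 0.01)


def test_raw_intensities_within_acquisition_range(panel, profiles):
    events = bf.sample_events(profiles["sediment"], 5_000, seed=2, panel=panel)
    assert (events.values >= 0).all()
    assert (events.values <= panel.saturation_limits).all()


def test_decay_series_monotone_red_only(panel, profiles):
    base = profiles["green_algae"]
    stages = bf.make_decay_series(base, 4, panel)
    assert len(stages) == 4
    red_ix = [panel.index(c) for c in RED_CHANNELS]
    other_ix = [i for i in range(len(panel)) if i not in red_ix]
    prev = base.location[red_ix]
    for stage in stages:
        cur = stage.location[red_ix]
        assert (cur < prev).all()
        np.testing.assert_array_equal(stage.location[other_ix],
                                      base.location[other_ix])
        prev = cur


def test_decay_observable_in_sampled_means(panel, profiles):
    """Red-channel arcsinh means of decay-stage samples decrease with stage."""
    base = profiles["green_algae"]
    stages = [base] + bf.make_decay_series(base, 3, panel)
    red_ix = [panel.index(c) for c in RED_CHANNELS]
    means = []
    for i, p in enumerate(stages):
        ev = bf.sample_events(p, 5_000, seed=100 + i, panel=panel)
        means.append(np.arcsinh(ev.values / 150.0)[:, red_ix].mean())
    assert all(a > b for a, b in zip(means, means[1:]))


def test_community_counts_multinomial(panel, profiles):
    spec = bf.CommunitySpec(((profiles["diatom"], 0.5),
                             (profiles["sediment"], 0.5)))
    sample, labels = bf.simulate_community(spec, 10_000, seed=9, panel=panel)
    assert labels.size == 10_000
    n_diatom = (labels == "diatom").sum()
    assert abs(n_diatom - 5_000) <= 200  # 4 sigma of Binomial(10000, .5)
    assert sample.n_events == 10_000
    np.testing.assert_array_equal(sample.event_labels, labels)


def test_community_single_component(panel, profiles):
    spec = bf.CommunitySpec(((profiles["diatom"], 1.0),))
    _, labels = bf.simulate_community(spec, 50, seed=0, panel=panel)
    assert set(labels) == {"diatom"}


def test_community_fraction_validation(profiles):
    with pytest.raises(ValueError):
        bf.CommunitySpec(((profiles["diatom"], 0.6), (profiles["sediment"], 0.6)))
    with pytest.raises(ValueError):
        bf.CommunitySpec(())


@pytest.mark.parametrize("n,fraction,expected", [
    (15_000, 1 / 150, 100),   # bead-spiking ratio 150:1
    (25_000, 0.01, 250),      # 1% of one 25,000-event site sample
])
def test_spike_rare_counts(panel, profiles, n, fraction, expected):
    spec = bf.CommunitySpec(((profiles["green_algae"], 1.0),))
    sample, _ = bf.simulate_community(spec, n, seed=1, panel=panel)
    spiked, idx = bf.spike_rare(sample, profiles["microplastic"], fraction, seed=2)
    assert idx.size == expected
    assert spiked.n_events == n
    assert (spiked.event_labels == "microplastic").sum() == expected
    np.testing.assert_array_equal(
        np.flatnonzero(spiked.event_labels == "microplastic"), idx)


def test_spike_rare_fraction_bounds(panel, profiles):
    spec = bf.CommunitySpec(((profiles["green_algae"], 1.0),))
    sample, _ = bf.simulate_community(spec, 200, seed=1, panel=panel)
    for bad in (0.0, 1.0, -0.1):
        with pytest.raises(ValueError):
            bf.spike_rare(sample, profiles["microplastic"], bad, seed=0)


def _simple_design(n_sites, noise_sd=0.0, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    env = pd.DataFrame({
        "flow": rng.uniform(0.1, 1.0, n_sites),
        "DOC": rng.uniform(1.0, 8.0, n_sites),
    }, index=[f"s{i}" for i in range(n_sites)])
    effects = pd.DataFrame(0.0, index=["flow"], columns=["green_algae"])
    effects.loc["flow", "green_algae"] = effect
    return bf.EnvEffectDesign(env, effects, noise_sd)


def test_site_series_no_effect_reproduces_base(panel, profiles):
    design = _simple_design(4)
    base = [0.4, 0.3, 0.3]
    profs = [profiles[k] for k in ("green_algae", "diatom", "sediment")]
    _, true_f = bf.simulate_site_series(design, base, profs, 500, seed=5,
                                        panel=panel)
    for _, row in true_f.iterrows():
        np.testing.assert_allclose(row.to_numpy(), base, atol=1e-12)


def test_site_series_monotone_driver(panel, profiles):
    design = _simple_design(6, effect=0.08)
    profs = [profiles[k] for k in ("green_algae", "diatom", "sediment")]
    _, true_f = bf.simulate_site_series(design, [0.4, 0.3, 0.3], profs, 500,
                                        seed=5, panel=panel)
    order = design.env["flow"].sort_values().index
    g = true_f.loc[order, "green_algae"].to_numpy()
    assert (np.diff(g) > 0).all()


def test_site_series_realized_fractions_track_truth(panel, profiles):
    design = _simple_design(3, noise_sd=0.02, effect=0.05)
    profs = [profiles[k] for k in ("green_algae", "diatom", "sediment")]
    n = 25_000
    samples, true_f = bf.simulate_site_series(design, [0.4, 0.3, 0.3], profs,
                                              n, seed=5, panel=panel)
    for s, (_, truth) in zip(samples, true_f.iterrows()):
        realized = pd.Series(s.event_labels).value_counts() / n
        for sub in true_f.columns:
            p = truth[sub]
            bound = 4 * np.sqrt(p * (1 - p) / n)
            assert abs(realized.get(sub, 0.0) - p) < bound


def test_site_series_fractions_renormalized(panel, profiles):
    design = _simple_design(5, noise_sd=0.05, effect=0.1, seed=3)
    profs = [profiles[k] for k in ("green_algae", "diatom", "sediment")]
    _, true_f = bf.simulate_site_series(design, [0.4, 0.3, 0.3], profs, 500,
                                        seed=6, panel=panel)
    np.testing.assert_allclose(true_f.sum(axis=1), 1.0, atol=1e-9)
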