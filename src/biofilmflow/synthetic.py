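"""Synthetic stain-free flow-cytometry communities.

Generates event data with the statistical structure of stream-biofilm
samples: mixtures of autofluorescent phenotypes (cyanobacteria-like,
green-algae/diatom-like), a chlorophyll-decay gradient of monotonically
fading red fluorescence, a non-organic "sediment" class (high sideward
scatter, lowest fluorescence everywhere), a rare microplastic-like class
with a polystyrene-bead signature, replicate noise, and site-level
subpopulation fractions linearly driven by environmental covariates.

Events are drawn as multivariate Gaussians in arcsinh space (the space the
downstream embedding operates in) and mapped back to raw intensities with
``raw = sinh(y) * cofactor``, clamped to the nonnegative acquisition range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fcio import (ARCSINH, RAW, Channel, ChannelPanel, DEFAULT_SATURATION,
                   EventTable, Sample)

#: Cofactor of the arcsinh transform linking raw and analysis space.
DEFAULT_COFACTOR = 150.0

#: Red (chlorophyll-range) fluorescence channels.
RED_CHANNELS = ("FL660", "FL695", "FL725", "FL755")

_FLUOR_NM = (425, 448, 510, 542, 575, 620, 660, 695, 725, 755)


def build_default_panel(saturation: float = DEFAULT_SATURATION) -> ChannelPanel:
    """The 12-channel default panel: FS, SS and ten fluorescence ranges.

    Fluorescence wavelengths span 425-755 nm, covering every wavelength the
    sort gates and redundancy analysis refer to (448, 510, 542, 575, 620,
    660, 695, 725, 755 nm).
    """
    channels = [Channel("FS", None, saturation), Channel("SS", None, saturation)]
    channels += [Channel(f"FL{nm}", float(nm), saturation) for nm in _FLUOR_NM]
    return ChannelPanel(tuple(channels))


@dataclass(frozen=True)
class PhenotypeProfile:
    """Optical signature of one subpopulation, in arcsinh space.

    ``location`` and ``scale`` are per-channel mean and spread of the
    arcsinh-transformed intensities; ``correlation`` is the 12x12 channel
    correlation (identity if omitted).
    """

    name: str
    location: np.ndarray
    scale: np.ndarray
    correlation: np.ndarray | None = None

    def __post_init__(self):
        loc = np.asarray(self.location, float)
        scale = np.asarray(self.scale, float)
        object.__setattr__(self, "location", loc)
        object.__setattr__(self, "scale", scale)
        if loc.shape != scale.shape or loc.ndim != 1:
            raise ValueError("location and scale must be 1-D of equal length")
        if not (scale > 0).all():
            raise ValueError("scale must be positive elementwise")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, float)
            object.__setattr__(self, "correlation", corr)
            if corr.shape != (loc.size, loc.size):
                raise ValueError("correlation shape mismatch")
            if not np.allclose(corr, corr.T, atol=1e-12):
                raise ValueError("correlation must be symmetric")
            if not np.allclose(np.diag(corr), 1.0, atol=1e-9):
                raise ValueError("correlation must have unit diagonal")
            if np.linalg.eigvalsh(corr).min() <= 0:
                raise ValueError("correlation must be positive definite")

    @property
    def covariance(self) -> np.ndarray:
        corr = self.correlation if self.correlation is not None \
            else np.eye(self.location.size)
        return corr * np.outer(self.scale, self.scale)

    def shifted(self, name: str, delta: np.ndarray) -> "PhenotypeProfile":
        return PhenotypeProfile(name, self.location + delta, self.scale,
                                self.correlation)


@dataclass(frozen=True)
class CommunitySpec:
    """Mixture of phenotype profiles with fractions summing to 1."""

    components: tuple[tuple[PhenotypeProfile, float], ...]

    def __post_init__(self):
        if not self.components:
            raise ValueError("community needs at least one component")
        fracs = np.array([f for _, f in self.components], float)
        if not ((fracs > 0) & (fracs <= 1)).all():
            raise ValueError("mixture fractions must be in (0, 1]")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {fracs.sum()}, not 1")

    @property
    def profiles(self) -> list[PhenotypeProfile]:
        return [p for p, _ in self.components]

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.components], float)


@dataclass(frozen=True)
class EnvEffectDesign:
    """Environmental driver design for site series.

    ``env`` is a sites x variables table (positive physico-chemical values,
    e.g. flow in m/s, DOC and Ca in mg/l); ``effects`` maps *standardized*
    (z-scored) environmental variables to additive shifts of subpopulation
    fractions; ``noise_sd`` is site-level Gaussian noise on the fractions.
    """

    env: pd.DataFrame
    effects: pd.DataFrame  # variables x subpopulations
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.env.isna().to_numpy().any():
            raise ValueError("env table has missing values")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        missing = [v for v in self.effects.index if v not in self.env.columns]
        if missing:
            raise ValueError(f"effect variables absent from env: {missing}")


def _raw_from_arcsinh(y: np.ndarray, cofactor: float, saturation: float) -> np.ndarray:
    raw = np.sinh(y) * cofactor
    return np.clip(raw, 0.0, saturation)


def sample_events(profile: PhenotypeProfile, n: int, seed: int,
                  panel: ChannelPanel | None = None,
                  cofactor: float = DEFAULT_COFACTOR) -> EventTable:
    """Draw ``n`` raw-space events from a phenotype profile (seeded)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    panel = panel or build_default_panel()
    if len(panel) != profile.location.size:
        raise ValueError("profile dimensionality does not match panel")
    rng = np.random.default_rng(seed)
    y = rng.multivariate_normal(profile.location, profile.covariance, size=n,
                                method="cholesky")
    sat = panel.saturation_limits
    raw = np.empty_like(y)
    for j in range(len(panel)):
        raw[:, j] = _raw_from_arcsinh(y[:, j], cofactor, sat[j])
    return EventTable(raw, panel, RAW)


def make_decay_series(base: PhenotypeProfile, n_stages: int,
                      panel: ChannelPanel | None = None,
                      step: float = 0.9) -> list[PhenotypeProfile]:
    """Profiles of progressively decaying phototrophs.

    Red-channel (FL660-FL755) arcsinh locations decrease strictly with the
    stage index — the optical correlate of consecutive chlorophyll decay —
    while all other channels are unchanged.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    panel = panel or build_default_panel()
    red_ix = [panel.index(c) for c in RED_CHANNELS]
    out = []
    for stage in range(1, n_stages + 1):
        delta = np.zeros(base.location.size)
        delta[red_ix] = -step * stage
        out.append(base.shifted(f"{base.name}_decay{stage}", delta))
    return out


def simulate_community(spec: CommunitySpec, n: int, seed: int,
                       panel: ChannelPanel | None = None,
                       sample_id: str = "community",
                       cofactor: float = DEFAULT_COFACTOR,
                       **meta) -> tuple[Sample, np.ndarray]:
    """Draw one mixed sample; component counts are multinomial in the fractions.

    Returns the sample (raw space, with ``event_labels`` set) and the
    per-event true component labels. Events are shuffled so that component
    membership is not encoded in row order.
    """
    panel = panel or build_default_panel()
    if n < len(spec.components):
        raise ValueError("n must be at least the number of components")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, spec.fractions)
    blocks, labels = [], []
    for (profile, _), c in zip(spec.components, counts):
        if c == 0:
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        blocks.append(sample_events(profile, c, sub_seed, panel, cofactor).values)
        labels.append(np.repeat(profile.name, c))
    values = np.vstack(blocks)
    labels = np.concatenate(labels)
    order = rng.permutation(n)
    values, labels = values[order], labels[order]
    sample = Sample(EventTable(values, panel, RAW), sample_id,
                    event_labels=labels, **meta)
    return sample, labels


def spike_rare(sample: Sample, profile: PhenotypeProfile, fraction: float,
               seed: int, cofactor: float = DEFAULT_COFACTOR) -> tuple[Sample, np.ndarray]:
    """Replace ``round(fraction * n)`` random events with rare-profile draws.

    Emulates spiking a community with reference particles (e.g. polystyrene
    beads at roughly 150:1). The event count is unchanged; the replaced
    indices are returned and the sample's ``event_labels`` updated to the
    rare profile's name at those positions.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = sample.n_events
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    spikes = sample_events(profile, max(k, 1), int(rng.integers(0, 2**31 - 1)),
                           sample.events.panel, cofactor)
    values = sample.events.values.copy()
    if k:
        values[idx] = spikes.values[:k]
    labels = (sample.event_labels.copy() if sample.event_labels is not None
              else np.full(n, "unspiked", dtype=object))
    labels = labels.astype(object)
    labels[idx] = profile.name
    spiked = Sample(EventTable(values, sample.events.panel, sample.events.space),
                    sample.sample_id, group=sample.group,
                    time_point=sample.time_point,
                    technical_replicate=sample.technical_replicate,
                    biological_replicate=sample.biological_replicate,
                    event_labels=labels, provenance=sample.provenance)
    return spiked, idx


def simulate_site_series(design: EnvEffectDesign,
                         base_fractions: Sequence[float],
                         profiles: Sequence[PhenotypeProfile],
                         n_per_site: int, seed: int,
                         panel: ChannelPanel | None = None,
                         cofactor: float = DEFAULT_COFACTOR,
                         ) -> tuple[list[Sample], pd.DataFrame]:
    """Samples whose subpopulation fractions respond linearly to covariates.

    Per site: ``fractions = renormalize(max(base + z(env) @ effects + noise, 0))``
    where ``z(env)`` is the column-standardized environment table. Returns
    the samples and the true fraction table used, enabling ordination
    parameter-recovery tests.
    """
    if n_per_site < 100:
        raise ValueError("n_per_site must be >= 100")
    base = np.asarray(base_fractions, float)
    if len(profiles) != base.size:
        raise ValueError("profiles and base_fractions lengths differ")
    subpops = [p.name for p in profiles]
    effects = design.effects.reindex(columns=subpops, fill_value=0.0)
    env = design.env
    z = (env - env.mean()) / env.std(ddof=0).replace(0.0, 1.0)
    shift = z[effects.index.tolist()].to_numpy() @ effects.to_numpy()

    rng = np.random.default_rng(seed)
    rows, samples = [], []
    for i, site in enumerate(env.index):
        f = base + shift[i] + rng.normal(0.0, design.noise_sd, size=base.size)
        if (f < 0).any():
            warnings.warn(f"site {site}: {int((f < 0).sum())} fraction(s) "
                          "floored at zero before renormalization")
            f = np.maximum(f, 0.0)
        f = f / f.sum()
        rows.append(f)
        spec = CommunitySpec(tuple(
            (p, float(fr)) for p, fr in zip(profiles, f) if fr > 0))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sample, _ = simulate_community(spec, n_per_site, sub_seed, panel,
                                       sample_id=str(site), cofactor=cofactor,
                                       group=str(site))
        samples.append(sample)
    true_fractions = pd.DataFrame(rows, index=env.index, columns=subpops)
    return samples, true_fractions


# ---------------------------------------------------------------------------
# Default phenotype library and study-analog fixtures
# ---------------------------------------------------------------------------

def _profile(name: str, panel: ChannelPanel, fs: float, ss: float,
             fl: dict[str, float], baseline: float = 0.8,
             scale: float = 0.35, corr: np.ndarray | None = None) -> PhenotypeProfile:
    loc = np.full(len(panel), baseline)
    loc[panel.index("FS")] = fs
    loc[panel.index("SS")] = ss
    for ch, v in fl.items():
        loc[panel.index(ch)] = v
    return PhenotypeProfile(name, loc, np.full(len(panel), scale), corr)


def default_profiles(panel: ChannelPanel | None = None) -> dict[str, PhenotypeProfile]:
    """Structural stand-ins for the optical classes seen in stream biofilms.

    Locations are arcsinh-space free parameters chosen for clear class
    geometry, not calibrated to any deposited instrument data: cyanobacteria
    carry phycocyanin-range (620/660 nm) fluorescence, green algae/diatoms
    strong chlorophyll red with correlated 510/542 nm, sediment has high SS
    and the lowest fluorescence everywhere, and the microplastic-like class
    has moderate FS, low red and elevated 448/575/620 nm — a polystyrene-bead
    signature.
    """
    panel = panel or build_default_panel()
    d = len(panel)
    # green algae/diatoms: collinear 510/542 loadings (redundant pair analog)
    corr = np.eye(d)
    for a, b in (("FL510", "FL542"), ("FL575", "FL620"), ("FL725", "FL755")):
        i, j = panel.index(a), panel.index(b)
        corr[i, j] = corr[j, i] = 0.97
    green = _profile("green_algae", panel, fs=5.0, ss=3.2,
                     fl={"FL425": 2.0, "FL448": 2.2, "FL510": 3.0, "FL542": 3.0,
                         "FL575": 2.2, "FL620": 2.4, "FL660": 5.4, "FL695": 5.2,
                         "FL725": 4.6, "FL755": 4.4}, corr=corr)
    cyano = _profile("cyanobacteria", panel, fs=3.6, ss=2.6,
                     fl={"FL425": 1.4, "FL448": 1.5, "FL510": 1.8, "FL542": 2.0,
                         "FL575": 3.4, "FL620": 5.2, "FL660": 5.6, "FL695": 4.4,
                         "FL725": 3.4, "FL755": 3.2}, corr=corr)
    diatom = _profile("diatom", panel, fs=6.0, ss=4.4,
                      fl={"FL425": 2.4, "FL448": 2.8, "FL510": 3.4, "FL542": 3.4,
                          "FL575": 2.6, "FL620": 2.6, "FL660": 6.0, "FL695": 5.8,
                          "FL725": 5.0, "FL755": 4.8}, corr=corr)
    sediment = _profile("sediment", panel, fs=4.2, ss=7.2,
                        fl={f"FL{nm}": 0.35 for nm in _FLUOR_NM},
                        baseline=0.35, scale=0.30)
    # brightest channels stay >3 sigma below the arcsinh saturation (~9.55)
    microplastic = _profile("microplastic", panel, fs=8.4, ss=1.2,
                            fl={"FL425": 5.2, "FL448": 8.2, "FL510": 2.2,
                                "FL542": 2.0, "FL575": 8.0, "FL620": 8.2,
                                "FL660": 0.7, "FL695": 0.6, "FL725": 0.5,
                                "FL755": 0.4}, scale=0.22)
    out = {p.name: p for p in (green, cyano, diatom, sediment, microplastic)}
    for stage in make_decay_series(green, 3, panel):
        out[stage.name] = stage
    return out


def field_analog_spec(panel: ChannelPanel | None = None) -> CommunitySpec:
    """Six-subpopulation baseline community used by the field-site fixtures."""
    prof = default_profiles(panel)
    return CommunitySpec((
        (prof["green_algae"], 0.28),
        (prof["diatom"], 0.17),
        (prof["cyanobacteria"], 0.15),
        (prof["green_algae_decay1"], 0.14),
        (prof["green_algae_decay2"], 0.14),
        (prof["sediment"], 0.12),
    ))


#: The three environmental drivers the site-series recovery fixture builds in.
TRUE_DRIVERS = ("flow", "DOC", "Ca")


def driver_recovery_design(seed: int, n_sites: int = 18,
                           effect: float = 0.05, noise_sd: float = 0.01,
                           panel: ChannelPanel | None = None,
                           ) -> tuple[EnvEffectDesign, list[float],
                                      list[PhenotypeProfile]]:
    """Site-series design with three true drivers among ten candidates.

    Flow pushes the healthy green-algae/diatom subpopulations, dissolved
    organic carbon (DOC) the cyanobacteria and decaying cells, and calcium
    the sediment class; the remaining seven physico-chemical candidates are
    generated independently of the community. Effects are per standard
    deviation of the (z-scored) variable and are five times the site-level
    noise by default. Returns (design, base_fractions, profiles).
    """
    panel = panel or build_default_panel()
    rng = np.random.default_rng(seed)
    # 10 candidates in total: 9 log-scale concentrations/rates plus pH
    log_mu = {"flow": -1.2, "DOC": 1.0, "Ca": 3.9, "chloride": 2.3,
              "potassium": 0.7, "sodium": 2.0, "silicate": 1.3,
              "conductivity": 6.0, "nitrate": 1.6}
    env = pd.DataFrame(
        {v: np.exp(rng.normal(mu, 0.5, n_sites)) for v, mu in log_mu.items()},
        index=[f"site{i:02d}" for i in range(n_sites)])
    env["pH"] = rng.uniform(7.4, 8.6, n_sites)
    spec = field_analog_spec(panel)
    subpops = [p.name for p in spec.profiles]
    effects = pd.DataFrame(0.0, index=list(TRUE_DRIVERS), columns=subpops)
    effects.loc["flow", "green_algae"] = effect
    effects.loc["flow", "diatom"] = 0.6 * effect
    effects.loc["DOC", "cyanobacteria"] = effect
    effects.loc["DOC", "green_algae_decay1"] = 0.6 * effect
    effects.loc["Ca", "sediment"] = effect
    design = EnvEffectDesign(env, effects, noise_sd)
    return design, list(spec.fractions), spec.profiles


def temperature_analog_samples(n_per_sample: int = 10_000, seed: int = 0,
                               time_points: Sequence[int] = (0, 7, 14, 21),
                               n_replicates: int = 3,
                               panel: ChannelPanel | None = None,
                               ) -> list[Sample]:
    """Temperature-stress analog: replicated samples over four time points.

    The decaying-cell fractions rise sharply by day 7 and then stay roughly
    stable, at the expense of the healthy green-algae/diatom fractions, so
    map structure is governed by time point rather than replicate noise.
    """
    panel = panel or build_default_panel()
    prof = default_profiles(panel)
    keys = ["green_algae", "diatom", "cyanobacteria",
            "green_algae_decay1", "green_algae_decay2", "sediment"]
    base = {0: (0.34, 0.22, 0.16, 0.10, 0.08, 0.10),
            7: (0.20, 0.14, 0.16, 0.22, 0.18, 0.10),
            14: (0.18, 0.13, 0.17, 0.23, 0.19, 0.10),
            21: (0.21, 0.15, 0.16, 0.21, 0.17, 0.10)}
    rng = np.random.default_rng(seed)
    samples = []
    for t in time_points:
        fracs = np.asarray(base.get(t, base[21]), float)
        for rep in range(1, n_replicates + 1):
            f = fracs * rng.uniform(0.95, 1.05, size=fracs.size)
            f = f / f.sum()
            spec = CommunitySpec(tuple(
                (prof[k], float(fr)) for k, fr in zip(keys, f)))
            s, _ = simulate_community(
                spec, n_per_sample, int(rng.integers(0, 2**31 - 1)), panel,
                sample_id=f"day{t}_rep{rep}", group=f"day{t}")
            s.time_point = t
            s.biological_replicate = rep
            samples.append(s)
    return samples


def field_analog_samples(n_per_site: int = 25_000, seed: int = 0,
                         sites: Sequence[str] = ("A", "B", "C", "D", "E", "F"),
                         spike_site: str | None = None,
                         spike_fraction: float = 0.01,
                         panel: ChannelPanel | None = None,
                         ) -> list[Sample]:
    """Six field-site analog samples; optionally spike one with microplastic.

    Site-to-site variation perturbs the baseline fractions mildly so sites
    differ without losing any subpopulation.
    """
    panel = panel or build_default_panel()
    spec = field_analog_spec(panel)
    prof = default_profiles(panel)
    rng = np.random.default_rng(seed)
    samples = []
    for site in sites:
        f = spec.fractions * rng.uniform(0.75, 1.25, size=len(spec.components))
        f = f / f.sum()
        site_spec = CommunitySpec(tuple(
            (p, float(fr)) for p, fr in zip(spec.profiles, f)))
        sample, _ = simulate_community(site_spec, n_per_site,
                                       int(rng.integers(0, 2**31 - 1)), panel,
                                       sample_id=f"site_{site}", group=site)
        if spike_site is not None and site == spike_site:
            sample, _ = spike_rare(sample, prof["microplastic"], spike_fraction,
                                   int(rng.integers(0, 2**31 - 1)))
        samples.append(sample)
    return samples
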