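"""Saturation gating, arcsinh transformation and equal-size pooling.

Acquisition gating removes every event at or above the digitizer's
saturation limit in any channel; analysis then proceeds on
arcsinh-transformed intensities (``y = asinh(x / cofactor)``, cofactor 150
by default), and embeddings are built from equal-sized per-sample pools
capped at 150,000 events to avoid t-SNE crowding.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr

from .errors import CrowdLimitError
from .fcio import ARCSINH, RAW, EventTable, Sample

DEFAULT_COFACTOR = 150.0
CROWD_LIMIT = 150_000


@dataclass
class PooledEvents:
    """Equal-sized per-sample pool in arcsinh space, ready for embedding."""

    events: EventTable
    origin: np.ndarray          # per-event originating sample id
    per_sample_n: int
    labels: np.ndarray | None = None  # optional per-event ground-truth labels

    def __post_init__(self):
        if self.events.space != ARCSINH:
            raise ValueError("pooled events must be in arcsinh space")
        if self.origin.shape[0] != self.events.n_events:
            raise ValueError("origin length != event count")
        if self.labels is not None and len(self.labels) != self.events.n_events:
            raise ValueError("labels length != event count")

    @property
    def n_events(self) -> int:
        return self.events.n_events

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.origin:
            seen.setdefault(s, None)
        return list(seen)


def filter_saturated(sample: Sample) -> tuple[Sample, int]:
    """Drop every event at or above the saturation limit in any channel.

    The limit value itself indicates clipping (digitizers clip *at* the
    limit), so the comparison is ``>=``. Idempotent.
    """
    if sample.events.space != RAW:
        raise ValueError("saturation gating operates on raw intensities")
    limits = sample.events.panel.saturation_limits
    keep = (sample.events.values < limits).all(axis=1)
    n_removed = int((~keep).sum())
    if n_removed == 0:
        return sample, 0
    out = sample.with_events(
        sample.events.take(keep),
        event_labels=None if sample.event_labels is None else sample.event_labels[keep],
        provenance=None if sample.provenance is None else sample.provenance[keep],
    )
    return out, n_removed


def arcsinh_transform(events: EventTable, cofactor: float = DEFAULT_COFACTOR) -> EventTable:
    """Map raw intensities to analysis space: ``x -> asinh(x / cofactor)``.

    Strictly monotone per channel and invertible by ``sinh(y) * cofactor``.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if events.space != RAW:
        raise ValueError("events are already transformed")
    return EventTable(np.arcsinh(events.values / cofactor), events.panel, ARCSINH)


def inverse_arcsinh(events: EventTable, cofactor: float = DEFAULT_COFACTOR) -> EventTable:
    """Inverse of :func:`arcsinh_transform`."""
    if events.space != ARCSINH:
        raise ValueError("events are not in arcsinh space")
    return EventTable(np.sinh(events.values) * cofactor, events.panel, RAW)


def transform_sample(sample: Sample, cofactor: float = DEFAULT_COFACTOR) -> Sample:
    """Convenience: arcsinh-transform a sample's events in place of raw ones."""
    return sample.with_events(arcsinh_transform(sample.events, cofactor))


def subsample_equal(samples: Sequence[Sample], per_sample_n: int, seed: int,
                    crowd_limit: int = CROWD_LIMIT) -> PooledEvents:
    """Pool a uniform without-replacement subsample of each sample.

    All samples must already be in arcsinh space and contain at least
    ``per_sample_n`` events; the pooled size may not exceed the crowd limit
    (hard error, never silent truncation). Deterministic given ``seed``.
    """
    if per_sample_n < 1:
        raise ValueError("per_sample_n must be >= 1")
    total = per_sample_n * len(samples)
    if total > crowd_limit:
        raise CrowdLimitError(
            f"pool of {total} events exceeds the crowd limit {crowd_limit}")
    panel = samples[0].events.panel
    rng = np.random.default_rng(seed)
    blocks, origins, labels = [], [], []
    have_labels = all(s.event_labels is not None for s in samples)
    for s in samples:
        if s.events.space != ARCSINH:
            raise ValueError(f"sample {s.sample_id}: transform to arcsinh first")
        if s.events.panel != panel:
            raise ValueError(f"sample {s.sample_id}: panel mismatch")
        if s.n_events < per_sample_n:
            raise ValueError(
                f"sample {s.sample_id} has {s.n_events} events, "
                f"fewer than per_sample_n={per_sample_n}")
        idx = rng.choice(s.n_events, size=per_sample_n, replace=False)
        idx.sort()
        blocks.append(s.events.values[idx])
        origins.append(np.repeat(s.sample_id, per_sample_n))
        if have_labels:
            labels.append(s.event_labels[idx])
    return PooledEvents(
        EventTable(np.vstack(blocks), panel, ARCSINH),
        np.concatenate(origins),
        per_sample_n,
        np.concatenate(labels) if have_labels else None,
    )


def channel_redundancy(events: EventTable, threshold: float = 0.95
                       ) -> list[tuple[str, str, float]]:
    """Channel pairs whose absolute Spearman correlation reaches ``threshold``.

    Rank correlation is used because it is invariant to the monotone raw
    scale. Returns ``(channel_a, channel_b, |rho|)`` sorted by correlation
    descending — e.g. instrument panels often carry redundant emission-range
    pairs that contribute no independent information.
    """
    if events.n_events < 100:
        raise ValueError("need at least 100 events for redundancy analysis")
    rho, _ = spearmanr(events.values)
    rho = np.atleast_2d(rho)
    names = events.panel.names
    pairs = []
    for i, j in combinations(range(len(names)), 2):
        r = abs(float(rho[i, j]))
        if r >= threshold:
            pairs.append((names[i], names[j], r))
    pairs.sort(key=lambda t: -t[2])
    return pairs
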