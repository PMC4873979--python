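"""Cytometry event containers and standard-format IO (CSV, FCS 3.0/3.1).

The pipeline works on event tables of stain-free flow-cytometry signal-area
intensities: forward scatter (FS), sideward scatter (SS) and ten
autofluorescence channels named by emission wavelength (``FL<nm>``).
Intensities live either in raw acquisition units or in arcsinh-transformed
analysis space; the :class:`EventTable` tracks which.
"""

from __future__ import annotations

import io
import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

RAW = "raw"
ARCSINH = "arcsinh"

#: Default saturation limit of the acquisition range, in arbitrary units.
DEFAULT_SATURATION = float(2**20 - 1)


@dataclass(frozen=True)
class Channel:
    """One detector channel of the panel.

    ``wavelength`` is the emission wavelength in nm for fluorescence
    channels and ``None`` for the scatter channels; ``saturation`` is the
    intensity at (or above) which the digitizer clips.
    """

    name: str
    wavelength: float | None = None
    saturation: float = DEFAULT_SATURATION

    def __post_init__(self):
        if self.saturation <= 0:
            raise ValueError(f"channel {self.name}: saturation must be > 0")

    @property
    def is_fluorescence(self) -> bool:
        return self.wavelength is not None


@dataclass(frozen=True)
class ChannelPanel:
    """Ordered set of detector channels with unique names."""

    channels: tuple[Channel, ...]

    def __post_init__(self):
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def saturation_limits(self) -> np.ndarray:
        return np.array([c.saturation for c in self.channels], dtype=float)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in panel {self.names}") from None

    def __len__(self) -> int:
        return len(self.channels)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChannelPanel):
            return NotImplemented
        return self.names == other.names

    def __hash__(self):
        return hash(tuple(self.names))


@dataclass
class EventTable:
    """n_events x n_channels matrix of signal-area intensities.

    Invariants: finite values, column count equals the panel size, and raw
    intensities are nonnegative.
    """

    values: np.ndarray
    panel: ChannelPanel
    space: str = RAW

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape[1] != len(self.panel):
            raise ValueError(
                f"{self.values.shape[1]} columns but panel has {len(self.panel)} channels"
            )
        if self.space not in (RAW, ARCSINH):
            raise ValueError(f"unknown space {self.space!r}")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("event table contains non-finite values")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.panel.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.panel.names)

    def take(self, indices: np.ndarray) -> "EventTable":
        return EventTable(self.values[indices], self.panel, self.space)


@dataclass
class Sample:
    """An event table plus acquisition metadata.

    ``event_labels`` optionally carries a per-event ground-truth or gate
    label (synthetic fixtures record the generating phenotype here);
    ``provenance`` carries the per-event originating sample id after
    replicate merging.
    """

    events: EventTable
    sample_id: str
    group: str | None = None
    time_point: str | int | None = None
    technical_replicate: str | int | None = None
    biological_replicate: str | int | None = None
    event_labels: np.ndarray | None = None
    provenance: np.ndarray | None = None

    def __post_init__(self):
        for name in ("event_labels", "provenance"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape[0] != self.events.n_events:
                    raise ValueError(f"{name} length != number of events")
                setattr(self, name, arr)

    @property
    def n_events(self) -> int:
        return self.events.n_events

    def with_events(self, events: EventTable, **kw) -> "Sample":
        return replace(self, events=events, **kw)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_events_csv(path: str | Path, panel: ChannelPanel, sample_id: str | None = None,
                    **meta) -> Sample:
    """Read a signal-area CSV export into a raw-space :class:`Sample`.

    The header must contain exactly the panel's channel names (any order);
    columns are reordered to the panel order and row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [n for n in panel.names if n not in df.columns]
    extra = [c for c in df.columns if c not in panel.names]
    if missing or extra:
        raise FormatError(
            f"{path.name}: column mismatch (missing={missing}, extra={extra})"
        )
    block = df[panel.names]
    bad = block.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0, 0])
        raise FormatError(f"{path.name}: non-numeric value at data row {row}")
    values = block.to_numpy(dtype=float)
    return Sample(EventTable(values, panel, RAW), sample_id or path.stem, **meta)


def write_events_csv(sample: Sample, path: str | Path) -> Path:
    """Write a sample's events as an RFC-4180 CSV (header row, '.' decimals)."""
    path = Path(path)
    sample.events.to_frame().to_csv(path, index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1
# ---------------------------------------------------------------------------

#: Map from instrument parameter names ($PnN) to this pipeline's channel
#: dialect. Extend for other instruments; suffix "-A" (area) is stripped
#: automatically, and height/width parameters ("-H"/"-W") are dropped.
DEFAULT_ALIASES: dict[str, str] = {
    "FS INT": "FS",
    "SS INT": "SS",
}


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    parts = raw.decode("latin-1").strip(delim).split(delim)
    if len(parts) % 2:
        parts = parts[:-1]
    return {k.strip().upper(): v for k, v in zip(parts[::2], parts[1::2])}


def _area_name(pnn: str, aliases: Mapping[str, str]) -> str | None:
    """Resolve an FCS parameter name to a panel channel, or None to drop it."""
    name = aliases.get(pnn, pnn)
    if name.endswith(("-H", "-W")):
        return None  # pulse height/width: area only is analysed
    if name.endswith("-A"):
        name = name[:-2]
    return name


def read_fcs(path: str | Path, panel: ChannelPanel,
             aliases: Mapping[str, str] | None = None, sample_id: str | None = None,
             **meta) -> Sample:
    """Read an FCS 3.0/3.1 list-mode file, keeping the panel's area parameters.

    Parameters whose resolved name is not in the panel (for example pulse
    height and width, or TIME) are ignored with a logged notice.
    """
    path = Path(path)
    aliases = {**DEFAULT_ALIASES, **(aliases or {})}
    blob = path.read_bytes()
    version = blob[:6].decode("latin-1", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"{path.name}: unsupported FCS version {version!r}")
    text_start = int(blob[10:18])
    text_end = int(blob[18:26])
    text = _parse_text_segment(blob[text_start:text_end + 1])
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F").upper()
    if datatype not in ("F", "D"):
        raise FormatError(f"{path.name}: unsupported $DATATYPE {datatype}")
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if datatype == "F" else 8
    data_start = int(text.get("$BEGINDATA") or blob[26:34])
    data_end = int(text.get("$ENDDATA") or blob[34:42])
    raw = blob[data_start:data_end + 1]
    need = n_tot * n_par * itemsize
    if len(raw) < need:
        raise FormatError(f"{path.name}: DATA segment shorter than $TOT*$PAR")
    dtype = np.dtype(f"{endian}f{itemsize}")
    data = np.frombuffer(raw[:need], dtype=dtype).reshape(n_tot, n_par).astype(float)

    pnn = [text.get(f"$P{i + 1}N", f"P{i + 1}") for i in range(n_par)]
    col_of: dict[str, int] = {}
    dropped = []
    for i, name in enumerate(pnn):
        resolved = _area_name(name, aliases)
        if resolved is not None and resolved in panel.names:
            col_of[resolved] = i
        else:
            dropped.append(name)
    missing = [n for n in panel.names if n not in col_of]
    if missing:
        raise FormatError(f"{path.name}: panel channels absent from FCS: {missing}")
    if dropped:
        logger.info("%s: ignoring %d non-area/unmatched parameters: %s",
                    path.name, len(dropped), dropped)
    values = data[:, [col_of[n] for n in panel.names]]
    return Sample(EventTable(values, panel, RAW), sample_id or path.stem, **meta)


def write_fcs(sample: Sample, path: str | Path,
              extra_params: Mapping[str, np.ndarray] | None = None) -> Path:
    """Write a minimal single-dataset FCS 3.0 file (fixture support only).

    Panel channels are written as ``<name>-A``; ``extra_params`` lets tests
    emit additional parameters (for example ``FL448-H``) to exercise the
    area-only reading rule.
    """
    path = Path(path)
    columns = {f"{n}-A": sample.events.column(n) for n in sample.events.panel.names}
    if extra_params:
        columns.update({k: np.asarray(v, float) for k, v in extra_params.items()})
    names = list(columns)
    data = np.column_stack([columns[n] for n in names]).astype("<f4")
    n_tot, n_par = data.shape

    kv = {
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$PAR": str(n_par), "$TOT": str(n_tot), "$NEXTDATA": "0",
    }
    for i, name in enumerate(names, start=1):
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = str(int(DEFAULT_SATURATION) + 1)

    def render(text_kv: dict[str, str]) -> bytes:
        out = "/" + "".join(f"{k}/{v}/" for k, v in text_kv.items())
        return out.encode("latin-1")

    header_len = 58
    # two passes: offsets depend on TEXT length, which depends on offsets
    begin_data = 0
    for _ in range(3):
        kv["$BEGINDATA"] = str(begin_data)
        kv["$ENDDATA"] = str(max(begin_data + data.nbytes - 1, 0))
        text = render(kv)
        new_begin = header_len + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    text = render(kv)
    text_start, text_end = header_len, header_len + len(text) - 1
    header = (f"FCS3.0    {text_start:>8d}{text_end:>8d}"
              f"{begin_data:>8d}{begin_data + data.nbytes - 1:>8d}"
              f"{0:>8d}{0:>8d}").encode("ascii")
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())
    return path


# ---------------------------------------------------------------------------
# Replicate merging
# ---------------------------------------------------------------------------

def merge_replicates(samples: Sequence[Sample], merged_id: str | None = None) -> Sample:
    """Concatenate technical/biological replicates into one sample.

    All inputs must share one panel, one intensity space and one group
    identity; per-event provenance (the originating sample id) is retained.
    """
    if not samples:
        raise ValueError("no samples to merge")
    panel = samples[0].events.panel
    space = samples[0].events.space
    group = samples[0].group
    for s in samples[1:]:
        if s.events.panel != panel:
            raise ValueError(f"sample {s.sample_id}: panel mismatch")
        if s.events.space != space:
            raise ValueError(f"sample {s.sample_id}: space mismatch")
        if s.group != group:
            raise ValueError(f"sample {s.sample_id}: group mismatch "
                             f"({s.group!r} != {group!r})")
    values = np.vstack([s.events.values for s in samples]) if samples else None
    provenance = np.concatenate(
        [np.repeat(s.sample_id, s.n_events) for s in samples])
    labels = None
    if all(s.event_labels is not None for s in samples):
        labels = np.concatenate([s.event_labels for s in samples])
    return Sample(
        EventTable(values, panel, space),
        merged_id or f"merged({','.join(s.sample_id for s in samples)})",
        group=group,
        event_labels=labels,
        provenance=provenance,
    )
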