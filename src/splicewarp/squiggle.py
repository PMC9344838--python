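"""Raw-signal handling: normalization, event tables, junction squiggles.

Raw current traces are normalized per read by median/MAD so that junction
squiggles are on the same scale as pore-model candidate squiggles.  A
signal-to-base *event table* (one row per basecalled read position giving
the half-open raw-sample interval assigned to it) links read coordinates
to signal; the junction squiggle of a JWR is the concatenation of the
samples of the event rows falling inside its read span, with isolated
current spikes removed.

The event table is a plain TSV (``read_id  base_index  start  end``) so
simulations and tests are fully self-contained; any resquiggle-style
aligner output can be converted to this dialect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .jwr import JWR

__all__ = [
    "EventTable",
    "JunctionSquiggle",
    "normalize_signal",
    "extract_junction_squiggle",
    "read_resquiggled_fast5",
    "load_event_tables",
    "write_event_tables",
    "load_signals",
    "write_signals",
]


@dataclass(frozen=True)
class EventTable:
    """Signal-to-base assignment for one read.

    ``base_index[i]`` is a 0-based position in the basecalled read whose
    raw samples are ``signal[start[i]:end[i]]``.  Rows are sorted by base
    index with non-overlapping, ordered sample intervals.
    """

    read_id: str
    base_index: np.ndarray
    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.base_index, dtype=int)
        s = np.asarray(self.start, dtype=int)
        e = np.asarray(self.end, dtype=int)
        if not (b.shape == s.shape == e.shape) or b.ndim != 1:
            raise ValueError("event table columns must be equal-length 1-D arrays")
        if np.any(np.diff(b) <= 0):
            raise ValueError("event rows must be strictly sorted by base index")
        if np.any(e <= s):
            raise ValueError("every event must contain at least one sample")
        if np.any(s[1:] < e[:-1]):
            raise ValueError("event sample intervals must be ordered and disjoint")
        object.__setattr__(self, "base_index", b)
        object.__setattr__(self, "start", s)
        object.__setattr__(self, "end", e)

    def __len__(self) -> int:
        return self.base_index.size


@dataclass(frozen=True)
class JunctionSquiggle:
    """Normalized current measurements x = (x1..xK) for one JWR."""

    measurements: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.measurements, dtype=float)
        if x.ndim != 1 or x.size < 1:
            raise ValueError("junction squiggle must be a non-empty 1-D array")
        if not np.all(np.isfinite(x)):
            raise ValueError("junction squiggle values must be finite")
        object.__setattr__(self, "measurements", x)

    @property
    def K(self) -> int:
        return int(self.measurements.size)


def normalize_signal(raw) -> np.ndarray:
    """Median/MAD normalization: (raw - median) / MAD.

    Removes per-read shift and scale so squiggles are mutually comparable;
    the output has median 0 and median absolute deviation 1.  Raises on a
    degenerate (MAD = 0) signal.
    """
    x = np.asarray(raw, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to normalize")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError("degenerate signal: median absolute deviation is zero")
    return (x - med) / mad


def extract_junction_squiggle(
    jwr: JWR,
    events: EventTable,
    normalized_signal,
    spike_threshold: float | None = 5.0,
) -> JunctionSquiggle:
    """Concatenate the samples of event rows inside the JWR read span.

    Samples further than ``spike_threshold`` normalized units from their
    event's median are dropped as current spikes (set to None to disable).
    Raises if no event row overlaps the span.
    """
    signal = np.asarray(normalized_signal, dtype=float)
    lo, hi = jwr.read_span
    mask = (events.base_index >= lo) & (events.base_index < hi)
    if not mask.any():
        raise ValueError(
            f"JWR {jwr.read_id} read span [{lo}, {hi}) not covered by event table"
        )
    pieces = []
    for s, e in zip(events.start[mask], events.end[mask]):
        seg = signal[s:e]
        if spike_threshold is not None and seg.size:
            med = np.median(seg)
            seg = seg[np.abs(seg - med) <= spike_threshold]
        if seg.size:
            pieces.append(seg)
    if not pieces:
        raise ValueError("all samples in the JWR span were removed as spikes")
    return JunctionSquiggle(np.concatenate(pieces))


def read_resquiggled_fast5(path, corrected_group: str = "RawGenomeCorrected_000"):
    """Optional adapter: one resquiggle-annotated single-read fast5 file
    into (read_id, raw signal, :class:`EventTable`).

    Reads the standard layout written by resquiggle-style tools: per-base
    event rows (``start``, ``length``) under
    ``Analyses/<corrected_group>/BaseCalled_template/Events`` with a
    ``read_start_rel_to_raw`` offset, and the raw samples under
    ``Raw/Reads/<read>/Signal``.  The event table dialect used everywhere
    else in this package is the supported interchange format; this adapter
    is a convenience for data that still lives in fast5 containers.
    """
    import h5py

    with h5py.File(str(path), "r") as fh:
        (read_name,) = list(fh["Raw/Reads"])
        raw_group = fh[f"Raw/Reads/{read_name}"]
        read_id = raw_group.attrs.get("read_id", read_name)
        if isinstance(read_id, bytes):
            read_id = read_id.decode()
        signal = np.asarray(raw_group["Signal"], dtype=float)
        bc = fh[f"Analyses/{corrected_group}/BaseCalled_template"]
        events = bc["Events"]
        offset = int(events.attrs.get("read_start_rel_to_raw", 0))
        starts = np.asarray(events["start"], dtype=int) + offset
        lengths = np.asarray(events["length"], dtype=int)
    table = EventTable(
        read_id=str(read_id),
        base_index=np.arange(starts.size),
        start=starts,
        end=starts + lengths,
    )
    return str(read_id), signal, table


def load_event_tables(path) -> dict[str, EventTable]:
    """Read the event-table TSV dialect into per-read tables."""
    frame = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    required = {"read_id", "base_index", "start", "end"}
    if not required.issubset(frame.columns):
        raise ValueError(f"event TSV must have columns {sorted(required)}")
    tables = {}
    for read_id, grp in frame.groupby("read_id", sort=False):
        grp = grp.sort_values("base_index")
        tables[str(read_id)] = EventTable(
            read_id=str(read_id),
            base_index=grp["base_index"].to_numpy(),
            start=grp["start"].to_numpy(),
            end=grp["end"].to_numpy(),
        )
    return tables


def write_event_tables(tables: dict[str, EventTable] | list[EventTable], path) -> None:
    items = tables.values() if isinstance(tables, dict) else tables
    rows = []
    for t in items:
        for b, s, e in zip(t.base_index, t.start, t.end):
            rows.append((t.read_id, int(b), int(s), int(e)))
    frame = pd.DataFrame(rows, columns=["read_id", "base_index", "start", "end"])
    frame.to_csv(path, sep="\t", index=False)


def load_signals(path) -> dict[str, np.ndarray]:
    """Read the signal store TSV: read_id, comma-joined raw samples."""
    signals = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError("signal TSV must start with a read_id header")
        for line in fh:
            read_id, payload = line.rstrip("\n").split("\t", 1)
            signals[read_id] = (
                np.array([float(v) for v in payload.split(",")])
                if payload
                else np.empty(0)
            )
    return signals


def write_signals(signals: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsamples\n")
        for read_id, sig in signals.items():
            joined = ",".join(repr(float(v)) for v in np.asarray(sig, dtype=float))
            fh.write(f"{read_id}\t{joined}\n")
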