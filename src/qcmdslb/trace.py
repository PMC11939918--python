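"""Multi-overtone QCM-D time series: container, CSV dialect, baseline tools.

The on-disk dialect is plain UTF-8 CSV with ``#``-prefixed metadata lines::

    # qcmdslb trace v1
    # units: time=min dF=Hz(F_n/n) dD=1e-6
    # normalized: true
    # baseline_window: 0.0,1.0
    # event: lipid_start=1.0
    # event: lipid_end=7.5
    # event: rinse=7.5
    time_min,f3,d3,f7,d7,f11,d11
    0.0,...

Frequency columns are ``f<n>`` and dissipation columns ``d<n>`` for each odd
overtone ``n``.  Values are written at full float precision so that
write -> read round-trips exactly.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    InvalidParameterError,
    InvalidWindowError,
    NormalizationStateError,
    OvertoneNotFoundError,
    TraceParseError,
)

_HEADER_MAGIC = "# qcmdslb trace v1"


@dataclass
class QcmdTrace:
    """Baseline-referenced dF/dD series for a set of overtones.

    ``df``/``dd`` map overtone number to a float array sharing ``time``'s
    length; ``events`` is an ordered tuple of ``(label, time_min)`` pairs
    recording the flow schedule (``lipid_start``, ``lipid_end``, ``rinse``).
    """

    time: np.ndarray                      # min, strictly increasing
    df: dict[int, np.ndarray]             # Hz, normalized F_n/n
    dd: dict[int, np.ndarray]             # 1e-6 units
    events: tuple[tuple[str, float], ...] = ()
    baseline_window: tuple[float, float] | None = None
    normalized: bool = True

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise TraceParseError("time vector must be 1-D with >= 2 samples")
        if not np.all(np.diff(self.time) > 0):
            raise TraceParseError("time vector must be strictly increasing")
        if not self.df:
            raise TraceParseError("at least one overtone is required")
        if set(self.df) != set(self.dd):
            raise TraceParseError("df and dd must cover the same overtones")
        for n in self.df:
            self.df[n] = np.asarray(self.df[n], dtype=float)
            self.dd[n] = np.asarray(self.dd[n], dtype=float)
            if len(self.df[n]) != len(self.time) or len(self.dd[n]) != len(self.time):
                raise TraceParseError(f"series length mismatch for overtone {n}")

    @property
    def overtones(self) -> tuple[int, ...]:
        return tuple(sorted(self.df))

    def event_time(self, label: str, default: float | None = None) -> float:
        for lab, t in self.events:
            if lab == label:
                return t
        if default is not None:
            return default
        raise KeyError(f"no event {label!r} in trace annotations")

    @property
    def lipid_start(self) -> float:
        """Start of lipid flow; defaults to the first time point if unannotated."""
        return self.event_time("lipid_start", default=float(self.time[0]))

    def series(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """(dF, dD) arrays for overtone ``n``."""
        if n not in self.df:
            raise OvertoneNotFoundError(
                f"overtone {n} not in trace (has {self.overtones})"
            )
        return self.df[n], self.dd[n]

    def to_dataframe(self):
        """Trace as a pandas DataFrame in column order time, f3, d3, ..."""
        import pandas as pd

        cols: dict[str, np.ndarray] = {"time_min": self.time}
        for n in self.overtones:
            cols[f"f{n}"] = self.df[n]
            cols[f"d{n}"] = self.dd[n]
        return pd.DataFrame(cols)

    def equals(self, other: "QcmdTrace") -> bool:
        return (
            self.overtones == other.overtones
            and np.array_equal(self.time, other.time)
            and all(np.array_equal(self.df[n], other.df[n]) for n in self.overtones)
            and all(np.array_equal(self.dd[n], other.dd[n]) for n in self.overtones)
            and self.events == other.events
            and self.baseline_window == other.baseline_window
            and self.normalized == other.normalized
        )


def write_trace(trace: QcmdTrace, destination) -> None:
    """Write ``trace`` in the v1 CSV dialect (deterministic byte output)."""
    lines = [_HEADER_MAGIC, "# units: time=min dF=Hz(F_n/n) dD=1e-6",
             f"# normalized: {'true' if trace.normalized else 'false'}"]
    if trace.baseline_window is not None:
        a, b = trace.baseline_window
        lines.append(f"# baseline_window: {a!r},{b!r}")
    for label, t in trace.events:
        lines.append(f"# event: {label}={t!r}")
    header = ["time_min"]
    for n in trace.overtones:
        header += [f"f{n}", f"d{n}"]
    lines.append(",".join(header))
    cols = [trace.time] + [s for n in trace.overtones for s in (trace.df[n], trace.dd[n])]
    for row in zip(*cols):
        lines.append(",".join(repr(float(v)) for v in row))
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(os.fspath(destination), "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)


def read_trace(source) -> QcmdTrace:
    """Parse a trace file in the v1 dialect.

    Missing overtone columns are allowed (at least one f/d pair required);
    rows containing non-finite values are rejected with their line numbers.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(os.fspath(source), "r", encoding="utf-8") as fh:
            text = fh.read()
    events: list[tuple[str, float]] = []
    baseline_window = None
    normalized = True
    header: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("event:"):
                try:
                    label, val = body[len("event:"):].strip().split("=", 1)
                    events.append((label.strip(), float(val)))
                except ValueError as exc:
                    raise TraceParseError(f"line {lineno}: bad event annotation") from exc
            elif body.startswith("baseline_window:"):
                try:
                    a, b = body[len("baseline_window:"):].strip().split(",")
                    baseline_window = (float(a), float(b))
                except ValueError as exc:
                    raise TraceParseError(f"line {lineno}: bad baseline_window") from exc
            elif body.startswith("normalized:"):
                normalized = body[len("normalized:"):].strip().lower() == "true"
            continue
        if header is None:
            header = [c.strip() for c in line.split(",")]
            continue
        try:
            rows.append([float(v) for v in line.split(",")])
        except ValueError as exc:
            raise TraceParseError(f"line {lineno}: non-numeric data") from exc
    if header is None or not rows:
        raise TraceParseError("no header/data rows found")
    if header[0] != "time_min":
        raise TraceParseError("missing time_min column")
    pairs: dict[int, tuple[int, int]] = {}
    for i, name in enumerate(header[1:], start=1):
        if name.startswith("f") and name[1:].isdigit():
            n = int(name[1:])
            dcol = f"d{n}"
            if dcol not in header:
                raise TraceParseError(f"column {name} has no matching {dcol}")
            pairs[n] = (i, header.index(dcol))
    if not pairs:
        raise TraceParseError("no overtone columns found")
    width = len(header)
    bad = [i for i, r in enumerate(rows)
           if len(r) != width or any(not math.isfinite(v) for v in r)]
    if bad:
        raise TraceParseError(f"non-finite or ragged data rows at indices {bad[:10]}")
    data = np.asarray(rows, dtype=float)
    time = data[:, 0]
    if not np.all(np.diff(time) > 0):
        i = int(np.argmin(np.diff(time)))
        raise TraceParseError(f"non-monotone time at data row {i + 1}")
    df = {n: data[:, fi].copy() for n, (fi, _) in pairs.items()}
    dd = {n: data[:, di].copy() for n, (_, di) in pairs.items()}
    return QcmdTrace(
        time=time, df=df, dd=dd, events=tuple(events),
        baseline_window=baseline_window, normalized=normalized,
    )


def default_baseline_window(trace: QcmdTrace) -> tuple[float, float]:
    """The minute preceding lipid flow (clipped to the trace start)."""
    start = trace.lipid_start
    return max(float(trace.time[0]), start - 1.0), start


def baseline_correct(
    trace: QcmdTrace, window: tuple[float, float] | None = None
) -> QcmdTrace:
    """Shift every series by its mean over ``window`` and record the window.

    The window must lie inside the time range and end no later than the
    lipid-flow start annotation (the baseline is recorded in buffer, before
    lipid injection).  Idempotent: correcting twice with the same window is
    a no-op up to floating-point roundoff.
    """
    if window is None:
        window = trace.baseline_window or default_baseline_window(trace)
    a, b = float(window[0]), float(window[1])
    if not (a < b):
        raise InvalidWindowError("baseline window must have t_start < t_end")
    if a < trace.time[0] - 1e-12 or b > trace.time[-1] + 1e-12:
        raise InvalidWindowError("baseline window outside the trace time range")
    if b > trace.lipid_start + 1e-9:
        raise InvalidWindowError("baseline window extends past lipid-flow start")
    mask = (trace.time >= a) & (trace.time <= b)
    if not mask.any():
        raise InvalidWindowError("baseline window contains no samples")
    df = {n: s - s[mask].mean() for n, s in trace.df.items()}
    dd = {n: s - s[mask].mean() for n, s in trace.dd.items()}
    return replace(trace, df=df, dd=dd, baseline_window=(a, b))


def normalize_overtones(trace: QcmdTrace) -> QcmdTrace:
    """Divide each raw frequency series by its overtone number.

    Instrument exports are usually already normalized (F_n/n); the
    ``normalized`` flag guards against dividing twice.
    """
    if trace.normalized:
        raise NormalizationStateError("trace is already overtone-normalized")
    df = {n: s / float(n) for n, s in trace.df.items()}
    return replace(trace, df=df, normalized=True)


def normalize_series(raw_f: np.ndarray, n: int) -> np.ndarray:
    """Normalized shift F_n/n for a single raw frequency-shift series."""
    if n < 1:
        raise InvalidParameterError("overtone number must be >= 1")
    return np.asarray(raw_f, dtype=float) / float(n)
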