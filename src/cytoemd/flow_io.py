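"""Event-level I/O, axis transforms and rectangular gating.

Flow cytometry events are carried through the pipeline as an
:class:`EventMatrix`: an N x d array of fluorescence intensities plus channel
labels and a tag recording which (if any) monotone transform has been applied.
Files are read either from FCS (2.0/3.0/3.1, list mode) or from delimited text
with a mandatory header row.  Compensation and density-based gating are out of
scope; population selection is rectangular gating or "take the file as given".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import (
    ChannelMismatchError,
    DegenerateInputError,
    ParameterError,
)

__all__ = [
    "EventMatrix",
    "RectGate",
    "read_events",
    "write_events",
    "transform",
    "gate",
    "asinh_transform",
    "logicle_transform",
    "LogicleParams",
]


@dataclass(frozen=True)
class EventMatrix:
    """N events by d channels of fluorescence intensities.

    Parameters
    ----------
    values
        Float array of shape (N, d).  No missing values are allowed.
    channels
        d unique channel labels.
    transform_tag
        ``"none"`` for raw intensities, ``"asinh"`` or ``"logicle"`` after
        :func:`transform` has been applied.
    """

    values: np.ndarray
    channels: tuple[str, ...]
    transform_tag: str = "none"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ParameterError("values must be a 2-D array of events x channels")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channels", tuple(str(c) for c in self.channels))
        n, d = values.shape
        if n < 1 or d < 1:
            raise DegenerateInputError(f"need at least one event and one channel, got shape {values.shape}")
        if d != len(self.channels):
            raise ParameterError(f"{d} columns but {len(self.channels)} channel labels")
        if len(set(self.channels)) != len(self.channels):
            raise ParameterError(f"channel labels must be unique: {self.channels}")
        if not np.all(np.isfinite(values)):
            raise ParameterError("event matrix contains non-finite values")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise ChannelMismatchError(
                f"channel {channel!r} not in {self.channels}"
            ) from None

    def column(self, channel: str) -> np.ndarray:
        return self.values[:, self.channel_index(channel)]

    def select_channels(self, channels: Sequence[str]) -> "EventMatrix":
        idx = [self.channel_index(c) for c in channels]
        return EventMatrix(self.values[:, idx], tuple(channels), self.transform_tag)


@dataclass(frozen=True)
class RectGate:
    """Axis-aligned gate: closed intervals on a subset of channels.

    Membership is inclusive on both boundaries.
    """

    intervals: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        clean = {}
        for channel, (lo, hi) in dict(self.intervals).items():
            lo, hi = float(lo), float(hi)
            if lo > hi:
                raise ParameterError(f"gate on {channel!r}: lower {lo} > upper {hi}")
            clean[str(channel)] = (lo, hi)
        if not clean:
            raise ParameterError("gate must constrain at least one channel")
        object.__setattr__(self, "intervals", clean)

    def to_json(self) -> str:
        return json.dumps({c: list(iv) for c, iv in self.intervals.items()})

    @classmethod
    def from_json(cls, text: str) -> "RectGate":
        data = json.loads(text)
        return cls({c: (lo, hi) for c, (lo, hi) in data.items()})


# ---------------------------------------------------------------------------
# reading / writing


def read_events(path: str | Path, format: str | None = None) -> EventMatrix:
    """Read an event matrix from an FCS or delimited-text file.

    ``format`` is ``"fcs"`` or ``"delimited"``; when omitted it is guessed
    from the file suffix (``.fcs`` => FCS, anything else delimited).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "delimited"
    if format == "fcs":
        values, channels = _read_fcs(path)
    elif format == "delimited":
        values, channels = _read_delimited(path)
    else:
        raise ParameterError(f"unknown format {format!r}")
    if values.shape[0] == 0:
        raise DegenerateInputError(f"{path} contains zero events")
    return EventMatrix(values, channels, transform_tag="none")


def write_events(events: EventMatrix, path: str | Path, sep: str = ",") -> None:
    """Write events as delimited text with a header row of channel names."""
    frame = pd.DataFrame(events.values, columns=list(events.channels))
    frame.to_csv(path, sep=sep, index=False)


def _read_delimited(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    try:
        # sniff comma vs tab from the header line
        with open(path) as fh:
            header = fh.readline()
        if not header.strip():
            raise DegenerateInputError(f"{path} is empty")
        sep = "\t" if "\t" in header else ","
        frame = pd.read_csv(path, sep=sep)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise DegenerateInputError(f"could not parse {path}: {exc}") from exc
    if frame.shape[0] == 0:
        raise DegenerateInputError(f"{path} has a header but zero events")
    values = frame.to_numpy(dtype=float)
    return values, tuple(str(c) for c in frame.columns)


def _read_fcs(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Minimal FCS 2.0/3.0/3.1 list-mode reader.

    Supports $DATATYPE F (float32), D (float64) and I (uniform-width
    unsigned integers), little- or big-endian.  Compensation keywords are
    ignored by design.
    """
    raw = path.read_bytes()
    if len(raw) < 58:
        raise DegenerateInputError(f"{path} too short to be an FCS file")
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS"):
        raise IOError(f"{path}: bad FCS magic {version!r}")

    def _offset(a: int, b: int) -> int:
        text = raw[a:b].decode("ascii", errors="replace").strip()
        return int(text) if text else 0

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)

    delim = raw[text_start : text_start + 1]
    body = raw[text_start + 1 : text_end]
    tokens = [t.decode("latin-1") for t in body.split(delim)]
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    if len(tokens) % 2:
        tokens = tokens[:-1]
    kw = {tokens[i].strip().upper(): tokens[i + 1] for i in range(0, len(tokens), 2)}

    if data_start == 0:
        data_start = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    if n_tot == 0:
        raise DegenerateInputError(f"{path}: $TOT is zero, no events")
    mode = kw.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise IOError(f"{path}: only list-mode ($MODE/L) FCS is supported, got {mode}")

    datatype = kw.get("$DATATYPE", "F").strip().upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32):
            raise IOError(f"{path}: unsupported integer widths {sorted(set(bits))}")
        dtype = np.dtype(f"{endian}u{bits[0] // 8}")
    else:
        raise IOError(f"{path}: unsupported $DATATYPE {datatype!r}")

    n_bytes = n_tot * n_par * dtype.itemsize
    if data_end and data_end - data_start + 1 < n_bytes:
        raise IOError(f"{path}: DATA segment shorter than $TOT*$PAR values")
    segment = raw[data_start : data_start + n_bytes]
    values = np.frombuffer(segment, dtype=dtype).reshape(n_tot, n_par).astype(float)

    channels = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N") or kw.get(f"$P{i}S") or f"P{i}"
        channels.append(name.strip())
    # de-duplicate defensively; some instruments emit repeated short names
    seen: dict[str, int] = {}
    unique = []
    for name in channels:
        if name in seen:
            seen[name] += 1
            name = f"{name}.{seen[name]}"
        else:
            seen[name] = 0
        unique.append(name)
    return values, tuple(unique)


# ---------------------------------------------------------------------------
# transforms


def asinh_transform(values: np.ndarray, cofactor: float = 150.0) -> np.ndarray:
    """Inverse hyperbolic sine scaling, asinh(x / cofactor)."""
    if cofactor <= 0:
        raise ParameterError(f"asinh cofactor must be positive, got {cofactor}")
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


@dataclass(frozen=True)
class LogicleParams:
    """Logicle (biexponential) display parameters.

    T is the top of scale, M the number of decades, W the linearization
    width in decades, A the number of additional negative decades.  The
    forward transform maps data value T to M + A decades.
    """

    T: float = 262144.0
    W: float = 0.5
    M: float = 4.5
    A: float = 0.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ParameterError(f"logicle T must be positive, got {self.T}")
        if self.W < 0:
            raise ParameterError(f"logicle W must be non-negative, got {self.W}")
        if self.M <= 0:
            raise ParameterError(f"logicle M must be positive, got {self.M}")
        if self.M + self.A <= 0:
            raise ParameterError("logicle requires M + A > 0")
        if (self.A + 2.0 * self.W) / (self.M + self.A) > 1.0:
            raise ParameterError("logicle W/A too large for the number of decades M")


def _logicle_coefficients(p: LogicleParams) -> tuple[float, float, float, float, float]:
    """Coefficients (a, b, c, d, f) of the biexponential S(y) = a e^{by} - c e^{-dy} - f.

    S maps normalized display position y in [0, 1] to data value, with
    S(1) = T and S(x1) = 0 at the transition point x1.  d solves
    2 (ln d - ln b) + w (b + d) = 0, the smoothness condition that makes the
    scale quasi-linear over width W decades around zero.
    """
    span = p.M + p.A
    w = p.W / span
    x2 = p.A / span
    x1 = x2 + w
    x0 = x2 + 2.0 * w
    b = span * np.log(10.0)
    if w == 0.0:
        d = b
    else:
        g = lambda d: 2.0 * (np.log(d) - np.log(b)) + w * (b + d)
        d = brentq(g, 1e-12, b, xtol=1e-14, rtol=8.9e-16)
    c_a = np.exp(x0 * (b + d))
    mf_a = np.exp(b * x1) - c_a * np.exp(-d * x1)
    a = p.T / (np.exp(b) - c_a * np.exp(-d) - mf_a)
    return a, b, c_a * a, d, mf_a * a


def logicle_inverse(y_decades: np.ndarray, params: LogicleParams) -> np.ndarray:
    """Biexponential: display position (decades) -> data value."""
    a, b, c, d, f = _logicle_coefficients(params)
    y = np.asarray(y_decades, dtype=float) / (params.M + params.A)
    return a * np.exp(b * y) - c * np.exp(-d * y) - f


def logicle_transform(values: np.ndarray, params: LogicleParams | None = None) -> np.ndarray:
    """Logicle scaling: data value -> display position in decades.

    The biexponential has no closed-form inverse; each value is solved by
    bracketed root finding, which is exact to solver tolerance and strictly
    monotone.
    """
    if params is None:
        params = LogicleParams()
    a, b, c, d, f = _logicle_coefficients(params)
    span = params.M + params.A

    def _solve(x: float) -> float:
        fn = lambda y: a * np.exp(b * y) - c * np.exp(-d * y) - f - x
        lo, hi = -1.0, 2.0
        while fn(lo) > 0:
            lo *= 2.0
        while fn(hi) < 0:
            hi *= 2.0
        return brentq(fn, lo, hi, xtol=1e-12, rtol=8.9e-16)

    flat = np.asarray(values, dtype=float).ravel()
    out = np.fromiter((_solve(x) for x in flat), dtype=float, count=flat.size)
    return (out * span).reshape(np.shape(values))


def transform(
    events: EventMatrix,
    method: str = "asinh",
    channels: Sequence[str] | None = None,
    cofactor: float = 150.0,
    logicle_params: LogicleParams | None = None,
) -> EventMatrix:
    """Apply a monotone axis transform to selected channels.

    ``channels=None`` transforms every channel.  The input must be untransformed
    (``transform_tag == "none"``); transforms are not stacked.
    """
    if events.transform_tag != "none":
        raise ParameterError(f"events already transformed ({events.transform_tag})")
    if channels is None:
        idx = list(range(events.n_channels))
    else:
        idx = [events.channel_index(c) for c in channels]
    values = events.values.copy()
    if method == "asinh":
        values[:, idx] = asinh_transform(values[:, idx], cofactor=cofactor)
    elif method == "logicle":
        values[:, idx] = logicle_transform(values[:, idx], logicle_params)
    else:
        raise ParameterError(f"unknown transform {method!r}")
    return EventMatrix(values, events.channels, transform_tag=method)


# ---------------------------------------------------------------------------
# gating


def gate(events: EventMatrix, g: RectGate) -> EventMatrix:
    """Keep events inside every gated interval (closed bounds); order preserved."""
    mask = np.ones(events.n_events, dtype=bool)
    for channel, (lo, hi) in g.intervals.items():
        col = events.column(channel)
        mask &= (col >= lo) & (col <= hi)
    surviving = int(mask.sum())
    if surviving == 0:
        raise DegenerateInputError(
            f"gate removed all events (0 of {events.n_events} survive)"
        )
    return EventMatrix(events.values[mask], events.channels, events.transform_tag)
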