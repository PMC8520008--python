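"""Reading and writing flow cytometry standard (FCS) files and compensation.

Implements the subset of FCS 3.0/3.1 needed for single-stain spillover
analysis: list-mode data in integer, float or double format, the standard
TEXT-segment keyword scaling ($PnE log amplification, $PnG linear gain),
and the spillover-matrix keyword in its standard ($SPILLOVER) and legacy
(SPILL, $COMP) spellings.  Files are written as FCS 3.1 with float32 data.

Compensation is the usual linear unmixing for conventional cytometers:
an observed event row ``o`` relates to the true fluorochrome signal ``t``
through the spillover matrix ``S`` (rows = fluorochromes, columns =
detectors, unit diagonal) as ``o = t @ S``; compensating solves for ``t``.
Negative compensated values are preserved, never floored.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChannelMeta",
    "EventTable",
    "SpilloverMatrix",
    "ControlManifest",
    "ManifestEntry",
    "FCSParseError",
    "CompensationError",
    "read_fcs",
    "write_fcs",
    "apply_compensation",
    "uncompensate",
]


class FCSParseError(ValueError):
    """Raised when a file does not parse as FCS 3.0/3.1."""


class CompensationError(ValueError):
    """Raised for singular spillover matrices or label mismatches."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelMeta:
    """Metadata for one detector channel.

    ``gain`` is the detector voltage or amplifier gain as recorded in the
    file ($PnV preferred, $PnG otherwise); ``dynamic_range`` is the total
    number of scale units the channel spans ($PnR), e.g. 262,144 on a
    5-decade instrument.
    """

    name: str
    detector_label: str = ""
    gain: float = 1.0
    dynamic_range: float = 262144.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("channel name must be non-empty")
        if self.dynamic_range <= 0:
            raise ValueError(f"dynamic_range must be > 0, got {self.dynamic_range}")
        if self.gain is not None and self.gain <= 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")


@dataclass
class EventTable:
    """Per-event channel intensities in scale units plus channel metadata."""

    channels: list[ChannelMeta]
    events: np.ndarray  # (n_events, n_channels), float
    compensated: bool = False

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            raise ValueError("events must be a 2-D matrix")
        if self.events.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.events.shape[1]} event columns for "
                f"{len(self.channels)} channels"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def channel(self, name: str) -> ChannelMeta:
        return self.channels[self.channel_index(name)]

    def column(self, name: str) -> np.ndarray:
        return self.events[:, self.channel_index(name)]


@dataclass
class SpilloverMatrix:
    """Square fluorochrome x detector spillover coefficients.

    Rows are source fluorochromes, columns detectors; the diagonal is one.
    Vendors disagree on orientation, hence :meth:`transposed`.
    """

    labels: list[str]
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n = len(self.labels)
        if self.coefficients.shape != (n, n):
            raise ValueError("spillover matrix must be square and match labels")
        if not np.allclose(np.diag(self.coefficients), 1.0, atol=1e-9):
            raise ValueError("spillover matrix diagonal must be exactly 1")
        off = self.coefficients[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0.0 or off.max() >= 1.0):
            raise ValueError("off-diagonal spillover coefficients must be in [0, 1)")
        if abs(np.linalg.det(self.coefficients)) < 1e-12:
            raise CompensationError("spillover matrix is singular")

    @property
    def n(self) -> int:
        return len(self.labels)

    def transposed(self) -> "SpilloverMatrix":
        return SpilloverMatrix(list(self.labels), self.coefficients.T.copy())

    # CSV with a header row and an index column of labels
    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.coefficients, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpilloverMatrix":
        frame = pd.read_csv(path, index_col=0)
        if list(frame.index) != list(frame.columns):
            raise ValueError("spillover CSV must have matching row/column labels")
        return cls(list(frame.columns), frame.to_numpy(dtype=float))

    def to_keyword(self) -> str:
        vals = ",".join(repr(float(v)) for v in self.coefficients.ravel())
        return f"{self.n},{','.join(self.labels)},{vals}"

    @classmethod
    def from_keyword(cls, text: str) -> "SpilloverMatrix":
        parts = [p.strip() for p in text.split(",")]
        try:
            n = int(parts[0])
            labels = parts[1 : 1 + n]
            values = np.array(parts[1 + n : 1 + n + n * n], dtype=float)
        except (ValueError, IndexError) as exc:
            raise FCSParseError(f"malformed spillover keyword: {text[:60]!r}") from exc
        if len(labels) != n or values.size != n * n:
            raise FCSParseError("spillover keyword has wrong element count")
        return cls(labels, values.reshape(n, n))


@dataclass(frozen=True)
class ManifestEntry:
    fluorochrome: str
    primary_detector: str
    path: str
    compensated: bool = False


@dataclass
class ControlManifest:
    """Maps each single-stain control file to its fluorochrome and detector."""

    entries: list[ManifestEntry]
    spillover_path: str | None = None

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for e in self.entries:
            if e.fluorochrome in seen:
                raise ValueError(f"fluorochrome {e.fluorochrome!r} listed with "
                                 "more than one primary detector"
                                 if seen[e.fluorochrome] != e.primary_detector else
                                 f"duplicate manifest entry for {e.fluorochrome!r}")
            seen[e.fluorochrome] = e.primary_detector

    def validate_paths(self, base: str | Path | None = None) -> None:
        root = Path(base) if base is not None else Path(".")
        for e in self.entries:
            p = Path(e.path)
            if not p.is_absolute():
                p = root / p
            if not p.exists():
                raise FileNotFoundError(f"control file not found: {e.path}")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "fluorochrome": [e.fluorochrome for e in self.entries],
                "primary_detector": [e.primary_detector for e in self.entries],
                "path": [e.path for e in self.entries],
                "compensated": [str(e.compensated).lower() for e in self.entries],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ControlManifest":
        frame = pd.read_csv(path, dtype=str)
        required = {"fluorochrome", "primary_detector", "path"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"manifest is missing columns: {sorted(missing)}")
        comp = frame.get("compensated")
        entries = []
        for i, row in frame.iterrows():
            flag = str(comp[i]).strip().lower() in {"true", "1", "yes"} if comp is not None else False
            entries.append(
                ManifestEntry(row["fluorochrome"], row["primary_detector"], row["path"], flag)
            )
        return cls(entries)


# --------------------------------------------------------------------------
# FCS reading
# --------------------------------------------------------------------------

_SPILL_KEYS = ("$SPILLOVER", "SPILL", "$COMP", "COMP")


def _split_text_segment(raw: bytes, delim: bytes) -> list[str]:
    # Doubled delimiters escape a literal delimiter inside a value.
    body = raw
    if body.startswith(delim):
        body = body[len(delim):]
    if body.endswith(delim):
        body = body[: -len(delim)]
    pieces = body.split(delim)
    merged: list[str] = []
    cur = pieces[0]
    i = 1
    while i < len(pieces):
        if pieces[i] == b"":
            # escaped delimiter: glue the next piece onto the current token
            nxt = pieces[i + 1] if i + 1 < len(pieces) else b""
            cur = cur + delim + nxt
            i += 2
        else:
            merged.append(cur.decode("utf-8", "replace"))
            cur = pieces[i]
            i += 1
    merged.append(cur.decode("utf-8", "replace"))
    return merged


def _parse_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSParseError("empty TEXT segment")
    delim = raw[:1]
    tokens = _split_text_segment(raw, delim)
    if len(tokens) < 2:
        raise FCSParseError("TEXT segment contains no keyword/value pairs")
    if len(tokens) % 2:
        tokens = tokens[:-1]
    kw: dict[str, str] = {}
    for key, value in zip(tokens[0::2], tokens[1::2]):
        k = key.strip()
        kw[k.upper() if k.startswith("$") else k] = value
    return kw


def _header_field(buf: bytes, start: int) -> int:
    text = buf[start : start + 8].decode("ascii", "replace").strip()
    if not text:
        return 0
    try:
        return int(text)
    except ValueError as exc:
        raise FCSParseError(f"bad HEADER offset field {text!r}") from exc


def read_fcs(path: str | Path) -> EventTable:
    """Read an FCS 3.0/3.1 file into an :class:`EventTable`.

    Event values are returned in scale units: $PnE log amplification and
    $PnG linear gain are applied per the standard.  The attached spillover
    matrix, if any, is available via :func:`read_spillover`.
    """
    table, _ = _read_fcs_full(path)
    return table


def read_spillover(path: str | Path) -> SpilloverMatrix | None:
    """Return the spillover matrix stored in an FCS file, if present."""
    _, spill = _read_fcs_full(path)
    return spill


def _read_fcs_full(path: str | Path) -> tuple[EventTable, SpilloverMatrix | None]:
    data = Path(path).read_bytes()
    if len(data) < 58:
        raise FCSParseError("file too short for an FCS HEADER segment")
    version = data[:6].decode("ascii", "replace")
    if version.startswith("FCS2"):
        raise FCSParseError("FCS 2.0 files are not supported (HEADER segment)")
    if not version.startswith("FCS3"):
        raise FCSParseError(f"not an FCS file: HEADER version {version!r}")

    text_begin = _header_field(data, 10)
    text_end = _header_field(data, 18)
    data_begin = _header_field(data, 26)
    data_end = _header_field(data, 34)
    if text_begin <= 0 or text_end < text_begin or text_end >= len(data):
        raise FCSParseError("invalid TEXT segment offsets in HEADER segment")
    kw = _parse_text(data[text_begin : text_end + 1])

    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    if data_begin <= 0 or data_end < data_begin or data_end >= len(data):
        raise FCSParseError("invalid DATA segment offsets")

    mode = kw.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise FCSParseError(f"only list mode ($MODE L) is supported, got {mode!r}")
    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
    except KeyError as exc:
        raise FCSParseError(f"TEXT segment missing required keyword {exc}") from exc

    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    datatype = kw.get("$DATATYPE", "F").strip().upper()

    channels: list[ChannelMeta] = []
    scales: list[tuple[float, float, float, float]] = []  # (f1, f2, gain, range)
    bits: list[int] = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N", f"P{i}")
        label = kw.get(f"$P{i}S", "")
        rng = float(kw.get(f"$P{i}R", 262144))
        pg = float(kw.get(f"$P{i}G", 1.0) or 1.0)
        pv = kw.get(f"$P{i}V")
        meta_gain = float(pv) if pv not in (None, "") else pg
        f1, f2 = 0.0, 0.0
        pe = kw.get(f"$P{i}E", "0,0")
        try:
            f1, f2 = (float(x) for x in pe.split(","))
        except ValueError:
            raise FCSParseError(f"malformed $P{i}E keyword {pe!r}") from None
        channels.append(ChannelMeta(name, label, meta_gain if meta_gain > 0 else 1.0, rng))
        scales.append((f1, f2, pg, rng))
        bits.append(int(kw.get(f"$P{i}B", 32)))

    raw = data[data_begin : data_end + 1]
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        width = bits[0]
        if any(b != width for b in bits) or width not in (16, 32):
            raise FCSParseError("only uniform 16/32-bit integer data supported")
        dtype = np.dtype(f"{endian}u{width // 8}")
    else:
        raise FCSParseError(f"unsupported $DATATYPE {datatype!r}")

    need = n_tot * n_par * dtype.itemsize
    if len(raw) < need:
        raise FCSParseError(
            f"DATA segment truncated: {len(raw)} bytes for {n_tot}x{n_par} events"
        )
    values = np.frombuffer(raw[:need], dtype=dtype).astype(float).reshape(n_tot, n_par)

    for j, (f1, f2, pg, rng) in enumerate(scales):
        if f1 > 0:  # log amplification: scale = f2 * 10^(f1 * x / R)
            values[:, j] = (f2 if f2 > 0 else 1.0) * 10.0 ** (f1 * values[:, j] / rng)
        elif pg not in (0.0, 1.0):
            values[:, j] = values[:, j] / pg

    spill = None
    for key in _SPILL_KEYS:
        if key in kw and kw[key].strip():
            spill = SpilloverMatrix.from_keyword(kw[key])
            break

    compensated = kw.get("SQIFLOW_COMPENSATED", "").strip().lower() == "true"
    return EventTable(channels, values, compensated=compensated), spill


# --------------------------------------------------------------------------
# FCS writing
# --------------------------------------------------------------------------


def write_fcs(
    table: EventTable,
    path: str | Path,
    spillover: SpilloverMatrix | None = None,
    extra_keywords: Mapping[str, str] | None = None,
) -> None:
    """Write an :class:`EventTable` as an FCS 3.1 file (float32 list mode)."""
    if table.n_events == 0 or not table.channels:
        raise ValueError("refusing to write an empty event table")
    n_par = len(table.channels)
    n_tot = table.n_events

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, ch in enumerate(table.channels, start=1):
        kw[f"$P{i}N"] = ch.name
        if ch.detector_label:
            kw[f"$P{i}S"] = ch.detector_label
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = repr(ch.dynamic_range)
        # Detector gain/voltage is recorded as $PnV so readers do not
        # rescale the (already linear) data with it.
        kw[f"$P{i}V"] = repr(ch.gain)
    if spillover is not None:
        kw["$SPILLOVER"] = spillover.to_keyword()
    if table.compensated:
        kw["SQIFLOW_COMPENSATED"] = "true"
    if extra_keywords:
        kw.update({str(k): str(v) for k, v in extra_keywords.items()})

    payload = table.events.astype("<f4").tobytes()

    delim = "/"
    # Fixed-width data offsets so TEXT length is stable across the two passes.
    kw["$BEGINDATA"] = "%012d" % 0
    kw["$ENDDATA"] = "%012d" % 0

    def render(d: dict[str, str]) -> bytes:
        out = [delim]
        for k, v in d.items():
            if v == "":
                v = " "
            out.append(k.replace(delim, delim * 2))
            out.append(delim)
            out.append(v.replace(delim, delim * 2))
            out.append(delim)
        return "".join(out).encode("utf-8")

    header_len = 58
    text = render(kw)
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(payload) - 1
    kw["$BEGINDATA"] = "%012d" % data_begin
    kw["$ENDDATA"] = "%012d" % data_end
    text = render(kw)
    assert text_end == text_begin + len(text) - 1

    def fmt(n: int) -> bytes:
        s = str(n) if n <= 99999999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        fmt(x)
        for x in (
            text_begin,
            text_end,
            data_begin if data_end <= 99999999 else 0,
            data_end if data_end <= 99999999 else 0,
            0,
            0,
        )
    )
    assert len(header) == header_len
    Path(path).write_bytes(header + text + payload)


# --------------------------------------------------------------------------
# compensation
# --------------------------------------------------------------------------


def _spill_submatrix(table: EventTable, spill: SpilloverMatrix) -> tuple[np.ndarray, list[int]]:
    try:
        idx = [table.channel_index(lbl) for lbl in spill.labels]
    except KeyError as exc:
        raise CompensationError(
            f"spillover label not present among channels: {exc.args[0]}"
        ) from exc
    return spill.coefficients, idx


def apply_compensation(table: EventTable, spill: SpilloverMatrix) -> EventTable:
    """Compensate observed events: solve ``observed = true @ spill`` per event.

    Channels not named in the spillover matrix pass through unchanged.
    Negative compensated values are preserved.
    """
    if table.compensated:
        raise CompensationError("event table is already compensated")
    coeff, idx = _spill_submatrix(table, spill)
    events = table.events.copy()
    try:
        events[:, idx] = np.linalg.solve(coeff.T, table.events[:, idx].T).T
    except np.linalg.LinAlgError as exc:
        raise CompensationError("spillover matrix is singular") from exc
    return EventTable(list(table.channels), events, compensated=True)


def uncompensate(table: EventTable, spill: SpilloverMatrix) -> EventTable:
    """Invert :func:`apply_compensation`: re-mix true signals into observed."""
    if not table.compensated:
        raise CompensationError("event table is not compensated")
    coeff, idx = _spill_submatrix(table, spill)
    events = table.events.copy()
    events[:, idx] = table.events[:, idx] @ coeff
    return EventTable(list(table.channels), events, compensated=False)
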