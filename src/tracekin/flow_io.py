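"""Flow-cytometry event I/O, transforms, rectangular gating and downsampling.

The FCS support is deliberately narrow: list-mode data, a single dataset per
file, ``$DATATYPE`` F (32/64-bit float) or I (16/32-bit unsigned integer),
little- or big-endian. Files outside this envelope are rejected with a
descriptive error rather than half-parsed.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "RectGate",
    "FCSFormatError",
    "read_fcs",
    "write_fcs",
    "read_csv",
    "write_csv",
    "apply_gate",
    "downsample_equal",
    "log10_transform",
    "arcsinh_transform",
]

TRUE_GENERATION_COLUMN = "true_generation"


class FCSFormatError(ValueError):
    """Raised when an FCS file violates the supported subset of the format."""


@dataclass
class EventTable:
    """Per-event measurements for one sample.

    Parameters
    ----------
    data : pandas.DataFrame
        One column per channel, one row per event. An optional
        ``true_generation`` column carries simulator ground truth and is not
        treated as a fluorescence channel.
    sample_id : str
        Identifier used in error messages and file metadata.
    transforms : dict
        Per-channel transform state, one of ``"linear"``, ``"log10"`` or
        ``"arcsinh(<cofactor>)"``. Channels default to ``"linear"``.
    """

    data: pd.DataFrame
    sample_id: str = "sample"
    transforms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data).reset_index(drop=True)
        for ch in self.channels:
            self.transforms.setdefault(ch, "linear")

    @property
    def channels(self) -> list[str]:
        return [c for c in self.data.columns if c != TRUE_GENERATION_COLUMN]

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def true_generation(self) -> np.ndarray | None:
        if TRUE_GENERATION_COLUMN in self.data.columns:
            return self.data[TRUE_GENERATION_COLUMN].to_numpy()
        return None

    def values(self, channel: str) -> np.ndarray:
        if channel not in self.data.columns:
            raise KeyError(
                f"channel {channel!r} not in sample {self.sample_id!r}; "
                f"available: {self.channels}"
            )
        return self.data[channel].to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame) -> "EventTable":
        return EventTable(data, sample_id=self.sample_id, transforms=dict(self.transforms))

    def copy(self) -> "EventTable":
        return self.with_data(self.data.copy())


@dataclass(frozen=True)
class RectGate:
    """Rectangular gate: closed interval per channel; boundary events kept."""

    intervals: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for ch, (lo, hi) in self.intervals.items():
            if lo > hi:
                raise ValueError(f"gate on {ch!r}: lower {lo} > upper {hi}")


def apply_gate(table: EventTable, gate: RectGate) -> EventTable:
    """Keep events inside all gate intervals (closed bounds)."""
    mask = np.ones(table.n_events, dtype=bool)
    for ch, (lo, hi) in gate.intervals.items():
        vals = table.values(ch)
        mask &= (vals >= lo) & (vals <= hi)
    return table.with_data(table.data.loc[mask])


def downsample_equal(
    tables: Sequence[EventTable], n: int, seed: int | None = None
) -> list[EventTable]:
    """Sample exactly ``n`` events without replacement from each table.

    Mirrors equal-event downsampling prior to pooled dimensionality
    reduction; deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for t in tables:
        if t.n_events < n:
            raise ValueError(
                f"sample {t.sample_id!r} has {t.n_events} events, fewer than n={n}"
            )
    rng = np.random.default_rng(seed)
    out = []
    for t in tables:
        idx = rng.choice(t.n_events, size=n, replace=False)
        out.append(t.with_data(t.data.iloc[idx]))
    return out


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def log10_transform(
    table: EventTable, channels: Sequence[str] | None = None, floor: float | None = None
) -> EventTable:
    """log10-transform channels in place of linear values.

    Values <= 0 are mapped to ``floor`` (default: smallest positive measured
    value / 10). Refuses to transform a channel twice.
    """
    out = table.copy()
    for ch in channels if channels is not None else out.channels:
        state = out.transforms.get(ch, "linear")
        if state != "linear":
            raise ValueError(f"channel {ch!r} already transformed ({state})")
        vals = out.values(ch)
        pos = vals[vals > 0]
        ch_floor = floor
        if ch_floor is None:
            ch_floor = np.log10(pos.min() / 10.0) if pos.size else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            logged = np.where(vals > 0, np.log10(np.maximum(vals, 1e-300)), ch_floor)
        out.data[ch] = logged
        out.transforms[ch] = "log10"
    return out


def arcsinh_transform(
    table: EventTable, channels: Sequence[str] | None = None, cofactor: float = 150.0
) -> EventTable:
    out = table.copy()
    for ch in channels if channels is not None else out.channels:
        state = out.transforms.get(ch, "linear")
        if state != "linear":
            raise ValueError(f"channel {ch!r} already transformed ({state})")
        out.data[ch] = np.arcsinh(out.values(ch) / cofactor)
        out.transforms[ch] = f"arcsinh({cofactor:g})"
    return out


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_csv(path: str | Path, sample_id: str | None = None) -> EventTable:
    df = pd.read_csv(path)
    if "event_id" in df.columns:
        df = df.drop(columns="event_id")
    return EventTable(df, sample_id=sample_id or Path(path).stem)


def write_csv(table: EventTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="event_id")


# ---------------------------------------------------------------------------
# FCS
# ---------------------------------------------------------------------------

_DELIM = "/"


def _build_text(keywords: dict[str, str], data_start_guess: int) -> bytes:
    # TEXT offsets are self-referential; iterate until stable.
    def render(kw: dict[str, str]) -> bytes:
        parts = [_DELIM]
        for k, v in kw.items():
            parts.append(f"{k}{_DELIM}{v}{_DELIM}")
        return "".join(parts).encode("ascii")

    kw = dict(keywords)
    data_len = int(kw["$TOT"]) * int(kw["$PAR"]) * 4
    start = data_start_guess
    for _ in range(10):
        kw["$BEGINDATA"] = str(start)
        kw["$ENDDATA"] = str(start + data_len - 1 if data_len else 0)
        text = render(kw)
        new_start = 58 + len(text)
        if new_start == start:
            return text
        start = new_start
    raise RuntimeError("TEXT offset computation did not converge")


def write_fcs(table: EventTable, path: str | Path) -> None:
    """Write FCS 3.1, float32 data, little-endian, single dataset."""
    channels = table.channels
    arr = table.data[channels].to_numpy(dtype=np.float32)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values cannot be written to FCS")
    n_events, n_par = arr.shape if arr.ndim == 2 else (0, len(channels))
    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
        "$FIL": str(Path(path).name),
    }
    for i, ch in enumerate(channels, start=1):
        keywords[f"$P{i}N"] = ch
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(np.ceil(float(arr[:, i - 1].max()) + 1)) if n_events else 1)
    text = _build_text(keywords, data_start_guess=58)
    data_start = 58 + len(text)
    data = arr.astype("<f4").tobytes()
    data_end = data_start + len(data) - 1 if data else 0
    header = (
        b"FCS3.1    "
        + f"{58:>8d}".encode()
        + f"{58 + len(text) - 1:>8d}".encode()
        + (f"{data_start:>8d}".encode() if data_start <= 99_999_999 else b"       0")
        + (f"{data_end:>8d}".encode() if data_end <= 99_999_999 else b"       0")
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    # strip leading delimiter; split (escaped double delimiters unsupported)
    tokens = body.split(delim)[1:]
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    if len(tokens) % 2 != 0:
        raise FCSFormatError("TEXT segment has an odd number of tokens")
    return {tokens[i].strip().upper(): tokens[i + 1] for i in range(0, len(tokens), 2)}


def read_fcs(path: str | Path, sample_id: str | None = None) -> EventTable:
    """Read a list-mode FCS 3.0/3.1 file into an :class:`EventTable`."""
    blob = Path(path).read_bytes()
    if len(blob) < 58:
        raise FCSFormatError(f"file too short for an FCS header ({len(blob)} bytes)")
    version = blob[:6].decode("latin-1")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FCSFormatError(f"unsupported FCS version {version!r}")
    try:
        text_start, text_end = int(blob[10:18]), int(blob[18:26])
        data_start, data_end = int(blob[26:34]), int(blob[34:42])
    except ValueError as exc:
        raise FCSFormatError(f"malformed HEADER offsets: {exc}") from exc
    kw = _parse_text_segment(blob[text_start : text_end + 1])

    for required in ("$DATATYPE", "$MODE", "$PAR", "$TOT", "$BYTEORD"):
        if required not in kw:
            raise FCSFormatError(f"missing required keyword {required}")
    if kw["$MODE"] != "L":
        raise FCSFormatError(f"only list mode ($MODE=L) supported, got {kw['$MODE']!r}")
    if kw.get("$NEXTDATA", "0").strip() not in ("0", ""):
        raise FCSFormatError("multiple datasets per file are not supported")

    n_par, n_tot = int(kw["$PAR"]), int(kw["$TOT"])
    datatype = kw["$DATATYPE"]
    byteord = kw["$BYTEORD"].strip()
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FCSFormatError(f"unsupported $BYTEORD {byteord!r}")

    names, widths = [], []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N") or kw.get(f"$P{i}S")
        if name is None:
            raise FCSFormatError(f"missing required keyword $P{i}N")
        if f"$P{i}B" not in kw:
            raise FCSFormatError(f"missing required keyword $P{i}B")
        names.append(name)
        widths.append(int(kw[f"$P{i}B"]))

    if data_start == 0 and "$BEGINDATA" in kw:
        data_start, data_end = int(kw["$BEGINDATA"]), int(kw["$ENDDATA"])
    raw = blob[data_start : data_end + 1] if n_tot else b""

    if datatype == "F":
        if any(w not in (32, 64) for w in widths):
            raise FCSFormatError("$DATATYPE=F requires $PnB of 32 or 64")
        codes = [f"{endian}f{w // 8}" for w in widths]
    elif datatype == "I":
        if any(w not in (16, 32) for w in widths):
            raise FCSFormatError("$DATATYPE=I requires $PnB of 16 or 32")
        codes = [f"{endian}u{w // 8}" for w in widths]
    else:
        raise FCSFormatError(f"unsupported $DATATYPE {datatype!r} (only F and I)")

    row_bytes = sum(w // 8 for w in widths)
    expected = row_bytes * n_tot
    if len(raw) < expected:
        raise FCSFormatError(
            f"truncated DATA segment: expected {expected} bytes, found {len(raw)}"
        )
    if len(set(codes)) == 1 and n_tot:
        arr = np.frombuffer(raw[:expected], dtype=codes[0]).reshape(n_tot, n_par)
        cols = {name: arr[:, j].astype(float) for j, name in enumerate(names)}
    else:
        cols = {name: np.empty(n_tot) for name in names}
        offset = 0
        fmt = endian + "".join(
            ("f" if datatype == "F" else ("H" if w == 16 else "I")) if w != 64 else "d"
            for w in widths
        )
        size = struct.calcsize(fmt)
        for r in range(n_tot):
            vals = struct.unpack_from(fmt, raw, offset)
            offset += size
            for name, v in zip(names, vals):
                cols[name][r] = v
    df = pd.DataFrame(cols, columns=names) if n_tot else pd.DataFrame(columns=names)
    return EventTable(df, sample_id=sample_id or kw.get("$FIL", Path(path).stem))
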