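"""Listmode event I/O and experiment-design configuration.

Events are carried as :class:`EventTable`, a thin column-oriented container
over five linear-scale detector channels plus an optional per-event
population label.  Two on-disk formats are supported: a plain CSV dialect
(comma separated, dot decimal, canonical header names, label column last)
and FCS 3.1 (list mode, 32-bit float, linear channels).
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

#: Canonical channel column names, in storage order.
CHANNELS: tuple[str, ...] = ("fsc", "ssc", "fl1_ige", "fl2_cd117", "fl3_7aad")

#: Short names written to FCS $PnN keywords, and the default map back.
FCS_CHANNEL_NAMES: tuple[str, ...] = ("FSC", "SSC", "FL1-IgE", "FL2-CD117", "FL3-7AAD")
DEFAULT_CHANNEL_MAP: dict[str, str] = dict(zip(FCS_CHANNEL_NAMES, CHANNELS))

#: Recognised population labels.
LABELS: frozenset[str] = frozenset(
    {"lymphocyte", "monocyte", "granulocyte", "precursor",
     "debris", "dead", "mast_cell", "other"}
)

MATRICES: tuple[str, ...] = ("PB", "BM", "LN")

#: Nominal spike fractions (percent of viable gated events), high to low.
DEFAULT_FRACTIONS: dict[str, tuple[float, ...]] = {
    "PB": (10, 7, 5, 3, 2, 1, 0.5, 0.3, 0.1),
    "BM": (10, 7, 5, 3, 2, 1, 0.5, 0.3, 0.1),
    "LN": (50, 25, 10, 5, 3, 1, 0.5, 0.3, 0.1),
}

#: Minimum acquisition counts in the morphology gate, per matrix.
DEFAULT_MIN_EVENTS: dict[str, int] = {"PB": 500_000, "BM": 100_000, "LN": 100_000}


@dataclass
class EventTable:
    """Per-event channel intensities with optional population labels.

    All channel arrays are 1-D, equal length, finite and non-negative.
    ``label``, when present, covers every event.
    """

    fsc: np.ndarray
    ssc: np.ndarray
    fl1_ige: np.ndarray
    fl2_cd117: np.ndarray
    fl3_7aad: np.ndarray
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        cols = [np.asarray(getattr(self, c), dtype=float) for c in CHANNELS]
        n = len(cols[0])
        for name, col in zip(CHANNELS, cols):
            if col.ndim != 1:
                raise ValidationError(f"channel {name!r} must be 1-D")
            if len(col) != n:
                raise ValidationError("channel columns must have equal length")
            if not np.all(np.isfinite(col)):
                raise ValidationError(f"channel {name!r} contains non-finite values")
            if len(col) and col.min() < 0:
                raise ValidationError(f"channel {name!r} contains negative values")
            setattr(self, name, col)
        if self.label is not None:
            lab = np.asarray(self.label, dtype=object)
            if len(lab) != n:
                raise ValidationError("label column must cover every event")
            unknown = set(lab) - LABELS
            if unknown:
                raise ValidationError(f"unknown labels: {sorted(map(str, unknown))}")
            self.label = lab

    def __len__(self) -> int:
        return len(self.fsc)

    @property
    def channels(self) -> np.ndarray:
        """Events as an (n, 5) float array in canonical channel order."""
        return np.column_stack([getattr(self, c) for c in CHANNELS])

    def subset(self, mask: np.ndarray) -> "EventTable":
        """Return a new table with the rows selected by a boolean mask or index array."""
        return EventTable(
            *(getattr(self, c)[mask] for c in CHANNELS),
            label=None if self.label is None else self.label[mask],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({c: getattr(self, c) for c in CHANNELS})
        if self.label is not None:
            df["label"] = self.label
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EventTable":
        label = df["label"].to_numpy(dtype=object) if "label" in df.columns else None
        return cls(*(df[c].to_numpy(dtype=float) for c in CHANNELS), label=label)

    @classmethod
    def empty(cls) -> "EventTable":
        z = np.empty(0)
        return cls(z, z, z, z, z)


def concat_events(tables: Sequence[EventTable]) -> EventTable:
    """Stack tables row-wise; labels kept only if every input carries them."""
    keep_labels = all(t.label is not None for t in tables)
    return EventTable(
        *(np.concatenate([getattr(t, c) for t in tables]) for c in CHANNELS),
        label=(np.concatenate([t.label for t in tables]) if keep_labels else None),
    )


# ---------------------------------------------------------------------------
# CSV

def _read_events_csv(path: Path) -> EventTable:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    for ch in CHANNELS:
        if ch not in df.columns:
            raise FormatError(f"{path}: missing channel column {ch!r}")
        if not pd.api.types.is_numeric_dtype(df[ch]):
            coerced = pd.to_numeric(df[ch], errors="coerce")
            bad = np.flatnonzero((coerced.isna() & df[ch].notna()).to_numpy())
            if len(bad):
                raise ParseError(f"{path}: non-numeric value in column {ch!r}",
                                 row=int(bad[0]))
            df[ch] = coerced  # NaNs surface as a non-finite ValidationError
    return EventTable.from_dataframe(df)


def _write_events_csv(events: EventTable, path: Path) -> None:
    events.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FCS 3.1 (list mode, float32, linear; the minimal self-consistent subset)

_HEADER_LEN = 58  # "FCS3.1    " + six 8-byte ASCII offset fields


def _build_fcs_text(n_events: int, n_bytes_data: int) -> bytes:
    delim = "/"
    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BEGINDATA": "{begin:012d}", "$ENDDATA": "{end:012d}",
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0", "$TOT": str(n_events), "$PAR": str(len(CHANNELS)),
    }
    for i, name in enumerate(FCS_CHANNEL_NAMES, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"
    template = delim + delim.join(f"{k}{delim}{v}" for k, v in kw.items()) + delim
    begin = _HEADER_LEN + len(template.format(begin=0, end=0))
    end = begin + n_bytes_data - 1 if n_bytes_data else 0
    return template.format(begin=begin, end=end).encode("ascii")


def _write_events_fcs(events: EventTable, path: Path) -> None:
    if events.label is not None:
        warnings.warn("FCS output drops per-event labels", stacklevel=3)
    data = np.ascontiguousarray(events.channels, dtype="<f4").tobytes()
    text = _build_fcs_text(len(events), len(data))
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data) - 1 if data else 0
    header = b"FCS3.1    " + "".join(
        f"{v:8d}" for v in (text_begin, text_end, data_begin, data_end, 0, 0)
    ).encode("ascii")
    assert len(header) == _HEADER_LEN
    path.write_bytes(header + text + data)


def _read_events_fcs(path: Path, channel_map: dict[str, str] | None = None) -> EventTable:
    channel_map = DEFAULT_CHANNEL_MAP if channel_map is None else channel_map
    raw = path.read_bytes()
    if len(raw) < _HEADER_LEN or not raw.startswith(b"FCS3"):
        raise FormatError(f"{path}: not an FCS 3.x file")
    offsets = [int(raw[10 + 8 * i: 18 + 8 * i]) for i in range(4)]
    text_begin, text_end, data_begin, data_end = offsets
    text = raw[text_begin: text_end + 1].decode("ascii", errors="replace")
    delim, body = text[0], text[1:]
    tokens = body.split(delim)
    kv = dict(zip(tokens[::2], tokens[1::2]))
    if data_begin == 0:
        data_begin, data_end = int(kv["$BEGINDATA"]), int(kv["$ENDDATA"])
    if kv.get("$DATATYPE") != "F" or kv.get("$MODE", "L") != "L":
        raise FormatError(f"{path}: only list-mode float FCS is supported")
    n_par, n_tot = int(kv["$PAR"]), int(kv["$TOT"])
    order = "<" if kv.get("$BYTEORD", "1,2,3,4") == "1,2,3,4" else ">"
    names = [kv.get(f"$P{i}N", "") for i in range(1, n_par + 1)]
    col_of = {channel_map.get(nm): i for i, nm in enumerate(names) if nm in channel_map}
    for ch in CHANNELS:
        if ch not in col_of:
            raise FormatError(f"{path}: missing channel {ch!r} "
                              f"(no $PnN maps onto it; have {names})")
    buf = raw[data_begin: data_end + 1] if n_tot else b""
    values = np.frombuffer(buf, dtype=f"{order}f4", count=n_tot * n_par)
    mat = values.reshape(n_tot, n_par).astype(float)
    return EventTable(*(mat[:, col_of[ch]] for ch in CHANNELS))


# ---------------------------------------------------------------------------
# Public event I/O

def read_events(path, format: str | None = None,
                channel_map: dict[str, str] | None = None) -> EventTable:
    """Read listmode events from ``path``.

    ``format`` is ``"fcs"`` or ``"csv"``; when omitted it is inferred from
    the file suffix.  ``channel_map`` (FCS only) maps $PnN short names onto
    the canonical channel names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("fcs" if path.suffix.lower() == ".fcs" else "csv")
    if fmt == "fcs":
        return _read_events_fcs(path, channel_map)
    if fmt == "csv":
        return _read_events_csv(path)
    raise ValidationError(f"unknown format {fmt!r}")


def write_events(events: EventTable, path, format: str | None = None) -> Path:
    """Write events to ``path`` in CSV or FCS 3.1; returns the path written."""
    path = Path(path)
    fmt = format or ("fcs" if path.suffix.lower() == ".fcs" else "csv")
    if fmt == "fcs":
        _write_events_fcs(events, path)
    elif fmt == "csv":
        _write_events_csv(events, path)
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# Experiment design

@dataclass(frozen=True)
class ExperimentDesign:
    """One matrix's dilution-series design: levels, repeats, blanks, minima."""

    matrix: str
    nominal_fractions: tuple[float, ...] = ()
    repeats_per_level: int = 3
    n_blanks: int = 10
    min_events: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise ValidationError(f"unknown matrix {self.matrix!r}; expected one of {MATRICES}")
        fr = tuple(float(f) for f in self.nominal_fractions) or DEFAULT_FRACTIONS[self.matrix]
        for f in fr:
            if not (0 < f <= 100):
                raise ValidationError(f"nominal fraction {f} outside (0, 100]")
        if any(a <= b for a, b in zip(fr, fr[1:])):
            raise ValidationError("nominal fractions must be strictly decreasing")
        object.__setattr__(self, "nominal_fractions", fr)
        if self.repeats_per_level < 1:
            raise ValidationError("repeats_per_level must be >= 1")
        if self.n_blanks < 0:
            raise ValidationError("n_blanks must be >= 0")
        if self.min_events <= 0:
            object.__setattr__(self, "min_events", DEFAULT_MIN_EVENTS[self.matrix])

    def with_seed(self, seed: int) -> "ExperimentDesign":
        return replace(self, rng_seed=seed)


def read_design(path) -> ExperimentDesign:
    """Load an :class:`ExperimentDesign` from a TOML file.

    Recognised keys: ``matrix`` (required), ``nominal_fractions``,
    ``repeats_per_level``, ``n_blanks``, ``min_events``, ``rng_seed``.
    Omitted keys fall back to per-matrix defaults.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "matrix" not in raw:
        raise ValidationError(f"{path}: design must name a matrix")
    known = {"matrix", "nominal_fractions", "repeats_per_level",
             "n_blanks", "min_events", "rng_seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown design keys {sorted(unknown)}")
    return ExperimentDesign(**raw)
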