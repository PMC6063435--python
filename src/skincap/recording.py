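"""Multichannel recording container and native text-matrix I/O.

The native format is a plain-text, inspectable matrix file:

    # skincap matrix 1
    rate <Hz>
    pulse_onset <sample index>
    labels <name> <name> ...
    meta <json object>            (optional)
    <sample row, tab-delimited>   (one channel per row)
    ...

Numbers are serialized with 17 significant digits so a write/read round
trip is bit-lossless.  BDF/EDF import is available through :mod:`mne` when
installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field

import numpy as np

__all__ = ["Recording", "read_matrix", "write_matrix", "read_bdf"]

_MAGIC = "# skincap matrix 1"


@dataclass
class Recording:
    """Channels x samples voltage matrix (uV) with acquisition metadata.

    ``pulse_onset`` is the sample index of the TMS pulse; times are reported
    in ms relative to it.
    """

    data: np.ndarray
    rate: float
    pulse_onset: int
    labels: list[str]
    metadata: dict = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.labels):
            raise ValueError("number of labels must match number of channels")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        if not (0 <= self.pulse_onset < self.data.shape[1]):
            raise ValueError("pulse_onset must lie within the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms, 0 at the TMS pulse onset."""
        return (np.arange(self.n_samples) - self.pulse_onset) * 1000.0 / self.rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None

    def copy(self, data: np.ndarray | None = None, **meta_updates) -> "Recording":
        md = dict(self.metadata)
        md.update(meta_updates)
        return Recording(
            data=self.data.copy() if data is None else np.asarray(data, float),
            rate=self.rate,
            pulse_onset=self.pulse_onset,
            labels=list(self.labels),
            metadata=md,
        )

    def log(self, operation: str, **parameters) -> None:
        """Append a provenance entry to the recording metadata."""
        self.metadata.setdefault("provenance", []).append(
            {"operation": operation, **parameters}
        )


class MatrixParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def write_matrix(path, rec: Recording) -> None:
    """Write a recording to the native text format (lossless round trip)."""
    if rec.n_channels == 0:
        raise ValueError("cannot write a recording with no channels")
    for lbl in rec.labels:
        if any(c.isspace() for c in lbl):
            raise ValueError(f"channel label {lbl!r} contains whitespace")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"rate {rec.rate!r}\n")
        fh.write(f"pulse_onset {rec.pulse_onset}\n")
        fh.write("labels " + " ".join(rec.labels) + "\n")
        if rec.metadata:
            fh.write("meta " + json.dumps(rec.metadata, default=_json_default) + "\n")
        for row in rec.data:
            fh.write("\t".join(f"{x:.17g}" for x in row) + "\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_matrix(path) -> Recording:
    """Read a recording from the native text format.

    Raises :class:`MatrixParseError` (with the offending line number) on a
    malformed header or ragged data rows.  CR/LF and LF line endings parse
    identically.
    """
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise MatrixParseError(f"expected header {_MAGIC!r}", 1)
    header: dict[str, str] = {}
    i = 1
    while i < len(lines):
        stripped = lines[i].strip()
        key = stripped.split(" ", 1)[0]
        if key not in ("rate", "pulse_onset", "labels", "meta"):
            break
        parts = stripped.split(" ", 1)
        header[key] = parts[1] if len(parts) > 1 else ""
        i += 1
    for required in ("rate", "pulse_onset", "labels"):
        if required not in header:
            raise MatrixParseError(f"missing header field {required!r}", i)
    labels = header["labels"].split()
    if not labels:
        raise MatrixParseError("empty channel list", i)
    rows = []
    width = None
    for j in range(i, len(lines)):
        if not lines[j].strip():
            continue
        vals = lines[j].split("\t")
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise MatrixParseError(f"ragged row: {len(vals)} values, expected {width}", j + 1)
        try:
            rows.append(np.array(vals, dtype=float))
        except ValueError as exc:
            raise MatrixParseError(str(exc), j + 1) from None
    if len(rows) != len(labels):
        raise MatrixParseError(
            f"{len(rows)} data rows for {len(labels)} labelled channels", len(lines)
        )
    try:
        rate = float(header["rate"])
        pulse_onset = int(header["pulse_onset"])
    except ValueError as exc:
        raise MatrixParseError(f"bad header value: {exc}", i) from None
    metadata = json.loads(header["meta"]) if "meta" in header else {}
    return Recording(
        data=np.vstack(rows), rate=rate, pulse_onset=pulse_onset, labels=labels,
        metadata=metadata,
    )


def read_bdf(path, pulse_onset: int = 0) -> Recording:
    """Import a Biosemi BDF (or EDF) file as a :class:`Recording`.

    Requires the optional :mod:`mne` dependency.  Voltages are converted to
    uV; the pulse-onset sample index must be supplied (BDF trigger-channel
    decoding is recorder-specific and out of scope).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("BDF/EDF import requires the 'mne' package") from exc
    path = str(path)
    if path.lower().endswith(".bdf"):
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,
        rate=float(raw.info["sfreq"]),
        pulse_onset=pulse_onset,
        labels=list(raw.ch_names),
        metadata={"source": path},
    )
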