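"""Reading and writing EOG recordings, label files and transcriptions.

All on-disk formats are isolated here so that the signal-processing and
modeling modules only ever see in-memory containers.  The canonical
recording format is delimited text with a one-line ``rate_hz=<value>``
header followed by one ``horizontal,vertical`` sample pair per line (values
in microvolts).  An ``npz`` dialect is available as a structured binary
container for larger archives.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EOGRecording",
    "LabelSegment",
    "Transcription",
    "IOFormatError",
    "ChannelMismatchError",
    "NonFiniteValueError",
    "UnknownDialectError",
    "SegmentValidationError",
    "read_recording",
    "write_recording",
    "read_labels",
    "write_labels",
    "read_transcription",
    "write_transcription",
]


class IOFormatError(ValueError):
    """A file does not match its declared dialect."""


class ChannelMismatchError(IOFormatError):
    """Horizontal and vertical channels have different lengths."""


class NonFiniteValueError(IOFormatError):
    """A recording contains NaN or infinite samples."""


class UnknownDialectError(ValueError):
    """The requested on-disk dialect is not registered."""


class SegmentValidationError(ValueError):
    """Label segments overlap, are reversed, or are otherwise malformed."""


@dataclass
class EOGRecording:
    """Raw two-channel EOG time series in microvolts.

    Attributes
    ----------
    sample_rate_hz:
        Sampling rate; the recording hardware default is 1000 Hz.
    horizontal, vertical:
        Equal-length 1-D float arrays (left-right and up-down channels).
    meta:
        Free-text provenance (user id, session id, ...).
    """

    sample_rate_hz: float
    horizontal: np.ndarray
    vertical: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.horizontal = np.asarray(self.horizontal, dtype=float)
        self.vertical = np.asarray(self.vertical, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        if self.horizontal.ndim != 1 or self.vertical.ndim != 1:
            raise ChannelMismatchError("channels must be 1-D arrays")
        if len(self.horizontal) != len(self.vertical):
            raise ChannelMismatchError(
                f"channel lengths differ: {len(self.horizontal)} vs {len(self.vertical)}"
            )
        if len(self.horizontal) == 0:
            raise ChannelMismatchError("recording is empty")
        if not (np.all(np.isfinite(self.horizontal)) and np.all(np.isfinite(self.vertical))):
            raise NonFiniteValueError("recording contains non-finite samples")

    def __len__(self) -> int:
        return len(self.horizontal)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    def as_array(self) -> np.ndarray:
        """Return an (n, 2) array with columns (horizontal, vertical)."""
        return np.stack([self.horizontal, self.vertical], axis=1)


@dataclass(frozen=True)
class LabelSegment:
    """Half-open labelled span ``[start, end)`` in sample (or frame) indices."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SegmentValidationError(
                f"segment must satisfy 0 <= start < end, got [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class Transcription:
    """Ordered symbol sequence on one tier (character, stroke or motion)."""

    symbols: tuple
    tier: str = "character"

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(self.symbols))
        if self.tier not in ("character", "stroke", "motion"):
            raise ValueError(f"unknown tier {self.tier!r}")

    def __len__(self) -> int:
        return len(self.symbols)


def validate_segments(segments) -> list:
    """Check that segments are sorted and non-overlapping; return them sorted."""
    segs = sorted(segments, key=lambda s: (s.start, s.end))
    for a, b in zip(segs, segs[1:]):
        if b.start < a.end:
            raise SegmentValidationError(f"segments overlap: {a} and {b}")
    return segs


# ---------------------------------------------------------------------------
# recordings

_RECORDING_DIALECTS = ("text", "npz")


def read_recording(path, dialect: str = "text") -> EOGRecording:
    """Read a two-channel recording; channel order (horizontal, vertical)."""
    if dialect not in _RECORDING_DIALECTS:
        raise UnknownDialectError(f"unknown recording dialect {dialect!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "npz":
        with np.load(path) as z:
            return EOGRecording(
                sample_rate_hz=float(z["rate_hz"]),
                horizontal=z["horizontal"],
                vertical=z["vertical"],
                meta={k: str(v) for k, v in z.items() if k.startswith("meta_")},
            )
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if "=" in header:
            key, _, value = header.partition("=")
            if key.strip() != "rate_hz":
                raise IOFormatError(f"expected 'rate_hz=<value>' header, got {header!r}")
            rate = float(value)
        else:
            # bare-number header, as in minimal hand-written fixtures
            rate = float(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.replace("\t", ",").split(",")
            if len(parts) != 2:
                raise ChannelMismatchError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise IOFormatError(f"{path}: no samples")
    arr = np.array(rows, dtype=float)
    return EOGRecording(sample_rate_hz=rate, horizontal=arr[:, 0], vertical=arr[:, 1])


def write_recording(rec: EOGRecording, path, dialect: str = "text") -> None:
    if dialect not in _RECORDING_DIALECTS:
        raise UnknownDialectError(f"unknown recording dialect {dialect!r}")
    rec.validate()
    if dialect == "npz":
        np.savez(
            path,
            rate_hz=rec.sample_rate_hz,
            horizontal=rec.horizontal,
            vertical=rec.vertical,
            **{f"meta_{k}": str(v) for k, v in rec.meta.items()},
        )
        return
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"rate_hz={rec.sample_rate_hz:g}\n")
        for h, v in zip(rec.horizontal, rec.vertical):
            fh.write(f"{h:.6f},{v:.6f}\n")


# ---------------------------------------------------------------------------
# labels and transcriptions

def read_labels(path) -> list:
    """Read a TSV label file of ``start<TAB>end<TAB>label`` segments."""
    segments = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise SegmentValidationError(f"{path}:{lineno}: expected 3 fields")
            segments.append(LabelSegment(int(parts[0]), int(parts[1]), parts[2]))
    return validate_segments(segments)


def write_labels(segments, path) -> None:
    segs = validate_segments(segments)
    with open(path, "w", encoding="utf-8") as fh:
        for s in segs:
            fh.write(f"{s.start}\t{s.end}\t{s.label}\n")


def read_transcription(path, tier: str = "character") -> list:
    """Read a UTF-8 transcription file, one whitespace-split symbol sequence per line."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            out.append(Transcription(tuple(line.split()), tier=tier))
    return out


def write_transcription(items, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in items:
            fh.write(" ".join(t.symbols) + "\n")
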