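"""Recording / event / adjacency containers and their on-disk formats.

This module owns the channel-label and coordinate conventions used by the
rest of the package: a :class:`Recording` is a channels x samples matrix in
microvolts, events are tab-separated tables of ``(onset_sample, label)``,
and connectivity matrices travel as labelled TSV files.  Scalp geometry for
the 10-20 system is shipped as a fixed 2-D projection table
(:data:`MONTAGE_2D`).

Conventions (used package-wide):

* samples are 0-based; an event's ``onset_sample`` indexes the
  stimulus-onset sample; windows are half-open ``[start, end)`` in samples;
* the physical unit is microvolts everywhere (EDF physical dimension
  ``uV``);
* adjacency TSVs are written with 12 significant digits.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "Adjacency",
    "FormatError",
    "MONTAGE_2D",
    "DEFAULT_CHANNELS",
    "montage_positions",
    "read_recording",
    "write_recording",
    "select_channels",
    "read_events",
    "write_events",
    "validate_events",
    "read_adjacency",
    "write_adjacency",
]


class FormatError(ValueError):
    """A file failed to parse or violated a format invariant."""


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

# 2-D scalp projection (azimuthal-equidistant style schematic, nose up,
# unit head radius).  Covers the 21 canonical 10-20 electrodes plus the
# centro-parietal row and the modern temporal aliases.
MONTAGE_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.309, 0.951), "Fpz": (0.0, 1.0), "Fp2": (0.309, 0.951),
    "F7": (-0.809, 0.588), "F3": (-0.375, 0.515), "Fz": (0.0, 0.5),
    "F4": (0.375, 0.515), "F8": (0.809, 0.588),
    "T3": (-1.0, 0.0), "T7": (-1.0, 0.0),
    "C3": (-0.5, 0.0), "Cz": (0.0, 0.0), "C4": (0.5, 0.0),
    "T4": (1.0, 0.0), "T8": (1.0, 0.0),
    "CP1": (-0.225, -0.25), "CPz": (0.0, -0.25), "CP2": (0.225, -0.25),
    "T5": (-0.809, -0.588), "P7": (-0.809, -0.588),
    "P3": (-0.375, -0.515), "Pz": (0.0, -0.5), "P4": (0.375, -0.515),
    "T6": (0.809, -0.588), "P8": (0.809, -0.588),
    "O1": (-0.309, -0.951), "Oz": (0.0, -1.0), "O2": (0.309, -0.951),
    "A1": (-1.15, -0.1), "A2": (1.15, -0.1),
}

# The 21 scalp sites used by default throughout the package.  The set is
# left-right symmetric and includes the five centro-parietal P3 electrodes
# (CPz, CP1, CP2, Cz, Pz).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "CP1", "CPz", "CP2",
    "P3", "Pz", "P4",
    "O1", "Oz", "O2",
)


def montage_positions(labels) -> np.ndarray:
    """Return the fixed 2-D scalp coordinates for ``labels`` (n x 2)."""
    missing = [lb for lb in labels if lb not in MONTAGE_2D]
    if missing:
        raise KeyError(f"no montage coordinates for channel(s): {missing}")
    return np.array([MONTAGE_2D[lb] for lb in labels], dtype=float)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """Continuous multichannel EEG, channels x samples, in microvolts."""

    data: np.ndarray
    fs: float
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.labels = list(self.labels)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("Recording.labels must be unique")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"Recording.data has {self.data.shape[0]} rows but "
                f"{len(self.labels)} labels"
            )
        if not self.fs > 0:
            raise ValueError("Recording.fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy(self, data: np.ndarray | None = None) -> "Recording":
        return Recording(
            data=self.data.copy() if data is None else data,
            fs=self.fs,
            labels=list(self.labels),
            meta=dict(self.meta),
        )


@dataclass
class Adjacency:
    """Symmetric weighted connectivity matrix with node labels.

    Weights live in [0, 1] with a zero diagonal; ``n_segments_used``
    records how many artifact-free segments the estimate averaged over.
    """

    w: np.ndarray
    labels: list[str]
    n_segments_used: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        self.labels = list(self.labels)
        n = len(self.labels)
        if self.w.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.w.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.w, self.w.T, atol=1e-9):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.w) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if self.w.min() < 0 or self.w.max() > 1:
            raise ValueError("adjacency weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def upper_values(self) -> np.ndarray:
        """The N(N-1)/2 upper-triangle weights, row-major order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.w[iu]


# ---------------------------------------------------------------------------
# recordings on disk
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(rec: Recording, path, format: str = "tsv") -> Path:
    """Write ``rec`` to ``path`` as ``tsv`` (lossless text) or ``edf``.

    The TSV layout is samples as rows, channels as columns, with a header
    row of channel labels and a JSON sidecar (``<path>.json``) holding the
    sampling rate and metadata.  EDF uses 16-bit samples over a symmetric
    physical range, so values round-trip only to the quantization step
    ``range / 2**16``.
    """
    path = Path(path)
    if format == "tsv":
        header = "\t".join(rec.labels)
        np.savetxt(path, rec.data.T, fmt="%.17g", delimiter="\t",
                   header=header, comments="")
        sidecar = {"fs": rec.fs, "labels": rec.labels, "unit": "uV",
                   "meta": rec.meta}
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1,
                                                  sort_keys=True))
        return path
    if format == "edf":
        _write_edf(rec, path)
        return path
    raise FormatError(f"unknown recording format: {format!r}")


def read_recording(path, format: str = "tsv") -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if format == "tsv":
        return _read_tsv_recording(path)
    if format == "edf":
        return _read_edf(path)
    raise FormatError(f"unknown recording format: {format!r}")


def _read_tsv_recording(path: Path) -> Recording:
    if not path.exists():
        raise FormatError(f"recording file not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar header {sidecar} for {path}")
    side = json.loads(sidecar.read_text())
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise FormatError(f"{path}, line 1: missing label row")
    labels = header.split("\t")
    if labels != list(side["labels"]):
        raise FormatError(
            f"{path}, line 1: label row {labels} does not match sidecar "
            f"labels {side['labels']}"
        )
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if data.shape[1] != len(labels):
        raise FormatError(
            f"{path}: {data.shape[1]} data columns but {len(labels)} labels"
        )
    return Recording(data=data.T, fs=float(side["fs"]), labels=labels,
                     meta=dict(side.get("meta", {})))


# --- minimal EDF writer ----------------------------------------------------
# EDF is a fixed-layout format: a 256-byte ASCII header, 256 ASCII bytes per
# signal, then little-endian int16 data records.  Records are one second
# long here, which requires an integer number of seconds of data.  Reading
# is delegated to MNE.


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    fs = rec.fs
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    if rec.n_samples % spr != 0:
        raise FormatError(
            "EDF writer requires a whole number of seconds of data; "
            f"got {rec.n_samples} samples at fs={fs} "
            "(use the tsv format for arbitrary lengths)"
        )
    n_records = rec.n_samples // spr
    ns = rec.n_channels
    # symmetric physical range per file, padded so the range is never zero
    pmax = float(np.max(np.abs(rec.data))) * 1.0001 + 1e-6
    pmin = -pmax
    dmin, dmax = -32768, 32767

    header = b"".join([
        _ascii("0", 8),                      # version
        _ascii("X X X X", 80),               # patient id
        _ascii("Startdate X X X X", 80),     # recording id
        _ascii("01.01.00", 8),               # start date
        _ascii("00.00.00", 8),               # start time
        _ascii(256 * (1 + ns), 8),           # header bytes
        _ascii("", 44),                      # reserved
        _ascii(n_records, 8),
        _ascii("1", 8),                      # record duration (s)
        _ascii(ns, 4),
    ])
    fields = [
        (16, [lb for lb in rec.labels]),            # label
        (80, ["" for _ in range(ns)]),              # transducer
        (8, ["uV" for _ in range(ns)]),             # physical dimension
        (8, [f"{pmin:.6g}"[:8] for _ in range(ns)]),
        (8, [f"{pmax:.6g}"[:8] for _ in range(ns)]),
        (8, [str(dmin) for _ in range(ns)]),
        (8, [str(dmax) for _ in range(ns)]),
        (80, ["" for _ in range(ns)]),              # prefiltering
        (8, [str(spr) for _ in range(ns)]),
        (32, ["" for _ in range(ns)]),              # reserved
    ]
    header += b"".join(
        b"".join(_ascii(v, width) for v in values) for width, values in fields
    )
    # physical -> digital with the declared (truncated-ASCII) range
    pmin_decl = float(f"{pmin:.6g}"[:8])
    pmax_decl = float(f"{pmax:.6g}"[:8])
    scale = (dmax - dmin) / (pmax_decl - pmin_decl)
    dig = np.round((rec.data - pmin_decl) * scale + dmin)
    dig = np.clip(dig, dmin, dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = dig[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())  # signal-major within each record


def _read_edf(path: Path) -> Recording:
    if not Path(path).exists():
        raise FormatError(f"recording file not found: {path}")
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     labels=list(raw.ch_names), meta={"source": str(path)})


def select_channels(rec: Recording, wanted) -> Recording:
    """Reorder/subset channels to ``wanted``; all must be present."""
    wanted = list(wanted)
    missing = [lb for lb in wanted if lb not in rec.labels]
    if missing:
        raise KeyError(
            "channel " + ", ".join(missing) + " not found in recording"
        )
    idx = [rec.labels.index(lb) for lb in wanted]
    return Recording(data=rec.data[idx], fs=rec.fs, labels=wanted,
                     meta=dict(rec.meta))


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


def validate_events(events: pd.DataFrame, vocabulary=None) -> pd.DataFrame:
    """Check the event-table invariants and return the frame unchanged."""
    for col in ("onset_sample", "label"):
        if col not in events.columns:
            raise FormatError(f"event table missing column {col!r}")
    onsets = events["onset_sample"].to_numpy()
    if len(onsets) and (onsets < 0).any():
        raise FormatError("event onsets must be >= 0")
    if len(onsets) > 1 and not (np.diff(onsets) > 0).all():
        raise FormatError("event onsets must be strictly increasing")
    if vocabulary is not None:
        bad = sorted(set(events["label"]) - set(vocabulary))
        if bad:
            raise FormatError(f"unknown event label(s): {bad}")
    return events


def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    validate_events(events)
    events[["onset_sample", "label"]].to_csv(path, sep="\t", index=False)
    return path


def read_events(path, vocabulary=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"event file not found: {path}")
    events = pd.read_csv(path, sep="\t", dtype={"onset_sample": np.int64,
                                                "label": str})
    return validate_events(events, vocabulary=vocabulary)


# ---------------------------------------------------------------------------
# adjacency matrices
# ---------------------------------------------------------------------------


def write_adjacency(adj: Adjacency, path) -> Path:
    """Write a labelled adjacency TSV (12 significant digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# n_segments_used=%d\n" % adj.n_segments_used)
        fh.write("\t" + "\t".join(adj.labels) + "\n")
        for lb, row in zip(adj.labels, adj.w):
            fh.write(lb + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")
    return path


def read_adjacency(path) -> Adjacency:
    """Read an adjacency TSV; asymmetric input is symmetrized with a warning."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"adjacency file not found: {path}")
    with open(path) as fh:
        first = fh.readline()
        n_seg = 0
        if first.startswith("#"):
            if "n_segments_used=" in first:
                n_seg = int(first.split("=", 1)[1])
            header = fh.readline()
        else:
            header = first
        labels = header.rstrip("\n").split("\t")[1:]
        rows = []
        row_labels = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row_labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if row_labels != labels:
        raise FormatError(f"{path}: row labels do not match column labels")
    w = np.array(rows, dtype=float)
    meta = {}
    asym = np.max(np.abs(w - w.T)) if w.size else 0.0
    if asym > 0:
        if asym > 1e-12:
            warnings.warn(
                f"{path}: asymmetry {asym:.3g} exceeds 1e-12; symmetrizing",
                stacklevel=2,
            )
            logger.warning("adjacency %s symmetrized (asymmetry %.3g)",
                           path, asym)
        w = (w + w.T) / 2.0
        meta["symmetrized"] = True
        meta["max_asymmetry"] = float(asym)
    np.fill_diagonal(w, 0.0)
    return Adjacency(w=w, labels=labels, n_segments_used=n_seg, meta=meta)
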