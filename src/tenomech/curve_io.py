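"""Reading, writing and phase segmentation of indentation force records.

The on-disk format is a plain TSV with a metadata header::

    # k_cant: 0.5
    # R_tip: 37.5
    # rate: 1000.0
    # label: day0_c01_s1
    time_s<TAB>base_um<TAB>force_uN
    0.0<TAB>0.0<TAB>0.0
    ...

Units are fixed in the file (seconds, micrometres, micronewtons); floats are
written with 17 significant digits so a write -> read round trip is
bit-identical.  All downstream mechanics converts to SI internally.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, NoLoadingError

logger = logging.getLogger(__name__)

#: metadata keys that must be present in every record / file header
REQUIRED_META = ("k_cant", "R_tip", "rate")

_COLUMNS = ("time_s", "base_um", "force_uN")

MIN_SAMPLES = 100


@dataclass
class ForceRecord:
    """One indentation experiment.

    Attributes
    ----------
    t : np.ndarray
        Time in seconds, strictly increasing.
    z : np.ndarray
        Cantilever *base* position in micrometres (not the tip position:
        the tip lags the base by the cantilever deflection F/k).
    F : np.ndarray
        Measured force in micronewtons.
    meta : dict
        Must contain ``k_cant`` (N/m), ``R_tip`` (um), ``rate`` (Hz);
        ``label`` is optional free text.
    phase : np.ndarray or None
        Optional per-sample phase annotation (``"load"``/``"hold"``/
        ``"unload"``) attached by the simulator; not serialised — phases are
        always recoverable from ``z`` via :func:`segment_phases`.
    """

    t: np.ndarray
    z: np.ndarray
    F: np.ndarray
    meta: dict
    phase: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if not (self.t.shape == self.z.shape == self.F.shape):
            raise FormatError("t, z, F must have identical shapes")
        if self.t.ndim != 1 or self.t.size < MIN_SAMPLES:
            raise FormatError(
                f"a force record needs at least {MIN_SAMPLES} samples, "
                f"got {self.t.size}"
            )
        if np.any(np.diff(self.t) <= 0):
            raise FormatError("time must be strictly increasing")
        for key in REQUIRED_META:
            if key not in self.meta:
                raise FormatError(f"missing required metadata key: {key!r}")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class SegmentedCurve:
    """A force record split into loading / hold / unloading index ranges.

    Ranges are half-open ``range`` objects into the record arrays; ``hold``
    and ``unload`` may be empty.
    """

    record: ForceRecord
    load: range
    hold: range
    unload: range

    def __post_init__(self) -> None:
        n = len(self.record)
        prev_stop = 0
        for r in (self.load, self.hold, self.unload):
            if len(r) == 0:
                continue
            if r.start < prev_stop or r.stop > n:
                raise FormatError("phase ranges must be ordered and in bounds")
            prev_stop = r.stop


def write_force_record(record: ForceRecord, path) -> None:
    """Write a record to the documented TSV dialect (lossless)."""
    meta = dict(record.meta)
    lines = []
    for key in REQUIRED_META:
        lines.append(f"# {key}: {float(meta[key]):.17g}\n")
    lines.append(f"# label: {meta.get('label', '')}\n")
    lines.append("\t".join(_COLUMNS) + "\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
        np.savetxt(
            fh,
            np.column_stack([record.t, record.z, record.F]),
            fmt="%.17g",
            delimiter="\t",
        )


def read_force_record(path) -> ForceRecord:
    """Read a TSV force record, validating header and columns."""
    meta: dict = {}
    body = io.StringIO()
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_header += 1
                try:
                    key, value = line[1:].split(":", 1)
                except ValueError as exc:
                    raise FormatError(f"malformed header line: {line!r}") from exc
                key = key.strip()
                value = value.strip()
                meta[key] = value if key == "label" else _parse_float(key, value)
            else:
                body.write(line)
                break
        for line in fh:
            body.write(line)
    text = body.getvalue()
    if not text.strip():
        raise FormatError(f"{path}: empty file or no data section")
    header, _, data_text = text.partition("\n")
    if tuple(header.strip().split("\t")) != _COLUMNS:
        raise FormatError(
            f"{path}: expected column header {'	'.join(_COLUMNS)!r}, "
            f"got {header.strip()!r}"
        )
    for key in REQUIRED_META:
        if key not in meta:
            raise FormatError(f"{path}: missing required metadata key {key!r}")
    try:
        data = np.loadtxt(io.StringIO(data_text), delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: ragged or non-numeric data rows") from exc
    if data.shape[1] != 3:
        raise FormatError(f"{path}: expected 3 columns, got {data.shape[1]}")
    return ForceRecord(t=data[:, 0], z=data[:, 1], F=data[:, 2], meta=meta)


def _parse_float(key: str, value: str) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise FormatError(f"non-numeric value for metadata key {key!r}: {value!r}") from exc


def segment_phases(record: ForceRecord, plateau_tol_um: float = 5e-3) -> SegmentedCurve:
    """Split a record into loading / hold / unloading phases from the base
    position profile only (force noise cannot move the boundaries).

    Loading is the first monotone advance of ``z``; a hold is a subsequent
    plateau whose samples stay within ``plateau_tol_um`` (default 5 nm, the
    piezo resolution scale) of the plateau median; unloading is a following
    monotone retreat.  A record with no plateau gets an empty hold range and
    a logged warning.
    """
    z = record.z
    dz = np.diff(z)
    cls = np.zeros(dz.size, dtype=int)
    cls[dz > plateau_tol_um / 10] = 1
    cls[dz < -plateau_tol_um / 10] = -1

    runs = _run_lengths(cls)  # list of (class, start, stop) over dz indices
    # skip any leading dwell, find the loading advance
    i = 0
    while i < len(runs) and runs[i][0] == 0:
        i += 1
    if i >= len(runs) or runs[i][0] != 1:
        raise NoLoadingError("record has no monotone advance of the base")
    # a dz run [a, b) of advances covers samples a..b; the peak sample b is
    # the first sample at the plateau position, so when a hold follows it is
    # assigned to the hold (hold onset = ramp end), otherwise to loading
    adv_start, adv_stop = runs[i][1], runs[i][2]
    i += 1

    hold = range(0)
    if i < len(runs) and runs[i][0] == 0:
        load = range(adv_start, adv_stop)
        start, stop = runs[i][1], runs[i][2] + 1
        seg = z[start:stop]
        med = np.median(seg)
        ok = np.abs(seg - med) < plateau_tol_um
        if ok.all():
            hold = range(start, stop)
        else:
            # trim to the contiguous in-band core around the median
            idx = np.flatnonzero(ok)
            hold = range(start + idx[0], start + idx[-1] + 1)
        i += 1
    else:
        load = range(adv_start, adv_stop + 1)
        logger.warning("no hold plateau detected in record %s", record.meta.get("label", ""))

    unload = range(0)
    if i < len(runs) and runs[i][0] == -1:
        start = max(runs[i][1] + 1, hold.stop if len(hold) else load.stop)
        unload = range(start, runs[i][2] + 1)

    return SegmentedCurve(record=record, load=load, hold=hold, unload=unload)


def _run_lengths(cls: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a class array as (class, start, stop) triples."""
    if cls.size == 0:
        return []
    bounds = np.flatnonzero(np.diff(cls)) + 1
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [cls.size]])
    return [(int(cls[a]), int(a), int(b)) for a, b in zip(starts, stops)]
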