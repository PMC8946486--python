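"""Read and write synchronized PPG/ECG/ABP records.

A record holds three time-aligned single-channel waveforms sampled on a
shared clock: fingertip photoplethysmography (PPG), electrocardiogram
(ECG), and invasive arterial blood pressure (ABP, in mmHg).  Two
on-disk layouts are supported:

* ``columnar`` — a CSV file with header ``ppg,ecg,abp`` and a JSON
  sidecar (``<file>.json``) carrying the sampling rate and record id;
* ``container`` — an HDF5 file with datasets ``/ppg``, ``/ecg``,
  ``/abp`` and root attributes ``fs`` and ``record_id``.

An optional adapter reads one record from a MAT v7.3 (HDF5-based)
container whose per-record matrix stores rows in the order
PPG, ABP, ECG — the layout of the public cuff-less blood-pressure
waveform collection this kind of pipeline is usually run on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SignalRecord",
    "ChannelMissingError",
    "LengthMismatchError",
    "read_record",
    "write_record",
    "read_source_dataset_record",
]

CHANNELS = ("ppg", "ecg", "abp")

#: plausible arterial-pressure band used by the validator (mmHg)
ABP_PLAUSIBLE = (0.0, 300.0)


class ChannelMissingError(KeyError):
    """A required waveform channel is absent from the input file."""


class LengthMismatchError(ValueError):
    """Channels of one record do not share a common length."""


@dataclass
class SignalRecord:
    """Synchronized PPG/ECG/ABP waveforms at a single sampling rate.

    Parameters
    ----------
    ppg, ecg : ndarray
        Optical and electrical waveforms in arbitrary sensor units.
    abp : ndarray
        Invasive arterial pressure in mmHg.
    fs : float
        Sampling rate in Hz (the same clock for all three channels).
    record_id : str
        Free-text label carried through I/O round-trips.
    """

    ppg: np.ndarray
    ecg: np.ndarray
    abp: np.ndarray
    fs: float
    record_id: str = field(default="")

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=np.float64)
        self.ecg = np.asarray(self.ecg, dtype=np.float64)
        self.abp = np.asarray(self.abp, dtype=np.float64)
        lengths = {len(self.ppg), len(self.ecg), len(self.abp)}
        if len(lengths) != 1:
            raise LengthMismatchError(
                "length mismatch: ppg/ecg/abp have lengths "
                f"{len(self.ppg)}/{len(self.ecg)}/{len(self.abp)}"
            )
        if self.n_samples < 1:
            raise LengthMismatchError("length mismatch: record is empty")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        for name in CHANNELS:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite samples in channel {name!r}")

    @property
    def n_samples(self) -> int:
        return len(self.ppg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def abp_in_plausible_range(self) -> bool:
        """True when every ABP sample lies inside [0, 300] mmHg.

        Out-of-band values are physiologically suspect but not an
        error; callers decide whether to warn or reject.
        """
        lo, hi = ABP_PLAUSIBLE
        return bool(np.all((self.abp >= lo) & (self.abp <= hi)))


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in {".h5", ".hdf5", ".hdf"}:
        return "container"
    return "columnar"


def read_record(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
) -> SignalRecord:
    """Read one record; ``format`` is inferred from the suffix if omitted.

    ``fs`` overrides (columnar) or supersedes (container) the stored
    sampling rate.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "columnar":
        return _read_csv(path, fs)
    if fmt == "container":
        return _read_h5(path, fs)
    raise ValueError(f"unknown format {fmt!r}")


def write_record(
    record: SignalRecord,
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write a record so that :func:`read_record` reproduces it exactly."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "columnar":
        _write_csv(record, path)
    elif fmt == "container":
        _write_h5(record, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _read_csv(path: Path, fs: float | None) -> SignalRecord:
    frame = pd.read_csv(path)
    frame.columns = [c.strip().lower() for c in frame.columns]
    for name in CHANNELS:
        if name not in frame.columns:
            raise ChannelMissingError(f"channel missing: {name}")
    meta: dict = {}
    sidecar = path.with_name(path.name + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    rate = fs if fs is not None else meta.get("fs")
    if rate is None:
        raise ValueError(f"no sampling rate: provide fs= or a sidecar {sidecar.name}")
    return SignalRecord(
        ppg=frame["ppg"].to_numpy(),
        ecg=frame["ecg"].to_numpy(),
        abp=frame["abp"].to_numpy(),
        fs=float(rate),
        record_id=str(meta.get("record_id", "")),
    )


def _write_csv(record: SignalRecord, path: Path) -> None:
    pd.DataFrame(
        {name: getattr(record, name) for name in CHANNELS}
    ).to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_name(path.name + ".json")
    sidecar.write_text(
        json.dumps({"fs": record.fs, "record_id": record.record_id})
    )


def _read_h5(path: Path, fs: float | None) -> SignalRecord:
    with h5py.File(path, "r") as handle:
        keys = {k.lower(): k for k in handle.keys()}
        data = {}
        for name in CHANNELS:
            if name not in keys:
                raise ChannelMissingError(f"channel missing: {name}")
            data[name] = np.asarray(handle[keys[name]], dtype=np.float64).ravel()
        rate = fs if fs is not None else handle.attrs.get("fs")
        record_id = handle.attrs.get("record_id", "")
        if isinstance(record_id, bytes):
            record_id = record_id.decode()
    if rate is None:
        raise ValueError("no sampling rate: container lacks an 'fs' attribute")
    return SignalRecord(fs=float(rate), record_id=str(record_id), **data)


def _write_h5(record: SignalRecord, path: Path) -> None:
    with h5py.File(path, "w") as handle:
        for name in CHANNELS:
            handle.create_dataset(name, data=getattr(record, name))
        handle.attrs["fs"] = record.fs
        handle.attrs["record_id"] = record.record_id


# Row order inside the source container's per-record matrix.
_SOURCE_ROW_ORDER = ("ppg", "abp", "ecg")
_SOURCE_FS = 125.0


def read_source_dataset_record(path: str | Path, part_index: int = 0) -> SignalRecord:
    """Read one record from a MAT v7.3 style container (optional adapter).

    The container stores a cell array of per-record matrices with three
    rows in the fixed order PPG, ABP, ECG; sampling rate is 125 Hz by
    the collection's documentation.  ``part_index`` selects the record.
    """
    path = Path(path)
    with h5py.File(path, "r") as handle:
        root = None
        for key in handle.keys():
            if key != "#refs#":
                root = handle[key]
                break
        if root is None:
            raise ValueError(f"malformed container: no record variable in {path}")
        if isinstance(root, h5py.Dataset) and root.dtype == h5py.ref_dtype:
            refs = np.asarray(root).ravel()
            if not 0 <= part_index < refs.size:
                raise IndexError(
                    f"part_index {part_index} out of range for {refs.size} records"
                )
            matrix = np.asarray(handle[refs[part_index]], dtype=np.float64)
        elif isinstance(root, h5py.Dataset):
            if part_index != 0:
                raise IndexError("container holds a single record; part_index must be 0")
            matrix = np.asarray(root, dtype=np.float64)
        else:
            raise ValueError("malformed container: unsupported record layout")
    # MAT files are column-major; accept either orientation of a 3 x T matrix.
    if matrix.ndim != 2:
        raise ValueError(f"malformed container: record is {matrix.ndim}-dimensional")
    if matrix.shape[0] != 3 and matrix.shape[1] == 3:
        matrix = matrix.T
    if matrix.shape[0] != 3:
        raise ValueError(
            f"malformed container: expected 3 channel rows, got shape {matrix.shape}"
        )
    channels = dict(zip(_SOURCE_ROW_ORDER, matrix))
    return SignalRecord(
        ppg=channels["ppg"],
        ecg=channels["ecg"],
        abp=channels["abp"],
        fs=_SOURCE_FS,
        record_id=f"{path.stem}[{part_index}]",
    )
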