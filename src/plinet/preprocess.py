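"""Montage handling, band-pass filtering and epoch selection for scalp EEG.

The processing chain mirrors standard clinical resting-state practice:
a 10-20 montage re-referenced to the common average (after dropping
artifact-prone frontopolar and auricular electrodes), zero-phase band-pass
filtering into the classical frequency bands, and selection of short
fixed-length epochs from the start of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "Montage",
    "BandDefinition",
    "EpochSet",
    "Record",
    "STANDARD_10_20_21",
    "DEFAULT_EXCLUDED",
    "ANALYSIS_BANDS",
    "POWER_BANDS",
    "default_montage",
    "read_ascii",
    "read_edf",
    "apply_montage",
    "bandpass",
    "select_epochs",
]

#: The 21 scalp electrodes of the international 10-20 system used for
#: acquisition, in acquisition order.
STANDARD_10_20_21: tuple[str, ...] = (
    "Fp1", "Fp2", "F8", "F4", "Fz", "F3", "F7", "A2", "T8", "C4", "Cz",
    "C3", "T7", "A1", "P8", "P4", "Pz", "P3", "P7", "O1", "O2",
)

#: Channels excluded before network construction (frontopolar and auricular
#: electrodes dominated by eye-movement and ECG artifact), leaving 17 nodes.
DEFAULT_EXCLUDED: tuple[str, ...] = ("Fp1", "Fp2", "A1", "A2")


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band with half-open interval semantics [low, high)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(
                f"band {self.name!r} requires 0 < low < high, got "
                f"({self.low}, {self.high})"
            )


#: Bands in which connectivity and network topology are analyzed.
ANALYSIS_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

#: Bands used for the relative power spectrum (alpha split in two).
POWER_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)


@dataclass(frozen=True)
class Montage:
    """An ordered electrode list with an exclusion set and reference scheme.

    Only the common-average reference is supported; ``excluded`` channels are
    dropped before the average is formed.
    """

    channel_labels: tuple[str, ...]
    reference: str = "average"
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("montage labels must be unique")
        extra = set(self.excluded) - set(self.channel_labels)
        if extra:
            raise ValueError(f"excluded labels not in montage: {sorted(extra)}")
        if self.reference != "average":
            raise ValueError(f"unsupported reference scheme {self.reference!r}")

    @property
    def retained(self) -> tuple[str, ...]:
        """Channels kept for analysis, in montage order."""
        return tuple(c for c in self.channel_labels if c not in set(self.excluded))


def default_montage() -> Montage:
    """The 21-electrode acquisition montage with the standard 4 exclusions."""
    return Montage(STANDARD_10_20_21, excluded=DEFAULT_EXCLUDED)


@dataclass
class Record:
    """A raw continuous multichannel recording (channels x samples)."""

    data: np.ndarray
    channel_labels: tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("record data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("record contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """A stack of fixed-length multichannel epochs for one subject/condition.

    ``epochs`` has shape (n_epochs, n_channels, n_samples).  ``band`` is set
    once the set has been band-pass filtered and is consumed downstream to
    size the analytic-signal edge exclusion.
    """

    epochs: np.ndarray
    channel_labels: tuple[str, ...]
    fs: float
    subject_id: str | None = None
    condition: str | None = None
    band: BandDefinition | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs, n_channels, n_samples)")
        if self.epochs.shape[1] != len(self.channel_labels):
            raise ValueError("channel count does not match labels")
        if not np.all(np.isfinite(self.epochs)):
            raise ValueError("epochs contain non-finite samples")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]


def read_ascii(path: str | Path, fs: float) -> Record:
    """Read a tab-separated ASCII sample matrix (samples x channels).

    The first row is a header of channel labels.  This is the plain-text
    export format used for the clinical recordings.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    data = np.loadtxt(path, skiprows=1, delimiter="\t", ndmin=2)
    return Record(data=data.T, channel_labels=tuple(header), fs=fs)


def write_ascii(record: Record, path: str | Path) -> None:
    """Write a record as a tab-separated samples x channels matrix."""
    path = Path(path)
    header = "\t".join(record.channel_labels)
    np.savetxt(path, record.data.T, fmt="%.6f", delimiter="\t",
               header=header, comments="")


def read_edf(path: str | Path) -> Record:
    """Read an EDF (European Data Format) recording via MNE."""
    import mne  # optional dependency, imported lazily

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Record(
        data=raw.get_data(),
        channel_labels=tuple(raw.ch_names),
        fs=float(raw.info["sfreq"]),
    )


def apply_montage(record: Record, montage: Montage) -> Record:
    """Drop excluded channels, canonicalize order, and average-reference.

    Every non-excluded montage channel must be present in the record; a
    missing channel is a hard error naming the channel.  After this step the
    per-sample mean across retained channels is zero.
    """
    index = {label: i for i, label in enumerate(record.channel_labels)}
    retained = montage.retained
    missing = [c for c in retained if c not in index]
    if missing:
        raise ValueError(f"record is missing required channel(s): {missing}")
    data = record.data[[index[c] for c in retained], :]
    data = data - data.mean(axis=0, keepdims=True)
    return Record(data=data, channel_labels=retained, fs=record.fs)


def _band_sos(band: BandDefinition, fs: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band {band.name!r} high edge {band.high} Hz exceeds Nyquist "
            f"{nyq} Hz"
        )
    return butter(order, [band.low / nyq, band.high / nyq],
                  btype="bandpass", output="sos")


def bandpass(epoch_set: EpochSet, band: BandDefinition, order: int = 4) -> EpochSet:
    """Zero-phase band-pass each channel of each epoch.

    Forward-backward 4th-order-per-pass Butterworth; zero phase distortion is
    essential because the downstream connectivity estimator is a pure phase
    statistic.  Output length equals input length.
    """
    sos = _band_sos(band, epoch_set.fs, order=order)
    filtered = sosfiltfilt(sos, epoch_set.epochs, axis=-1)
    return replace(epoch_set, epochs=filtered, band=band)


def select_epochs(
    record: Record,
    n_epochs: int = 4,
    epoch_len: int = 4096,
    offset: int = 0,
    subject_id: str | None = None,
    condition: str | None = None,
) -> EpochSet:
    """Cut contiguous non-overlapping fixed-length windows from a record.

    Epochs are taken from the beginning of the recording (after ``offset``
    samples), preserving sample values bit-exactly.  Defaults give four
    4096-sample epochs.
    """
    needed = offset + n_epochs * epoch_len
    if record.n_samples < needed:
        raise ValueError(
            f"record has {record.n_samples} samples; need {needed} "
            f"({needed - record.n_samples} short)"
        )
    windows = [
        record.data[:, offset + k * epoch_len: offset + (k + 1) * epoch_len]
        for k in range(n_epochs)
    ]
    epochs = (np.stack(windows, axis=0) if windows
              else np.empty((0, len(record.channel_labels), epoch_len)))
    return EpochSet(
        epochs=epochs,
        channel_labels=record.channel_labels,
        fs=record.fs,
        subject_id=subject_id,
        condition=condition,
    )
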