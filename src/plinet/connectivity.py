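"""Phase Lag Index connectivity and relative band power.

The Phase Lag Index (PLI) quantifies the consistency of the *sign* of the
instantaneous phase difference between two signals:

    PLI = | < sign(dPhi(t_k)) > |

where dPhi is the phase difference wrapped to (-pi, pi], t_k are sample
times, and <.> averages over time.  A value of 0 means no coupling or
coupling with a phase difference centered on 0 or +-pi radians (the
zero-lag case produced by volume conduction); 1 means a perfectly
consistent nonzero lag.  Phase differences of exactly zero contribute 0 to
the average (sign(0) = 0), which is what makes the index insensitive to
instantaneously mixed (volume-conducted) signals.  Because only phase is
used, the index is independent of signal amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert, welch

from .preprocess import BandDefinition, EpochSet, POWER_BANDS

__all__ = [
    "PhaseSeries",
    "ConnectivityMatrix",
    "instantaneous_phase",
    "edge_exclusion",
    "pli",
    "pli_matrix",
    "relative_power",
]


@dataclass
class PhaseSeries:
    """Instantaneous phase of one channel, with edge samples flagged.

    ``n_edge`` samples at each end are excluded from downstream averaging:
    the analytic signal is distorted near the record boundaries and that
    distortion is the dominant bias at epoch lengths of a few seconds.
    """

    values: np.ndarray
    fs: float
    label: str | None = None
    band: BandDefinition | None = None
    n_edge: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phase series contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def retained(self) -> np.ndarray:
        """Phase samples with the edge exclusion applied."""
        n = self.n_edge
        return self.values[n: len(self) - n] if n else self.values


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N PLI weight matrix with zero diagonal, one band."""

    weights: np.ndarray
    labels: tuple[str, ...]
    band: BandDefinition | None = None
    n_epochs_averaged: int = 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        validate_weights(self.weights)
        if self.weights.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def validate_weights(w: np.ndarray) -> None:
    """Check symmetry, zero diagonal and the [0, 1] weight range."""
    w = np.asarray(w)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    if not np.allclose(np.diag(w), 0.0, atol=1e-12):
        raise ValueError("weight matrix diagonal must be zero")
    if w.min() < -1e-12 or w.max() > 1 + 1e-12:
        raise ValueError("weights must lie in [0, 1]")


def edge_exclusion(n_samples: int, fs: float,
                   band: BandDefinition | None) -> int:
    """Number of samples to drop at each end of an analytic-signal phase.

    10% of the epoch at each end, capped at one period of the band's lowest
    frequency (ceil(fs / band.low)); without a band tag the plain 10% rule
    applies.
    """
    ten_pct = n_samples // 10
    if band is None:
        return ten_pct
    return min(int(math.ceil(fs / band.low)), ten_pct)


def instantaneous_phase(samples: np.ndarray, fs: float,
                        label: str | None = None,
                        band: BandDefinition | None = None,
                        n_edge: int | None = None) -> PhaseSeries:
    """Instantaneous phase of a band-limited signal via the analytic signal.

    The phase is the complex argument of the Hilbert-transform analytic
    signal, sample-aligned with the input.  Raises for constant input, whose
    phase is undefined.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D signal of length >= 2")
    if np.ptp(x) == 0:
        raise ValueError("constant signal: instantaneous phase is undefined")
    phase = np.angle(hilbert(x))
    if n_edge is None:
        n_edge = edge_exclusion(x.size, fs, band)
    return PhaseSeries(values=phase, fs=fs, label=label, band=band,
                       n_edge=n_edge)


def _wrap(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences to (-pi, pi]."""
    return np.angle(np.exp(1j * dphi))


def pli(phase_a: PhaseSeries, phase_b: PhaseSeries) -> float:
    """Phase Lag Index between two phase series: |<sign(dPhi)>|.

    Edge-flagged samples are removed identically from both series (using the
    larger of the two exclusions); sign(0) contributes 0.
    """
    if len(phase_a) != len(phase_b):
        raise ValueError(
            f"length mismatch: {len(phase_a)} vs {len(phase_b)}"
        )
    if phase_a.fs != phase_b.fs:
        raise ValueError("sampling rates differ")
    n_edge = max(phase_a.n_edge, phase_b.n_edge)
    n = len(phase_a)
    sl = slice(n_edge, n - n_edge)
    dphi = _wrap(phase_a.values[sl] - phase_b.values[sl])
    if dphi.size == 0:
        raise ValueError("no samples retained after edge exclusion")
    return float(abs(np.mean(np.sign(dphi))))


def _epoch_pli(epoch: np.ndarray, fs: float,
               band: BandDefinition | None) -> np.ndarray:
    """All-pairs PLI for one epoch (channels x samples), vectorized."""
    n_ch, n_samp = epoch.shape
    phase = np.angle(hilbert(epoch, axis=-1))
    n_edge = edge_exclusion(n_samp, fs, band)
    phase = phase[:, n_edge: n_samp - n_edge]
    # sign of wrapped pairwise differences, averaged over time
    dphi = phase[:, None, :] - phase[None, :, :]
    m = np.abs(np.mean(np.sign(_wrap(dphi)), axis=-1))
    # wrapping maps +-pi to the same point; enforce exact symmetry from i<j
    iu = np.triu_indices(n_ch, 1)
    out = np.zeros((n_ch, n_ch))
    out[iu] = m[iu]
    out += out.T
    return out


def pli_matrix(epoch_set: EpochSet) -> ConnectivityMatrix:
    """Epoch-averaged all-pairs PLI matrix for a band-filtered epoch set.

    A PLI value is computed per electrode pair per epoch and the arithmetic
    mean over epochs is used as the connection weight.
    """
    if epoch_set.n_channels < 2:
        raise ValueError("need at least 2 channels for connectivity")
    if epoch_set.n_epochs < 1:
        raise ValueError("need at least one epoch")
    mats = [_epoch_pli(ep, epoch_set.fs, epoch_set.band)
            for ep in epoch_set.epochs]
    return ConnectivityMatrix(
        weights=np.mean(mats, axis=0),
        labels=epoch_set.channel_labels,
        band=epoch_set.band,
        n_epochs_averaged=epoch_set.n_epochs,
    )


def relative_power(
    epoch_set: EpochSet,
    power_bands: tuple[BandDefinition, ...] = POWER_BANDS,
    total_band: tuple[float, float] = (0.5, 30.0),
    nperseg: int | None = None,
) -> dict[str, float]:
    """Relative power per band from a broadband (unfiltered) epoch set.

    Welch periodograms are computed per channel and epoch; power in each
    band (half-open [low, high) bins, so adjacent bands are disjoint) is
    divided by power in ``total_band``, and the fractions are averaged over
    channels and epochs.
    """
    if epoch_set.band is not None:
        raise ValueError("relative power requires the broadband epoch set")
    if nperseg is None:
        nperseg = min(epoch_set.n_samples, int(4 * epoch_set.fs))
    freqs, psd = welch(epoch_set.epochs, fs=epoch_set.fs,
                       nperseg=nperseg, axis=-1)
    total_mask = (freqs >= total_band[0]) & (freqs <= total_band[1])
    total = psd[..., total_mask].sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("zero total power in at least one channel/epoch")
    fractions: dict[str, float] = {}
    for band in power_bands:
        mask = (freqs >= band.low) & (freqs < band.high) & total_mask
        frac = psd[..., mask].sum(axis=-1) / total
        fractions[band.name] = float(frac.mean())
    return fractions
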