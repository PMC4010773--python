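"""Synthetic multichannel EEG: band-limited phase-coupled oscillators.

Every channel is a narrowband oscillation ``cos(phi_i(t))`` plus additive
white noise.  The intrinsic phase of channel i is a carrier at the band
centre frequency with a mean-reverting (Ornstein-Uhlenbeck) jitter, so
that uncoupled channels drift independently and their phase-difference
sign averages to zero over long epochs.  Coupling is realized as
intermittent entrainment: time is divided into short blocks and, within
each block, channel i follows a coupled lower-index channel j (with the
imposed phase offset ``lag[i, j]``) with probability ``coupling[i, j]``,
and its own intrinsic phase otherwise.  The estimated Phase Lag Index
between a directly coupled pair is therefore approximately the coupling
strength itself, indirect (two-hop) pairs are systematically weaker, and
the maximum spanning tree of the estimated PLI matrix recovers the
programmed coupling backbone.

Cohorts emulate a two-group (patient/control) by two-condition
(routine / sleep-deprived) design in which the coupling backbone is a
convex interpolation between a chain (path-like) and a star (hub-like)
matrix, and sleep deprivation moves patients toward the chain and
controls toward the star.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSet, Record, write_ascii

__all__ = [
    "OscillatorSpec",
    "TopologyShift",
    "CohortSpec",
    "chain_coupling",
    "star_coupling",
    "uniform_lag",
    "generate_epochs",
    "generate_cohort",
    "write_cohort",
]

#: Entrainment block duration (s).  Short enough for many independent
#: locking decisions per epoch, long enough for the band-pass filter not to
#: erase the locked segments.
BLOCK_SECONDS = 0.25
#: Stationary SD (rad) of the intrinsic Ornstein-Uhlenbeck phase jitter.
PHASE_JITTER_SD = 1.2
#: Correlation time (s) of the phase jitter; sets the oscillator linewidth
#: (roughly sd^2 / tau, i.e. < 1 Hz: narrowband within any analysis band).
PHASE_JITTER_TAU = 0.3
#: Default imposed phase offset (rad) on coupled pairs.  A quarter cycle
#: makes directly coupled pairs maximally detectable while the accumulated
#: two-hop offset (pi) sits where the phase-difference sign is symmetric,
#: so indirect pairs do not masquerade as backbone edges.
DEFAULT_LAG = math.pi / 2
#: SD (rad) and correlation time (s) of the small always-on per-channel
#: phase jitter; keeps entrained phase offsets from being numerically exact
#: so sign statistics behave continuously even for noiseless specs.
CHANNEL_JITTER_SD = 0.15
CHANNEL_JITTER_TAU = 0.05


def _check_coupling(coupling: np.ndarray, lag: np.ndarray) -> None:
    n = coupling.shape[0]
    if coupling.shape != (n, n) or lag.shape != (n, n):
        raise ValueError("coupling and lag must be square and equally sized")
    if not np.allclose(coupling, coupling.T):
        raise ValueError("coupling matrix must be symmetric")
    if not np.allclose(np.diag(coupling), 0.0):
        raise ValueError("coupling diagonal must be zero")
    if coupling.min() < 0 or coupling.max() > 1:
        raise ValueError("coupling strengths must lie in [0, 1]")
    if not np.allclose(lag, lag.T):
        raise ValueError("lag matrix must be symmetric")
    coupled = coupling > 0
    if np.any(coupled & ~((lag > 0) & (lag < math.pi))):
        raise ValueError("lag must lie in (0, pi) wherever coupling > 0")


@dataclass
class OscillatorSpec:
    """Parameters of one multichannel coupled-oscillator epoch set."""

    n_channels: int
    fs: float
    n_samples: int
    n_epochs: int
    carrier_band: tuple[float, float]
    coupling: np.ndarray
    lag: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.lag = np.asarray(self.lag, dtype=float)
        if self.coupling.shape[0] != self.n_channels:
            raise ValueError("coupling size does not match n_channels")
        _check_coupling(self.coupling, self.lag)
        low, high = self.carrier_band
        if not 0 < low < high < self.fs / 2:
            raise ValueError("carrier band must satisfy 0 < low < high < fs/2")
        min_samples = 2 * self.fs / low
        if self.n_samples < min_samples:
            raise ValueError(
                f"n_samples = {self.n_samples} is below the two-cycle "
                f"minimum {math.ceil(min_samples)} for low = {low} Hz"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def chain_coupling(n: int, strength: float = 0.85) -> np.ndarray:
    """Chain backbone: only |i - j| = 1 pairs coupled."""
    c = np.zeros((n, n))
    idx = np.arange(n - 1)
    c[idx, idx + 1] = strength
    c[idx + 1, idx] = strength
    return c

def star_coupling(n: int, strength: float = 0.85, hub: int = 0) -> np.ndarray:
    """Star backbone: every channel coupled to one hub."""
    c = np.zeros((n, n))
    c[hub, :] = strength
    c[:, hub] = strength
    c[hub, hub] = 0.0
    return c

def uniform_lag(coupling: np.ndarray, lag: float = DEFAULT_LAG) -> np.ndarray:
    """A lag matrix with one constant offset on every coupled pair."""
    return np.where(coupling > 0, lag, 0.0)


def _ou_series(rng: np.random.Generator, n: int, dt: float,
               sd: float, tau: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path (AR(1) recursion)."""
    from scipy.signal import lfilter

    a = math.exp(-dt / tau)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - a * a), size=n)
    innov[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -a], innov)


def _one_epoch(spec: OscillatorSpec, rng: np.random.Generator) -> np.ndarray:
    n_ch, n_samp, fs = spec.n_channels, spec.n_samples, spec.fs
    dt = 1.0 / fs
    f0 = 0.5 * (spec.carrier_band[0] + spec.carrier_band[1])
    t = np.arange(n_samp) * dt
    carrier = 2.0 * math.pi * f0 * t
    intrinsic = np.stack([
        carrier + _ou_series(rng, n_samp, dt, PHASE_JITTER_SD,
                             PHASE_JITTER_TAU)
        for _ in range(n_ch)
    ])

    block = max(1, int(round(BLOCK_SECONDS * fs)))
    starts = np.arange(0, n_samp, block)
    phases = np.empty_like(intrinsic)
    phases[0] = intrinsic[0]
    # entrainment is resolved in index order: the lower-index channel of a
    # coupled pair acts as the driver and its *final* phase is inherited,
    # so chains propagate phase (with accumulating lag) hop by hop
    for i in range(1, n_ch):
        drivers = np.flatnonzero(spec.coupling[i, :i] > 0)
        if drivers.size == 0:
            phases[i] = intrinsic[i]
            continue
        probs = spec.coupling[i, drivers].astype(float)
        total = probs.sum()
        if total > 1.0:
            probs = probs / total
        phases[i] = intrinsic[i]
        for s in starts:
            u = rng.random()
            acc = 0.0
            for j, p in zip(drivers, probs):
                acc += p
                if u < acc:
                    phases[i, s:s + block] = (
                        phases[j, s:s + block] + spec.lag[i, j]
                    )
                    break
    # small independent jitter per channel, added after entrainment so the
    # inherited offsets are never numerically exact
    phases = phases + np.stack([
        _ou_series(rng, n_samp, dt, CHANNEL_JITTER_SD, CHANNEL_JITTER_TAU)
        for _ in range(n_ch)
    ])
    signal = np.cos(phases)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
    return signal


def generate_epochs(spec: OscillatorSpec,
                    subject_id: str | None = None,
                    condition: str | None = None) -> EpochSet:
    """Generate ``spec.n_epochs`` coupled-oscillator epochs.

    Deterministic given ``spec.seed``; epochs are mutually independent
    draws of the same process.
    """
    from .preprocess import default_montage

    rng = np.random.default_rng(spec.seed)
    epochs = np.stack([_one_epoch(spec, rng) for _ in range(spec.n_epochs)])
    retained = default_montage().retained
    if spec.n_channels == len(retained):
        labels = retained  # emulate the 17 analysis electrodes by name
    else:
        labels = tuple(f"ch{i:02d}" for i in range(spec.n_channels))
    return EpochSet(epochs=epochs, channel_labels=labels, fs=spec.fs,
                    subject_id=subject_id, condition=condition)


@dataclass(frozen=True)
class TopologyShift:
    """How the chain-vs-star mixture changes from routine to sleep-deprived.

    The coupling backbone is ``alpha * chain + (1 - alpha) * star``; after
    sleep deprivation alpha moves by ``patient_delta`` in patients (positive
    = more path-like) and by ``control_delta`` in controls (negative = more
    star-like), with per-subject normal jitter of sd ``subject_sd`` on both
    the baseline mixture and the shift.
    """

    patient_delta: float = 0.35
    control_delta: float = -0.35
    baseline_alpha: float = 0.5
    subject_sd: float = 0.08

    @staticmethod
    def null() -> "TopologyShift":
        """No programmed condition effect in either group."""
        return TopologyShift(patient_delta=0.0, control_delta=0.0)


@dataclass
class CohortSpec:
    """A two-group, two-condition synthetic cohort.

    Defaults follow the study design: 21 patients, 17 controls, four
    4096-sample epochs at 512 Hz per recording, 17 channels, an alpha-band
    carrier, and 15/21 of patients flagged as having an added-value
    sleep-deprivation recording.
    """

    n_patients: int = 21
    n_controls: int = 17
    conditions: tuple[str, str] = ("routine", "sd")
    n_channels: int = 17
    fs: float = 512.0
    n_samples: int = 4096
    n_epochs: int = 4
    carrier_band: tuple[float, float] = (8.0, 13.0)
    backbone_strength: float = 0.85
    lag: float = DEFAULT_LAG
    noise_sd: float = 0.3
    topology_shift: TopologyShift = field(default_factory=TopologyShift)
    added_value_fraction: float = 15 / 21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are required")


def _mixture_coupling(alpha: float, n: int, strength: float) -> np.ndarray:
    alpha = float(np.clip(alpha, 0.0, 1.0))
    return (alpha * chain_coupling(n, strength)
            + (1.0 - alpha) * star_coupling(n, strength))


def generate_cohort(spec: CohortSpec
                    ) -> tuple[pd.DataFrame, dict[tuple[str, str], EpochSet]]:
    """Generate manifest and per-subject/condition epoch sets.

    The manifest has one row per subject x condition with columns
    ``subject_id, group, condition, added_value``.  One global seed fans
    out to per-subject substreams, so subjects are independent and the
    whole cohort is reproducible.
    """
    shift = spec.topology_shift
    root = np.random.SeedSequence(spec.seed)
    subjects = ([("patient", i) for i in range(spec.n_patients)]
                + [("control", i) for i in range(spec.n_controls)])
    children = root.spawn(len(subjects) + 1)
    meta_rng = np.random.default_rng(children[-1])

    n_added = int(round(spec.added_value_fraction * spec.n_patients))
    added_ids = set(meta_rng.choice(spec.n_patients, size=n_added,
                                    replace=False))

    rows = []
    epoch_sets: dict[tuple[str, str], EpochSet] = {}
    routine, sd = spec.conditions
    for (group, idx), child in zip(subjects, children):
        subject_id = f"{group[0]}{idx + 1:02d}"
        srng = np.random.default_rng(child)
        base = shift.baseline_alpha + srng.normal(0.0, shift.subject_sd)
        delta = (shift.patient_delta if group == "patient"
                 else shift.control_delta)
        delta = delta + srng.normal(0.0, shift.subject_sd)
        alphas = {routine: base, sd: base + delta}
        added = bool(group == "patient" and idx in added_ids)
        for condition in spec.conditions:
            coupling = _mixture_coupling(alphas[condition], spec.n_channels,
                                         spec.backbone_strength)
            osc = OscillatorSpec(
                n_channels=spec.n_channels,
                fs=spec.fs,
                n_samples=spec.n_samples,
                n_epochs=spec.n_epochs,
                carrier_band=spec.carrier_band,
                coupling=coupling,
                lag=uniform_lag(coupling, spec.lag),
                noise_sd=spec.noise_sd,
                seed=int(srng.integers(2**31)),
            )
            epoch_sets[(subject_id, condition)] = generate_epochs(
                osc, subject_id=subject_id, condition=condition)
            rows.append({
                "subject_id": subject_id,
                "group": group,
                "condition": condition,
                "added_value": added,
            })
    return pd.DataFrame(rows), epoch_sets


def write_cohort(manifest: pd.DataFrame,
                 epoch_sets: dict[tuple[str, str], EpochSet],
                 outdir: str | Path) -> Path:
    """Write a cohort as ASCII sample matrices plus a CSV manifest.

    One tab-separated samples x channels file (header = channel labels) per
    subject x condition, with the epochs concatenated into one continuous
    record; the manifest gains ``file`` and ``fs`` columns.  Returns the
    manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    files, rates = [], []
    for _, row in manifest.iterrows():
        es = epoch_sets[(row["subject_id"], row["condition"])]
        data = np.concatenate(list(es.epochs), axis=-1)
        fname = f"{row['subject_id']}_{row['condition']}.txt"
        write_ascii(Record(data=data, channel_labels=es.channel_labels,
                           fs=es.fs), outdir / fname)
        files.append(fname)
        rates.append(es.fs)
    manifest["file"] = files
    manifest["fs"] = rates
    path = outdir / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path
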