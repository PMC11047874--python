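"""Synthetic 8-lead ECG generation with controllable rhythm, labels and noise.

The generator is the data stand-in for clinical multi-lead recordings: each
beat is a sum of five Gaussian bumps (P, Q, R, S, T waves), repeated at
RR intervals drawn from a rhythm specification and projected to the eight
independent leads (I, II, V1–V6) by a fixed, seeded per-lead gain vector
with leads I and II anchored so the augmented-lead derivation identities
stay meaningful.

Labels live in a fixed 34-slot multi-hot vocabulary.  A handful of slots are
mechanistically synthesisable (rate, rhythm irregularity, T-wave and QRS
amplitude changes); the remaining slots are populated by seeded morphology-
parameter perturbations so the full 34-way head can be exercised.  Strong
class imbalance is the default sampling regime.

Three noise families are provided — Gaussian white noise, baseline wander
(sum of low-frequency sinusoids) and impulse noise — plus composites, each
scalable to an exact target signal-to-noise ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

N_CLASSES = 34
LEADS_8 = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")
LEADS_12 = LEADS_8 + ("III", "aVR", "aVL", "aVF")

TACHYCARDIA_BPM = 100.0
BRADYCARDIA_BPM = 60.0
ARRHYTHMIA_RR_CV = 0.12  # RR-jitter coefficient above which rhythm is irregular

#: nominal 34-class vocabulary; the first six slots have mechanistic synthesis
CLASS_NAMES = (
    "sinus_rhythm",
    "sinus_tachycardia",
    "sinus_bradycardia",
    "sinus_arrhythmia",
    "t_wave_change",
    "qrs_low_voltage",
) + tuple(f"morphology_variant_{i:02d}" for i in range(6, N_CLASSES))

# default beat morphology: (centre offset from R in s, width in s, amplitude in mV)
DEFAULT_MORPHOLOGY = {
    "P": (-0.200, 0.030, 0.15),
    "Q": (-0.035, 0.012, -0.12),
    "R": (0.000, 0.014, 1.00),
    "S": (0.035, 0.013, -0.25),
    "T": (0.260, 0.060, 0.35),
}

# fixed seeded per-lead gains; leads I and II anchored
_lead_rng = np.random.default_rng(7)
LEAD_GAINS = np.concatenate(
    [[1.0, 1.1], np.sign(_lead_rng.uniform(-1, 1, 6)) * _lead_rng.uniform(0.5, 1.4, 6)]
)
del _lead_rng


class ParameterError(ValueError):
    """Invalid generator or noise parameters."""


@dataclass
class EcgRecord:
    """Multi-lead ECG segment: (leads x samples) amplitudes in millivolts."""

    signal: np.ndarray
    fs: float
    lead_names: tuple[str, ...] = LEADS_8
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.lead_names = tuple(self.lead_names)
        if self.signal.ndim != 2:
            raise ParameterError("signal must be a 2-D (leads x samples) matrix")
        if self.signal.shape[0] != len(self.lead_names):
            raise ParameterError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.lead_names)} lead names"
            )
        if not np.isfinite(self.signal).all():
            raise ParameterError("signal contains non-finite amplitudes")
        if not self.fs > 0:
            raise ParameterError("sampling frequency must be positive")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self, signal: np.ndarray | None = None, **meta) -> "EcgRecord":
        return EcgRecord(
            signal=self.signal.copy() if signal is None else signal,
            fs=self.fs,
            lead_names=self.lead_names,
            meta={**self.meta, **meta},
        )


@dataclass
class LabelSet:
    """Multi-hot indicator over the 34-class vocabulary."""

    vector: np.ndarray

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.int8)
        if self.vector.shape != (N_CLASSES,):
            raise ParameterError(f"label vector must have length {N_CLASSES}")
        if not np.isin(self.vector, (0, 1)).all():
            raise ParameterError("label entries must be 0 or 1")

    @classmethod
    def from_indices(cls, indices: Sequence[int]) -> "LabelSet":
        v = np.zeros(N_CLASSES, dtype=np.int8)
        v[list(indices)] = 1
        return cls(v)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(int(i) for i in np.flatnonzero(self.vector))

    def __contains__(self, idx: int) -> bool:
        return bool(self.vector[idx])


@dataclass
class RhythmSpec:
    """Rhythm and morphology parameters driving one synthetic record."""

    heart_rate_bpm: float = 75.0
    rate_variability: float = 0.03
    morphology_params: dict = field(default_factory=lambda: dict(DEFAULT_MORPHOLOGY))
    active_labels: tuple[int, ...] = (0,)

    def __post_init__(self):
        if not self.heart_rate_bpm > 0:
            raise ParameterError("heart rate must be positive")
        if self.rate_variability < 0:
            raise ParameterError("rate variability must be non-negative")
        if len(self.active_labels) == 0:
            raise ParameterError("active_labels must be nonempty")
        if any(not (0 <= k < N_CLASSES) for k in self.active_labels):
            raise ParameterError(f"label indices must lie in [0, {N_CLASSES})")

    def labels(self) -> LabelSet:
        return LabelSet.from_indices(self.active_labels)


@dataclass
class NoiseSpec:
    """Parameterised corruption: kind, strength (target SNR xor amplitude), seed."""

    kind: str = "gaussian_white"
    target_snr_db: float | None = None
    amplitude: float | None = None
    params: dict = field(default_factory=dict)
    seed: int = 0
    children: tuple["NoiseSpec", ...] = ()

    _KINDS = ("gaussian_white", "baseline_wander", "impulse", "composite")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ParameterError(f"unknown noise kind {self.kind!r}")
        if (self.target_snr_db is None) == (self.amplitude is None):
            raise ParameterError(
                "exactly one of target_snr_db / amplitude must be set"
            )
        if self.kind == "composite" and len(self.children) < 2:
            raise ParameterError("composite noise needs at least two children")


def rate_labels(mean_bpm: float, rr_cv: float = 0.0) -> frozenset[int]:
    """Rate/rhythm-derived label indices implied by an RR-interval summary."""
    labels = set()
    if mean_bpm > TACHYCARDIA_BPM:
        labels.add(1)
    if mean_bpm < BRADYCARDIA_BPM:
        labels.add(2)
    if rr_cv > ARRHYTHMIA_RR_CV:
        labels.add(3)
    return frozenset(labels)


def detect_r_peaks(record: EcgRecord, lead: str = "II") -> np.ndarray:
    """Sample indices of R peaks on one lead.

    Peaks must clear half the lead's maximum, be at least 250 ms apart, and be
    narrow (QRS-width); the width bound keeps broad T waves out even when a
    low-voltage QRS shrinks the R peak to T-wave amplitude.
    """
    x = record.signal[record.lead_names.index(lead)]
    height = 0.5 * np.abs(x).max()
    peaks, _ = find_peaks(
        x,
        height=height,
        distance=max(1, int(0.25 * record.fs)),
        width=(None, 0.08 * record.fs),
    )
    return peaks


def _beat_waveform(t: np.ndarray, beat_times: np.ndarray, morphology: dict) -> np.ndarray:
    x = np.zeros_like(t)
    for centre, width, amp in morphology.values():
        # each wave contributes one Gaussian bump per beat
        for tb in beat_times:
            mu = tb + centre
            lo = np.searchsorted(t, mu - 5 * width)
            hi = np.searchsorted(t, mu + 5 * width)
            if hi > lo:
                x[lo:hi] += amp * np.exp(-((t[lo:hi] - mu) ** 2) / (2 * width**2))
    return x


def generate_clean(
    rhythm: RhythmSpec,
    duration_s: float = 10.0,
    fs: float = 500.0,
    seed: int = 0,
) -> EcgRecord:
    """Generate one clean 8-lead record; deterministic in (spec, seed)."""
    if duration_s <= 0 or fs <= 0:
        raise ParameterError("duration and sampling rate must be positive")
    if duration_s * fs < fs * 60.0 / rhythm.heart_rate_bpm:
        raise ParameterError(
            "record shorter than one cardiac cycle at the requested rate"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    rr_base = 60.0 / rhythm.heart_rate_bpm
    beat_times = []
    tb = 0.5 * rr_base
    while tb < duration_s:
        beat_times.append(tb)
        jitter = np.clip(rhythm.rate_variability * rng.standard_normal(), -0.45, 0.45)
        tb += rr_base * (1.0 + jitter)
    x = _beat_waveform(t, np.asarray(beat_times), rhythm.morphology_params)
    signal = np.outer(LEAD_GAINS, x)
    return EcgRecord(
        signal=signal,
        fs=fs,
        lead_names=LEADS_8,
        meta={
            "seed": seed,
            "heart_rate_bpm": rhythm.heart_rate_bpm,
            "rate_variability": rhythm.rate_variability,
            "active_labels": tuple(rhythm.active_labels),
            "n_beats": len(beat_times),
        },
    )


# -- noise synthesis -------------------------------------------------------------


def _raw_noise(shape: tuple[int, ...], spec: NoiseSpec, rng: np.random.Generator,
               fs: float) -> np.ndarray:
    if spec.kind == "gaussian_white":
        return rng.standard_normal(shape)
    if spec.kind == "baseline_wander":
        freqs = np.atleast_1d(spec.params.get("freqs", (0.15, 0.3)))
        amps = np.atleast_1d(spec.params.get("amps", np.ones_like(freqs)))
        n = shape[-1]
        t = np.arange(n) / fs
        out = np.zeros(shape)
        rows = out.reshape(-1, n)
        for row in rows:
            for f, a in zip(freqs, amps):
                row += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        return out
    if spec.kind == "impulse":
        prob = spec.params.get("prob", 0.01)
        magnitude = spec.params.get("magnitude", 1.0)
        mask = rng.random(shape) < prob
        signs = rng.choice((-1.0, 1.0), size=shape)
        return mask * signs * magnitude
    if spec.kind == "composite":
        out = np.zeros(shape)
        for child in spec.children:
            w = child.amplitude if child.amplitude is not None else 1.0
            out += w * _raw_noise(shape, child, rng, fs)
        return out
    raise ParameterError(f"unknown noise kind {spec.kind!r}")


def sample_noise(
    signal: np.ndarray,
    spec: NoiseSpec,
    rng: np.random.Generator | None = None,
    fs: float = 500.0,
) -> np.ndarray:
    """Noise matched to `signal`'s shape, scaled per row to the spec's strength.

    When ``target_snr_db`` is set the noise is scaled so that
    10*log10(sum X^2 / sum noise^2) equals the target exactly on each row.
    """
    signal = np.asarray(signal, dtype=float)
    if not np.isfinite(signal).all():
        raise ParameterError("signal contains non-finite amplitudes")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    noise = _raw_noise(signal.shape, spec, rng, fs)
    if spec.amplitude is not None:
        return spec.amplitude * noise
    rows_x = np.atleast_2d(signal)
    rows_n = np.atleast_2d(noise)
    p_sig = (rows_x**2).sum(axis=1)
    p_noise = (rows_n**2).sum(axis=1)
    if np.any(p_noise == 0):
        raise ParameterError("generated noise has zero power; cannot hit target SNR")
    scale = np.sqrt(p_sig / (p_noise * 10.0 ** (spec.target_snr_db / 10.0)))
    return (rows_n * scale[:, None]).reshape(signal.shape)


def corrupt(record: EcgRecord, noise: NoiseSpec) -> tuple[EcgRecord, EcgRecord]:
    """Return (noisy copy, noise-only residual); the input is left unmodified."""
    n = sample_noise(record.signal, noise, fs=record.fs)
    noisy = record.copy(signal=record.signal + n, noise_kind=noise.kind,
                        noise_seed=noise.seed)
    residual = record.copy(signal=n, noise_kind=noise.kind, noise_seed=noise.seed)
    return noisy, residual


# -- labelled dataset sampling ------------------------------------------------------

# seeded per-class morphology perturbations for the non-mechanistic slots:
# each class scales the amplitude and width of two waves
_pert_rng = np.random.default_rng(2024)
_CLASS_PERTURBATIONS: dict[int, list[tuple[str, float, float]]] = {}
for _k in range(6, N_CLASSES):
    _waves = _pert_rng.choice(list(DEFAULT_MORPHOLOGY), size=2, replace=False)
    _CLASS_PERTURBATIONS[_k] = [
        (w, float(_pert_rng.uniform(0.4, 1.8)), float(_pert_rng.uniform(0.6, 1.6)))
        for w in _waves
    ]
del _pert_rng, _k, _waves


def rhythm_for_class(k: int, rng: np.random.Generator) -> RhythmSpec:
    """A rhythm spec expressing class `k`, rate-consistent with its label."""
    morph = {w: list(p) for w, p in DEFAULT_MORPHOLOGY.items()}
    rate = rng.uniform(65.0, 95.0)
    variability = 0.03
    if k == 1:
        rate = rng.uniform(110.0, 160.0)
    elif k == 2:
        rate = rng.uniform(40.0, 55.0)
    elif k == 3:
        variability = 0.18
    elif k == 4:
        morph["T"][2] *= -0.6  # T-wave inversion
    elif k == 5:
        for w in ("Q", "R", "S"):
            morph[w][2] *= 0.35  # low-voltage QRS complex
    elif k >= 6:
        for wave, amp_scale, width_scale in _CLASS_PERTURBATIONS[k]:
            morph[wave][2] *= amp_scale
            morph[wave][1] *= width_scale
    morphology = {w: tuple(p) for w, p in morph.items()}
    return RhythmSpec(
        heart_rate_bpm=rate,
        rate_variability=variability,
        morphology_params=morphology,
        active_labels=(k,),
    )


def default_class_frequencies() -> np.ndarray:
    """Strongly imbalanced sampling weights (geometric decay over 34 slots)."""
    return 0.8 ** np.arange(N_CLASSES)


def make_dataset(
    n: int,
    class_frequencies: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    duration_s: float = 10.0,
    fs: float = 500.0,
) -> list[tuple[EcgRecord, EcgRecord, LabelSet]]:
    """Sample n (clean, noisy, labels) triples with the given class weights."""
    if n <= 0:
        raise ParameterError("dataset size must be positive")
    if class_frequencies is None:
        class_frequencies = default_class_frequencies()
    freqs = np.asarray(class_frequencies, dtype=float)
    if freqs.shape != (N_CLASSES,):
        raise ParameterError(f"class_frequencies must have length {N_CLASSES}")
    if (freqs < 0).any() or freqs.sum() == 0:
        raise ParameterError("class_frequencies must be non-negative, not all zero")
    if noise is None:
        noise = NoiseSpec(kind="gaussian_white", target_snr_db=5.0, seed=seed)
    p = freqs / freqs.sum()
    rng = np.random.default_rng(seed)
    triples = []
    for _ in range(n):
        k = int(rng.choice(N_CLASSES, p=p))
        rhythm = rhythm_for_class(k, rng)
        clean = generate_clean(
            rhythm, duration_s=duration_s, fs=fs, seed=int(rng.integers(2**31))
        )
        record_noise = replace(noise, seed=int(rng.integers(2**31)))
        noisy, _ = corrupt(clean, record_noise)
        triples.append((clean, noisy, rhythm.labels()))
    return triples
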