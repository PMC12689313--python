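"""Audio I/O, normalization, endpoint detection and 3-s segmentation.

All downstream analysis runs at a fixed 22.05 kHz rate on zero-mean mono
signals.  Events are cut into exactly 3-second clips (66150 samples); an
event shorter than 3 s yields one zero-padded clip, a longer one is tiled
into ceil(L/3) clips with the last zero-padded.  Dataset partitioning is
strictly patient-level: all clips of a patient land in exactly one side of
any split or fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

TARGET_SR = 22050
SEGMENT_SECONDS = 3.0
SEGMENT_SAMPLES = int(round(SEGMENT_SECONDS * TARGET_SR))  # 66150

__all__ = [
    "TARGET_SR", "SEGMENT_SAMPLES", "AudioSignal", "AudioSegment", "FrameGrid",
    "EndpointConfig", "load_and_normalize", "detect_endpoints", "segment_3s",
    "patient_split", "make_cv_folds", "write_wav",
]


@dataclass
class AudioSignal:
    samples: np.ndarray          # mono, zero-mean after preprocessing
    sample_rate: int
    patient_id: str | None = None
    group: str | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class AudioSegment:
    """A labeled fixed-length (3 s) clip."""

    samples: np.ndarray
    sample_rate: int = TARGET_SR
    label: int = 0               # 1 = snoring, 0 = non-snoring
    patient_id: str | None = None
    group: str | None = None
    pad_length: int = 0          # trailing zero samples
    source_interval: tuple | None = None

    def __post_init__(self):
        if len(self.samples) != SEGMENT_SAMPLES and self.sample_rate == TARGET_SR:
            raise ValueError(
                f"segment must be exactly {SEGMENT_SAMPLES} samples, "
                f"got {len(self.samples)}")


@dataclass(frozen=True)
class FrameGrid:
    """20 ms Hamming-windowed frames with a 10 ms hop."""

    frame_length_ms: float = 20.0
    hop_ms: float = 10.0
    window: str = "hamming"

    def __post_init__(self):
        if not self.frame_length_ms > self.hop_ms > 0:
            raise ValueError("require frame_length_ms > hop_ms > 0")

    def frame_samples(self, sample_rate: int) -> int:
        return int(round(self.frame_length_ms * 1e-3 * sample_rate))

    def hop_samples(self, sample_rate: int) -> int:
        return int(round(self.hop_ms * 1e-3 * sample_rate))


def load_and_normalize(path) -> AudioSignal:
    """Read a WAV file, average to mono, band-limited resample to 22.05 kHz,
    subtract the mean."""
    path = Path(path)
    try:
        sr, data = wavfile.read(path)
    except (FileNotFoundError, ValueError) as exc:
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise IOError(f"empty WAV file: {path}")
    x = np.asarray(data, dtype=np.float64)
    if np.issubdtype(data.dtype, np.integer):
        x = x / float(np.iinfo(data.dtype).max)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if sr != TARGET_SR:
        frac = Fraction(TARGET_SR, int(sr)).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator)
    x = x - x.mean()
    return AudioSignal(samples=x, sample_rate=TARGET_SR)


def write_wav(path, samples: np.ndarray, sample_rate: int = TARGET_SR):
    """Write float32 RIFF WAV, peak-limited to [-1, 1]."""
    x = np.asarray(samples, dtype=np.float32)
    peak = np.abs(x).max() if x.size else 0.0
    if peak > 1.0:
        x = x / peak
    wavfile.write(path, sample_rate, x)


@dataclass(frozen=True)
class EndpointConfig:
    """Double-threshold short-time-energy voice-activity detection.

    Thresholds are adaptive: the noise floor is the median frame energy;
    a region must exceed ``high_factor`` x floor somewhere and is then
    extended outward while energy stays above ``low_factor`` x floor (or the
    zero-crossing rate stays above ``zcr_factor`` x its median, catching
    fricative-like edges).
    """

    frame_ms: float = 20.0
    hop_ms: float = 10.0
    high_factor: float = 8.0
    low_factor: float = 2.0
    zcr_factor: float = 3.0
    min_event_s: float = 0.05
    merge_gap_s: float = 0.1


def _frame_view(x: np.ndarray, n: int, hop: int) -> np.ndarray:
    if len(x) < n:
        return np.empty((0, n))
    n_frames = (len(x) - n) // hop + 1
    idx = np.arange(n)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def detect_endpoints(signal: AudioSignal,
                     config: EndpointConfig = EndpointConfig()) -> list[tuple[float, float]]:
    """Return sorted, non-overlapping (start_s, end_s) active intervals."""
    sr = signal.sample_rate
    n = int(round(config.frame_ms * 1e-3 * sr))
    hop = int(round(config.hop_ms * 1e-3 * sr))
    frames = _frame_view(signal.samples, n, hop)
    if frames.shape[0] == 0:
        return []
    energy = (frames**2).mean(axis=1)
    floor = np.median(energy)
    if floor <= 0:
        active = energy > 0
        if not active.any():
            return []
        hi = lo = active
    else:
        hi = energy > config.high_factor * floor
        lo = energy > config.low_factor * floor
        zcr = (np.abs(np.diff(np.signbit(frames), axis=1)).sum(axis=1)) / n
        zfloor = np.median(zcr)
        if zfloor > 0:
            lo = lo | ((zcr > config.zcr_factor * zfloor) & (energy > floor))
    intervals = []
    i, nf = 0, len(energy)
    while i < nf:
        if hi[i]:
            a = i
            while a > 0 and lo[a - 1]:
                a -= 1
            b = i
            while b + 1 < nf and lo[b + 1]:
                b += 1
            intervals.append((a, b))
            i = b + 1
        else:
            i += 1
    # frames -> seconds, merge close neighbours, drop too-short events
    out = []
    for a, b in intervals:
        start = a * hop / sr
        end = (b * hop + n) / sr
        if out and start - out[-1][1] <= config.merge_gap_s:
            out[-1] = (out[-1][0], end)
        else:
            out.append((start, end))
    return [(s, e) for s, e in out if e - s >= config.min_event_s]


def segment_3s(signal: AudioSignal, events, labels) -> list[AudioSegment]:
    """Cut labeled events into exact 3-s clips (tile + zero-pad)."""
    if len(labels) != len(events):
        raise ValueError("one label per event is required")
    segs = []
    for (start_s, end_s), label in zip(events, labels):
        if label is None:
            raise ValueError(f"missing label for event ({start_s}, {end_s})")
        i0 = int(round(start_s * signal.sample_rate))
        i1 = int(round(end_s * signal.sample_rate))
        if i0 < 0 or i1 > len(signal.samples) or i1 <= i0:
            raise ValueError(f"event ({start_s}, {end_s}) outside signal bounds")
        chunk = signal.samples[i0:i1]
        n_clips = max(1, -(-len(chunk) // SEGMENT_SAMPLES))
        for c in range(n_clips):
            piece = chunk[c * SEGMENT_SAMPLES:(c + 1) * SEGMENT_SAMPLES]
            pad = SEGMENT_SAMPLES - len(piece)
            if pad:
                piece = np.concatenate([piece, np.zeros(pad)])
            segs.append(AudioSegment(
                samples=piece, sample_rate=TARGET_SR, label=int(label),
                patient_id=signal.patient_id, group=signal.group,
                pad_length=pad, source_interval=(start_s, end_s)))
    return segs


def _patient_ids(records) -> list:
    ids = []
    for r in records:
        pid = r.patient_id if hasattr(r, "patient_id") else r["patient_id"]
        if pid not in ids:
            ids.append(pid)
    return ids


def _of_patients(records, wanted) -> list:
    wanted = set(wanted)
    return [r for r in records
            if (r.patient_id if hasattr(r, "patient_id") else r["patient_id"]) in wanted]


def patient_split(records, ratio: float = 0.8, seed: int = 0):
    """Split records into (train, validation) with disjoint patient-ID sets."""
    ids = _patient_ids(records)
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_train = int(round(ratio * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train_ids, val_ids = order[:n_train], order[n_train:]
    return _of_patients(records, train_ids), _of_patients(records, val_ids)


def make_cv_folds(records, k: int = 5, seed: int = 0):
    """Partition records into k patient-level folds (every patient in
    exactly one fold)."""
    ids = _patient_ids(records)
    if len(ids) < k:
        raise ValueError(f"need at least {k} patients for {k} folds")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    chunks = np.array_split(np.arange(len(order)), k)
    return [_of_patients(records, [order[i] for i in chunk]) for chunk in chunks]
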