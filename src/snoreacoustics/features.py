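"""The four acoustic feature representations and the adaptive filter-bank
enhancement.

Every representation is framed as a filter bank applied to the short-time
power spectrum: triangular Mel filters, constant-Q bins (geometrically
spaced centers, constant center-to-bandwidth ratio Q), and a 12-class
chroma bank; MFCCs are the type-II cosine transform of the log Mel
energies.  The enhancement step scales, per frame, the filters whose energy
strictly exceeds the 80th percentile of that frame's filter-energy
distribution by a factor beta (default 1.5, selected by grid search over
{1.1, ..., 2.0}); all other filters pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .audioprep import AudioSegment, FrameGrid, TARGET_SR

LOG_FLOOR = 1e-10

__all__ = [
    "Spectrum", "FilterBankResponse", "EnhancementConfig", "CQTParams",
    "FeatureImage", "stft_frames", "mel_filterbank", "mel_spectrogram",
    "mfcc", "cqt_filterbank", "cqt_spectrogram", "chroma_filterbank", "cens",
    "enhance", "grid_search_beta", "render_image", "feature_image",
    "FEATURE_KINDS",
]

FEATURE_KINDS = ("mel", "mfcc", "cqt", "cens")


@dataclass
class Spectrum:
    """Per-frame DFT of Hamming-windowed frames."""

    coeffs: np.ndarray         # (n_frames, n_fft) complex
    sample_rate: int
    n_fft: int

    @property
    def power(self) -> np.ndarray:
        """|X(k)|^2 over the non-negative frequency bins."""
        return np.abs(self.coeffs[:, : self.n_fft // 2 + 1]) ** 2

    @property
    def freqs(self) -> np.ndarray:
        return np.fft.rfftfreq(self.n_fft, d=1.0 / self.sample_rate)


@dataclass
class FilterBankResponse:
    bank_kind: str                      # mel | cqt_bins | chroma
    H: np.ndarray                       # (M, n_bins) filter responses, >= 0
    energies: np.ndarray                # (n_frames, M), finite and >= 0
    freqs: np.ndarray                   # spectral grid of H's columns
    centers: np.ndarray | None = None   # per-filter center frequency
    bandwidths: np.ndarray | None = None
    gains: np.ndarray | None = None     # set by enhance()

    @property
    def n_filters(self) -> int:
        return self.H.shape[0]

    def log_energies(self, floor: float = LOG_FLOOR) -> np.ndarray:
        return np.log(np.maximum(self.energies, floor))


@dataclass(frozen=True)
class EnhancementConfig:
    beta: float = 1.5
    percentile: float = 80.0

    def __post_init__(self):
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")


@dataclass(frozen=True)
class CQTParams:
    f1: float = 32.70            # lowest-bin center (C1), Hz
    bins_per_octave: int = 12
    n_bins: int = 84

    def center(self, k: int) -> float:
        """Center frequency of bin k (1-based): f_k = f1 * 2^((k-1)/B)."""
        return self.f1 * 2.0 ** ((k - 1) / self.bins_per_octave)

    @property
    def centers(self) -> np.ndarray:
        return self.f1 * 2.0 ** (np.arange(self.n_bins) / self.bins_per_octave)

    @property
    def q_factor(self) -> float:
        return 1.0 / (2.0 ** (1.0 / self.bins_per_octave) - 1.0)


@dataclass
class FeatureImage:
    pixels: np.ndarray           # (H, W, 3) in [0, 1]
    feature_kind: str
    enhanced: bool = False


# ------------------------------------------------------------------- STFT
def stft_frames(segment, grid: FrameGrid = FrameGrid()) -> Spectrum:
    """Frame the segment (Hamming window) and DFT each frame."""
    if hasattr(segment, "samples"):
        x = np.asarray(segment.samples, dtype=float)
        sr = getattr(segment, "sample_rate", TARGET_SR)
    else:
        x = np.asarray(segment, dtype=float)
        sr = TARGET_SR
    n = grid.frame_samples(sr)
    hop = grid.hop_samples(sr)
    if n > len(x):
        raise ValueError(f"frame length {n} exceeds segment length {len(x)}")
    n_frames = (len(x) - n) // hop + 1
    idx = np.arange(n)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hamming(n)[None, :]
    return Spectrum(coeffs=np.fft.fft(frames, axis=1), sample_rate=sr, n_fft=n)


# ------------------------------------------------------------------- banks
def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(sample_rate: int, n_fft: int, n_filters: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Unit-peak triangular filters equally spaced on the Mel scale.

    Returns (n_filters, n_fft//2 + 1).
    """
    fmax = fmax if fmax is not None else sample_rate / 2.0
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    if n_filters > len(freqs) - 2:
        raise ValueError(f"{n_filters} filters exceed the {len(freqs)} usable bins")
    edges = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_filters + 2))
    H = np.zeros((n_filters, len(freqs)))
    for m in range(n_filters):
        lo, c, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (freqs - lo) / max(c - lo, 1e-12)
        down = (hi - freqs) / max(hi - c, 1e-12)
        H[m] = np.clip(np.minimum(up, down), 0.0, None)
    return H


def mel_spectrogram(spec: Spectrum, n_filters: int = 128,
                    fmin: float = 0.0, fmax: float | None = None) -> FilterBankResponse:
    H = mel_filterbank(spec.sample_rate, spec.n_fft, n_filters, fmin, fmax)
    freqs = spec.freqs
    return FilterBankResponse(bank_kind="mel", H=H, energies=spec.power @ H.T,
                              freqs=freqs)


def mfcc(log_energies: np.ndarray, n_coeffs: int = 13) -> np.ndarray:
    """Cosine transform of log filter-bank energies.

    C(l) = sum_{m=1..M} s(m) cos(pi l (m - 0.5) / M) for l = 1..n_coeffs;
    a constant s yields zero for every l by cosine orthogonality.
    """
    s = np.atleast_2d(log_energies)
    M = s.shape[1]
    if n_coeffs > M:
        raise ValueError(f"cannot take {n_coeffs} coefficients from {M} filters")
    m = np.arange(1, M + 1)
    ls = np.arange(1, n_coeffs + 1)
    basis = np.cos(np.pi * ls[:, None] * (m[None, :] - 0.5) / M)  # (L, M)
    out = s @ basis.T
    return out if log_energies.ndim > 1 else out[0]


def cqt_filterbank(params: CQTParams, sample_rate: int, n_fft: int):
    """Triangular constant-Q filters on the linear DFT grid.

    Bin k has center f_k = f1 * 2^((k-1)/B) and bandwidth
    df_k = f_k * (2^(1/B) - 1), so Q = f_k / df_k is the same for all bins.
    """
    centers = params.centers
    if centers[-1] >= sample_rate / 2:
        raise ValueError(
            f"top CQT bin {centers[-1]:.1f} Hz reaches the Nyquist frequency "
            f"{sample_rate / 2:.1f} Hz")
    bandwidths = centers * (2.0 ** (1.0 / params.bins_per_octave) - 1.0)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    H = np.clip(1.0 - np.abs(freqs[None, :] - centers[:, None]) / bandwidths[:, None],
                0.0, None)
    return H, freqs, centers, bandwidths


def cqt_spectrogram(segment, params: CQTParams = CQTParams(),
                    grid: FrameGrid = FrameGrid()) -> FilterBankResponse:
    spec = stft_frames(segment, grid)
    H, freqs, centers, bandwidths = cqt_filterbank(params, spec.sample_rate, spec.n_fft)
    return FilterBankResponse(bank_kind="cqt_bins", H=H, energies=spec.power @ H.T,
                              freqs=freqs, centers=centers, bandwidths=bandwidths)


PITCH_CLASSES = ("C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B")

# Pitch-class analysis needs finer frequency resolution than the 20 ms
# classification frames: ~93 ms frames give ~10.8 Hz bins at 22.05 kHz.
CHROMA_GRID = FrameGrid(frame_length_ms=92.9, hop_ms=23.2)


def chroma_filterbank(sample_rate: int, n_fft: int,
                      fmin: float = 30.0, fmax: float = 5000.0) -> np.ndarray:
    """Map DFT bins to the 12 pitch classes (C=0 ... B=11) of their nearest
    equal-tempered pitch."""
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    H = np.zeros((12, len(freqs)))
    valid = (freqs >= fmin) & (freqs <= fmax)
    # A4 = 440 Hz is MIDI 69; class = midi mod 12 with C = 0
    midi = 69.0 + 12.0 * np.log2(np.where(valid, freqs, 440.0) / 440.0)
    cls = np.mod(np.round(midi), 12).astype(int)
    H[cls[valid], np.nonzero(valid)[0]] = 1.0
    return H


def chroma_energies(segment, grid: FrameGrid = None) -> FilterBankResponse:
    grid = grid or CHROMA_GRID
    spec = stft_frames(segment, grid)
    H = chroma_filterbank(spec.sample_rate, spec.n_fft)
    return FilterBankResponse(bank_kind="chroma", H=H, energies=spec.power @ H.T,
                              freqs=spec.freqs)


_CENS_THRESHOLDS = (0.4, 0.2, 0.1, 0.05)
_CENS_VALUES = (1.0, 0.75, 0.5, 0.25)


def cens(segment_or_resp, smooth_frames: int = 41, downsample: int = 10,
         grid: FrameGrid = None) -> np.ndarray:
    """Chroma energy normalized statistics.

    Per frame: L1-normalize the 12 chroma energies (silent frames become
    uniform 1/12), quantize into the standard 4-level staircase, smooth each
    class with a Hann window, downsample, then L2-normalize per frame
    (degenerate frames become the uniform unit vector).  Returns
    (n_out_frames, 12).
    """
    resp = (segment_or_resp if isinstance(segment_or_resp, FilterBankResponse)
            else chroma_energies(segment_or_resp, grid))
    E = resp.energies
    tot = E.sum(axis=1, keepdims=True)
    silent = tot[:, 0] <= LOG_FLOOR
    norm = np.where(tot > LOG_FLOOR, tot, 1.0)
    V = E / norm
    V[silent] = 1.0 / 12.0
    Q = np.zeros_like(V)
    for thr, val in zip(_CENS_THRESHOLDS, _CENS_VALUES):
        Q = np.where((Q == 0) & (V >= thr), val, Q)
    win = np.hanning(smooth_frames)
    win /= win.sum()
    pad = smooth_frames // 2
    Qp = np.pad(Q, ((pad, pad), (0, 0)), mode="edge")
    S = np.empty_like(Q)
    for c in range(12):
        S[:, c] = np.convolve(Qp[:, c], win, mode="valid")
    S = S[::downsample]
    l2 = np.linalg.norm(S, axis=1, keepdims=True)
    out = np.where(l2 > LOG_FLOOR, S / np.where(l2 > 0, l2, 1.0),
                   1.0 / np.sqrt(12.0))
    return out


# ------------------------------------------------------------- enhancement
def enhance(resp: FilterBankResponse,
            cfg: EnhancementConfig = EnhancementConfig()) -> FilterBankResponse:
    """Scale, per frame, filters whose energy strictly exceeds the frame's
    80th percentile (sorted linear interpolation) by beta; leave the rest
    bit-identical.  A single-filter bank has a degenerate percentile and
    passes through unchanged.  The mask depends only on pre-enhancement
    energies, so re-applying with beta=1 is the identity.
    """
    E = resp.energies
    if resp.n_filters == 1:
        return replace(resp, gains=np.ones_like(E))
    thresh = np.percentile(E, cfg.percentile, axis=1, keepdims=True)
    gains = np.where(E > thresh, cfg.beta, 1.0)
    return replace(resp, energies=np.where(E > thresh, cfg.beta * E, E),
                   gains=gains)


DEFAULT_BETA_GRID = tuple(round(1.1 + 0.1 * i, 1) for i in range(10))


def grid_search_beta(eval_fn, candidates=DEFAULT_BETA_GRID) -> float:
    """Return the candidate maximizing ``eval_fn``; ties go to the smallest
    beta (candidates are scanned in ascending order with strict >)."""
    best_beta, best_score = None, -np.inf
    for beta in sorted(candidates):
        score = eval_fn(beta)
        if score > best_score:
            best_beta, best_score = beta, score
    return best_beta


# ---------------------------------------------------------------- imaging
def _bilinear_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = img.shape
    if h == out_h and w == out_w:
        return img.copy()
    # align-corners coordinate mapping
    rs = np.linspace(0, h - 1, out_h) if h > 1 else np.zeros(out_h)
    cs = np.linspace(0, w - 1, out_w) if w > 1 else np.zeros(out_w)
    r0 = np.clip(np.floor(rs).astype(int), 0, max(h - 2, 0))
    c0 = np.clip(np.floor(cs).astype(int), 0, max(w - 2, 0))
    dr = (rs - r0)[:, None]
    dc = (cs - c0)[None, :]
    r1 = np.clip(r0 + 1, 0, h - 1)
    c1 = np.clip(c0 + 1, 0, w - 1)
    return ((1 - dr) * (1 - dc) * img[np.ix_(r0, c0)]
            + (1 - dr) * dc * img[np.ix_(r0, c1)]
            + dr * (1 - dc) * img[np.ix_(r1, c0)]
            + dr * dc * img[np.ix_(r1, c1)])


def render_image(feature_map: np.ndarray, feature_kind: str = "mel",
                 enhanced: bool = False, size: int = 224,
                 log_compress: bool = False) -> FeatureImage:
    """Render a 2-D feature map as a (size, size, 3) image in [0, 1].

    Optional log compression, per-image min-max normalization (a constant
    map renders as all zeros), bilinear resize, channel replication.  The
    min-max step makes the output invariant to positive affine rescaling of
    the input.
    """
    m = np.asarray(feature_map, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("feature map must be 2-D (filters x frames)")
    if log_compress:
        m = np.log(np.maximum(m, LOG_FLOOR))
    lo, hi = m.min(), m.max()
    m = (m - lo) / (hi - lo) if hi > lo else np.zeros_like(m)
    m = np.clip(_bilinear_resize(m, size, size), 0.0, 1.0)
    return FeatureImage(pixels=np.repeat(m[:, :, None], 3, axis=2),
                        feature_kind=feature_kind, enhanced=enhanced)


def feature_image(segment, kind: str, enhanced: bool = True,
                  cfg: EnhancementConfig = EnhancementConfig(),
                  size: int = 224, n_mel: int = 128,
                  cqt_params: CQTParams = CQTParams(),
                  grid: FrameGrid = FrameGrid()) -> FeatureImage:
    """Full pipeline: segment -> (enhanced) filter-bank -> rendered image.

    Enhancement always acts on linear filter-bank energies, before any log
    compression; for MFCCs it therefore precedes both the log and the cosine
    transform.
    """
    if kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {kind!r}; choose from {FEATURE_KINDS}")
    if kind in ("mel", "mfcc"):
        resp = mel_spectrogram(stft_frames(segment, grid), n_mel)
    elif kind == "cqt":
        resp = cqt_spectrogram(segment, cqt_params, grid)
    else:
        resp = chroma_energies(segment)   # pitch analysis needs its finer grid
    if enhanced:
        resp = enhance(resp, cfg)
    if kind == "mfcc":
        m = mfcc(resp.log_energies(), 13).T          # (13, frames)
    elif kind == "cens":
        m = cens(resp).T                             # (12, frames)
    else:
        m = resp.log_energies().T                    # (M, frames)
    return render_image(m, kind, enhanced, size=size)
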