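"""Acoustic statistics: low-frequency energy ratio, per-patient summaries,
and the stenotic vs non-stenotic group comparison.

The low-frequency energy ratio (LFER) of a segment is the fraction of its
Welch power-spectral-density energy below 650 Hz.  Per patient, the median
LFER across snore segments, the nightly event count normalized to 8 h, and
the median event duration are the three group-comparison variables, tested
with the two-sided Mann-Whitney U test (exact enumeration for small
tie-free samples, tie-corrected normal approximation with continuity
correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import welch

from .audioprep import AudioSegment
from .synth import LFER_CUTOFF_HZ, Cohort, PatientRecord

__all__ = [
    "SnoreEvent", "PatientAcousticSummary", "GroupTestResult",
    "lf_energy_ratio", "summarize_patient", "summarize_cohort",
    "mann_whitney", "group_comparison", "sensitivity_excluding",
    "t_test", "categorical_test",
]

GROUP_VARIABLES = ("lfer", "events_per_8h", "duration")


@dataclass(frozen=True)
class SnoreEvent:
    patient_id: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class PatientAcousticSummary:
    patient_id: str
    group: str
    lfer_median: float | None        # None when no usable snore segment
    events_per_8h: float | None
    duration_median_s: float | None
    excluded_flag: bool = False


@dataclass
class GroupTestResult:
    variable: str
    median_a: float
    iqr_a: tuple
    median_b: float
    iqr_b: tuple
    n_a: int
    n_b: int
    U: float
    Z: float
    p: float
    method: str                      # exact | normal

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def lf_energy_ratio(segment, sample_rate: int | None = None,
                    cutoff_hz: float = LFER_CUTOFF_HZ,
                    nperseg: int = 2048) -> float:
    """PSD energy below ``cutoff_hz`` over total (Welch, Hamming window,
    50% overlap, trapezoidal integration).  Scale-invariant; raises on an
    all-zero segment where the ratio is undefined."""
    if isinstance(segment, AudioSegment):
        x, sr = segment.samples, segment.sample_rate
    else:
        x = np.asarray(segment, dtype=float)
        if sample_rate is None:
            raise ValueError("sample_rate required for a bare array")
        sr = sample_rate
    if not np.any(x):
        raise ValueError("LFER undefined for an all-zero segment")
    nseg = min(nperseg, len(x))
    f, psd = welch(x, fs=sr, window="hamming", nperseg=nseg,
                   noverlap=nseg // 2)
    total = np.trapezoid(psd, f)
    low = np.trapezoid(psd[f < cutoff_hz], f[f < cutoff_hz])
    return float(low / total)


def summarize_patient(patient: PatientRecord,
                      recording_hours: float | None = None) -> PatientAcousticSummary:
    """Per-patient medians: LFER over snore-labeled segments, event count
    normalized to 8 h, median event duration.  Missing inputs yield None
    fields rather than silent zeros."""
    hours = recording_hours or patient.recording_hours
    lfers = []
    for seg in patient.segments:
        if seg.label == 1 and np.any(seg.samples):
            lfers.append(lf_energy_ratio(seg))
    lfer_median = float(np.median(lfers)) if lfers else None
    if patient.n_events:
        events_per_8h = patient.n_events * 8.0 / hours
        duration_median = float(np.median(patient.event_durations_s))
    else:
        events_per_8h = duration_median = None
    return PatientAcousticSummary(
        patient_id=patient.patient_id, group=patient.group,
        lfer_median=lfer_median, events_per_8h=events_per_8h,
        duration_median_s=duration_median, excluded_flag=patient.excluded_flag)


def summarize_cohort(cohort: Cohort, use_audio: bool = True):
    """Summaries for every patient.  With ``use_audio=False`` (no rendered
    segments) the patient's generator LFER parameter is reported instead of
    the audio-measured median."""
    out = []
    for p in cohort.patients:
        s = summarize_patient(p)
        if not use_audio or s.lfer_median is None and p.lfer is not None:
            if not p.segments:
                s.lfer_median = p.lfer
        out.append(s)
    return out


# ----------------------------------------------------------- Mann-Whitney
def _exact_u_cdf(n1: int, n2: int) -> np.ndarray:
    """Counts of rank assignments per U value (0..n1*n2) by dynamic
    programming over the Gaussian-binomial recurrence."""
    max_u = n1 * n2
    # F(i, j, u) = F(i-1, j, u-j) + F(i, j-1, u)
    F = np.zeros((n1 + 1, n2 + 1, max_u + 1))
    F[0, :, 0] = 1.0
    F[:, 0, 0] = 1.0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            F[i, j, j:] += F[i - 1, j, : max_u + 1 - j]
            F[i, j] += F[i, j - 1]
    return F[n1, n2]


def mann_whitney(group_a, group_b, variable: str = "") -> GroupTestResult:
    """Two-sided Mann-Whitney U test.

    Exact distribution when min(n) <= 8 and there are no ties; otherwise a
    normal approximation with mid-rank tie correction and continuity
    correction.  Z carries the direction of group A relative to B
    (negative when A ranks lower)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)            # mid-ranks
    r1 = ranks[:n1].sum()
    U = r1 - n1 * (n1 + 1) / 2.0              # U of group A
    mu = n1 * n2 / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    tie_term = (tie_counts**3 - tie_counts).sum()
    nt = n1 + n2
    var = n1 * n2 / 12.0 * ((nt + 1) - tie_term / (nt * (nt - 1)))
    if var > 0:
        cc = 0.5 if abs(U - mu) >= 0.5 else 0.0   # continuity correction
        z = (U - mu - np.sign(U - mu) * cc) / np.sqrt(var)
    else:
        z = 0.0

    if not has_ties and min(n1, n2) <= 8:
        counts = _exact_u_cdf(n1, n2)
        total = counts.sum()
        u_int = int(round(U))
        p_low = counts[: u_int + 1].sum() / total
        p_high = counts[u_int:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "exact"
    else:
        p = 2.0 * stats.norm.sf(abs(z))
        method = "normal"

    q = lambda v: (float(np.percentile(v, 25)), float(np.percentile(v, 75)))
    return GroupTestResult(
        variable=variable, median_a=float(np.median(a)), iqr_a=q(a),
        median_b=float(np.median(b)), iqr_b=q(b), n_a=n1, n_b=n2,
        U=float(U), Z=float(z), p=float(p), method=method)


def _collect(summaries, attr):
    a, b = [], []
    for s in summaries:
        v = getattr(s, attr)
        if v is None:
            continue
        (a if s.group == "stenotic" else b).append(v)
    return a, b


def group_comparison(summaries) -> dict:
    """Mann-Whitney tests for the three acoustic variables, stenotic (A)
    vs non-stenotic (B)."""
    out = {}
    for var, attr in (("lfer", "lfer_median"),
                      ("events_per_8h", "events_per_8h"),
                      ("duration", "duration_median_s")):
        a, b = _collect(summaries, attr)
        out[var] = mann_whitney(a, b, variable=var)
    return out


def sensitivity_excluding(summaries, excluded_ids=None) -> dict:
    """Re-run the group comparison after removing flagged patients
    (e.g. cerebral infarction/ischemia history)."""
    if excluded_ids is None:
        kept = [s for s in summaries if not s.excluded_flag]
    else:
        excluded_ids = set(excluded_ids)
        kept = [s for s in summaries if s.patient_id not in excluded_ids]
    groups = {s.group for s in kept}
    if {"stenotic", "non_stenotic"} - groups:
        raise ValueError("exclusion emptied one of the groups")
    return group_comparison(kept)


# --------------------------------------------- demographic-table utilities
def t_test(a, b):
    """Independent-samples t-test (equal variances), mean +/- SD style."""
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def categorical_test(table):
    """Chi-square when all expected counts allow it, else Fisher's exact
    (2x2 only).  Returns (statistic_or_None, p)."""
    table = np.asarray(table)
    if table.shape == (2, 2):
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            _, p = stats.fisher_exact(table)
            return None, float(p)
    chi2, p, _, _ = stats.chi2_contingency(table)
    return float(chi2), float(p)
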