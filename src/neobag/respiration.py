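"""Breath detection and apnoea rates from impedance pneumography (IP).

The chest-impedance trace is band-pass filtered to the respiratory band,
breaths are detected with an adaptive amplitude threshold (0.4 times the
standard deviation of the signal over the span of the preceding 15
detected breaths), and the resulting inter-breath intervals (IBIs) carry
the two respiratory outcomes:

* respiratory rate  = 60 / median(IBI)  [breaths/min]
* apnoea rate       = number of validated apnoeas per hour, where a
  candidate apnoea is an IBI strictly longer than 15 s.

Because low-amplitude noise or shallow breathing can masquerade as an
apnoea, every candidate is screened by a linear support-vector
classifier trained on labelled segments; candidates rejected as
noise/shallow breathing are discarded from *all* downstream rate
computations (they contribute neither to the apnoea count nor to the
median IBI).  Recordings with fewer than 100 IBIs fail quality control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.model_selection import train_test_split
from sklearn.metrics import balanced_accuracy_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

#: candidate apnoeas are IBIs strictly longer than this many seconds
APNOEA_THRESHOLD_S = 15.0
#: recordings with fewer IBIs than this fail quality control
MIN_IBIS_QC = 100

LABEL_APNOEA = "apnoea"
LABEL_REJECTED = "rejected_noise_or_shallow"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IPSignal:
    """Uniformly sampled impedance pneumography trace (arbitrary units)."""

    samples: np.ndarray
    fs: float = 62.5
    start_time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("IP samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.fs


@dataclass(frozen=True)
class BreathEvent:
    """A single detected breath (time of the breath peak)."""

    onset_time: float
    peak_amplitude: float


@dataclass(frozen=True)
class IBISeries:
    """Ordered inter-breath intervals of one recording."""

    intervals: np.ndarray          # seconds
    interval_start_times: np.ndarray
    total_duration_h: float

    def __post_init__(self):
        object.__setattr__(self, "intervals", np.asarray(self.intervals, dtype=float))
        object.__setattr__(
            self, "interval_start_times",
            np.asarray(self.interval_start_times, dtype=float))
        if np.any(self.intervals <= 0):
            raise ValueError("all inter-breath intervals must be positive")
        if len(self.intervals) != len(self.interval_start_times):
            raise ValueError("intervals and start times must align")

    @property
    def n_ibis(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class ApnoeaEvent:
    """A candidate apnoea (IBI > 15 s) with its screening label."""

    start_time: float
    duration: float
    label: str

    def __post_init__(self):
        if self.duration <= APNOEA_THRESHOLD_S:
            raise ValueError("candidate apnoeas must be longer than 15 s")
        if self.label not in (LABEL_APNOEA, LABEL_REJECTED):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class RespSummary:
    """Per-recording respiratory outcomes."""

    resp_rate: float       # breaths/min
    apnoea_rate: float     # apnoeas/h
    n_ibis: int
    qc_pass: bool


# ---------------------------------------------------------------------------
# filtering and breath detection
# ---------------------------------------------------------------------------

def filter_ip(sig: IPSignal, band: tuple[float, float] = (0.1, 2.0),
              order: int = 6) -> IPSignal:
    """Zero-phase band-pass to the respiratory band.

    The default 0.1-2 Hz pass band removes baseline drift and attenuates
    the cardiac component of the impedance trace (~2.3 Hz in neonates).
    """
    sos = sps.butter(order, band, btype="bandpass", fs=sig.fs, output="sos")
    min_padlen = 3 * (2 * sos.shape[0] + 1)
    if len(sig.samples) <= min_padlen:
        raise ValueError(
            f"signal too short for filtering ({len(sig.samples)} samples, "
            f"need > {min_padlen})")
    # generous reflection padding keeps the low-frequency edge transient
    # of the 0.1 Hz high-pass away from the first/last breaths
    padlen = min(int(15.0 * sig.fs), len(sig.samples) - 1)
    out = sps.sosfiltfilt(sos, sig.samples, padlen=padlen)
    return IPSignal(out, fs=sig.fs, start_time=sig.start_time)


def detect_breaths(sig: IPSignal, rel_threshold: float = 0.4,
                   window_breaths: int = 15, cold_start_s: float = 15.0,
                   min_separation_s: float = 0.3) -> list[BreathEvent]:
    """Detect breaths with an adaptive amplitude threshold.

    A positive peak of the filtered trace is accepted as a breath when
    its height exceeds ``rel_threshold`` times the standard deviation of
    the signal over the span of the preceding ``window_breaths`` accepted
    breaths.  Before 15 breaths have been accepted, the standard
    deviation of the first ``cold_start_s`` seconds of signal is used.
    The threshold is relative, so detection is invariant to amplitude
    rescaling of the whole recording.
    """
    x = sig.samples
    fs = sig.fs
    if len(x) == 0 or not np.any(x > 0):
        return []
    peaks, props = sps.find_peaks(x, height=0.0,
                                  distance=max(1, int(min_separation_s * fs)))
    if len(peaks) == 0:
        return []
    heights = props["peak_heights"]

    # cumulative moments for O(1) windowed standard deviations
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def window_sd(i0: int, i1: int) -> float:
        n = i1 - i0
        if n < 2:
            return 0.0
        m = (c1[i1] - c1[i0]) / n
        v = (c2[i1] - c2[i0]) / n - m * m
        return float(np.sqrt(max(v, 0.0)))

    cold_end = min(len(x), max(2, int(cold_start_s * fs)))
    accepted_idx: list[int] = []
    events: list[BreathEvent] = []
    for p, h in zip(peaks, heights):
        if len(accepted_idx) >= window_breaths:
            # span of the preceding 15 accepted breaths
            sd = window_sd(accepted_idx[-window_breaths], accepted_idx[-1] + 1)
        else:
            sd = window_sd(0, cold_end)
        if h > rel_threshold * sd:
            accepted_idx.append(p)
            # sub-sample peak time by parabolic interpolation
            if 0 < p < len(x) - 1:
                denom = x[p - 1] - 2 * x[p] + x[p + 1]
                delta = 0.5 * (x[p - 1] - x[p + 1]) / denom if denom != 0 else 0.0
                delta = float(np.clip(delta, -0.5, 0.5))
            else:
                delta = 0.0
            events.append(BreathEvent(onset_time=sig.start_time + (p + delta) / fs,
                                      peak_amplitude=float(h)))
    return events


def extract_ibis(breaths: list[BreathEvent]) -> IBISeries:
    """Successive differences of breath times."""
    if len(breaths) < 2:
        raise ValueError("need at least two breaths to form an interval")
    onsets = np.array([b.onset_time for b in breaths])
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("breath onsets must be strictly increasing")
    intervals = np.diff(onsets)
    return IBISeries(intervals=intervals, interval_start_times=onsets[:-1],
                     total_duration_h=float(onsets[-1] - onsets[0]) / 3600.0)


# ---------------------------------------------------------------------------
# apnoea screening classifier
# ---------------------------------------------------------------------------

FEATURE_NAMES = ("rms_ratio", "log_gap_variance", "resp_band_fraction")


def long_ibi_features(sig: IPSignal, start_time: float, end_time: float,
                      margin_s: float = 2.0, context_s: float = 15.0) -> np.ndarray:
    """Amplitude/spectral features of one candidate apnoea window.

    * RMS of the gap interior relative to the surrounding breathing,
    * log variance of the gap interior,
    * fraction of gap power in the respiratory band (0.1-2 Hz).

    Computed on the RAW (unfiltered) trace: during a true central
    apnoea the residual activity is cardiac artefact and noise outside
    the respiratory band, whereas shallow breathing retains a
    scaled-down breath oscillation inside it.
    """
    x = sig.samples - np.mean(sig.samples)
    fs = sig.fs
    i0 = int((start_time - sig.start_time + margin_s) * fs)
    i1 = int((end_time - sig.start_time - margin_s) * fs)
    i0 = max(i0, 0)
    i1 = min(i1, len(x))
    if i1 - i0 < int(2 * fs):       # degenerate window: fall back to full gap
        i0 = max(int((start_time - sig.start_time) * fs), 0)
        i1 = min(int((end_time - sig.start_time) * fs), len(x))
    gap = x[i0:i1]
    before = x[max(0, i0 - int(context_s * fs)):i0]
    after = x[i1:i1 + int(context_s * fs)]
    ctx = np.concatenate([before, after]) if (len(before) + len(after)) else gap
    rms_gap = float(np.sqrt(np.mean(gap ** 2)))
    rms_ctx = float(np.sqrt(np.mean(ctx ** 2)))
    ratio = rms_gap / (rms_ctx + 1e-12)
    var_gap = float(np.var(gap))
    f, p = sps.periodogram(gap, fs)
    total = float(np.sum(p)) + 1e-24
    band = float(np.sum(p[(f >= 0.1) & (f <= 2.0)]))
    return np.array([ratio, np.log10(var_gap + 1e-12), band / total])


@dataclass
class ApnoeaClassifier:
    """Linear-margin screen separating true apnoeas from noise/shallow breathing."""

    model: Pipeline = field(default=None)
    holdout_balanced_accuracy: float = float("nan")

    @property
    def is_trained(self) -> bool:
        return self.model is not None

    def predict(self, features: np.ndarray) -> np.ndarray:
        if not self.is_trained:
            raise RuntimeError("classifier has not been trained")
        return self.model.predict(np.atleast_2d(features))


def train_apnoea_classifier(features: np.ndarray, labels: np.ndarray,
                            seed: int = 0) -> ApnoeaClassifier:
    """Fit the linear SVM screen on labelled candidate windows.

    ``labels`` holds 1 for a true apnoea and 0 for a noise/shallow
    segment.  A quarter of the data is held out to report a balanced
    accuracy for the fitted screen.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    x_tr, x_te, y_tr, y_te = train_test_split(
        features, labels, test_size=0.25, random_state=seed, stratify=labels)
    model = Pipeline([("scale", StandardScaler()),
                      ("svm", SVC(kernel="linear", C=1.0, random_state=seed))])
    model.fit(x_tr, y_tr)
    acc = balanced_accuracy_score(y_te, model.predict(x_te))
    logger.info("apnoea screen held-out balanced accuracy: %.3f", acc)
    return ApnoeaClassifier(model=model, holdout_balanced_accuracy=float(acc))


def classify_long_ibis(ibis: IBISeries, sig: IPSignal,
                       clf: ApnoeaClassifier) -> list[ApnoeaEvent]:
    """Label every IBI strictly longer than 15 s as apnoea or rejected.

    ``sig`` should be the raw (unfiltered) trace so the screening
    features can see the out-of-band cardiac/noise content of the gap.
    """
    if not clf.is_trained:
        raise RuntimeError("classifier has not been trained")
    events = []
    for start, dur in zip(ibis.interval_start_times, ibis.intervals):
        if dur <= APNOEA_THRESHOLD_S:
            continue
        feats = long_ibi_features(sig, start, start + dur)
        pred = int(clf.predict(feats)[0])
        events.append(ApnoeaEvent(
            start_time=float(start), duration=float(dur),
            label=LABEL_APNOEA if pred == 1 else LABEL_REJECTED))
    return events


# ---------------------------------------------------------------------------
# rates and quality control
# ---------------------------------------------------------------------------

def drop_rejected_ibis(ibis: IBISeries, events: list[ApnoeaEvent]) -> IBISeries:
    """Remove long IBIs screened out as noise/shallow breathing.

    Rejected intervals leave the IBI pool entirely: they are counted
    neither as apnoeas nor towards the median IBI.
    """
    rejected = {e.start_time for e in events if e.label == LABEL_REJECTED}
    keep = np.array([t not in rejected for t in ibis.interval_start_times])
    return IBISeries(intervals=ibis.intervals[keep],
                     interval_start_times=ibis.interval_start_times[keep],
                     total_duration_h=ibis.total_duration_h)


def respiratory_rate(ibis: IBISeries) -> float:
    """Median breathing rate: 60 / median inter-breath interval."""
    if ibis.n_ibis == 0:
        raise ValueError("no inter-breath intervals available")
    return 60.0 / float(np.median(ibis.intervals))


def apnoea_rate(events: list[ApnoeaEvent], total_duration_h: float) -> float:
    """Validated apnoeas per hour of recording."""
    if total_duration_h <= 0:
        raise ValueError("recording duration must be positive")
    n = sum(1 for e in events if e.label == LABEL_APNOEA)
    return n / total_duration_h


def qc_recording(ibis: IBISeries, min_ibis: int = MIN_IBIS_QC) -> bool:
    """Quality control: at least 100 IBIs must be available."""
    return ibis.n_ibis >= min_ibis


def summarise_recording(ibis: IBISeries,
                        events: list[ApnoeaEvent]) -> RespSummary:
    """Respiratory and apnoea rates after discarding rejected long IBIs."""
    kept = drop_rejected_ibis(ibis, events)
    ok = qc_recording(kept)
    rate = respiratory_rate(kept) if kept.n_ibis else float("nan")
    return RespSummary(resp_rate=rate,
                       apnoea_rate=apnoea_rate(events, ibis.total_duration_h)
                       if ibis.total_duration_h > 0 else float("nan"),
                       n_ibis=kept.n_ibis, qc_pass=ok)
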