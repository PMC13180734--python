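"""Resting-state brain age from background EEG activity.

The published resting-state estimator is a deep network; here a
transparent feature-based surrogate preserves its input/output contract
so the downstream brain-age-gap pipeline is faithful:

* input: the first 20 min of stimulus-free EEG, bipolar C3-C4,
  downsampled to 64 Hz;
* the segment is cut into 30-second epochs (40 of them);
* a 10-member ensemble predicts an age per epoch; the median over
  members is taken per epoch, then the median over epochs gives a single
  resting brain age.  The double median is robust to artefactual epochs.

Each ensemble member is a ridge regression on per-epoch features that
track neonatal EEG maturation: relative band powers (discontinuous
low-frequency activity gives way to faster rhythms with age), the 95%
spectral edge frequency, amplitude percentiles and the burst fraction
(tracé discontinu shortens its inter-burst intervals as the brain
matures).  All claims about this estimator are surrogate-level: it
reproduces the aggregation scheme, not the published network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from sklearn.linear_model import Ridge
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .evoked import EEGRecording

logger = logging.getLogger(__name__)

RESTING_FS = 64.0
RESTING_DURATION_S = 1200.0
EPOCH_S = 30.0
N_ENSEMBLE = 10

BANDS = ((0.5, 3.0), (3.0, 8.0), (8.0, 15.0), (15.0, 30.0))
FEATURE_NAMES = tuple(f"relpow_{lo:g}_{hi:g}" for lo, hi in BANDS) + (
    "sef95", "amp_p5", "amp_p95", "burst_fraction")


@dataclass(frozen=True)
class RestingSegment:
    """Bipolar C3-C4 trace, 64 Hz, first 20 minutes of the recording."""

    samples: np.ndarray
    fs: float = RESTING_FS

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class RestingAgeModel:
    """10-member ensemble mapping per-epoch features to age (weeks)."""

    members: list = None
    cv_mae_weeks: float = float("nan")

    @property
    def is_trained(self) -> bool:
        return bool(self.members)


class InsufficientDataError(ValueError):
    """Raised when less than 20 min of stimulus-free EEG is available."""


def prepare_resting_segment(rec: EEGRecording,
                            duration_s: float = RESTING_DURATION_S,
                            target_fs: float = RESTING_FS) -> RestingSegment:
    """Bipolar C3-C4, anti-alias filtered and downsampled to 64 Hz.

    Raises :class:`InsufficientDataError` when the recording is shorter
    than 20 min -- the caller then marks the occasion's resting age
    unavailable and falls back to the sensory estimate alone.
    """
    for ch in ("C3", "C4"):
        if ch not in rec.channels:
            raise ValueError(f"missing channel {ch}")
    if rec.duration_s < duration_s:
        raise InsufficientDataError(
            f"need {duration_s:.0f} s of resting EEG, have {rec.duration_s:.0f} s")
    bipolar = rec.channels["C3"] - rec.channels["C4"]
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    x = sps.resample_poly(bipolar, frac.numerator, frac.denominator)
    n = int(round(duration_s * target_fs))
    return RestingSegment(samples=x[:n], fs=target_fs)


def _epoch_features(x: np.ndarray, fs: float) -> np.ndarray:
    f, p = sps.periodogram(x, fs)
    lo_edge, hi_edge = BANDS[0][0], BANDS[-1][1]
    mask = (f >= lo_edge) & (f < hi_edge)
    total = float(np.sum(p[mask])) + 1e-24
    rel = [float(np.sum(p[(f >= lo) & (f < hi)])) / total for lo, hi in BANDS]
    # 95% spectral edge over the analysed range
    cum = np.cumsum(p[mask])
    sef = float(f[mask][np.searchsorted(cum, 0.95 * cum[-1])])
    p5, p95 = np.percentile(x, [5, 95])
    # burst fraction: time the smoothed rectified amplitude spends above the
    # midpoint of its low/high envelope levels (bimodal burst vs inter-burst)
    win = max(1, int(0.25 * fs))
    env = np.convolve(np.abs(x), np.ones(win) / win, mode="same")
    e10, e90 = np.percentile(env, [10, 90])
    burst = float(np.mean(env > 0.5 * (e10 + e90)))
    return np.array(rel + [sef, float(p5), float(p95), burst])


def epoch_30s(seg: RestingSegment, epoch_s: float = EPOCH_S) -> np.ndarray:
    """Per-epoch feature matrix (n_epochs x 8) over 30-second epochs."""
    n = int(epoch_s * seg.fs)
    n_epochs = len(seg.samples) // n
    return np.array([_epoch_features(seg.samples[i * n:(i + 1) * n], seg.fs)
                     for i in range(n_epochs)])


def train_resting_model(feature_sets: list[np.ndarray], ages: np.ndarray,
                        n_members: int = N_ENSEMBLE, alpha: float = 1.0,
                        seed: int = 0) -> RestingAgeModel:
    """Fit the 10-member ridge ensemble.

    Each member is trained on a bootstrap resample of *recordings* (all
    epochs of a resampled recording share its age label), which gives
    the ensemble its spread.  Deterministic given ``seed``.
    """
    ages = np.asarray(ages, dtype=float)
    if len(feature_sets) < 20:
        raise ValueError("need at least 20 training recordings")
    if np.ptp(ages) <= 0:
        raise ValueError("training ages are degenerate (constant)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7e57]))
    members = []
    n_rec = len(feature_sets)
    for _ in range(n_members):
        idx = rng.integers(0, n_rec, size=n_rec)
        x = np.vstack([feature_sets[i] for i in idx])
        y = np.concatenate([np.full(len(feature_sets[i]), ages[i]) for i in idx])
        member = Pipeline([("scale", StandardScaler()),
                           ("ridge", Ridge(alpha=alpha))])
        member.fit(x, y)
        members.append(member)
    return RestingAgeModel(members=members)


def predict_resting_age(model: RestingAgeModel, features: np.ndarray) -> float:
    """Median over ensemble members per epoch, then median over epochs."""
    if not model.is_trained:
        raise RuntimeError("resting model has not been trained")
    features = np.atleast_2d(np.asarray(features, dtype=float))
    per_member = np.array([m.predict(features) for m in model.members])
    per_epoch = np.median(per_member, axis=0)
    return float(np.median(per_epoch))
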