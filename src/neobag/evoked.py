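"""Sensory-evoked brain age from visual and tactile evoked potentials.

The maturation of sensory pathways in preterm infants is read out from
the morphology of stimulus-evoked EEG responses.  The evoked response of
a test occasion is summarised by the slopes of an ordinary
least-squares fit of the epoch-average response onto a fixed basis of
neurodynamic response functions (NRFs): four waveforms for the visual
response at Oz and two for the tactile response at Cz.  The six slopes
feed a linear-kernel support-vector regression that predicts the
infant's brain age in weeks.

Processing chain per occasion:

1. zero-phase high-pass (0.05 Hz) then low-pass (33.75 Hz) filtering,
2. epoching from -0.5 to 1.0 s around stimulus onsets with baseline
   subtraction over [-0.5, 0) s,
3. rejection of epochs whose pre-stimulus amplitude exceeds +/-150 uV
   (occasions with fewer than five surviving sensory epochs are flagged
   so downstream code falls back to the resting-state estimate),
4. single-pass Woody alignment of each epoch to the NRF-subspace
   projection of the current average (maximum jitter 50 ms),
5. joint OLS of the epoch average onto the modality's NRFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.model_selection import KFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

logger = logging.getLogger(__name__)

EPOCH_WINDOW_S = (-0.5, 1.0)
ARTIFACT_LIMIT_UV = 150.0
MIN_SENSORY_EPOCHS = 5
MAX_WOODY_JITTER_MS = 50.0

VISUAL, TACTILE = "visual", "tactile"
#: EEG channel carrying each modality's evoked response
MODALITY_CHANNELS = {VISUAL: "Oz", TACTILE: "Cz"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EEGRecording:
    """Multi-channel EEG with stimulus annotations.

    ``channels`` maps channel names to equally long traces in microvolts;
    ``annotations`` is a table with columns ``time_s`` and ``modality``.
    """

    channels: dict[str, np.ndarray]
    fs: float
    annotations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["time_s", "modality"]))

    def __post_init__(self):
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.annotations):
            t = self.annotations["time_s"].to_numpy(dtype=float)
            if t.min() < 0 or t.max() > self.duration_s:
                raise ValueError("annotation times must lie within the recording")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def epoch_grid(fs: float, window: tuple[float, float] = EPOCH_WINDOW_S) -> np.ndarray:
    """Time axis of the epoch window (half-open at the right edge)."""
    n = int(round((window[1] - window[0]) * fs))
    return window[0] + np.arange(n) / fs


@dataclass(frozen=True)
class EpochSet:
    """Stimulus-locked epochs of one modality on the fixed -0.5..1.0 s grid."""

    epochs: np.ndarray        # (n_epochs, n_samples), microvolts
    times: np.ndarray         # (n_samples,)
    fs: float
    modality: str
    kept_mask: np.ndarray = None

    def __post_init__(self):
        object.__setattr__(self, "epochs", np.asarray(self.epochs, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.kept_mask is None:
            object.__setattr__(self, "kept_mask",
                               np.ones(len(self.epochs), dtype=bool))
        else:
            object.__setattr__(self, "kept_mask",
                               np.asarray(self.kept_mask, dtype=bool))
        if self.epochs.ndim != 2 or self.epochs.shape[1] != len(self.times):
            raise ValueError("epochs must be (n_epochs, n_samples)")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    @property
    def pre_stimulus(self) -> np.ndarray:
        return self.epochs[:, self.times < 0]

    def average(self) -> np.ndarray:
        """Mean over kept epochs."""
        if self.n_kept == 0:
            raise ValueError("no kept epochs to average")
        return self.epochs[self.kept_mask].mean(axis=0)


@dataclass(frozen=True)
class NRFBasis:
    """Orthonormal neurodynamic response functions on the epoch grid.

    The first ``n_visual`` rows of ``waveforms`` model the visual response
    at Oz, the remaining ``n_tactile`` rows the tactile response at Cz.
    """

    times: np.ndarray
    waveforms: np.ndarray          # (n_visual + n_tactile, n_samples)
    n_visual: int
    n_tactile: int
    fs: float

    @property
    def n_components(self) -> int:
        return self.n_visual + self.n_tactile

    def for_modality(self, modality: str) -> np.ndarray:
        if modality == VISUAL:
            return self.waveforms[:self.n_visual]
        if modality == TACTILE:
            return self.waveforms[self.n_visual:]
        raise ValueError(f"unknown modality {modality!r}")

    def slope_slice(self, modality: str) -> slice:
        return (slice(0, self.n_visual) if modality == VISUAL
                else slice(self.n_visual, self.n_components))


@dataclass
class SensoryAgeModel:
    """Linear-kernel SVR mapping six NRF slopes to brain age (weeks)."""

    model: Pipeline = None
    cv_mae_weeks: float = float("nan")

    @property
    def is_trained(self) -> bool:
        return self.model is not None


# ---------------------------------------------------------------------------
# preprocessing / epoching
# ---------------------------------------------------------------------------

def preprocess_eeg(rec: EEGRecording, hp_hz: float = 0.05,
                   lp_hz: float = 33.75, order: int = 6) -> EEGRecording:
    """Consecutive zero-phase high-pass then low-pass filtering."""
    if rec.fs < 100:
        raise ValueError("expected a raw EEG sampling rate of at least 100 Hz")
    sos_hp = sps.butter(order, hp_hz, btype="highpass", fs=rec.fs, output="sos")
    sos_lp = sps.butter(order, lp_hz, btype="lowpass", fs=rec.fs, output="sos")
    padlen = 3 * (2 * sos_hp.shape[0] + 1)
    if rec.n_samples <= padlen:
        raise ValueError("recording too short to filter")
    out = {}
    for name, x in rec.channels.items():
        y = sps.sosfiltfilt(sos_hp, x)
        out[name] = sps.sosfiltfilt(sos_lp, y)
    return EEGRecording(channels=out, fs=rec.fs, annotations=rec.annotations)


def epoch_and_baseline(rec: EEGRecording,
                       window: tuple[float, float] = EPOCH_WINDOW_S
                       ) -> dict[str, EpochSet]:
    """Cut stimulus-locked epochs and subtract the pre-stimulus mean.

    Annotations too close to the recording edge for a full window are
    skipped (logged).  Returns one EpochSet per modality present.
    """
    if len(rec.annotations) == 0:
        raise ValueError("recording has no stimulus annotations")
    t = epoch_grid(rec.fs, window)
    n = len(t)
    out: dict[str, EpochSet] = {}
    for modality, channel in MODALITY_CHANNELS.items():
        rows = rec.annotations[rec.annotations["modality"] == modality]
        if len(rows) == 0 or channel not in rec.channels:
            continue
        x = rec.channels[channel]
        epochs = []
        for t0 in rows["time_s"].to_numpy(dtype=float):
            i0 = int(round((t0 + window[0]) * rec.fs))
            if i0 < 0 or i0 + n > len(x):
                logger.info("skipping %s annotation at %.3f s: too close to edge",
                            modality, t0)
                continue
            ep = x[i0:i0 + n].astype(float).copy()
            ep -= ep[t < 0].mean()
            epochs.append(ep)
        if epochs:
            out[modality] = EpochSet(np.array(epochs), t, rec.fs, modality)
    return out


def reject_artifacts(eps: EpochSet,
                     limit_uv: float = ARTIFACT_LIMIT_UV) -> EpochSet:
    """Flag epochs whose pre-stimulus amplitude strictly exceeds the limit.

    The rejection window is the available pre-stimulus span of the epoch
    (-0.5 to 0 s).  An amplitude of exactly ``limit_uv`` is kept.
    """
    pre = eps.pre_stimulus
    peak = np.abs(pre).max(axis=1) if pre.size else np.zeros(eps.n_epochs)
    keep = eps.kept_mask & (peak <= limit_uv)
    return replace(eps, kept_mask=keep)


def sensory_available(epoch_sets: list[EpochSet],
                      min_epochs: int = MIN_SENSORY_EPOCHS) -> bool:
    """At least five sensory epochs must survive artifact rejection."""
    return sum(e.n_kept for e in epoch_sets) >= min_epochs


# ---------------------------------------------------------------------------
# Woody alignment and slope fitting
# ---------------------------------------------------------------------------

def nrf_template(eps: EpochSet, basis: NRFBasis) -> np.ndarray:
    """Projection of the current epoch average onto the NRF subspace."""
    w = basis.for_modality(eps.modality)
    avg = eps.average()
    return w.T @ (w @ avg)


def _shift(x: np.ndarray, lag: int) -> np.ndarray:
    """Shift right by ``lag`` samples, zero-filling the exposed edge."""
    out = np.zeros_like(x)
    if lag > 0:
        out[lag:] = x[:-lag]
    elif lag < 0:
        out[:lag] = x[-lag:]
    else:
        out[:] = x
    return out


def woody_align(eps: EpochSet, template: np.ndarray,
                max_jitter_ms: float = MAX_WOODY_JITTER_MS,
                n_iter: int = 1) -> tuple[EpochSet, np.ndarray]:
    """Woody filtering: realign each epoch to the template.

    For every epoch the integer-sample lag (bounded by ``max_jitter_ms``)
    maximising the cross-correlation with the template is found, and the
    epoch is shifted back by that lag.  Returns the aligned epochs and
    the per-epoch estimated latencies in seconds (the correction applied
    is the negative of the estimate).  Epoch count is never changed.
    """
    max_lag = int(round(max_jitter_ms / 1000.0 * eps.fs))
    lags_s = np.zeros(eps.n_epochs)
    epochs = eps.epochs.copy()
    for _ in range(max(1, n_iter)):
        for i in range(eps.n_epochs):
            scores = [np.dot(_shift(epochs[i], -lag), template)
                      for lag in range(-max_lag, max_lag + 1)]
            best = int(np.argmax(scores)) - max_lag
            epochs[i] = _shift(epochs[i], -best)
            lags_s[i] += best / eps.fs
    return replace(eps, epochs=epochs), lags_s


def fit_nrf_slopes(visual_eps: EpochSet | None, tactile_eps: EpochSet | None,
                   basis: NRFBasis, per_epoch: bool = False) -> np.ndarray:
    """OLS slopes of the evoked responses onto the six NRFs.

    The visual epoch average (Oz) is regressed jointly onto the four
    visual NRFs and the tactile average (Cz) onto the two tactile NRFs;
    the six coefficients are returned in basis order.  With
    ``per_epoch=True`` slopes are fitted per epoch and averaged instead
    (alternative convention, off by default).
    """
    slopes = np.full(basis.n_components, np.nan)
    for eps in (visual_eps, tactile_eps):
        if eps is None:
            continue
        w = basis.for_modality(eps.modality)      # (k, n)
        design = w.T                              # (n, k)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient NRF design")
        if per_epoch:
            coefs = np.array([np.linalg.lstsq(design, ep, rcond=None)[0]
                              for ep in eps.epochs[eps.kept_mask]])
            beta = coefs.mean(axis=0)
        else:
            beta, *_ = np.linalg.lstsq(design, eps.average(), rcond=None)
        slopes[basis.slope_slice(eps.modality)] = beta
    return slopes


# ---------------------------------------------------------------------------
# sensory brain-age model
# ---------------------------------------------------------------------------

def train_sensory_model(slopes: np.ndarray, ages: np.ndarray,
                        c: float = 10.0, epsilon: float = 0.1,
                        cv_folds: int = 5, seed: int = 0) -> SensoryAgeModel:
    """Fit the linear-kernel SVR from NRF slopes to age.

    Requires at least 20 occasions spanning at least 3 weeks of age.
    The reported MAE is cross-validated (K-fold).
    """
    slopes = np.asarray(slopes, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(slopes) < 20:
        raise ValueError("need at least 20 training occasions")
    if np.ptp(ages) < 3.0:
        raise ValueError("training ages must span at least 3 weeks")
    model = Pipeline([("scale", StandardScaler()),
                      ("svr", SVR(kernel="linear", C=c, epsilon=epsilon))])
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(model, slopes, ages, cv=cv)
    mae = float(np.mean(np.abs(pred - ages)))
    model.fit(slopes, ages)
    logger.info("sensory brain-age model CV MAE: %.3f weeks", mae)
    return SensoryAgeModel(model=model, cv_mae_weeks=mae)


def predict_sensory_age(model: SensoryAgeModel, slopes: np.ndarray) -> np.ndarray:
    """Predict sensory brain age (weeks) from six NRF slopes."""
    if not model.is_trained:
        raise RuntimeError("sensory model has not been trained")
    return model.model.predict(np.atleast_2d(np.asarray(slopes, dtype=float)))
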