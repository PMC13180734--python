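"""Synthetic cohorts of neonatal respiration, SpO2 and EEG recordings.

Every downstream stage of the pipeline is exercised against data from
this module, which emulates the statistical structure of a
moderate-to-late preterm cohort (default scale: 74 infants studied on
roughly 138 test occasions between 31 and 36 weeks postmenstrual age)
with known ground truth:

* a latent brain-age gap per occasion, Normal(0, 0.91 wk) by default,
  with an infant-level shared component so repeated occasions of one
  infant are correlated;
* an expected apnoea rate that decreases with the gap
  (-0.22 apnoeas/h per week by default) on top of an infant random
  effect, and a respiratory rate that decreases with PMA
  (-1.87 breaths/min per week);
* impedance-pneumography traces built from raised-cosine breath cycles
  with multiplicative amplitude drift, a small cardiac component and
  white noise, into which breath-free apnoeic pauses (all > 15 s) and
  optional shallow-breathing segments are inserted;
* SpO2 traces with desaturation dips, a configurable fraction of which
  co-occur with apnoeas;
* evoked potentials built from a fixed orthonormal basis of
  neurodynamic response functions with age-dependent magnitudes; and
* resting EEG alternating bursts and inter-burst intervals whose
  durations and spectral tilt mature with age (a documented generator
  law, a synthetic convention rather than physiology).

All generators are pure functions of their parameters and seed: a
single global seed fans out to per-recording substreams, so adding one
recording never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from . import respiration as resp
from .desaturation import SpO2Signal
from .evoked import EEGRecording, EpochSet, NRFBasis, epoch_grid
from .gap import bias_correct

# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def child_rng(seed: int, *keys: int) -> np.random.Generator:
    """Independent substream derived from a global seed and integer keys."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


# stream tags (arbitrary, fixed)
_T_COHORT, _T_IP, _T_SPO2, _T_EVOKED, _T_REST, _T_TRAIN = 11, 22, 33, 44, 55, 66


# ---------------------------------------------------------------------------
# cohort-level generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Study conditions of the synthetic cohort.

    Defaults reproduce the cohort structure the analysis assumes: ~2
    test occasions per infant, gaps Normal(0, 0.91 wk), an apnoea-rate
    slope of -0.22 apnoeas/h per week of gap and a respiratory-rate
    slope of -1.87 breaths/min per week of PMA.
    """

    n_infants: int = 74
    occasions_per_infant: tuple[int, int] = (1, 3)
    occasion_probs: tuple[float, ...] = (0.38, 0.38, 0.24)
    pma_range: tuple[float, float] = (31.0, 36.9)
    gap_mean: float = 0.0
    gap_sd: float = 0.91
    gap_shared_fraction: float = 0.5      # infant-level share of gap variance
    apnoea_gap_slope: float = -0.22       # apnoeas/h per week of gap
    apnoea_baseline: float = 1.0          # apnoeas/h at gap 0, no infection
    infant_random_sd: float = 0.25        # apnoeas/h
    infection_probs: tuple[float, float, float] = (0.442, 0.123, 0.435)
    infection_effects: tuple[float, float, float] = (0.0, 0.15, 0.3)
    resp_pma_slope: float = -1.87         # breaths/min per week of PMA
    resp_rate_ref: float = 55.0           # breaths/min at 34 weeks PMA
    resp_infant_sd: float = 2.0
    resp_obs_sd: float = 1.5
    ip_length_mean_h: float = 8.5
    ip_length_sd_h: float = 8.7
    desat_coupling: float = 0.5           # desats per apnoea (expected)
    desat_independent_rate: float = 0.1   # desats/h unrelated to apnoea
    caffeine_stop_ref: float = 34.0       # weeks PMA
    caffeine_stop_gap_slope: float = -0.26
    caffeine_stop_sd: float = 1.2
    longitudinal_fraction: float = 0.31
    seed: int = 0

    def __post_init__(self):
        if self.n_infants < 1:
            raise ValueError("need at least one infant")
        if self.gap_sd <= 0:
            raise ValueError("gap_sd must be positive")
        if abs(sum(self.infection_probs) - 1.0) > 1e-9:
            raise ValueError("infection_probs must sum to 1")
        if not 0.0 <= self.gap_shared_fraction <= 1.0:
            raise ValueError("gap_shared_fraction must lie in [0, 1]")
        for name in ("gap_mean", "gap_sd", "apnoea_gap_slope", "resp_pma_slope",
                     "apnoea_baseline", "infant_random_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth aligned row-by-row with the occasion table."""

    true_gap: np.ndarray
    infant_gap: np.ndarray
    true_brain_age: np.ndarray
    true_apnoea_rate: np.ndarray
    true_resp_rate: np.ndarray
    true_desat_rate: np.ndarray
    true_evoked_slopes: np.ndarray        # (n_occasions, 6)
    post_caffeine: pd.DataFrame           # per-infant sub-study truth


def default_slope_age_map(age_weeks) -> np.ndarray:
    """Linear map from brain age to the six NRF magnitudes (a.u.).

    Synthetic convention: each component grows (or shrinks) linearly
    with age around 33.5 weeks, which makes age identifiable from the
    slope vector.
    """
    age = np.asarray(age_weeks, dtype=float)
    base = np.array([5.0, -2.5, 1.8, -1.2, 4.0, -2.0])
    rate = np.array([0.9, -0.45, 0.6, 0.35, 0.8, -0.5])
    return base + np.multiply.outer(age - 33.5, rate)


def simulate_cohort(params: CohortParams) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw a repeated-measures cohort with table-level observed rates.

    Returns the tidy occasion table (one row per test occasion) and the
    aligned ground truth.  Observed apnoea and desaturation rates are
    Poisson draws over the recording length; observed respiratory rate
    carries Gaussian measurement noise.  The ``corrected_gap`` column is
    the age-bias-corrected true brain age, so table-level statistical
    analyses can run without simulating raw signals.
    """
    p = params
    rng = child_rng(p.seed, _T_COHORT)
    lo, hi = p.pma_range

    rows, truth_rows, slopes_rows = [], [], []
    post_rows = []
    occ_id = 0
    for i in range(p.n_infants):
        n_occ = int(rng.choice(np.arange(p.occasions_per_infant[0],
                                         p.occasions_per_infant[1] + 1),
                               p=np.asarray(p.occasion_probs)))
        ga = float(np.clip(rng.normal(31.0, 2.8), 23.6, hi - 1.0))
        infant_effect = rng.normal(0.0, p.infant_random_sd)
        resp_effect = rng.normal(0.0, p.resp_infant_sd)
        shared_sd = p.gap_sd * np.sqrt(p.gap_shared_fraction)
        occ_sd = p.gap_sd * np.sqrt(1.0 - p.gap_shared_fraction)
        infant_gap = p.gap_mean + (rng.normal(0.0, shared_sd) if shared_sd > 0
                                   else 0.0)
        stop_pma = float(np.clip(
            p.caffeine_stop_ref
            + p.caffeine_stop_gap_slope * (infant_gap - p.gap_mean)
            + rng.normal(0.0, p.caffeine_stop_sd), 31.5, 38.0))
        longitudinal = bool(rng.random() < p.longitudinal_fraction)

        pmas = np.sort(rng.uniform(max(lo, ga), hi, size=n_occ))
        for pma in pmas:
            gap = infant_gap + (rng.normal(0.0, occ_sd) if occ_sd > 0 else 0.0)
            infection = rng.choice(len(p.infection_probs),
                                   p=np.asarray(p.infection_probs))
            length_h = _gamma_length(rng, p.ip_length_mean_h, p.ip_length_sd_h)
            true_apnoea = max(0.0, p.apnoea_baseline
                              + p.apnoea_gap_slope * (gap - p.gap_mean)
                              + infant_effect
                              + p.infection_effects[infection])
            obs_apnoea = rng.poisson(true_apnoea * length_h) / length_h
            true_resp = float(np.clip(
                p.resp_rate_ref + p.resp_pma_slope * (pma - 34.0) + resp_effect,
                15.0, 115.0))
            obs_resp = true_resp + rng.normal(0.0, p.resp_obs_sd)
            true_desat = p.desat_coupling * true_apnoea + p.desat_independent_rate
            obs_desat = rng.poisson(true_desat * length_h) / length_h
            brain_age = pma + gap
            rows.append(dict(
                infant_id=f"inf{i:04d}", occasion_id=f"occ{occ_id:04d}",
                ga_weeks=ga, pma_weeks=float(pma),
                infection=("no", "suspected", "treated")[infection],
                ip_length_h=length_h,
                caffeine_on=int(pma < stop_pma),
                caffeine_stop_pma_weeks=stop_pma,
                longitudinal_vitals=int(longitudinal),
                apnoea_rate=float(obs_apnoea), resp_rate=float(obs_resp),
                desat_rate=float(obs_desat)))
            truth_rows.append((gap, infant_gap, brain_age, true_apnoea,
                               true_resp, true_desat))
            slopes_rows.append(default_slope_age_map(brain_age))
            occ_id += 1

        if longitudinal:
            # sub-study truth: rates in the week after caffeine stop depend
            # on the gap measured shortly before discontinuation
            g = infant_gap + (rng.normal(0.0, occ_sd) if occ_sd > 0 else 0.0)
            post_apnoea = max(0.0, 0.7 - 0.35 * g + rng.normal(0.0, 0.3))
            post_desat = max(0.0, 0.35 - 0.12 * g + rng.normal(0.0, 0.25))
            post_rows.append(dict(
                infant_id=f"inf{i:04d}", corrected_gap=float(g),
                caffeine_stop_pma_weeks=stop_pma,
                apnoea_rate=(post_apnoea if rng.random() < 11 / 17 else np.nan),
                desat_rate=post_desat,
                infection=("no", "suspected", "treated")[
                    rng.choice(3, p=np.asarray(p.infection_probs))]))

    table = pd.DataFrame(rows)
    tr = np.array(truth_rows)
    corrected, _ = bias_correct(tr[:, 2], table["pma_weeks"].to_numpy()) \
        if len(table) >= 3 and np.ptp(table["pma_weeks"]) > 0 \
        else (tr[:, 2] - table["pma_weeks"].to_numpy(), None)
    table["corrected_gap"] = corrected
    truth = CohortTruth(
        true_gap=tr[:, 0], infant_gap=tr[:, 1], true_brain_age=tr[:, 2],
        true_apnoea_rate=tr[:, 3], true_resp_rate=tr[:, 4],
        true_desat_rate=tr[:, 5], true_evoked_slopes=np.array(slopes_rows),
        post_caffeine=pd.DataFrame(post_rows))
    return table, truth


def _gamma_length(rng: np.random.Generator, mean: float, sd: float) -> float:
    shape = (mean / sd) ** 2
    return float(np.clip(rng.gamma(shape, mean / shape), 0.4, 24.0))


# ---------------------------------------------------------------------------
# impedance pneumography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Nuisance components of the synthetic IP trace."""

    cardiac_rel_amp: float = 0.1     # fraction of breath amplitude
    cardiac_freq_hz: float = 2.3
    white_sd: float = 0.05           # fraction of breath amplitude
    drift_sigma: float = 0.03        # per-cycle log-amplitude random walk
    cycle_jitter: float = 0.04       # fractional SD of cycle duration

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(cardiac_rel_amp=0.0, white_sd=0.0, drift_sigma=0.0,
                   cycle_jitter=0.0)


@dataclass(frozen=True)
class IPGroundTruth:
    """Inserted-event truth of one synthetic IP recording."""

    breath_times: np.ndarray
    apnoeas: tuple[tuple[float, float], ...]     # (onset_s, duration_s)
    shallow: tuple[tuple[float, float, float], ...]  # (onset, duration, scale)

    @property
    def ibis(self) -> np.ndarray:
        return np.diff(self.breath_times)


def draw_apnoea_events(duration_s: float, rate_per_h: float,
                       rng: np.random.Generator,
                       mean_excess_s: float = 5.0,
                       edge_margin_s: float = 30.0,
                       min_gap_s: float = 30.0
                       ) -> list[tuple[float, float]]:
    """Apnoea onsets from a thinned Poisson process.

    Durations are 15 s plus an exponential tail (mean 5 s by default),
    so every inserted event satisfies the > 15 s apnoea definition.
    Events overlapping an earlier event or the recording edges are
    thinned out.
    """
    if rate_per_h <= 0 or duration_s <= 2 * edge_margin_s:
        return []
    n = rng.poisson(rate_per_h * duration_s / 3600.0)
    onsets = np.sort(rng.uniform(edge_margin_s,
                                 duration_s - edge_margin_s - 40.0, size=n))
    events: list[tuple[float, float]] = []
    for onset in onsets:
        dur = 15.0 + 0.2 + rng.exponential(mean_excess_s)
        if events and onset < events[-1][0] + events[-1][1] + min_gap_s:
            continue
        if onset + dur > duration_s - edge_margin_s:
            continue
        events.append((float(onset), float(dur)))
    return events


def simulate_ip(duration_s: float, resp_rate: float = 60.0,
                apnoea_spec: list[tuple[float, float]] | None = None,
                noise_spec: NoiseSpec | None = None,
                shallow_spec: list[tuple[float, float, float]] | None = None,
                seed: int = 0, fs: float = 62.5, amplitude: float = 1.0
                ) -> tuple[resp.IPSignal, IPGroundTruth]:
    """Synthesise an impedance-pneumography trace with known truth.

    The trace is a train of raised-cosine breath cycles (amplitude
    slow-drifting) plus a small cardiac sinusoid and white noise.
    ``apnoea_spec`` lists breath-free pauses as (onset_s, duration_s);
    ``shallow_spec`` lists (onset_s, duration_s, scale) segments whose
    breath amplitudes are scaled down.  Truth records the breath-peak
    times, so diff(truth.breath_times) is the exact IBI series.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not 10.0 < resp_rate < 120.0:
        raise ValueError("respiratory rate must lie in (10, 120) breaths/min")
    apnoeas = list(apnoea_spec or [])
    for onset, dur in apnoeas:
        if dur <= 0 or onset < 0 or onset + dur > duration_s:
            raise ValueError("apnoeas must lie inside the recording")
    shallow = list(shallow_spec or [])
    noise = noise_spec if noise_spec is not None else NoiseSpec()
    rng = child_rng(seed, _T_IP)

    base_t = 60.0 / resp_rate
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    # lay out breath cycles, then drop those overlapping an apnoea
    starts, durs = [], []
    t = 0.0
    while True:
        ct = base_t * (1.0 + noise.cycle_jitter * rng.standard_normal()) \
            if noise.cycle_jitter > 0 else base_t
        ct = float(np.clip(ct, 0.5 * base_t, 1.5 * base_t))
        if t + ct > duration_s:
            break
        starts.append(t)
        durs.append(ct)
        t += ct
    walk = (np.cumsum(noise.drift_sigma * rng.standard_normal(len(starts)))
            if noise.drift_sigma > 0 else np.zeros(len(starts)))
    amps = amplitude * np.clip(np.exp(walk), 0.3, 3.0)

    breath_times = []
    for s, ct, a in zip(starts, durs, amps):
        if any(s < ao + ad and s + ct > ao for ao, ad in apnoeas):
            continue
        peak = s + ct / 2.0
        for so, sd, scale in shallow:
            if so <= peak < so + sd:
                a = a * scale
        i0, i1 = int(round(s * fs)), min(int(round((s + ct) * fs)), n)
        tau = (np.arange(i0, i1) / fs - s) / ct
        x[i0:i1] += a * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau))
        breath_times.append(peak)

    tgrid = np.arange(n) / fs
    if noise.cardiac_rel_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += (noise.cardiac_rel_amp * amplitude
              * np.sin(2 * np.pi * noise.cardiac_freq_hz * tgrid + phase))
    if noise.white_sd > 0:
        x += noise.white_sd * amplitude * rng.standard_normal(n)

    truth = IPGroundTruth(breath_times=np.array(breath_times),
                          apnoeas=tuple((float(a), float(b)) for a, b in apnoeas),
                          shallow=tuple((float(a), float(b), float(c))
                                        for a, b, c in shallow))
    return resp.IPSignal(samples=x, fs=fs), truth


# ---------------------------------------------------------------------------
# oxygen saturation
# ---------------------------------------------------------------------------

def simulate_spo2(duration_s: float,
                  desat_spec: list[tuple[float, float, float]] | None = None,
                  seed: int = 0, fs: float = 0.97, baseline_pct: float = 97.0,
                  noise_sd: float = 0.3
                  ) -> tuple[SpO2Signal, tuple[tuple[float, float], ...]]:
    """SpO2 trace near baseline with inserted desaturation dips.

    ``desat_spec`` lists (onset_s, duration_s, depth_pct) dips; the
    returned truth is the tuple of inserted (onset, duration) windows.
    """
    if not 85.0 < baseline_pct <= 100.0:
        raise ValueError("baseline saturation must lie in (85, 100]%")
    dips = list(desat_spec or [])
    for onset, dur, depth in dips:
        if not 0.0 <= depth <= 100.0:
            raise ValueError("dip depth must lie in [0, 100]%")
        if onset < 0 or onset + dur > duration_s:
            raise ValueError("dips must lie inside the recording")
    rng = child_rng(seed, _T_SPO2)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = baseline_pct + noise_sd * rng.standard_normal(n)
    for onset, dur, depth in dips:
        mask = (t >= onset) & (t < onset + dur)
        x[mask] = depth + 0.2 * rng.standard_normal(mask.sum())
        x[mask] = np.minimum(x[mask], 79.5) if depth < 80 else x[mask]
    x = np.clip(x, 0.0, 100.0)
    truth = tuple((float(a), float(b)) for a, b, _ in dips)
    return SpO2Signal(samples=x, fs=fs), truth


def desat_windows_for_apnoeas(apnoeas, rng: np.random.Generator,
                              coupling: float = 0.5, depth_pct: float = 75.0,
                              duration_s: float = 12.0
                              ) -> list[tuple[float, float, float]]:
    """Desaturation dips co-occurring with a fraction of apnoeas."""
    return [(onset + 3.0, duration_s, depth_pct) for onset, _ in apnoeas
            if rng.random() < coupling]


# ---------------------------------------------------------------------------
# evoked potentials
# ---------------------------------------------------------------------------

def _hermite_gauss(t: np.ndarray, center: float, width: float,
                   order: int) -> np.ndarray:
    z = (t - center) / width
    h = np.polynomial.hermite.hermval(z, [0] * order + [1])
    return h * np.exp(-0.5 * z ** 2)


def make_nrf_basis(n_visual: int = 4, n_tactile: int = 2, fs: float = 2000.0,
                   window: tuple[float, float] = (-0.5, 1.0)) -> NRFBasis:
    """Orthonormal neurodynamic response functions on the epoch grid.

    Smooth Hermite-Gaussian shapes (deterministic in the parameters),
    orthonormalised jointly by QR so all pairwise dot products vanish
    and every waveform has unit norm.  Real-data users supply the
    published basis instead; this one is the synthetic default.
    """
    t = epoch_grid(fs, window)
    raw = [_hermite_gauss(t, 0.30, 0.10, k) for k in range(n_visual)]
    raw += [_hermite_gauss(t, 0.25, 0.08, k) for k in range(n_tactile)]
    m = np.column_stack(raw)
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    return NRFBasis(times=t, waveforms=q.T, n_visual=n_visual,
                    n_tactile=n_tactile, fs=fs)


def simulate_evoked(true_brain_age: float, basis: NRFBasis, modality: str,
                    slope_age_map=default_slope_age_map,
                    jitter_ms: float = 10.0, noise_sd: float = 3.0,
                    n_epochs: int = 15, artifact_fraction: float = 0.0,
                    seed: int = 0) -> tuple[EpochSet, np.ndarray]:
    """Stimulus-locked epochs with age-dependent NRF magnitudes.

    Each epoch is the clean modality response (sum of slope-weighted
    NRFs for ``true_brain_age``) shifted by a per-epoch latency jitter,
    plus white noise.  ``artifact_fraction`` of the epochs additionally
    receive a large (> 150 uV) pre-stimulus artefact.  Returns the
    epochs and the full 6-vector of true slopes.
    """
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    if jitter_ms > 50.0:
        raise ValueError("latency jitter must not exceed 50 ms")
    rng = child_rng(seed, _T_EVOKED)
    slopes6 = np.asarray(slope_age_map(true_brain_age), dtype=float)
    sub = slopes6[basis.slope_slice(modality)]
    clean = basis.for_modality(modality).T @ sub
    max_lag = int(round(jitter_ms / 1000.0 * basis.fs))
    n = len(clean)
    epochs = np.empty((n_epochs, n))
    for i in range(n_epochs):
        lag = int(rng.integers(-max_lag, max_lag + 1)) if max_lag else 0
        ep = np.zeros(n)
        if lag > 0:
            ep[lag:] = clean[:-lag]
        elif lag < 0:
            ep[:lag] = clean[-lag:]
        else:
            ep[:] = clean
        if noise_sd > 0:
            ep = ep + noise_sd * rng.standard_normal(n)
        epochs[i] = ep
    n_artifacts = int(round(artifact_fraction * n_epochs))
    if n_artifacts:
        chosen = rng.choice(n_epochs, size=n_artifacts, replace=False)
        bump = 400.0 * np.exp(-0.5 * ((basis.times + 0.25) / 0.05) ** 2)
        epochs[chosen] += bump
    eps = EpochSet(epochs=epochs, times=basis.times, fs=basis.fs,
                   modality=modality)
    return eps, slopes6


# ---------------------------------------------------------------------------
# resting EEG
# ---------------------------------------------------------------------------

def _unit_band_noise(rng, n, fs, lo, hi):
    x = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y / (np.std(y) + 1e-12)


def simulate_resting_eeg(true_brain_age: float, duration_s: float = 1230.0,
                         fs: float = 2000.0, seed: int = 0
                         ) -> tuple[EEGRecording, dict]:
    """Resting EEG (C3/C4) with an age-dependent burst structure.

    Generator law (synthetic convention): the mean inter-burst interval
    shrinks linearly with age, 5.5 s at 31 weeks to 2.0 s at 36 weeks,
    and the relative power of fast (8-25 Hz) continuous activity grows
    linearly with age.  Bursts are shared between C3 and C4 (their
    bipolar derivative keeps the burst envelope) while the noise
    carriers are channel-specific.
    """
    if duration_s < 1.0:
        raise ValueError("duration must be at least 1 s")
    age = float(true_brain_age)
    rng = child_rng(seed, _T_REST)
    n = int(round(duration_s * fs))

    ibi_mean = max(0.5, 5.5 - 0.7 * (age - 31.0))
    burst_mean = 2.5
    env = np.zeros(n, dtype=float)
    t = 0.0
    interburst_durs, burst_onsets = [], []
    while t < duration_s:
        gap = float(np.clip(ibi_mean * rng.exponential(1.0), 0.4, 30.0))
        interburst_durs.append(gap)
        t += gap
        if t >= duration_s:
            break
        burst_onsets.append(t)
        bd = float(np.clip(0.8 + burst_mean * rng.exponential(1.0), 0.8, 12.0))
        i0, i1 = int(t * fs), min(int((t + bd) * fs), n)
        env[i0:i1] = 1.0
        t += bd
    env = gaussian_filter1d(env, sigma=max(1.0, 0.15 * fs))

    high_amp = 2.0 + 1.1 * (age - 31.0)
    channels = {}
    for k, name in enumerate(("C3", "C4")):
        crng = child_rng(seed, _T_REST, k + 1)
        burst_carrier = _unit_band_noise(crng, n, fs, 0.5, 3.0)
        cont_low = _unit_band_noise(crng, n, fs, 0.5, 4.0)
        cont_high = _unit_band_noise(crng, n, fs, 8.0, 25.0)
        channels[name] = (40.0 * env * burst_carrier + 8.0 * cont_low
                          + high_amp * cont_high
                          + 1.0 * crng.standard_normal(n))
    rec = EEGRecording(channels=channels, fs=fs)
    truth = {"ibi_mean_s": ibi_mean,
             "interburst_durations_s": np.array(interburst_durs),
             "burst_onsets_s": np.array(burst_onsets),
             "high_band_amp": high_amp}
    return rec, truth


# ---------------------------------------------------------------------------
# labelled segments for the apnoea screen
# ---------------------------------------------------------------------------

def make_apnoea_training_set(n_per_class: int = 200, seed: int = 0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Labelled candidate-window features: true apnoeas vs shallow breathing.

    Each example is a 120-s IP trace with one 20-s inserted event --
    either a breath-free pause (label 1) or a shallow-breathing segment
    at a small fraction of the local amplitude (label 0) -- summarised
    by :func:`neobag.respiration.long_ibi_features` on the raw trace.
    """
    feats, labels = [], []
    for j in range(2 * n_per_class):
        is_apnoea = j % 2 == 0
        rng = child_rng(seed, _T_TRAIN, j)
        scale = float(rng.uniform(0.15, 0.35))
        window = (50.0, 20.0)
        sig, _ = simulate_ip(
            120.0, resp_rate=float(rng.uniform(40, 70)),
            apnoea_spec=[window] if is_apnoea else None,
            shallow_spec=None if is_apnoea else [(window[0], window[1], scale)],
            seed=int(rng.integers(2 ** 31)))
        feats.append(resp.long_ibi_features(sig, window[0],
                                            window[0] + window[1]))
        labels.append(int(is_apnoea))
    return np.array(feats), np.array(labels)
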