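"""End-to-end pipeline: cohort -> signals -> brain age -> gap -> statistics.

The pipeline runs in two modes.  In ``synthetic`` mode a cohort is
drawn from :mod:`neobag.synthetic` and every occasion's signals are
generated in memory; in ``files`` mode the per-occasion signals are read
from CSV files under ``indir`` (see :func:`simulate_to_files` for the
layout, and :func:`validate_inputs` for a schema check).  Both modes
share the same analysis code and write the same set of plain-text
artifacts to ``outdir``, and a run is a pure function of (config, seed):
re-running the same configuration reproduces every output byte for
byte.

In the pipeline the two brain-age models are trained against
postmenstrual age with infant-grouped cross-validation (each occasion's
brain age is predicted by models that never saw that infant), mirroring
how normative brain-age models are built from infants whose brain
matures typically; the subsequent age-bias correction absorbs any
residual linear calibration error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict
from sklearn.model_selection import GroupKFold

from . import densities as D
from . import desaturation as DS
from . import evoked as E
from . import gap as G
from . import resting as RS
from . import respiration as R
from . import stats as ST
from . import synthetic as S

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["infant_id", "occasion_id", "ga_weeks", "pma_weeks",
                    "infection", "ip_length_h", "caffeine_on",
                    "caffeine_stop_pma_weeks", "longitudinal_vitals"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_infants: int = 74
    gap_mean: float = 0.0
    gap_sd: float = 0.91
    apnoea_gap_slope: float = -0.22
    apnoea_baseline: float = 1.0
    resp_pma_slope: float = -1.87
    infant_random_sd: float = 0.25
    longitudinal_fraction: float = 0.31


class SignalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ip_fs: float = 62.5
    max_ip_hours: float = 2.0          # simulated IP trace length cap
    spo2_fs: float = 0.97
    evoked_fs: float = 500.0
    n_visual_epochs: int = 15
    n_tactile_epochs: int = 10
    evoked_noise_sd: float = 3.0
    evoked_jitter_ms: float = 10.0
    artifact_fraction: float = 0.1
    resting_fs: float = 128.0
    resting_duration_s: float = 1230.0


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bootstrap_reps: int = 10_000
    cv_folds: int = 5


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    mode: Literal["synthetic", "files"] = "synthetic"
    seed: int = 0
    outdir: Path = Path("neobag_out")
    indir: Optional[Path] = None
    bias_correction: bool = True
    cohort: CohortConfig = CohortConfig()
    signals: SignalConfig = SignalConfig()
    stats: StatsConfig = StatsConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def _cohort_params(config: PipelineConfig) -> S.CohortParams:
    return S.CohortParams(seed=config.seed, **config.cohort.model_dump())


# ---------------------------------------------------------------------------
# per-occasion signals
# ---------------------------------------------------------------------------

@dataclass
class OccasionSignals:
    ip: R.IPSignal | None
    spo2: DS.SpO2Signal | None
    visual: E.EpochSet | None
    tactile: E.EpochSet | None
    resting: E.EEGRecording | None
    truth: dict | None = None


def synthesize_occasion_signals(row: pd.Series, true_brain_age: float,
                                true_apnoea_rate: float, true_resp_rate: float,
                                basis: E.NRFBasis,
                                config: PipelineConfig, index: int
                                ) -> OccasionSignals:
    """Generate one occasion's IP, SpO2, evoked and resting signals."""
    sc = config.signals
    seed = config.seed
    dur_s = min(float(row["ip_length_h"]), sc.max_ip_hours) * 3600.0
    rng = S.child_rng(seed, 7, index)
    apnoeas = S.draw_apnoea_events(dur_s, true_apnoea_rate, rng)
    ip, ip_truth = S.simulate_ip(dur_s, resp_rate=true_resp_rate,
                                 apnoea_spec=apnoeas, fs=sc.ip_fs,
                                 seed=int(rng.integers(2 ** 31)))
    dips = S.desat_windows_for_apnoeas(apnoeas, rng)
    spo2, desat_truth = S.simulate_spo2(dur_s, dips, fs=sc.spo2_fs,
                                        seed=int(rng.integers(2 ** 31)))
    visual, _ = S.simulate_evoked(
        true_brain_age, basis, E.VISUAL, noise_sd=sc.evoked_noise_sd,
        jitter_ms=sc.evoked_jitter_ms, n_epochs=sc.n_visual_epochs,
        artifact_fraction=sc.artifact_fraction, seed=int(rng.integers(2 ** 31)))
    tactile, _ = S.simulate_evoked(
        true_brain_age, basis, E.TACTILE, noise_sd=sc.evoked_noise_sd,
        jitter_ms=sc.evoked_jitter_ms, n_epochs=sc.n_tactile_epochs,
        artifact_fraction=sc.artifact_fraction, seed=int(rng.integers(2 ** 31)))
    resting, rest_truth = S.simulate_resting_eeg(
        true_brain_age, duration_s=sc.resting_duration_s, fs=sc.resting_fs,
        seed=int(rng.integers(2 ** 31)))
    truth = {"apnoeas": list(ip_truth.apnoeas),
             "desat_windows": list(desat_truth),
             "breath_times": ip_truth.breath_times.tolist(),
             "true_brain_age": float(true_brain_age),
             "ibi_mean_s": rest_truth["ibi_mean_s"]}
    return OccasionSignals(ip=ip, spo2=spo2, visual=visual, tactile=tactile,
                           resting=resting, truth=truth)


# ---------------------------------------------------------------------------
# file I/O (two-column CSV per signal + JSON truth sidecar)
# ---------------------------------------------------------------------------

def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input file is missing: {path}")
    return path


def write_occasion_signals(sig_dir: Path, occ_id: str,
                           signals: OccasionSignals) -> None:
    sig_dir.mkdir(parents=True, exist_ok=True)
    ip = signals.ip
    pd.DataFrame({"time_s": ip.times, "value": ip.samples}).to_csv(
        sig_dir / f"ip_{occ_id}.csv", index=False)
    sp = signals.spo2
    t = sp.start_time + np.arange(len(sp.samples)) / sp.fs
    pd.DataFrame({"time_s": t, "value": sp.samples}).to_csv(
        sig_dir / f"spo2_{occ_id}.csv", index=False)
    rec = signals.resting
    tr = np.arange(rec.n_samples) / rec.fs
    pd.DataFrame({"time_s": tr, "C3": rec.channels["C3"],
                  "C4": rec.channels["C4"]}).to_csv(
        sig_dir / f"resting_{occ_id}.csv", index=False)
    for eps in (signals.visual, signals.tactile):
        pd.DataFrame(eps.epochs).to_csv(
            sig_dir / f"evoked_{occ_id}_{eps.modality}.csv", index=False)
        meta = {"fs": eps.fs, "window_s": [float(eps.times[0]),
                                           float(eps.times[0]) + len(eps.times) / eps.fs],
                "modality": eps.modality}
        (sig_dir / f"evoked_{occ_id}_{eps.modality}.json").write_text(
            json.dumps(meta, sort_keys=True))
    if signals.truth is not None:
        (sig_dir / f"truth_{occ_id}.json").write_text(
            json.dumps(signals.truth, sort_keys=True))


def load_occasion_signals(indir: Path, occ_id: str,
                          only: set[str] | None = None) -> OccasionSignals:
    """Read one occasion's signals; IP is required, the rest optional.

    ``only`` restricts loading to a subset of
    {"ip", "spo2", "evoked", "resting"} (stage commands use this to
    avoid reading signals they do not analyse).
    """
    indir = Path(indir)
    want = only or {"ip", "spo2", "evoked", "resting"}
    ip = spo2 = visual = tactile = resting = None
    if "ip" in want:
        ip_df = pd.read_csv(_require(indir / f"ip_{occ_id}.csv"))
        fs = 1.0 / float(np.median(np.diff(ip_df["time_s"])))
        ip = R.IPSignal(ip_df["value"].to_numpy(), fs=fs,
                        start_time=float(ip_df["time_s"].iloc[0]))
    p = indir / f"spo2_{occ_id}.csv"
    if "spo2" in want and p.exists():
        df = pd.read_csv(p)
        spo2 = DS.SpO2Signal(df["value"].to_numpy(),
                             fs=1.0 / float(np.median(np.diff(df["time_s"]))),
                             start_time=float(df["time_s"].iloc[0]))
    for mod in (E.VISUAL, E.TACTILE) if "evoked" in want else ():
        pcsv = indir / f"evoked_{occ_id}_{mod}.csv"
        pjson = indir / f"evoked_{occ_id}_{mod}.json"
        if pcsv.exists() and pjson.exists():
            meta = json.loads(pjson.read_text())
            epochs = pd.read_csv(pcsv).to_numpy(dtype=float)
            times = E.epoch_grid(meta["fs"],
                                 (meta["window_s"][0],
                                  meta["window_s"][0] + epochs.shape[1] / meta["fs"]))
            eps = E.EpochSet(epochs, times, meta["fs"], mod)
            if mod == E.VISUAL:
                visual = eps
            else:
                tactile = eps
    p = indir / f"resting_{occ_id}.csv"
    if "resting" in want and p.exists():
        df = pd.read_csv(p)
        resting = E.EEGRecording(
            channels={"C3": df["C3"].to_numpy(), "C4": df["C4"].to_numpy()},
            fs=1.0 / float(np.median(np.diff(df["time_s"]))))
    return OccasionSignals(ip=ip, spo2=spo2, visual=visual, tactile=tactile,
                           resting=resting)


def simulate_to_files(config: PipelineConfig) -> Path:
    """Write a synthetic cohort to ``outdir`` in the file-mode layout.

    Produces ``metadata.csv`` plus, per occasion, two-column signal CSVs
    and a JSON ground-truth sidecar.  Intended for small cohorts -- raw
    traces dominate the disk footprint.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = S.simulate_cohort(_cohort_params(config))
    basis = S.make_nrf_basis(fs=config.signals.evoked_fs)
    table[METADATA_COLUMNS].to_csv(out / "metadata.csv", index=False)
    for i, row in table.reset_index(drop=True).iterrows():
        sig = synthesize_occasion_signals(
            row, truth.true_brain_age[i], truth.true_apnoea_rate[i],
            truth.true_resp_rate[i], basis, config, i)
        write_occasion_signals(out, row["occasion_id"], sig)
    return out


def validate_inputs(indir: str | Path) -> pd.DataFrame:
    """Schema check of a file-mode input bundle (reports, never raises).

    One row per (occasion, check) with a pass flag and a message.
    """
    indir = Path(indir)
    rows = []

    def note(occ, check, ok, msg=""):
        rows.append(dict(occasion_id=occ, check=check, passed=bool(ok),
                         message=msg))

    meta_path = indir / "metadata.csv"
    if not meta_path.exists():
        note("-", "metadata_exists", False, f"missing {meta_path}")
        return pd.DataFrame(rows)
    meta = pd.read_csv(meta_path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    note("-", "metadata_columns", not missing,
         f"missing columns: {missing}" if missing else "")
    for occ in meta.get("occasion_id", pd.Series(dtype=str)):
        p = indir / f"ip_{occ}.csv"
        if not p.exists():
            note(occ, "ip_present", False, f"missing {p}")
        else:
            df = pd.read_csv(p, nrows=200)
            ok_cols = {"time_s", "value"} <= set(df.columns)
            note(occ, "ip_columns", ok_cols)
            if ok_cols and len(df) > 2:
                fs = 1.0 / float(np.median(np.diff(df["time_s"])))
                note(occ, "ip_fs", abs(fs - 62.5) < 1.0,
                     f"sampling rate {fs:.2f} Hz, expected 62.5")
        have_evoked = all((indir / f"evoked_{occ}_{m}.csv").exists()
                          for m in (E.VISUAL, E.TACTILE))
        note(occ, "evoked_present", have_evoked,
             "" if have_evoked else "sensory brain age will be unavailable")
        p = indir / f"resting_{occ}.csv"
        if p.exists():
            cols = set(pd.read_csv(p, nrows=1).columns)
            note(occ, "resting_channels", {"C3", "C4"} <= cols,
                 "" if {"C3", "C4"} <= cols else "need channels C3 and C4")
        else:
            note(occ, "resting_present", False,
                 "resting brain age will be unavailable")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-occasion analyses
# ---------------------------------------------------------------------------

def analyse_respiration(sig: R.IPSignal, clf: R.ApnoeaClassifier):
    """Filter, detect breaths, screen long IBIs, summarise one recording."""
    filtered = R.filter_ip(sig)
    breaths = R.detect_breaths(filtered)
    if len(breaths) < 2:
        return None, [], None
    ibis = R.extract_ibis(breaths)
    events = R.classify_long_ibis(ibis, sig, clf)    # screen on the raw trace
    summary = R.summarise_recording(ibis, events)
    kept = R.drop_rejected_ibis(ibis, events)
    return summary, events, kept


def analyse_evoked(visual: E.EpochSet | None, tactile: E.EpochSet | None,
                   basis: E.NRFBasis):
    """Artifact rejection, Woody alignment, NRF slopes; None if unavailable."""
    kept_sets = []
    for eps in (visual, tactile):
        if eps is None:
            continue
        kept_sets.append(E.reject_artifacts(eps))
    if not kept_sets or not E.sensory_available(kept_sets):
        return None
    aligned = {}
    for eps in kept_sets:
        if eps.n_kept == 0:
            continue
        eps, _ = E.woody_align(eps, E.nrf_template(eps, basis))
        aligned[eps.modality] = eps
    return E.fit_nrf_slopes(aligned.get(E.VISUAL), aligned.get(E.TACTILE), basis)


def _association_tables(analysis: pd.DataFrame):
    """The four association models plus their E-values.

    Models with a singular design (e.g. a constant outcome in a tiny
    cohort) are skipped and reported back as failure messages.
    """
    assoc_rows, evalue_rows, failures = [], [], []
    for response in (ST.APNOEA_RATE, ST.RESP_RATE):
        for predictor in (ST.PMA, ST.GAP):
            name = f"{response}~{predictor}"
            try:
                fr = ST.fit_association(analysis, response, predictor)
            except ValueError as err:
                failures.append(f"{name}: {err}")
                continue
            assoc_rows.append(dict(model=name, beta=fr.beta, ci_lo=fr.ci_low,
                                   ci_hi=fr.ci_high, p=fr.p_value,
                                   partial_rho=fr.partial_rho, n=fr.n))
            rr = ST.rho_to_rr(fr.partial_rho)
            ci_rho = (fr.rho_ci_high if fr.partial_rho < 0 else fr.rho_ci_low)
            ev = ST.evalue(rr, ST.rho_to_rr(ci_rho))
            evalue_rows.append(dict(model=name, rr=ev.rr, e_point=ev.e_point,
                                    e_ci=ev.e_ci))
    return assoc_rows, evalue_rows, failures


def _grouped_cv_predict(fit, predict, features, ages, groups, n_splits):
    """Infant-grouped cross-validated predictions.

    Small cohorts (fewer than 30 usable occasions) are fitted once on
    all data and predicted in-sample, since held-out folds would fall
    below the models' minimum training size.
    """
    n = len(ages)
    pred = np.full(n, np.nan)
    if n < 30:
        model = fit(np.arange(n))
        for i in range(n):
            pred[i] = predict(model, i)
        return pred
    splits = min(n_splits, len(np.unique(groups)))
    cv = GroupKFold(n_splits=splits)
    for tr, te in cv.split(np.arange(n), groups=groups):
        model = fit(tr)
        for i in te:
            pred[i] = predict(model, i)
    return pred


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle to ``outdir``.

    Returns the report dictionary (also written as ``report.json``).
    Stage failures for individual statistics (e.g. a caffeine-stop
    subset that is too small) are recorded in the manifest while the
    remaining outputs are still produced.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    sc = config.signals

    # ----- cohort ---------------------------------------------------------
    if config.mode == "synthetic":
        table, truth = S.simulate_cohort(_cohort_params(config))
        table = table.reset_index(drop=True)
    else:
        if config.indir is None:
            raise ValueError("files mode requires 'indir'")
        table = pd.read_csv(_require(Path(config.indir) / "metadata.csv"))
        truth = None
    manifest["cohort"] = f"ok ({len(table)} occasions)"

    basis = S.make_nrf_basis(fs=sc.evoked_fs)
    feats, labels = S.make_apnoea_training_set(150, seed=config.seed)
    clf = R.train_apnoea_classifier(feats, labels, seed=config.seed)

    # ----- per-occasion signal analysis ----------------------------------
    resp_rows, event_rows, desat_rows = [], [], []
    slopes = np.full((len(table), basis.n_components), np.nan)
    rest_feats: list[np.ndarray | None] = []
    ibi_store: dict[str, np.ndarray] = {}
    for i, row in table.iterrows():
        occ = row["occasion_id"]
        if config.mode == "synthetic":
            sig = synthesize_occasion_signals(
                row, truth.true_brain_age[i], truth.true_apnoea_rate[i],
                truth.true_resp_rate[i], basis, config, i)
        else:
            sig = load_occasion_signals(config.indir, occ)

        summary, events, kept = analyse_respiration(sig.ip, clf)
        hours = sig.ip.duration_s / 3600.0
        if summary is None:
            resp_rows.append(dict(occasion_id=occ, resp_rate_bpm=np.nan,
                                  apnoea_rate_per_h=np.nan, n_ibis=0,
                                  qc_pass=False, ip_hours=hours))
        else:
            resp_rows.append(dict(occasion_id=occ, resp_rate_bpm=summary.resp_rate,
                                  apnoea_rate_per_h=summary.apnoea_rate,
                                  n_ibis=summary.n_ibis,
                                  qc_pass=summary.qc_pass, ip_hours=hours))
            ibi_store[occ] = kept.intervals
            event_rows += [dict(occasion_id=occ, start_time_s=e.start_time,
                                duration_s=e.duration, label=e.label)
                           for e in events]

        if sig.spo2 is not None:
            evs = DS.detect_desaturations(sig.spo2)
            desat_rows.append(dict(
                occasion_id=occ,
                desat_rate_per_h=DS.desat_rate(evs, sig.spo2.duration_s / 3600.0),
                n_desats=len(evs)))
        else:
            desat_rows.append(dict(occasion_id=occ, desat_rate_per_h=np.nan,
                                   n_desats=0))

        sl = analyse_evoked(sig.visual, sig.tactile, basis)
        if sl is not None:
            slopes[i] = sl
        if sig.resting is not None:
            try:
                seg = RS.prepare_resting_segment(sig.resting)
                rest_feats.append(RS.epoch_30s(seg))
            except RS.InsufficientDataError:
                rest_feats.append(None)
        else:
            rest_feats.append(None)

    resp_df = pd.DataFrame(resp_rows)
    desat_df = pd.DataFrame(desat_rows)
    pd.DataFrame(event_rows,
                 columns=["occasion_id", "start_time_s", "duration_s",
                          "label"]).to_csv(out / "apnoea_events.csv", index=False)
    resp_df.to_csv(out / "resp_summary.csv", index=False)
    desat_df.to_csv(out / "desat_events.csv", index=False)
    manifest["respiration"] = f"ok ({int(resp_df.qc_pass.sum())} of " \
                              f"{len(resp_df)} passed QC)"

    # ----- brain age ------------------------------------------------------
    pma = table["pma_weeks"].to_numpy(float)
    groups = table["infant_id"].to_numpy()
    sens_ok = ~np.isnan(slopes).any(axis=1)
    sensory_age = np.full(len(table), np.nan)
    if sens_ok.sum() >= 20 and np.ptp(pma[sens_ok]) >= 3.0:
        idx = np.flatnonzero(sens_ok)
        pred = _grouped_cv_predict(
            lambda tr: E.train_sensory_model(slopes[idx[tr]], pma[idx[tr]],
                                             seed=config.seed),
            lambda m, i: float(E.predict_sensory_age(m, slopes[idx[i]])[0]),
            None, pma[idx], groups[idx], config.stats.cv_folds)
        sensory_age[idx] = pred
        manifest["sensory_age"] = f"ok ({int(sens_ok.sum())} occasions)"
    else:
        manifest["sensory_age"] = "skipped: too few occasions with evoked data"

    rest_ok = np.array([f is not None for f in rest_feats])
    resting_age = np.full(len(table), np.nan)
    if rest_ok.sum() >= 20:
        idx = np.flatnonzero(rest_ok)
        pred = _grouped_cv_predict(
            lambda tr: RS.train_resting_model([rest_feats[idx[i]] for i in tr],
                                              pma[idx[tr]], seed=config.seed),
            lambda m, i: RS.predict_resting_age(m, rest_feats[idx[i]]),
            None, pma[idx], groups[idx], config.stats.cv_folds)
        resting_age[idx] = pred
        manifest["resting_age"] = f"ok ({int(rest_ok.sum())} occasions)"
    else:
        manifest["resting_age"] = "skipped: too few occasions with resting data"

    pd.DataFrame({"occasion_id": table["occasion_id"],
                  **{f"slope_{k}": slopes[:, k] for k in range(6)}}
                 ).to_csv(out / "slopes.csv", index=False)

    usable = ~(np.isnan(sensory_age) & np.isnan(resting_age))
    if usable.sum() < 3:
        raise RuntimeError("too few occasions with any brain-age estimate")
    gap_df = G.build_gap_table(table.loc[usable, "occasion_id"],
                               pma[usable], sensory_age[usable],
                               resting_age[usable],
                               correct_bias=config.bias_correction)
    gap_df.to_csv(out / "gap.csv", index=False)
    manifest["gap"] = f"ok ({len(gap_df)} occasions)"

    # ----- analysis table -------------------------------------------------
    # measured quantities replace any table-level observed columns
    base = table.drop(columns=["corrected_gap", "apnoea_rate", "resp_rate",
                               "desat_rate"], errors="ignore")
    merged = (base.merge(resp_df, on="occasion_id")
                   .merge(desat_df, on="occasion_id")
                   .merge(gap_df[["occasion_id", "corrected_gap", "raw_gap",
                                  "combined_age", "maturity"]], on="occasion_id"))
    merged = merged[merged["qc_pass"]].reset_index(drop=True)
    analysis = merged.rename(columns={"apnoea_rate_per_h": "apnoea_rate",
                                      "resp_rate_bpm": "resp_rate"})
    analysis["ip_length_h"] = analysis["ip_hours"]
    analysis.to_csv(out / "cohort.csv", index=False)

    # ----- IBI densities --------------------------------------------------
    report: dict = {"n_infants": int(table["infant_id"].nunique()),
                    "n_occasions": int(len(table)),
                    "n_qc_passed": int(resp_df.qc_pass.sum()),
                    "gap_mean_weeks": float(gap_df["corrected_gap"].mean()),
                    "gap_sd_weeks": float(gap_df["corrected_gap"].std(ddof=1)),
                    "maturity_split": gap_df["maturity"].value_counts().to_dict()}
    for axis, col in (("pma", "pma_weeks"), ("gap", "corrected_gap")):
        sub = analysis[analysis["occasion_id"].isin(ibi_store)]
        dens, vals = [], []
        for _, row in sub.iterrows():
            iv = ibi_store[row["occasion_id"]]
            if np.any(iv <= D.MAX_IBI_S):
                dens.append(D.recording_density(iv))
                vals.append(float(row[col]))
        try:
            grid = D.build_density_grid(vals, dens, axis=axis)
            grid.to_frame().to_csv(out / f"densities_{axis}.csv", index=False)
            report[f"apnoea_tail_mass_{axis}"] = {
                f"{v:.2f}": float(m) for v, m in
                zip(grid.axis_values, D.tail_mass(grid)) if np.isfinite(m)}
            manifest[f"densities_{axis}"] = "ok"
        except ValueError as err:
            manifest[f"densities_{axis}"] = f"skipped: {err}"

    # ----- association statistics ----------------------------------------
    assoc_rows, evalue_rows, failures = _association_tables(analysis)
    assoc_df = pd.DataFrame(assoc_rows)
    assoc_df.to_csv(out / "associations.csv", index=False)
    pd.DataFrame(evalue_rows).to_csv(out / "evalues.csv", index=False)
    report["associations"] = assoc_rows
    manifest["associations"] = ("ok" if not failures
                                else "partial: " + "; ".join(failures))

    try:
        boot = ST.bootstrap_compare(analysis, n_reps=config.stats.bootstrap_reps,
                                    seed=config.seed)
        boot_payload = dict(n_reps=boot.n_reps, rho_gap=boot.rho_gap,
                            rho_pma=boot.rho_pma, p_one_tailed=boot.p_one_tailed,
                            ci=[boot.ci_low, boot.ci_high],
                            n_degenerate_redraws=boot.n_degenerate_redraws)
        (out / "bootstrap.json").write_text(json.dumps(boot_payload,
                                                       sort_keys=True, indent=1))
        report["bootstrap"] = boot_payload
        manifest["bootstrap"] = "ok"
    except ValueError as err:
        manifest["bootstrap"] = f"skipped: {err}"

    # caffeine-stop regression: occasions on caffeine with the gap assessed
    # within two weeks before discontinuation (latest such occasion/infant)
    sub = analysis[(analysis["caffeine_on"] == 1)
                   & (analysis["caffeine_stop_pma_weeks"] - analysis["pma_weeks"]
                      <= 2.0)]
    sub = (sub.sort_values("pma_weeks").groupby("infant_id").tail(1)
           .reset_index(drop=True))
    try:
        fr = ST.caffeine_stop_regression(sub)
        report["caffeine_stop"] = dict(beta=fr.beta, ci=[fr.ci_low, fr.ci_high],
                                       p=fr.p_value, partial_rho=fr.partial_rho,
                                       n=fr.n)
        manifest["caffeine_stop"] = f"ok (n={fr.n})"
    except ValueError as err:
        manifest["caffeine_stop"] = f"skipped: {err}"

    # post-caffeine exploratory group comparison (synthetic sub-study truth)
    if truth is not None and len(truth.post_caffeine):
        groups_cmp = ST.post_caffeine_group_rates(truth.post_caffeine)
        rows = []
        post = {}
        for name, gc in groups_cmp.items():
            entry = dict(outcome=name, mature_mean=gc.mature_mean,
                         mature_sd=gc.mature_sd, n_mature=gc.n_mature,
                         immature_mean=gc.immature_mean,
                         immature_sd=gc.immature_sd, n_immature=gc.n_immature)
            if gc.available and gc.immature_mean > 0:
                entry["percent_reduction"] = ST.percent_reduction(
                    gc.mature_mean, gc.immature_mean)
            rows.append(entry)
            post[name] = entry
        pd.DataFrame(rows).to_csv(out / "post_caffeine_groups.csv", index=False)
        report["post_caffeine"] = post
        manifest["post_caffeine"] = "ok"
    else:
        manifest["post_caffeine"] = "skipped: no longitudinal sub-study data"

    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True,
                                                  indent=1))
    return report


# ---------------------------------------------------------------------------
# file-bundle stage commands (each independently re-runnable)
# ---------------------------------------------------------------------------

def _read_metadata(indir: Path) -> pd.DataFrame:
    return pd.read_csv(_require(Path(indir) / "metadata.csv"))


def stage_respiration(indir: Path, outdir: Path, seed: int = 0) -> pd.DataFrame:
    """Breath/apnoea analysis of every IP trace in a file bundle."""
    meta = _read_metadata(indir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    feats, labels = S.make_apnoea_training_set(150, seed=seed)
    clf = R.train_apnoea_classifier(feats, labels, seed=seed)
    rows, event_rows = [], []
    for occ in meta["occasion_id"]:
        sig = load_occasion_signals(indir, occ, only={"ip"})
        summary, events, kept = analyse_respiration(sig.ip, clf)
        hours = sig.ip.duration_s / 3600.0
        if summary is None:
            rows.append(dict(occasion_id=occ, resp_rate_bpm=np.nan,
                             apnoea_rate_per_h=np.nan, n_ibis=0,
                             qc_pass=False, ip_hours=hours))
            continue
        rows.append(dict(occasion_id=occ, resp_rate_bpm=summary.resp_rate,
                         apnoea_rate_per_h=summary.apnoea_rate,
                         n_ibis=summary.n_ibis, qc_pass=summary.qc_pass,
                         ip_hours=hours))
        event_rows += [dict(occasion_id=occ, start_time_s=e.start_time,
                            duration_s=e.duration, label=e.label)
                       for e in events]
        pd.DataFrame({"start_time_s": kept.interval_start_times,
                      "interval_s": kept.intervals}).to_csv(
            out / f"ibis_{occ}.csv", index=False)
    df = pd.DataFrame(rows)
    df.to_csv(out / "resp_summary.csv", index=False)
    pd.DataFrame(event_rows, columns=["occasion_id", "start_time_s",
                                      "duration_s", "label"]).to_csv(
        out / "apnoea_events.csv", index=False)
    return df


def stage_desat(indir: Path, outdir: Path) -> pd.DataFrame:
    """Desaturation events and rates for every SpO2 trace in a bundle."""
    meta = _read_metadata(indir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for occ in meta["occasion_id"]:
        sig = load_occasion_signals(indir, occ, only={"spo2"})
        if sig.spo2 is None:
            rows.append(dict(occasion_id=occ, desat_rate_per_h=np.nan,
                             n_desats=0))
            continue
        evs = DS.detect_desaturations(sig.spo2)
        rows.append(dict(occasion_id=occ,
                         desat_rate_per_h=DS.desat_rate(
                             evs, sig.spo2.duration_s / 3600.0),
                         n_desats=len(evs)))
    df = pd.DataFrame(rows)
    df.to_csv(out / "desat_events.csv", index=False)
    return df


def stage_brainage(indir: Path, outdir: Path, seed: int = 0,
                   evoked_fs: float = 500.0, cv_folds: int = 5
                   ) -> pd.DataFrame:
    """NRF slopes and cross-validated sensory/resting brain ages."""
    meta = _read_metadata(indir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    basis = S.make_nrf_basis(fs=evoked_fs)
    pma = meta["pma_weeks"].to_numpy(float)
    groups = meta["infant_id"].to_numpy()
    slopes = np.full((len(meta), basis.n_components), np.nan)
    rest_feats: list[np.ndarray | None] = []
    for i, occ in enumerate(meta["occasion_id"]):
        sig = load_occasion_signals(indir, occ, only={"evoked", "resting"})
        sl = analyse_evoked(sig.visual, sig.tactile, basis)
        if sl is not None:
            slopes[i] = sl
        if sig.resting is not None:
            try:
                rest_feats.append(RS.epoch_30s(
                    RS.prepare_resting_segment(sig.resting)))
            except RS.InsufficientDataError:
                rest_feats.append(None)
        else:
            rest_feats.append(None)

    sensory_age = np.full(len(meta), np.nan)
    sens_ok = ~np.isnan(slopes).any(axis=1)
    if sens_ok.sum() >= 20 and np.ptp(pma[sens_ok]) >= 3.0:
        idx = np.flatnonzero(sens_ok)
        sensory_age[idx] = _grouped_cv_predict(
            lambda tr: E.train_sensory_model(slopes[idx[tr]], pma[idx[tr]],
                                             seed=seed),
            lambda m, i: float(E.predict_sensory_age(m, slopes[idx[i]])[0]),
            None, pma[idx], groups[idx], cv_folds)
    resting_age = np.full(len(meta), np.nan)
    rest_ok = np.array([f is not None for f in rest_feats])
    if rest_ok.sum() >= 20:
        idx = np.flatnonzero(rest_ok)
        resting_age[idx] = _grouped_cv_predict(
            lambda tr: RS.train_resting_model([rest_feats[idx[i]] for i in tr],
                                              pma[idx[tr]], seed=seed),
            lambda m, i: RS.predict_resting_age(m, rest_feats[idx[i]]),
            None, pma[idx], groups[idx], cv_folds)

    pd.DataFrame({"occasion_id": meta["occasion_id"],
                  **{f"slope_{k}": slopes[:, k] for k in range(6)}}
                 ).to_csv(out / "slopes.csv", index=False)
    df = pd.DataFrame({"occasion_id": meta["occasion_id"],
                       "sensory_age_weeks": sensory_age,
                       "sensory_available": sens_ok,
                       "resting_age_weeks": resting_age,
                       "resting_available": rest_ok})
    df[["occasion_id", "sensory_age_weeks", "sensory_available"]].to_csv(
        out / "sensory_age.csv", index=False)
    df[["occasion_id", "resting_age_weeks", "resting_available"]].to_csv(
        out / "resting_age.csv", index=False)
    return df


def stage_gap(indir: Path, outdir: Path,
              bias_correction: bool = True) -> pd.DataFrame:
    """Combine brain-age estimates and apply age-bias correction."""
    meta = _read_metadata(indir)
    out = Path(outdir)
    sens = pd.read_csv(_require(out / "sensory_age.csv"))
    rest = pd.read_csv(_require(out / "resting_age.csv"))
    df = meta.merge(sens, on="occasion_id").merge(rest, on="occasion_id")
    usable = ~(df["sensory_age_weeks"].isna() & df["resting_age_weeks"].isna())
    df = df[usable]
    gap_df = G.build_gap_table(df["occasion_id"],
                               df["pma_weeks"].to_numpy(float),
                               df["sensory_age_weeks"].to_numpy(float),
                               df["resting_age_weeks"].to_numpy(float),
                               correct_bias=bias_correction)
    gap_df.to_csv(out / "gap.csv", index=False)
    return gap_df


def stage_densities(indir: Path, outdir: Path) -> None:
    """Conditional IBI densities from stage_respiration / stage_gap outputs."""
    meta = _read_metadata(indir)
    out = Path(outdir)
    gap_df = pd.read_csv(_require(out / "gap.csv"))
    merged = meta.merge(gap_df[["occasion_id", "corrected_gap"]],
                        on="occasion_id", how="left")
    for axis, col in (("pma", "pma_weeks"), ("gap", "corrected_gap")):
        dens, vals = [], []
        for _, row in merged.iterrows():
            p = out / f"ibis_{row['occasion_id']}.csv"
            if not p.exists() or not np.isfinite(row[col]):
                continue
            iv = pd.read_csv(p)["interval_s"].to_numpy(float)
            if np.any(iv <= D.MAX_IBI_S):
                dens.append(D.recording_density(iv))
                vals.append(float(row[col]))
        grid = D.build_density_grid(vals, dens, axis=axis)
        grid.to_frame().to_csv(out / f"densities_{axis}.csv", index=False)


def stage_stats(indir: Path, outdir: Path, seed: int = 0,
                bootstrap_reps: int = 10_000) -> pd.DataFrame:
    """Association models, bootstrap and E-values from stage outputs."""
    meta = _read_metadata(indir)
    out = Path(outdir)
    resp = pd.read_csv(_require(out / "resp_summary.csv"))
    desat = pd.read_csv(_require(out / "desat_events.csv"))
    gap_df = pd.read_csv(_require(out / "gap.csv"))
    analysis = (meta.merge(resp, on="occasion_id")
                    .merge(desat, on="occasion_id")
                    .merge(gap_df[["occasion_id", "corrected_gap"]],
                           on="occasion_id"))
    analysis = analysis[analysis["qc_pass"]].reset_index(drop=True)
    analysis = analysis.rename(columns={"apnoea_rate_per_h": "apnoea_rate",
                                        "resp_rate_bpm": "resp_rate"})
    analysis["ip_length_h"] = analysis["ip_hours"]
    rows, evalue_rows, failures = _association_tables(analysis)
    for msg in failures:
        logger.warning("association model skipped: %s", msg)
    df = pd.DataFrame(rows)
    df.to_csv(out / "associations.csv", index=False)
    pd.DataFrame(evalue_rows).to_csv(out / "evalues.csv", index=False)
    try:
        boot = ST.bootstrap_compare(analysis, n_reps=bootstrap_reps, seed=seed)
        (out / "bootstrap.json").write_text(json.dumps(
            dict(n_reps=boot.n_reps, rho_gap=boot.rho_gap, rho_pma=boot.rho_pma,
                 p_one_tailed=boot.p_one_tailed, ci=[boot.ci_low, boot.ci_high],
                 n_degenerate_redraws=boot.n_degenerate_redraws),
            sort_keys=True, indent=1))
    except ValueError as err:
        logger.warning("bootstrap skipped: %s", err)
    return df


# ---------------------------------------------------------------------------
# recovery benchmark
# ---------------------------------------------------------------------------

def brain_age_recovery_benchmark(seed: int = 1, resting_fs: float = 128.0,
                                 evoked_fs: float = 500.0) -> dict:
    """Parameter-recovery benchmark of both brain-age models.

    Draws the default synthetic cohort, runs the full evoked pipeline
    (artifact rejection, Woody alignment, NRF slopes) and the resting
    feature extraction per occasion, and cross-validates both models
    against the generator's true brain ages -- emulating training on a
    normative cohort in which brain age and chronological age agree.
    Returns the cross-validated MAEs (weeks), the correlation between
    combined predicted and true age, and the residual gap statistics.
    """
    from sklearn.model_selection import KFold

    table, truth = S.simulate_cohort(S.CohortParams(seed=seed))
    n = len(table)
    ages = truth.true_brain_age
    basis = S.make_nrf_basis(fs=evoked_fs)
    slopes = np.empty((n, basis.n_components))
    rest_feats = []
    for i in range(n):
        rng = S.child_rng(seed, 77, i)
        visual, _ = S.simulate_evoked(
            ages[i], basis, E.VISUAL, noise_sd=3.0, jitter_ms=10.0,
            n_epochs=15, artifact_fraction=0.1,
            seed=int(rng.integers(2 ** 31)))
        tactile, _ = S.simulate_evoked(
            ages[i], basis, E.TACTILE, noise_sd=3.0, jitter_ms=10.0,
            n_epochs=10, artifact_fraction=0.1,
            seed=int(rng.integers(2 ** 31)))
        sl = analyse_evoked(visual, tactile, basis)
        slopes[i] = sl if sl is not None else np.nan
        rec, _ = S.simulate_resting_eeg(ages[i], duration_s=1230.0,
                                        fs=resting_fs,
                                        seed=int(rng.integers(2 ** 31)))
        rest_feats.append(RS.epoch_30s(RS.prepare_resting_segment(rec)))

    ok = ~np.isnan(slopes).any(axis=1)
    cv = KFold(n_splits=5, shuffle=True, random_state=seed)
    sensory_pred = np.full(n, np.nan)
    idx = np.flatnonzero(ok)
    for tr, te in cv.split(idx):
        model = E.train_sensory_model(slopes[idx[tr]], ages[idx[tr]],
                                      seed=seed)
        sensory_pred[idx[te]] = E.predict_sensory_age(model, slopes[idx[te]])
    resting_pred = np.full(n, np.nan)
    for tr, te in cv.split(np.arange(n)):
        model = RS.train_resting_model([rest_feats[i] for i in tr],
                                       ages[tr], seed=seed)
        for i in te:
            resting_pred[i] = RS.predict_resting_age(model, rest_feats[i])

    combined = G.combine_ages(sensory_pred, resting_pred)
    corrected, _ = G.bias_correct(combined, table["pma_weeks"].to_numpy())
    return {
        "n_occasions": n,
        "sensory_mae_weeks": float(np.nanmean(np.abs(sensory_pred - ages))),
        "resting_mae_weeks": float(np.mean(np.abs(resting_pred - ages))),
        "combined_age_r": float(np.corrcoef(combined, ages)[0, 1]),
        "gap_vs_true_gap_r": float(np.corrcoef(corrected,
                                               truth.true_gap)[0, 1]),
    }
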