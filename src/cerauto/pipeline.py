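"""Per-epoch metric extraction and cohort-level tables.

``run_epoch`` turns one protocol epoch of a recording into a flat metrics
row: summary physiology (mean ABP/CBv, FFT heart rate, end-tidal CO2,
respiratory rate with the +/-1 breaths/min compliance gate), transfer-
function autoregulation metrics in the VLF and epoch-appropriate breathing-
frequency bands, ECG-derived HRV, and ABP-derived xBRS and joint-symbolic-
dynamics coupling. Every metric is either a number or NaN with a reason in
the row's flags; nothing fails silently.

``run_cohort`` maps a manifest of recordings to per-epoch rows plus cohort
tables: median +/- IQR per condition, Friedman / Kendall's W / Wilcoxon
post-hoc markers, per-condition Spearman matrices (autonomic vs
autoregulation), and mixed-model tables per autoregulation metric.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cohort_stats, preprocess
from .hrv import HRV
from .io import Epoch, Manifest, read_recording
from .jsd import JointSymbolicDynamics
from .signals import InsufficientDataError, NoBeatsError, Recording
from .tfa import VLF_BAND, SEGMENT_SAMPLES, TransferFunctionAnalysis, bf_band
from .xbrs import BaroreflexSensitivity

logger = logging.getLogger("cerauto.pipeline")

__all__ = ["run_epoch", "run_cohort", "ANS_METRICS", "CA_METRICS"]

#: Autonomic columns used in cohort correlation / mixed-model tables.
ANS_METRICS = [
    "sdnn_ms", "rmssd_ms", "meannn_ms", "pnn20_pct", "pnn50_pct",
    "lfn", "hfn", "lf_hf", "xbrs_ms_per_mmHg", "jsd_sym", "jsd_diam",
    "apen", "sampen", "fuzzyen", "msen",
]
#: Cerebral-autoregulation columns.
CA_METRICS = ["ps_vlf_deg", "gain_vlf", "coh_vlf", "ps_bf_deg", "gain_bf", "coh_bf"]

MIN_EPOCH_S = 120.0
MIN_TFA_S = SEGMENT_SAMPLES / 4.0  # one Welch window of the 4 Hz series


def _flag(row: dict, metric: str, reason: str) -> None:
    row.setdefault("flags", {})[metric] = reason


def run_epoch(rec: Recording, epoch: Epoch, participant: str = "") -> dict:
    """Analyse one epoch of a recording into a flat metrics row (dict)."""
    row: dict = {
        "participant": participant,
        "epoch": epoch.label,
        "flags": {},
        "excluded": False,
    }
    try:
        sub = rec.slice(epoch.start_s, epoch.end_s)
    except InsufficientDataError:
        row["excluded"] = True
        _flag(row, "epoch", "empty epoch slice")
        return row
    duration = sub.duration

    abp, n_art = preprocess.remove_artifacts(sub["abp"])
    row["abp_artifacts"] = n_art
    row["mean_abp_mmHg"] = float(abp.values.mean())

    # --- summary physiology -------------------------------------------------
    try:
        hr = preprocess.estimate_hr_fft(abp)
        row["hr_bpm"] = hr.bpm
        if hr.band_edge:
            _flag(row, "hr_bpm", "spectral maximum at band edge")
    except InsufficientDataError as exc:
        row["hr_bpm"] = np.nan
        _flag(row, "hr_bpm", str(exc))

    etco2 = sub.get("etco2")
    resp_rate = np.nan
    if etco2 is not None:
        try:
            est = preprocess.estimate_resp_rate(etco2, target_bpm=epoch.target_bpm)
            resp_rate = est.bpm
            row["resp_rate_bpm"] = est.bpm
            row["compliant"] = est.compliant
            if est.compliant is False:
                row["excluded"] = True
                _flag(row, "resp_rate_bpm", "non-compliant with paced rate (+/-1 bpm)")
            et_vals = preprocess.end_tidal_values(etco2)
            row["mean_etco2_mmHg"] = float(et_vals.values.mean())
        except (InsufficientDataError, NoBeatsError) as exc:
            row["resp_rate_bpm"] = np.nan
            row["mean_etco2_mmHg"] = np.nan
            _flag(row, "resp_rate_bpm", str(exc))
    else:
        row["resp_rate_bpm"] = np.nan
        row["mean_etco2_mmHg"] = np.nan
        _flag(row, "resp_rate_bpm", "etco2 channel absent")

    # --- beats from ABP -----------------------------------------------------
    try:
        sap = preprocess.detect_systolic_peaks(abp)
    except NoBeatsError as exc:
        _flag(row, "beats", str(exc))
        for m in CA_METRICS + ["xbrs_ms_per_mmHg", "jsd_sym", "jsd_diam"]:
            row[m] = np.nan
        return row
    row["n_beats"] = sap.n

    # --- transfer function analysis ----------------------------------------
    cbv = sub.get("cbv")
    if cbv is not None:
        row["mean_cbv_cm_s"] = float(cbv.values.mean())
    if cbv is None:
        for m in CA_METRICS:
            row[m] = np.nan
        _flag(row, "tfa", "cbv channel absent; TFA skipped")
    elif duration < MIN_TFA_S:
        for m in CA_METRICS:
            row[m] = np.nan
        _flag(row, "tfa", f"epoch shorter than one TFA window ({MIN_TFA_S:.1f} s)")
    else:
        cbv_clean, _ = preprocess.remove_artifacts(cbv)
        try:
            if epoch.label == "baseline":
                band = bf_band(spontaneous_stats=(resp_rate if np.isfinite(resp_rate) else 15.0, 2.0))
            else:
                band = bf_band(resp_bpm=float(epoch.label))
            abp4 = preprocess.beat_average_resample(abp, sap)
            cbv4 = preprocess.beat_average_resample(cbv_clean, sap)
            n = min(abp4.n, cbv4.n)
            abp4.values, cbv4.values = abp4.values[:n], cbv4.values[:n]
            res = TransferFunctionAnalysis(abp4, cbv4).fit(bands=[VLF_BAND, band])
            for key, b in (("vlf", VLF_BAND), ("bf", band)):
                m = res.band(b)
                row[f"ps_{key}_deg"] = m.ps_deg
                row[f"gain_{key}"] = m.gain
                row[f"coh_{key}"] = m.coherence
                row[f"n_bins_{key}"] = m.n_bins_used
                if not m.defined:
                    _flag(row, f"ps_{key}_deg", "all bins excluded by coherence gating")
            row["tfa_n_windows"] = res.spectral.n_windows
        except (InsufficientDataError, ValueError) as exc:
            for m in CA_METRICS:
                row[m] = np.nan
            _flag(row, "tfa", str(exc))

    # --- HRV from ECG -------------------------------------------------------
    ecg = sub.get("ecg")
    hrv_keys = ["sdnn_ms", "rmssd_ms", "meannn_ms", "pnn20_pct", "pnn50_pct",
                "lf_ms2", "hf_ms2", "lfn", "hfn", "lf_hf",
                "apen", "sampen", "fuzzyen", "msen"]
    if ecg is None:
        for m in hrv_keys:
            row[m] = np.nan
        _flag(row, "hrv", "ecg channel absent")
    elif duration < MIN_EPOCH_S:
        for m in hrv_keys:
            row[m] = np.nan
        _flag(row, "hrv", f"epoch shorter than {MIN_EPOCH_S:.0f} s")
    else:
        try:
            rr_ecg = preprocess.detect_r_peaks(ecg)
            hrv_res = HRV(rr_ecg).fit()
            row.update(hrv_res.metrics.to_dict())
        except (NoBeatsError, InsufficientDataError) as exc:
            for m in hrv_keys:
                row[m] = np.nan
            _flag(row, "hrv", str(exc))

    # --- xBRS and JSD from ABP-derived pulse intervals ----------------------
    if duration < MIN_EPOCH_S or sap.n < 12:
        row["xbrs_ms_per_mmHg"] = row["jsd_sym"] = row["jsd_diam"] = np.nan
        _flag(row, "xbrs", f"epoch shorter than {MIN_EPOCH_S:.0f} s")
    else:
        pi = preprocess.pulse_intervals(sap, anchor="end")
        try:
            bx = BaroreflexSensitivity(pi, sap).fit()
            row["xbrs_ms_per_mmHg"] = bx.result.xbrs_ms_per_mmHg
            row["xbrs_delay_mode_s"] = bx.result.delay_mode_s
            row["xbrs_n_windows"] = bx.result.n_windows_used
            if not bx.result.defined:
                _flag(row, "xbrs_ms_per_mmHg", "no window passed acceptance")
        except InsufficientDataError as exc:
            row["xbrs_ms_per_mmHg"] = np.nan
            _flag(row, "xbrs_ms_per_mmHg", str(exc))
        # JSD pairs the interval ending at beat n+1 with SAP at beat n: a
        # pressure change drives the subsequent interval.
        from .signals import BeatSeries

        sap_for_jsd = BeatSeries(sap.times[1:], sap.values[:-1])
        pi_for_jsd = BeatSeries(pi.times, pi.values)
        jres = JointSymbolicDynamics(pi_for_jsd, sap_for_jsd).fit()
        row["jsd_sym"] = jres.jsd_sym
        row["jsd_diam"] = jres.jsd_diam

    logger.info(
        "epoch %s/%s: beats=%s tfa_windows=%s flags=%d",
        participant, epoch.label, row.get("n_beats"), row.get("tfa_n_windows"),
        len(row["flags"]),
    )
    return row


def _median_iqr(s: pd.Series) -> str:
    s = s.dropna()
    if s.empty:
        return "NA"
    q1, q3 = s.quantile([0.25, 0.75])
    return f"{s.median():.3g} ± {q3 - q1:.3g}"


def run_cohort(manifest: Manifest, out_dir) -> dict:
    """Run every manifest epoch and write cohort tables.

    Writes ``metrics.csv`` (raw per-epoch rows), ``summary.csv`` (median +/-
    IQR per condition with Friedman / Kendall / Wilcoxon results),
    ``spearman_<condition>.csv`` matrices, ``lmm.csv`` (mixed-model table per
    CA metric), and ``exclusions.log``.
    """
    if not manifest.entries:
        raise ValueError("empty manifest")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    exclusions = []
    for entry in manifest.entries:
        rec = read_recording(entry.path)
        for epoch in entry.epochs:
            row = run_epoch(rec, epoch, participant=entry.participant)
            if row["excluded"]:
                exclusions.append(
                    f"{entry.participant}\t{epoch.label}\t{'; '.join(row['flags'].values())}"
                )
            rows.append(row)
    metrics = pd.DataFrame(rows)
    flags_col = metrics.pop("flags").apply(json.dumps)
    metrics["flags"] = flags_col
    metrics.to_csv(out / "metrics.csv", index=False)
    (out / "exclusions.log").write_text("\n".join(exclusions) + ("\n" if exclusions else ""))

    usable = metrics[~metrics["excluded"]]
    conditions = ["6", "10", "15"]
    metric_cols = [c for c in metrics.columns
                   if c in set(ANS_METRICS) | set(CA_METRICS)
                   | {"mean_abp_mmHg", "mean_cbv_cm_s", "hr_bpm", "mean_etco2_mmHg"}]

    n_participants = usable["participant"].nunique()
    summary_rows = []
    tests = {}
    for col in metric_cols:
        wide = usable.pivot_table(index="participant", columns="epoch", values=col,
                                  aggfunc="first")
        srow = {"metric": col}
        for cond in ["baseline", *conditions]:
            srow[cond] = _median_iqr(wide[cond]) if cond in wide else "NA"
        if n_participants >= 3 and all(c in wide for c in conditions):
            table = wide[conditions].dropna()
            if table.shape[0] >= 3:
                fr = cohort_stats.friedman_test(table)
                srow["friedman_chi2"] = fr.chi2
                srow["friedman_p"] = fr.p
                srow["kendalls_w"] = cohort_stats.kendalls_w(table)
                post = cohort_stats.wilcoxon_posthoc(table)
                srow["posthoc"] = "; ".join(
                    f"{r['pair']}: p={r['p']:.3g}{'*' if r['significant'] else ''}"
                    for _, r in post.iterrows()
                )
                tests[col] = {"friedman": fr, "posthoc": post}
        summary_rows.append(srow)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.csv", index=False)

    # per-condition Spearman matrices (ANS vs CA)
    for cond in ["baseline", *conditions]:
        sub = usable[usable["epoch"] == cond]
        ans_cols = [c for c in ANS_METRICS if c in sub]
        ca_cols = [c for c in CA_METRICS if c in sub]
        if len(sub) >= 10 and ans_cols and ca_cols:
            r, _p = cohort_stats.spearman_matrix(sub[ans_cols], sub[ca_cols])
            r.to_csv(out / f"spearman_{cond}.csv")

    # mixed models: each CA metric explained by one ANS metric + respiratory covariates
    lmm_rows = []
    lmm_data = usable[usable["epoch"].isin(conditions)].copy()
    if not lmm_data.empty:
        lmm_data["resp_rate"] = lmm_data["epoch"].astype(float)
        lmm_data = lmm_data.rename(columns={"mean_etco2_mmHg": "etco2"})
        for ca in CA_METRICS:
            for ans_metric in ANS_METRICS:
                if ca not in lmm_data or ans_metric not in lmm_data:
                    continue
                spec = cohort_stats.LMMSpec(response=ca, ans_metric=ans_metric)
                try:
                    res = cohort_stats.fit_lmm(lmm_data, spec)
                except (ValueError, KeyError, np.linalg.LinAlgError):
                    continue
                for _, r in res.iterrows():
                    lmm_rows.append({"ca_metric": ca, "ans_metric": ans_metric, **r})
    pd.DataFrame(lmm_rows).to_csv(out / "lmm.csv", index=False)

    return {"metrics": metrics, "summary": summary, "tests": tests,
            "n_excluded": len(exclusions)}
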