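"""Relating per-trial volley size to behavioural performance.

Trials that at least reached the active-movement phase (success and
short-hold errors) are scored by the mean z-scored volley area in two
assessment windows — dynamic (300 ms from EMG onset, which holds exactly
three stimuli at 10 Hz stimulation) and static (Delay ∪ Active Hold) —
then split into tertiles by window mean.  Ten behavioural measures are
compared between the large- and small-tertile trials with paired t-tests
across the volley population.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import Session
from .epochs import DIRECTION_SIGN, EpochSegmentation, _smooth_rectified
from .modulation import safe_ttest_rel
from .filters import lowpass

log = logging.getLogger(__name__)

ANALYSED_OUTCOMES = ("perfect", "success", "short_hold")
DYNAMIC_WINDOW_S = 0.3
#: Behavioural measures; the flagged subset is z-normalised per recording day.
MEASURES = ("reaction_time", "ah_torque_mean", "ah_torque_sd", "peak_speed",
            "peak_speed_latency", "peak_accel", "peak_accel_latency",
            "ah_emg_mean", "ah_emg_sd", "success")
DAY_NORMALIZED = ("reaction_time", "ah_torque_mean", "ah_torque_sd",
                  "peak_speed", "peak_accel", "ah_emg_mean", "ah_emg_sd")


def window_mean_adv(measures: pd.DataFrame, seg: EpochSegmentation,
                    window: str,
                    dynamic_s: float = DYNAMIC_WINDOW_S) -> Optional[float]:
    """Mean z-area of this trial's stimuli in the assessment window.

    ``dynamic`` = [EMG onset, EMG onset + 300 ms); ``static`` = Delay ∪ AH.
    Returns None (trial excluded, logged) when the window holds no
    stimulus or the needed epochs are missing.
    """
    trial = measures[measures.trial_id == seg.trial_id]
    t = trial["stim_time"].to_numpy()
    if window == "dynamic":
        if seg.emg_onset is None:
            return None
        m = (t >= seg.emg_onset) & (t < seg.emg_onset + dynamic_s)
    elif window == "static":
        if seg.delay is None or seg.ah is None:
            return None
        m = ((t >= seg.delay[0]) & (t < seg.delay[1])
             | (t >= seg.ah[0]) & (t < seg.ah[1]))
    else:
        raise ValueError("window must be 'dynamic' or 'static'")
    if not m.any():
        log.info("trial %d: no stimuli in %s window", seg.trial_id, window)
        return None
    return float(trial["z_area"].to_numpy()[m].mean())


def tertile_split(values) -> np.ndarray:
    """Labels small/intermediate/large by ascending thirds.

    Extreme groups get ``n // 3`` trials each (kept equal-sized for
    pairing); any remainder goes to the intermediate group.  Ties are
    broken by input order (stable sort).
    """
    v = np.asarray(values, float)
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 trials for a tertile split")
    order = np.argsort(v, kind="stable")
    k = n // 3
    labels = np.array(["intermediate"] * n, dtype=object)
    labels[order[:k]] = "small"
    labels[order[-k:]] = "large"
    if np.unique(v).size == 1:
        log.warning("all window means equal; tertile split is order-based")
    return labels


def compute_measures(trial, torque, emg, seg: EpochSegmentation) -> dict:
    """The ten behavioural performance measures for one trial.

    Speed is the derivative of <5 Hz filtered torque, acceleration its
    second derivative; latencies are relative to movement onset; EMG
    statistics use the rectified, 10 Hz-smoothed agonist during AH.
    Missing AH leaves the AH-dependent measures NaN.
    """
    out = {m: np.nan for m in MEASURES}
    if seg.torque_onset is not None:
        out["reaction_time"] = seg.torque_onset - trial.cue_on
    f = lowpass(torque, 5.0)
    sign = DIRECTION_SIGN[trial.direction]
    if seg.torque_onset is not None and seg.torque_offset is not None:
        j0, j1 = f.index_at(seg.torque_onset), f.index_at(seg.torque_offset)
        if j1 > j0 + 2:
            d = np.gradient(f.samples[j0:j1]) * f.rate * sign
            pk = int(np.argmax(d))
            out["peak_speed"] = float(d[pk])
            out["peak_speed_latency"] = pk / f.rate
            a = np.gradient(d) * f.rate
            pa = int(np.argmax(a))
            out["peak_accel"] = float(a[pa])
            out["peak_accel_latency"] = pa / f.rate
    if seg.ah is not None:
        tq = f.slice(*seg.ah).samples * sign
        out["ah_torque_mean"] = float(np.mean(tq))
        out["ah_torque_sd"] = float(np.std(tq, ddof=1))
        em = _smooth_rectified(emg, 10.0).slice(*seg.ah).samples
        out["ah_emg_mean"] = float(np.mean(em))
        out["ah_emg_sd"] = float(np.std(em, ddof=1))
    return out


def day_normalize(table: pd.DataFrame,
                  columns=DAY_NORMALIZED) -> pd.DataFrame:
    """z-normalise the stated measure subset within each recording day."""
    out = table.copy()
    for col in columns:
        v = out[col].to_numpy(float)
        sd = np.nanstd(v, ddof=1)
        if sd > 0:
            out[col] = (v - np.nanmean(v)) / sd
    return out


def build_performance_table(session: Session, measures: pd.DataFrame,
                            segmentations: dict, outcomes: dict,
                            agonists: dict,
                            normalize: bool = True) -> pd.DataFrame:
    """Per-trial window means, tertile labels and behavioural measures.

    Only trials completed to the AM phase (success, perfect, short hold)
    are analysed; wrong-direction and no-movement trials are excluded.
    Tertiles are assigned per direction and window.
    """
    torque = session.signals["torque"]
    rows = []
    for trial in session.trials:
        out = outcomes.get(trial.trial_id)
        if out not in ANALYSED_OUTCOMES:
            continue
        seg = segmentations[trial.trial_id]
        emg = session.signals[agonists[trial.direction]]
        row = {"trial_id": trial.trial_id, "direction": trial.direction,
               "outcome": out,
               "dynamic_mean": window_mean_adv(measures, seg, "dynamic"),
               "static_mean": window_mean_adv(measures, seg, "static")}
        row.update(compute_measures(trial, torque, emg, seg))
        row["success"] = float(out in ("perfect", "success"))
        rows.append(row)
    table = pd.DataFrame(rows)
    if normalize and len(table):
        table = day_normalize(table)
    for window in ("dynamic", "static"):
        col = f"{window}_tertile"
        table[col] = None
        for direction in ("flexion", "extension"):
            m = (table.direction == direction) \
                & table[f"{window}_mean"].notna()
            if m.sum() >= 3:
                table.loc[m, col] = tertile_split(
                    table.loc[m, f"{window}_mean"].to_numpy())
    return table


def tertile_measure_means(table: pd.DataFrame, window: str,
                          direction: str) -> pd.DataFrame:
    """Per-measure means in the small and large tertiles for one volley."""
    col = f"{window}_tertile"
    sub = table[table.direction == direction]
    rows = []
    for measure in MEASURES:
        small = sub.loc[sub[col] == "small", measure].mean()
        large = sub.loc[sub[col] == "large", measure].mean()
        rows.append({"measure": measure, "small": small, "large": large})
    return pd.DataFrame(rows)


def contrast_tertiles(per_adv: pd.DataFrame) -> pd.DataFrame:
    """Paired t-test of large vs small tertile means across volleys.

    ``per_adv`` rows: (adv_id, measure, small, large); the pairing unit is
    the volley, matching the study's n = 77 design.
    """
    out = []
    for measure, grp in per_adv.groupby("measure", sort=False):
        s = grp["small"].to_numpy(float)
        l = grp["large"].to_numpy(float)
        ok = np.isfinite(s) & np.isfinite(l)
        if ok.sum() < 2:
            raise ValueError(f"measure {measure!r}: fewer than 2 volleys")
        t, p = safe_ttest_rel(l[ok], s[ok])
        out.append({"measure": measure, "t": float(t), "p": float(p),
                    "df": int(ok.sum() - 1),
                    "mean_small": float(np.mean(s[ok])),
                    "mean_large": float(np.mean(l[ok]))})
    return pd.DataFrame(out)
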