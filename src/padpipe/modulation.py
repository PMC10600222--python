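"""Epoch- and event-dependent compilation of normalised volley areas.

Per-stimulus z-scored areas from perfect trials are averaged per
behavioural epoch and per direction (the per-volley modulation profile),
summarised across the volley population with cumulative-sum curves, and
aligned to behavioural events with a 0.2 s bin moved in 0.1 s steps over
[−1, 1] s.  Contrasts follow the study's statistics: paired two-tailed
t-tests against the Rest level (zero by construction) with Bonferroni
correction, a rank-based many-to-one permutation test standing in for
Steel's procedure, and a paired flexion-vs-extension comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import MOVEMENT_EPOCHS

EVENT_NAMES = ("Rest", "Delay", "AM", "AH", "PM",
               "emg_onset", "emg_offset", "torque_onset", "torque_offset")

#: Bonferroni correction sizes as printed in the study's contrasts.
DEFAULT_CORRECTIONS = {"epochs": 4, "static": 2, "events": 11}


@dataclass
class ModulationProfile:
    """Per-volley modulation summary: epoch means and event-aligned series."""

    adv_id: object
    epoch_table: pd.DataFrame                 # direction, epoch, mean_z, n
    event_tables: dict = field(default_factory=dict)

    def epoch_row(self, direction: str) -> dict:
        sub = self.epoch_table[self.epoch_table.direction == direction]
        return {r.epoch: r.mean_z for r in sub.itertuples()}


def compile_epoch_modulation(measures: pd.DataFrame,
                             perfect_only: bool = True,
                             adv_id: object = 0) -> ModulationProfile:
    """Mean z-area per behavioural epoch and direction.

    Each stimulus of a perfect trial belongs to exactly one epoch cell
    (half-open interval assignment upstream); epochs with zero stimuli
    are simply absent from the table.
    """
    df = measures
    if perfect_only:
        df = df[df["perfect"]]
    df = df[df["epoch"].notna()]
    rows = []
    for (direction, epoch), grp in df.groupby(["direction", "epoch"]):
        rows.append({"direction": direction, "epoch": epoch,
                     "mean_z": float(grp["z_area"].mean()),
                     "n": int(len(grp))})
    table = pd.DataFrame(rows, columns=["direction", "epoch", "mean_z", "n"])
    return ModulationProfile(adv_id, table)


def cumulative_sum_profile(values) -> tuple[np.ndarray, int]:
    """Cumulative sum of ascending-sorted values and its argmin.

    Visualises the bias of a distribution of per-volley epoch means: an
    all-negative-biased sample drives the curve's minimum to the end.
    """
    v = np.sort(np.asarray(values, float))
    if v.size == 0:
        raise ValueError("empty input")
    curve = np.cumsum(v)
    return curve, int(np.argmin(curve))


def compile_event_modulation(measures: pd.DataFrame,
                             event_times: dict,
                             bin_s: float = 0.2, step_s: float = 0.1,
                             span: tuple = (-1.0, 1.0)) -> pd.DataFrame:
    """Event-aligned mean z-area in a sliding peri-event bin.

    ``event_times`` maps trial id to the alignment event's time; for each
    event occurrence every stimulus whose time relative to the event falls
    in a bin is compiled.  Defaults (0.2 s bin, 0.1 s step, [−1, 1] s span)
    give 19 bins.
    """
    if bin_s <= 0 or step_s <= 0:
        raise ValueError("bin and step must be positive")
    centers = np.arange(span[0] + bin_s / 2, span[1] - bin_s / 2 + 1e-9,
                        step_s)
    times = measures["stim_time"].to_numpy()
    z = measures["z_area"].to_numpy()
    sums = np.zeros(centers.size)
    counts = np.zeros(centers.size, dtype=int)
    for ev in event_times.values():
        if ev is None or not np.isfinite(ev):
            continue
        rel = times - ev
        for i, c in enumerate(centers):
            m = (rel >= c - bin_s / 2) & (rel < c + bin_s / 2)
            sums[i] += z[m].sum()
            counts[i] += int(m.sum())
    mean = np.divide(sums, counts, out=np.full_like(sums, np.nan),
                     where=counts > 0)
    return pd.DataFrame({"bin_center": centers, "mean_z": mean, "n": counts})


def event_profile_stats(per_adv: pd.DataFrame,
                        confidence: float = 0.95) -> pd.DataFrame:
    """Population mean and t-based CI per bin across volleys.

    ``per_adv`` has one row per volley, one column per bin center.
    """
    vals = per_adv.to_numpy(float)
    n = vals.shape[0]
    mean = np.nanmean(vals, axis=0)
    sem = np.nanstd(vals, axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + confidence / 2, n - 1)
    return pd.DataFrame({"bin_center": per_adv.columns.astype(float),
                         "mean": mean, "ci_lo": mean - tcrit * sem,
                         "ci_hi": mean + tcrit * sem, "n": n})


def safe_ttest_1samp(values: np.ndarray, popmean: float = 0.0
                     ) -> tuple[float, float]:
    """One-sample t robust to zero variance (t = 0, p = 1 at the mean)."""
    v = np.asarray(values, float)
    if np.std(v) == 0:
        return (0.0, 1.0) if np.isclose(np.mean(v), popmean) \
            else (np.inf, 0.0)
    t, p = stats.ttest_1samp(v, popmean)
    return float(t), float(p)


def safe_ttest_rel(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired t robust to identical samples (t = 0, p = 1)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    return safe_ttest_1samp(d, 0.0)


def _profile_matrix(profiles: pd.DataFrame, direction: str) -> pd.DataFrame:
    sub = profiles[profiles.direction == direction]
    return sub.set_index("adv_id")[list(MOVEMENT_EPOCHS)]


def epoch_contrasts(profiles: pd.DataFrame,
                    corrections: Optional[dict] = None) -> dict:
    """The study's epoch-level statistics on a volley population.

    ``profiles`` rows: (adv_id, direction, Delay, AM, AH, PM) mean z-areas.
    Returns per-epoch paired t vs the Rest level (0) with Bonferroni
    correction, the static-epoch (Delay+AH) aggregate per direction, and
    the paired flexion-vs-extension contrast on all epoch cells.
    """
    corrections = dict(DEFAULT_CORRECTIONS, **(corrections or {}))
    n_adv = profiles.adv_id.nunique()
    if n_adv < 2:
        raise ValueError("need at least 2 volleys for contrasts")
    out = {"per_epoch": {}, "static": {}, "direction": {}}
    size = corrections["epochs"]
    for direction in ("flexion", "extension"):
        mat = _profile_matrix(profiles, direction)
        for epoch in MOVEMENT_EPOCHS:
            v = mat[epoch].dropna().to_numpy()
            t, p = safe_ttest_1samp(v)
            out["per_epoch"][(direction, epoch)] = {
                "mean": float(np.mean(v)), "t": float(t), "df": v.size - 1,
                "p": float(p), "p_bonf": float(min(p * size, 1.0))}
    fl = _profile_matrix(profiles, "flexion")
    ex = _profile_matrix(profiles, "extension")
    size = corrections["static"]
    static = {}
    for direction, mat in (("flexion", fl), ("extension", ex)):
        agg = np.concatenate([mat["Delay"].to_numpy(), mat["AH"].to_numpy()])
        t, p = safe_ttest_1samp(agg)
        static[direction] = {"mean": float(np.mean(agg)), "t": float(t),
                             "df": agg.size - 1, "p": float(p),
                             "p_bonf": float(min(p * size, 1.0))}
        out["static"][direction] = static[direction]
    agg_f = np.concatenate([fl["Delay"].to_numpy(), fl["AH"].to_numpy()])
    agg_e = np.concatenate([ex["Delay"].to_numpy(), ex["AH"].to_numpy()])
    t, p = safe_ttest_rel(agg_f, agg_e)
    out["static"]["flexion_vs_extension"] = {"t": float(t), "p": float(p),
                                             "df": agg_f.size - 1}
    all_f = fl.to_numpy().ravel()
    all_e = ex.to_numpy().ravel()
    t, p = safe_ttest_rel(all_f, all_e)
    out["direction"] = {"mean_flexion": float(np.mean(all_f)),
                        "mean_extension": float(np.mean(all_e)),
                        "t": float(t), "p": float(p), "df": all_f.size - 1}
    return out


def _mw_z(pooled_ranks: np.ndarray, n1: int, n2: int,
          idx1: np.ndarray) -> float:
    r1 = pooled_ranks[idx1].sum()
    u = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return (u - mu) / sd


def steel_test(samples: dict, control: str = "Rest",
               n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Rank-based many-to-one comparison with permutation p-values.

    Each non-control group is compared with the control by a standardised
    Mann-Whitney statistic; family-wise adjusted p-values come from the
    permutation distribution of the maximal |statistic| (labels permuted
    jointly across all groups), which by construction controls the
    many-to-one multiplicity the original tabulated procedure addresses.
    """
    if control not in samples:
        raise ValueError(f"control group {control!r} missing")
    names = [k for k in samples if k != control]
    groups = [np.asarray(samples[control], float)] + \
             [np.asarray(samples[k], float) for k in names]
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    bounds = np.cumsum([0] + sizes)
    n_c = sizes[0]

    def pairwise_z(values: np.ndarray, i: int) -> float:
        pair = np.concatenate([values[bounds[0]:bounds[1]],
                               values[bounds[i + 1]:bounds[i + 2]]])
        pr = stats.rankdata(pair)
        return _mw_z(pr, n_c, sizes[i + 1], np.arange(n_c))

    obs = np.array([pairwise_z(pooled, i) for i in range(len(names))])
    rng = np.random.default_rng(seed)
    count = np.zeros(len(names))
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        mx = max(abs(pairwise_z(perm, i)) for i in range(len(names)))
        count += (mx >= np.abs(obs) - 1e-12)
    p_adj = (count + 1) / (n_perm + 1)
    return pd.DataFrame({"epoch": names, "z": obs, "p_adj": p_adj})
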