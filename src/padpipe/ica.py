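"""Independent-component decomposition of epoch-modulation patterns.

The per-volley epoch-mean profiles form a matrix with one row per
(volley, direction) — flexion block stacked on the extension block — and
one column per movement epoch (Delay, AM, AH, PM).  Fixed-point
negentropy ICA (tanh contrast, symmetric decorrelation) factorises it
into epoch patterns (components) and per-row mixing weights; bootstrap
resampling of rows yields percentile confidence intervals after aligning
each bootstrap solution to the reference solution by maximal absolute
correlation.  With four epoch columns at most four components are
extractable.

Scale and sign indeterminacies are fixed by normalising each component to
unit norm (amplitude carried by the weights) and orienting its largest
entry positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA

from .core import MOVEMENT_EPOCHS

log = logging.getLogger(__name__)

#: Representative epoch durations (s) for reconstructed time courses.
EPOCH_DURATIONS = {"Delay": 0.5, "AM": 0.2, "AH": 1.0, "PM": 0.2}


@dataclass
class ICAResult:
    """Components (rows, unit norm), per-row mixing weights and CIs."""

    matrix: np.ndarray                 # (2·n_adv) × n_epoch input
    components: np.ndarray             # n_comp × n_epoch
    weights: np.ndarray                # (2·n_adv) × n_comp
    mean: np.ndarray                   # column means removed before ICA
    n_flexion_rows: int
    ci_components: Optional[np.ndarray] = None     # n_comp × n_epoch × 2
    ci_weight_medians: Optional[np.ndarray] = None  # n_comp × 2
    n_boot: int = 0
    n_dropped: int = 0
    adv_ids: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def median_weights(self, direction: Optional[str] = None) -> np.ndarray:
        if direction == "flexion":
            w = self.weights[:self.n_flexion_rows]
        elif direction == "extension":
            w = self.weights[self.n_flexion_rows:]
        else:
            w = self.weights
        return np.median(w, axis=0)


def build_matrix(profiles: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Stack per-volley epoch means: flexion block over extension block.

    Volleys missing any epoch cell in either direction are excluded (and
    logged), so every retained volley contributes exactly two rows.
    """
    cols = list(MOVEMENT_EPOCHS)
    wide = profiles.pivot_table(index="adv_id", columns="direction",
                                values=cols, sort=True)
    keep = []
    for adv in wide.index:
        vals = [wide.loc[adv].get((c, d)) for c in cols
                for d in ("flexion", "extension")]
        if all(v is not None and np.isfinite(v) for v in vals):
            keep.append(adv)
        else:
            log.warning("volley %r lacks epoch cells; excluded", adv)
    if not keep:
        raise ValueError("no volley has complete epoch profiles")
    flex = np.array([[wide.loc[a][(c, "flexion")] for c in cols]
                     for a in keep])
    ext = np.array([[wide.loc[a][(c, "extension")] for c in cols]
                    for a in keep])
    return np.vstack([flex, ext]), keep


def run_ica(matrix: np.ndarray, n_comp: int, seed: int) -> ICAResult:
    """Fixed-point ICA of the epoch-mean matrix, deterministic per seed."""
    X = np.asarray(matrix, float)
    n_rows, n_cols = X.shape
    if n_comp > n_cols:
        raise ValueError(f"cannot extract {n_comp} components from "
                         f"{n_cols} epoch columns")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_comp > rank:
        log.warning("matrix rank %d < requested %d components; reducing",
                    rank, n_comp)
        n_comp = rank
    ica = FastICA(n_components=n_comp, algorithm="parallel", fun="logcosh",
                  whiten="unit-variance", max_iter=1000, tol=1e-6,
                  random_state=seed)
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(X)      # rows × n_comp
    mixing = ica.mixing_                    # n_cols × n_comp
    comps = mixing.T.astype(float)
    weights = sources.astype(float)
    # unit-norm components, amplitude carried by the weights
    norms = np.linalg.norm(comps, axis=1)
    norms[norms == 0] = 1.0
    comps = comps / norms[:, None]
    weights = weights * norms[None, :]
    # orient the largest-|entry| of each component positive
    for k in range(comps.shape[0]):
        if comps[k, np.argmax(np.abs(comps[k]))] < 0:
            comps[k] = -comps[k]
            weights[:, k] = -weights[:, k]
    # stable order: by descending weight energy
    order = np.argsort(-np.sum(weights ** 2, axis=0), kind="stable")
    return ICAResult(X, comps[order], weights[:, order],
                     ica.mean_.astype(float), n_rows // 2)


def align_components(reference: np.ndarray, comps: np.ndarray,
                     weights: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                   np.ndarray]:
    """Greedy sign/permutation alignment by maximal |Pearson correlation|.

    Returns the reordered, sign-flipped components and weights along with
    the matched |correlation| per reference component.
    """
    def _similarity(a: np.ndarray, b: np.ndarray) -> float:
        # Pearson correlation; cosine similarity when either profile is
        # (near-)constant, where correlation is undefined
        if np.std(a) < 1e-12 * max(np.abs(a).max(), 1.0) \
                or np.std(b) < 1e-12 * max(np.abs(b).max(), 1.0):
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            return float(a @ b / (na * nb)) if na > 0 and nb > 0 else 0.0
        return float(np.corrcoef(a, b)[0, 1])

    k = reference.shape[0]
    cor = np.zeros((k, comps.shape[0]))
    for i in range(k):
        for j in range(comps.shape[0]):
            c = _similarity(reference[i], comps[j])
            cor[i, j] = 0.0 if np.isnan(c) else c
    out_c = np.zeros_like(reference)
    out_w = np.zeros((weights.shape[0], k))
    matched = np.zeros(k)
    used: set = set()
    done: set = set()
    for _ in range(k):
        masked = np.abs(cor).copy()
        if used:
            masked[:, list(used)] = -np.inf
        if done:
            masked[list(done), :] = -np.inf
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        done.add(i)
        sign = 1.0 if cor[i, j] >= 0 else -1.0
        out_c[i] = sign * comps[j]
        out_w[:, i] = sign * weights[:, j]
        matched[i] = abs(cor[i, j])
        used.add(j)
    return out_c, out_w, matched


def bootstrap_ci(matrix: np.ndarray, n_comp: int, n_boot: int = 1000,
                 seed: int = 0, min_match: float = 0.5,
                 ci: float = 0.95) -> ICAResult:
    """Bootstrap (rows, with replacement) percentile CIs for the ICA.

    Each replicate's solution is aligned to the reference before the
    per-entry 2.5/97.5 percentile bounds of components and of the median
    mixing weights are formed; replicates whose best match falls below
    ``min_match`` |correlation| are dropped and counted.
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    res = run_ica(matrix, n_comp, seed)
    rng = np.random.default_rng(seed)
    n = matrix.shape[0]
    comp_samples, med_samples = [], []
    dropped = 0
    for b in range(n_boot):
        rows = rng.integers(0, n, n)
        sub_seed = int(rng.integers(2 ** 31))
        try:
            rb = run_ica(matrix[rows], res.n_components, sub_seed)
        except Exception:       # non-convergence on a degenerate resample
            dropped += 1
            continue
        comps, weights, matched = align_components(
            res.components, rb.components, rb.weights)
        if (matched < min_match).any():
            dropped += 1
            continue
        comp_samples.append(comps)
        med_samples.append(np.median(weights, axis=0))
    if not comp_samples:
        raise ValueError("all bootstrap replicates failed alignment")
    lo, hi = 50 * (1 - ci), 50 * (1 + ci)
    comp_arr = np.stack(comp_samples)
    med_arr = np.stack(med_samples)
    res.ci_components = np.stack(
        [np.percentile(comp_arr, lo, axis=0),
         np.percentile(comp_arr, hi, axis=0)], axis=-1)
    res.ci_weight_medians = np.stack(
        [np.percentile(med_arr, lo, axis=0),
         np.percentile(med_arr, hi, axis=0)], axis=-1)
    res.n_boot = len(comp_samples)
    res.n_dropped = dropped
    return res


def reconstruct_timecourse(component: np.ndarray, median_weight: float,
                           fs: float = 100.0,
                           smooth_bins: int = 10) -> tuple[np.ndarray,
                                                           np.ndarray]:
    """Presumed modulation time course from one component.

    A square wave over the representative epoch durations (Delay 0.5 s,
    AM 0.2 s, AH 1 s, PM 0.2 s) with amplitude = component × median mixing
    weight, smoothed by a ``smooth_bins``-point moving average (0.1 s at
    100 points/s).  Returns (times, values); the default grid has
    (0.5+0.2+1+0.2)·100 = 190 points.
    """
    component = np.asarray(component, float)
    segs = []
    for val, epoch in zip(component, MOVEMENT_EPOCHS):
        n = int(round(EPOCH_DURATIONS[epoch] * fs))
        segs.append(np.full(n, val * median_weight))
    y = np.concatenate(segs)
    kernel = np.ones(smooth_bins) / smooth_bins
    y = np.convolve(y, kernel, mode="same")
    t = np.arange(y.size) / fs
    return t, y
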