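"""Univariate song-vs-speech contrast over the modulation plane.

The contrast is a paired (within-speaker) comparison per grid cell: a
one-sample t statistic on song-minus-speech differences whose null
distribution is built nonparametrically by random within-pair sign flips,
with Benjamini-Hochberg FDR applied jointly across all non-origin cells.
Peak extraction, per-society overlap counting and k-means clustering of
per-society statistical peaks summarize the resulting maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError, ParameterError
from .modspec import STMDataset

__all__ = [
    "StatMap",
    "PeakSet",
    "paired_permutation_map",
    "find_peaks",
    "society_overlap_map",
    "kmeans_stat_peaks",
    "pair_differences",
]

log = logging.getLogger(__name__)


@dataclass
class StatMap:
    """Per-cell paired t statistic, permutation p and FDR significance mask."""

    statistic: np.ndarray  # (n_spectral, n_temporal); NaN where undefined
    p: np.ndarray
    mask: np.ndarray  # boolean, FDR-significant
    spectral_axis: np.ndarray
    temporal_axis: np.ndarray
    alpha: float
    n_permutations: int
    n_pairs: int
    tail: str = "two"


def pair_differences(stm: STMDataset) -> tuple[np.ndarray, list[str]]:
    """Song-minus-speech row differences per speaker, in speaker order of
    first appearance."""
    meta = stm.meta
    speakers = list(dict.fromkeys(meta["speaker_id"]))
    diffs, kept = [], []
    for spk in speakers:
        rows = meta.index[meta["speaker_id"] == spk]
        cats = meta.loc[rows, "category"]
        if set(cats) != {"song", "speech"}:
            continue
        i_song = rows[cats == "song"][0]
        i_speech = rows[cats == "speech"][0]
        diffs.append(stm.X[i_song] - stm.X[i_speech])
        kept.append(spk)
    if not diffs:
        raise DataError("no complete song/speech pairs in dataset")
    return np.vstack(diffs), kept


def _t_from_signed_means(m: np.ndarray, ss: np.ndarray, n: int) -> np.ndarray:
    # t statistic from per-cell means, using the sign-flip invariance of the
    # sum of squares: var = (ss - n*m^2)/(n-1).
    var = (ss - n * m**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    return t


def paired_permutation_map(
    stm: STMDataset,
    n_perm: int = 10000,
    alpha: float = 0.001,
    seed: int = 0,
    exclude_origin: bool = True,
    _block: int = 500,
) -> StatMap:
    """Permutation contrast map of song vs speech.

    Per cell, the statistic is a one-sample t on within-speaker differences;
    the two-tailed p-value is the rank of |t| in the distribution obtained by
    randomly flipping the sign of each pair's difference (the add-one
    permutation p convention), and significance is Benjamini-Hochberg FDR at
    ``alpha`` across all valid cells jointly. Zero-variance cells (and the
    origin) are excluded and reported as NaN.
    """
    if n_perm < 100:
        raise ParameterError(f"n_perm must be >= 100, got {n_perm}")
    D, _ = pair_differences(stm)
    n = D.shape[0]
    if n < 2:
        raise DataError(f"need >= 2 pairs for a paired statistic, got {n}")

    ss = (D**2).sum(axis=0)
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    valid = sd > 0
    if exclude_origin:
        valid[stm.origin_index] = False
    n_invalid = int((~valid).sum())
    if n_invalid:
        log.info("excluding %d zero-variance/origin cells from the map", n_invalid)

    t_obs = np.full(D.shape[1], np.nan)
    # all-zero differences are a true null, not an undefined statistic
    t_obs[(sd == 0) & (mean == 0)] = 0.0
    t_obs[valid] = _t_from_signed_means(mean[valid], ss[valid], n)

    rng = np.random.default_rng(seed)
    Dv = D[:, valid]
    ssv = ss[valid]
    abs_obs = np.abs(t_obs[valid])
    count = np.zeros(valid.sum())
    done = 0
    while done < n_perm:
        b = min(_block, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(b, n))
        m = (signs @ Dv) / n
        t_perm = _t_from_signed_means(m, ssv[None, :], n)
        count += (np.abs(t_perm) >= abs_obs[None, :]).sum(axis=0)
        done += b
    p_valid = (1.0 + count) / (1.0 + n_perm)

    p = np.full(D.shape[1], np.nan)
    p[(sd == 0) & (mean == 0)] = 1.0
    p[valid] = p_valid
    mask = np.zeros(D.shape[1], dtype=bool)
    if valid.any():
        mask[valid] = multipletests(p_valid, alpha=alpha, method="fdr_bh")[0]

    shape = stm.shape2d
    return StatMap(
        statistic=t_obs.reshape(shape),
        p=p.reshape(shape),
        mask=mask.reshape(shape),
        spectral_axis=stm.spectral_axis,
        temporal_axis=stm.temporal_axis,
        alpha=alpha,
        n_permutations=n_perm,
        n_pairs=n,
    )


@dataclass
class PeakSet:
    """Local maxima of |statistic| inside the significant mask."""

    peaks: pd.DataFrame  # spectral_cyc_per_khz, temporal_hz, stat, sign
    group: str = "corpus"

    def __len__(self) -> int:
        return len(self.peaks)

    def coords(self) -> np.ndarray:
        return self.peaks[["spectral_cyc_per_khz", "temporal_hz"]].to_numpy()


def find_peaks(statmap: StatMap, sign: int = 1, min_separation: int = 1) -> PeakSet:
    """Ranked local maxima of ``sign * statistic`` within the FDR mask.

    ``min_separation`` is a Chebyshev distance in grid cells below which the
    weaker of two candidate peaks is suppressed. An empty mask yields an empty
    PeakSet.
    """
    if sign not in (-1, 1):
        raise ParameterError("sign must be +1 or -1")
    stat = statmap.statistic
    field = np.where(np.isfinite(stat), sign * stat, -np.inf)
    eligible = statmap.mask & (field > 0)
    if not eligible.any():
        return PeakSet(
            peaks=pd.DataFrame(columns=["spectral_cyc_per_khz", "temporal_hz", "stat", "sign"])
        )
    size = 2 * max(min_separation, 1) + 1
    local_max = field == ndimage.maximum_filter(field, size=size, mode="nearest")
    cand = np.argwhere(local_max & eligible)
    order = np.argsort(-field[cand[:, 0], cand[:, 1]])
    kept: list[np.ndarray] = []
    for idx in cand[order]:
        if all(np.max(np.abs(idx - k)) >= min_separation for k in kept):
            kept.append(idx)
    rows = [
        {
            "spectral_cyc_per_khz": float(statmap.spectral_axis[i]),
            "temporal_hz": float(statmap.temporal_axis[j]),
            "stat": float(stat[i, j]),
            "sign": sign,
        }
        for i, j in kept
    ]
    return PeakSet(peaks=pd.DataFrame(rows))


def _subset(stm: STMDataset, rows: np.ndarray) -> STMDataset:
    return STMDataset(
        X=stm.X[rows],
        spectral_axis=stm.spectral_axis,
        temporal_axis=stm.temporal_axis,
        meta=stm.meta.iloc[rows].reset_index(drop=True),
        grid=stm.grid,
    )


def society_overlap_map(
    stm: STMDataset,
    n_perm: int = 2000,
    alpha: float = 0.001,
    seed: int = 0,
    by: str = "fieldsite",
    corpus_map: StatMap | None = None,
) -> tuple[np.ndarray, StatMap, dict[str, StatMap]]:
    """Count, per cell, the groups whose own contrast map is significant with
    the corpus-level sign.

    Returns ``(counts, corpus_map, per_group_maps)``. Groups contributing a
    single pair cannot be tested and are skipped with a warning.
    """
    if by not in stm.meta.columns:
        raise ParameterError(f"unknown grouping column {by!r}")
    if corpus_map is None:
        corpus_map = paired_permutation_map(stm, n_perm=n_perm, alpha=alpha, seed=seed)
    corpus_sign = np.sign(np.nan_to_num(corpus_map.statistic))

    counts = np.zeros(stm.shape2d, dtype=int)
    per_group: dict[str, StatMap] = {}
    groups = sorted(stm.meta[by].unique())
    for gi, g in enumerate(groups):
        rows = np.flatnonzero((stm.meta[by] == g).to_numpy())
        sub = _subset(stm, rows)
        n_pairs = sub.meta["speaker_id"].nunique()
        if n_pairs < 2:
            log.warning("group %s has a single pair; skipped from overlap map", g)
            continue
        gmap = paired_permutation_map(sub, n_perm=n_perm, alpha=alpha, seed=seed + 1 + gi)
        per_group[g] = gmap
        agree = gmap.mask & (np.sign(np.nan_to_num(gmap.statistic)) == corpus_sign)
        counts += agree.astype(int)
    return counts, corpus_map, per_group


def kmeans_stat_peaks(
    per_group_peaks: list[PeakSet], k: int = 2, seed: int = 0, n_restarts: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """k-means on peak coordinates using (spectral, |temporal|).

    Absolute temporal modulation is used because vocalizations are symmetric
    between upward and downward sweeps, so +6.33 and -6.33 Hz peaks describe
    the same structure. Returns ``(centroids, assignments, points)`` with
    centroids sorted by descending spectral coordinate.
    """
    pts = [ps.coords() for ps in per_group_peaks if len(ps)]
    if not pts:
        raise ParameterError("no peaks supplied")
    points = np.vstack(pts)
    points = np.column_stack([points[:, 0], np.abs(points[:, 1])])
    if len(points) < k:
        raise ParameterError(f"{len(points)} peak points for k={k} clusters")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(points)
    order = np.argsort(-km.cluster_centers_[:, 0])
    centroids = km.cluster_centers_[order]
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return centroids, relabel[labels], points
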