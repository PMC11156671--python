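"""Listener-rating analyses and their linkage to the STM plane.

Ratings live on a 5-point speaking(-1)..singing(+1) scale. The central
construct is the per-speaker normalized difference score, bounded in
[-1, 1]: the ratio form (song - speech)/(|song| + |speech|) cell-wise for
nonnegative STM power, and the scale-width form (song - speech)/2 for the
signed ratings. Correlating the two across speakers maps which
modulation-plane regions drive listeners' judgments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decode import WilcoxonResult, wilcoxon_vs_chance
from .exceptions import DataError, ParameterError
from .modspec import STMDataset

__all__ = [
    "attach_metadata",
    "mean_ratings",
    "normalized_difference",
    "speaker_behavior_diffs",
    "stm_diff_matrix",
    "stm_behavior_corr_map",
    "decoding_behavior_corr",
    "rating_accuracy_wilcoxon",
    "CorrMap",
]

log = logging.getLogger(__name__)

_GROUP_KEYS = {
    "listener": "listener_id",
    "fieldsite": "fieldsite",
    "country": "country",
    "language_family": "language_family",
    "subregion": "subregion",
    "region": "region",
}


def attach_metadata(ratings: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Join stimulus metadata (speaker, category, group labels) onto a
    (listener_id, stimulus_id, rating) table via stimulus_id =
    '<speaker_id>_<category>'."""
    meta = meta.copy()
    meta["stimulus_id"] = meta["speaker_id"] + "_" + meta["category"]
    cols = ["stimulus_id", "speaker_id", "category"] + [
        c for c in _GROUP_KEYS.values() if c in meta.columns and c != "listener_id"
    ]
    return ratings.merge(meta[cols].drop_duplicates("stimulus_id"), on="stimulus_id", how="left")


def mean_ratings(table: pd.DataFrame, by: str = "listener", category: str | None = None) -> pd.DataFrame:
    """Mean rating per unit (listener, society, ...) and category.

    Trials with missing ratings (e.g. response timeouts) are excluded; units
    with no remaining trials are absent from the result and logged.
    """
    if by not in _GROUP_KEYS:
        raise ParameterError(f"unknown grouping {by!r}; expected one of {sorted(_GROUP_KEYS)}")
    key = _GROUP_KEYS[by]
    if key not in table.columns or "category" not in table.columns:
        raise ParameterError("table lacks metadata; run attach_metadata first")
    if table.empty:
        raise DataError("empty rating table")
    t = table.dropna(subset=["rating"])
    n_dropped = len(table) - len(t)
    if n_dropped:
        log.info("excluded %d trials with missing ratings", n_dropped)
    means = t.groupby([key, "category"], observed=True)["rating"].mean().unstack("category")
    if category is not None:
        return means[category]
    return means


def normalized_difference(song_value, speech_value):
    """(song - speech) / (|song| + |speech|), elementwise; 0 where both are 0.

    Positive values mean the song member exceeds the speech member; bounded
    in [-1, 1] for any finite inputs, reducing to (a-b)/(a+b) for
    nonnegative power values.
    """
    a = np.asarray(song_value, dtype=float)
    b = np.asarray(speech_value, dtype=float)
    denom = np.abs(a) + np.abs(b)
    out = np.divide(a - b, denom, out=np.zeros_like(denom), where=denom > 0)
    if out.ndim == 0:
        return float(out)
    return out


def speaker_behavior_diffs(table: pd.DataFrame) -> pd.Series:
    """Per-speaker normalized difference of mean song vs mean speech ratings.

    Ratings are signed, so the ratio form (a-b)/(|a|+|b|) would collapse to
    exactly 1 for every speaker rated positive on song and negative on
    speech; the behavioural score is instead normalized by the width of the
    rating scale, (song - speech)/2, which is bounded in [-1, 1] and varies
    continuously with how confidently listeners separated the pair.
    """
    if "speaker_id" not in table.columns:
        raise ParameterError("table lacks speaker metadata; run attach_metadata first")
    means = (
        table.dropna(subset=["rating"])
        .groupby(["speaker_id", "category"], observed=True)["rating"]
        .mean()
        .unstack("category")
    )
    means = means.dropna()
    return pd.Series(
        (means["song"].to_numpy() - means["speech"].to_numpy()) / 2.0,
        index=means.index,
        name="behavior_diff",
    )


def stm_diff_matrix(stm: STMDataset) -> tuple[np.ndarray, list[str]]:
    """Per-speaker cell-wise normalized STM difference (song vs speech power
    on the duration-matched pair), as a speakers x cells matrix."""
    meta = stm.meta
    speakers = list(dict.fromkeys(meta["speaker_id"]))
    rows, kept = [], []
    for spk in speakers:
        idx = meta.index[meta["speaker_id"] == spk]
        cats = meta.loc[idx, "category"]
        if set(cats) != {"song", "speech"}:
            continue
        a = stm.X[idx[cats == "song"][0]]
        b = stm.X[idx[cats == "speech"][0]]
        rows.append(normalized_difference(a, b))
        kept.append(spk)
    if not rows:
        raise DataError("no complete pairs in dataset")
    return np.vstack(rows), kept


@dataclass
class CorrMap:
    """Per-cell Pearson r between STM and behavioural difference scores."""

    r: np.ndarray
    p: np.ndarray
    mask: np.ndarray  # FDR-significant at alpha
    alpha: float
    n: int


def stm_behavior_corr_map(
    stm_diffs: np.ndarray, behavior_diffs: np.ndarray, alpha: float = 0.05
) -> CorrMap:
    """Correlate, per grid cell, the speakers' STM difference scores with
    their behavioural difference scores; BH-FDR mask at ``alpha`` over all
    cells with variance (zero-variance cells are excluded and NaN)."""
    X = np.asarray(stm_diffs, dtype=float)
    y = np.asarray(behavior_diffs, dtype=float)
    if X.shape[0] != len(y):
        raise ParameterError("speaker indices of STM and behaviour differences are not aligned")
    n = len(y)
    if n < 5:
        raise ParameterError(f"need >= 5 speakers, got {n}")
    if y.std() == 0:
        raise DataError("behavioural differences have zero variance")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = X.std(axis=0)
    valid = sx > 0
    n_invalid = int((~valid).sum())
    if n_invalid:
        log.info("excluding %d zero-variance cells from the correlation map", n_invalid)
    r = np.full(X.shape[1], np.nan)
    r[valid] = (Xc[:, valid] * yc[:, None]).sum(axis=0) / (n * sx[valid] * y.std())
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.full_like(r, np.nan)
    p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df=n - 2)
    p[valid & (np.abs(r) >= 1.0)] = 0.0
    mask = np.zeros(X.shape[1], dtype=bool)
    mask[valid] = multipletests(p[valid], alpha=alpha, method="fdr_bh")[0]
    return CorrMap(r=r, p=p, mask=mask, alpha=alpha, n=n)


def decoding_behavior_corr(
    per_group_accuracy: pd.Series, per_group_behavior_diff: pd.Series
) -> tuple[float, float]:
    """Pearson correlation between per-group decoding accuracy and per-group
    behavioural normalized difference (aligned on group labels)."""
    a, b = per_group_accuracy.align(per_group_behavior_diff, join="inner")
    if len(a) < 4:
        raise ParameterError(f"need >= 4 common groups, got {len(a)}")
    if a.std() == 0 or b.std() == 0:
        raise DataError("correlation undefined: zero variance")
    r, p = stats.pearsonr(a.to_numpy(), b.to_numpy())
    return float(r), float(p)


def rating_accuracy_wilcoxon(per_unit_means: pd.Series) -> WilcoxonResult:
    """Wilcoxon signed-rank test of per-unit mean ratings against 0 (the
    scale's chance level); W = n(n+1)/2 when every unit rates song positive,
    W = 0 when every unit rates speech negative."""
    return wilcoxon_vs_chance(per_unit_means.to_numpy(), chance=0.0)
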