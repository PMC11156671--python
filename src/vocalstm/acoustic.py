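"""Linking conventional acoustic features to the STM plane via PLS.

One PLS1 regression per modulation-plane cell predicts that cell's power
across vocalizations from the full (multicollinear) acoustic feature table;
the in-sample correlation between fitted and observed power, FDR-masked,
maps where in the plane the conventional features carry STM information.
Variable importance in projection (VIP) scores rank the features at the
statistical peaks; VIP > 1 is the conventional importance threshold, and the
mean squared VIP equals 1 by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError, ParameterError
from .modspec import STMDataset

__all__ = [
    "PlsFit",
    "PLSMap",
    "pls_fit_cell",
    "pls_correlation_map",
    "vip_scores",
    "important_features",
]

log = logging.getLogger(__name__)


@dataclass
class PlsFit:
    """A fitted per-cell PLS1 model with the pieces VIP scoring needs."""

    fitted: np.ndarray  # (n,)
    x_weights: np.ndarray  # (p, A)
    x_scores: np.ndarray  # (n, A)
    y_loadings: np.ndarray  # (A,)
    feature_names: list[str]
    n_components: int


def _prepare_X(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(arr.shape[1])]
    n_missing = int(np.isnan(arr).sum())
    if n_missing:
        log.info("mean-imputing %d missing feature values", n_missing)
        col_mean = np.nanmean(arr, axis=0)
        arr = np.where(np.isnan(arr), col_mean[None, :], arr)
    return arr, names


def pls_fit_cell(X, y, n_components: int = 10) -> PlsFit:
    """PLS1 regression of one STM cell on the acoustic features.

    Features and response are standardized internally (NIPALS as implemented
    in scikit-learn); ``n_components`` is capped at min(n-1, p). Missing
    feature values are mean-imputed with a logged count.
    """
    arr, names = _prepare_X(X)
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise DataError("constant response: degenerate PLS fit")
    n, p = arr.shape
    A = min(n_components, n - 1, p)
    if A < 1:
        raise ParameterError(f"cannot fit {n_components} components with n={n}, p={p}")
    pls = PLSRegression(n_components=A, scale=True)
    pls.fit(arr, y)
    return PlsFit(
        fitted=pls.predict(arr).ravel(),
        x_weights=pls.x_weights_,
        x_scores=pls.x_scores_,
        y_loadings=pls.y_loadings_.ravel(),
        feature_names=names,
        n_components=A,
    )


def vip_scores(fit: PlsFit) -> np.ndarray:
    """Variable importance in projection for every feature.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ), where
    SSY_a is the response variance explained by component a; a weighted sum
    of the features' squared (normalized) weights, weighted by each
    component's explained response variance. mean(VIP^2) = 1 identically, and
    a single-feature model has VIP = 1 exactly.
    """
    W = fit.x_weights
    p = W.shape[0]
    ssy = fit.y_loadings**2 * (fit.x_scores**2).sum(axis=0)
    total = ssy.sum()
    if total <= 0:
        raise DataError("PLS model explains zero response variance; VIP undefined")
    wnorm2 = (W**2).sum(axis=0)
    frac = W**2 / wnorm2[None, :]
    return np.sqrt(p * (frac * ssy[None, :]).sum(axis=1) / total)


@dataclass
class PLSMap:
    """Per-cell fitted-vs-observed correlation with FDR mask, plus the VIP
    vectors at named peak cells."""

    r: np.ndarray  # (n_spectral, n_temporal); NaN where degenerate
    p: np.ndarray
    mask: np.ndarray
    spectral_axis: np.ndarray
    temporal_axis: np.ndarray
    alpha: float
    n_components: int
    peak_vips: dict[str, pd.Series]


def pls_correlation_map(
    X,
    stm: STMDataset,
    n_components: int = 10,
    alpha: float = 0.05,
    peaks: dict[str, tuple[float, float]] | None = None,
    exclude_origin: bool = True,
    cv: int | None = None,
) -> PLSMap:
    """Fit one PLS per grid cell and map the correlation between fitted and
    observed STM power, BH-FDR-masked at ``alpha``.

    By default the correlation is in-sample (the conventional reading of a
    "fitted vs observed" map); it is therefore optimistically biased under
    the null, and ``cv`` switches to k-fold cross-validated predictions for
    honestly calibrated significance. ``peaks`` optionally names (spectral,
    temporal) coordinates at which the per-feature VIP vector is computed and
    attached (e.g. the statistical peaks of the song/speech contrast).
    Degenerate (constant) cells are excluded and logged.
    """
    arr, names = _prepare_X(X)
    if arr.shape[0] != stm.X.shape[0]:
        raise ParameterError("feature table rows are not aligned with the STM dataset")
    n_cells = stm.X.shape[1]
    r = np.full(n_cells, np.nan)
    pvals = np.full(n_cells, np.nan)
    valid = stm.X.std(axis=0) > 0
    if exclude_origin:
        valid[stm.origin_index] = False
    n_deg = int((~valid).sum())
    if n_deg:
        log.info("excluding %d degenerate cells from the PLS map", n_deg)
    folds = None
    if cv:
        from sklearn.model_selection import KFold

        folds = list(KFold(n_splits=cv, shuffle=False).split(arr))
    for idx in np.flatnonzero(valid):
        y = stm.X[:, idx]
        if folds is None:
            fitted = pls_fit_cell(arr, y, n_components=n_components).fitted
        else:
            fitted = np.empty_like(y)
            for tr, te in folds:
                A = min(n_components, len(tr) - 1, arr.shape[1])
                model = PLSRegression(n_components=A, scale=True).fit(arr[tr], y[tr])
                fitted[te] = model.predict(arr[te]).ravel()
        if np.std(fitted) == 0:
            continue
        rr, pp = stats.pearsonr(fitted, y)
        r[idx], pvals[idx] = rr, pp
    mask = np.zeros(n_cells, dtype=bool)
    tested = valid & np.isfinite(pvals)
    if tested.any():
        mask[tested] = multipletests(pvals[tested], alpha=alpha, method="fdr_bh")[0]
    # "the model fits the data" is a positive claim; anticorrelated CV
    # predictions (the generic null behaviour) do not count as fits
    mask &= np.nan_to_num(r) > 0

    peak_vips: dict[str, pd.Series] = {}
    for name, (s, t) in (peaks or {}).items():
        idx = stm.cell_index(s, t)
        fit = pls_fit_cell(X, stm.X[:, idx], n_components=n_components)
        peak_vips[name] = pd.Series(vip_scores(fit), index=fit.feature_names, name=name)

    shape = stm.shape2d
    return PLSMap(
        r=r.reshape(shape),
        p=pvals.reshape(shape),
        mask=mask.reshape(shape),
        spectral_axis=stm.spectral_axis,
        temporal_axis=stm.temporal_axis,
        alpha=alpha,
        n_components=n_components,
        peak_vips=peak_vips,
    )


def important_features(
    vip: pd.Series, threshold: float = 1.0, label_map: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Features whose VIP exceeds the importance threshold, optionally
    aggregated by label group (pitch, intensity, ...)."""
    sel = vip[vip > threshold].sort_values(ascending=False)
    out = sel.rename("vip").rename_axis("feature").reset_index()
    if label_map is not None:
        if not set(vip.index) <= set(label_map["feature"]):
            raise ParameterError("label map does not cover all features")
        out = out.merge(label_map, on="feature", how="left")
    return out
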