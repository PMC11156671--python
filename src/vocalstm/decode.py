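"""Grouped cross-validated linear SVM decoding of song vs speech.

Leave-one-group-out validation (one fold per society, country, language
family, subregion or region) is the cross-cultural generalization test: the
classifier never sees the held-out culture during training, so above-chance
accuracy requires category structure shared across cultures. Regularization
follows the lambda parameterization of penalized linear SVMs (C = 1/(n*lambda)
on the training fold); song is the positive class throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc, roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .exceptions import DataError, ParameterError
from .modspec import STMDataset

__all__ = [
    "GROUPINGS",
    "DecodeResult",
    "group_cv_svm",
    "decode_stm",
    "select_lambda",
    "wilcoxon_vs_chance",
    "roc_per_group",
    "compare_feature_sets",
    "correlate_accuracy_with_covariate",
    "friedman_test",
    "durbin_conover",
    "WilcoxonResult",
    "FeatureSetComparison",
]

log = logging.getLogger(__name__)

GROUPINGS = ("fieldsite", "country", "language_family", "subregion", "region")
LAMBDA_GRID = (0.1, 0.05, 0.01, 0.005, 0.001)
POSITIVE_CLASS = "song"


def _encode_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        return np.where(y == POSITIVE_CLASS, 1, -1)
    return np.where(np.asarray(y, dtype=float) > 0, 1, -1)


def _fit_fold(X_tr, y_tr, lam: float) -> tuple[StandardScaler, LinearSVC]:
    scaler = StandardScaler().fit(X_tr)
    C = 1.0 / (lam * len(y_tr))
    clf = LinearSVC(C=C, random_state=0, max_iter=20000)
    clf.fit(scaler.transform(X_tr), y_tr)
    return scaler, clf


@dataclass
class DecodeResult:
    """Fold-wise predictions and metrics of one grouped-CV decoding run."""

    grouping: str
    lam: float
    fold_groups: list[str]
    fold_accuracy: np.ndarray  # %
    fold_sensitivity: np.ndarray  # % recall of song; NaN if no songs in fold
    fold_specificity: np.ndarray  # % recall of speech
    fold_y_true: list[np.ndarray] = field(repr=False, default_factory=list)
    fold_decision: list[np.ndarray] = field(repr=False, default_factory=list)
    fold_pred: list[np.ndarray] = field(repr=False, default_factory=list)
    fold_weights_z: list[np.ndarray] = field(repr=False, default_factory=list)
    weight_z: np.ndarray | None = field(repr=False, default=None)
    weight_map: np.ndarray | None = field(repr=False, default=None)

    @property
    def accuracy_mean(self) -> float:
        """Pooled accuracy as the mean over folds (each society weighted
        equally, regardless of its sample count)."""
        return float(np.mean(self.fold_accuracy))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=1))

    @property
    def pooled_prediction_accuracy(self) -> float:
        """Accuracy over all pooled predictions (sample-weighted alternative
        to the fold mean)."""
        y = np.concatenate(self.fold_y_true)
        p = np.concatenate(self.fold_pred)
        return float(100.0 * np.mean(y == p))

    def accuracy_by_group(self) -> pd.Series:
        return pd.Series(self.fold_accuracy, index=self.fold_groups, name="accuracy")

    def top_weight_cells(self, fraction: float = 0.05, smooth_sd: float = 1.25) -> np.ndarray:
        """Boolean mask of the top-``fraction`` |weight| cells of the
        fold-averaged weight map.

        The map is lightly Gaussian-smoothed (in grid steps) before
        thresholding: fold-averaged SVM weight maps carry single-cell speckle
        from standardized low-variance cells, and the spatially coherent
        structure is what identifies the discriminative modulation regions.
        """
        if self.weight_map is None:
            raise DataError("no weight map attached; decode via decode_stm")
        from scipy.ndimage import gaussian_filter

        wm = np.abs(gaussian_filter(self.weight_map, smooth_sd)) if smooth_sd > 0 else np.abs(
            self.weight_map
        )
        return wm >= np.quantile(wm, 1.0 - fraction)


def group_cv_svm(
    features: np.ndarray,
    labels,
    groups,
    lam: float = 0.01,
    grouping: str = "group",
) -> DecodeResult:
    """Leave-one-group-out linear SVM decoding.

    Per fold: features are standardized with training-fold statistics only,
    a linear soft-margin SVM is fitted on all groups but one and tested on
    the held-out group. Sensitivity is the recall of song, specificity the
    recall of speech; a test group missing one class gets NaN for the missing
    class's metric and is excluded from that metric's pooling.
    """
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise DataError("features contain non-finite values")
    y = _encode_labels(labels)
    groups = np.asarray(groups)
    uniq = sorted(pd.unique(groups))
    if len(uniq) < 2:
        raise ParameterError("need >= 2 groups for grouped cross-validation")

    res = DecodeResult(
        grouping=grouping,
        lam=lam,
        fold_groups=[str(g) for g in uniq],
        fold_accuracy=np.zeros(len(uniq)),
        fold_sensitivity=np.zeros(len(uniq)),
        fold_specificity=np.zeros(len(uniq)),
    )
    weights_z = []
    for i, g in enumerate(uniq):
        test = groups == g
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise DataError(f"training fold for held-out group {g!r} has one class only")
        scaler, clf = _fit_fold(X[train], y[train], lam)
        Xt = scaler.transform(X[test])
        pred = clf.predict(Xt)
        dec = clf.decision_function(Xt)
        if clf.classes_[1] != 1:  # ensure decision > 0 means song
            dec = -dec
        yt = y[test]
        res.fold_accuracy[i] = 100.0 * np.mean(pred == yt)
        for val, attr, name in ((1, "fold_sensitivity", "song"), (-1, "fold_specificity", "speech")):
            sel = yt == val
            if sel.any():
                getattr(res, attr)[i] = 100.0 * np.mean(pred[sel] == val)
            else:
                getattr(res, attr)[i] = np.nan
                log.info("held-out group %s has no %s samples", g, name)
        res.fold_y_true.append(yt)
        res.fold_decision.append(dec)
        res.fold_pred.append(pred)
        w = clf.coef_[0] * (1 if clf.classes_[1] == 1 else -1)
        weights_z.append((w - w.mean()) / w.std())
    res.fold_weights_z = weights_z
    res.weight_z = np.mean(weights_z, axis=0)
    return res


def decode_stm(
    stm: STMDataset,
    grouping: str = "fieldsite",
    lam: float = 0.01,
    extra_features: np.ndarray | None = None,
) -> DecodeResult:
    """Decode category from flattened modulograms (origin cell excluded),
    optionally concatenated with extra feature columns; attaches the
    fold-averaged z-scored weight map on the modulogram grid."""
    if grouping not in stm.meta.columns:
        raise ParameterError(f"unknown grouping column {grouping!r}")
    X, cell_idx = stm.feature_matrix(exclude_origin=True)
    if extra_features is not None:
        X = np.column_stack([X, np.asarray(extra_features, dtype=float)])
    res = group_cv_svm(
        X, stm.meta["category"].to_numpy(), stm.meta[grouping].to_numpy(), lam=lam,
        grouping=grouping,
    )
    wmap = np.zeros(stm.n_cells)
    wmap[cell_idx] = res.weight_z[: len(cell_idx)]
    res.weight_map = stm.reshape_cells(wmap)
    return res


def select_lambda(
    train_features,
    train_labels,
    val_features,
    val_labels,
    grid=LAMBDA_GRID,
) -> float:
    """Pick the regularization strength maximizing accuracy on a held-out
    validation set; ties resolve to the larger lambda (stronger
    regularization)."""
    if len(np.asarray(val_labels)) == 0:
        raise ParameterError("validation set is empty")
    X_tr = np.asarray(train_features, dtype=float)
    y_tr = _encode_labels(train_labels)
    X_val = np.asarray(val_features, dtype=float)
    y_val = _encode_labels(val_labels)
    best_lam, best_acc = None, -np.inf
    for lam in sorted(grid, reverse=True):
        scaler, clf = _fit_fold(X_tr, y_tr, lam)
        acc = np.mean(clf.predict(scaler.transform(X_val)) == y_val)
        if acc > best_acc:
            best_lam, best_acc = lam, acc
    return best_lam


@dataclass
class WilcoxonResult:
    w: float  # W+ = sum of ranks of positive differences
    p: float
    rank_biserial: float
    ci: tuple[float, float]  # bootstrap 95% CI of the mean difference
    n: int


def wilcoxon_vs_chance(
    per_group_accuracies,
    chance: float = 50.0,
    n_boot: int = 5000,
    seed: int = 0,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test of per-group accuracies against chance.

    Reports W+ (so all-above-chance gives W = n(n+1)/2), the two-tailed
    p-value, the rank-biserial correlation (W+ - W-)/(W+ + W-), and a
    bootstrap 95% CI of the mean accuracy-minus-chance difference.
    """
    acc = np.asarray(per_group_accuracies, dtype=float)
    if len(acc) < 5:
        raise ParameterError(f"need >= 5 groups, got {len(acc)}")
    d = acc - chance
    nz = d[d != 0]
    if len(nz) == 0:
        raise DataError("all differences from chance are zero; statistic undefined")
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    w_minus = float(ranks[nz < 0].sum())
    rb = (w_plus - w_minus) / (w_plus + w_minus)
    p = float(stats.wilcoxon(d, alternative="two-sided", zero_method="wilcox").pvalue)
    rng = np.random.default_rng(seed)
    boots = rng.choice(d, size=(n_boot, len(d)), replace=True).mean(axis=1)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return WilcoxonResult(w=w_plus, p=p, rank_biserial=rb, ci=ci, n=len(acc))


def roc_per_group(result: DecodeResult) -> dict[str, dict]:
    """Per-held-out-group ROC curves and AUC from the signed decision values;
    single-class groups yield no curve."""
    out: dict[str, dict] = {}
    for g, yt, dec in zip(result.fold_groups, result.fold_y_true, result.fold_decision):
        if len(np.unique(yt)) < 2:
            log.info("group %s has a single class; no ROC", g)
            continue
        fpr, tpr, _ = roc_curve(yt, dec, pos_label=1)
        out[g] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
    return out


def friedman_test(accuracy_table: pd.DataFrame) -> tuple[float, float, float]:
    """Friedman chi-square across the table's columns (treatments) with
    groups as blocks; returns (chi2, p, Kendall's W effect size)."""
    n, k = accuracy_table.shape
    cols = [accuracy_table[c].to_numpy() for c in accuracy_table.columns]
    if np.allclose(np.ptp(accuracy_table.to_numpy(), axis=1), 0):
        return 0.0, 1.0, 0.0
    chi2, p = stats.friedmanchisquare(*cols)
    w = chi2 / (n * (k - 1))
    return float(chi2), float(p), float(w)


def durbin_conover(accuracy_table: pd.DataFrame, bonferroni: bool = True) -> pd.DataFrame:
    """Conover's pairwise post hoc after Friedman on a blocks x treatments
    table; two-tailed t-distributed p-values, Bonferroni-corrected over all
    treatment pairs by default."""
    ranks = accuracy_table.rank(axis=1)
    n, k = ranks.shape
    R = ranks.sum(axis=0)
    A = float((ranks.to_numpy() ** 2).sum())
    C = n * k * (k + 1) ** 2 / 4.0
    if A == C:
        raise DataError("all treatments identical within every block")
    # tie-corrected Friedman statistic (Conover's T1)
    T2 = (k - 1) * float(((R - n * (k + 1) / 2.0) ** 2).sum()) / (A - C)
    df = (n - 1) * (k - 1)
    # perfectly consistent rankings drive the residual factor to 0; floor it
    # so the statistic degenerates to +/-inf (p -> 0) rather than NaN
    factor = max(1.0 - T2 / (n * (k - 1.0)), 1e-12)
    denom = np.sqrt((A - C) * 2.0 * n / df * factor)
    cols = list(accuracy_table.columns)
    n_pairs = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            t = (R[cols[i]] - R[cols[j]]) / denom
            p = 2.0 * stats.t.sf(abs(t), df)
            if bonferroni:
                p = min(1.0, p * n_pairs)
            rows.append({"a": cols[i], "b": cols[j], "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


@dataclass
class FeatureSetComparison:
    accuracy_table: pd.DataFrame  # groups x feature sets, %
    friedman_chi2: float
    friedman_p: float
    kendalls_w: float
    posthoc: pd.DataFrame
    results: dict[str, DecodeResult]


def compare_feature_sets(
    stm: STMDataset,
    acoustic_table: pd.DataFrame,
    vip_excluded: list[str],
    grouping: str = "fieldsite",
    lam: float = 0.01,
) -> FeatureSetComparison:
    """Decode with four feature sets on identical folds — STM only,
    STM + acoustic, acoustic only, acoustic without the VIP-important
    variables — and compare fold accuracies with Friedman plus
    Durbin-Conover post hocs (Bonferroni over the 6 pairs)."""
    if len(acoustic_table) != stm.X.shape[0]:
        raise ParameterError("acoustic table rows are not aligned with the STM dataset")
    missing = [f for f in vip_excluded if f not in acoustic_table.columns]
    if missing:
        raise ParameterError(f"vip_excluded names absent from table: {missing}")
    ac = acoustic_table.to_numpy(dtype=float)
    ac_novip = acoustic_table.drop(columns=vip_excluded).to_numpy(dtype=float)
    stm_X, _ = stm.feature_matrix(exclude_origin=True)
    y = stm.meta["category"].to_numpy()
    g = stm.meta[grouping].to_numpy()
    sets = {
        "stm": stm_X,
        "stm+acoustic": np.column_stack([stm_X, ac]),
        "acoustic": ac,
        "acoustic_novip": ac_novip,
    }
    results = {
        name: group_cv_svm(X, y, g, lam=lam, grouping=grouping) for name, X in sets.items()
    }
    first = next(iter(results.values()))
    table = pd.DataFrame(
        {name: r.fold_accuracy for name, r in results.items()}, index=first.fold_groups
    )
    chi2, p, w = friedman_test(table)
    posthoc = durbin_conover(table) if chi2 > 0 else pd.DataFrame(columns=["a", "b", "t", "p"])
    return FeatureSetComparison(
        accuracy_table=table,
        friedman_chi2=chi2,
        friedman_p=p,
        kendalls_w=w,
        posthoc=posthoc,
        results=results,
    )


def correlate_accuracy_with_covariate(per_group_accuracies, covariate) -> tuple[float, float]:
    """Pearson correlation (r, two-tailed p) between per-group accuracies and
    a per-group covariate such as mean sample duration."""
    a = np.asarray(per_group_accuracies, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if len(a) != len(c):
        raise ParameterError("vectors must have equal length")
    if len(a) < 4:
        raise ParameterError("need >= 4 groups for a correlation")
    if a.std() == 0 or c.std() == 0:
        raise DataError("correlation undefined: zero variance")
    r, p = stats.pearsonr(a, c)
    return float(r), float(p)
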