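"""Mobility-state clustering of track ensembles.

Tracks are clustered in the six-dimensional biophysical feature space
(D, alpha, Rc, Dr, MSD at the first lag, residence duration within
0.25 µm). Two routes are provided, mirroring common practice for
single-molecule state analysis:

* a full-covariance Gaussian mixture model (k = 6 by default), fitted on a
  condition-balanced training set and then applied to later experiments;
* Ward hierarchical clustering whose labels train a Laplacian-kernel
  support-vector classifier (C = 8) for cross-experiment assignment.

Heavily right-skewed features (D, Rc, MSD@dT1) are log-transformed before
clustering (config-switchable). Components are canonicalized by descending
mean diffusion coefficient, so the last cluster index is always the
slowest / most confined state and indices are comparable across runs.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_score
from sklearn.metrics.pairwise import laplacian_kernel
from sklearn.mixture import GaussianMixture
from sklearn.svm import SVC

__all__ = [
    "FEATURE_COLUMNS",
    "LOG_FEATURES",
    "TrainingSet",
    "StateModel",
    "build_training_set",
    "fit_gmm",
    "fit_ward_svm",
    "classify_tracks",
    "classify_tracks_array",
    "cluster_fold_changes",
    "model_selection_report",
]

FEATURE_COLUMNS = ("D_um2_s", "alpha", "Rc_um", "Dr_um2_s",
                   "msd_dt1_um2", "res_025_s")
LOG_FEATURES = ("D_um2_s", "Rc_um", "msd_dt1_um2")


@dataclass
class TrainingSet:
    """Condition-balanced, complete-case feature matrix."""

    X: np.ndarray
    conditions: np.ndarray
    index: np.ndarray
    feature_names: tuple[str, ...]
    balancing: dict[str, int]


@dataclass
class StateModel:
    """A fitted mobility-state model (gmm or ward+svm)."""

    kind: str
    k: int
    feature_names: tuple[str, ...]
    log_features: tuple[str, ...]
    rng_seed: int
    # gmm parameters
    means: np.ndarray | None = None
    covariances: np.ndarray | None = None
    weights: np.ndarray | None = None
    # scaling (ward+svm)
    scale_mean: np.ndarray | None = None
    scale_std: np.ndarray | None = None
    svm: SVC | None = None
    train_labels: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "StateModel":
        return joblib.load(path)

    def to_bytes(self) -> bytes:
        buf = _io.BytesIO()
        joblib.dump(self, buf)
        return buf.getvalue()


class _LaplacianKernel:
    """Picklable Laplacian kernel exp(−γ·||x−y||₁) for SVC."""

    def __init__(self, gamma: float):
        self.gamma = gamma

    def __call__(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        return laplacian_kernel(A, B, gamma=self.gamma)


def _complete_case(features: pd.DataFrame,
                   cols: tuple[str, ...] = FEATURE_COLUMNS) -> pd.DataFrame:
    sub = features[list(cols)].apply(pd.to_numeric, errors="coerce")
    ok = np.isfinite(sub.to_numpy(dtype=float)).all(axis=1)
    for c in LOG_FEATURES:
        if c in cols:
            ok &= sub[c].to_numpy(dtype=float) > 0
    return features.loc[ok]


def _transform(X: np.ndarray, feature_names: tuple[str, ...],
               log_features: tuple[str, ...]) -> np.ndarray:
    Xt = X.astype(float).copy()
    for j, name in enumerate(feature_names):
        if name in log_features:
            Xt[:, j] = np.log(Xt[:, j])
    return Xt


def build_training_set(
    features: pd.DataFrame,
    conditions: list[str],
    n_per_condition: int,
    seed: int,
    feature_cols: tuple[str, ...] = FEATURE_COLUMNS,
    condition_col: str = "condition",
) -> TrainingSet:
    """Reproducible, condition-balanced subsample of complete-case tracks."""
    rng = np.random.default_rng(seed)
    usable = _complete_case(features, feature_cols)
    rows: list[np.ndarray] = []
    balancing: dict[str, int] = {}
    for cond in conditions:
        pool = usable.index[usable[condition_col] == cond].to_numpy()
        if len(pool) < n_per_condition:
            raise ValueError(
                f"condition {cond!r} has only {len(pool)} complete-case "
                f"tracks, need {n_per_condition}")
        rows.append(rng.choice(pool, size=n_per_condition, replace=False))
        balancing[cond] = n_per_condition
    idx = np.concatenate(rows)
    sub = usable.loc[idx]
    return TrainingSet(
        X=sub[list(feature_cols)].to_numpy(dtype=float),
        conditions=sub[condition_col].to_numpy(),
        index=idx,
        feature_names=tuple(feature_cols),
        balancing=balancing,
    )


def _canonical_order(means_D: np.ndarray) -> np.ndarray:
    """Component order: descending mean D, so the last cluster is slowest."""
    return np.argsort(-means_D, kind="stable")


def fit_gmm(
    train: TrainingSet,
    k: int = 6,
    seed: int = 0,
    km_iter: int = 20,
    em_iter: int = 20,
    km_restarts: int = 10,
    log_features: tuple[str, ...] = LOG_FEATURES,
    reg_covar: float = 1e-6,
) -> StateModel:
    """Full-covariance Gaussian mixture over the (log-transformed) features.

    Initialization draws k random data points as k-means seeds (≤ km_iter
    iterations, best of ``km_restarts`` random restarts) and refines with
    ≤ em_iter EM iterations. Components are reordered by descending mean D
    after fitting.
    """
    Xt = _transform(train.X, train.feature_names, log_features)
    if len(Xt) < 10 * k:
        raise ValueError(f"need at least {10 * k} rows to fit k={k}")
    km = KMeans(n_clusters=k, init="random", n_init=km_restarts,
                max_iter=km_iter, random_state=seed)
    km.fit(Xt)
    gm = GaussianMixture(n_components=k, covariance_type="full",
                         max_iter=em_iter, reg_covar=reg_covar,
                         means_init=km.cluster_centers_, random_state=seed)
    gm.fit(Xt)
    d_col = train.feature_names.index("D_um2_s") if "D_um2_s" in train.feature_names else 0
    order = _canonical_order(gm.means_[:, d_col])
    model = StateModel(
        kind="gmm", k=k, feature_names=train.feature_names,
        log_features=tuple(f for f in log_features if f in train.feature_names),
        rng_seed=seed,
        means=gm.means_[order].copy(),
        covariances=gm.covariances_[order].copy(),
        weights=gm.weights_[order].copy(),
    )
    model.train_labels = classify_tracks_array(model, train.X)
    return model


def fit_ward_svm(
    train: TrainingSet,
    k: int = 6,
    seed: int = 0,
    C: float = 8.0,
    gamma: float | None = None,
    n_svm_train: int | None = None,
    log_features: tuple[str, ...] = LOG_FEATURES,
) -> StateModel:
    """Ward clustering on standardized features + Laplacian-kernel SVM.

    Ward labels (cut at k clusters, canonicalized by descending mean D)
    train a multi-class SVC with the Laplacian kernel exp(−γ·|x−y|₁) and
    cost C; the classifier carries the states to later experiments.
    """
    Xt = _transform(train.X, train.feature_names, log_features)
    mu, sd = Xt.mean(axis=0), Xt.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Xt - mu) / sd
    ward = AgglomerativeClustering(n_clusters=k, linkage="ward")
    raw = ward.fit_predict(Z)
    counts = np.bincount(raw, minlength=k)
    if counts.min() < 2:
        raise ValueError("degenerate Ward cluster with fewer than 2 members")
    d_col = train.feature_names.index("D_um2_s") if "D_um2_s" in train.feature_names else 0
    mean_D = np.array([Xt[raw == c, d_col].mean() for c in range(k)])
    order = _canonical_order(mean_D)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw]

    if gamma is None:
        gamma = 1.0 / Z.shape[1]
    rng = np.random.default_rng(seed)
    if n_svm_train is not None and n_svm_train < len(Z):
        sel = rng.choice(len(Z), size=n_svm_train, replace=False)
    else:
        sel = np.arange(len(Z))
    svm = SVC(C=C, kernel=_LaplacianKernel(gamma))
    svm.fit(Z[sel], labels[sel])
    return StateModel(
        kind="ward+svm", k=k, feature_names=train.feature_names,
        log_features=tuple(f for f in log_features if f in train.feature_names),
        rng_seed=seed, scale_mean=mu, scale_std=sd, svm=svm,
        train_labels=labels, extras={"gamma": gamma, "C": C},
    )


def _gmm_log_resp(model: StateModel, Xt: np.ndarray) -> np.ndarray:
    logp = np.empty((len(Xt), model.k))
    for c in range(model.k):
        logp[:, c] = (np.log(model.weights[c])
                      + stats.multivariate_normal.logpdf(
                          Xt, mean=model.means[c], cov=model.covariances[c],
                          allow_singular=True))
    return logp


def classify_tracks_array(model: StateModel, X: np.ndarray) -> np.ndarray:
    """Assign cluster indices (0..k−1, canonical order) to feature rows."""
    Xt = _transform(np.asarray(X, float), model.feature_names,
                    model.log_features)
    if model.kind == "gmm":
        if model.means is None:
            raise ValueError("model is not fitted")
        return np.argmax(_gmm_log_resp(model, Xt), axis=1)
    if model.svm is None:
        raise ValueError("model is not fitted")
    Z = (Xt - model.scale_mean) / model.scale_std
    return model.svm.predict(Z)


def classify_tracks(model: StateModel, features: pd.DataFrame) -> pd.Series:
    """Cluster assignment per complete-case feature-table row.

    Deterministic: GMM rows go to the maximum-posterior component, ward+svm
    rows to the classifier prediction. Incomplete rows get -1.
    """
    usable = _complete_case(features, model.feature_names)
    labels = pd.Series(-1, index=features.index, dtype=int, name="cluster")
    if len(usable):
        labels.loc[usable.index] = classify_tracks_array(
            model, usable[list(model.feature_names)].to_numpy(dtype=float))
    return labels


# ---------------------------------------------------------------------------
# condition comparisons
# ---------------------------------------------------------------------------

def cluster_fold_changes(
    assignments: dict[str, np.ndarray],
    cond_a: str,
    cond_b: str,
    k: int,
    n_boot: int = 1000,
    seed: int = 0,
    cell_ids: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-cluster fraction fold change (condition b over condition a).

    Bootstrap CIs resample tracks within each condition. When per-cell
    grouping is supplied, per-cell cluster fractions are compared with a
    two-tailed two-sample t-test per cluster. Fold changes with an empty
    denominator cluster are reported missing (NaN), never infinite.
    """
    rng = np.random.default_rng(seed)
    la = np.asarray(assignments[cond_a])
    lb = np.asarray(assignments[cond_b])

    def fractions(lab: np.ndarray) -> np.ndarray:
        counts = np.bincount(lab[lab >= 0], minlength=k).astype(float)
        tot = counts.sum()
        return counts / tot if tot else counts

    fa, fb = fractions(la), fractions(lb)
    fold = np.where(fa > 0, fb / np.where(fa > 0, fa, 1.0), np.nan)

    boots = np.empty((n_boot, k))
    for i in range(n_boot):
        ra = fractions(rng.choice(la, size=len(la)))
        rb = fractions(rng.choice(lb, size=len(lb)))
        boots[i] = np.where(ra > 0, rb / np.where(ra > 0, ra, 1.0), np.nan)
    any_finite = np.isfinite(boots).any(axis=0)
    lo = np.full(k, np.nan)
    hi = np.full(k, np.nan)
    lo[any_finite] = np.nanpercentile(boots[:, any_finite], 2.5, axis=0)
    hi[any_finite] = np.nanpercentile(boots[:, any_finite], 97.5, axis=0)

    pvals = np.full(k, np.nan)
    if cell_ids is not None:
        ca = np.asarray(cell_ids[cond_a])
        cb = np.asarray(cell_ids[cond_b])
        for c in range(k):
            pa = [np.mean(la[ca == cell] == c) for cell in np.unique(ca)]
            pb = [np.mean(lb[cb == cell] == c) for cell in np.unique(cb)]
            if len(pa) >= 2 and len(pb) >= 2:
                pvals[c] = stats.ttest_ind(pa, pb).pvalue

    return pd.DataFrame(
        {
            "cluster": np.arange(1, k + 1),
            f"n_{cond_a}": np.bincount(la[la >= 0], minlength=k),
            f"n_{cond_b}": np.bincount(lb[lb >= 0], minlength=k),
            f"fraction_{cond_a}": fa,
            f"fraction_{cond_b}": fb,
            "fold_change": fold,
            "ci_low": lo,
            "ci_high": hi,
            "p_value": pvals,
        }
    )


def model_selection_report(train: TrainingSet, k_values: range = range(2, 9),
                           seed: int = 0,
                           compare: tuple[str, str] | None = None
                           ) -> pd.DataFrame:
    """Silhouette and between-condition divergence per candidate k.

    Emitted so the cluster count can be audited against the criterion of
    maximal between-condition differences; k is never auto-chosen.
    """
    rows = []
    for k in k_values:
        try:
            m = fit_gmm(train, k=k, seed=seed)
        except ValueError:
            continue
        lab = classify_tracks_array(m, train.X)
        Xt = _transform(train.X, train.feature_names, m.log_features)
        sil = silhouette_score(Xt, lab) if len(set(lab)) > 1 else np.nan
        div = np.nan
        if compare is not None:
            a = lab[train.conditions == compare[0]]
            b = lab[train.conditions == compare[1]]
            pa = np.bincount(a, minlength=k) / max(len(a), 1)
            pb = np.bincount(b, minlength=k) / max(len(b), 1)
            div = float(0.5 * np.abs(pa - pb).sum())  # total variation
        rows.append({"k": k, "silhouette": sil,
                     "between_condition_tv": div})
    return pd.DataFrame(rows)
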