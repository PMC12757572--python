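"""Two-stage SVM classification of mutation hotspots from ϕ/I features.

Each mutation contributes, per pore point, the feature vector
{ϕ_2k, I_2k, ϕ_2k+1,⊥, I_2k+1,⊥} for k = 0..5 evaluated at l = l_mut (24
features): the log composite susceptibilities probe inertia (even orders)
and conductivity (odd perpendicular orders) constraints; the interfacial
coupling strengths are their radial derivatives.  A stratified k-fold
RBF-SVM is trained locally (per pore point); the final classification
round runs on per-mutation features summarized by the median over pore
points.  Hyperparameters are deliberately left at plain defaults (C = 1,
'scale' bandwidth, balanced class weights) so the features carry the
signal, and a bootstrap of the out-of-fold class probabilities yields the
decision threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.inspection import permutation_importance as _sk_perm_importance
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

# Platt-scaled SVC probabilities are part of the published protocol; silence
# the upstream deprecation chatter about the `probability` flag.
warnings.filterwarnings(
    "ignore", message="The `probability` parameter was deprecated",
    category=FutureWarning)

__all__ = [
    "MutationFeatureTable", "LocalCVResult", "MLResult", "EXPERIMENTS",
    "assemble_features", "make_experiment", "summarize_by_median",
    "local_cv", "global_model", "feature_importances", "feature_subset",
]

# dataset definitions: (class_0 = disease, positive; class_1 = control)
EXPERIMENTS = {
    "I": ({"GoF", "LoF"}, {"neutral"}),
    "II": ({"GoF", "LoF"}, {"neutral", "benign"}),
    "III": ({"GoF", "LoF", "pathogenic_other"}, {"neutral", "benign"}),
}

MAX_MISSING_FRACTION = 0.5  # rows above this are dropped before training


@dataclass
class MutationFeatureTable:
    """Long-format table: one row per (pore point, mutation)."""
    df: pd.DataFrame
    feature_cols: list
    use_absolute: bool = False
    n_masked_rows: int = 0


def _feature_name(kind: str, j: int) -> str:
    return f"{kind}_{j}" if j % 2 == 0 else f"{kind}_{j}_perp"


def feature_subset(feature_cols, which: str = "all") -> list:
    """Select the inertia (even-order), conductivity (odd-order ⊥), or full
    feature set."""
    if which == "all":
        return list(feature_cols)
    if which == "inertia":
        return [c for c in feature_cols if not c.endswith("_perp")]
    if which == "conductivity":
        return [c for c in feature_cols if c.endswith("_perp")]
    raise ValueError("feature_set must be all|inertia|conductivity")


def _read_trace(l_values, trace, l_mut):
    """Linear interpolation on the finite part of a trace; NaN outside."""
    if trace is None:
        return np.nan
    finite = np.isfinite(trace)
    if finite.sum() < 2:
        return np.nan
    lv, tv = l_values[finite], trace[finite]
    if not (lv[0] <= l_mut <= lv[-1]):
        return np.nan
    return float(np.interp(l_mut, lv, tv))


def assemble_features(moment_sets, pore_points, mutations, orders_k=range(6),
                      use_absolute: bool = False) -> MutationFeatureTable:
    """Read ϕ_j / I_j off the traces at l = l_mut for every pore point.

    ``moment_sets`` maps pore index → decomposed :class:`MomentSet` with
    couplings computed.  Mutations whose l_mut falls outside the scale
    range of a pore point are masked there; undecomposable orders yield
    missing features (imputed within training folds only).
    ``use_absolute`` replaces every feature by its magnitude.
    """
    orders_j = [2 * k for k in orders_k] + [2 * k + 1 for k in orders_k]
    feature_cols = []
    for j in sorted(orders_j):
        feature_cols += [_feature_name("phi", j), _feature_name("I", j)]

    rows, n_masked = [], 0
    points = np.asarray(pore_points)
    for idx, mset in moment_sets.items():
        p = points[idx]
        lv = mset.l_values
        for m_id, mut in enumerate(mutations):
            l_mut = float(np.linalg.norm(mut.center - p))
            if not (lv[0] <= l_mut <= lv[-1]):
                n_masked += 1
                continue
            row = {"pore_index": idx, "mutation_id": m_id,
                   "chain": mut.chain, "residue_seq": mut.residue_seq,
                   "label": mut.label, "l_mut": l_mut}
            for j in sorted(orders_j):
                prof = mset[j]
                phi = _read_trace(lv, prof.log_susceptibility, l_mut)
                coup = _read_trace(lv, prof.coupling, l_mut)
                row[_feature_name("phi", j)] = phi
                row[_feature_name("I", j)] = coup
            rows.append(row)
    df = pd.DataFrame(rows)
    if use_absolute and len(df):
        df[feature_cols] = df[feature_cols].abs()
    return MutationFeatureTable(df=df, feature_cols=feature_cols,
                                use_absolute=use_absolute,
                                n_masked_rows=n_masked)


def make_experiment(table: MutationFeatureTable,
                    experiment: str = "I") -> pd.DataFrame:
    """Filter the table to one dataset and attach the binary target.

    y = 1 for the disease class (class_0 of the experiment), 0 for the
    control class; other labels are dropped.
    """
    class0, class1 = EXPERIMENTS[experiment]
    df = table.df[table.df["label"].isin(class0 | class1)].copy()
    df["y"] = df["label"].isin(class0).astype(int)
    return df


def _make_pipeline(C: float, seed: int) -> Pipeline:
    return Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("scale", StandardScaler()),
        ("svm", SVC(C=C, kernel="rbf", gamma="scale",
                    class_weight="balanced", probability=True,
                    random_state=seed)),
    ])


def _drop_sparse_rows(df: pd.DataFrame, feature_cols) -> pd.DataFrame:
    frac_missing = df[feature_cols].isna().mean(axis=1)
    return df[frac_missing <= MAX_MISSING_FRACTION]


@dataclass
class LocalCVResult:
    """Out-of-fold probabilities and fold scores at one pore point."""
    pore_index: int
    oof_prob: np.ndarray
    y: np.ndarray
    mutation_ids: np.ndarray
    auc_train: list
    auc_test: list
    f1_train: list
    f1_test: list
    fold_stats: list  # (imputer medians, scaler means) per fold

    @property
    def auc(self) -> float:
        return roc_auc_score(self.y, self.oof_prob)


def local_cv(df_point: pd.DataFrame, feature_cols, k_folds: int = 5,
             seed: int = 0, C: float = 1.0) -> LocalCVResult | None:
    """Stratified k-fold RBF-SVM at one pore point.

    Standardization and imputation are fitted within training folds only.
    Returns None (with a warning) for single-class input; raises when
    k_folds exceeds the minority class count.
    """
    df_point = _drop_sparse_rows(df_point, feature_cols)
    y = df_point["y"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        warnings.warn("single-class input at pore point; skipped")
        return None
    if k_folds > counts.min():
        raise ValueError(f"k_folds={k_folds} exceeds the minority class "
                         f"count ({counts.min()})")
    X = df_point[feature_cols].to_numpy()
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    auc_tr, auc_te, f1_tr, f1_te, stats_ = [], [], [], [], []
    for train, test in cv.split(X, y):
        pipe = _make_pipeline(C, seed)
        pipe.fit(X[train], y[train])
        pos = list(pipe.classes_).index(1)
        prob_tr = pipe.predict_proba(X[train])[:, pos]
        prob_te = pipe.predict_proba(X[test])[:, pos]
        oof[test] = prob_te
        auc_tr.append(roc_auc_score(y[train], prob_tr))
        auc_te.append(roc_auc_score(y[test], prob_te))
        f1_tr.append(f1_score(y[train], (prob_tr >= 0.5).astype(int)))
        f1_te.append(f1_score(y[test], (prob_te >= 0.5).astype(int)))
        stats_.append((pipe["impute"].statistics_.copy(),
                       pipe["scale"].mean_.copy()))
    idx = df_point["pore_index"].iloc[0] if "pore_index" in df_point else -1
    return LocalCVResult(
        pore_index=int(idx), oof_prob=oof, y=y,
        mutation_ids=df_point["mutation_id"].to_numpy()
        if "mutation_id" in df_point else np.arange(len(y)),
        auc_train=auc_tr, auc_test=auc_te, f1_train=f1_tr, f1_test=f1_te,
        fold_stats=stats_)


def summarize_by_median(df: pd.DataFrame, feature_cols) -> pd.DataFrame:
    """Median-summarize features over pore points, one row per mutation."""
    agg = {c: "median" for c in feature_cols}
    agg["label"] = "first"
    agg["y"] = "first"
    return df.groupby("mutation_id").agg(agg).reset_index()


def _best_f1_threshold(prob: np.ndarray, y: np.ndarray) -> float:
    """F1-maximizing cut on disease-class probabilities (vectorized scan)."""
    order = np.argsort(-prob, kind="stable")
    y_sorted = y[order]
    p_sorted = prob[order]
    tp = np.cumsum(y_sorted)                 # predictions: prob >= p_sorted[k]
    fp = np.cumsum(1 - y_sorted)
    fn = y.sum() - tp
    f1 = 2 * tp / np.maximum(2 * tp + fp + fn, 1)
    # restrict to the last index of each distinct probability value
    last = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    idx = np.flatnonzero(last)
    best = idx[np.argmax(f1[idx])]
    return float(p_sorted[best])


@dataclass
class MLResult:
    """Final-round score distributions, threshold, and misclassified set."""
    auc_train: np.ndarray
    auc_test: np.ndarray
    f1_train: np.ndarray
    f1_test: np.ndarray
    threshold: float
    oof_prob: np.ndarray
    y: np.ndarray
    mutation_ids: np.ndarray
    misclassified: list
    n_degenerate_resamples: int = 0

    @property
    def median_auc_test(self) -> float:
        return float(np.median(self.auc_test))

    @property
    def median_auc_train(self) -> float:
        return float(np.median(self.auc_train))

    @property
    def median_f1_test(self) -> float:
        return float(np.median(self.f1_test))

    @property
    def median_f1_train(self) -> float:
        return float(np.median(self.f1_train))


def global_model(summary_df: pd.DataFrame, feature_cols, k_folds: int = 5,
                 n_repeats: int = 20, bootstrap_rounds: int = 1000,
                 seed: int = 0, C: float = 1.0) -> MLResult:
    """Final classification round on median-summarized features.

    Repeated stratified CV yields train/test AUC and F1 distributions; the
    decision threshold is the median over bootstrap resamples of the
    F1-maximizing cut on out-of-fold disease-class probabilities.
    Misclassified mutations are disease-class rows whose probability fails
    the threshold.
    """
    summary_df = _drop_sparse_rows(summary_df, feature_cols)
    y = summary_df["y"].to_numpy()
    X = summary_df[feature_cols].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("global model needs both classes")
    if k_folds > counts.min():
        raise ValueError("k_folds exceeds the minority class count")

    cv = RepeatedStratifiedKFold(n_splits=k_folds, n_repeats=n_repeats,
                                 random_state=seed)
    auc_tr, auc_te, f1_tr, f1_te = [], [], [], []
    oof = np.full(len(y), np.nan)
    for split_no, (train, test) in enumerate(cv.split(X, y)):
        pipe = _make_pipeline(C, seed)
        pipe.fit(X[train], y[train])
        pos = list(pipe.classes_).index(1)
        prob_tr = pipe.predict_proba(X[train])[:, pos]
        prob_te = pipe.predict_proba(X[test])[:, pos]
        if split_no < k_folds:  # first repeat provides the o.o.f. probabilities
            oof[test] = prob_te
        auc_tr.append(roc_auc_score(y[train], prob_tr))
        auc_te.append(roc_auc_score(y[test], prob_te))
        f1_tr.append(f1_score(y[train], (prob_tr >= 0.5).astype(int)))
        f1_te.append(f1_score(y[test], (prob_te >= 0.5).astype(int)))

    rng = np.random.default_rng(seed)
    thresholds, degenerate = [], 0
    for _ in range(bootstrap_rounds):
        while True:
            pick = rng.integers(0, len(y), len(y))
            if len(np.unique(y[pick])) == 2:
                break
            degenerate += 1
        thresholds.append(_best_f1_threshold(oof[pick], y[pick]))
    threshold = float(np.median(thresholds))

    ids = summary_df["mutation_id"].to_numpy() \
        if "mutation_id" in summary_df else np.arange(len(y))
    mis = [int(i) for i, yy, pp in zip(ids, y, oof)
           if yy == 1 and pp < threshold]
    return MLResult(
        auc_train=np.array(auc_tr), auc_test=np.array(auc_te),
        f1_train=np.array(f1_tr), f1_test=np.array(f1_te),
        threshold=threshold, oof_prob=oof, y=y, mutation_ids=ids,
        misclassified=mis, n_degenerate_resamples=degenerate)


def feature_importances(df_point: pd.DataFrame, feature_cols,
                        n_rounds: int = 200, seed: int = 0,
                        C: float = 1.0) -> pd.DataFrame:
    """Permutation importances (mean AUC drop over ``n_rounds`` shuffles).

    The model is fitted on all rows of the pore point; each feature column
    is independently permuted ``n_rounds`` times.  Only the ordering of
    importances is contractual, not their sum.
    """
    df_point = _drop_sparse_rows(df_point, feature_cols)
    y = df_point["y"].to_numpy()
    X = df_point[feature_cols].to_numpy()
    pipe = _make_pipeline(C, seed)
    pipe.fit(X, y)
    res = _sk_perm_importance(pipe, X, y, scoring="roc_auc",
                              n_repeats=n_rounds, random_state=seed)
    return pd.DataFrame({"feature": feature_cols,
                         "importance": res.importances_mean,
                         "importance_sd": res.importances_std})
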