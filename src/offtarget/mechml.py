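"""Mechanism-of-action signature learning from drug-panel metabolomics.

A panel of reference antibiotics with known mechanisms (antifolate, cell
wall, DNA synthesis, translation, oxidative stress) is profiled by the same
metabolomics pipeline as the query compound.  After confidence filtering and
per-drug averaging, a multinomial logistic regression learns per-class weight
vectors over the shared metabolite features; the query compound's profile is
scored against them to yield class probabilities, and the class signature can
be projected out to leave a residual, compound-specific signature.  Model
quality is assessed by leave-one-out cross-validation; the panel's structure
is inspected with a 2-D embedding plus DBSCAN and a drug-drug correlation
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.linear_model import LogisticRegression

from .metabstats import AbundanceTable, log_fold_change

__all__ = [
    "DrugProfileSet",
    "MechanismModel",
    "profiles_from_abundance",
    "filter_profiles",
    "train_mechanism_model",
    "evaluate_loocv",
    "predict_mechanism",
    "feature_importance",
    "residual_signature",
    "embed_2d",
    "dbscan_cluster",
    "drug_correlation_matrix",
]


@dataclass
class DrugProfileSet:
    """Drug/condition profiles over a shared metabolite feature namespace.

    features: profile x metabolite log2 fold changes (index = profile id).
    meta: per profile at least 'drug' and 'time_point'; a 'label' column
    carries the mechanism class where known.
    """

    features: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.features.index.equals(self.meta.index):
            raise ValueError("features and meta indices differ")

    def labels(self) -> pd.Series:
        return self.meta["label"]


def profiles_from_abundance(
    table: AbundanceTable,
    labels: dict[str, str],
    control_condition: str = "control",
    pseudocount: float = 0.0,
) -> DrugProfileSet:
    """Convert an abundance panel to per-drug/time log2 fold-change profiles.

    Each treated condition is contrasted against the control at the same time
    point, one profile per (drug, time point).
    """
    rows, meta = [], []
    times = sorted(table.sample_meta["time_point"].unique())
    for cond in table.conditions():
        if cond == control_condition:
            continue
        for t in times:
            tr = table.subset(cond, t)
            ct = table.subset(control_condition, t)
            if tr.empty or ct.empty:
                continue
            lfc = [log_fold_change(tr[m], ct[m], pseudocount)
                   for m in table.intensities.columns]
            rows.append(lfc)
            meta.append({"profile": f"{cond}_t{t:g}", "drug": cond,
                         "time_point": t, "label": labels.get(cond, "unknown")})
    meta = pd.DataFrame(meta).set_index("profile")
    feats = pd.DataFrame(rows, index=meta.index, columns=table.intensities.columns)
    return DrugProfileSet(feats, meta)


def filter_profiles(
    profiles: DrugProfileSet,
    annotation_scores: pd.Series,
    score_threshold: float = 50.0,
    shared_ids=None,
    exclude_zero_time: bool = True,
    average_per_drug: bool = True,
) -> DrugProfileSet:
    """Confidence filtering and per-drug averaging.

    Keeps metabolites with annotation score strictly above the threshold and
    (optionally) present in `shared_ids`, drops zero-time profiles, and
    averages the remaining profiles of each drug feature-wise.
    """
    keep = annotation_scores[annotation_scores > score_threshold].index
    cols = [c for c in profiles.features.columns if c in set(keep)]
    if shared_ids is not None:
        shared = set(shared_ids)
        cols = [c for c in cols if c in shared]
    if not cols:
        raise ValueError("no metabolite features survive filtering")

    feats = profiles.features[cols]
    meta = profiles.meta
    if exclude_zero_time:
        mask = meta["time_point"] > 0
        if not mask.any():
            raise ValueError("all profiles are at time zero; nothing left")
        feats, meta = feats.loc[mask.to_numpy()], meta.loc[mask.to_numpy()]
    if average_per_drug:
        grouped = feats.groupby(meta["drug"]).mean()
        labels = meta.groupby("drug")["label"].first()
        meta = pd.DataFrame({"drug": grouped.index, "time_point": np.nan,
                             "label": labels[grouped.index]},
                            index=grouped.index)
        meta.index.name = "profile"
        grouped.index.name = "profile"
        feats = grouped
    return DrugProfileSet(feats, meta)


@dataclass
class MechanismModel:
    """Trained multinomial softmax model over metabolite features."""

    classes: list[str]
    feature_names: list[str]
    weights: np.ndarray  # class x feature, on standardized features
    intercepts: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    meta: dict = field(default_factory=dict)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_scale

    def predict_proba(self, features: pd.DataFrame) -> pd.DataFrame:
        X = _check_features(features, self.feature_names)
        z = self._standardize(X) @ self.weights.T + self.intercepts
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        return pd.DataFrame(p, index=features.index, columns=self.classes)


def _check_features(features: pd.DataFrame, names: list[str]) -> np.ndarray:
    if list(features.columns) != list(names):
        if set(features.columns) != set(names):
            raise ValueError("profile feature space does not match the model")
        features = features[names]
    return features.to_numpy(dtype=float)


def train_mechanism_model(
    profiles: DrugProfileSet,
    C: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> MechanismModel:
    """Fit an L2-regularized multinomial logistic regression.

    Features are z-scored on the training set (constant features get unit
    scale).  Deterministic given the data order (lbfgs, fixed tolerance).
    """
    labels = profiles.labels()
    known = labels != "unknown"
    X = profiles.features.loc[known.to_numpy()].to_numpy(dtype=float)
    y = labels[known.to_numpy()].to_numpy()
    if len(set(y)) < 2:
        raise ValueError("need at least two mechanism classes to train")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    lr = LogisticRegression(C=C, tol=tol, max_iter=max_iter, solver="lbfgs")
    lr.fit(Xs, y)
    return MechanismModel(
        classes=list(lr.classes_),
        feature_names=list(profiles.features.columns),
        weights=lr.coef_ if len(lr.classes_) > 2 else np.vstack([-lr.coef_, lr.coef_]),
        intercepts=(lr.intercept_ if len(lr.classes_) > 2
                    else np.array([-lr.intercept_[0], lr.intercept_[0]])),
        feature_mean=mean,
        feature_scale=scale,
        meta={"C": C, "tol": tol, "max_iter": max_iter, "n_iter": int(lr.n_iter_[0])},
    )


def predict_mechanism(model: MechanismModel, profiles: DrugProfileSet | pd.DataFrame) -> pd.DataFrame:
    """Class probabilities for one or more profiles (rows sum to 1)."""
    feats = profiles.features if isinstance(profiles, DrugProfileSet) else profiles
    return model.predict_proba(feats)


def evaluate_loocv(profiles: DrugProfileSet, **train_kw):
    """Leave-one-out cross-validation.

    Returns (confusion, per_class_accuracy): confusion rows are true classes
    normalized to 1; classes left with a single member are flagged by NaN
    accuracy (they cannot be held out and still trained on).
    """
    labels = profiles.labels()
    known = (labels != "unknown").to_numpy()
    feats = profiles.features.loc[known]
    labs = labels[known]
    classes = sorted(labs.unique())
    counts = labs.value_counts()
    confusion = pd.DataFrame(0.0, index=classes, columns=classes)
    untrainable = {c for c in classes if counts[c] < 2}
    for pid in feats.index:
        true = labs[pid]
        if true in untrainable:
            continue
        rest = DrugProfileSet(feats.drop(index=pid),
                              profiles.meta.loc[feats.index].drop(index=pid))
        model = train_mechanism_model(rest, **train_kw)
        proba = model.predict_proba(feats.loc[[pid]])
        confusion.loc[true, proba.iloc[0].idxmax()] += 1
    acc = {}
    for c in classes:
        row = confusion.loc[c]
        acc[c] = np.nan if c in untrainable else row[c] / row.sum()
        if row.sum() > 0:
            confusion.loc[c] = row / row.sum()
    return confusion, pd.Series(acc, name="accuracy")


def feature_importance(model: MechanismModel, cls: str) -> pd.DataFrame:
    """Metabolites ranked by |weight| for one class (signed scores retained).

    Weights refer to standardized features, so magnitudes are comparable
    across metabolites.  Ties break deterministically by metabolite id.
    """
    if cls not in model.classes:
        raise KeyError(f"unknown class {cls!r}")
    w = model.weights[model.classes.index(cls)]
    out = pd.DataFrame({"metabolite": model.feature_names, "score": w})
    out["abs_score"] = out["score"].abs()
    out = out.sort_values(["abs_score", "metabolite"], ascending=[False, True])
    return out.drop(columns="abs_score").reset_index(drop=True)


def residual_signature(model: MechanismModel, profile: pd.Series, cls: str) -> pd.Series:
    """Remove a class signature from a profile by orthogonal projection.

    r = x - (<x,w>/<w,w>) w, where w is the class weight vector; <r,w> = 0,
    so the residual carries only variation the class signature cannot
    explain — the compound-specific part of the response.
    """
    if cls not in model.classes:
        raise KeyError(f"unknown class {cls!r}")
    w = model.weights[model.classes.index(cls)]
    x = profile[model.feature_names].to_numpy(dtype=float)
    ww = float(w @ w)
    if ww == 0:
        raise ValueError("class weight vector is zero; projection undefined")
    r = x - (float(x @ w) / ww) * w
    return pd.Series(r, index=model.feature_names, name=f"{profile.name}_residual")


def embed_2d(
    profiles: DrugProfileSet | pd.DataFrame,
    n_neighbors: int = 14,
    random_state: int = 42,
    method: str = "umap",
) -> pd.DataFrame:
    """Deterministic 2-D embedding of profiles (UMAP by default, PCA optional).

    The contract is on the interface — two output components, reproducible
    under random_state — not on a particular algorithm.
    """
    feats = profiles.features if isinstance(profiles, DrugProfileSet) else profiles
    if len(feats) < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1 = {n_neighbors + 1} profiles, got {len(feats)}"
        )
    if method == "umap":
        import umap  # deferred: numba-backed import is heavy

        emb = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        random_state=random_state).fit_transform(
            feats.to_numpy(dtype=float))
    elif method == "pca":
        from sklearn.decomposition import PCA

        emb = PCA(n_components=2, random_state=random_state).fit_transform(
            feats.to_numpy(dtype=float))
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(emb, index=feats.index, columns=["dim1", "dim2"])


def dbscan_cluster(points: pd.DataFrame, eps: float = 0.5, min_samples: int = 5) -> pd.Series:
    """DBSCAN labels for embedded points; noise points are labelled -1."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(
        points.to_numpy(dtype=float))
    return pd.Series(labels, index=points.index, name="cluster")


def drug_correlation_matrix(profiles: DrugProfileSet | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between drug profiles (symmetric, unit diagonal).

    Zero-variance profiles yield NaN rows/columns, flagging the undefined
    entries rather than hiding them.
    """
    feats = profiles.features if isinstance(profiles, DrugProfileSet) else profiles
    if len(feats) < 2 or feats.shape[1] < 2:
        raise ValueError("need >= 2 profiles over >= 2 shared features")
    return feats.T.corr(method="pearson")
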