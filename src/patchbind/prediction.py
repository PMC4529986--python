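"""Ensemble prediction of RNA-binding residues and its evaluation protocol.

Two sklearn-style estimators cover the learning stages:

* :class:`PatchFeaturizer` — a transformer fitted on annotated training
  complexes; it extracts the positive template patches, clusters them into
  the representative set, derives the interface-propensity table, and
  transforms complexes into the 81-column feature frame.
* :class:`EnsembleBindingClassifier` — ridge regression (on +/-1 targets), a
  perceptron and a small multilayer perceptron, each tuned by an inner
  5-fold cross-validation maximizing AUC; the ensemble score is the mean of
  the member outputs clipped to [-1, 1], and a residue is called binding
  when the score reaches the threshold theta (default 0).

:func:`crossvalidate` runs the protein-level 4-fold protocol: proteins (never
residues) are partitioned into folds, and templates, representatives,
propensities and the classifier are all rebuilt from the training proteins of
each fold, so no information from a test protein can leak into its own
prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Perceptron, Ridge
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .clustering import build_representative_set
from .evaluation import MetricsReport, compute_metrics
from .features import assemble_features, compute_propensity, feature_columns
from .patches import extract_templates
from .structure import annotate_complex

__all__ = [
    "PatchFeaturizer",
    "EnsembleBindingClassifier",
    "BindingModel",
    "train_model",
    "crossvalidate",
    "run_ablation",
    "ABLATION_GRID",
    "CrossValResult",
]

#: The feature-ablation design: structural only, sequence-profile only,
#: structural + profile, and all features.
ABLATION_GRID = {
    "structural": dict(structural=True, pssm=False, propensity=False),
    "pssm": dict(structural=False, pssm=True, propensity=False),
    "structural+pssm": dict(structural=True, pssm=True, propensity=False),
    "all": dict(structural=True, pssm=True, propensity=True),
}


class PatchFeaturizer(BaseEstimator, TransformerMixin):
    """Learn the representative patches and propensity table; emit features.

    Parameters
    ----------
    pssms : mapping
        (source_id, chain_id) -> PSI-BLAST profile rows aligned with the
        chain's residues.  PSSMs are data, not learned state, so they are
        supplied at construction.
    d_N : float
        Surface neighbor cutoff in angstrom.
    n3, n2 : int
        Number of 3-aa and 2-aa representative patches (L = n3 + n2).
    n_max : int
        Subsample cap for 3-aa templates before clustering.
    alpha : float
        Additive smoothing pseudo-count of the propensity table.
    random_state : int
        Seed for the template subsample.
    """

    def __init__(self, pssms=None, d_N: float = 3.0, n3: int = 40, n2: int = 20,
                 n_max: int = 10000, alpha: float = 1.0,
                 same_chain_only: bool = False, random_state: int = 0):
        self.pssms = pssms
        self.d_N = d_N
        self.n3 = n3
        self.n2 = n2
        self.n_max = n_max
        self.alpha = alpha
        self.same_chain_only = same_chain_only
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on a list of annotated complexes (surface/binding labels set)."""
        t3, t2 = extract_templates(X, d_N=self.d_N,
                                   same_chain_only=self.same_chain_only)
        self.n_templates_3aa_ = len(t3)
        self.n_templates_2aa_ = len(t2)
        self.representatives_ = build_representative_set(
            t3, t2, n3=self.n3, n2=self.n2, n_max=self.n_max,
            seed=self.random_state)
        self.propensity_ = compute_propensity(X, alpha=self.alpha)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Feature frame (provenance + label + 81 feature columns)."""
        check_is_fitted(self, "representatives_")
        return assemble_features(X, self.representatives_, self.pssms or {},
                                 self.propensity_, d_N=self.d_N,
                                 same_chain_only=self.same_chain_only)


class EnsembleBindingClassifier(BaseEstimator, ClassifierMixin):
    """Mean-aggregated ensemble of ridge regression, perceptron and MLP.

    Labels are encoded +/-1 internally; features are z-scored with training
    statistics stored in the model.  Each member's hyperparameter (ridge
    penalty, perceptron epoch budget, MLP hidden width) is chosen by an inner
    stratified 5-fold cross-validation maximizing AUC.  ``decision_function``
    returns the mean member score clipped to [-1, 1]; ``predict`` thresholds
    it at ``theta``.
    """

    def __init__(self, theta: float = 0.0, ridge_alphas=(0.1, 1.0, 10.0),
                 perceptron_iters=(5, 20, 50), mlp_widths=(5, 10, 20),
                 inner_folds: int = 5, random_state: int = 0):
        self.theta = theta
        self.ridge_alphas = ridge_alphas
        self.perceptron_iters = perceptron_iters
        self.mlp_widths = mlp_widths
        self.inner_folds = inner_folds
        self.random_state = random_state

    # -- member construction -------------------------------------------------

    def _member_grid(self):
        rs = self.random_state
        yield ("ridge", [Ridge(alpha=a) for a in self.ridge_alphas])
        yield ("perceptron",
               [Perceptron(max_iter=int(it), tol=None, random_state=rs + 1)
                for it in self.perceptron_iters])
        yield ("mlp",
               [MLPRegressor(hidden_layer_sizes=(int(w),), activation="tanh",
                             solver="lbfgs", max_iter=500, random_state=rs + 2)
                for w in self.mlp_widths])

    @staticmethod
    def _member_score(model, X) -> np.ndarray:
        if isinstance(model, Perceptron):
            return np.tanh(model.decision_function(X))
        return np.clip(model.predict(X), -1.0, 1.0)

    @staticmethod
    def _fit_member(model, X, y_pm):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            if isinstance(model, Perceptron):
                model.fit(X, y_pm)
            else:
                model.fit(X, y_pm.astype(float))
        return model

    def _tune_member(self, candidates, X, y_pm) -> BaseEstimator:
        """Inner-CV AUC selection; the first best candidate wins ties."""
        if len(candidates) == 1:
            return candidates[0]
        counts = np.bincount((y_pm > 0).astype(int))
        n_splits = min(self.inner_folds, int(counts.min()))
        if n_splits < 2:
            return candidates[len(candidates) // 2]
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                             random_state=self.random_state)
        best, best_auc = candidates[0], -np.inf
        for cand in candidates:
            aucs = []
            for tr, te in cv.split(X, y_pm):
                model = self._fit_member(clone(cand), X[tr], y_pm[tr])
                s = self._member_score(model, X[te])
                if len(np.unique(y_pm[te])) < 2:
                    continue
                aucs.append(roc_auc_score(y_pm[te], s))
            mean_auc = float(np.mean(aucs)) if aucs else -np.inf
            if mean_auc > best_auc:
                best, best_auc = cand, mean_auc
        return best

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        if classes.size > 2:
            raise ValueError("binary classification only")
        self.classes_ = classes
        y_pm = np.where(y == classes[1], 1.0, -1.0)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.members_ = []
        self.tuning_record_ = {}
        for name, candidates in self._member_grid():
            chosen = self._tune_member(candidates, Xs, y_pm)
            fitted = self._fit_member(clone(chosen), Xs, y_pm)
            self.members_.append((name, fitted))
            self.tuning_record_[name] = chosen.get_params()
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Ensemble binding score in [-1, 1] (higher = more likely binding)."""
        check_is_fitted(self, "members_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        Xs = self.scaler_.transform(X)
        scores = np.mean([self._member_score(m, Xs) for _, m in self.members_],
                         axis=0)
        return np.clip(scores, -1.0, 1.0)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores >= self.theta, self.classes_[1], self.classes_[0])

    # -- portable serialization ----------------------------------------------

    def to_dict(self) -> dict:
        """JSON-serializable snapshot of the fitted ensemble (weights, the
        feature-scaling statistics, and the tuning record)."""
        check_is_fitted(self, "members_")
        members = []
        for name, model in self.members_:
            entry = {"name": name}
            if name == "ridge":
                entry["params"] = {"alpha": model.alpha}
                entry["coef"] = model.coef_.tolist()
                entry["intercept"] = float(model.intercept_)
            elif name == "perceptron":
                entry["params"] = {"max_iter": model.max_iter}
                entry["coef"] = model.coef_.tolist()
                entry["intercept"] = model.intercept_.tolist()
                entry["classes"] = model.classes_.tolist()
            else:  # mlp
                entry["params"] = {
                    "hidden_layer_sizes": list(model.hidden_layer_sizes)}
                entry["coefs"] = [c.tolist() for c in model.coefs_]
                entry["intercepts"] = [b.tolist() for b in model.intercepts_]
            members.append(entry)
        return {
            "theta": self.theta,
            "random_state": self.random_state,
            "classes": self.classes_.tolist(),
            "n_features_in": int(self.n_features_in_),
            "scaler_mean": self.scaler_.mean_.tolist(),
            "scaler_scale": self.scaler_.scale_.tolist(),
            "tuning_record": self.tuning_record_,
            "members": members,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleBindingClassifier":
        clf = cls(theta=d["theta"], random_state=d["random_state"])
        clf.classes_ = np.asarray(d["classes"])
        clf.n_features_in_ = int(d["n_features_in"])
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(d["scaler_mean"])
        scaler.scale_ = np.asarray(d["scaler_scale"])
        scaler.var_ = scaler.scale_ ** 2
        scaler.n_features_in_ = clf.n_features_in_
        clf.scaler_ = scaler
        clf.tuning_record_ = d.get("tuning_record", {})
        members = []
        for entry in d["members"]:
            name = entry["name"]
            if name == "ridge":
                model = Ridge(alpha=entry["params"]["alpha"])
                model.coef_ = np.asarray(entry["coef"])
                model.intercept_ = entry["intercept"]
                model.n_features_in_ = clf.n_features_in_
            elif name == "perceptron":
                model = Perceptron(max_iter=entry["params"]["max_iter"],
                                   tol=None)
                model.coef_ = np.asarray(entry["coef"])
                model.intercept_ = np.asarray(entry["intercept"])
                model.classes_ = np.asarray(entry["classes"])
                model.n_features_in_ = clf.n_features_in_
            else:
                model = MLPRegressor(
                    hidden_layer_sizes=tuple(
                        entry["params"]["hidden_layer_sizes"]),
                    activation="tanh")
                model.coefs_ = [np.asarray(c) for c in entry["coefs"]]
                model.intercepts_ = [np.asarray(b)
                                     for b in entry["intercepts"]]
                model.n_layers_ = len(model.coefs_) + 1
                model.n_outputs_ = 1
                model.out_activation_ = "identity"
                model.n_features_in_ = clf.n_features_in_
            members.append((name, model))
        clf.members_ = members
        return clf


# ---------------------------------------------------------------------------
# cross-validation protocol
# ---------------------------------------------------------------------------

@dataclass
class CrossValResult:
    """Per-fold and pooled evaluation of the full pipeline."""

    pooled: MetricsReport
    fold_metrics: list[MetricsReport]
    predictions: pd.DataFrame
    fold_details: list[dict] = field(default_factory=list)
    per_category: dict[str, MetricsReport] = field(default_factory=dict)
    fold_metric_means: dict[str, float] = field(default_factory=dict)


def _assign_folds(source_ids: list[str], n_folds: int, seed: int
                  ) -> list[list[str]]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(source_ids))
    return [[source_ids[i] for i in part]
            for part in np.array_split(order, n_folds)]


def crossvalidate(complexes, pssms, n_folds: int = 4, seed: int = 0,
                  d_N: float = 3.0, binding_cutoff: float = 5.0,
                  probe_radius: float = 1.4, n_sphere_points: int = 960,
                  n3: int = 40, n2: int = 20, n_max: int = 10000,
                  theta: float = 0.0, alpha: float = 1.0,
                  structural: bool = True, pssm: bool = True,
                  propensity: bool = True, annotate: bool = True,
                  categories: dict | None = None) -> CrossValResult:
    """Protein-level n-fold cross-validation of the whole pipeline.

    Complexes are annotated (SASA, surface, binding), partitioned into folds
    at the protein level under ``seed``, and for each fold the templates,
    representative patches, propensity table and classifier are derived from
    the training proteins only.  Reports per-fold metrics, pooled metrics
    over the concatenated test scores, and (when ``categories`` maps
    source_id -> tag) a per-category breakdown.
    """
    complexes = list(complexes)
    if len(complexes) < n_folds:
        raise ValueError(f"need at least {n_folds} proteins, got {len(complexes)}")
    if annotate:
        for cm in complexes:
            annotate_complex(cm, probe_radius=probe_radius,
                             n_sphere_points=n_sphere_points,
                             binding_cutoff=binding_cutoff)
    by_id = {cm.source_id: cm for cm in complexes}
    folds = _assign_folds(list(by_id), n_folds, seed)
    cols = feature_columns(structural=structural, pssm=pssm,
                           propensity=propensity, L=n3 + n2)

    all_preds = []
    fold_metrics = []
    fold_details = []
    for fold_i, test_ids in enumerate(folds):
        test_set = set(test_ids)
        train_cms = [cm for sid, cm in by_id.items() if sid not in test_set]
        test_cms = [by_id[sid] for sid in test_ids]

        feat = PatchFeaturizer(pssms=pssms, d_N=d_N, n3=n3, n2=n2,
                               n_max=n_max, alpha=alpha,
                               random_state=seed).fit(train_cms)
        train_frame = feat.transform(train_cms)
        test_frame = feat.transform(test_cms)

        clf = EnsembleBindingClassifier(theta=theta, random_state=seed)
        clf.fit(train_frame[cols].to_numpy(), train_frame["label"].to_numpy())
        scores = clf.decision_function(test_frame[cols].to_numpy())

        pred = test_frame[["source_id", "chain_id", "seq_index", "label"]].copy()
        pred["score"] = scores
        pred["predicted"] = (scores >= theta).astype(int)
        pred["fold"] = fold_i
        all_preds.append(pred)
        fold_metrics.append(compute_metrics(scores,
                                            test_frame["label"].to_numpy(),
                                            theta=theta))
        fold_details.append({
            "train_ids": sorted(cm.source_id for cm in train_cms),
            "test_ids": sorted(test_ids),
            "template_sources": sorted({p.origin[0]
                                        for p in feat.representatives_.ordered()}),
            "n_templates_3aa": feat.n_templates_3aa_,
            "n_templates_2aa": feat.n_templates_2aa_,
        })

    predictions = pd.concat(all_preds, ignore_index=True)
    pooled = compute_metrics(predictions["score"].to_numpy(),
                             predictions["label"].to_numpy(), theta=theta)
    per_category = {}
    if categories:
        predictions["category"] = predictions["source_id"].map(categories)
        for cat, grp in predictions.groupby("category"):
            per_category[cat] = compute_metrics(grp["score"].to_numpy(),
                                                grp["label"].to_numpy(),
                                                theta=theta)
    means = {}
    for name in ("sensitivity", "accuracy", "precision", "specificity",
                 "f_score", "mcc", "auc"):
        vals = [getattr(m, name) for m in fold_metrics]
        means[name] = float(np.nanmean(vals))
    return CrossValResult(pooled=pooled, fold_metrics=fold_metrics,
                          predictions=predictions, fold_details=fold_details,
                          per_category=per_category, fold_metric_means=means)


@dataclass
class BindingModel:
    """The portable trained artifact: representative patches, propensity
    table, the fitted ensemble, and the feature-block configuration."""

    featurizer: PatchFeaturizer
    classifier: EnsembleBindingClassifier
    columns: list[str]

    def predict_frame(self, complexes, pssms) -> pd.DataFrame:
        """Score annotated complexes; returns provenance + score + label."""
        feat = self.featurizer
        feat.pssms = pssms
        frame = feat.transform(complexes)
        scores = self.classifier.decision_function(
            frame[self.columns].to_numpy())
        out = frame[["source_id", "chain_id", "seq_index", "label"]].copy()
        out["score"] = scores
        out["predicted"] = (scores >= self.classifier.theta).astype(int)
        return out

    def save(self, path) -> None:
        import json

        payload = {
            "representatives": self.featurizer.representatives_.to_dict(),
            "propensity": self.featurizer.propensity_,
            "featurizer_params": {
                k: v for k, v in self.featurizer.get_params().items()
                if k != "pssms"},
            "ensemble": self.classifier.to_dict(),
            "columns": self.columns,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "BindingModel":
        import json

        from .clustering import RepresentativeSet

        with open(path) as fh:
            payload = json.load(fh)
        feat = PatchFeaturizer(**payload["featurizer_params"])
        feat.representatives_ = RepresentativeSet.from_dict(
            payload["representatives"])
        feat.propensity_ = payload["propensity"]
        feat.n_templates_3aa_ = -1
        feat.n_templates_2aa_ = -1
        clf = EnsembleBindingClassifier.from_dict(payload["ensemble"])
        return cls(featurizer=feat, classifier=clf,
                   columns=list(payload["columns"]))


def train_model(complexes, pssms, d_N: float = 3.0, n3: int = 40,
                n2: int = 20, n_max: int = 10000, alpha: float = 1.0,
                theta: float = 0.0, seed: int = 0, structural: bool = True,
                pssm: bool = True, propensity: bool = True) -> BindingModel:
    """Fit the featurizer and ensemble on annotated training complexes."""
    feat = PatchFeaturizer(pssms=pssms, d_N=d_N, n3=n3, n2=n2, n_max=n_max,
                           alpha=alpha, random_state=seed).fit(complexes)
    frame = feat.transform(complexes)
    cols = feature_columns(structural=structural, pssm=pssm,
                           propensity=propensity, L=n3 + n2)
    clf = EnsembleBindingClassifier(theta=theta, random_state=seed)
    clf.fit(frame[cols].to_numpy(), frame["label"].to_numpy())
    return BindingModel(featurizer=feat, classifier=clf, columns=cols)


def run_ablation(complexes, pssms, **kwargs) -> dict[str, CrossValResult]:
    """The feature-ablation design over identical folds.

    Runs the four block configurations (structural / pssm / structural+pssm /
    all) with the same seed, so the fold assignment is shared and results are
    directly comparable.
    """
    results = {}
    annotate = kwargs.pop("annotate", True)
    for name, blocks in ABLATION_GRID.items():
        results[name] = crossvalidate(complexes, pssms, annotate=annotate,
                                      **{**kwargs, **blocks})
        annotate = False  # labels persist on the complex objects
    return results
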