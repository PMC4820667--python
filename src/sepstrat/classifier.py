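"""Sparse gene-signature classification of SRS membership and mortality.

An L1-penalized logistic regression is fitted over a decreasing penalty
path. The default path criterion is the extended BIC (deviance +
k log n + 2 gamma k log p), which is consistent for support recovery in
the p >> n regime; cross-validated deviance with the one-standard-error
rule is available as an alternative but over-selects when spurious
whole-sample correlations survive into every CV fold. Features are
standardized internally and the scaling is stored so a trained model can
be re-applied exactly to new cohorts. Leave-one-out cross-validation
repeats the entire selection (screening, path and penalty choice) inside
every fold, so the reported misclassification rate is free of selection
leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = ["SparseSignatureModel", "SrsModel", "CvResult",
           "select_predictive_model", "loocv_misclassification", "assign_srs",
           "compare_predictor_families"]


@dataclass
class SrsModel:
    """Trained sparse logistic model with stored standardization."""

    selected_features: list
    coefficients: np.ndarray  # on the standardized scale, selected features only
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    response: str = "SRS"
    positive_class: str = "SRS1"
    penalty_C: float = 1.0
    separation_warning: bool = False

    def decision(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in X.columns]
        if missing:
            raise KeyError(f"features absent from input: {missing}")
        Z = (X[self.selected_features].to_numpy(float) - self.feature_means) / self.feature_sds
        return self.intercept + Z @ self.coefficients

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision(X)))

    def summary(self) -> str:
        lines = [f"Sparse logistic model ({self.response}; positive = {self.positive_class})",
                 f"  features selected: {len(self.selected_features)}",
                 f"  penalty C:         {self.penalty_C:.4g}"]
        for f, c in zip(self.selected_features, self.coefficients):
            lines.append(f"    {f}: {c:+.3f}")
        if self.separation_warning:
            lines.append("  warning: complete separation at the chosen penalty")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "selected_features": list(self.selected_features),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "response": self.response,
            "positive_class": self.positive_class,
            "penalty_C": self.penalty_C,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SrsModel":
        return cls(
            selected_features=list(d["selected_features"]),
            coefficients=np.asarray(d["coefficients"], float),
            intercept=float(d["intercept"]),
            feature_means=np.asarray(d["feature_means"], float),
            feature_sds=np.asarray(d["feature_sds"], float),
            response=d.get("response", "SRS"),
            positive_class=d.get("positive_class", "SRS1"),
            penalty_C=float(d.get("penalty_C", 1.0)),
        )


@dataclass
class CvResult:
    misclassification_rate: float
    predictions: pd.Series  # held-out predicted class per sample
    probabilities: pd.Series
    n_folds: int
    degenerate_folds: int = 0

    def summary(self) -> str:
        return (f"LOOCV over {self.n_folds} folds: misclassification "
                f"{100 * self.misclassification_rate:.1f}%"
                + (f" ({self.degenerate_folds} degenerate folds)"
                   if self.degenerate_folds else ""))


def _screen_features(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Top-k features by absolute two-sample t (cheap univariate screen)."""
    if k >= X.shape[1]:
        return np.arange(X.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t, _ = stats.ttest_ind(X[y == 1], X[y == 0], axis=0, equal_var=False)
    t = np.nan_to_num(t)
    return np.sort(np.argsort(-np.abs(t))[:k])


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -2.0 * float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class SparseSignatureModel:
    """Model object: features + binary response -> sparse logistic fit.

    Parameters
    ----------
    features : samples x features DataFrame (expression and/or covariates)
    response : binary Series aligned to features (positive class below)
    positive_class : value of ``response`` coded as 1
    screen_top_k : optional univariate pre-screen (applied inside CV folds
        as well, so it never leaks); ``None`` disables screening
    max_support : optional cap on support size for demonstration panels;
        the path point with at most this many features and best CV
        deviance is used
    """

    features: pd.DataFrame
    response: pd.Series
    positive_class: object = "SRS1"
    response_name: str = "SRS"
    n_penalties: int = 20
    penalty_selection: str = "ebic"  # or "cv1se"
    ebic_gamma: float = 0.5
    cv_folds: int = 5
    screen_top_k: int | None = None
    max_support: int | None = None
    seed: int = 0

    def _xy(self):
        X = self.features.to_numpy(float)
        y = (self.response.loc[self.features.index] == self.positive_class).to_numpy(int)
        return X, y

    def fit(self) -> SrsModel:
        X, y = self._xy()
        if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
            raise ValueError("need at least 2 samples in each response class")
        return self._fit_arrays(X, y, np.asarray(self.features.columns, dtype=object))

    # ---- internals shared by fit() and LOOCV ----

    @staticmethod
    def _l1_fit(Z, y, C):
        clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                 max_iter=2000, random_state=0)
        clf.fit(Z, y)
        return clf

    def _fit_arrays(self, X: np.ndarray, y: np.ndarray, names: np.ndarray) -> SrsModel:
        keep = _screen_features(X, y, self.screen_top_k) \
            if self.screen_top_k else np.arange(X.shape[1])
        Xs = X[:, keep]
        mu, sd = Xs.mean(axis=0), Xs.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (Xs - mu) / sd
        Cs = np.logspace(-2.5, 1.5, self.n_penalties)
        if self.penalty_selection == "ebic":
            C_star = self._choose_penalty_ebic(Z, y, Cs)
        elif self.penalty_selection == "cv1se":
            C_star = self._choose_penalty(Z, y, Cs)
        else:
            raise ValueError(f"unknown penalty_selection {self.penalty_selection!r}")
        clf = self._l1_fit(Z, y, C_star)
        coefs = clf.coef_.ravel()
        support = np.nonzero(coefs)[0]
        if support.size == 0:
            # nothing survives the penalty: degenerate model carrying the
            # strongest univariate feature with a zero coefficient, predicting
            # every sample from the intercept (training log-odds)
            j = int(np.argmax(np.abs(Z.T @ (y - y.mean()))))
            prior = float(np.clip(y.mean(), 1e-9, 1 - 1e-9))
            return SrsModel(
                selected_features=[names[keep[j]]],
                coefficients=np.array([0.0]),
                intercept=float(np.log(prior / (1 - prior))),
                feature_means=mu[[j]],
                feature_sds=sd[[j]],
                response=self.response_name,
                positive_class=self.positive_class,
                penalty_C=float(C_star),
            )
        p_in = 1.0 / (1.0 + np.exp(-(clf.intercept_[0] + Z @ coefs)))
        separated = bool(np.all((p_in > 0.5) == (y == 1))) and \
            (np.min(np.abs(p_in - 0.5)) > 0.499)
        if separated:
            warnings.warn("complete separation at the chosen penalty; "
                          "coefficients remain penalized")
        return SrsModel(
            selected_features=[names[keep[j]] for j in support],
            coefficients=coefs[support],
            intercept=float(clf.intercept_[0]),
            feature_means=mu[support],
            feature_sds=sd[support],
            response=self.response_name,
            positive_class=self.positive_class,
            penalty_C=float(C_star),
            separation_warning=separated,
        )

    def _choose_penalty_ebic(self, Z: np.ndarray, y: np.ndarray, Cs: np.ndarray) -> float:
        """Extended BIC over the path: -2 loglik + k log n + 2 gamma k log p."""
        n, p = Z.shape
        best_C, best_score = Cs[0], np.inf
        for C in Cs:
            clf = self._l1_fit(Z, y, C)
            pr = np.clip(clf.predict_proba(Z)[:, 1], 1e-12, 1 - 1e-12)
            m2ll = -2.0 * float(np.sum(y * np.log(pr) + (1 - y) * np.log(1 - pr)))
            k = int(np.count_nonzero(clf.coef_))
            if self.max_support is not None and k > self.max_support:
                continue
            score = m2ll + k * np.log(n) + 2.0 * self.ebic_gamma * k * np.log(max(p, 2))
            if score < best_score:
                best_score, best_C = score, C
        return float(best_C)

    def _choose_penalty(self, Z: np.ndarray, y: np.ndarray, Cs: np.ndarray) -> float:
        """CV deviance over the path; sparsest C within 1 SE of the best."""
        rng = np.random.default_rng(self.seed)
        n = len(y)
        folds = np.zeros(n, dtype=int)
        # stratified folds so every fold sees both classes where possible
        for cls in (0, 1):
            idx = np.nonzero(y == cls)[0]
            rng.shuffle(idx)
            folds[idx] = np.arange(len(idx)) % self.cv_folds
        dev = np.zeros((self.cv_folds, len(Cs)))
        support_sizes = np.zeros(len(Cs))
        for f in range(self.cv_folds):
            tr, te = folds != f, folds == f
            if len(np.unique(y[tr])) < 2 or te.sum() == 0:
                continue
            for j, C in enumerate(Cs):
                clf = self._l1_fit(Z[tr], y[tr], C)
                p = clf.predict_proba(Z[te])[:, 1]
                dev[f, j] = _deviance(y[te], p) / te.sum()
        mean_dev = dev.mean(axis=0)
        se_dev = dev.std(axis=0, ddof=1) / np.sqrt(self.cv_folds)
        best = int(np.argmin(mean_dev))
        limit = mean_dev[best] + se_dev[best]
        candidates = [j for j in range(len(Cs)) if mean_dev[j] <= limit]
        if self.max_support is not None:
            for j in sorted(candidates):  # smallest C = sparsest first
                clf = self._l1_fit(Z, y, Cs[j])
                if np.count_nonzero(clf.coef_) <= self.max_support:
                    return float(Cs[j])
        # 1-SE rule: the smallest C (strongest penalty) within one SE
        return float(Cs[min(candidates)])

    # ---- leave-one-out CV with in-fold selection ----

    def loocv(self) -> CvResult:
        X, y = self._xy()
        n = len(y)
        if n < 10:
            raise ValueError("LOOCV needs at least 10 samples")
        names = np.asarray(self.features.columns, dtype=object)
        preds = np.empty(n, dtype=int)
        probs = np.empty(n)
        degenerate = 0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            ytr = y[mask]
            if len(np.unique(ytr)) < 2 or min(np.bincount(ytr)) < 2:
                degenerate += 1
                preds[i] = int(np.round(ytr.mean()))
                probs[i] = ytr.mean()
                continue
            model = self._fit_arrays(X[mask], ytr, names)
            probs[i] = float(model.predict_proba(self.features.iloc[[i]])[0])
            preds[i] = int(probs[i] >= 0.5)
        rate = float(np.mean(preds != y))
        idx = self.features.index
        neg = [c for c in pd.unique(self.response) if c != self.positive_class]
        neg_label = neg[0] if neg else f"not-{self.positive_class}"
        pred_labels = pd.Series(
            np.where(preds == 1, self.positive_class, neg_label), index=idx)
        if degenerate:
            warnings.warn(f"{degenerate} folds lost an entire class; "
                          "predicted by majority class")
        return CvResult(rate, pred_labels, pd.Series(probs, index=idx), n, degenerate)


# ------------------------------------------------------- functional surface

def select_predictive_model(features: pd.DataFrame, response: pd.Series,
                            positive_class="SRS1", **kwargs) -> SrsModel:
    return SparseSignatureModel(features, response, positive_class, **kwargs).fit()


def loocv_misclassification(features: pd.DataFrame, response: pd.Series,
                            positive_class="SRS1", **kwargs) -> CvResult:
    return SparseSignatureModel(features, response, positive_class, **kwargs).loocv()


def assign_srs(expr_new: pd.DataFrame, model: SrsModel) -> pd.DataFrame:
    """Apply a trained model to a new samples x features table.

    Fails listing absent feature ids rather than imputing. Label is the
    positive class iff predicted probability >= 0.5.
    """
    proba = model.predict_proba(expr_new)
    neg_label = "SRS2" if model.positive_class == "SRS1" else f"not-{model.positive_class}"
    return pd.DataFrame(
        {
            "probability": proba,
            "label": np.where(proba >= 0.5, model.positive_class, neg_label),
        },
        index=expr_new.index,
    )


def compare_predictor_families(families: dict, response: pd.Series,
                               positive_class="SRS1", **kwargs) -> pd.DataFrame:
    """LOOCV misclassification for each named feature family.

    ``families`` maps family name -> samples x features DataFrame. Empty
    families are skipped with a warning.
    """
    rows = []
    for name, feats in families.items():
        if feats is None or feats.shape[1] == 0:
            warnings.warn(f"family '{name}' is empty; skipped")
            continue
        cv = loocv_misclassification(feats, response, positive_class, **kwargs)
        rows.append((name, feats.shape[1], cv.misclassification_rate))
    return pd.DataFrame(rows, columns=["family", "n_features", "misclassification"])
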