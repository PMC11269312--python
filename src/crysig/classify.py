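"""Supervised identification of baby identity from cry features.

Four train/test regimes probe how well individual vocal signatures generalize:
within-discomfort (leave-one-out), mixed discomfort+pain (leave-one-out),
cross-condition (fit on all discomfort cries, test on all pain cries in one
pass), and within-pain (leave-one-out).  Classifiers operate on one of three
feature spaces: the first 20 principal components of the flattened MPS
(refitted on each training fold to avoid leakage), the 22 predefined acoustic
features, or the 10-feature spectral subset.  Results are reported as a
confusion matrix of mean posterior probabilities (rows sum to one) together
with hard correct/total counts under the maximum-posterior rule, and regimes
are compared with exact Fisher and binomial tests on those counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ClassificationError",
    "EligibilityRule",
    "ClassifierSpec",
    "CVScheme",
    "CorpusFeatures",
    "ClassificationReport",
    "SCHEMES",
    "select_eligible",
    "classify_identity",
    "fisher_compare",
    "binomial_vs_chance",
]


class ClassificationError(ValueError):
    """Invalid classification setup."""


@dataclass(frozen=True)
class EligibilityRule:
    """Minimum per-baby sample counts for inclusion in the analyses.

    Leave-one-out regimes that train on discomfort cries require one extra
    discomfort exemplar beyond the training minimum (the held-out cry).
    """

    min_discomfort_train: int = 5
    min_pain: int = 4
    min_total: int = 10
    extra_for_loo: int = 1

    def validate(self) -> None:
        if min(self.min_discomfort_train, self.min_pain, self.min_total) < 1:
            raise ClassificationError("eligibility thresholds must be >= 1")


@dataclass(frozen=True)
class ClassifierSpec:
    model: str = "LDA"  # LDA | QDA | RF
    feature_space: str = "MPS-PC20"  # MPS-PC20 | PAF22 | PAF10
    standardize: bool = True
    pca_components: int = 20
    seed: int = 0


@dataclass(frozen=True)
class CVScheme:
    kind: str  # "LOO-within" | "cross-condition"
    train_conditions: tuple[str, ...]
    test_conditions: tuple[str, ...]

    def validate(self) -> None:
        if self.kind == "cross-condition":
            if set(self.train_conditions) & set(self.test_conditions):
                raise ClassificationError(
                    "cross-condition requires disjoint train/test condition sets"
                )
        elif self.kind == "LOO-within":
            if tuple(self.train_conditions) != tuple(self.test_conditions):
                raise ClassificationError("LOO-within uses one condition set")
        else:
            raise ClassificationError(f"unknown CV scheme kind {self.kind!r}")


SCHEMES = {
    "within-discomfort": CVScheme("LOO-within", ("discomfort",), ("discomfort",)),
    "mixed": CVScheme("LOO-within", ("discomfort", "pain"), ("discomfort", "pain")),
    "cross": CVScheme("cross-condition", ("discomfort",), ("pain",)),
    "within-pain": CVScheme("LOO-within", ("pain",), ("pain",)),
}


@dataclass
class CorpusFeatures:
    """Feature matrix plus per-cry labels, the common input to the classifiers."""

    X: np.ndarray
    baby_ids: np.ndarray
    conditions: np.ndarray
    sequence_ids: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.baby_ids = np.asarray(self.baby_ids)
        self.conditions = np.asarray(self.conditions)
        if len(self.baby_ids) != len(self.X) or len(self.conditions) != len(self.X):
            raise ClassificationError("label arrays must match the feature matrix")

    def subset(self, mask: np.ndarray) -> "CorpusFeatures":
        return CorpusFeatures(
            self.X[mask],
            self.baby_ids[mask],
            self.conditions[mask],
            None if self.sequence_ids is None else np.asarray(self.sequence_ids)[mask],
        )


@dataclass
class ClassificationReport:
    confusion: pd.DataFrame  # true baby x predicted baby, mean posteriors
    mean_diag_posterior: float
    diag_posterior_2se: float
    correct_count: int
    total_count: int
    chance_level: float
    scheme: str = ""
    model: str = ""
    feature_space: str = ""
    tie_count: int = 0

    @property
    def accuracy(self) -> float:
        return self.correct_count / self.total_count


def select_eligible(
    metadata: pd.DataFrame, rule: EligibilityRule, scheme: CVScheme
) -> list[str]:
    """Babies with enough cries for the requested regime.

    Requires >= min_pain pain cries, >= min_total cries overall and
    >= min_discomfort_train discomfort cries (plus ``extra_for_loo`` when the
    regime holds discomfort cries out one at a time).
    """
    rule.validate()
    scheme.validate()
    counts = (
        metadata.groupby(["baby_id", "condition"]).size().unstack(fill_value=0)
    )
    for cond in ("discomfort", "pain"):
        if cond not in counts.columns:
            counts[cond] = 0
    need_disc = rule.min_discomfort_train
    if scheme.kind == "LOO-within" and "discomfort" in scheme.train_conditions:
        need_disc += rule.extra_for_loo
    ok = (
        (counts["discomfort"] >= need_disc)
        & (counts["pain"] >= rule.min_pain)
        & ((counts["discomfort"] + counts["pain"]) >= rule.min_total)
    )
    eligible = sorted(counts.index[ok])
    if not eligible:
        raise ClassificationError(
            "no baby satisfies the eligibility thresholds; consider relaxing them"
        )
    return eligible


def _make_model(spec: ClassifierSpec):
    if spec.model == "LDA":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.01)
    if spec.model == "QDA":
        # eigen solver + shrinkage keeps tiny per-class folds well-posed
        return QuadraticDiscriminantAnalysis(solver="eigen", shrinkage=0.1)
    if spec.model == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=spec.seed)
    raise ClassificationError(f"unknown model {spec.model!r}")


def _align_proba(model, proba, classes):
    out = np.zeros((proba.shape[0], len(classes)))
    idx = {c: i for i, c in enumerate(classes)}
    for j, c in enumerate(model.classes_):
        out[:, idx[c]] = proba[:, j]
    return out


def _fit_predict(spec: ClassifierSpec, X_train, y_train, X_test, classes):
    """Fit preprocessing + model on the training fold, return test posteriors
    aligned to ``classes``.

    PAF spaces are standardized on the training fold; the MPS space (dB values
    on a common scale) is projected onto its leading principal components,
    refitted per fold.
    """
    if spec.standardize and spec.feature_space != "MPS-PC20":
        scaler = StandardScaler().fit(X_train)
        X_train = scaler.transform(X_train)
        X_test = scaler.transform(X_test)
    if spec.feature_space == "MPS-PC20":
        k = min(spec.pca_components, X_train.shape[0] - 1, X_train.shape[1])
        pca = PCA(n_components=k, svd_solver="auto", random_state=spec.seed).fit(X_train)
        X_train = pca.transform(X_train)
        X_test = pca.transform(X_test)
    model = _make_model(spec)
    model.fit(X_train, y_train)
    proba = model.predict_proba(np.atleast_2d(X_test))
    return _align_proba(model, proba, classes)


def _loo_gram_pca_posteriors(spec: ClassifierSpec, X, y, classes):
    """Leave-one-out posteriors with exact per-fold PCA via the Gram matrix.

    For n samples in d >> n dimensions, each fold's centered PCA is obtained
    from the eigendecomposition of the double-centered (n-1)x(n-1) Gram
    submatrix, so the d-dimensional data are touched only once.  Numerically
    identical to refitting a full PCA per fold, at a fraction of the cost.
    """
    from scipy.linalg import eigh

    n = len(X)
    G = X @ X.T
    out = []
    for i in range(n):
        T = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        GTT = G[np.ix_(T, T)]
        row_means = GTT.mean(axis=1)
        total = row_means.mean()
        Gc = GTT - row_means[None, :] - row_means[:, None] + total
        k = min(spec.pca_components, len(T) - 1)
        evals, evecs = eigh(Gc, subset_by_index=(len(T) - k, len(T) - 1))
        order = np.argsort(evals)[::-1]
        evals, evecs = np.maximum(evals[order], 1e-12), evecs[:, order]
        scores_train = evecs * np.sqrt(evals)
        gi = G[i, T]
        ci = gi - gi.mean() - row_means + total
        score_test = (ci @ evecs) / np.sqrt(evals)
        model = _make_model(spec)
        model.fit(scores_train, y[T])
        proba = model.predict_proba(score_test[None, :])
        out.append(_align_proba(model, proba, classes)[0])
    return out


def classify_identity(
    features: CorpusFeatures, spec: ClassifierSpec, scheme: CVScheme
) -> ClassificationReport:
    """Run one classifier x feature-space x CV-scheme combination.

    LOO-within refits the preprocessing and model for every held-out cry;
    cross-condition fits once on the training conditions and scores all test-
    condition cries.  Posteriors are aggregated by true baby into a confusion
    matrix whose rows are mean posterior vectors (each summing to one); hard
    counts use the maximum-posterior rule with ties broken toward the lowest
    baby label.
    """
    scheme.validate()
    classes = sorted(set(features.baby_ids))
    if len(classes) < 2:
        raise ClassificationError("need at least 2 babies")
    post_rows = []  # (true_baby, posterior vector)
    tie_count = 0

    if scheme.kind == "LOO-within":
        mask = np.isin(features.conditions, scheme.train_conditions)
        sub = features.subset(mask)
        if set(classes) - set(sub.baby_ids):
            raise ClassificationError("a baby has no cries in the scheme's conditions")
        n = len(sub.X)
        ids, counts = np.unique(sub.baby_ids, return_counts=True)
        if counts.min() < 2:
            raise ClassificationError(
                f"baby {ids[np.argmin(counts)]} absent from training fold"
            )
        if spec.feature_space == "MPS-PC20":
            probas = _loo_gram_pca_posteriors(spec, sub.X, sub.baby_ids, classes)
            post_rows.extend(zip(sub.baby_ids, probas))
        else:
            for i in range(n):
                keep = np.ones(n, dtype=bool)
                keep[i] = False
                proba = _fit_predict(
                    spec, sub.X[keep], sub.baby_ids[keep], sub.X[i : i + 1], classes
                )
                post_rows.append((sub.baby_ids[i], proba[0]))
    else:
        train_mask = np.isin(features.conditions, scheme.train_conditions)
        test_mask = np.isin(features.conditions, scheme.test_conditions)
        train, test = features.subset(train_mask), features.subset(test_mask)
        missing = set(test.baby_ids) - set(train.baby_ids)
        if missing:
            raise ClassificationError(
                f"test babies absent from the training set: {sorted(missing)}"
            )
        proba = _fit_predict(spec, train.X, train.baby_ids, test.X, classes)
        for i in range(len(test.X)):
            post_rows.append((test.baby_ids[i], proba[i]))

    confusion = pd.DataFrame(0.0, index=classes, columns=classes)
    counts = pd.Series(0, index=classes)
    correct = 0
    for true_baby, p in post_rows:
        confusion.loc[true_baby] += p
        counts[true_baby] += 1
        ties = np.flatnonzero(p == p.max())
        if len(ties) > 1:
            tie_count += 1
        if classes[ties[0]] == true_baby:
            correct += 1
    confusion = confusion.div(counts, axis=0)
    diag = np.diag(confusion.to_numpy())
    return ClassificationReport(
        confusion=confusion,
        mean_diag_posterior=float(diag.mean()),
        diag_posterior_2se=float(2 * diag.std(ddof=1) / np.sqrt(len(diag))),
        correct_count=int(correct),
        total_count=len(post_rows),
        chance_level=1.0 / len(classes),
        scheme=scheme.kind + ":" + "+".join(scheme.test_conditions),
        model=spec.model,
        feature_space=spec.feature_space,
        tie_count=tie_count,
    )


def fisher_compare(correct_a: int, n_a: int, correct_b: int, n_b: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table of correct/incorrect counts."""
    for c, n in ((correct_a, n_a), (correct_b, n_b)):
        if not 0 <= c <= n:
            raise ClassificationError("counts must satisfy 0 <= correct <= n")
    table = [[correct_a, n_a - correct_a], [correct_b, n_b - correct_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def binomial_vs_chance(correct: int, n: int, chance_p: float) -> float:
    """Exact upper-tail binomial p of >= ``correct`` successes under chance."""
    if not 0 < chance_p < 1:
        raise ClassificationError("chance_p must lie in (0, 1)")
    return float(stats.binomtest(correct, n, chance_p, alternative="greater").pvalue)
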