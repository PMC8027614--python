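"""Machine-learning triage of candidate variants.

Each candidate is summarized by eight explanatory variables — genome-wide
absolute position, log10 deletion and insertion lengths, copy-number ratio,
control-minus-sample normalized depth difference, variant frequency, total
split-read count, and strand bias of the supporting reads — and labeled 1
if the variant was confirmed by PCR, 0 otherwise. Seven classical
classifiers (logistic regression, decision tree, k-nearest neighbours,
random forest, linear discriminant analysis, Gaussian naive Bayes, linear
support-vector machine) are trained on a confirmed set and used to predict
true vs false positives in new candidate sets. Features are z-scored with
training-set statistics only; missing values are imputed with the
training-set median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

ALGORITHMS = ("LR", "DT", "kNN", "RF", "LDA", "NB", "SVM")

FEATURE_NAMES = ("abs_pos", "log_del_len", "log_ins_len", "cn_ratio",
                 "depth_diff", "frequency", "split_total", "strand_bias")


@dataclass
class CandidateFeatureVector:
    abs_pos: float
    log_del_len: float
    log_ins_len: float
    cn_ratio: float | None
    depth_diff: float | None
    frequency: float | None
    split_total: int
    strand_bias: float
    label: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.strand_bias <= 1:
            raise ValueError("strand_bias must lie in [0,1]")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class ClassifierResult:
    algorithm: str
    accuracy_train: float
    accuracy_test: float | None
    predictions: np.ndarray


def build_features(call, genome, tracks=None, label=None) -> CandidateFeatureVector:
    """Assemble the feature vector for one StructuralVariantCall.

    abs_pos uses cumulative contig offsets in the reference's declared
    order; lengths enter as log10(length + 1).
    """
    offsets = genome.offsets()
    del_len = call.length if call.svtype in ("DEL", "DELINS") else 0
    ins_len = len(call.novel_seq)
    cn = call.cn_ratio_mean
    if cn is not None and math.isnan(cn):
        cn = None
    depth_diff = None
    if tracks is not None and call.contig in tracks:
        tr = tracks[call.contig]
        b0 = call.start // tr.bin_size
        b1 = max(b0 + 1, -(-call.end // tr.bin_size))
        diff = tr.control_norm[b0:b1] - tr.sample_norm[b0:b1]
        if diff.size:
            depth_diff = float(np.mean(diff))
    total = call.fwd_support + call.rev_support
    bias = abs(call.fwd_support - call.rev_support) / total if total else 0.0
    return CandidateFeatureVector(
        abs_pos=offsets[call.contig] + call.start,
        log_del_len=math.log10(del_len + 1),
        log_ins_len=math.log10(ins_len + 1),
        cn_ratio=cn,
        depth_diff=depth_diff,
        frequency=call.frequency,
        split_total=call.support,
        strand_bias=bias,
        label=label,
    )


def features_to_frame(features: list[CandidateFeatureVector]) -> pd.DataFrame:
    rows = [{f.name: getattr(v, f.name) for f in dc_fields(v)}
            for v in features]
    return pd.DataFrame(rows)


def _make_estimator(algorithm: str, seed: int, params: dict | None = None):
    params = params or {}
    if algorithm == "LR":
        return LogisticRegression(C=params.get("C", 1.0), max_iter=1000)
    if algorithm == "DT":
        return DecisionTreeClassifier(
            min_samples_leaf=params.get("min_samples_leaf", 1),
            random_state=seed)
    if algorithm == "kNN":
        return KNeighborsClassifier(n_neighbors=params.get("k", 5))
    if algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 100), random_state=seed)
    if algorithm == "LDA":
        return LinearDiscriminantAnalysis()
    if algorithm == "NB":
        return GaussianNB()
    if algorithm == "SVM":
        return SVC(kernel="linear", C=params.get("C", 1.0), random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


class VariantClassifier:
    """One trained filter: estimator plus the training standardization."""

    def __init__(self, algorithm: str, seed: int = 0, params: dict | None = None):
        self.algorithm = algorithm
        self.seed = seed
        self.estimator = _make_estimator(algorithm, seed, params)
        self.means: np.ndarray | None = None
        self.sds: np.ndarray | None = None
        self.medians: np.ndarray | None = None

    def _matrix(self, features: list[CandidateFeatureVector],
                fit: bool) -> np.ndarray:
        df = features_to_frame(features)[list(FEATURE_NAMES)].astype(float)
        X = df.to_numpy()
        if fit:
            med = np.nanmedian(X, axis=0)
            med = np.where(np.isnan(med), 0.0, med)
            self.medians = med
        if self.medians is None:
            raise RuntimeError("classifier is not trained")
        idx = np.where(np.isnan(X))
        X[idx] = self.medians[idx[1]]
        if fit:
            self.means = X.mean(axis=0)
            sds = X.std(axis=0)
            self.sds = np.where(sds == 0, 1.0, sds)
        return (X - self.means) / self.sds

    def train(self, features: list[CandidateFeatureVector]) -> float:
        """Fit on labeled candidates; returns training accuracy."""
        y = np.asarray([v.label for v in features])
        if any(v.label is None for v in features):
            raise ValueError("all training candidates need a 0/1 label")
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        X = self._matrix(features, fit=True)
        self.estimator.fit(X, y)
        return float((self.estimator.predict(X) == y).mean())

    def predict(self, features: list[CandidateFeatureVector]) -> np.ndarray:
        X = self._matrix(features, fit=False)
        return self.estimator.predict(X)

    def evaluate(self, features: list[CandidateFeatureVector],
                 ) -> ClassifierResult:
        """Accuracy and per-candidate predictions on a labeled set."""
        if any(v.label is None for v in features):
            raise ValueError("evaluation candidates need a 0/1 label")
        y = np.asarray([v.label for v in features])
        pred = self.predict(features)
        return ClassifierResult(
            algorithm=self.algorithm,
            accuracy_train=float("nan"),
            accuracy_test=float((pred == y).mean()),
            predictions=pred,
        )


def train(features: list[CandidateFeatureVector], algorithm: str,
          seed: int = 0, params: dict | None = None,
          ) -> tuple[VariantClassifier, float]:
    clf = VariantClassifier(algorithm, seed, params)
    acc = clf.train(features)
    return clf, acc


def evaluate(model: VariantClassifier,
             features: list[CandidateFeatureVector]) -> ClassifierResult:
    return model.evaluate(features)


def benchmark(train_set: list[CandidateFeatureVector],
              test_set: list[CandidateFeatureVector],
              algorithms=ALGORITHMS, seed: int = 0) -> pd.DataFrame:
    """Train every algorithm on one set and test on another; returns a
    per-algorithm accuracy table."""
    rows = []
    for algo in algorithms:
        clf, acc_train = train(train_set, algo, seed)
        res = clf.evaluate(test_set)
        rows.append({"algorithm": algo, "accuracy_train": acc_train,
                     "accuracy_test": res.accuracy_test})
    return pd.DataFrame(rows)
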