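"""Sub-genome classification of sub-assemblies from progenitor similarity.

An allo-hexaploid genome carries three homeologous sub-genomes (A, B, D),
each closest to a different extant progenitor species.  For every
sub-assembly with a hit to *all three* progenitor sequence sets, six
similarity features (best-hit percent identity and length-normalized
score per progenitor) feed a margin classifier with calibrated
probabilities; predictions below a probability threshold are rejected as
unclassified — the case of a sequence matching all progenitors equally
well.  Model quality is reported by stratified k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import warnings

from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import _align
from .io_formats import SequenceRecord

SUBGENOMES = ("A", "B", "D")


class _QuietSVC(SVC):
    """SVC whose deprecation chatter about `probability` is silenced; the
    pairwise-coupled probability estimates are used deliberately."""

    def fit(self, X, y, sample_weight=None):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            return super().fit(X, y, sample_weight=sample_weight)

_FAMILIES = {
    # pairwise Platt coupling: near-equal class probabilities at points
    # equally similar to all three progenitors (sigmoid calibration of
    # one-vs-rest margins is too steep there and over-commits)
    "svm": lambda seed: make_pipeline(
        StandardScaler(), _QuietSVC(probability=True, random_state=seed)
    ),
    "logistic": lambda seed: make_pipeline(
        StandardScaler(), LogisticRegression(max_iter=1000, random_state=seed)
    ),
    "naive_bayes": lambda seed: make_pipeline(StandardScaler(), GaussianNB()),
    "decision_tree": lambda seed: make_pipeline(
        StandardScaler(), DecisionTreeClassifier(random_state=seed)
    ),
}


@dataclass
class FeatureVector:
    subassembly_id: str
    values: np.ndarray  # (identity_A, score_A, identity_B, score_B, identity_D, score_D)
    label: str = "unlabeled"


@dataclass
class ClassifierModel:
    estimator: object
    classes: list[str]
    probability_threshold: float = 0.6


def _best_hit_features(
    seq: str,
    progenitor_set: Sequence[SequenceRecord],
    min_identity: float = 70.0,
) -> Optional[tuple[float, float]]:
    """(percent identity, length-normalized match score) of the best hit.

    Alignments below ``min_identity`` are noise (two random nucleotide
    sequences align near ~55%), not hits; None when nothing qualifies.
    """
    best = None
    for ref in progenitor_set:
        query, subject = (seq, ref.seq) if len(seq) <= len(ref.seq) else (ref.seq, seq)
        hit = _align.best_local_nt_hit(query, subject)
        if hit is None or hit.pct_identity < min_identity:
            continue
        norm = hit.score / max(len(query), 1)
        if best is None or (hit.score, hit.pct_identity) > (best[2], best[0]):
            best = (hit.pct_identity, norm, hit.score)
    if best is None:
        return None
    return best[0], best[1]


def extract_features(
    sub_assemblies: Sequence[SequenceRecord],
    progenitor_sets: Mapping[str, Sequence[SequenceRecord]],
) -> tuple[list[FeatureVector], int]:
    """Six similarity features per sub-assembly against the three progenitors.

    Sub-assemblies missing a hit to any progenitor set are excluded; the
    second return value counts them.
    """
    missing = [k for k in SUBGENOMES if k not in progenitor_sets]
    if missing:
        raise ValueError(f"progenitor sets required for all of {SUBGENOMES}; missing {missing}")
    out: list[FeatureVector] = []
    n_excluded = 0
    for rec in sub_assemblies:
        feats: list[float] = []
        ok = True
        for sg in SUBGENOMES:
            f = _best_hit_features(rec.seq, progenitor_sets[sg])
            if f is None:
                ok = False
                break
            feats.extend(f)
        if ok:
            out.append(FeatureVector(rec.id, np.array(feats)))
        else:
            n_excluded += 1
    return out, n_excluded


def build_training_set(
    labeled_partition: Mapping[str, Sequence[SequenceRecord]],
    progenitor_sets: Mapping[str, Sequence[SequenceRecord]],
) -> list[FeatureVector]:
    """Label training sequences by their best progenitor and featurize them.

    ``labeled_partition`` maps each sub-genome letter to sequences known
    to derive from it (e.g. from chromosome-sorted data, or a synthetic
    catalogue).  Each sequence's label is re-derived as the argmax
    similarity; sequences tying between progenitors are dropped
    (ambiguous), keeping label noise out of training.
    """
    if not any(labeled_partition.values()):
        raise ValueError("labeled set is empty")
    out: list[FeatureVector] = []
    for sg in SUBGENOMES:
        seqs = labeled_partition.get(sg, [])
        feats, _ = extract_features(seqs, progenitor_sets)
        for fv in feats:
            identities = fv.values[0::2]
            top = np.flatnonzero(identities == identities.max())
            if len(top) != 1:
                continue  # ambiguous: equally similar to several progenitors
            fv.label = SUBGENOMES[top[0]]
            out.append(fv)
    return out


def train_and_validate(
    features: Sequence[FeatureVector],
    k: int = 10,
    family: str = "svm",
    probability_threshold: float = 0.6,
    seed: int = 0,
) -> tuple[ClassifierModel, pd.DataFrame]:
    """Stratified k-fold cross-validation, then refit on all data.

    Returns the fitted model and a per-class precision/recall/F1 table
    aggregated over the folds.
    """
    labeled = [f for f in features if f.label in SUBGENOMES]
    if not labeled:
        raise ValueError("no labeled feature vectors")
    X = np.vstack([f.values for f in labeled])
    y = np.array([f.label for f in labeled])
    class_sizes = pd.Series(y).value_counts()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > class_sizes.min():
        raise ValueError(
            f"k={k} exceeds smallest class size {class_sizes.min()}"
        )
    if family not in _FAMILIES:
        raise ValueError(f"unknown classifier family {family!r}; options: {sorted(_FAMILIES)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tp = {c: 0 for c in SUBGENOMES}
    fp = {c: 0 for c in SUBGENOMES}
    fn = {c: 0 for c in SUBGENOMES}
    for train_idx, test_idx in skf.split(X, y):
        est = _FAMILIES[family](seed)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        for truth, p in zip(y[test_idx], pred):
            if truth == p:
                tp[truth] += 1
            else:
                fp[p] += 1
                fn[truth] += 1
    rows = []
    for c in SUBGENOMES:
        precision = tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else 0.0
        recall = tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append({"class": c, "precision": precision, "recall": recall, "f1": f1})
    table = pd.DataFrame(rows).set_index("class")
    final = _FAMILIES[family](seed)
    final.fit(X, y)
    model = ClassifierModel(
        estimator=final,
        classes=list(final.classes_),
        probability_threshold=probability_threshold,
    )
    return model, table


def classify(
    model: ClassifierModel, features: Sequence[FeatureVector]
) -> pd.DataFrame:
    """Predict sub-genome labels with probability-threshold rejection.

    Returns a table (id, label, p_A, p_B, p_D) where ``label`` is
    "unclassified" whenever the top class probability falls below the
    model's threshold.
    """
    if not features:
        return pd.DataFrame(columns=["id", "label", "p_A", "p_B", "p_D"])
    X = np.vstack([f.values for f in features])
    probs = model.estimator.predict_proba(X)
    order = [model.classes.index(c) for c in SUBGENOMES]
    rows = []
    for fv, p in zip(features, probs):
        p = p[order]
        top = int(np.argmax(p))
        label = SUBGENOMES[top] if p[top] >= model.probability_threshold else "unclassified"
        rows.append(
            {"id": fv.subassembly_id, "label": label, "p_A": p[0], "p_B": p[1], "p_D": p[2]}
        )
    return pd.DataFrame(rows)


def summarize(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per category (the shape of a classification
    summary table: used, per-class, unclassified)."""
    n = len(classified)
    rows = [{"category": "used_for_classification", "count": n, "percent": 100.0}]
    for c in SUBGENOMES + ("unclassified",):
        cnt = int((classified["label"] == c).sum()) if n else 0
        rows.append(
            {"category": f"classified_as_{c}" if c in SUBGENOMES else c,
             "count": cnt,
             "percent": 100.0 * cnt / n if n else 0.0}
        )
    return pd.DataFrame(rows)
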