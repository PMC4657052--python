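"""Primary-structure predictors of methionine oxidation and the RF protocol.

Each methionine is described by 40 "distance" variables: for every canonical
amino acid X, NT_X (CT_X) is the number of residues between the methionine
and the closest X toward the N-terminus (C-terminus). When a direction holds
no X, the protein length serves as the default value. A random forest is
trained on these features; recursive feature elimination (RFE) ranks them and
scores candidate subset sizes by cross-validated AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from .io_data import CANONICAL_AA, MetSite, ProteinRecord

FEATURE_NAMES = [f"NT_{aa}" for aa in CANONICAL_AA] + [f"CT_{aa}" for aa in CANONICAL_AA]

# published protocol constants
N_TREES = 1000
MTRY = 6  # floor(sqrt(40))
TEST_FRACTION = 0.25
CV_FOLDS = 10
CV_REPEATS = 5


@dataclass(frozen=True)
class ClassifierReport:
    """Performance of one trained model (CV over the training part + held-out test)."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    split: str  # "training-CV" | "testing"
    selected_features: tuple[str, ...] = ()
    oob_score: float | None = None


def distance_features(protein: ProteinRecord, pos: int) -> dict[str, int]:
    """The 40 nearest-occurrence distances for the methionine at ``pos``.

    NT_X = pos - (largest index < pos holding X); CT_X symmetric toward the
    C-terminus; absent X in a direction -> len(protein).
    """
    if not 1 <= pos <= len(protein.seq) or protein.seq[pos - 1] != "M":
        raise ValueError(f"{protein.id}: position {pos} is not a methionine")
    seq = protein.seq
    default = len(seq)
    features = {name: default for name in FEATURE_NAMES}
    seen_nt: set[str] = set()
    for i in range(pos - 2, -1, -1):  # scan toward the N-terminus
        aa = seq[i]
        if aa != "X" and aa not in seen_nt:
            features[f"NT_{aa}"] = pos - (i + 1)
            seen_nt.add(aa)
    seen_ct: set[str] = set()
    for i in range(pos, len(seq)):
        aa = seq[i]
        if aa != "X" and aa not in seen_ct:
            features[f"CT_{aa}"] = (i + 1) - pos
            seen_ct.add(aa)
    return features


def assemble_benchmark(
    sites: Sequence[MetSite],
    proteins: Sequence[ProteinRecord] | Mapping[str, ProteinRecord],
) -> pd.DataFrame:
    """Feature table with one row per labelled methionine (duplicates collapsed)."""
    lookup = proteins if isinstance(proteins, Mapping) else {p.id: p for p in proteins}
    rows = []
    seen: set[tuple[str, int]] = set()
    for site in sites:
        key = (site.protein_id, site.pos)
        if key in seen:
            continue
        seen.add(key)
        feats = distance_features(lookup[site.protein_id], site.pos)
        feats["protein_id"] = site.protein_id
        feats["pos"] = site.pos
        feats["oxidized"] = int(site.oxidized)
        rows.append(feats)
    table = pd.DataFrame(rows, columns=["protein_id", "pos", *FEATURE_NAMES, "oxidized"])
    return table


def _metrics(y_true: np.ndarray, y_pred: np.ndarray, y_score: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return {
        "auc": float(roc_auc_score(y_true, y_score)),
        "accuracy": (tp + tn) / len(y_true),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def _forest(seed: int, n_trees: int, mtry: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        random_state=seed,
        oob_score=True,
        n_jobs=1,
    )


def _split_table(table: pd.DataFrame, features: Sequence[str]):
    X = table[list(features)].to_numpy(dtype=float)
    y = table["oxidized"].to_numpy(dtype=int)
    return X, y


def train_rf(
    table: pd.DataFrame,
    seed: int = 0,
    split: float = 1 - TEST_FRACTION,
    features: Sequence[str] = tuple(FEATURE_NAMES),
    n_trees: int = N_TREES,
    mtry: int | None = None,
    cv_folds: int = CV_FOLDS,
    cv_repeats: int = CV_REPEATS,
    run_cv: bool = True,
) -> tuple[ClassifierReport | None, ClassifierReport]:
    """Random-forest protocol: stratified 75/25 split, repeated-CV, final test.

    Defaults follow the published recipe — 1000 trees, 6 candidate predictors
    per split (floor of sqrt(40)), 10-fold cross-validation with 5 repetitions
    (50 resamplings, averaged) on the training part, and a final model refit
    on the whole training part scored on the held-out quarter. The positive
    class is "oxidized". Returns ``(cv_report, test_report)``; ``cv_report``
    is None when ``run_cv`` is False.
    """
    if table["oxidized"].nunique() < 2:
        raise ValueError("both classes must be present")
    if len(table) < 50:
        raise ValueError("need at least 50 rows to follow the split protocol")
    if mtry is None:
        mtry = min(int(np.sqrt(len(features))), len(features))
    X, y = _split_table(table, features)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, stratify=y, random_state=seed
    )

    cv_report = None
    if run_cv:
        cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
        fold_metrics = []
        for k, (tr, va) in enumerate(cv.split(X_tr, y_tr)):
            clf = _forest(seed + 1 + k, n_trees, mtry)
            clf.fit(X_tr[tr], y_tr[tr])
            score = clf.predict_proba(X_tr[va])[:, 1]
            fold_metrics.append(_metrics(y_tr[va], (score >= 0.5).astype(int), score))
        agg = {k: float(np.mean([m[k] for m in fold_metrics])) for k in fold_metrics[0]}
        cv_report = ClassifierReport(split="training-CV", selected_features=tuple(features), **agg)

    final = _forest(seed, n_trees, mtry)
    final.fit(X_tr, y_tr)
    score = final.predict_proba(X_te)[:, 1]
    test_metrics = _metrics(y_te, (score >= 0.5).astype(int), score)
    test_report = ClassifierReport(
        split="testing",
        selected_features=tuple(features),
        oob_score=float(final.oob_score_),
        **test_metrics,
    )
    return cv_report, test_report


@dataclass(frozen=True)
class RfeResult:
    selected: tuple[str, ...]
    curve: tuple[tuple[int, float], ...]  # (subset size, mean CV AUC)
    ranking: tuple[str, ...]  # features ordered from most to least relevant


def rfe_select(
    table: pd.DataFrame,
    seed: int = 0,
    sizes: Sequence[int] | None = None,
    n_trees: int = N_TREES,
    cv_folds: int = CV_FOLDS,
    cv_repeats: int = CV_REPEATS,
    split: float = 1 - TEST_FRACTION,
) -> RfeResult:
    """Backward feature elimination scored by cross-validated AUC.

    Features are ranked once by recursive elimination with random-forest
    importances; every candidate subset size (default 1..40) keeps the
    top-ranked features and is scored by repeated stratified CV on the
    training part of the 75/25 split. The best size wins; ties break toward
    fewer features.
    """
    if table["oxidized"].nunique() < 2:
        raise ValueError("both classes must be present")
    X, y = _split_table(table, FEATURE_NAMES)
    X_tr, _, y_tr, _ = train_test_split(X, y, train_size=split, stratify=y, random_state=seed)

    mtry = MTRY if len(FEATURE_NAMES) >= 36 else None
    ranker = RFE(
        estimator=RandomForestClassifier(
            n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1
        ),
        n_features_to_select=1,
        step=1,
    )
    ranker.fit(X_tr, y_tr)
    order = np.argsort(ranker.ranking_)  # rank 1 first
    ranking = tuple(FEATURE_NAMES[i] for i in order)

    if sizes is None:
        sizes = range(1, len(FEATURE_NAMES) + 1)
    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
    splits = list(cv.split(X_tr, y_tr))
    curve = []
    for size in sizes:
        cols = order[:size]
        aucs = []
        for k, (tr, va) in enumerate(splits):
            m = min(int(np.sqrt(size)), size) or 1
            clf = RandomForestClassifier(
                n_estimators=n_trees, max_features=m, random_state=seed + 1 + k, n_jobs=1
            )
            clf.fit(X_tr[tr][:, cols], y_tr[tr])
            aucs.append(roc_auc_score(y_tr[va], clf.predict_proba(X_tr[va][:, cols])[:, 1]))
        curve.append((int(size), float(np.mean(aucs))))
    best_size = max(curve, key=lambda sc: (sc[1], -sc[0]))[0]
    return RfeResult(selected=ranking[:best_size], curve=tuple(curve), ranking=ranking)
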