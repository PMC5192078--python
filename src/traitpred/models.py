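"""Phenotype classifiers: sparse linear SVM committees over phyletic patterns.

Two model flavours are trained per phenotype:

* ``phypat`` — an L1-regularised L2-loss linear SVM (the LIBLINEAR primal,
  via scikit-learn) on the binary leaf phyletic patterns and observed
  phenotype labels;
* ``phypat+PGL`` — the same, with extra training rows representing
  inferred ancestral protein-family and phenotype gain/loss events on the
  branches of a phylogeny pruned to the labelled taxa.  Event rows carry
  real-valued change probabilities in [0, 1] and binary phenotype event
  labels; they are appended to the training matrix with unit weight and
  never used for testing.

Model selection follows the nested cross-validation protocol: an outer
k-fold split estimates the test error on observed leaf labels only, and an
inner cross-validation on each training fold picks the regularisation
parameter C.  In gain/loss-aware mode, the ancestral reconstruction is
recomputed for every (inner and outer) training fold on the tree pruned to
that fold's taxa, so no test leaf ever informs the event rows.

The deployed classifier is a *committee* of five SVMs — the models trained
with the five C values of highest cross-validated accuracy — and an unseen
genome is assigned to the committee's majority class.  A minority of
positive votes (1 or 2 of 5) is reported as a "weak" call rather than a
positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import LinearSVC

from . import events as ev
from .phylo import Phylogeny, prune_to_labeled

__all__ = [
    "LinearModel",
    "CommitteeModel",
    "PhenotypeCall",
    "NestedCVResult",
    "DEFAULT_C_GRID",
    "train_svm",
    "train_committee",
    "nested_cv_train",
    "predict",
    "predict_matrix",
    "consensus",
    "save_committees",
    "load_committees",
]

#: C grid for model selection: {1e-3} plus {10^k * f} for k in {-2, -1, 0}
#: and f in {0.1, 0.2, 0.5, 0.7, 1}, capped at 1.
DEFAULT_C_GRID: tuple[float, ...] = tuple(
    sorted(
        {1e-3}
        | {
            round(10.0**k * f, 10)
            for k in (-2, -1, 0)
            for f in (0.1, 0.2, 0.5, 0.7, 1.0)
            if 10.0**k * f <= 1.0
        }
    )
)

MODES = ("phypat", "phypat+PGL")


@dataclass
class LinearModel:
    """One sparse linear classifier: sign(w.x + b)."""

    weights: np.ndarray
    bias: float
    C: float
    cv_score: float | None = None

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias


@dataclass
class CommitteeModel:
    """Five linear SVMs voting on one phenotype.

    Members are sorted by descending cross-validation score; the family
    universe is fixed at training time so prediction-time profiles align
    by family id, never by position.
    """

    phenotype_id: str
    members: list[LinearModel]
    family_ids: list[str]
    mode: str = "phypat"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) != 5:
            raise ValueError(f"committee must have exactly 5 members, got {len(self.members)}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        for m in self.members:
            if len(m.weights) != len(self.family_ids):
                raise ValueError("member weight length must equal family universe size")

    @property
    def member_cv_scores(self) -> list[float | None]:
        return [m.cv_score for m in self.members]


@dataclass(frozen=True)
class PhenotypeCall:
    """A committee's verdict on one (sample, phenotype) pair.

    ``positive`` means a majority (>= 3 of 5) of positive votes, ``weak``
    a minority (1-2), ``negative`` none.
    """

    sample_id: str
    phenotype_id: str
    positive_votes: int
    call: str
    provenance: tuple[str, ...] = ()

    @staticmethod
    def from_votes(sample_id: str, phenotype_id: str, votes: int, provenance=()) -> "PhenotypeCall":
        if not 0 <= votes <= 5:
            raise ValueError(f"votes must be in 0..5, got {votes}")
        call = "positive" if votes >= 3 else ("weak" if votes >= 1 else "negative")
        return PhenotypeCall(sample_id, phenotype_id, votes, call, tuple(provenance))


# ---------------------------------------------------------------------------
# core SVM fit


def train_svm(
    X,
    y,
    C: float,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> LinearModel:
    """Fit one L1-regularised L2-loss linear SVM (LIBLINEAR primal).

    Minimises ``||w||_1 + C * sum_i max(0, 1 - y_i (w.x_i + b))^2``; the L1
    penalty drives most family weights to exactly zero, linking the model
    directly to a small set of phenotype-relevant families.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training labels contain a single class ({classes.tolist()})")
    clf = LinearSVC(
        penalty="l1",
        loss="squared_hinge",
        dual=False,
        C=C,
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    clf.fit(X, y)
    return LinearModel(weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]), C=C)


# ---------------------------------------------------------------------------
# gain/loss event rows


def event_training_rows(
    tree: Phylogeny,
    matrix: pd.DataFrame,
    y: pd.Series,
    *,
    gain_rate=None,
    loss_rate=None,
    t: float = 0.5,
    r: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral gain/loss training rows for the labelled taxa in ``y``.

    Prunes the tree to the taxa of ``y`` (all labelled, no NaN), runs the
    two-state posterior inference for every family plus the phenotype on
    the pruned tree, and keeps branches with a confident phenotype event
    probability.  Returns ``(X_events, y_events)`` with columns aligned to
    ``matrix.columns``.
    """
    taxa = list(y.index)
    if y.isna().any():
        raise ValueError("event rows require fully labelled taxa")
    pruned, _ = prune_to_labeled(tree, taxa)
    phen = str(y.name) if y.name is not None else "__phenotype__"
    if phen in matrix.columns:
        phen = "__phenotype__"
    chars = matrix.loc[taxa].astype(float).copy()
    chars[phen] = y.astype(float)
    post = ev.infer_posteriors(pruned, chars, gain_rate=gain_rate, loss_rate=loss_rate)
    sample_set = ev.build_event_samples(post, phen, t=t, r=r)
    X_events = sample_set.X.reindex(columns=matrix.columns).to_numpy(dtype=float)
    return X_events, sample_set.y_binary.to_numpy()


# ---------------------------------------------------------------------------
# cross-validation machinery


def _stratified_folds(y: np.ndarray, folds: int, seed: int):
    """Stratified folds, degrading the split count to the smaller class."""
    counts = np.bincount(y.astype(int), minlength=2)
    n_splits = int(min(folds, counts[counts > 0].min()))
    if n_splits >= 2:
        return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed).split(
            np.zeros(len(y)), y
        )
    return KFold(n_splits=2, shuffle=True, random_state=seed).split(np.zeros(len(y)))


def _fit_fold(X_leaf, y_leaf, train_idx, C, seed, mode, event_data):
    """Train one model on a training split, with event rows in PGL mode."""
    X_tr = X_leaf[train_idx]
    y_tr = y_leaf[train_idx]
    if mode == "phypat+PGL" and event_data is not None:
        X_ev, y_ev = event_data
        if len(y_ev):
            X_tr = np.vstack([X_tr, X_ev])
            y_tr = np.concatenate([y_tr, y_ev])
    return train_svm(X_tr, y_tr, C, seed=seed)


def _cv_accuracy_per_C(
    X_leaf: np.ndarray,
    y_leaf: np.ndarray,
    sample_ids: list[str],
    folds: int,
    C_grid: Sequence[float],
    seed: int,
    mode: str,
    tree: Phylogeny | None,
    matrix: pd.DataFrame,
    phenotype_id: str,
    rates: tuple,
    t: float,
    r: float,
) -> dict[float, float]:
    """Pooled CV accuracy (on leaf labels) for every C of the grid."""
    correct = {C: 0 for C in C_grid}
    total = {C: 0 for C in C_grid}
    for tr_idx, te_idx in _stratified_folds(y_leaf, folds, seed):
        if len(np.unique(y_leaf[tr_idx])) < 2:
            continue
        event_data = None
        if mode == "phypat+PGL":
            y_tr = pd.Series(
                y_leaf[tr_idx], index=[sample_ids[i] for i in tr_idx], name=phenotype_id
            )
            event_data = event_training_rows(
                tree, matrix, y_tr, gain_rate=rates[0], loss_rate=rates[1], t=t, r=r
            )
        for C in C_grid:
            model = _fit_fold(X_leaf, y_leaf, tr_idx, C, seed, mode, event_data)
            pred = (model.decision(X_leaf[te_idx]) > 0).astype(int)
            correct[C] += int((pred == y_leaf[te_idx]).sum())
            total[C] += len(te_idx)
    return {C: (correct[C] / total[C] if total[C] else 0.0) for C in C_grid}


@dataclass
class NestedCVResult:
    committee: CommitteeModel
    confusion: dict  # TP/TN/FP/FN pooled over outer test folds
    fold_confusions: list[dict]
    test_votes: pd.Series  # outer-test decision per labelled sample (0/1)


def train_committee(
    matrix: pd.DataFrame,
    y: pd.Series,
    *,
    tree: Phylogeny | None = None,
    mode: str = "phypat",
    folds: int = 10,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
    gain_rate=None,
    loss_rate=None,
    t: float = 0.5,
    r: float = 0.05,
) -> CommitteeModel:
    """Train the 5-member voting committee for one phenotype.

    Each C of the grid is scored by pooled k-fold CV accuracy on the
    labelled samples; the five C values with the best scores (ties broken
    toward stronger regularisation, i.e. smaller C) are each retrained on
    all labelled data — plus, in gain/loss-aware mode, the event rows
    derived from all labelled taxa — and form the committee, sorted by
    descending CV score.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "phypat+PGL" and tree is None:
        raise ValueError("phypat+PGL mode requires a phylogeny")
    labeled = y.dropna()
    sample_ids = list(labeled.index)
    X_leaf = matrix.loc[sample_ids].to_numpy(dtype=float)
    y_leaf = labeled.to_numpy(dtype=int)
    phen = str(y.name) if y.name is not None else "phenotype"

    scores = _cv_accuracy_per_C(
        X_leaf, y_leaf, sample_ids, folds, C_grid, seed, mode, tree, matrix, phen,
        (gain_rate, loss_rate), t, r,
    )
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    chosen = ranked[:5]

    event_data = None
    if mode == "phypat+PGL":
        event_data = event_training_rows(
            tree, matrix, labeled.rename(phen), gain_rate=gain_rate, loss_rate=loss_rate, t=t, r=r
        )
    members = []
    for C, score in chosen:
        model = _fit_fold(X_leaf, y_leaf, np.arange(len(y_leaf)), C, seed, mode, event_data)
        model.cv_score = score
        members.append(model)
    members.sort(key=lambda m: (-(m.cv_score or 0.0), m.C))
    return CommitteeModel(
        phenotype_id=phen,
        members=members,
        family_ids=list(matrix.columns),
        mode=mode,
        metadata={
            "seed": seed,
            "folds": folds,
            "C_grid": list(map(float, C_grid)),
            "n_labeled": len(sample_ids),
            "t": t,
            "r": r,
        },
    )


def nested_cv_train(
    matrix: pd.DataFrame,
    y: pd.Series,
    *,
    tree: Phylogeny | None = None,
    mode: str = "phypat",
    folds: int = 10,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
    gain_rate=None,
    loss_rate=None,
    t: float = 0.5,
    r: float = 0.05,
) -> NestedCVResult:
    """Nested cross-validation: unbiased test error plus a final committee.

    The outer k-fold split runs over the labelled leaf samples only.  For
    each outer fold, an inner CV on the training fold selects the C with
    the best pooled accuracy; a model trained on the outer training fold
    with that C is then scored on the held-out fold, and the confusion is
    accumulated on observed leaf labels only.  In gain/loss-aware mode the
    ancestral reconstruction is recomputed for every inner and outer
    training fold from that fold's taxa alone.  The returned committee is
    trained on all labelled data via :func:`train_committee`.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "phypat+PGL" and tree is None:
        raise ValueError("phypat+PGL mode requires a phylogeny")
    labeled = y.dropna()
    if len(labeled) < folds:
        raise ValueError(f"{len(labeled)} labelled samples < {folds} folds")
    if labeled.nunique() < 2:
        raise ValueError("phenotype labels contain a single class")
    sample_ids = list(labeled.index)
    X_leaf = matrix.loc[sample_ids].to_numpy(dtype=float)
    y_leaf = labeled.to_numpy(dtype=int)
    phen = str(y.name) if y.name is not None else "phenotype"

    fold_confusions: list[dict] = []
    votes = pd.Series(index=pd.Index(sample_ids), dtype=float)
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for k, (tr_idx, te_idx) in enumerate(outer.split(X_leaf, y_leaf)):
        inner_scores = _cv_accuracy_per_C(
            X_leaf[tr_idx],
            y_leaf[tr_idx],
            [sample_ids[i] for i in tr_idx],
            folds,
            C_grid,
            seed + 1,
            mode,
            tree,
            matrix,
            phen,
            (gain_rate, loss_rate),
            t,
            r,
        )
        best_C = sorted(inner_scores.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        event_data = None
        if mode == "phypat+PGL":
            y_tr = pd.Series(
                y_leaf[tr_idx], index=[sample_ids[i] for i in tr_idx], name=phen
            )
            event_data = event_training_rows(
                tree, matrix, y_tr, gain_rate=gain_rate, loss_rate=loss_rate, t=t, r=r
            )
        model = _fit_fold(X_leaf, y_leaf, tr_idx, best_C, seed, mode, event_data)
        pred = (model.decision(X_leaf[te_idx]) > 0).astype(int)
        truth = y_leaf[te_idx]
        conf = {
            "TP": int(((pred == 1) & (truth == 1)).sum()),
            "TN": int(((pred == 0) & (truth == 0)).sum()),
            "FP": int(((pred == 1) & (truth == 0)).sum()),
            "FN": int(((pred == 0) & (truth == 1)).sum()),
            "C": best_C,
            "fold": k,
        }
        fold_confusions.append(conf)
        votes.iloc[te_idx] = pred

    pooled = {
        key: sum(c[key] for c in fold_confusions) for key in ("TP", "TN", "FP", "FN")
    }
    committee = train_committee(
        matrix,
        y,
        tree=tree,
        mode=mode,
        folds=folds,
        C_grid=C_grid,
        seed=seed,
        gain_rate=gain_rate,
        loss_rate=loss_rate,
        t=t,
        r=r,
    )
    return NestedCVResult(
        committee=committee,
        confusion=pooled,
        fold_confusions=fold_confusions,
        test_votes=votes,
    )


# ---------------------------------------------------------------------------
# prediction


def _align_profile(committee: CommitteeModel, profile) -> np.ndarray:
    if isinstance(profile, pd.Series):
        return profile.reindex(committee.family_ids, fill_value=0).to_numpy(dtype=float)
    arr = np.asarray(profile, dtype=float)
    if arr.shape[-1] != len(committee.family_ids):
        raise ValueError(
            f"profile length {arr.shape[-1]} != family universe {len(committee.family_ids)}; "
            "pass a pandas Series to align by family id"
        )
    return arr


def predict(committee: CommitteeModel, profile, sample_id: str = "") -> PhenotypeCall:
    """Committee majority vote on one phyletic profile.

    Families absent from the profile count as 0 (absence); families in the
    profile but unknown to the committee are ignored.
    """
    x = _align_profile(committee, profile)
    votes = int(sum(1 for m in committee.members if m.decision(x) > 0))
    if isinstance(profile, pd.Series) and not sample_id:
        sample_id = str(profile.name) if profile.name is not None else ""
    return PhenotypeCall.from_votes(sample_id, committee.phenotype_id, votes, (committee.mode,))


def predict_matrix(committee: CommitteeModel, matrix: pd.DataFrame) -> list[PhenotypeCall]:
    """Vectorised committee vote over a samples x families matrix."""
    X = matrix.reindex(columns=committee.family_ids, fill_value=0).to_numpy(dtype=float)
    votes = np.zeros(len(matrix), dtype=int)
    for m in committee.members:
        votes += (X @ m.weights + m.bias > 0).astype(int)
    return [
        PhenotypeCall.from_votes(str(s), committee.phenotype_id, int(v), (committee.mode,))
        for s, v in zip(matrix.index, votes)
    ]


def consensus(call_a: PhenotypeCall, call_b: PhenotypeCall) -> PhenotypeCall:
    """Intersection vote of two classifiers' calls on the same pair.

    Positive only when both calls are positive (a weak call is a minority
    vote and does not count); otherwise negative.  Vote counts carry the
    smaller of the two committees' counts when positive.
    """
    if (call_a.sample_id, call_a.phenotype_id) != (call_b.sample_id, call_b.phenotype_id):
        raise ValueError("consensus requires calls on the same sample and phenotype")
    both = call_a.call == "positive" and call_b.call == "positive"
    provenance = tuple(dict.fromkeys(call_a.provenance + call_b.provenance))
    return PhenotypeCall(
        sample_id=call_a.sample_id,
        phenotype_id=call_a.phenotype_id,
        positive_votes=min(call_a.positive_votes, call_b.positive_votes) if both else 0,
        call="positive" if both else "negative",
        provenance=provenance if both else (),
    )


# ---------------------------------------------------------------------------
# persistence (versioned JSON archive; text-only, round-trip exact)

_ARCHIVE_FORMAT = "traitpred-committees"
_ARCHIVE_VERSION = 1


def _committee_to_dict(c: CommitteeModel) -> dict:
    return {
        "phenotype_id": c.phenotype_id,
        "mode": c.mode,
        "family_ids": c.family_ids,
        "metadata": c.metadata,
        "members": [
            {
                # sparse weight storage: only non-zero entries
                "weights": {c.family_ids[j]: float(w) for j, w in enumerate(m.weights) if w != 0.0},
                "bias": m.bias,
                "C": m.C,
                "cv_score": m.cv_score,
            }
            for m in c.members
        ],
    }


def _committee_from_dict(d: dict) -> CommitteeModel:
    family_ids = list(d["family_ids"])
    col = {f: j for j, f in enumerate(family_ids)}
    members = []
    for md in d["members"]:
        w = np.zeros(len(family_ids))
        for f, v in md["weights"].items():
            w[col[f]] = v
        members.append(LinearModel(weights=w, bias=md["bias"], C=md["C"], cv_score=md["cv_score"]))
    return CommitteeModel(
        phenotype_id=d["phenotype_id"],
        members=members,
        family_ids=family_ids,
        mode=d["mode"],
        metadata=d.get("metadata", {}),
    )


def save_committees(committees: dict[str, CommitteeModel], path) -> None:
    """Write one or more committees to a versioned JSON archive."""
    payload = {
        "format": _ARCHIVE_FORMAT,
        "version": _ARCHIVE_VERSION,
        "committees": {p: _committee_to_dict(c) for p, c in committees.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_committees(path) -> dict[str, CommitteeModel]:
    """Load a committee archive written by :func:`save_committees`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != _ARCHIVE_FORMAT:
        raise ValueError(f"not a committee archive: {path}")
    return {p: _committee_from_dict(d) for p, d in payload["committees"].items()}
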