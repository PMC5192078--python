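"""Confusion accounting, macro/pooled metrics, per-taxon pooling, and the
incomplete-genome robustness experiment.

Two accuracy notions are reported.  *Macroaccuracy* balances over
phenotypes: per-phenotype positive and negative recalls are averaged over
the n phenotypes, then the two macro recalls are averaged.  *Pooled
accuracy* sums the confusion counts over phenotypes first, so large
phenotype classes dominate:

    MacrorecallPos = (sum_i TP_i / (TP_i + FN_i)) / n
    MacrorecallNeg = (sum_i TN_i / (FP_i + TN_i)) / n
    Macroaccuracy  = (MacrorecallPos + MacrorecallNeg) / 2
    RecallPos      = sum TP_i / (sum TP_i + sum FN_i)
    RecallNeg      = sum TN_i / (sum TN_i + sum FP_i)
    Accuracy       = (RecallPos + RecallNeg) / 2

A "weak" call (minority of committee votes) counts as a negative
prediction throughout: assignment is to the committee's majority class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import CommitteeModel, PhenotypeCall, consensus, predict_matrix

__all__ = [
    "ConfusionSummary",
    "MetricReport",
    "confusion",
    "macro_metrics",
    "pooled_fraction_correct",
    "taxon_accuracy",
    "completeness_experiment",
]

logger = logging.getLogger(__name__)

_CONF_COLS = ["TP", "TN", "FP", "FN"]


@dataclass
class ConfusionSummary:
    """Per-phenotype TP/TN/FP/FN counts (rows = phenotypes)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CONF_COLS if c not in self.counts.columns]
        if missing:
            raise ValueError(f"confusion table missing columns {missing}")
        if (self.counts[_CONF_COLS] < 0).any().any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return len(self.counts)


@dataclass
class MetricReport:
    macrorecall_pos: float
    macrorecall_neg: float
    macroaccuracy: float
    recall_pos: float
    recall_neg: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def confusion(calls: Iterable[PhenotypeCall], labels: pd.DataFrame) -> ConfusionSummary:
    """Tally calls against a ternary label table.

    Positive calls on present labels are TP, on absent labels FP; weak and
    negative calls are negative predictions (FN on present, TN on absent).
    Calls on unknown or unlabelled pairs are skipped and logged.
    """
    counts: dict[str, np.ndarray] = {}
    skipped = 0
    for call in calls:
        if (
            call.sample_id not in labels.index
            or call.phenotype_id not in labels.columns
            or pd.isna(labels.at[call.sample_id, call.phenotype_id])
        ):
            skipped += 1
            continue
        truth = int(labels.at[call.sample_id, call.phenotype_id])
        pred = 1 if call.call == "positive" else 0
        row = counts.setdefault(call.phenotype_id, np.zeros(4, dtype=int))
        if pred == 1 and truth == 1:
            row[0] += 1
        elif pred == 0 and truth == 0:
            row[1] += 1
        elif pred == 1 and truth == 0:
            row[2] += 1
        else:
            row[3] += 1
    if skipped:
        logger.info("confusion: skipped %d calls on unlabelled pairs", skipped)
    df = pd.DataFrame.from_dict(counts, orient="index", columns=_CONF_COLS).astype(int)
    if df.empty:
        df = pd.DataFrame(columns=_CONF_COLS, dtype=int)
    df.index.name = "phenotype"
    return ConfusionSummary(counts=df.sort_index())


def macro_metrics(
    summary: ConfusionSummary, min_pos: int = 1, min_neg: int = 1
) -> MetricReport:
    """Compute the macro and pooled metrics from a confusion summary.

    Phenotypes with fewer than ``min_pos`` positive or ``min_neg``
    negative labels are excluded from the macro averages (their counts
    still enter the pooled recalls); exclusions are logged.
    """
    df = summary.counts
    pos_n = df["TP"] + df["FN"]
    neg_n = df["TN"] + df["FP"]
    ok = (pos_n >= max(min_pos, 1)) & (neg_n >= max(min_neg, 1))
    if (~ok).any():
        logger.info("macro_metrics: excluded phenotypes %s", df.index[~ok].tolist())
    sub = df[ok]
    if len(sub):
        mr_pos = float((sub["TP"] / (sub["TP"] + sub["FN"])).mean())
        mr_neg = float((sub["TN"] / (sub["FP"] + sub["TN"])).mean())
    else:
        mr_pos = mr_neg = float("nan")
    tp, tn, fp, fn = (int(df[c].sum()) for c in ("TP", "TN", "FP", "FN"))
    r_pos = tp / (tp + fn) if tp + fn else float("nan")
    r_neg = tn / (tn + fp) if tn + fp else float("nan")
    return MetricReport(
        macrorecall_pos=mr_pos,
        macrorecall_neg=mr_neg,
        macroaccuracy=(mr_pos + mr_neg) / 2,
        recall_pos=r_pos,
        recall_neg=r_neg,
        accuracy=(r_pos + r_neg) / 2,
    )


def pooled_fraction_correct(summary: ConfusionSummary) -> float:
    """Plain fraction of correct assignments over all pooled decisions.

    Alternative pooled accuracy reading: (TP + TN) / (TP + TN + FP + FN)
    summed over phenotypes, rather than the balanced
    (RecallPos + RecallNeg) / 2.
    """
    df = summary.counts
    total = int(df[_CONF_COLS].to_numpy().sum())
    return float((df["TP"].sum() + df["TN"].sum()) / total) if total else float("nan")


def taxon_accuracy(
    calls: Iterable[PhenotypeCall],
    labels: pd.DataFrame,
    taxon_members: Mapping[str, Iterable[str]],
    min_species: int = 5,
) -> dict[str, MetricReport]:
    """Pooled metrics per taxon, over its member species only.

    ``taxon_members`` maps a taxon name to the species (sample ids) that
    descend from it.  Taxa with fewer than ``min_species`` labelled
    members are excluded and logged.  Unknown species raise.
    """
    calls = list(calls)
    reports: dict[str, MetricReport] = {}
    for taxon, members in taxon_members.items():
        members = set(members)
        unknown = members - set(labels.index)
        if unknown:
            raise ValueError(f"taxon {taxon!r}: unknown species {sorted(unknown)}")
        member_labels = labels.loc[sorted(members)]
        labeled_members = member_labels.notna().any(axis=1).sum()
        if labeled_members < min_species:
            logger.info("taxon_accuracy: %r has %d labelled species < %d, excluded",
                        taxon, int(labeled_members), min_species)
            continue
        sub_calls = [c for c in calls if c.sample_id in members]
        reports[taxon] = macro_metrics(confusion(sub_calls, member_labels))
    return reports


def completeness_experiment(
    matrix: pd.DataFrame,
    committees: Mapping[str, CommitteeModel] | Mapping[str, Mapping[str, CommitteeModel]],
    labels: pd.DataFrame,
    fractions: Sequence[float],
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotype incomplete genomes by random family deletion.

    Emulates genome incompleteness: per replicate and retention fraction,
    each sample keeps a uniform random subset of its present families
    (``round(fraction * k)`` of k), all committees re-predict the degraded
    profiles, and metrics are computed against the full-genome labels.

    ``committees`` maps mode name to either one committee or a
    per-phenotype mapping of committees.  Returns a long-format table with
    columns (fraction, rep, mode, metric, value), reproducible under the
    seed.
    """
    fractions = list(fractions)
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    norm: dict[str, dict[str, CommitteeModel]] = {}
    for mode, val in committees.items():
        norm[mode] = {val.phenotype_id: val} if isinstance(val, CommitteeModel) else dict(val)

    rng = np.random.default_rng(seed)
    rows = []
    X = matrix.to_numpy()
    for frac in fractions:
        for rep in range(reps):
            degraded = np.zeros_like(X)
            for i in range(X.shape[0]):
                present = np.flatnonzero(X[i])
                keep = int(round(frac * len(present)))
                if keep:
                    kept = rng.choice(present, size=keep, replace=False)
                    degraded[i, kept] = 1
            deg_df = pd.DataFrame(degraded, index=matrix.index, columns=matrix.columns)
            for mode, comms in norm.items():
                calls = [c for committee in comms.values() for c in predict_matrix(committee, deg_df)]
                report = macro_metrics(confusion(calls, labels))
                for metric, value in report.as_dict().items():
                    rows.append(
                        {"fraction": frac, "rep": rep, "mode": mode, "metric": metric, "value": value}
                    )
    return pd.DataFrame(rows)
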