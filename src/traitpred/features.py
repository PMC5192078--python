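"""Phenotype-associated protein families: majority selection and ranking.

The L1 penalty leaves most family weights at exactly zero, so a non-zero
positive weight is an explicit vote that the family's presence argues for
the phenotype.  A family is *selected* when at least three of the five
committee members give it a strictly positive weight; selected families
are then ranked by the Pearson correlation of their presence/absence
column with the observed phenotype labels (unknown labels excluded).  For
two binary vectors Pearson's r is the phi coefficient of the 2x2
contingency table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .models import CommitteeModel

__all__ = ["majority_features", "positive_weight_counts", "rank_by_correlation", "feature_ranking"]

logger = logging.getLogger(__name__)


def positive_weight_counts(committee: CommitteeModel) -> pd.Series:
    """Number of members (0..5) assigning each family a weight > 0."""
    W = np.vstack([m.weights for m in committee.members])
    return pd.Series((W > 0).sum(axis=0), index=committee.family_ids, name="selected_by")


def majority_features(committee: CommitteeModel) -> set[str]:
    """Families with a strictly positive weight in >= 3 of 5 members."""
    counts = positive_weight_counts(committee)
    return set(counts.index[counts >= 3])


def rank_by_correlation(
    selected,
    matrix: pd.DataFrame,
    y: pd.Series,
    selected_by: pd.Series | None = None,
) -> pd.DataFrame:
    """Rank selected families by Pearson correlation with the phenotype.

    Returns a DataFrame (family_id, selected_by, pearson_r, rank) sorted
    by descending r, ties broken lexicographically by family id.  A
    constant family column has undefined correlation; it is reported as
    r = 0 and logged.  Unknown labels are excluded pairwise-complete.
    """
    labeled = y.dropna()
    yv = labeled.to_numpy(dtype=float)
    if len(np.unique(yv)) < 2:
        raise ValueError("phenotype labels must contain both classes")
    families = sorted(set(selected) - (set(selected) - set(matrix.columns)))
    missing = set(selected) - set(matrix.columns)
    if missing:
        raise ValueError(f"selected families outside the matrix universe: {sorted(missing)}")
    rows = []
    for fam in families:
        col = matrix.loc[labeled.index, fam].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            logger.info("rank_by_correlation: %r is constant, r set to 0", fam)
            r = 0.0
        else:
            r = float(np.corrcoef(col, yv)[0, 1])
        rows.append({"family_id": fam, "pearson_r": r})
    out = pd.DataFrame(rows, columns=["family_id", "pearson_r"])
    if selected_by is not None:
        out["selected_by"] = selected_by.reindex(out["family_id"]).to_numpy()
    out = out.sort_values(
        ["pearson_r", "family_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def feature_ranking(committee: CommitteeModel, matrix: pd.DataFrame, y: pd.Series) -> pd.DataFrame:
    """Majority-selected families of a committee, ranked by correlation."""
    counts = positive_weight_counts(committee)
    selected = majority_features(committee)
    out = rank_by_correlation(selected, matrix, y, selected_by=counts)
    out.insert(0, "phenotype_id", committee.phenotype_id)
    return out
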