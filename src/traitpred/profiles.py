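"""Protein-domain hit tables and binary phyletic-pattern matrices.

A *phyletic pattern* is the binary presence/absence vector of protein
families (e.g. Pfam accessions) across a genome.  This module reads HMMER3
per-domain tabular output (``domtblout``), applies the fixed bit-score /
E-value filter, collapses surviving hits into presence/absence matrices,
forms species pangenome profiles as the union over strains, and applies the
phenotype eligibility rule used for model training.

Matrices are plain :class:`pandas.DataFrame` objects: rows are samples,
columns are protein families, values are 0/1 (``int8``).  Phenotype label
tables use values ``1`` (present), ``0`` (absent) and ``NaN`` (unknown).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DomainHit",
    "DomtbloutParseError",
    "parse_domtblout",
    "filter_hits",
    "build_phyletic_matrix",
    "pangenome_union",
    "filter_eligible_phenotypes",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
]

#: Default bit-score threshold below which domain hits are discarded.
DEFAULT_BIT_MIN = 25.0
#: Default E-value threshold above which domain hits are discarded.
DEFAULT_E_MAX = 1e-2


@dataclass(frozen=True)
class DomainHit:
    """One protein-family hit for one sample.

    ``bit_score`` is the full-sequence log-odds score and ``e_value`` the
    full-sequence E-value, as reported in columns 8 and 7 of domtblout.
    """

    sample_id: str
    family_id: str
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if not self.family_id:
            raise ValueError("family_id must be non-empty")
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")


class DomtbloutParseError(ValueError):
    """Raised for a malformed domtblout row; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


# domtblout layout: 0=target name, 1=target acc, 2=tlen, 3=query name,
# 4=query acc, 5=qlen, 6=full-seq E-value, 7=full-seq score, 8=full-seq bias,
# then per-domain columns.  The query is the profile HMM (protein family)
# when produced by ``hmmsearch``.
_N_DOMTBL_COLS = 23
_COL_QUERY_NAME = 3
_COL_QUERY_ACC = 4
_COL_FULL_EVALUE = 6
_COL_FULL_SCORE = 7


def parse_domtblout(stream, sample_id: str = "") -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output into :class:`DomainHit` rows.

    Parameters
    ----------
    stream
        Text lines (file handle, path string, or iterable of lines) in
        domtblout layout.  Lines starting with ``#`` are comments.
    sample_id
        Sample identifier stamped onto every hit (domtblout itself does not
        record the originating sample).

    The family identifier is taken from the query accession column when
    present (not ``-``), else from the query name; the score and E-value are
    the full-sequence columns.
    """
    if isinstance(stream, str):
        with open(stream) as handle:
            return parse_domtblout(handle, sample_id=sample_id)

    hits: list[DomainHit] = []
    for lineno, line in enumerate(stream, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < _N_DOMTBL_COLS:
            raise DomtbloutParseError(
                lineno, f"expected >= {_N_DOMTBL_COLS} columns, found {len(fields)}"
            )
        acc = fields[_COL_QUERY_ACC]
        family = acc if acc != "-" else fields[_COL_QUERY_NAME]
        try:
            e_value = float(fields[_COL_FULL_EVALUE])
            score = float(fields[_COL_FULL_SCORE])
        except ValueError as exc:
            raise DomtbloutParseError(lineno, f"non-numeric score/E-value: {exc}") from None
        if e_value < 0:
            raise DomtbloutParseError(lineno, f"negative E-value {e_value}")
        hits.append(DomainHit(sample_id=sample_id, family_id=family, bit_score=score, e_value=e_value))
    return hits


def filter_hits(
    hits: Iterable[DomainHit],
    bit_min: float = DEFAULT_BIT_MIN,
    e_max: float = DEFAULT_E_MAX,
) -> list[DomainHit]:
    """Keep hits with ``bit_score >= bit_min`` and ``e_value <= e_max``.

    The defaults are the fixed thresholds of the annotation procedure: a
    bit score of at least 25, and E-values above 1e-2 discarded.  Order is
    preserved.
    """
    if not (np.isfinite(bit_min) and np.isfinite(e_max)):
        raise ValueError("thresholds must be finite")
    return [h for h in hits if h.bit_score >= bit_min and h.e_value <= e_max]


def build_phyletic_matrix(
    hits_by_sample: Mapping[str, Iterable[DomainHit]],
    family_universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Collapse filtered hits into a binary samples x families matrix.

    A cell is 1 iff the sample has at least one surviving hit for the
    family (counts are collapsed to presence).  If ``family_universe`` is
    given, families outside it are ignored and the column order is the
    universe's; otherwise the universe is the sorted union of observed
    families.
    """
    sample_ids = list(hits_by_sample)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")

    present: dict[str, set[str]] = {s: {h.family_id for h in hs} for s, hs in hits_by_sample.items()}
    if family_universe is None:
        families = sorted(set().union(*present.values())) if present else []
    else:
        families = list(family_universe)
        if len(set(families)) != len(families):
            raise ValueError("duplicate family ids in universe")

    data = np.zeros((len(sample_ids), len(families)), dtype=np.int8)
    col = {f: j for j, f in enumerate(families)}
    for i, s in enumerate(sample_ids):
        for f in present[s]:
            j = col.get(f)
            if j is not None:
                data[i, j] = 1
    return pd.DataFrame(data, index=pd.Index(sample_ids, name="sample"), columns=families)


def pangenome_union(
    strain_matrix: pd.DataFrame, strain_to_species: Mapping[str, str]
) -> pd.DataFrame:
    """Union strain phyletic patterns into one row per species.

    A species has a family iff any of its strains has it (the pangenome
    union rule).  Every strain row must be mapped to exactly one species.
    """
    missing = [s for s in strain_matrix.index if s not in strain_to_species]
    if missing:
        raise ValueError(f"strains missing from species map: {missing}")
    species = strain_matrix.groupby(
        [strain_to_species[s] for s in strain_matrix.index]
    ).max()
    species.index.name = "sample"
    return species.astype(np.int8)


def filter_eligible_phenotypes(
    labels: pd.DataFrame,
    min_total: int = 20,
    min_pos: int = 10,
    min_neg: int = 10,
) -> pd.DataFrame:
    """Drop phenotypes with too few observed labels for robust training.

    Keeps phenotype columns with at least ``min_total`` non-unknown labels,
    at least ``min_pos`` present (1) and at least ``min_neg`` absent (0).
    """
    n_pos = (labels == 1).sum(axis=0)
    n_neg = (labels == 0).sum(axis=0)
    keep = (n_pos + n_neg >= min_total) & (n_pos >= min_pos) & (n_neg >= min_neg)
    return labels.loc[:, keep[keep].index]


# ---------------------------------------------------------------------------
# tab-delimited interchange


def write_matrix(matrix: pd.DataFrame, path_or_buf) -> None:
    """Write a binary matrix as TSV (header = family ids, first col = sample)."""
    matrix.to_csv(path_or_buf, sep="\t", index_label="sample")


def read_matrix(path_or_buf) -> pd.DataFrame:
    """Read a TSV binary matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path_or_buf, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("matrix values must be 0/1")
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return df.astype(np.int8)


def write_labels(labels: pd.DataFrame, path_or_buf) -> None:
    """Write a ternary label table as TSV with values {1, 0, NA}."""
    out = labels.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path_or_buf, sep="\t", index_label="sample")


def read_labels(path_or_buf) -> pd.DataFrame:
    """Read a TSV label table with values {1, 0, NA}."""
    df = pd.read_csv(path_or_buf, sep="\t", index_col=0, na_values=["NA"])
    bad = df.stack().loc[lambda s: ~s.isin([0, 1])]
    if len(bad):
        raise ValueError(f"label values must be 1/0/NA; offending cells: {bad.index.tolist()[:5]}")
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return df.astype(float)
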