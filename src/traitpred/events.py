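"""Per-branch gain/loss posteriors and the augmented event training set.

A binary character (protein family, or the phenotype itself) evolves along
a rooted tree under a two-state continuous-time Markov chain with gain
rate ``a`` (0 -> 1) and loss rate ``b`` (1 -> 0).  Given the leaf states,
the posterior probability of a *gain* on a branch is the probability that
the parent endpoint is in state 0 and the child endpoint in state 1; a
*loss* is the reverse.  :func:`infer_posteriors` computes these exactly by
the standard inside/outside (pruning) recursions, vectorised over
characters.

When per-branch posteriors are transferred onto a pruned tree whose
branches each absorb a chain of original branches, the chain probabilities
are combined with :func:`combine_event_posteriors`:
``h_1 = g_1``, ``h_{n+1} = h_n + (1 - h_n) * g_{n+1}``, i.e. the
probability of at least one event along the chain, ``1 - prod(1 - g_i)``.

Gains and losses are finally merged per branch into a single "the
character changed here" probability ``x = g + (1 - g) * l`` — phenotype
and family events are treated alike — and branches whose phenotype change
probability is uncertain (above the reporting threshold ``r`` but below
the decision threshold ``t``) are discarded, yielding the extra training
rows used by the gain/loss-aware classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .phylo import BranchMapping, Phylogeny

__all__ = [
    "BranchEventPosteriors",
    "EventSampleSet",
    "combine_event_posteriors",
    "joint_event_probability",
    "infer_posteriors",
    "estimate_rates",
    "map_posteriors",
    "read_event_posteriors",
    "write_event_posteriors",
    "build_event_samples",
]


@dataclass
class BranchEventPosteriors:
    """Per-branch, per-character gain and loss posterior probabilities.

    ``gain`` and ``loss`` are DataFrames indexed by branch id with one
    column per character (families plus, typically, the phenotype).
    """

    gain: pd.DataFrame
    loss: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.gain.index.equals(self.loss.index) or not self.gain.columns.equals(
            self.loss.columns
        ):
            raise ValueError("gain and loss matrices must share branch ids and characters")
        for name, df in (("gain", self.gain), ("loss", self.loss)):
            vals = df.to_numpy()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{name} posteriors must lie in [0, 1]")

    @property
    def branch_ids(self) -> list[str]:
        return list(self.gain.index)

    @property
    def character_ids(self) -> list[str]:
        return list(self.gain.columns)


@dataclass
class EventSampleSet:
    """Augmented training rows derived from confident phenotype events.

    ``X`` holds, per retained branch, the joint gain-or-loss probability of
    every family; ``y`` the phenotype's joint probability; ``y_binary`` the
    discretised label (1 iff ``y >= t``).  Branches with ``r <= y < t``
    have been dropped as uncertain.
    """

    X: pd.DataFrame
    y: pd.Series
    y_binary: pd.Series
    t: float = 0.5
    r: float = 0.05


def combine_event_posteriors(probs: Sequence[float]) -> float:
    """Probability of at least one event along a chain of merged branches.

    Iterates ``h_{n+1} = h_n + (1 - h_n) * g_{n+1}`` (equivalently
    ``1 - prod(1 - g_i)``); used identically for gains and losses when a
    pruned branch absorbs several original branches.
    """
    probs = list(probs)
    if not probs:
        raise ValueError("cannot combine an empty probability chain")
    arr = np.asarray(probs, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    h = arr[0]
    for g in arr[1:]:
        h = h + (1.0 - h) * g
    return float(h)


def joint_event_probability(gain: float, loss: float) -> float:
    """Probability that the character changed on a branch: ``g + (1-g)*l``.

    Symmetric in its arguments (equals ``g + l - g*l``); gains and losses
    are deliberately not distinguished.
    """
    if not (0.0 <= gain <= 1.0 and 0.0 <= loss <= 1.0):
        raise ValueError(f"probabilities must lie in [0, 1], got ({gain}, {loss})")
    return float(gain + (1.0 - gain) * loss)


# ---------------------------------------------------------------------------
# two-state CTMC posterior inference (ancestral-reconstruction stand-in)


def _transition_matrices(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """P(child state | parent state) over a branch of length t.

    Returns an array of shape (2, 2, n_characters); ``a`` is the gain rate
    0->1 and ``b`` the loss rate 1->0 (per character).
    """
    q = a + b
    e = np.exp(-q * t)
    p = np.empty((2, 2) + a.shape)
    p[0, 0] = (b + a * e) / q
    p[0, 1] = (a - a * e) / q
    p[1, 0] = (b - b * e) / q
    p[1, 1] = (a + b * e) / q
    return p


def _binary_states(matrix: pd.DataFrame, leaf_labels: list[str]) -> np.ndarray:
    states = matrix.loc[leaf_labels].to_numpy()
    if not np.isin(states, (0, 1)).all():
        raise ValueError("leaf character states must be 0/1")
    return states.astype(int)


def _as_rate_array(rate, n: int) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(rate, dtype=float), (n,)).copy()
    if (arr <= 0).any():
        raise ValueError("rates must be > 0")
    return arr


def infer_posteriors(
    tree: Phylogeny,
    matrix: pd.DataFrame,
    gain_rate=None,
    loss_rate=None,
    root_prior: str = "stationary",
) -> BranchEventPosteriors:
    """Exact per-branch gain/loss posteriors under a two-state Markov chain.

    Parameters
    ----------
    tree
        Rooted bifurcating tree whose leaf labels equal ``matrix`` rows.
    matrix
        Binary leaf-state matrix, samples x characters.
    gain_rate, loss_rate
        Scalar or per-character arrays of transition rates per unit branch
        length.  If omitted, per-character maximum-likelihood point
        estimates on a coarse grid are used (:func:`estimate_rates`).
    root_prior
        ``"stationary"`` (the chain's equilibrium) or ``"state0"`` (root
        known absent).

    For each branch the posterior that the parent endpoint is 0 and the
    child endpoint 1 (gain), and that the parent is 1 and the child 0
    (loss), is computed by inside/outside marginalisation over all
    ancestral states — exact for any tree size, verifiable by brute-force
    enumeration on small trees.
    """
    leaf_labels = tree.leaf_labels()
    if set(leaf_labels) != set(matrix.index):
        raise ValueError("matrix sample ids must equal tree leaf labels")
    chars = list(matrix.columns)
    n_char = len(chars)
    if gain_rate is None or loss_rate is None:
        est_a, est_b = estimate_rates(tree, matrix)
        a = est_a if gain_rate is None else _as_rate_array(gain_rate, n_char)
        b = est_b if loss_rate is None else _as_rate_array(loss_rate, n_char)
    else:
        a = _as_rate_array(gain_rate, n_char)
        b = _as_rate_array(loss_rate, n_char)

    states = _binary_states(matrix, leaf_labels)
    leaf_row = {lab: i for i, lab in enumerate(leaf_labels)}

    if root_prior == "stationary":
        pi = np.stack([b / (a + b), a / (a + b)])  # (2, n_char)
    elif root_prior == "state0":
        pi = np.stack([np.ones(n_char), np.zeros(n_char)])
    else:
        raise ValueError(f"unknown root_prior {root_prior!r}")

    nodes = list(tree.postorder())
    # inside pass: L[node][s] = P(leaf data below node | node state s)
    inside: dict[str, np.ndarray] = {}
    trans: dict[str, np.ndarray] = {}
    for node in nodes:
        if node.parent is not None:
            trans[node.id] = _transition_matrices(a, b, node.length)
        if node.is_leaf:
            L = np.zeros((2, n_char))
            L[states[leaf_row[node.id]], np.arange(n_char)] = 1.0
        else:
            L = np.ones((2, n_char))
            for child in node.children:
                P = trans[child.id]
                # msg[s] = sum_s' P[s, s'] * L_child[s']
                msg = np.einsum("abc,bc->ac", P, inside[child.id])
                L = L * msg
        inside[node.id] = L

    total = (pi * inside[tree.root.id]).sum(axis=0)  # (n_char,)
    if (total <= 0).any():
        raise ValueError("zero likelihood — inconsistent states or degenerate rates")

    # outside pass: F[node][s] = P(data outside node's subtree, node state s)
    outside: dict[str, np.ndarray] = {tree.root.id: pi}
    gain = {}
    loss = {}
    for node in tree.preorder():
        F_u = outside[node.id]
        for child in node.children:
            P = trans[child.id]
            sib_msg = np.ones((2, n_char))
            for sib in node.children:
                if sib is child:
                    continue
                sib_msg *= np.einsum("abc,bc->ac", trans[sib.id], inside[sib.id])
            G = F_u * sib_msg  # (2, n_char): outside data given parent state
            # joint[pa, ch] = G[pa] * P[pa, ch] * inside_child[ch] / total
            joint = np.einsum("ac,abc,bc->abc", G, P, inside[child.id]) / total
            gain[child.id] = joint[0, 1]
            loss[child.id] = joint[1, 0]
            outside[child.id] = np.einsum("ac,abc->bc", G, P)

    branch_ids = tree.branch_ids()
    gain_df = pd.DataFrame(
        np.vstack([gain[b_] for b_ in branch_ids]), index=branch_ids, columns=chars
    ).clip(0.0, 1.0)
    loss_df = pd.DataFrame(
        np.vstack([loss[b_] for b_ in branch_ids]), index=branch_ids, columns=chars
    ).clip(0.0, 1.0)
    gain_df.index.name = loss_df.index.name = "branch_id"
    return BranchEventPosteriors(gain=gain_df, loss=loss_df)


DEFAULT_RATE_GRID = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0)


def estimate_rates(
    tree: Phylogeny, matrix: pd.DataFrame, grid: Sequence[float] = DEFAULT_RATE_GRID
) -> tuple[np.ndarray, np.ndarray]:
    """Coarse per-character ML point estimates of the transition rate.

    A 1-D grid search over a common gain = loss rate scale: for each value
    the data likelihood of every character is computed by the inside pass,
    and each character keeps the grid value maximising its likelihood.
    Returns ``(gain_rates, loss_rates)`` arrays aligned with the matrix
    columns.
    """
    leaf_labels = tree.leaf_labels()
    if set(leaf_labels) != set(matrix.index):
        raise ValueError("matrix sample ids must equal tree leaf labels")
    n_char = matrix.shape[1]
    states = _binary_states(matrix, leaf_labels)
    leaf_row = {lab: i for i, lab in enumerate(leaf_labels)}
    nodes = list(tree.postorder())

    loglik = np.empty((len(grid), n_char))
    for k, rho in enumerate(grid):
        a = np.full(n_char, float(rho))
        b = a
        pi = np.full((2, n_char), 0.5)
        inside: dict[str, np.ndarray] = {}
        for node in nodes:
            if node.is_leaf:
                L = np.zeros((2, n_char))
                L[states[leaf_row[node.id]], np.arange(n_char)] = 1.0
            else:
                L = np.ones((2, n_char))
                for child in node.children:
                    P = _transition_matrices(a, b, child.length)
                    L = L * np.einsum("abc,bc->ac", P, inside[child.id])
            inside[node.id] = L
        total = (pi * inside[tree.root.id]).sum(axis=0)
        loglik[k] = np.log(np.maximum(total, 1e-300))
    best = np.asarray(grid, dtype=float)[np.argmax(loglik, axis=0)]
    return best, best.copy()


def map_posteriors(post: BranchEventPosteriors, mapping: BranchMapping) -> BranchEventPosteriors:
    """Transfer full-tree posteriors onto a pruned tree's branches.

    Each pruned branch's gain (loss) posterior is the combined probability
    of at least one gain (loss) along its absorbed chain of original
    branches.
    """
    rows_g, rows_l, ids = [], [], []
    for target, chain in mapping.chains.items():
        g = 1.0 - (1.0 - post.gain.loc[chain].to_numpy()).prod(axis=0)
        l = 1.0 - (1.0 - post.loss.loc[chain].to_numpy()).prod(axis=0)
        ids.append(target)
        rows_g.append(g)
        rows_l.append(l)
    gain = pd.DataFrame(np.vstack(rows_g), index=ids, columns=post.gain.columns)
    loss = pd.DataFrame(np.vstack(rows_l), index=ids, columns=post.loss.columns)
    gain.index.name = loss.index.name = "branch_id"
    return BranchEventPosteriors(gain=gain, loss=loss)


# ---------------------------------------------------------------------------
# interchange with external gain/loss mappers


def write_event_posteriors(post: BranchEventPosteriors, path_or_buf) -> None:
    """Write posteriors as TSV: branch_id, character_id, gain_prob, loss_prob."""
    long = pd.DataFrame(
        {
            "branch_id": np.repeat(post.branch_ids, len(post.character_ids)),
            "character_id": np.tile(post.character_ids, len(post.branch_ids)),
            "gain_prob": post.gain.to_numpy().ravel(),
            "loss_prob": post.loss.to_numpy().ravel(),
        }
    )
    long.to_csv(path_or_buf, sep="\t", index=False)


def read_event_posteriors(path_or_buf) -> BranchEventPosteriors:
    """Read a posterior table written by an external tool or by
    :func:`write_event_posteriors`.

    Columns (header required): ``branch_id``, ``character_id``,
    ``gain_prob``, ``loss_prob``.  Pairs absent from the file default to
    probability 0; out-of-range probabilities raise with the offending row
    number.
    """
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"branch_id": str, "character_id": str})
    required = ["branch_id", "character_id", "gain_prob", "loss_prob"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"posterior table missing columns: {missing}")
    for col in ("gain_prob", "loss_prob"):
        bad = df.index[(df[col] < 0) | (df[col] > 1)]
        if len(bad):
            # +2: header line plus 1-based counting
            raise ValueError(f"{col} outside [0, 1] at row {bad[0] + 2}")
    branches = list(dict.fromkeys(df["branch_id"]))
    characters = list(dict.fromkeys(df["character_id"]))
    gain = pd.DataFrame(0.0, index=branches, columns=characters)
    loss = pd.DataFrame(0.0, index=branches, columns=characters)
    for _, row in df.iterrows():
        gain.at[row["branch_id"], row["character_id"]] = row["gain_prob"]
        loss.at[row["branch_id"], row["character_id"]] = row["loss_prob"]
    gain.index.name = loss.index.name = "branch_id"
    return BranchEventPosteriors(gain=gain, loss=loss)


# ---------------------------------------------------------------------------
# event training rows


def build_event_samples(
    post: BranchEventPosteriors,
    phenotype_id: str,
    t: float = 0.5,
    r: float = 0.05,
) -> EventSampleSet:
    """Assemble confident gain/loss training rows from branch posteriors.

    Per branch ``i``: ``x_ij = g_ij + (1 - g_ij) * l_ij`` for every family
    ``j`` and likewise ``y_i`` for the phenotype.  Branches with
    ``r <= y_i < t`` are discarded as uncertain phenotype events; retained
    branches receive the binary label ``y' = [y_i >= t]``.
    """
    if phenotype_id not in post.character_ids:
        raise ValueError(f"phenotype {phenotype_id!r} not among characters")
    if not (0.0 < r < t <= 1.0):
        raise ValueError(f"need 0 < r < t <= 1, got r={r}, t={t}")

    g = post.gain.to_numpy()
    l = post.loss.to_numpy()
    x_all = g + (1.0 - g) * l
    x_df = pd.DataFrame(x_all, index=post.gain.index, columns=post.gain.columns)
    y = x_df[phenotype_id]
    X = x_df.drop(columns=[phenotype_id])
    keep = (y < r) | (y >= t)
    X = X.loc[keep]
    y = y.loc[keep]
    y_binary = (y >= t).astype(np.int8)
    y_binary.name = "y_binary"
    return EventSampleSet(X=X, y=y, y_binary=y_binary, t=t, r=r)
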