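"""Synthetic phylogenies, co-evolving binary characters, and fixture files.

The generator emulates the data regime the trait-prediction engine is
built for: a bifurcating species tree, protein families evolving as
two-state (presence/absence) Markov chains along its branches, and a
binary phenotype whose causal families tend to be gained and lost
together with it.  Three regimes are provided:

* ``iid`` — phenotype and families evolve from stationary root states;
* ``clade_confounded`` — additionally, a block of phenotype-neutral
  families is planted as a single gain in one clade, mimicking lineage-
  specific gene content that correlates with any clade-aligned phenotype
  through shared ancestry alone;
* ``hgt_like`` — the phenotype is gained independently in at least three
  disjoint clades, the horizontal-transfer-like situation in which
  phylogeny-naive feature selection is most misleading.

Per-branch transitions are sampled from the exact two-state transition
probabilities (no event-time simulation), and every sampled state change
is recorded, so the true gain/loss events are available for validating
the posterior inference.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .phylo import Node, Phylogeny

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_tree",
    "simulate_evolution",
    "write_fixture_domtblout",
]

PHENOTYPE_ID = "phenotype"


@dataclass
class SimulationConfig:
    """Study conditions for one simulated data set.

    Defaults follow the scale of a realistic training corpus: a couple of
    hundred species, several hundred protein families of which a handful
    are causally linked to the phenotype, strong but imperfect linkage,
    and a few percent label noise.  Rates are per unit branch length;
    with gain = loss the phenotype is balanced in expectation.
    """

    n_leaves: int = 200
    n_families: int = 500
    n_causal: int = 10
    gain_rate: float = 0.3
    loss_rate: float = 0.3
    phenotype_linkage: float = 0.9
    label_noise: float = 0.05
    regime: Literal["iid", "clade_confounded", "hgt_like"] = "iid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_families:
            raise ValueError("n_causal must be <= n_families")
        if not (0 <= self.phenotype_linkage <= 1):
            raise ValueError("phenotype_linkage must lie in [0, 1]")
        if not (0 <= self.label_noise < 1):
            raise ValueError("label_noise must lie in [0, 1)")
        if self.gain_rate <= 0 or self.loss_rate <= 0:
            raise ValueError("rates must be > 0")


@dataclass
class SimulatedTruth:
    """A simulated data set plus everything needed to verify inference."""

    tree: Phylogeny
    matrix: pd.DataFrame  # leaves x families, 0/1
    labels: pd.DataFrame  # leaves x {phenotype}, possibly noise-flipped
    causal_families: set[str]
    true_branch_events: pd.DataFrame  # branches x characters: +1 gain, -1 loss, 0 none
    true_leaf_states: pd.Series = field(default=None)  # noise-free phenotype leaf states
    phenotype_id: str = PHENOTYPE_ID


def simulate_tree(n_leaves: int, seed: int) -> Phylogeny:
    """Random rooted bifurcating tree (Yule splits, Exp(1) branch lengths)."""
    if n_leaves < 3:
        raise ValueError(f"need >= 3 leaves, got {n_leaves}")
    rng = np.random.default_rng(seed)
    root = Node(id="", children=[Node(id=""), Node(id="")])
    for c in root.children:
        c.parent = root
    leaves = list(root.children)
    for _ in range(n_leaves - 2):
        idx = int(rng.integers(len(leaves)))
        leaf = leaves.pop(idx)
        kids = [Node(id="", parent=leaf), Node(id="", parent=leaf)]
        leaf.children = kids
        leaves.extend(kids)

    width = len(str(n_leaves))
    leaf_counter = internal_counter = 0

    def name(node: Node) -> None:
        nonlocal leaf_counter, internal_counter
        for c in node.children:
            name(c)
        if node.is_leaf:
            leaf_counter += 1
            node.id = f"S{leaf_counter:0{width}d}"
        else:
            internal_counter += 1
            node.id = f"N{internal_counter}"
        if node.parent is not None:
            node.length = float(rng.exponential(1.0))

    name(root)
    return Phylogeny(root)


def _transition(rng, parent_state: np.ndarray, a, b, t: float) -> np.ndarray:
    """Sample child states from exact two-state transition probabilities."""
    q = a + b
    e = math.e ** (-q * t) if np.isscalar(q) else np.exp(-q * t)
    p01 = a * (1 - e) / q  # P(child=1 | parent=0)
    p11 = (a + b * e) / q  # P(child=1 | parent=1)
    p_one = np.where(parent_state == 1, p11, p01)
    return (rng.random(np.shape(parent_state)) < p_one).astype(np.int8)


def _clade_nodes(tree: Phylogeny) -> list[Node]:
    return [n for n in tree.postorder() if n.children and n.parent is not None]


def _leaf_count(node: Node) -> int:
    return 1 if node.is_leaf else sum(_leaf_count(c) for c in node.children)


def _leaves_under(node: Node) -> list[str]:
    if node.is_leaf:
        return [node.id]
    return [lab for c in node.children for lab in _leaves_under(c)]


def simulate_evolution(cfg: SimulationConfig) -> SimulatedTruth:
    """Evolve the phenotype and families along a simulated tree.

    Causal families copy each phenotype branch outcome with probability
    ``phenotype_linkage`` (at linkage 1 their leaf patterns equal the
    phenotype's) and otherwise evolve independently from their current
    state; neutral families always evolve independently.  Leaf phenotype
    labels are flipped with probability ``label_noise``.
    """
    tree = simulate_tree(cfg.n_leaves, cfg.seed)
    rng = np.random.default_rng([cfg.seed, 1])
    a, b = cfg.gain_rate, cfg.loss_rate
    pi1 = a / (a + b)
    fam_width = len(str(cfg.n_families))
    families = [f"PF{j + 1:0{fam_width}d}" for j in range(cfg.n_families)]
    causal = set(families[: cfg.n_causal])
    nodes = list(tree.preorder())

    # -- phenotype states per node ------------------------------------------
    phen: dict[str, int] = {}
    if cfg.regime == "hgt_like":
        # >= 3 independent gains: phenotype present exactly below chosen
        # disjoint mid-sized clades, absent elsewhere
        n = cfg.n_leaves
        candidates = [
            nd for nd in _clade_nodes(tree) if max(2, n // 25) <= _leaf_count(nd) <= max(4, n // 5)
        ]
        rng.shuffle(candidates)
        chosen: list[Node] = []
        taken: set[str] = set()
        for nd in candidates:
            under = set(_leaves_under(nd))
            if under & taken:
                continue
            chosen.append(nd)
            taken |= under
            if len(chosen) >= max(3, n // 40):
                break
        if len(chosen) < 3:
            raise RuntimeError("could not place 3 disjoint phenotype-gain clades; trivial tree?")
        gained = {nd.id for nd in chosen}
        for node in nodes:
            if node.parent is None:
                phen[node.id] = 0
            elif node.id in gained:
                phen[node.id] = 1
            else:
                phen[node.id] = phen[node.parent.id]
    else:
        for node in nodes:
            if node.parent is None:
                phen[node.id] = int(rng.random() < pi1)
            else:
                phen[node.id] = int(
                    _transition(rng, np.array([phen[node.parent.id]]), a, b, node.length)[0]
                )

    # -- family states, vectorised over families ----------------------------
    states: dict[str, np.ndarray] = {}
    causal_mask = np.array([f in causal for f in families])
    for node in nodes:
        if node.parent is None:
            st = (rng.random(cfg.n_families) < pi1).astype(np.int8)
            st[causal_mask] = phen[node.id]
        else:
            parent = states[node.parent.id]
            st = _transition(rng, parent, a, b, node.length)
            copy = causal_mask & (rng.random(cfg.n_families) < cfg.phenotype_linkage)
            st = st.copy()
            st[copy] = phen[node.id]
        states[node.id] = st

    # -- confounder block: one clade shares a block of neutral families -----
    if cfg.regime == "clade_confounded":
        n_block = max(5, cfg.n_families // 20)
        neutral = [f for f in families if f not in causal]
        block = neutral[-n_block:]
        block_mask = np.array([f in block for f in families])
        clades = [nd for nd in _clade_nodes(tree) if _leaf_count(nd) >= max(3, cfg.n_leaves // 6)]
        clade = clades[int(rng.integers(len(clades)))] if clades else tree.root.children[0]
        inside: set[str] = set()

        def mark(nd: Node) -> None:
            inside.add(nd.id)
            for c in nd.children:
                mark(c)

        mark(clade)
        for node in nodes:
            st = states[node.id]
            st[block_mask] = 1 if node.id in inside else 0

    # -- assemble outputs ----------------------------------------------------
    leaf_ids = tree.leaf_labels()
    matrix = pd.DataFrame(
        np.vstack([states[l] for l in leaf_ids]),
        index=pd.Index(leaf_ids, name="sample"),
        columns=families,
        dtype=np.int8,
    )
    true_leaf = pd.Series([phen[l] for l in leaf_ids], index=leaf_ids, name=PHENOTYPE_ID)
    flips = rng.random(len(leaf_ids)) < cfg.label_noise
    observed = true_leaf.to_numpy() ^ flips.astype(int)
    labels = pd.DataFrame({PHENOTYPE_ID: observed.astype(float)}, index=matrix.index)

    branch_ids = tree.branch_ids()
    by_id = tree.nodes_by_id()
    ev = np.zeros((len(branch_ids), cfg.n_families + 1), dtype=np.int8)
    for i, bid in enumerate(branch_ids):
        node = by_id[bid]
        ev[i, :-1] = states[node.id].astype(np.int16) - states[node.parent.id]
        ev[i, -1] = phen[node.id] - phen[node.parent.id]
    events = pd.DataFrame(ev, index=pd.Index(branch_ids, name="branch_id"),
                          columns=families + [PHENOTYPE_ID])

    return SimulatedTruth(
        tree=tree,
        matrix=matrix,
        labels=labels,
        causal_families=causal,
        true_branch_events=events,
        true_leaf_states=true_leaf,
    )


# ---------------------------------------------------------------------------
# fixture domtblout files

_DOMTBL_HEADER = (
    "#                                                               --- full sequence ---"
    " -------------- this domain -------------   hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           accession   qlen   E-value"
    "  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from"
    "    to  acc description of target\n"
)


def _hit_row(gene: str, family: str, e_value: float, score: float) -> str:
    return (
        f"{gene} - 350 {family} {family} 200 {e_value:.3g} {score:.1f} 0.1 "
        f"1 1 {e_value:.3g} {e_value:.3g} {score:.1f} 0.1 1 200 10 210 5 215 0.95 -\n"
    )


def write_fixture_domtblout(matrix: pd.DataFrame, out_dir, seed: int) -> list[str]:
    """Write one domtblout fixture file per sample.

    Each present family gets a hit row passing the default filters
    (bit score in [26, 300], E-value in [1e-30, 1e-3]); about 5% extra
    decoy rows fail the filters (low score or high E-value) so that
    parsing + filtering + matrix building reproduces the input exactly.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    families = list(matrix.columns)
    paths = []
    for sample in matrix.index:
        path = os.path.join(out_dir, f"{sample}.domtblout")
        present = [f for f in families if matrix.at[sample, f] == 1]
        with open(path, "w") as fh:
            fh.write(_DOMTBL_HEADER)
            gene_no = 0
            for fam in present:
                gene_no += 1
                score = float(rng.uniform(26.0, 300.0))
                e_value = float(10.0 ** rng.uniform(-30, -3))
                fh.write(_hit_row(f"{sample}_g{gene_no:05d}", fam, e_value, score))
            n_decoys = math.ceil(0.05 * len(present)) if present else 1
            for _ in range(n_decoys):
                gene_no += 1
                fam = families[int(rng.integers(len(families)))]
                if rng.random() < 0.5:
                    score, e_value = float(rng.uniform(2.0, 24.9)), float(10.0 ** rng.uniform(-6, -3))
                else:
                    score, e_value = float(rng.uniform(26.0, 100.0)), float(rng.uniform(0.05, 5.0))
                fh.write(_hit_row(f"{sample}_g{gene_no:05d}", fam, e_value, score))
        paths.append(path)
    return paths
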