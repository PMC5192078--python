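import numpy as np
import pandas as pd
import pytest

from traitpred.phylo import Phylogeny
from traitpred.synthetic import SimulationConfig, simulate_evolution


@pytest.fixture(scope="session")
def four_leaf_tree() -> Phylogeny:
    """((A,B),(C,D)) with assorted branch lengths <= 1."""
    return Phylogeny.from_newick("((A:0.5,B:1.0)X:0.8,(C:0.3,D:0.9)Y:0.4)R;")


@pytest.fixture(scope="session")
def small_truth():
    """A small simulated data set shared by read-only tests."""
    cfg = SimulationConfig(n_leaves=40, n_families=60, n_causal=5, seed=11)
    return simulate_evolution(cfg)


@pytest.fixture(scope="session")
def separable_truth():
    """Noise-free, perfectly linked simulation: phenotype == causal patterns."""
    cfg = SimulationConfig(
        n_leaves=50, n_families=30, n_causal=1, phenotype_linkage=1.0, label_noise=0.0, seed=7
    )
    return simulate_evolution(cfg)


def brute_force_posteriors(tree: Phylogeny, leaf_states: dict, a: float, b: float,
                           root_prior=None):
    """Exhaustive enumeration over all internal-state assignments.

    Independent oracle for the pruning-based posterior inference: sums the
    joint probability of every ancestral state vector, tallying mass where
    a branch's parent/child endpoints are (0,1) (gain) or (1,0) (loss).
    """
    import itertools

    q = a + b
    if root_prior is None:
        root_prior = np.array([b / q, a / q])

    def P(t):
        e = np.exp(-q * t)
        return np.array([[(b + a * e) / q, (a - a * e) / q],
                         [(b - b * e) / q, (a + b * e) / q]])

    nodes = {n.id: n for n in tree.postorder()}
    internal = [n.id for n in tree.postorder() if not n.is_leaf]
    branch_ids = tree.branch_ids()
    total = 0.0
    joint = {bid: np.zeros((2, 2)) for bid in branch_ids}
    for assign in itertools.product([0, 1], repeat=len(internal)):
        st = dict(zip(internal, assign))
        st.update(leaf_states)
        p = root_prior[st[tree.root.id]]
        for bid in branch_ids:
            n = nodes[bid]
            p *= P(n.length)[st[n.parent.id], st[n.id]]
        total += p
        for bid in branch_ids:
            n = nodes[bid]
            joint[bid][st[n.parent.id], st[n.id]] += p
    gain = {bid: joint[bid][0, 1] / total for bid in branch_ids}
    loss = {bid: joint[bid][1, 0] / total for bid in branch_ids}
    return gain, loss


def macro_brute(counts: pd.DataFrame) -> dict:
    """Independent per-phenotype loop implementation of the printed metrics."""
    rp, rn = [], []
    for _, row in counts.iterrows():
        if row.TP + row.FN > 0 and row.TN + row.FP > 0:
            rp.append(row.TP / (row.TP + row.FN))
            rn.append(row.TN / (row.TN + row.FP))
    mr_pos = sum(rp) / len(rp)
    mr_neg = sum(rn) / len(rn)
    tp, tn, fp, fn = counts.TP.sum(), counts.TN.sum(), counts.FP.sum(), counts.FN.sum()
    r_pos = tp / (tp + fn)
    r_neg = tn / (tn + fp)
    return {
        "macrorecall_pos": mr_pos,
        "macrorecall_neg": mr_neg,
        "macroaccuracy": (mr_pos + mr_neg) / 2,
        "recall_pos": r_pos,
        "recall_neg": r_neg,
        "accuracy": (r_pos + r_neg) / 2,
    }
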