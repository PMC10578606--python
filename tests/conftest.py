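"""Shared fixtures: small count matrices, random trees, and the species-tree
topology of the W-region worked example."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from wregion.counts_de import CountMatrix
from wregion.wphylo import ABSENT, PRESENT, Tree, parse_newick


def make_count_matrix(counts: np.ndarray, groups: list[str],
                      gene_ids=None, sample_ids=None) -> CountMatrix:
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {"group": groups, "genotype": "NA", "phenotype": "NA", "batch": "b1"},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids), meta)


@pytest.fixture
def tiny_cm() -> CountMatrix:
    """4 genes x 4 samples, two groups of two."""
    counts = np.array(
        [
            [10, 12, 30, 28],
            [0, 0, 0, 0],
            [5, 7, 5, 6],
            [100, 90, 110, 95],
        ]
    )
    return make_count_matrix(counts, ["a", "a", "b", "b"])


def random_tree(rng: np.random.Generator, n_tips: int) -> Tree:
    """A random rooted tree built by recursive splitting (binary or multifurcating)."""
    labels = [f"t{i}" for i in range(n_tips)]

    def build(tips: list[str]) -> str:
        if len(tips) == 1:
            return tips[0]
        k = 2 if len(tips) == 2 else int(rng.integers(2, min(3, len(tips)) + 1))
        rng.shuffle(tips)
        cuts = sorted(rng.choice(np.arange(1, len(tips)), size=k - 1, replace=False))
        parts, start = [], 0
        for c in list(cuts) + [len(tips)]:
            parts.append(tips[start:c])
            start = c
        return "(" + ",".join(build(p) for p in parts) + ")"

    return parse_newick(build(labels) + ";")


def dollo_oracle(tree: Tree, states: dict[str, str]):
    """Brute-force Dollo optimum: enumerate gain nodes x loss-edge subsets.

    Returns (min_total_losses, best_gain_nodes, losses_by_gain) where
    losses_by_gain maps each admissible gain node to its minimal loss count.
    Independent of the production algorithm: feasibility of a (gain, losses)
    pair is checked tip by tip from first principles.
    """
    present = {t for t, s in states.items() if s == PRESENT}
    absent = {t for t, s in states.items() if s == ABSENT}

    def feasible(gain: str, losses: set[str]) -> bool:
        clade = set(tree.preorder(gain))
        for tip in tree.tip_names():
            on_path = set(tree.path_to_root(tip))
            has = (tip in clade) and not (losses & on_path & (clade - {gain}))
            if tip in present and not has:
                return False
            if tip in absent and has:
                return False
        return True

    losses_by_gain: dict[str, int] = {}
    for gain in tree.node_ids():
        if not all(tree.is_ancestor(gain, t) for t in present):
            continue
        edges = [n for n in tree.preorder(gain) if n != gain]
        best = None
        for r in range(len(edges) + 1):
            for combo in itertools.combinations(edges, r):
                if feasible(gain, set(combo)):
                    best = r
                    break
            if best is not None:
                break
        if best is not None:
            losses_by_gain[gain] = best
    min_losses = min(losses_by_gain.values())
    best_gains = [g for g, n in losses_by_gain.items() if n == min_losses]
    return min_losses, best_gains, losses_by_gain


#: Species-tree topology for the W-region worked example: the dm-w exon 4
#: clade is the MRCA of X. largeni and X. laevis with X. vestitus nested
#: inside it, X. clivii sister to that clade, and two outgroups.
XENOPUS_NEWICK = (
    "(X_tropicalis,(X_muelleri,(X_clivii,"
    "((X_pygmaeus,(X_itombwensis,(X_kobeli,X_andrei))),"
    "(X_vestitus,(X_largeni,((X_gilli,X_laevis),"
    "(X_petersii,(X_poweri,X_victorianus)))))))));"
)

#: Capture-sequencing presence/absence of dm-w exon 4: detected in ten
#: species, undetected in X. vestitus and X. clivii (which carry exons 2-3),
#: and absent outside the clade.
DMW_EXON4_STATES = {
    "X_laevis": PRESENT, "X_gilli": PRESENT, "X_petersii": PRESENT,
    "X_poweri": PRESENT, "X_victorianus": PRESENT, "X_largeni": PRESENT,
    "X_pygmaeus": PRESENT, "X_itombwensis": PRESENT, "X_kobeli": PRESENT,
    "X_andrei": PRESENT,
    "X_vestitus": ABSENT, "X_clivii": ABSENT,
    "X_muelleri": ABSENT, "X_tropicalis": ABSENT,
}


@pytest.fixture
def xenopus_tree() -> Tree:
    return parse_newick(XENOPUS_NEWICK)
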