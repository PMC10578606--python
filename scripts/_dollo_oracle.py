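"""Brute-force Dollo oracle and random-tree builder for the acceptance script.

Feasibility of a (gain node, loss-edge set) pair is checked tip by tip from
first principles, independently of the production algorithm.
"""

from __future__ import annotations

import itertools

import numpy as np

from wregion.wphylo import Tree, parse_newick


def random_tree(rng: np.random.Generator, n_tips: int) -> Tree:
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
    present = {t for t, s in states.items() if s == "present"}
    absent = {t for t, s in states.items() if s == "absent"}

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
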