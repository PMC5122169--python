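"""Gain/loss reconstruction of snoRNA family histories on a species tree.

Each family's per-species paralog counts are reconstructed backwards in
time under a Dollo constraint: the family originates exactly once, at the
last common ancestor of all species that carry it, and copy numbers evolve
along branches at a linear cost |parent - child| (one event per copy
gained or lost). Ancestral copy numbers are found by the Sankoff dynamic
program over the states {0..max_count} restricted to the origin subtree;
ties are broken toward the smallest ancestral count, which prefers later
duplication over early duplication followed by loss.

States above the maximum observed leaf count can never reduce a linear
cost (moving an ancestral state above every descendant count adds at least
as much on some incident branch as it saves on the others), so the default
state ceiling is the maximum observed count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import pandas as pd

from snofamkit.core_io import node_label


@dataclass
class GainLossHistory:
    family: str
    origin: str                                   # node label
    ancestral: dict[str, int]                     # node label -> copy count
    branch_events: dict[str, tuple[int, int]]     # node label -> (gained, lost) on entering branch
    leaf_counts: dict[str, int]
    cost: int


# ---------------------------------------------------------------------------


def build_presence_matrix(
    counts: dict[str, dict[str, int]], tree: dendropy.Tree
) -> pd.DataFrame:
    """Family x species paralog-count matrix, species in tree leaf order,
    with a boolean ``conserved`` column (present in >=2 species)."""
    leaf_order = [node_label(lf) for lf in tree.leaf_node_iter()]
    df = pd.DataFrame(
        {sp: {fam: counts[fam].get(sp, 0) for fam in counts} for sp in leaf_order}
    )
    df = df.loc[df.sum(axis=1) > 0]
    df["conserved"] = (df[leaf_order] > 0).sum(axis=1) >= 2
    return df


def dollo_origin(leaf_counts: dict[str, int], tree: dendropy.Tree) -> dendropy.Node:
    """The single-origin Dollo ancestor: LCA of all leaves with count > 0."""
    positive = sorted(sp for sp, c in leaf_counts.items() if c > 0)
    if not positive:
        raise ValueError("dollo_origin needs at least one positive leaf count")
    if len(positive) == 1:
        return tree.find_node_with_taxon_label(positive[0])
    return tree.mrca(taxon_labels=positive)


def sankoff_counts(
    tree: dendropy.Tree,
    leaf_counts: dict[str, int],
    family: str = "",
    max_count: int | None = None,
) -> GainLossHistory:
    """Minimum-cost ancestral copy numbers under the Dollo constraint.

    Cost of a branch a -> b is |a - b|; outside the origin subtree all
    counts are 0; the origin's ancestral count is >= 1; and once a lineage
    reaches 0 copies it stays at 0 (the family is gained exactly once, at
    the origin). Backtracking breaks ties toward the smallest state.
    Per-branch gains/losses are the signed count differences split into
    nonnegative parts, plus the family-level gain of ``origin`` copies on
    the branch entering the origin.
    """
    observed_max = max(leaf_counts.values())
    if max_count is None:
        max_count = observed_max
    if observed_max > max_count:
        raise ValueError(f"leaf count {observed_max} exceeds max_count {max_count}")
    origin = dollo_origin(leaf_counts, tree)
    K = max_count
    INF = math.inf

    cost: dict[dendropy.Node, list[float]] = {}
    for node in origin.postorder_iter():
        if node.is_leaf():
            c = leaf_counts.get(node_label(node), 0)
            cost[node] = [0.0 if s == c else INF for s in range(K + 1)]
        else:
            vec = []
            for s in range(K + 1):
                total = 0.0
                for ch in node.child_nodes():
                    # Dollo: a 0-copy ancestor cannot regain the family
                    reachable = range(K + 1) if s > 0 else range(1)
                    total += min(abs(s - t) + cost[ch][t] for t in reachable)
                vec.append(total)
            cost[node] = vec

    # origin state must be >= 1
    best = min(cost[origin][1:])
    state = {origin: next(s for s in range(1, K + 1) if cost[origin][s] == best)}
    for node in origin.preorder_iter():
        s_parent = state[node]
        for ch in node.child_nodes():
            reachable = range(K + 1) if s_parent > 0 else range(1)
            best_t = min(
                reachable, key=lambda t: (abs(s_parent - t) + cost[ch][t], t)
            )
            state[ch] = best_t

    ancestral: dict[str, int] = {}
    branch_events: dict[str, tuple[int, int]] = {}
    subtree = set(origin.preorder_iter())
    for node in tree.preorder_node_iter():
        lbl = node_label(node)
        if node not in subtree:
            ancestral[lbl] = 0
            branch_events[lbl] = (0, 0)
            continue
        ancestral[lbl] = state[node]
        if node is origin:
            branch_events[lbl] = (state[node], 0)  # family-level gain here
        else:
            diff = state[node] - state[node.parent_node]
            branch_events[lbl] = (max(diff, 0), max(-diff, 0))

    return GainLossHistory(
        family=family,
        origin=node_label(origin),
        ancestral=ancestral,
        branch_events=branch_events,
        leaf_counts=dict(leaf_counts),
        cost=int(best),
    )


# ---------------------------------------------------------------------------
# Cohort summaries


def summarize_families(
    histories: list[GainLossHistory], tree: dendropy.Tree
) -> pd.DataFrame:
    """Node-wise summary over all families.

    Per node: families present (ancestral count >= 1), families gained on
    the entering branch (origin here), families lost (>=1 -> 0), and the
    gene-level analogues. Satisfies, at every non-root node,
    observed = parent_observed + gained - lost.
    """
    labels = [node_label(n) for n in tree.preorder_node_iter()]
    for h in histories:
        if set(h.ancestral) != set(labels):
            raise ValueError(
                f"history of family {h.family} does not match the tree's node set: "
                "tree mismatch"
            )
    rows = []
    for node in tree.preorder_node_iter():
        lbl = node_label(node)
        fam_obs = sum(1 for h in histories if h.ancestral[lbl] >= 1)
        fam_gain = sum(1 for h in histories if h.origin == lbl)
        fam_loss = 0
        if node.parent_node is not None:
            plbl = node_label(node.parent_node)
            fam_loss = sum(
                1 for h in histories if h.ancestral[plbl] >= 1 and h.ancestral[lbl] == 0
            )
        gene_obs = sum(h.ancestral[lbl] for h in histories)
        gene_gain = sum(h.branch_events[lbl][0] for h in histories)
        gene_loss = sum(h.branch_events[lbl][1] for h in histories)
        rows.append(
            {
                "node": lbl,
                "is_leaf": node.is_leaf(),
                "observed_families": fam_obs,
                "gained_families": fam_gain,
                "lost_families": fam_loss,
                "observed_genes": gene_obs,
                "gained_genes": gene_gain,
                "lost_genes": gene_loss,
            }
        )
    return pd.DataFrame(rows).set_index("node")


def annotated_newick(tree: dendropy.Tree, summary: pd.DataFrame) -> str:
    """Newick string with per-node observed/gained/lost family counts as
    bracketed comments after each node label."""

    def fmt(node: dendropy.Node) -> str:
        lbl = node_label(node)
        row = summary.loc[lbl]
        tag = f"[obs={row.observed_families},gain={row.gained_families},loss={row.lost_families}]"
        if node.is_leaf():
            return f"{lbl}{tag}"
        inner = ",".join(fmt(ch) for ch in node.child_nodes())
        return f"({inner}){lbl}{tag}"

    return fmt(tree.seed_node) + ";"
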