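"""Ancestral-state tracing of a binary trait on a species tree.

The trait here is presence (1) / absence (0) of the heterodimerization
interaction in each organism.  Two reconstructions are provided: maximum
parsimony (unit-cost Sankoff, which returns the full set of states each node
takes in at least one most-parsimonious reconstruction, and is exact on
polytomies) and marginal likelihood under a symmetric two-state Markov (Mk2)
model with an equal root prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .io import SpeciesTree

INF = float("inf")


def _tip_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon else (node.label or "")


def _check_tips(tree: SpeciesTree, tips: dict) -> None:
    for leaf in tree.leaf_node_iter():
        label = _tip_label(leaf)
        if label not in tips:
            raise KeyError(f"tip {label!r} has no assigned state")
        if tips[label] not in (0, 1):
            raise ValueError(f"tip {label!r}: state must be 0 or 1")


def _node_name(node: dendropy.Node, k: int) -> str:
    if node.is_leaf():
        return _tip_label(node)
    return node.label or f"node{k}"


@dataclass
class FitchResult:
    node_states: dict  # node name -> frozenset of MPR states
    root_states: frozenset
    n_changes: int


def fitch_trace(tree: SpeciesTree, tips: dict) -> FitchResult:
    """Minimum-change reconstruction of a binary trait.

    ``node_states`` holds, per node, the states realized in at least one
    most-parsimonious labeling (computed by a min-plus down/up pass, so the
    count and the sets are exact for polytomies as well).
    """
    _check_tips(tree, tips)
    root = tree.seed_node
    down: dict = {}  # node -> [cost state 0, cost state 1] for its subtree
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tips[_tip_label(node)]
            down[node] = [0 if s == 0 else INF, 0 if s == 1 else INF]
        else:
            cost = [0.0, 0.0]
            for child in node.child_nodes():
                c = down[child]
                for s in (0, 1):
                    cost[s] += min(c[0] + (s != 0), c[1] + (s != 1))
            down[node] = cost
    n_changes = int(min(down[root]))

    up: dict = {root: [0.0, 0.0]}  # cost of the rest of the tree given node state
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        for child in children:
            sib_cost = [0.0, 0.0]
            for sib in children:
                if sib is child:
                    continue
                c = down[sib]
                for s in (0, 1):
                    sib_cost[s] += min(c[0] + (s != 0), c[1] + (s != 1))
            u = up[node]
            up[child] = [
                min(u[s] + sib_cost[s] + (s != sc) for s in (0, 1)) for sc in (0, 1)
            ]

    node_states = {}
    root_states = None
    for k, node in enumerate(tree.preorder_node_iter()):
        total = [down[node][s] + up[node][s] for s in (0, 1)]
        best = min(total)
        states = frozenset(s for s in (0, 1) if total[s] == best)
        name = _node_name(node, k)
        node_states[name] = states
        if node is root:
            root_states = states
    return FitchResult(node_states, root_states, n_changes)


# ---------------------------------------------------------------------------
# Mk2 likelihood


def _p_same(rate: float, t: float) -> float:
    """Transition kernel of the symmetric 2-state model: P(stay) over time t."""
    return 0.5 + 0.5 * math.exp(-2.0 * rate * t)


def _edge_length(node: dendropy.Node, default: float) -> float:
    return node.edge.length if node.edge.length is not None else default


def mk2_loglik(tree: SpeciesTree, tips: dict, rate: float,
               default_branch_length: float = 1.0) -> float:
    """Log-likelihood of the tip data under Mk2 with equal root prior."""
    _check_tips(tree, tips)
    if rate <= 0:
        raise ValueError("rate must be positive")
    partial: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tips[_tip_label(node)]
            partial[node] = np.array([1.0 - s, float(s)])
        else:
            lik = np.ones(2)
            for child in node.child_nodes():
                t = _edge_length(child, default_branch_length)
                ps = _p_same(rate, t)
                P = np.array([[ps, 1 - ps], [1 - ps, ps]])
                lik *= P @ partial[child]
            partial[node] = lik
    root_lik = 0.5 * partial[tree.seed_node].sum()
    if root_lik <= 0:
        return -INF
    return math.log(root_lik)


@dataclass
class Mk2Result:
    posteriors: dict  # node name -> P(state 1)
    rate: float
    loglik: float


def mk2_marginal(
    tree: SpeciesTree,
    tips: dict,
    rate: float | None = None,
    default_branch_length: float = 1.0,
) -> Mk2Result:
    """Marginal posterior of state 1 at every node under Mk2.

    ``rate`` fixed, or optimized by bounded 1-D search on the log-likelihood
    when None.  Cladograms (no branch lengths) use unit branches.
    """
    _check_tips(tree, tips)
    total_len = sum(
        _edge_length(n, default_branch_length)
        for n in tree.preorder_node_iter()
        if n.parent_node is not None
    )
    if total_len <= 0:
        raise ValueError("tree has zero total branch length")
    if rate is None:
        res = minimize_scalar(
            lambda lg: -mk2_loglik(tree, tips, math.exp(lg), default_branch_length),
            bounds=(math.log(1e-4), math.log(50.0)),
            method="bounded",
        )
        rate = math.exp(res.x)

    down: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tips[_tip_label(node)]
            down[node] = np.array([1.0 - s, float(s)])
        else:
            lik = np.ones(2)
            for child in node.child_nodes():
                t = _edge_length(child, default_branch_length)
                ps = _p_same(rate, t)
                P = np.array([[ps, 1 - ps], [1 - ps, ps]])
                lik *= P @ down[child]
            down[node] = lik

    root = tree.seed_node
    up: dict = {root: np.array([0.5, 0.5])}  # prior-weighted outside message
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        for child in children:
            msg = up[node].copy()
            for sib in children:
                if sib is child:
                    continue
                t = _edge_length(sib, default_branch_length)
                ps = _p_same(rate, t)
                P = np.array([[ps, 1 - ps], [1 - ps, ps]])
                msg *= P @ down[sib]
            t = _edge_length(child, default_branch_length)
            ps = _p_same(rate, t)
            P = np.array([[ps, 1 - ps], [1 - ps, ps]])
            up[child] = P.T @ msg

    posteriors = {}
    loglik = math.log(float((up[root] * down[root]).sum()))
    for k, node in enumerate(tree.preorder_node_iter()):
        joint = up[node] * down[node]
        posteriors[_node_name(node, k)] = float(joint[1] / joint.sum())
    return Mk2Result(posteriors, rate, loglik)
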