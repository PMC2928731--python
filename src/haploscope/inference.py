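"""Tree search and nested-model statistics.

A Jukes–Cantor-corrected distance matrix seeds a neighbor-joining tree;
maximum-likelihood search then hill-climbs over nearest-neighbor
interchanges (NNI), re-optimising model parameters for every candidate
topology.  Nested model pairs are compared with a likelihood ratio test
against the χ² distribution, and model families are ranked by AIC.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .io import Alignment
from .model import (
    LikelihoodResult,
    ModelSpec,
    optimize_parameters,
    parse_model_spec,
)
from .trees import Node, Tree

logger = logging.getLogger(__name__)

SATURATION_CAP = 5.0


@dataclasses.dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    flagged: np.ndarray  # True where distance was saturated / incomparable

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")


@dataclasses.dataclass
class LRTResult:
    stat: float
    df: int
    p_value: float
    critical_value: float
    level: float
    reject: bool


def jc_distance_matrix(
    aln: Alignment, saturation_cap: float = SATURATION_CAP
) -> DistanceMatrix:
    """Pairwise Jukes–Cantor distances d = −(3/4)·ln(1 − 4p/3).

    Only positions where both sequences carry an unambiguous base
    (A,C,G,T) are compared.  Pairs with mismatch fraction ≥ 0.75, or
    with no comparable site, are flagged and set to ``saturation_cap``.
    """
    M = aln.to_matrix()
    good = M < 4
    for row, rec in zip(good, aln):
        if not row.any():
            raise ValueError(f"record {rec.id!r} has no unambiguous bases")
    n = len(aln.records)
    d = np.zeros((n, n))
    flagged = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            both = good[i] & good[j]
            m = int(both.sum())
            if m == 0:
                d[i, j] = d[j, i] = saturation_cap
                flagged[i, j] = flagged[j, i] = True
                continue
            p = float((M[i, both] != M[j, both]).sum()) / m
            if p >= 0.75:
                d[i, j] = d[j, i] = saturation_cap
                flagged[i, j] = flagged[j, i] = True
            else:
                val = -0.75 * math.log1p(-4.0 * p / 3.0)
                d[i, j] = d[j, i] = val
    return DistanceMatrix(labels=aln.ids(), d=d, flagged=flagged)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster labels (a cluster is labelled by its smallest member
    leaf).  Negative branch lengths are clamped to zero.  The result is
    unrooted: a trifurcating root for n ≥ 3, a single edge for n = 2.
    """
    if dm.flagged.any():
        logger.warning(
            "distance matrix contains %d saturated entries (capped)",
            int(dm.flagged.sum()) // 2,
        )
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least two records")
    nodes = [Node(label=lab) for lab in dm.labels]
    names = list(dm.labels)
    D = dm.d.copy()
    if n == 2:
        root = Node()
        a = root.add_child(nodes[0])
        b = root.add_child(nodes[1])
        a.length = max(0.0, float(D[0, 1]))
        b.length = 0.0
        return Tree(root)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((names[i], names[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = D[i, j] - vi
        parent = Node()
        parent.add_child(nodes[i]).length = max(0.0, vi)
        parent.add_child(nodes[j]).length = max(0.0, vj)
        # distances to the new cluster
        new_row = np.zeros(D.shape[0] + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        new_idx = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[new_idx, k] = D[k, new_idx] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        names.append(min(names[i], names[j]))
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j, k = active
    root = Node()
    root.add_child(nodes[i]).length = max(
        0.0, 0.5 * (D[i, j] + D[i, k] - D[j, k])
    )
    root.add_child(nodes[j]).length = max(
        0.0, 0.5 * (D[i, j] + D[j, k] - D[i, k])
    )
    root.add_child(nodes[k]).length = max(
        0.0, 0.5 * (D[i, k] + D[j, k] - D[i, j])
    )
    return Tree(root)


# --------------------------------------------------------------------------
# NNI hill climbing
# --------------------------------------------------------------------------


def _internal_edge_indices(tree: Tree) -> list[int]:
    return [
        idx
        for idx, node in enumerate(tree.edges())
        if not node.is_leaf
    ]


def _nni_neighbors(tree: Tree, edge_index: int) -> list[Tree]:
    """The two NNI rearrangements around one internal edge (as copies)."""
    out = []
    for which in (0, 1):
        t = tree.copy()
        v = t.edges()[edge_index]
        u = v.parent
        t.reroot_at(u)
        sib = next(c for c in u.children if c is not v)
        c = v.children[which]
        ui = u.children.index(sib)
        vi = v.children.index(c)
        u.children[ui], v.children[vi] = c, sib
        c.parent, sib.parent = u, v
        out.append(t)
    return out


def nni_search(
    aln: Alignment,
    spec: ModelSpec | str,
    seed: int = 0,
    *,
    candidate_rounds: int = 4,
    tol: float = 1e-4,
) -> LikelihoodResult:
    """Maximum-likelihood topology search by NNI hill climbing.

    Starts from the neighbor-joining tree on Jukes–Cantor distances,
    then repeatedly scans internal edges in deterministic order,
    evaluating both NNI rearrangements per edge with model parameters
    re-optimised; the first rearrangement improving lnL by more than
    ``tol`` is accepted and the scan restarts.  Terminates when no edge
    improves.  ``seed`` is recorded for provenance; the search itself is
    deterministic.
    """
    if isinstance(spec, str):
        spec = parse_model_spec(spec)
    start = nj_tree(jc_distance_matrix(aln))
    best = optimize_parameters(aln, start, spec)
    if len(aln.records) < 4:
        return best
    improved = True
    while improved:
        improved = False
        for edge_index in _internal_edge_indices(best.tree):
            for cand_tree in _nni_neighbors(best.tree, edge_index):
                cand = optimize_parameters(
                    aln,
                    cand_tree,
                    spec,
                    max_rounds=candidate_rounds,
                    init_params=best.params,
                )
                if cand.lnL > best.lnL + tol:
                    best = cand
                    improved = True
                    break
            if improved:
                break
    # final polish of the accepted topology
    final = optimize_parameters(aln, best.tree, spec)
    if final.lnL > best.lnL:
        best = final
    return best


# --------------------------------------------------------------------------
# nested-model statistics
# --------------------------------------------------------------------------


def chi2_quantile(tail_prob: float, df: int) -> float:
    """Upper-tail χ² quantile: the x with P(X ≥ x) = tail_prob."""
    if not (0 < tail_prob <= 1):
        raise ValueError("tail_prob must be in (0, 1]")
    if df < 1:
        raise ValueError("df must be a positive integer")
    return float(chi2_dist.isf(tail_prob, df))


def lrt_decision(stat: float, df: int, level: float = 0.05) -> LRTResult:
    """Refer an observed 2ΔlnL to the χ²(df) distribution."""
    if stat < 0:
        raise ValueError("LRT statistic must be >= 0")
    crit = chi2_quantile(level, df)
    p = float(chi2_dist.sf(stat, df))
    return LRTResult(
        stat=float(stat),
        df=df,
        p_value=p,
        critical_value=crit,
        level=level,
        reject=stat > crit,
    )


def lrt(
    null: LikelihoodResult, alt: LikelihoodResult, level: float = 0.05
) -> LRTResult:
    """Likelihood ratio test between two nested model fits.

    ``stat = 2(lnL_alt − lnL_null)`` with df the difference in free
    parameter counts.  The null must be nested in the alternative.
    """
    if null.spec is not None and alt.spec is not None:
        if not null.spec.is_nested_in(alt.spec):
            raise ValueError(
                f"{null.spec.name} is not nested in {alt.spec.name}"
            )
    df = alt.n_free_params - null.n_free_params
    if df < 1:
        raise ValueError("alternative must have more free parameters than null")
    if alt.lnL < null.lnL - 1e-6:
        raise ValueError(
            f"alternative lnL ({alt.lnL:.6f}) below null lnL ({null.lnL:.6f}); "
            "fits are inconsistent with nesting"
        )
    stat = max(0.0, 2.0 * (alt.lnL - null.lnL))
    return lrt_decision(stat, df, level)


@dataclasses.dataclass
class ModelRank:
    spec: ModelSpec
    aic: float
    fit: LikelihoodResult


def select_model(
    aln: Alignment,
    candidates: Sequence[ModelSpec | str],
    *,
    K: int = 8,
) -> list[ModelRank]:
    """Rank substitution models by AIC on a fixed NJ starting topology.

    AIC = 2k − 2lnL with k counting free model parameters plus branch
    lengths (identical across candidates, so the ranking depends only on
    model fit).  Ties are broken in favour of fewer parameters.
    """
    specs = [
        parse_model_spec(c, K=K) if isinstance(c, str) else c for c in candidates
    ]
    if len(specs) < 2 and len(specs) != 1:
        raise ValueError("need at least one candidate model")
    topo = nj_tree(jc_distance_matrix(aln))
    n_branches = len(topo.edges())
    ranks: list[ModelRank] = []
    for spec in specs:
        try:
            fit = optimize_parameters(aln, topo, spec)
        except Exception as exc:  # noqa: BLE001 - candidate exclusion is the contract
            logger.warning("model %s excluded: %s", spec.name, exc)
            continue
        k = spec.n_free_params() + n_branches
        ranks.append(ModelRank(spec=spec, aic=2.0 * k - 2.0 * fit.lnL, fit=fit))
    ranks.sort(key=lambda r: (r.aic, r.spec.n_free_params()))
    return ranks
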