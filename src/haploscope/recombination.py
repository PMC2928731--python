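"""Pairwise homoplasy index (PHI) test for recombination.

For every pair of nearby parsimony-informative sites, the refined
incompatibility score measures how many extra mutational steps are
needed to explain both sites on a single genealogy, beyond the minimum
each site needs alone.  Recombination creates spatial structure: nearby
site pairs stay compatible within non-recombining blocks while distant
pairs conflict, so the observed mean incompatibility over close pairs
(Φ) is compared against a null built by permuting the order of the
informative sites, which destroys spatial signal while preserving the
site columns themselves.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Optional

import numpy as np

from .io import BASES, Alignment

DEFAULT_WINDOW = 100


@dataclasses.dataclass
class PhiResult:
    phi: Optional[float]
    n_informative_pairs: int
    n_informative_sites: int
    window: int
    p_value: Optional[float] = None
    n_perm: int = 0
    untestable: bool = False


def _column_states(column: str) -> list[str]:
    return [c for c in column if c in BASES]


def is_parsimony_informative(column: str) -> bool:
    """True iff ≥2 states each occur ≥2 times (ambiguous bases ignored)."""
    counts: dict[str, int] = {}
    for c in column:
        if c in BASES:
            counts[c] = counts.get(c, 0) + 1
    return sum(1 for v in counts.values() if v >= 2) >= 2


def informative_sites(aln: Alignment) -> list[int]:
    """0-based indices of parsimony-informative columns."""
    return [
        j for j in range(aln.length) if is_parsimony_informative(aln.column(j))
    ]


def _pair_score(col_i: str, col_j: str) -> int:
    """Cyclomatic number of the partition intersection graph.

    Vertices are the states of each site, edges the observed joint
    states (over sequences unambiguous at both sites); the number of
    independent cycles, edges − vertices + components, equals the extra
    changes required to fit both sites on one tree.
    """
    joint = {
        (a, b)
        for a, b in zip(col_i, col_j)
        if a in BASES and b in BASES
    }
    if not joint:
        return 0
    verts: dict[str, int] = {}
    for a, b in joint:
        for v in (f"i{a}", f"j{b}"):
            if v not in verts:
                verts[v] = len(verts)
    parent = list(range(len(verts)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in joint:
        pa, pb = find(verts[f"i{a}"]), find(verts[f"j{b}"])
        if pa != pb:
            parent[pa] = pb
    components = len({find(v) for v in range(len(verts))})
    return len(joint) - len(verts) + components


def site_pair_incompatibility(col_i: str, col_j: str) -> int:
    """Refined incompatibility score for two parsimony-informative columns.

    Zero iff the two sites fit on a common tree without extra homoplasy;
    for a pair of binary sites this reduces to the four-gamete test.
    Sequences ambiguous at either site are excluded pairwise.
    """
    for name, col in (("col_i", col_i), ("col_j", col_j)):
        if not is_parsimony_informative(col):
            raise ValueError(f"{name} is not parsimony-informative")
    if len(col_i) != len(col_j):
        raise ValueError("columns must have equal length")
    return _pair_score(col_i, col_j)


def _score_matrix(aln: Alignment, sites: list[int]) -> np.ndarray:
    cols = [aln.column(j) for j in sites]
    k = len(sites)
    S = np.zeros((k, k))
    for a, b in itertools.combinations(range(k), 2):
        S[a, b] = S[b, a] = _pair_score(cols[a], cols[b])
    return S


def _window_pairs(positions: list[int], window: int) -> list[tuple[int, int]]:
    pairs = []
    for a, b in itertools.combinations(range(len(positions)), 2):
        if positions[b] - positions[a] <= window:
            pairs.append((a, b))
    return pairs


def phi_statistic(aln: Alignment, window: int = DEFAULT_WINDOW) -> PhiResult:
    """Mean refined incompatibility over informative-site pairs within
    ``window`` alignment positions of each other."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(aln.records) < 4:
        raise ValueError("PHI requires at least 4 sequences")
    sites = informative_sites(aln)
    if len(sites) < 2:
        return PhiResult(
            phi=None,
            n_informative_pairs=0,
            n_informative_sites=len(sites),
            window=window,
            untestable=True,
        )
    pairs = _window_pairs(sites, window)
    if not pairs:
        return PhiResult(
            phi=None,
            n_informative_pairs=0,
            n_informative_sites=len(sites),
            window=window,
            untestable=True,
        )
    S = _score_matrix(aln, sites)
    phi = float(np.mean([S[a, b] for a, b in pairs]))
    return PhiResult(
        phi=phi,
        n_informative_pairs=len(pairs),
        n_informative_sites=len(sites),
        window=window,
    )


def phi_permutation_test(
    aln: Alignment,
    window: int = DEFAULT_WINDOW,
    n_perm: int = 999,
    seed: int = 0,
) -> PhiResult:
    """PHI permutation test.

    The null permutes which informative column sits at which informative
    position (columns preserved, spatial order destroyed); the p-value
    is (1 + #{Φ_perm ≤ Φ_obs}) / (n_perm + 1), small when nearby pairs
    are unusually compatible relative to distant ones — the signature of
    recombination.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    base = phi_statistic(aln, window=window)
    if base.untestable:
        return base
    sites = informative_sites(aln)
    pairs = _window_pairs(sites, window)
    S = _score_matrix(aln, sites)
    rng = np.random.default_rng(seed)
    k = len(sites)
    hits = 0
    idx_a = np.array([a for a, _ in pairs])
    idx_b = np.array([b for _, b in pairs])
    for _ in range(n_perm):
        perm = rng.permutation(k)
        phi_perm = float(S[perm[idx_a], perm[idx_b]].mean())
        if phi_perm <= base.phi + 1e-12:
            hits += 1
    return PhiResult(
        phi=base.phi,
        n_informative_pairs=base.n_informative_pairs,
        n_informative_sites=base.n_informative_sites,
        window=window,
        p_value=(1 + hits) / (n_perm + 1),
        n_perm=n_perm,
    )
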