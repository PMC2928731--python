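"""Synthetic data with the statistical structure of a small viral
amplicon survey: random genealogies, haplotype alignments evolved under
GTR+Γ+I, two-haplotype mixture chromatogram signals at unequal
abundance, and missing-data patterns concentrated at fragment ends.

Defaults emulate a ~500 bp helicase-region amplicon with strongly
L-shaped site-rate heterogeneity (gamma shape ≈ 0.1), a fraction of
invariant sites, and up to 18% Ns at the fragment ends.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import BASES, Alignment, PeakTable, SequenceRecord
from .model import SubstModelParams, _Eigen, discrete_gamma_rates
from .trees import Node, Tree

DEFAULT_SEQ_LENGTH = 500
DEFAULT_ALPHA = 0.101
DEFAULT_P_INV = 0.3


def default_model(
    alpha: float | None = DEFAULT_ALPHA,
    p_inv: float | None = DEFAULT_P_INV,
    K: int = 8,
) -> SubstModelParams:
    """A GTR+Γ+I parameterisation with mild frequency/exchangeability skew."""
    return SubstModelParams(
        exchangeabilities=np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0]),
        pi=np.array([0.30, 0.20, 0.22, 0.28]),
        alpha=alpha,
        p_inv=p_inv,
        K=K,
    )


@dataclasses.dataclass
class SimParams:
    """Knobs of the synthetic-survey generator."""

    n_taxa: int = 16
    seq_length: int = DEFAULT_SEQ_LENGTH
    model: SubstModelParams = dataclasses.field(default_factory=default_model)
    mixture_ratio: float = 0.7
    noise_sd: float = 0.02
    missing_fraction: float = 0.1
    mean_branch: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.seq_length < 3:
            raise ValueError("seq_length must be >= 3")
        if not (0.5 < self.mixture_ratio <= 1.0):
            raise ValueError("mixture_ratio must be in (0.5, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must be in [0, 1)")


def simulate_tree(n_taxa: int, seed: int, mean_branch: float = 0.02) -> Tree:
    """Random unrooted binary genealogy with exponential branch lengths.

    Topology by random coalescent-style joining of lineages; each of the
    2·n_taxa−3 edges gets an i.i.d. Exponential(mean_branch) length.
    Leaves are labelled ``t01``, ``t02``, ...
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if mean_branch <= 0:
        raise ValueError("mean_branch must be positive")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_taxa)))
    lineages: list[Node] = [
        Node(label=f"t{i + 1:0{width}d}") for i in range(n_taxa)
    ]
    if n_taxa == 2:
        root = Node()
        root.add_child(lineages[0])
        root.add_child(lineages[1])
        lineages[0].length = float(rng.exponential(mean_branch))
        lineages[1].length = 0.0
        return Tree(root)
    while len(lineages) > 3:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        joint = Node()
        joint.add_child(lineages[i])
        joint.add_child(lineages[j])
        lineages = [n for k, n in enumerate(lineages) if k not in (i, j)]
        lineages.append(joint)
    root = Node()
    for n in lineages:
        root.add_child(n)
    tree = Tree(root)
    for edge in tree.edges():
        edge.length = float(rng.exponential(mean_branch))
    return tree


def evolve_sequences(
    tree: Tree, model: SubstModelParams, length: int, seed: int
) -> Alignment:
    """Evolve sequences down the tree under the model's GTR+Γ+I process.

    Per-site rates follow the discrete mixture used in inference: a site
    is invariant with probability p_inv, otherwise it draws one of the K
    discrete gamma category rates uniformly (or rate 1 if α is off).
    The root sequence is drawn from the stationary frequencies π.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if tree.n_leaves() < 2:
        raise ValueError("tree must have >= 2 leaves")
    rng = np.random.default_rng(seed)
    rates_cat, p_inv = model.category_rates()
    site_rates = np.empty(length)
    invariant = rng.random(length) < p_inv
    site_rates[invariant] = 0.0
    n_var = int((~invariant).sum())
    if model.alpha is None:
        site_rates[~invariant] = 1.0
    else:
        cats = rng.integers(0, model.K, size=n_var)
        site_rates[~invariant] = discrete_gamma_rates(model.alpha, model.K).rates[cats]

    eig = _Eigen(model)
    unique_rates = np.unique(site_rates)
    groups = {r: np.flatnonzero(site_rates == r) for r in unique_rates}

    root_states = rng.choice(4, size=length, p=model.pi)
    states: dict[int, np.ndarray] = {id(tree.root): root_states}
    records: list[SequenceRecord] = []
    for node in tree.preorder():
        if node.parent is not None:
            parent_states = states[id(node.parent)]
            child = parent_states.copy()
            for r, idx in groups.items():
                if r == 0.0 or node.length == 0.0 or idx.size == 0:
                    continue
                P = eig.pmat(node.length * r)
                cum = np.cumsum(P, axis=1)
                u = rng.random(idx.size)
                child[idx] = (
                    u[:, None] > cum[parent_states[idx]]
                ).sum(axis=1)
            states[id(node)] = child
        if node.is_leaf:
            seq = "".join(BASES[s] for s in states[id(node)])
            records.append(SequenceRecord(id=node.label, bases=seq))
    records.sort(key=lambda r: r.id)
    return Alignment(records)


def simulate_mixture_peaks(
    hapA: SequenceRecord,
    hapB: SequenceRecord,
    ratio: float,
    noise_sd: float,
    seed: int,
) -> PeakTable:
    """Two-haplotype Sanger signal: hapA at abundance ``ratio``, hapB at
    ``1−ratio``, independent truncated-Gaussian noise on both strands.

    At each position the base of hapA receives intensity ``ratio`` and
    the base of hapB ``1−ratio`` (summed where the haplotypes agree);
    every channel then gets N(0, noise_sd²) noise truncated at zero.
    """
    if len(hapA) != len(hapB):
        raise ValueError(
            f"haplotype lengths differ: {len(hapA)} vs {len(hapB)}"
        )
    if not (0.5 < ratio <= 1.0):
        raise ValueError("ratio must be in (0.5, 1]")
    if "-" in hapA.bases or "-" in hapB.bases:
        raise ValueError("gapped haplotypes cannot be rendered as peaks")
    rng = np.random.default_rng(seed)
    n = len(hapA)
    clean = np.zeros((n, 4))
    for pos, (a, b) in enumerate(zip(hapA.bases, hapB.bases)):
        if a in BASES:
            clean[pos, BASES.index(a)] += ratio
        if b in BASES:
            clean[pos, BASES.index(b)] += 1.0 - ratio
    intensity = {}
    for strand in "FR":
        noisy = clean + rng.normal(0.0, noise_sd, size=(n, 4)) if noise_sd > 0 else clean.copy()
        intensity[strand] = np.maximum(noisy, 0.0)
    return PeakTable(
        start=1,
        intensity=intensity,
        has_strand={s: np.ones(n, dtype=bool) for s in "FR"},
    )


def inject_missing(
    record: SequenceRecord, fraction: float, seed: int, mode: str = "ends"
) -> SequenceRecord:
    """Replace round(fraction·length) bases with N.

    ``mode='ends'`` splits the Ns between a run at the start and a run at
    the end of the fragment (low-quality read ends); ``mode='random'``
    scatters them uniformly.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    if mode not in ("ends", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(record)
    k = round(fraction * n)
    if k == 0:
        return SequenceRecord(id=record.id, bases=record.bases, meta=dict(record.meta))
    rng = np.random.default_rng(seed)
    bases = list(record.bases)
    if mode == "ends":
        front = int(rng.integers(0, k + 1))
        back = k - front
        for i in range(front):
            bases[i] = "N"
        for i in range(n - back, n):
            bases[i] = "N"
    else:
        for i in rng.choice(n, size=k, replace=False):
            bases[i] = "N"
    return SequenceRecord(id=record.id, bases="".join(bases), meta=dict(record.meta))
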