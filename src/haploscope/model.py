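"""GTR+Γ+I substitution model and Felsenstein pruning likelihood.

The general time-reversible (GTR) model is parameterised by six
exchangeabilities (AC, AG, AT, CG, CT, GT), stationary base frequencies
π, an optional gamma shape α governing among-site rate variation
(discretised into K equal-probability categories, each carrying the
conditional mean rate of its quantile bin), and an optional proportion
of invariant sites p_inv.  The rate matrix is normalised to one expected
substitution per site per unit time at stationarity, so branch lengths
are in expected substitutions per variable site.

Transition probabilities come from the eigendecomposition of the
π-symmetrised generator, which is numerically stable for any reversible
model.  The tree likelihood is computed by Felsenstein's pruning
algorithm over compressed site patterns; `N` and `-` contribute a
partial likelihood of 1 for every state.  Parameters and branch lengths
are optimised by deterministic coordinate ascent with bounded Brent line
searches.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from scipy import special
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .io import Alignment
from .trees import Tree

EXCH_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

DEFAULT_K = 8


class OptimizationError(RuntimeError):
    """Non-finite likelihood encountered during parameter search."""


class ModelSpecError(ValueError):
    """Unrecognised substitution-model family name."""


# --------------------------------------------------------------------------
# model family specifications
# --------------------------------------------------------------------------

_BASE_FAMILIES = ("JC", "HKY", "GTR")


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A member of the nested family {JC, HKY, GTR} x {plain, +I, +G, +G+I}."""

    base: str
    gamma: bool
    invariant: bool
    K: int = DEFAULT_K

    @property
    def name(self) -> str:
        s = self.base
        if self.gamma:
            s += "+G"
        if self.invariant:
            s += "+I"
        return s

    def n_free_params(self) -> int:
        k = {"JC": 0, "HKY": 4, "GTR": 8}[self.base]
        return k + int(self.gamma) + int(self.invariant)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        base_ok = _BASE_FAMILIES.index(self.base) <= _BASE_FAMILIES.index(other.base)
        return (
            base_ok
            and (other.gamma or not self.gamma)
            and (other.invariant or not self.invariant)
        )


def parse_model_spec(name: str, K: int = DEFAULT_K) -> ModelSpec:
    parts = name.replace("Γ", "G").upper().split("+")
    base = parts[0]
    if base not in _BASE_FAMILIES:
        raise ModelSpecError(f"unknown base model {base!r}; expected JC, HKY or GTR")
    extras = set(parts[1:])
    if not extras <= {"G", "GAMMA", "I", ""}:
        raise ModelSpecError(f"unknown model suffix in {name!r}")
    return ModelSpec(
        base=base,
        gamma=bool({"G", "GAMMA"} & extras),
        invariant="I" in extras,
        K=K,
    )


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------


@dataclasses.dataclass
class SubstModelParams:
    """Numerical parameters of a GTR-family substitution model.

    ``alpha=None`` switches gamma rate variation off; ``p_inv=None``
    switches the invariant-site class off.
    """

    exchangeabilities: np.ndarray = dataclasses.field(
        default_factory=lambda: np.ones(6)
    )
    pi: np.ndarray = dataclasses.field(default_factory=lambda: np.full(4, 0.25))
    alpha: Optional[float] = None
    p_inv: Optional[float] = None
    K: int = DEFAULT_K

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.exchangeabilities.shape != (6,) or (self.exchangeabilities < 0).any():
            raise ValueError("exchangeabilities must be 6 non-negative reals")
        if self.pi.shape != (4,) or (self.pi <= 0).any():
            raise ValueError("pi must be 4 positive frequencies")
        self.pi = self.pi / self.pi.sum()
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape alpha must be positive")
        if self.p_inv is not None and not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must be in [0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")

    def copy(self) -> "SubstModelParams":
        return SubstModelParams(
            exchangeabilities=self.exchangeabilities.copy(),
            pi=self.pi.copy(),
            alpha=self.alpha,
            p_inv=self.p_inv,
            K=self.K,
        )

    def rate_matrix(self) -> np.ndarray:
        """Normalised GTR generator Q (expected rate 1 at stationarity)."""
        Q = np.zeros((4, 4))
        for s, (i, j) in zip(self.exchangeabilities, _PAIRS):
            Q[i, j] = s * self.pi[j]
            Q[j, i] = s * self.pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(self.pi, np.diag(Q))
        if mu <= 0:
            raise ValueError("degenerate rate matrix (all exchangeabilities zero?)")
        return Q / mu

    def category_rates(self) -> tuple[np.ndarray, float]:
        """(per-category rates, p_inv) for the likelihood mixture."""
        if self.alpha is None:
            rates = np.array([1.0])
        else:
            rates = discrete_gamma_rates(self.alpha, self.K).rates
        return rates, (self.p_inv or 0.0)


@dataclasses.dataclass
class RateCategories:
    rates: np.ndarray
    weights: np.ndarray


@dataclasses.dataclass
class LikelihoodResult:
    lnL: float
    params: SubstModelParams
    tree: Tree
    n_free_params: int
    spec: Optional[ModelSpec] = None


# --------------------------------------------------------------------------
# discrete gamma
# --------------------------------------------------------------------------


_ALPHA_DEGENERATE = 1e5  # above this the gamma is numerically a point mass


def _discrete_gamma_rates_cached(alpha: float, K: int) -> np.ndarray:
    bounds = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([special.gammainc(alpha + 1.0, bounds * alpha), [1.0]])
    lower = np.concatenate([[0.0], upper[:-1]])
    return K * (upper - lower)


_gamma_rate_cache: dict[tuple[float, int], np.ndarray] = {}


def discrete_gamma_rates(alpha: float, K: int) -> RateCategories:
    """K equal-probability rate categories for a mean-one gamma.

    Each category's rate is the conditional mean of Gamma(α, 1/α) within
    its quantile bin, computed in closed form from the regularised lower
    incomplete gamma function; the category means average to exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1 or alpha >= _ALPHA_DEGENERATE:
        # the discrete approximation collapses to a point mass at rate 1
        return RateCategories(
            rates=np.ones(K), weights=np.full(K, 1.0 / K)
        )
    key = (float(alpha), int(K))
    rates = _gamma_rate_cache.get(key)
    if rates is None:
        # E[X; X in bin] for the mean-one gamma equals
        # P(alpha+1, alpha*upper) - P(alpha+1, alpha*lower)
        rates = _discrete_gamma_rates_cached(alpha, K)
        if len(_gamma_rate_cache) > 4096:
            _gamma_rate_cache.clear()
        _gamma_rate_cache[key] = rates
    return RateCategories(rates=rates.copy(), weights=np.full(K, 1.0 / K))


# --------------------------------------------------------------------------
# transition probabilities
# --------------------------------------------------------------------------


class _Eigen:
    """Eigendecomposition of the π-symmetrised GTR generator."""

    __slots__ = ("w", "left", "right", "pi")

    def __init__(self, model: SubstModelParams):
        Q = model.rate_matrix()
        sqrt_pi = np.sqrt(model.pi)
        B = (Q / sqrt_pi[None, :]) * sqrt_pi[:, None]  # D^{1/2} Q D^{-1/2}
        B = (B + B.T) / 2.0  # clean off rounding asymmetry
        w, V = np.linalg.eigh(B)
        self.w = w
        self.right = V / sqrt_pi[:, None]  # D^{-1/2} V
        self.left = V.T * sqrt_pi[None, :]  # V^T D^{1/2}
        self.pi = model.pi

    def pmat(self, t: float) -> np.ndarray:
        if t <= 0:
            return np.eye(4)
        P = (self.right * np.exp(self.w * t)) @ self.left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def pmats(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Batched transition matrices, one per rate category: (K, 4, 4)."""
        ts = max(t, 0.0) * np.asarray(rates, dtype=float)
        expw = np.exp(self.w[None, :] * ts[:, None])
        P = (self.right[None, :, :] * expw[:, None, :]) @ self.left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def transition_probs(
    model: SubstModelParams, t: float, rate: float = 1.0
) -> np.ndarray:
    """4x4 transition probability matrix P = exp(Q·t·rate).

    Rows sum to 1; entries are non-negative; detailed balance
    π_i P_ij = π_j P_ji holds to numerical precision.
    """
    if t < 0:
        raise ValueError("branch length t must be >= 0")
    if rate < 0:
        raise ValueError("rate multiplier must be >= 0")
    return _Eigen(model).pmat(t * rate)


# --------------------------------------------------------------------------
# pruning likelihood
# --------------------------------------------------------------------------


class _PatternData:
    """Compressed site patterns plus per-leaf partial likelihoods."""

    def __init__(self, aln: Alignment):
        M = aln.to_matrix()  # (n, L) codes 0..3 = ACGT, 4 = missing
        patterns, counts = np.unique(M, axis=1, return_counts=True)
        self.patterns = patterns  # (n, P)
        self.weights = counts.astype(float)
        self.ids = aln.ids()
        n, P = patterns.shape
        self.leaf_partials = {}
        eye = np.eye(4)
        ones = np.ones(4)
        for row, rec_id in enumerate(self.ids):
            codes = patterns[row]
            part = np.where(codes[None, :] < 4, eye[:, np.minimum(codes, 3)], ones[:, None])
            self.leaf_partials[rec_id] = part
        # invariant-class compatibility: L_inv(pattern) = sum_s pi_s over
        # states s such that every non-missing base equals s
        self._compat = np.zeros((4, P), dtype=bool)
        for s in range(4):
            self._compat[s] = np.all((patterns == s) | (patterns == 4), axis=0)

    def invariant_likelihood(self, pi: np.ndarray) -> np.ndarray:
        return pi @ self._compat


def _check_labels(aln_ids: list[str], tree: Tree) -> None:
    leaf = tree.leaf_labels()
    missing = sorted(set(aln_ids) - set(leaf))
    extra = sorted(set(leaf) - set(aln_ids))
    if missing or extra:
        raise ValueError(
            "tree leaves and alignment ids must match; "
            f"missing from tree: {missing}; extra in tree: {extra}"
        )
    if len(leaf) != len(set(leaf)):
        raise ValueError("duplicate leaf labels in tree")


def _pruning_site_likelihoods(
    tree: Tree,
    model: SubstModelParams,
    data: _PatternData,
    eig: Optional[_Eigen] = None,
) -> np.ndarray:
    if eig is None:
        eig = _Eigen(model)
    rates, p_inv = model.category_rates()
    K = len(rates)
    P = data.patterns.shape[1]
    partial: dict[int, np.ndarray] = {}  # node -> (K, 4, P)
    for node in tree.postorder():
        if node.is_leaf:
            leaf = data.leaf_partials[node.label]
            partial[id(node)] = np.broadcast_to(leaf, (K, 4, P))
        else:
            part = None
            for child in node.children:
                Pk = eig.pmats(child.length, rates)
                term = Pk @ partial.pop(id(child))
                part = term if part is None else part * term
            partial[id(node)] = part
    root_part = partial[id(tree.root)]
    mix = np.einsum("j,kjp->p", model.pi, root_part) / K
    if p_inv > 0:
        mix = p_inv * data.invariant_likelihood(model.pi) + (1.0 - p_inv) * mix
    return mix


def tree_log_likelihood(
    aln: Alignment, tree: Tree, model: SubstModelParams
) -> float:
    """Log-likelihood of the alignment on the tree under GTR(+Γ)(+I).

    The value is invariant to root placement and to leaf ordering.
    Missing data (`N`, `-`) contribute a partial likelihood of 1 for all
    four states.
    """
    _check_labels(aln.ids(), tree)
    data = _PatternData(aln)
    return _lnL_from_data(tree, model, data)


def _lnL_from_data(
    tree: Tree,
    model: SubstModelParams,
    data: _PatternData,
    eig: Optional[_Eigen] = None,
) -> float:
    site = _pruning_site_likelihoods(tree, model, data, eig)
    if np.any(site <= 0.0) or not np.all(np.isfinite(site)):
        return -math.inf
    return float(np.dot(data.weights, np.log(site)))


# --------------------------------------------------------------------------
# parameter optimisation
# --------------------------------------------------------------------------

_BL_BOUNDS = (1e-9, 10.0)
_ALPHA_BOUNDS = (math.log(0.02), math.log(1e6))
_PINV_BOUNDS = (0.0, 0.9)
_EXCH_BOUNDS = (math.log(1e-3), math.log(1e3))


def _edge_partials(
    tree: Tree, model: SubstModelParams, data: _PatternData, eig: _Eigen
):
    """Inside ('down') and outside ('up') partial likelihoods per node.

    ``down[v]`` is the partial likelihood of the subtree below v before
    crossing v's parent edge; ``up[v]`` carries π and the contribution
    of the entire tree outside v's subtree, indexed by the state at v's
    parent.  Together they let the likelihood be re-evaluated after a
    change to one branch length at the cost of a single edge.
    """
    rates, _ = model.category_rates()
    K = len(rates)
    P = data.patterns.shape[1]
    down: dict[int, np.ndarray] = {}
    terms: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            down[id(node)] = np.broadcast_to(
                data.leaf_partials[node.label], (K, 4, P)
            )
        else:
            part = None
            for child in node.children:
                Pk = eig.pmats(child.length, rates)
                t = Pk @ down[id(child)]
                terms[id(child)] = t
                part = t if part is None else part * t
            down[id(node)] = part
    # outside[v]: contribution of everything except v's subtree, indexed by
    # the state at v's *parent* end (π included).  The descent applies the
    # sibling terms at each node and the edge's transition when crossing it.
    at_node: dict[int, np.ndarray] = {
        id(tree.root): np.broadcast_to(model.pi[None, :, None], (K, 4, P))
    }
    outside: dict[int, np.ndarray] = {}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        base = at_node[id(node)]
        for child in node.children:
            out = base
            for sib in node.children:
                if sib is child:
                    continue
                out = out * terms[id(sib)]
            outside[id(child)] = out
            if child.children:
                Pk = eig.pmats(child.length, rates)
                at_node[id(child)] = np.swapaxes(Pk, 1, 2) @ out
    return down, outside


def _branch_sweep(
    tree: Tree, model: SubstModelParams, data: _PatternData, eig: _Eigen
) -> float:
    """One coordinate-ascent pass over all branch lengths."""
    rates, p_inv = model.category_rates()
    K = len(rates)
    Linv = data.invariant_likelihood(model.pi) if p_inv > 0 else None
    w = data.weights
    for edge in tree.edges():
        down, up = _edge_partials(tree, model, data, eig)
        dv = down[id(edge)]
        uv = up[id(edge)]

        def f_bl(t):
            Pk = eig.pmats(t, rates)
            site = np.einsum("kip,kip->p", uv, Pk @ dv) / K
            if p_inv > 0:
                site = p_inv * Linv + (1.0 - p_inv) * site
            if np.any(site <= 0.0) or not np.all(np.isfinite(site)):
                return math.inf
            return -float(np.dot(w, np.log(site)))

        x, _ = _line_search(f_bl, *_BL_BOUNDS, x0=edge.length)
        edge.length = x
    return _lnL_from_data(tree, model, data, eig)


def empirical_frequencies(aln: Alignment) -> np.ndarray:
    """Observed A,C,G,T frequencies with a +1 pseudocount."""
    M = aln.to_matrix()
    counts = np.array([(M == s).sum() for s in range(4)], dtype=float) + 1.0
    return counts / counts.sum()


def _initial_params(aln: Alignment, spec: ModelSpec) -> SubstModelParams:
    if spec.base == "JC":
        pi = np.full(4, 0.25)
        exch = np.ones(6)
    else:
        pi = empirical_frequencies(aln)
        exch = np.ones(6)
        if spec.base == "HKY":
            exch = _hky_exch(2.0)
    return SubstModelParams(
        exchangeabilities=exch,
        pi=pi,
        alpha=0.5 if spec.gamma else None,
        p_inv=0.1 if spec.invariant else None,
        K=spec.K,
    )


def _hky_exch(kappa: float) -> np.ndarray:
    # transitions: AG and CT
    return np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])


def _line_search(fun, lo: float, hi: float, x0: float) -> tuple[float, float]:
    res = minimize_scalar(
        fun, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6, "maxiter": 40}
    )
    f0 = fun(x0)
    if res.fun < f0:
        return float(res.x), float(res.fun)
    return float(x0), float(f0)


def optimize_parameters(
    aln: Alignment,
    tree: Tree,
    spec: ModelSpec | str,
    *,
    max_rounds: int = 20,
    tol: float = 1e-4,
    init_params: Optional[SubstModelParams] = None,
) -> LikelihoodResult:
    """Fit branch lengths and free model parameters by coordinate ascent.

    Each round sweeps bounded Brent line searches over, in fixed order:
    every branch length, then α (if +Γ), then p_inv (if +I), then the
    exchangeabilities (κ for HKY; five free rates for GTR, GT fixed at
    1).  Rounds repeat until the log-likelihood improves by less than
    ``tol``.  The returned tree is a copy carrying optimised branch
    lengths; the input tree is not modified.

    ``init_params`` warm-starts the search, e.g. from the fit of a
    nested model: parameters the richer model adds start at values that
    make it coincide with the nested fit (α at its degenerate upper
    range, p_inv at 0), so the fitted lnL can only move up from there.
    """
    if isinstance(spec, str):
        spec = parse_model_spec(spec)
    _check_labels(aln.ids(), tree)
    data = _PatternData(aln)
    work = tree.copy()
    model = _initial_params(aln, spec)
    if init_params is not None:
        model.exchangeabilities = init_params.exchangeabilities.copy()
        model.pi = init_params.pi.copy()
        if spec.gamma:
            model.alpha = (
                init_params.alpha if init_params.alpha is not None else 1e6
            )
        if spec.invariant:
            model.p_inv = (
                init_params.p_inv if init_params.p_inv is not None else 0.0
            )

    def lnL() -> float:
        return _lnL_from_data(work, model, data)

    cur = lnL()
    if not np.isfinite(cur):
        # pathological start (e.g. huge branch lengths): shrink and retry
        for e in work.edges():
            e.length = min(e.length, 1.0)
        cur = lnL()
    if not np.isfinite(cur):
        raise OptimizationError(f"non-finite initial lnL for {spec.name}")

    for _ in range(max_rounds):
        start = cur

        eig = _Eigen(model)  # model fixed during the branch sweep
        cur = _branch_sweep(work, model, data, eig)

        if spec.gamma:
            def f_alpha(la):
                model.alpha = math.exp(la)
                return -_lnL_from_data(work, model, data)

            x, fx = _line_search(f_alpha, *_ALPHA_BOUNDS, x0=math.log(model.alpha))
            model.alpha = math.exp(x)
            cur = -fx

        if spec.invariant:
            def f_pinv(p):
                model.p_inv = p
                return -_lnL_from_data(work, model, data)

            x, fx = _line_search(f_pinv, *_PINV_BOUNDS, x0=model.p_inv)
            model.p_inv = x
            cur = -fx

        if spec.base == "HKY":
            def f_kappa(lk):
                model.exchangeabilities = _hky_exch(math.exp(lk))
                return -_lnL_from_data(work, model, data)

            kappa0 = model.exchangeabilities[1]
            x, fx = _line_search(f_kappa, *_EXCH_BOUNDS, x0=math.log(kappa0))
            model.exchangeabilities = _hky_exch(math.exp(x))
            cur = -fx
        elif spec.base == "GTR":
            for idx in range(5):  # GT (index 5) fixed at 1
                def f_exch(lx, _idx=idx):
                    model.exchangeabilities[_idx] = math.exp(lx)
                    return -_lnL_from_data(work, model, data)

                x, fx = _line_search(
                    f_exch, *_EXCH_BOUNDS, x0=math.log(model.exchangeabilities[idx])
                )
                model.exchangeabilities[idx] = math.exp(x)
                cur = -fx

        if not np.isfinite(cur):
            raise OptimizationError(
                f"non-finite lnL during optimisation of {spec.name}: {model}"
            )
        if cur - start < tol:
            break

    return LikelihoodResult(
        lnL=cur,
        params=model,
        tree=work,
        n_free_params=spec.n_free_params(),
        spec=spec,
    )
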