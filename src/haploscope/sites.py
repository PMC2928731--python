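"""Per-site evolution on a fixed topology and haplotype bookkeeping.

Fitch parsimony gives the minimum number of mutational steps each
aligned site requires on the inferred genealogy; sites are then mapped
to codons to flag (possibly recurrent) amino-acid-changing mutations.
Synonymous differences against a dated reference isolate bound the
mutation rate as s_syn / (length × years).  Distinct haplotypes are
counted either by exact sequence identity or with a missing-tolerant
single-linkage rule.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .io import BASES, Alignment, SequenceRecord
from .trees import Tree

logger = logging.getLogger(__name__)

# state bitmasks: A=1, C=2, G=4, T=8; N/- = all four
_FULL_MASK = 15


@dataclasses.dataclass
class SiteStepProfile:
    """Per-site minimum mutational steps with codon annotation."""

    min_steps: np.ndarray  # (L,) int
    codon_index: Optional[np.ndarray] = None  # (L,) int, -1 where no codon
    codon_position: Optional[np.ndarray] = None  # (L,) int in {1,2,3}, -1 n/a
    aa_change_flag: Optional[np.ndarray] = None  # (L,) bool

    def __len__(self) -> int:
        return len(self.min_steps)


@dataclasses.dataclass
class FlaggedSite:
    site: int  # 0-based alignment column
    position: int  # 1-based
    codon_index: int
    codon_position: int  # 1..3
    amino_acids: tuple
    recurrent: bool


@dataclasses.dataclass
class RateEstimate:
    s_syn: int
    length: int
    years: float
    rate: float


@dataclasses.dataclass
class SynCounts:
    syn: int
    nonsyn: int
    ambiguous: int

    def astuple(self) -> tuple:
        return (self.syn, self.nonsyn, self.ambiguous)


@dataclasses.dataclass
class HaplotypeGroups:
    groups: list
    n_distinct: int
    n_policy: str


def _leaf_masks(aln: Alignment) -> dict:
    masks = {}
    lut = np.full(256, _FULL_MASK, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = 1 << i
    for rec in aln:
        masks[rec.id] = lut[np.frombuffer(rec.bases.encode(), dtype=np.uint8)]
    return masks


def fitch_site_steps(aln: Alignment, tree: Tree) -> SiteStepProfile:
    """Minimum mutational steps per site on the tree (Fitch parsimony).

    Missing bases (`N`, `-`) carry the full state set.  Multifurcations
    (the trifurcating root of an unrooted tree) are resolved by pairwise
    folding, which preserves the parsimony score of the underlying
    unrooted binary topology.  Constant columns score 0.
    """
    leaf_labels = set(tree.leaf_labels())
    aln_ids = set(aln.ids())
    if leaf_labels != aln_ids:
        raise ValueError(
            "tree/alignment label mismatch; only in tree: "
            f"{sorted(leaf_labels - aln_ids)}; only in alignment: "
            f"{sorted(aln_ids - leaf_labels)}"
        )
    masks = _leaf_masks(aln)
    steps = np.zeros(aln.length, dtype=int)
    state: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            state[id(node)] = masks[node.label]
            continue
        children = [state.pop(id(c)) for c in node.children]
        acc = children[0]
        for child in children[1:]:
            inter = acc & child
            union = acc | child
            empty = inter == 0
            steps += empty
            acc = np.where(empty, union, inter)
        state[id(node)] = acc
    return SiteStepProfile(min_steps=steps)


def consensus_bases(aln: Alignment) -> str:
    """Column-wise majority base over A,C,G,T (ties broken alphabetically).

    Columns with no unambiguous base yield 'N'.
    """
    M = aln.to_matrix()
    out = []
    for j in range(aln.length):
        col = M[:, j]
        counts = [(int((col == s).sum()), BASES[s]) for s in range(4)]
        best = max(counts, key=lambda c: (c[0], -ord(c[1])))
        out.append(best[1] if best[0] > 0 else "N")
    return "".join(out)


def _translate(codon: str) -> Optional[str]:
    if any(b not in BASES for b in codon):
        return None
    return str(Seq(codon).translate())


def classify_recurrent_aa_changes(
    profile: SiteStepProfile, aln: Alignment, frame: int = 0
) -> list[FlaggedSite]:
    """Flag variable sites whose observed bases change the amino acid.

    A site is flagged iff it has min_steps ≥ 1 and at least one pair of
    observed bases yields different amino acids when substituted into
    the column-consensus codon; a flagged site with min_steps ≥ 2 is a
    recurrent amino-acid change.  Sites outside a complete codon of the
    chosen reading frame are skipped.  The profile's codon annotation
    arrays are filled in place.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if aln.length < 3:
        raise ValueError("alignment shorter than one codon")
    L = aln.length
    cons = consensus_bases(aln)
    codon_index = np.full(L, -1, dtype=int)
    codon_position = np.full(L, -1, dtype=int)
    aa_flag = np.zeros(L, dtype=bool)
    flagged: list[FlaggedSite] = []
    M = aln.to_matrix()
    for j in range(L):
        if j < frame or j >= frame + 3 * ((L - frame) // 3):
            continue
        ci = (j - frame) // 3
        cp = (j - frame) % 3
        codon_index[j] = ci
        codon_position[j] = cp + 1
        if profile.min_steps[j] < 1:
            continue
        start = frame + 3 * ci
        codon = list(cons[start : start + 3])
        context_ok = all(
            codon[k] in BASES for k in range(3) if k != cp
        )
        if not context_ok:
            logger.warning(
                "site %d: consensus codon context ambiguous; not flagged", j + 1
            )
            continue
        observed = sorted({BASES[s] for s in M[:, j] if s < 4})
        aa_pair = None
        for x, y in itertools.combinations(observed, 2):
            cx, cy = codon[:], codon[:]
            cx[cp], cy[cp] = x, y
            ax, ay = _translate("".join(cx)), _translate("".join(cy))
            if ax is None or ay is None:
                continue
            if "*" in (ax, ay):
                logger.warning(
                    "site %d: stop codon in consensus translation", j + 1
                )
            if ax != ay:
                aa_pair = (ax, ay)
                break
        if aa_pair is not None:
            aa_flag[j] = True
            flagged.append(
                FlaggedSite(
                    site=j,
                    position=j + 1,
                    codon_index=ci,
                    codon_position=cp + 1,
                    amino_acids=aa_pair,
                    recurrent=bool(profile.min_steps[j] >= 2),
                )
            )
    profile.codon_index = codon_index
    profile.codon_position = codon_position
    profile.aa_change_flag = aa_flag
    return flagged


def count_synonymous_diffs(
    a: SequenceRecord, b: SequenceRecord, frame: int = 0
) -> SynCounts:
    """Classify per-site differences between two sequences as synonymous,
    non-synonymous or ambiguous.

    Differences are counted only where both bases are unambiguous.  A
    codon containing exactly one difference, with both sequences
    agreeing on unambiguous context bases, is classified by substituting
    each variant into the shared codon; codons with two or more internal
    differences, or with missing context, contribute their differing
    sites to the ambiguous count.  Trailing bases beyond the last
    complete codon are excluded.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    L = len(a)
    n_codons = (L - frame) // 3
    end = frame + 3 * n_codons
    if end < L or frame > 0:
        logger.debug(
            "excluding %d leading / %d trailing bases outside complete codons",
            frame,
            L - end,
        )
    syn = nonsyn = ambiguous = 0
    for ci in range(n_codons):
        start = frame + 3 * ci
        ca = a.bases[start : start + 3]
        cb = b.bases[start : start + 3]
        diffs = [
            k
            for k in range(3)
            if ca[k] in BASES and cb[k] in BASES and ca[k] != cb[k]
        ]
        if not diffs:
            continue
        if len(diffs) >= 2:
            ambiguous += len(diffs)
            continue
        k = diffs[0]
        context_ok = all(
            ca[m] == cb[m] and ca[m] in BASES for m in range(3) if m != k
        )
        if not context_ok:
            ambiguous += 1
            continue
        aa_a, aa_b = _translate(ca), _translate(cb)
        if aa_a is None or aa_b is None:
            ambiguous += 1
        elif aa_a == aa_b:
            syn += 1
        else:
            nonsyn += 1
    return SynCounts(syn=syn, nonsyn=nonsyn, ambiguous=ambiguous)


def mutation_rate(s_syn: int, length: int, years: float) -> RateEstimate:
    """Upper-bound mutation rate: variable synonymous sites per site-year."""
    if length <= 0:
        raise ValueError("length must be positive")
    if years <= 0:
        raise ValueError("years must be positive")
    if s_syn < 0:
        raise ValueError("s_syn must be >= 0")
    return RateEstimate(
        s_syn=s_syn,
        length=length,
        years=years,
        rate=s_syn / (length * years),
    )


def distinct_haplotypes(
    aln: Alignment, n_policy: str = "strict"
) -> HaplotypeGroups:
    """Group records into distinct haplotypes.

    ``strict`` groups by exact sequence identity.  ``missing-tolerant``
    single-links records that agree at every position where both carry a
    non-N base, which can chain groups through heavily-masked records.
    """
    if n_policy not in ("strict", "missing-tolerant"):
        raise ValueError(f"unknown policy {n_policy!r}")
    ids = aln.ids()
    n = len(ids)
    if n_policy == "strict":
        by_seq: dict[str, list[str]] = {}
        for rec in aln:
            by_seq.setdefault(rec.bases, []).append(rec.id)
        groups = sorted(by_seq.values(), key=lambda g: g[0])
    else:
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        seqs = [rec.bases for rec in aln]
        for i in range(n):
            for j in range(i + 1, n):
                if all(
                    x == y
                    for x, y in zip(seqs[i], seqs[j])
                    if x != "N" and y != "N"
                ):
                    parent[find(i)] = find(j)
        buckets: dict[int, list[str]] = {}
        for i in range(n):
            buckets.setdefault(find(i), []).append(ids[i])
        groups = sorted(buckets.values(), key=lambda g: g[0])
    return HaplotypeGroups(
        groups=groups, n_distinct=len(groups), n_policy=n_policy
    )


def _categorical_fitch(tree: Tree, leaf_cat: dict, n_cat: int) -> int:
    """Fitch parsimony score of one categorical character on the tree."""
    steps = 0
    state: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            state[id(node)] = 1 << leaf_cat[node.label]
            continue
        masks = [state.pop(id(c)) for c in node.children]
        acc = masks[0]
        for msk in masks[1:]:
            inter = acc & msk
            if inter == 0:
                steps += 1
                acc |= msk
            else:
                acc = inter
        state[id(node)] = acc
    return steps


def label_association_test(
    tree: Tree, labels: dict, n_perm: int = 999, seed: int = 0
) -> float:
    """Permutation test for clustering of a leaf label on the genealogy.

    The statistic is the Fitch parsimony score of the categorical label
    character; labels clustered on the tree need fewer changes than
    expected.  The null shuffles labels across leaves; the p-value is
    (1 + #{permuted ≤ observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    leaf_names = tree.leaf_labels()
    missing = [l for l in leaf_names if l not in labels]
    if missing:
        raise ValueError(f"labels missing for leaves: {missing}")
    cats = sorted({labels[l] for l in leaf_names})
    counts = {c: sum(1 for l in leaf_names if labels[l] == c) for c in cats}
    if len(cats) < 2 or min(counts.values()) < 2:
        raise ValueError(
            "need >= 2 categories with >= 2 members each; got "
            + ", ".join(f"{c}:{k}" for c, k in counts.items())
        )
    cat_idx = {c: i for i, c in enumerate(cats)}
    leaf_cat = {l: cat_idx[labels[l]] for l in leaf_names}
    observed = _categorical_fitch(tree, leaf_cat, len(cats))
    rng = np.random.default_rng(seed)
    values = np.array([leaf_cat[l] for l in leaf_names])
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        perm_cat = dict(zip(leaf_names, perm))
        if _categorical_fitch(tree, perm_cat, len(cats)) <= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)
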