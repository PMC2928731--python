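"""Haplotype phasing from double-peaked Sanger chromatogram signals.

A sample infected by two viral haplotypes at unequal abundance shows, at
every site where the haplotypes differ, two overlapping base peaks whose
relative heights mirror the abundance ratio — consistently on both
sequencing strands.  Sites with a strand-consistent secondary peak are
called heterozygous; the taller peak at every such site is assigned to a
high-abundance haplotype and the shorter peak to a low-abundance one.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .io import BASES, PeakTable, SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_MINOR_RATIO = 0.25
DEFAULT_MAX_MISSING = 0.18


class PhasingConflictError(ValueError):
    """Major base disagrees between strands at a heterozygous site."""


class UnphaseableError(ValueError):
    """Three or more overlapping peaks on both strands: >2 haplotypes."""


@dataclasses.dataclass
class HetSite:
    """A strand-consistent double-peak site (1-based position)."""

    position: int
    major_base: str
    minor_base: str
    major_frac_F: float
    major_frac_R: float


@dataclasses.dataclass
class PhasedHaplotypes:
    high: SequenceRecord
    low: SequenceRecord
    het_sites: list
    n_haplotypes: int


def call_het_sites(
    peaks: PeakTable, minor_ratio_min: float = DEFAULT_MINOR_RATIO
) -> list[HetSite]:
    """Call heterozygous sites from a two-strand peak table.

    A site is heterozygous iff on *both* strands the second-highest
    intensity is at least ``minor_ratio_min`` times the highest, and the
    identities of the top two bases agree between strands.  Positions
    covered by a single strand are skipped (logged), never called.

    Raises :class:`UnphaseableError` if a third peak also clears the
    threshold on both strands (more than two haplotypes).
    """
    if not (0 < minor_ratio_min < 1):
        raise ValueError("minor_ratio_min must be in (0, 1)")
    sites: list[HetSite] = []
    both = peaks.both_strands()
    for i, pos in enumerate(peaks.positions):
        if not both[i]:
            logger.warning(
                "position %d covered by one strand only; skipped", pos
            )
            continue
        order: dict[str, np.ndarray] = {}
        double: dict[str, bool] = {}
        triple: dict[str, bool] = {}
        for strand in "FR":
            inten = peaks.intensity[strand][i]
            idx = np.argsort(inten)[::-1]  # descending
            top = inten[idx[0]]
            if top <= 0:
                double[strand] = False
                triple[strand] = False
                order[strand] = idx
                continue
            double[strand] = inten[idx[1]] >= minor_ratio_min * top
            triple[strand] = inten[idx[2]] >= minor_ratio_min * top
            order[strand] = idx
        if triple.get("F") and triple.get("R"):
            raise UnphaseableError(
                f"position {pos}: three or more overlapping peaks on both "
                "strands; more than two haplotypes cannot be phased"
            )
        if not (double.get("F") and double.get("R")):
            continue
        top2_f = {int(order["F"][0]), int(order["F"][1])}
        top2_r = {int(order["R"][0]), int(order["R"][1])}
        if top2_f != top2_r:
            continue
        # Major/minor by strand-averaged intensity over the shared top pair.
        a, b = sorted(top2_f)
        avg = (peaks.intensity["F"][i] + peaks.intensity["R"][i]) / 2.0
        major_i, minor_i = (a, b) if avg[a] >= avg[b] else (b, a)
        fracs = {}
        for strand in "FR":
            inten = peaks.intensity[strand][i]
            pair_sum = inten[major_i] + inten[minor_i]
            fracs[strand] = float(inten[major_i] / pair_sum) if pair_sum else 0.5
        sites.append(
            HetSite(
                position=int(pos),
                major_base=BASES[major_i],
                minor_base=BASES[minor_i],
                major_frac_F=fracs["F"],
                major_frac_R=fracs["R"],
            )
        )
    sites.sort(key=lambda s: s.position)
    return sites


def consensus_sequence(peaks: PeakTable) -> str:
    """Per-position consensus base by maximum strand-summed intensity."""
    total = np.zeros((peaks.n_positions, 4))
    for strand in "FR":
        total += np.where(
            peaks.has_strand[strand][:, None], peaks.intensity[strand], 0.0
        )
    return "".join(BASES[j] for j in np.argmax(total, axis=1))


CONFLICT_MARGIN = 1.5


def phase_haplotypes(
    peaks: PeakTable,
    het_sites: list[HetSite],
    conflict_margin: float = CONFLICT_MARGIN,
) -> PhasedHaplotypes:
    """Split a peak table into a high- and a low-abundance haplotype.

    Non-heterozygous positions take the consensus base in both outputs.
    At each heterozygous site the strand-averaged major base goes to the
    high haplotype and the minor base to the low one.  If a strand
    *decisively* contradicts the site's major call — its own taller peak
    is the site's minor base by more than ``conflict_margin``-fold — a
    :class:`PhasingConflictError` names the position.  Sub-margin
    disagreements are treated as peak-height noise and resolved by the
    strand average.
    """
    cons = list(consensus_sequence(peaks))
    high, low = cons[:], cons[:]
    for site in het_sites:
        i = site.position - peaks.start
        mj, mn = BASES.index(site.major_base), BASES.index(site.minor_base)
        for strand in "FR":
            inten = peaks.intensity[strand][i]
            if inten[mn] > conflict_margin * inten[mj]:
                raise PhasingConflictError(
                    f"position {site.position}: major base differs between "
                    f"strands ({site.major_base} vs {site.minor_base})"
                )
        high[i] = site.major_base
        low[i] = site.minor_base
    n_hap = 2 if het_sites else 1
    if n_hap == 1:
        low = high[:]
    return PhasedHaplotypes(
        high=SequenceRecord(id="high", bases="".join(high)),
        low=SequenceRecord(id="low", bases="".join(low)),
        het_sites=list(het_sites),
        n_haplotypes=n_hap,
    )


def missing_fraction_ok(
    record: SequenceRecord, max_fraction: float = DEFAULT_MAX_MISSING
) -> bool:
    """True iff the record's N fraction is *strictly* below ``max_fraction``.

    The QC rule keeps sequences whose missing-base content stays under
    the threshold (default 18% of the sequence); a record sitting exactly
    at the threshold is rejected.
    """
    if len(record) == 0:
        raise ValueError("empty sequence record")
    return record.n_fraction() < max_fraction
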