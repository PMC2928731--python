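"""Readers and writers for the on-disk formats used by the pipeline.

Sequences travel as FASTA (via Biopython), trees as Newick (via
:mod:`haploscope.trees`), chromatogram peak signals as a small TSV
dialect with columns ``position, strand, A, C, G, T`` (1-based
contiguous positions, strand F or R), and sample metadata as TSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .trees import NewickParseError, Tree, parse_newick  # noqa: F401  (re-export)

ALPHABET = frozenset("ACGTN-")
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

PathLike = Union[str, Path]


class FastaParseError(ValueError):
    """Malformed FASTA content (illegal character, duplicate id, ...)."""


class AlignmentError(ValueError):
    """Records do not form a valid alignment (unequal lengths, empty)."""


class PeakTableFormatError(ValueError):
    """Peak-table TSV violates the required dialect."""


@dataclasses.dataclass
class SequenceRecord:
    """One aligned sequence with optional sample metadata.

    ``bases`` is an uppercase string over ``A C G T N -``; ``meta`` may
    carry host_species, origin, lab_duration and strand_coverage.
    """

    id: str
    bases: str
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaParseError("sequence record with empty id")
        self.bases = self.bases.upper()
        for pos, ch in enumerate(self.bases):
            if ch not in ALPHABET:
                raise FastaParseError(
                    f"record {self.id!r}: illegal character {ch!r} at position "
                    f"{pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def n_fraction(self) -> float:
        return self.bases.count("N") / len(self.bases)


class Alignment:
    """An ordered collection of equal-length :class:`SequenceRecord`."""

    def __init__(self, records: list[SequenceRecord]):
        if not records:
            raise AlignmentError("alignment requires at least one record")
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            detail = ", ".join(f"{r.id}={len(r)}" for r in records)
            raise AlignmentError(f"records have unequal lengths: {detail}")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FastaParseError(f"duplicate record ids: {dupes}")
        self.records = list(records)
        self.length = lengths.pop()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key: Union[int, str]) -> SequenceRecord:
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, j: int) -> str:
        """Aligned column ``j`` (0-based) as a string, one char per record."""
        return "".join(r.bases[j] for r in self.records)

    def to_matrix(self) -> np.ndarray:
        """Integer matrix (records x columns): A,C,G,T -> 0..3, N/- -> 4."""
        lut = np.full(256, 4, dtype=np.int8)
        for b, i in BASE_INDEX.items():
            lut[ord(b)] = i
        rows = [
            lut[np.frombuffer(r.bases.encode(), dtype=np.uint8)]
            for r in self.records
        ]
        return np.vstack(rows)

    def subset(self, keep_ids: list[str]) -> "Alignment":
        wanted = set(keep_ids)
        return Alignment([r for r in self.records if r.id in wanted])


def read_fasta(path: PathLike) -> Alignment:
    """Read an aligned FASTA file.

    Records keep file order; lowercase bases are uppercased; ``N`` and
    ``-`` are preserved.  Unequal record lengths raise
    :class:`AlignmentError`; an illegal character raises
    :class:`FastaParseError` naming the record and position.
    """
    records = [
        SequenceRecord(id=rec.id, bases=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    return Alignment(records)


def write_fasta(aln_or_records, path: PathLike) -> None:
    records = list(aln_or_records)
    bio = [
        _BioRecord(Seq(r.bases), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


@dataclasses.dataclass
class PeakTable:
    """Per-position, per-strand base intensities for one sample.

    ``intensity[strand]`` is an ``(n_positions, 4)`` array in A,C,G,T
    order; ``has_strand[strand]`` marks positions covered by that strand.
    Positions are contiguous and 1-based, starting at ``start``.
    """

    start: int
    intensity: dict  # strand -> (n, 4) float array
    has_strand: dict  # strand -> (n,) bool array

    @property
    def n_positions(self) -> int:
        return self.intensity["F"].shape[0]

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.n_positions)

    @property
    def single_stranded(self) -> bool:
        return not (self.has_strand["F"].any() and self.has_strand["R"].any())

    def both_strands(self) -> np.ndarray:
        return self.has_strand["F"] & self.has_strand["R"]


_PEAK_COLUMNS = ["position", "strand", "A", "C", "G", "T"]


def read_peak_table(path: PathLike) -> PeakTable:
    """Read a two-strand peak-intensity TSV into a :class:`PeakTable`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"expected {_PEAK_COLUMNS}"
        )
    bad_strand = set(df["strand"].unique()) - {"F", "R"}
    if bad_strand:
        raise PeakTableFormatError(
            f"{path}: strand values must be F or R, got {sorted(bad_strand)}"
        )
    inten = df[["A", "C", "G", "T"]].to_numpy(dtype=float)
    if np.isnan(inten).any() or (inten < 0).any():
        raise ValueError(f"{path}: peak intensities must be finite and >= 0")
    return build_peak_table(
        df["position"].to_numpy(dtype=int), df["strand"].to_numpy(), inten
    )


def build_peak_table(
    positions: np.ndarray, strands: np.ndarray, intensities: np.ndarray
) -> PeakTable:
    pos_unique = np.unique(positions)
    if pos_unique.size == 0:
        raise PeakTableFormatError("peak table is empty")
    start, stop = int(pos_unique[0]), int(pos_unique[-1])
    if pos_unique.size != stop - start + 1:
        raise PeakTableFormatError(
            "peak-table positions must be contiguous; "
            f"found {pos_unique.size} positions spanning {start}..{stop}"
        )
    n = stop - start + 1
    intensity = {s: np.zeros((n, 4)) for s in "FR"}
    has_strand = {s: np.zeros(n, dtype=bool) for s in "FR"}
    for pos, strand, row in zip(positions, strands, intensities):
        i = int(pos) - start
        intensity[strand][i] = row
        has_strand[strand][i] = True
    covered = has_strand["F"] | has_strand["R"]
    if not covered.all():
        gap = start + int(np.flatnonzero(~covered)[0])
        raise PeakTableFormatError(f"position {gap} has no strand coverage")
    return PeakTable(start=start, intensity=intensity, has_strand=has_strand)


def write_peak_table(table: PeakTable, path: PathLike) -> None:
    rows = []
    for i, pos in enumerate(table.positions):
        for strand in "FR":
            if table.has_strand[strand][i]:
                a, c, g, t = table.intensity[strand][i]
                rows.append((int(pos), strand, a, c, g, t))
    pd.DataFrame(rows, columns=_PEAK_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_metadata(path: PathLike) -> dict:
    """Sample metadata TSV (column ``id`` plus arbitrary fields) -> dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns:
        raise PeakTableFormatError(f"{path}: metadata TSV needs an 'id' column")
    out = {}
    for _, row in df.iterrows():
        rec = row.to_dict()
        out[rec.pop("id")] = rec
    return out


def attach_metadata(aln: Alignment, meta: dict) -> None:
    for rec in aln:
        if rec.id in meta:
            rec.meta.update(meta[rec.id])


def synthetic_figs1_peaks_path() -> Path:
    """Path to the bundled synthetic stand-in for the Fig-S1 electropherogram.

    The original figure is a rendered chromatogram; this TSV is a synthetic
    reconstruction with the same qualitative content: three strand-consistent
    double-peak positions whose high-haplotype bases are C, T, T and
    low-haplotype bases T, C, C.
    """
    return Path(__file__).parent / "data" / "synthetic_figS1_peaks.tsv"
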