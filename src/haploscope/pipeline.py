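"""End-to-end pipeline driver.

A single JSON-serialisable configuration drives the stage chain
simulate → phase → QC → tree → LRT → parsimony → PHI → rates →
haplotypes.  All randomness flows from one seed, split deterministically
per stage, so identical config + seed yields a byte-identical report
payload.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .inference import lrt, nj_tree, jc_distance_matrix, nni_search
from .io import Alignment, read_fasta, read_peak_table, write_fasta
from .model import optimize_parameters, parse_model_spec
from .phasing import call_het_sites, missing_fraction_ok, phase_haplotypes
from .recombination import phi_permutation_test
from .simulate import (
    SimParams,
    default_model,
    evolve_sequences,
    inject_missing,
    simulate_mixture_peaks,
    simulate_tree,
)
from .sites import (
    classify_recurrent_aa_changes,
    count_synonymous_diffs,
    distinct_haplotypes,
    fitch_site_steps,
    mutation_rate,
)

STAGES = (
    "phasing",
    "qc",
    "tree",
    "lrt",
    "parsimony",
    "phi",
    "rates",
    "haplotypes",
)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial = partial


@dataclasses.dataclass
class AnalysisConfig:
    """Pipeline configuration; every field has a JSON representation."""

    seed: int = 0
    # synthetic-data stage (used when no input FASTA is given)
    simulate: bool = True
    n_taxa: int = 16
    seq_length: int = 500
    sim_alpha: Optional[float] = 0.101
    sim_p_inv: Optional[float] = 0.3
    mixture_ratio: float = 0.7
    noise_sd: float = 0.02
    missing_fraction: float = 0.1
    mean_branch: float = 0.02
    # inputs (override simulation)
    fasta_path: Optional[str] = None
    peaks_path: Optional[str] = None
    # model and search
    model: str = "GTR+G+I"
    K: int = 8
    tree_search: str = "nni"  # or "nj" (no rearrangement search)
    lrt_null: str = "GTR+I"
    lrt_alt: str = "GTR+G+I"
    lrt_level: float = 0.05
    # thresholds
    minor_ratio_min: float = 0.25
    max_missing: float = 0.18
    phi_window: int = 100
    n_perm: int = 199
    frame: int = 0
    years: float = 11.0
    reference_id: Optional[str] = None
    # stage toggles
    enabled: dict = dataclasses.field(
        default_factory=lambda: {s: True for s in STAGES}
    )

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0 <= self.max_missing <= 1):
            raise ValueError("max_missing must be in [0, 1]")
        for s in self.enabled:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        self.enabled = {s: self.enabled.get(s, True) for s in STAGES}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        return cls.from_json(Path(path).read_text())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclasses.dataclass
class Report:
    sections: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {"sections": self.sections, "provenance": self.provenance},
            sort_keys=True,
            indent=2,
        )


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def run_pipeline(config: AnalysisConfig, report_path=None) -> Report:
    """Run all enabled stages and return the report.

    On stage failure a :class:`PipelineStageError` is raised carrying the
    stage name and the partial report assembled so far; if
    ``report_path`` is set, the partial report is written with a failure
    marker.
    """
    sections: dict = {}
    seeds = {s: stage_seed(config.seed, s) for s in ("sim",) + STAGES}
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "version": __version__,
    }

    def fail(stage: str, exc: Exception):
        report = Report(
            sections={**sections, "_failed_stage": stage}, provenance=provenance
        )
        if report_path is not None:
            Path(report_path).write_text(report.to_json())
        raise PipelineStageError(stage, exc, sections) from exc

    # ------------------------------------------------------------- inputs
    peaks = None
    if config.fasta_path:
        aln = read_fasta(config.fasta_path)
        if config.peaks_path:
            peaks = read_peak_table(config.peaks_path)
    elif config.simulate:
        model = default_model(config.sim_alpha, config.sim_p_inv, config.K)
        true_tree = simulate_tree(
            config.n_taxa, seeds["sim"], config.mean_branch
        )
        clean = evolve_sequences(
            true_tree, model, config.seq_length, seeds["sim"] + 1
        )
        # mixed-infection signal from the most dissimilar haplotype pair
        best_pair = max(
            (
                (i, j)
                for i in range(len(clean.records))
                for j in range(i + 1, len(clean.records))
            ),
            key=lambda ij: sum(
                a != b
                for a, b in zip(
                    clean.records[ij[0]].bases, clean.records[ij[1]].bases
                )
            ),
        )
        peaks = simulate_mixture_peaks(
            clean.records[best_pair[0]],
            clean.records[best_pair[1]],
            config.mixture_ratio,
            config.noise_sd,
            seeds["sim"] + 2,
        )
        aln = Alignment(
            [
                inject_missing(
                    rec, config.missing_fraction, seeds["sim"] + 3 + i, "ends"
                )
                for i, rec in enumerate(clean.records)
            ]
        )
    else:
        raise ValueError("no input FASTA and simulation disabled")

    # ------------------------------------------------------------ phasing
    if config.enabled["phasing"]:
        try:
            if peaks is None:
                sections["phasing"] = {"available": False}
            else:
                het = call_het_sites(peaks, config.minor_ratio_min)
                phased = phase_haplotypes(peaks, het)
                sections["phasing"] = {
                    "available": True,
                    "n_het_sites": len(het),
                    "het_positions": [s.position for s in het],
                    "high_bases": [s.major_base for s in het],
                    "low_bases": [s.minor_base for s in het],
                    "n_haplotypes": phased.n_haplotypes,
                }
        except Exception as exc:  # noqa: BLE001
            fail("phasing", exc)

    # ----------------------------------------------------------------- QC
    working = aln
    if config.enabled["qc"]:
        try:
            status = {
                rec.id: missing_fraction_ok(rec, config.max_missing)
                for rec in aln
            }
            kept = [rid for rid, ok in status.items() if ok]
            sections["qc"] = {
                "max_missing": config.max_missing,
                "n_input": len(aln.records),
                "n_passed": len(kept),
                "failed": sorted(r for r, ok in status.items() if not ok),
            }
            working = aln.subset(kept)
        except Exception as exc:  # noqa: BLE001
            fail("qc", exc)

    # --------------------------------------------------------------- tree
    ml = None
    if config.enabled["tree"]:
        try:
            if config.tree_search == "nni":
                ml = nni_search(working, config.model, seeds["tree"])
            else:
                topo = nj_tree(jc_distance_matrix(working))
                ml = optimize_parameters(
                    working, topo, parse_model_spec(config.model, K=config.K)
                )
            sections["tree"] = {
                "model": config.model,
                "lnL": ml.lnL,
                "alpha": ml.params.alpha,
                "p_inv": ml.params.p_inv,
                "newick": ml.tree.newick(),
            }
        except Exception as exc:  # noqa: BLE001
            fail("tree", exc)

    # ---------------------------------------------------------------- LRT
    if config.enabled["lrt"]:
        try:
            topo = ml.tree if ml is not None else nj_tree(
                jc_distance_matrix(working)
            )
            null_fit = optimize_parameters(
                working, topo, parse_model_spec(config.lrt_null, K=config.K)
            )
            alt_fit = optimize_parameters(
                working,
                null_fit.tree,
                parse_model_spec(config.lrt_alt, K=config.K),
                init_params=null_fit.params,
            )
            res = lrt(null_fit, alt_fit, config.lrt_level)
            sections["lrt"] = {
                "null": config.lrt_null,
                "alt": config.lrt_alt,
                "lnL_null": null_fit.lnL,
                "lnL_alt": alt_fit.lnL,
                "stat": res.stat,
                "df": res.df,
                "p_value": res.p_value,
                "critical_value": res.critical_value,
                "level": res.level,
                "reject": res.reject,
            }
        except Exception as exc:  # noqa: BLE001
            fail("lrt", exc)

    # ---------------------------------------------------------- parsimony
    if config.enabled["parsimony"]:
        try:
            topo = ml.tree if ml is not None else nj_tree(
                jc_distance_matrix(working)
            )
            profile = fitch_site_steps(working, topo)
            flagged = classify_recurrent_aa_changes(
                profile, working, config.frame
            )
            steps = profile.min_steps
            sections["parsimony"] = {
                "total_steps": int(steps.sum()),
                "max_steps": int(steps.max()),
                "n_variable_sites": int((steps > 0).sum()),
                "n_aa_change_sites": len(flagged),
                "n_recurrent_aa_changes": sum(f.recurrent for f in flagged),
                "steps_histogram": {
                    str(k): int((steps == k).sum())
                    for k in range(int(steps.max()) + 1)
                },
            }
        except Exception as exc:  # noqa: BLE001
            fail("parsimony", exc)

    # ---------------------------------------------------------------- PHI
    if config.enabled["phi"]:
        try:
            res = phi_permutation_test(
                working,
                window=config.phi_window,
                n_perm=config.n_perm,
                seed=seeds["phi"],
            )
            sections["phi"] = {
                "phi": res.phi,
                "p_value": res.p_value,
                "n_informative_sites": res.n_informative_sites,
                "n_informative_pairs": res.n_informative_pairs,
                "n_perm": res.n_perm,
                "untestable": res.untestable,
            }
        except Exception as exc:  # noqa: BLE001
            fail("phi", exc)

    # -------------------------------------------------------------- rates
    if config.enabled["rates"]:
        try:
            ref_id = config.reference_id or working.ids()[0]
            ref = working[ref_id]
            syn_counts = [
                count_synonymous_diffs(ref, rec, config.frame).syn
                for rec in working
                if rec.id != ref_id
            ]
            lo, hi = min(syn_counts), max(syn_counts)
            sections["rates"] = {
                "reference": ref_id,
                "years": config.years,
                "syn_min": lo,
                "syn_max": hi,
                "syn_mean": float(np.mean(syn_counts)),
                "rate_low": mutation_rate(lo, working.length, config.years).rate,
                "rate_high": mutation_rate(hi, working.length, config.years).rate,
            }
        except Exception as exc:  # noqa: BLE001
            fail("rates", exc)

    # --------------------------------------------------------- haplotypes
    if config.enabled["haplotypes"]:
        try:
            strict = distinct_haplotypes(working, "strict")
            tolerant = distinct_haplotypes(working, "missing-tolerant")
            sections["haplotypes"] = {
                "n_samples": len(working.records),
                "n_distinct_strict": strict.n_distinct,
                "n_distinct_missing_tolerant": tolerant.n_distinct,
                "groups_strict": strict.groups,
            }
        except Exception as exc:  # noqa: BLE001
            fail("haplotypes", exc)

    report = Report(sections=sections, provenance=provenance)
    if report_path is not None:
        Path(report_path).write_text(report.to_json())
    return report
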