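"""End-to-end identification: deconvolute, filter, rank, cross-validate.

Chains the stages the peptidogenomic identification runs by hand:
charge-envelope detection and neutral-mass deconvolution from the precursor
peak list, precursor mass filtering and MS/MS ranking of the candidate
translations, a coding-match search in supplied nucleotide sequence, and a
conservation summary across the candidates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .config import PipelineConfig
from .genomics import NucSeq, conservation, find_coding_matches
from .spectral import Spectrum, assign_charges, deconvolute
from .validation import CandidateSequence, rank_candidates

__all__ = ["IdentificationError", "run_identify", "report_markdown"]

logger = logging.getLogger("peptidogenomics")


class IdentificationError(RuntimeError):
    """No charge-state series could be detected in the precursor data."""


def run_identify(
    precursor: Spectrum,
    msms: Optional[Spectrum],
    candidates: Sequence[CandidateSequence],
    nucleotides: Optional[Sequence[NucSeq]] = None,
    config: Optional[PipelineConfig] = None,
) -> Dict:
    """Run the full identification chain; returns a JSON-serialisable report.

    The report carries the inferred neutral mass and its ppm spread, ranked
    candidate scores, genomic coding matches for the top passing candidate,
    and the pairwise conservation matrix over the candidate sequences.
    With an empty or absent MS/MS spectrum the ranking falls back to the
    precursor comparison alone and the report flags it.
    """
    cfg = config or PipelineConfig()
    if not candidates:
        raise ValueError("no candidate sequences supplied")
    logger.info(
        "identify: %d precursor peaks, %d candidates, tolerances %s/%s ppm",
        len(precursor), len(candidates),
        cfg.precursor_tol_ppm, cfg.fragment_tol_ppm,
    )
    observations = assign_charges(precursor)
    if not observations:
        raise IdentificationError(
            "no isotope envelope with an assignable charge state found "
            "in the precursor peak list"
        )
    series = deconvolute(observations)
    logger.info(
        "deconvolution: M=%.4f Da from charges %s (spread %.2f ppm)",
        series.inferred_neutral_mass, series.charges, series.ppm_spread,
    )
    msms_used = msms is not None and len(msms) > 0
    scores = rank_candidates(
        candidates,
        series.inferred_neutral_mass,
        msms if msms_used else None,
        precursor_tol_ppm=cfg.precursor_tol_ppm,
        fragment_tol_ppm=cfg.fragment_tol_ppm,
    )
    any_pass = any(s.passes_precursor for s in scores)
    top = scores[0]
    hits = []
    if nucleotides and any_pass:
        for nuc in nucleotides:
            for hit in find_coding_matches(
                top.sequence, nuc, max_exons=cfg.max_exons
            ):
                hits.append(
                    {
                        "seq_id": hit.seq_id,
                        "strand": hit.strand,
                        "exons": list(map(list, hit.exons)),
                        "frame": hit.frame,
                    }
                )
    cons = None
    unique_seqs = {c.id: c.sequence for c in candidates}
    if len(set(unique_seqs.values())) >= 2:
        report = conservation(unique_seqs)
        cons = {
            "identity_matrix": report.identity_matrix.round(2).to_dict(),
            "variant_columns": list(report.variant_columns),
        }
    return {
        "inferred_neutral_mass": series.inferred_neutral_mass,
        "ppm_spread": series.ppm_spread,
        "charge_states": list(series.charges),
        "observations": [list(o) for o in series.observations],
        "msms_used": msms_used,
        "ranking_basis": "precursor+msms" if msms_used else "precursor-only",
        "any_candidate_passes": any_pass,
        "top_candidate": None if not any_pass else top.candidate_id,
        "candidates": [asdict(s) for s in scores],
        "genomic_hits": hits,
        "conservation": cons,
        "config": asdict(cfg),
    }


def report_markdown(report: Dict) -> str:
    """Human-readable summary of a run_identify report."""
    lines = [
        "# Peptide identification report",
        "",
        f"Inferred neutral mass: **{report['inferred_neutral_mass']:.4f} Da** "
        f"(charge states {report['charge_states']}, "
        f"spread {report['ppm_spread']:.2f} ppm)",
        "",
        f"Ranking basis: {report['ranking_basis']}",
        "",
    ]
    if not report["any_candidate_passes"]:
        lines.append(
            "**No candidate sequence passes the precursor mass filter.**"
        )
    else:
        lines.append(f"Top candidate: **{report['top_candidate']}**")
    lines += ["", "| rank | id | ppm | pass | coverage | ions |",
              "|---|---|---|---|---|---|"]
    for c in report["candidates"]:
        lines.append(
            f"| {c['rank']} | {c['candidate_id']} | {c['precursor_ppm']:+.2f} "
            f"| {'yes' if c['passes_precursor'] else 'no'} "
            f"| {c['fragment_coverage']:.2f} | {c['matched_ion_count']} |"
        )
    if report["genomic_hits"]:
        lines += ["", "## Genomic coding matches", ""]
        for h in report["genomic_hits"]:
            lines.append(
                f"- {h['seq_id']} strand {h['strand']} exons {h['exons']}"
            )
    return "\n".join(lines) + "\n"


def write_report(report: Dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    (out_dir / "report.md").write_text(report_markdown(report))
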