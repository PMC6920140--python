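"""Candidate-sequence discrimination against observed precursor and MS/MS data.

The peptidogenomic cross-check: each candidate translation of the hepcidin
gene is scored against the measured neutral mass (disulfide-corrected
monoisotopic mass, signed ppm error) and against the product-ion spectrum
(b/y bond coverage and matched-ion count), then ranked.  A database
translation that is off by one residue substitution fails the precursor
filter by tens of Da — the discrimination that exposed the misreported
canine hepcidin sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .chem import (
    DEFAULT_TABLE,
    AminoAcidTable,
    Peptide,
    composition_of,
    monoisotopic_mass,
)
from .fragments import annotate
from .spectral import Spectrum

__all__ = [
    "CandidateSequence",
    "CandidateScore",
    "candidate_peptide",
    "precursor_filter",
    "rank_candidates",
]

PROVENANCES = ("mRNA", "DNA", "peptide", "recombinant")


@dataclass(frozen=True)
class CandidateSequence:
    """One reported translation of the peptide, e.g. a Table-of-accessions row."""

    id: str
    sequence: str
    provenance: str = "peptide"


@dataclass(frozen=True)
class CandidateScore:
    candidate_id: str
    sequence: str
    precursor_ppm: float
    passes_precursor: bool
    fragment_coverage: float
    matched_ion_count: int
    rank: int = 0


def candidate_peptide(
    candidate: CandidateSequence, max_disulfides: int = 4
) -> Peptide:
    """Build a Peptide from a candidate row.

    Disulfide count is ``max_disulfides`` when the sequence has enough
    cysteines, otherwise floor(n_cys / 2) — malformed database entries are
    scored rather than rejected.
    """
    n_cys = candidate.sequence.count("C")
    return Peptide(
        sequence=candidate.sequence,
        n_disulfides=min(max_disulfides, n_cys // 2),
    )


def precursor_filter(
    candidates: Sequence[CandidateSequence],
    observed_mass: float,
    tol_ppm: float = 20.0,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> List[CandidateScore]:
    """Signed ppm error of each candidate's theoretical mass vs observed."""
    if observed_mass <= 0:
        raise ValueError("observed mass must be positive")
    scores = []
    for cand in candidates:
        mass = monoisotopic_mass(
            composition_of(candidate_peptide(cand), table), table
        )
        ppm = (observed_mass - mass) / mass * 1e6
        scores.append(
            CandidateScore(
                candidate_id=cand.id,
                sequence=cand.sequence,
                precursor_ppm=ppm,
                passes_precursor=abs(ppm) <= tol_ppm,
                fragment_coverage=0.0,
                matched_ion_count=0,
            )
        )
    return scores


def rank_candidates(
    candidates: Sequence[CandidateSequence],
    observed_mass: float,
    msms: Optional[Spectrum] = None,
    precursor_tol_ppm: float = 20.0,
    fragment_tol_ppm: float = 10.0,
    cys_correction: bool = True,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> List[CandidateScore]:
    """Rank candidates by precursor pass, then MS/MS support, then ppm.

    Sort key: passes_precursor desc, fragment_coverage desc,
    matched_ion_count desc, \\|precursor_ppm\\| asc, id asc (deterministic
    tie-break).  With no MS/MS spectrum the fragment fields stay zero and
    the ordering reduces to the precursor comparison.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    scores = precursor_filter(candidates, observed_mass, precursor_tol_ppm, table)
    if msms is not None and len(msms) > 0:
        enriched = []
        for cand, score in zip(candidates, scores):
            ann = annotate(
                msms,
                candidate_peptide(cand),
                tol_ppm=fragment_tol_ppm,
                cys_correction=cys_correction,
                table=table,
            )
            enriched.append(
                CandidateScore(
                    candidate_id=score.candidate_id,
                    sequence=score.sequence,
                    precursor_ppm=score.precursor_ppm,
                    passes_precursor=score.passes_precursor,
                    fragment_coverage=ann.coverage,
                    matched_ion_count=ann.matched_ion_count,
                )
            )
        scores = enriched
    scores.sort(
        key=lambda s: (
            not s.passes_precursor,
            -s.fragment_coverage,
            -s.matched_ion_count,
            abs(s.precursor_ppm),
            s.candidate_id,
        )
    )
    return [
        CandidateScore(
            candidate_id=s.candidate_id,
            sequence=s.sequence,
            precursor_ppm=s.precursor_ppm,
            passes_precursor=s.passes_precursor,
            fragment_coverage=s.fragment_coverage,
            matched_ion_count=s.matched_ion_count,
            rank=i + 1,
        )
        for i, s in enumerate(scores)
    ]
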