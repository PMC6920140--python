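"""Nucleotide <-> peptide cross-validation and ortholog conservation.

Frame translation, degenerate reverse translation, exon-split coding-match
search, and pairwise conservation analysis.  Coordinates follow the BED
convention: 0-based half-open intervals on the forward strand; minus-strand
hits are reported in forward coordinates with a strand flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

__all__ = [
    "NucSeq",
    "GenomicHit",
    "ConservationReport",
    "translate",
    "reverse_translate_pattern",
    "find_coding_matches",
    "conservation",
]

_NUC_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class NucSeq:
    """An uppercase A/C/G/T/N nucleotide sequence with an identifier."""

    id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("empty nucleotide sequence")
        bad = set(seq) - _NUC_ALPHABET
        if bad:
            raise ValueError(f"invalid nucleotide characters {sorted(bad)!r}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicHit:
    """A peptide-coding match: one or more in-order exons on one strand.

    ``exons`` are 0-based half-open intervals in forward-strand coordinates,
    listed in coding order (so descending along the chromosome for minus-
    strand hits).  ``frame`` is the frame of the first coding base on the
    coding strand.
    """

    seq_id: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    frame: int
    translated: str

    @property
    def interval(self) -> Tuple[int, int]:
        """Genomic span (min start, max end) across all exons."""
        return (
            min(s for s, _ in self.exons),
            max(e for _, e in self.exons),
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class ConservationReport:
    """Pairwise % identity matrix and the columns where orthologs differ."""

    sequences: Dict[str, str]
    identity_matrix: pd.DataFrame
    variant_columns: Tuple[int, ...]  # 1-based; only for equal-length input


_CODON_TABLE = unambiguous_dna_by_id[1]  # standard nuclear code


def translate(nuc: NucSeq, frame: int = 0, strand: str = "+") -> str:
    """Translate one frame of one strand with the standard codon table.

    The trailing partial codon is dropped; stop codons render as '*'; any
    codon containing N that is not resolvable renders as 'X'.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = Seq(nuc.sequence)
    if strand == "-":
        seq = seq.reverse_complement()
    sub = seq[frame:]
    sub = sub[: 3 * (len(sub) // 3)]
    if len(sub) == 0:
        return ""
    return str(sub.translate(table=1))


@lru_cache(maxsize=None)
def _codons_for(residue: str) -> Tuple[str, ...]:
    codons = tuple(
        sorted(
            codon
            for codon, aa in _CODON_TABLE.forward_table.items()
            if aa == residue
        )
    )
    if not codons:
        raise ValueError(f"no codon encodes residue {residue!r}")
    return codons


def reverse_translate_pattern(peptide: str) -> str:
    """Regex matching exactly the DNA sequences that encode ``peptide``.

    Each residue becomes an alternation over its codons (collapsed to a
    character class at the degenerate third base where possible).  The
    pattern is unanchored; wrap in ``^...$`` for a full-string match.
    """
    if not peptide:
        raise ValueError("empty peptide")
    parts = []
    for aa in peptide:
        codons = _codons_for(aa)
        if len(codons) == 1:
            parts.append(codons[0])
            continue
        prefixes = {c[:2] for c in codons}
        if len(prefixes) == 1:
            thirds = "".join(sorted(c[2] for c in codons))
            parts.append(f"{codons[0][:2]}[{thirds}]")
        else:
            parts.append("(?:" + "|".join(codons) + ")")
    return "".join(parts)


def _find_occurrences(pattern: str, text: str) -> List[int]:
    """All (possibly overlapping) match start positions of a regex."""
    rx = re.compile(f"(?=({pattern}))")
    return [m.start() for m in rx.finditer(text)]


def _chain_segments(
    peptide: str,
    text: str,
    max_exons: int,
    min_exon_codons: int,
    max_gap: int,
    occ_cache: Dict[Tuple[int, int], List[int]],
) -> List[List[Tuple[int, int, int, int]]]:
    """Find in-order chains of coding segments covering the whole peptide.

    Returns lists of (pep_start, pep_end, text_start, text_end) segments.
    Search is over codon-aligned splits of the peptide with each segment at
    least ``min_exon_codons`` residues, consecutive segments separated in the
    text by at most ``max_gap`` bases.
    """
    n = len(peptide)

    def occurrences(i: int, j: int) -> List[int]:
        key = (i, j)
        if key not in occ_cache:
            occ_cache[key] = _find_occurrences(
                reverse_translate_pattern(peptide[i:j]), text
            )
        return occ_cache[key]

    results: List[List[Tuple[int, int, int, int]]] = []

    def extend(pep_pos: int, text_pos: int, exons_left: int,
               chain: List[Tuple[int, int, int, int]]) -> None:
        remaining = n - pep_pos
        if exons_left == 1:
            ends = [remaining] if remaining >= min_exon_codons else []
        else:
            ends = [
                L for L in range(min_exon_codons, remaining - min_exon_codons + 1)
            ] + ([remaining] if remaining >= min_exon_codons else [])
        for seg_len in ends:
            i, j = pep_pos, pep_pos + seg_len
            for start in occurrences(i, j):
                if chain and not (
                    text_pos <= start <= text_pos + max_gap
                ):
                    continue
                seg = (i, j, start, start + 3 * seg_len)
                if j == n:
                    results.append(chain + [seg])
                elif exons_left > 1:
                    extend(j, start + 3 * seg_len, exons_left - 1,
                           chain + [seg])

    extend(0, 0, max_exons, [])
    return results


def find_coding_matches(
    peptide: str,
    nuc: NucSeq,
    max_exons: int = 3,
    min_exon_codons: int = 4,
    max_gap: int = 50_000,
) -> List[GenomicHit]:
    """Find where a peptide is encoded in a nucleotide sequence.

    Scans both strands for contiguous coding matches; with ``max_exons`` > 1
    the peptide may be split across up to that many in-order, non-overlapping,
    codon-aligned segments separated by at most ``max_gap`` bases (a simple
    chained search, not a spliced aligner).  Hits on the minus strand are
    reported in forward coordinates with exons in coding order.
    """
    if len(peptide) < 4:
        raise ValueError("peptide query must be at least 4 residues")
    L = len(nuc)
    hits: List[GenomicHit] = []
    seen = set()
    for strand in ("+", "-"):
        text = (
            nuc.sequence
            if strand == "+"
            else str(Seq(nuc.sequence).reverse_complement())
        )
        occ_cache: Dict[Tuple[int, int], List[int]] = {}
        chains = _chain_segments(
            peptide, text, max_exons, min_exon_codons, max_gap, occ_cache
        )
        for chain in chains:
            if strand == "+":
                exons = tuple((s, e) for _, _, s, e in chain)
                frame = chain[0][2] % 3
            else:
                exons = tuple((L - e, L - s) for _, _, s, e in chain)
                frame = chain[0][2] % 3
            key = (strand, exons)
            if key in seen:
                continue
            seen.add(key)
            hits.append(
                GenomicHit(
                    seq_id=nuc.id,
                    strand=strand,
                    exons=exons,
                    frame=frame,
                    translated=peptide,
                )
            )
    hits.sort(key=lambda h: (h.interval, h.strand, h.n_exons))
    return hits


def _identity_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def _pair_identity(a: str, b: str) -> float:
    """% identity over alignment columns (direct columns if equal length)."""
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a, b))
        return matches / len(a) * 100.0
    aln = _identity_aligner().align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return matches / len(sa) * 100.0


def conservation(sequences: Dict[str, str]) -> ConservationReport:
    """Pairwise identity matrix and variant columns for a set of orthologs.

    Sequences of equal length are compared column-by-column; a global
    alignment (match 1 / mismatch 0 / gap -1) handles length differences.
    ``variant_columns`` (1-based) are reported only when all sequences have
    equal length.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    ids = list(sequences)
    n = len(ids)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = _pair_identity(sequences[ids[i]], sequences[ids[j]])
            mat[i, j] = mat[j, i] = ident
    lengths = {len(s) for s in sequences.values()}
    variant: Tuple[int, ...] = ()
    if len(lengths) == 1:
        cols = []
        seqs = list(sequences.values())
        for pos in range(lengths.pop()):
            if len({s[pos] for s in seqs}) > 1:
                cols.append(pos + 1)
        variant = tuple(cols)
    return ConservationReport(
        sequences=dict(sequences),
        identity_matrix=pd.DataFrame(mat, index=ids, columns=ids),
        variant_columns=variant,
    )
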