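"""Readers and writers for the formats the workflow exchanges.

MGF peak lists (via pyteomics), two-column m/z,intensity CSV, FASTA
(via Biopython), candidate tables as CSV, BED-like hit TSV, and long-format
feature tables.  All text is UTF-8 with '.' as the decimal separator.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyteomics import mgf as _mgf

from .genomics import GenomicHit, NucSeq
from .spectral import IsotopePattern, Spectrum
from .validation import CandidateSequence

__all__ = [
    "read_mgf",
    "write_mgf",
    "read_peaks_csv",
    "write_peaks_csv",
    "read_candidates",
    "read_nucleotide_fasta",
    "read_peptide_fasta",
    "write_pattern_csv",
    "write_hits_tsv",
    "write_conservation_csv",
    "read_feature_table",
    "write_feature_table",
]

PathLike = Union[str, Path]


class InputFormatError(ValueError):
    """Raised when an input file cannot be parsed; names file and location."""


def read_mgf(path: PathLike) -> List[Spectrum]:
    """Read all BEGIN IONS/END IONS blocks from an MGF peak list."""
    spectra = []
    try:
        with _mgf.read(str(path)) as reader:
            for entry in reader:
                params = entry.get("params", {})
                rt = params.get("rtinseconds")
                spectra.append(
                    Spectrum(
                        peaks=tuple(
                            zip(entry["m/z array"], entry["intensity array"])
                        ),
                        source=params.get("title", str(path)),
                        retention_time=float(rt) / 60.0 if rt else None,
                    )
                )
    except Exception as exc:  # pyteomics raises various parse errors
        raise InputFormatError(f"{path}: cannot parse MGF ({exc})") from exc
    return spectra


def write_mgf(path: PathLike, spectra: Sequence[Spectrum]) -> None:
    entries = []
    for i, spec in enumerate(spectra):
        params = {"title": spec.source or f"spectrum_{i}"}
        if spec.retention_time is not None:
            params["rtinseconds"] = spec.retention_time * 60.0
        entries.append(
            {
                "m/z array": np.array(spec.mz),
                "intensity array": np.array(spec.intensity),
                "params": params,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_peaks_csv(path: PathLike) -> Spectrum:
    """Two-column CSV of m/z,intensity (header optional)."""
    peaks = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or not row[0].strip():
                continue
            try:
                peaks.append((float(row[0]), float(row[1])))
            except (ValueError, IndexError):
                if lineno == 1:  # header row
                    continue
                raise InputFormatError(
                    f"{path}: line {lineno}: expected 'mz,intensity'"
                ) from None
    if not peaks:
        raise InputFormatError(f"{path}: no peaks found")
    return Spectrum(peaks=tuple(peaks), source=str(path))


def write_peaks_csv(path: PathLike, spectrum: Spectrum) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mz", "intensity"])
        writer.writerows(spectrum.peaks)


def read_candidates(path: PathLike) -> List[CandidateSequence]:
    """Candidate sequences from CSV (id,sequence,provenance) or FASTA."""
    path = Path(path)
    if path.suffix.lower() in (".fasta", ".fa", ".faa"):
        return [
            CandidateSequence(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sequence" not in [
            f.lower() for f in reader.fieldnames
        ]:
            raise InputFormatError(
                f"{path}: need a CSV header with id,sequence[,provenance]"
            )
        fields = {f.lower(): f for f in reader.fieldnames}
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    CandidateSequence(
                        id=row[fields["id"]],
                        sequence=row[fields["sequence"]].strip().upper(),
                        provenance=row.get(
                            fields.get("provenance", ""), "peptide"
                        )
                        or "peptide",
                    )
                )
            except KeyError:
                raise InputFormatError(
                    f"{path}: line {lineno}: missing id or sequence"
                ) from None
    if not out:
        raise InputFormatError(f"{path}: no candidates found")
    return out


def read_nucleotide_fasta(path: PathLike) -> List[NucSeq]:
    records = [
        NucSeq(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputFormatError(f"{path}: no FASTA records found")
    return records


def read_peptide_fasta(path: PathLike) -> Dict[str, str]:
    records = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not records:
        raise InputFormatError(f"{path}: no FASTA records found")
    return records


def write_pattern_csv(path: PathLike, pattern: IsotopePattern) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = "mz" if pattern.charge else "mass"
        writer.writerow([header, "relative_abundance"])
        writer.writerows(pattern.entries)


def write_hits_tsv(path: PathLike, hits: Sequence[GenomicHit]) -> None:
    """BED-like TSV: one row per exon, hits numbered in the name column."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["seq_id", "start", "end", "name", "strand", "frame", "translated"]
        )
        for i, hit in enumerate(hits, start=1):
            for j, (s, e) in enumerate(hit.exons, start=1):
                writer.writerow(
                    [
                        hit.seq_id, s, e,
                        f"hit{i}_exon{j}of{hit.n_exons}",
                        hit.strand, hit.frame, hit.translated,
                    ]
                )


def write_conservation_csv(path: PathLike, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, float_format="%.2f")


def read_feature_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample", "feature", "mz", "rt", "area"} - set(df.columns)
    if missing:
        raise InputFormatError(
            f"{path}: feature table missing columns {sorted(missing)}"
        )
    return df


def write_feature_table(path: PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)
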