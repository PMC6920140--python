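"""Theoretical b/y fragment ions with disulfide-aware cysteine correction.

For a disulfide-bonded precursor, backbone fragments that retain a cysteine
engaged in an S-S bridge are lighter than their reduced-peptide values.  The
approximation used here subtracts one hydrogen atom per cysteine contained
in the fragment — a uniform correction applied to every Cys, since the
bridge connectivity is unknown.  Predictions default to singly charged b/y
series, which is what collision-induced dissociation of small peptides
predominantly yields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .chem import (
    DEFAULT_TABLE,
    AminoAcidTable,
    Peptide,
    monoisotopic_mass,
)
from .spectral import Spectrum

__all__ = [
    "FragmentIon",
    "AnnotatedSpectrum",
    "fragment_mz",
    "theoretical_spectrum",
    "annotate",
]


@dataclass(frozen=True)
class FragmentIon:
    """One backbone fragment: series ('b' or 'y'), residue count, charge."""

    series: str
    index: int
    z: int
    mz: float
    n_cys: int

    @property
    def label(self) -> str:
        zs = "+" * self.z
        return f"{self.series}{self.index}{zs if self.z > 1 else ''}"


@dataclass(frozen=True)
class AnnotatedSpectrum:
    """An observed spectrum with fragment-ion annotations.

    ``coverage`` is the fraction of the n-1 inter-residue bonds supported
    by at least one annotated b or y ion.
    """

    spectrum: Spectrum
    peptide: Peptide
    annotations: Tuple[Tuple[int, FragmentIon, float], ...]
    coverage: float

    @property
    def matched_ion_count(self) -> int:
        return len(self.annotations)


def _residue_masses(
    peptide: Peptide, table: AminoAcidTable
) -> np.ndarray:
    return np.array(
        [monoisotopic_mass(table.residue(a), table) for a in peptide.sequence]
    )


def fragment_mz(
    peptide: Peptide,
    series: str,
    index: int,
    z: int = 1,
    cys_correction: bool = False,
    table: AminoAcidTable = DEFAULT_TABLE,
    cys_hydrogen: Optional[float] = None,
) -> float:
    """m/z of the b_index or y_index ion at charge z.

    b_i = sum of the first i residues plus z protons; y_i = sum of the last
    i residues plus water plus z protons; both divided by z.  With
    ``cys_correction`` one hydrogen atom is subtracted per cysteine in the
    fragment (``cys_hydrogen`` overrides the H mass used; the legacy
    1.00794 Da value of older calculators can be passed here).
    """
    n = len(peptide)
    if series not in ("b", "y"):
        raise ValueError(f"unknown series {series!r}")
    if not (1 <= index <= n - 1):
        raise ValueError(f"fragment index {index} out of range for n={n}")
    if z < 1:
        raise ValueError("charge must be >= 1")
    res = _residue_masses(peptide, table)
    if series == "b":
        frag_seq = peptide.sequence[:index]
        neutral = float(res[:index].sum())
    else:
        frag_seq = peptide.sequence[n - index:]
        neutral = float(res[n - index:].sum()) + monoisotopic_mass(
            table.water, table
        )
    if cys_correction:
        h = table.hydrogen_mass if cys_hydrogen is None else cys_hydrogen
        neutral -= frag_seq.count("C") * h
    return (neutral + z * table.proton_mass) / z


def theoretical_spectrum(
    peptide: Peptide,
    series_set: Sequence[str] = ("b", "y"),
    z_set: Sequence[int] = (1,),
    cys_correction: bool = False,
    table: AminoAcidTable = DEFAULT_TABLE,
    cys_hydrogen: Optional[float] = None,
) -> Tuple[Spectrum, List[FragmentIon]]:
    """All informative fragment ions of a peptide, as a unit-intensity spectrum.

    Returns the spectrum (sorted by m/z) and the parallel-order ion list.
    """
    ions: List[FragmentIon] = []
    n = len(peptide)
    seen = set()
    for series in series_set:
        for z in z_set:
            for i in range(1, n):
                key = (series, i, z)
                if key in seen:
                    continue
                seen.add(key)
                frag_seq = (
                    peptide.sequence[:i] if series == "b"
                    else peptide.sequence[n - i:]
                )
                ions.append(
                    FragmentIon(
                        series=series,
                        index=i,
                        z=z,
                        mz=fragment_mz(
                            peptide, series, i, z, cys_correction, table,
                            cys_hydrogen,
                        ),
                        n_cys=frag_seq.count("C"),
                    )
                )
    ions.sort(key=lambda ion: ion.mz)
    spec = Spectrum(peaks=tuple((ion.mz, 1.0) for ion in ions))
    return spec, ions


def annotate(
    observed: Spectrum,
    peptide: Peptide,
    tol_ppm: float = 10.0,
    series_set: Sequence[str] = ("b", "y"),
    z_set: Sequence[int] = (1,),
    cys_correction: bool = True,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> AnnotatedSpectrum:
    """Match observed peaks to theoretical fragments and compute bond coverage.

    Each theoretical ion is matched to the nearest observed peak within
    ``tol_ppm`` (ties toward higher intensity).  Bond i (between residues i
    and i+1) is covered when b_i or y_{n-i} is annotated.
    """
    if len(observed) == 0:
        raise ValueError("observed spectrum is empty")
    _, ions = theoretical_spectrum(
        peptide, series_set, z_set, cys_correction, table
    )
    obs_mz = observed.mz
    obs_int = observed.intensity
    annotations: List[Tuple[int, FragmentIon, float]] = []
    n = len(peptide)
    covered = np.zeros(n - 1, dtype=bool)
    for ion in ions:
        tol = tol_ppm * 1e-6 * ion.mz
        d = np.abs(obs_mz - ion.mz)
        j = int(np.argmin(d))
        if d[j] > tol:
            continue
        tied = np.where(np.isclose(d, d[j], rtol=0, atol=1e-12))[0]
        if len(tied) > 1:
            j = int(tied[np.argmax(obs_int[tied])])
        ppm = (obs_mz[j] - ion.mz) / ion.mz * 1e6
        annotations.append((j, ion, ppm))
        bond = ion.index if ion.series == "b" else n - ion.index
        if 1 <= bond <= n - 1:
            covered[bond - 1] = True
    return AnnotatedSpectrum(
        spectrum=observed,
        peptide=peptide,
        annotations=tuple(annotations),
        coverage=float(covered.mean()) if n > 1 else 0.0,
    )
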