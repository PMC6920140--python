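"""Isotope-envelope prediction, envelope comparison, and charge-state handling.

The isotope distribution of a composition is computed by iterative
convolution of per-element isotope vectors, aggregated per nucleon number
(unit-mass binning with abundance-weighted centroid masses).  This matches
what a ~30,000-resolution TOF instrument resolves: isotopologue peaks spaced
~1.0033/z apart, without fine structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import (
    DEFAULT_TABLE,
    AminoAcidTable,
    ElementalComposition,
    mz_of,
    neutral_mass_from_mz,
)

__all__ = [
    "NEUTRON_SPACING",
    "IsotopePattern",
    "Spectrum",
    "ChargeStateSeries",
    "isotope_pattern",
    "envelope_similarity",
    "deconvolute",
    "assign_charges",
]

#: C13 - C12 mass difference: the m/z spacing of isotopologues is
#: approximately NEUTRON_SPACING / z.
NEUTRON_SPACING = 1.00335

# Isotope tables: element -> list of (nucleon offset, mass Da, abundance).
_ISOTOPES: Dict[str, List[Tuple[int, float, float]]] = {
    "H": [(0, 1.00782503207, 0.999885), (1, 2.0141017778, 0.000115)],
    "C": [(0, 12.0, 0.9893), (1, 13.0033548378, 0.0107)],
    "N": [(0, 14.0030740048, 0.99636), (1, 15.0001088982, 0.00364)],
    "O": [
        (0, 15.9949146196, 0.99757),
        (1, 16.9991317, 0.00038),
        (2, 17.9991610, 0.00205),
    ],
    "S": [
        (0, 31.97207100, 0.9499),
        (1, 32.97145876, 0.0075),
        (2, 33.96786690, 0.0425),
        (4, 35.96708076, 0.0001),
    ],
}


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated isotopologue distribution of one species.

    ``entries`` are (mass or m/z, relative abundance) in increasing mass
    order, abundances normalised to sum to 1.  ``charge`` is None for a
    neutral-mass pattern, otherwise the entries are m/z of [M+zH]^z+.
    """

    entries: Tuple[Tuple[float, float], ...]
    charge: Optional[int] = None

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for m, _ in self.entries])

    @property
    def abundances(self) -> np.ndarray:
        return np.array([a for _, a in self.entries])

    @property
    def base_index(self) -> int:
        """Index of the most abundant isotopologue."""
        return int(np.argmax(self.abundances))

    def as_spectrum(self, scale: float = 1.0) -> "Spectrum":
        return Spectrum(
            peaks=tuple((m, a * scale) for m, a in self.entries),
        )


@dataclass(frozen=True)
class Spectrum:
    """Centroided peak list: (m/z, intensity) sorted by m/z."""

    peaks: Tuple[Tuple[float, float], ...]
    source: Optional[str] = None
    retention_time: Optional[float] = None

    def __post_init__(self):
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i < 0 for _, i in pk):
            raise ValueError("negative peak intensity")
        object.__setattr__(self, "peaks", pk)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])

    @property
    def base_peak(self) -> Tuple[float, float]:
        return max(self.peaks, key=lambda p: p[1])


@dataclass(frozen=True)
class ChargeStateSeries:
    """A set of (m/z, z) observations of one analyte and the implied mass."""

    observations: Tuple[Tuple[float, int], ...]
    inferred_neutral_mass: float
    ppm_spread: float
    consistent: bool = True

    @property
    def charges(self) -> Tuple[int, ...]:
        return tuple(z for _, z in self.observations)


def _convolve(
    a: Dict[int, Tuple[float, float]],
    b: Dict[int, Tuple[float, float]],
    prune: float,
) -> Dict[int, Tuple[float, float]]:
    """Convolve two {offset: (prob, prob-weighted mass sum)} distributions."""
    out: Dict[int, List[float]] = {}
    for ka, (pa, ma) in a.items():
        for kb, (pb, mb) in b.items():
            p = pa * pb
            if p < prune:
                continue
            # E[mass] adds for independent components:
            # weighted sum = p_a*p_b*(m_a/p_a + m_b/p_b)
            m = pb * ma + pa * mb
            k = ka + kb
            if k in out:
                out[k][0] += p
                out[k][1] += m
            else:
                out[k] = [p, m]
    return {k: (p, m) for k, (p, m) in out.items()}


def _element_power(
    element: str, n: int, prune: float
) -> Dict[int, Tuple[float, float]]:
    """Isotope distribution of n atoms of one element, by squaring."""
    try:
        iso = _ISOTOPES[element]
    except KeyError:
        raise KeyError(f"no isotope data for element {element!r}") from None
    base = {k: (p, p * m) for k, m, p in iso}
    result: Dict[int, Tuple[float, float]] = {0: (1.0, 0.0)}
    while n:
        if n & 1:
            result = _convolve(result, base, prune)
        n >>= 1
        if n:
            base = _convolve(base, base, prune)
    return result


def isotope_pattern(
    comp: ElementalComposition,
    z: int = 0,
    abundance_floor: float = 1e-4,
    max_isotopologues: int = 12,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> IsotopePattern:
    """Aggregated isotope distribution of a composition.

    Parameters
    ----------
    comp : elemental composition of the neutral molecule.
    z : charge; 0 returns neutral masses, z > 0 returns m/z of [M+zH]^z+.
    abundance_floor : isotopologues below this relative abundance (after
        normalising the base peak region) are dropped before renormalising.
    max_isotopologues : hard cap on the envelope length.
    """
    if not comp.counts:
        raise ValueError("empty composition")
    if not (0 <= abundance_floor < 1):
        raise ValueError("abundance_floor must be in [0, 1)")
    prune = 1e-18
    dist: Dict[int, Tuple[float, float]] = {0: (1.0, 0.0)}
    for el, n in comp:
        dist = _convolve(dist, _element_power(el, n, prune), prune)
    entries = []
    for k in sorted(dist):
        p, msum = dist[k]
        entries.append((msum / p, p))
    # truncate + cap, then renormalise
    entries = [(m, p) for m, p in entries if p >= abundance_floor]
    entries = entries[:max_isotopologues]
    total = sum(p for _, p in entries)
    entries = [(m, p / total) for m, p in entries]
    if z > 0:
        entries = [(mz_of(m, z, table.proton_mass), p) for m, p in entries]
    return IsotopePattern(entries=tuple(entries), charge=z if z > 0 else None)


def envelope_similarity(
    theoretical: IsotopePattern,
    observed: Spectrum,
    match_tol_ppm: float = 10.0,
) -> Tuple[float, List[Optional[float]]]:
    """Cosine similarity between a predicted envelope and measured peaks.

    Each theoretical isotopologue is greedily paired (most abundant first)
    with the nearest unused observed peak within ``match_tol_ppm``; ties in
    ppm distance break toward the more intense observed peak.  Unpaired
    theoretical peaks contribute zero intensity.  Returns the normalised
    intensity cosine over the theoretical entries and the per-entry signed
    ppm error (None where unpaired).
    """
    if len(theoretical.entries) == 0 or len(observed) == 0:
        return 0.0, []
    obs_mz = observed.mz
    obs_int = observed.intensity
    used = np.zeros(len(obs_mz), dtype=bool)
    n_t = len(theoretical.entries)
    matched_int = np.zeros(n_t)
    ppm_errors: List[Optional[float]] = [None] * n_t
    order = np.argsort(-theoretical.abundances)
    t_mz = theoretical.masses
    for ti in order:
        tol = match_tol_ppm * 1e-6 * t_mz[ti]
        d = np.abs(obs_mz - t_mz[ti])
        candidates = np.where((d <= tol) & ~used)[0]
        if len(candidates) == 0:
            continue
        dc = d[candidates]
        best_d = dc.min()
        tied = candidates[np.isclose(dc, best_d, rtol=0, atol=1e-12)]
        j = tied[np.argmax(obs_int[tied])]
        used[j] = True
        matched_int[ti] = obs_int[j]
        ppm_errors[ti] = (obs_mz[j] - t_mz[ti]) / t_mz[ti] * 1e6
    t_int = theoretical.abundances
    denom = np.linalg.norm(t_int) * np.linalg.norm(matched_int)
    score = float(t_int @ matched_int / denom) if denom > 0 else 0.0
    return score, ppm_errors


def deconvolute(
    observations: Sequence[Tuple[float, int]],
    max_ppm_spread: float = 20.0,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> ChargeStateSeries:
    """Infer a neutral mass from one or more (m/z, z) observations.

    The inferred mass is the unweighted mean of the per-observation neutral
    masses; ``ppm_spread`` is the maximum pairwise deviation in ppm of the
    mean.  A spread above ``max_ppm_spread`` flags the series as
    inconsistent but is not fatal.
    """
    if not observations:
        raise ValueError("need at least one (m/z, z) observation")
    charges = [z for _, z in observations]
    if len(set(charges)) != len(charges):
        raise ValueError("charge states must be distinct")
    masses = [
        neutral_mass_from_mz(mz, z, table.proton_mass) for mz, z in observations
    ]
    mean = float(np.mean(masses))
    spread = (
        (max(masses) - min(masses)) / mean * 1e6 if len(masses) > 1 else 0.0
    )
    return ChargeStateSeries(
        observations=tuple((float(m), int(z)) for m, z in observations),
        inferred_neutral_mass=mean,
        ppm_spread=spread,
        consistent=spread <= max_ppm_spread,
    )


def _cluster_peaks(
    spectrum: Spectrum, gap: float = 1.5
) -> List[List[Tuple[float, float]]]:
    clusters: List[List[Tuple[float, float]]] = []
    for mz, inten in spectrum.peaks:
        if clusters and mz - clusters[-1][-1][0] <= gap:
            clusters[-1].append((mz, inten))
        else:
            clusters.append([(mz, inten)])
    return clusters


def assign_charges(
    spectrum: Spectrum,
    z_candidates: Sequence[int] = (1, 2, 3, 4, 5, 6),
    spacing_tol: float = 0.02,
    min_peaks: int = 3,
) -> List[Tuple[float, int]]:
    """Detect isotope envelopes and assign a charge to each from its spacing.

    Peaks are grouped into clusters separated by > 1.5 Th; within a cluster
    the charge is chosen by laying an isotopologue grid (spacing 1.00335/z)
    through the most intense peak and scoring how much intensity falls on
    the grid within ``spacing_tol`` Th.  Clusters supporting fewer than
    ``min_peaks`` grid positions for every candidate charge are skipped.
    Returns (monoisotopic m/z of the envelope, z) per accepted cluster.
    """
    out: List[Tuple[float, int]] = []
    for cluster in _cluster_peaks(spectrum):
        if len(cluster) < min_peaks:
            continue
        mzs = np.array([m for m, _ in cluster])
        ints = np.array([i for _, i in cluster])
        anchor = mzs[np.argmax(ints)]
        best: Optional[Tuple[float, int, float]] = None  # score, z, mono mz
        for z in z_candidates:
            step = NEUTRON_SPACING / z
            k = np.rint((mzs - anchor) / step)
            resid = np.abs(mzs - (anchor + k * step))
            on_grid = resid <= spacing_tol
            # require distinct grid positions, not multiple peaks per slot
            slots = set(k[on_grid].astype(int))
            if len(slots) < min_peaks:
                continue
            score = float(ints[on_grid].sum()) * len(slots)
            # report the observed lowest-slot peak as the monoisotopic m/z
            mono = float(mzs[on_grid].min())
            if best is None or score > best[0]:
                best = (score, z, mono)
        if best is not None:
            out.append((best[2], best[1]))
    return out
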