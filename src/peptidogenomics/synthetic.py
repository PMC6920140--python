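"""Synthetic data with known ground truth for every pipeline stage.

Generates the inputs the identification and quantitation workflows consume:
multi-charge precursor envelopes with noise and an optional co-eluting
contaminant, b/y product-ion spectra with dropout and m/z jitter, genome-like
nucleotide sequences with an exon-split coding region planted on either
strand, an 8-point internal-standard calibration series, and a repeated-
measures serum time course with a rising hepcidin trajectory and a
post-transfusion iron spike that declines as hepcidin rises.

Defaults reproduce the study conditions of the hepcidin identification:
the 25-residue, 8-cysteine peptide DTHFPICIFCCGCCKTPKCGFCCRT with four
disulfide bridges, 5+/4+/3+ charge states, 0.6-75 nM 8-point calibration
with an 18.75 nM internal standard, and ten subjects sampled at 0, 2, 4 and
6 hours.  Intensity noise is multiplicative lognormal; m/z jitter is uniform
in ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import Peptide, composition_of, monoisotopic_mass, mz_of
from .fragments import theoretical_spectrum
from .genomics import GenomicHit, NucSeq, _codons_for
from .spectral import IsotopePattern, Spectrum, isotope_pattern

__all__ = [
    "HEPCIDIN_SEQUENCE",
    "SimulationConfig",
    "simulate_precursor_spectrum",
    "simulate_fragment_spectrum",
    "simulate_genome_with_gene",
    "simulate_quant_study",
]

#: The Canidae hepcidin-25 sequence (genome-curated translation).
HEPCIDIN_SEQUENCE = "DTHFPICIFCCGCCKTPKCGFCCRT"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-data generators, with study defaults."""

    seed: int = 0
    peptide: str = HEPCIDIN_SEQUENCE
    n_disulfides: int = 4
    charges: Tuple[int, ...] = (5, 4, 3)
    # noise model
    intensity_cv: float = 0.05
    mz_jitter_ppm: float = 2.0
    dropout: float = 0.0
    contaminant: bool = False
    contaminant_rel_intensity: float = 0.3
    # genome plan
    genome_length: int = 100_000
    exon_plan: Tuple[int, ...] = (7, 10, 8)  # residues per exon
    strand: Optional[str] = None  # None: choose at random
    min_intron: int = 200
    max_intron: int = 20_000
    # calibration design (nM)
    calibration_levels: Tuple[float, ...] = (
        0.6, 1.2, 2.4, 4.7, 9.4, 18.75, 37.5, 75.0,
    )
    internal_standard_nm: float = 18.75
    calibration_cv: float = 0.05
    n_injections: int = 117
    is_area_mean: float = 1.0e5
    is_area_cv: float = 0.14
    # time-course design
    n_subjects: int = 10
    timepoints_h: Tuple[float, ...] = (0.0, 2.0, 4.0, 6.0)
    hepcidin_medians_nm: Tuple[float, ...] = (4.0, 6.0, 9.0, 12.0)
    iron_medians_nm: Tuple[float, ...] = (15.0, 45.0, 35.0, 28.0)
    subject_sigma: float = 0.25  # lognormal sigma of within-cell noise

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _jitter(rng: np.random.Generator, mz: np.ndarray, ppm: float) -> np.ndarray:
    if ppm <= 0:
        return mz
    return mz * (1.0 + rng.uniform(-ppm, ppm, size=mz.shape) * 1e-6)


def _lognoise(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    if cv <= 0:
        return values
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return values * rng.lognormal(-sigma**2 / 2, sigma, size=values.shape)


def simulate_precursor_spectrum(
    cfg: SimulationConfig,
) -> Tuple[Spectrum, Dict]:
    """Render a multi-charge precursor spectrum of the configured peptide.

    Each configured charge state contributes its predicted isotope envelope
    (envelope heights decay with decreasing charge, mimicking the observed
    charge-state distribution); intensities get lognormal noise, m/z values
    uniform ppm jitter.  With ``contaminant`` enabled, extra peaks are
    overlaid on the high-mass flank of the lowest-charge envelope, as seen
    for co-eluting analytes.  Returns the spectrum and ground truth
    {'neutral_mass', 'envelopes': {z: monoisotopic m/z}}.
    """
    rng = cfg.rng()
    pep = Peptide(cfg.peptide, cfg.n_disulfides)
    comp = composition_of(pep)
    mass = monoisotopic_mass(comp)
    peaks: List[Tuple[float, float]] = []
    envelopes: Dict[int, float] = {}
    scale = 1.0
    for z in cfg.charges:
        pattern = isotope_pattern(comp, z=z)
        envelopes[z] = mz_of(mass, z)
        mzs = _jitter(rng, pattern.masses, cfg.mz_jitter_ppm)
        ints = _lognoise(rng, pattern.abundances * scale, cfg.intensity_cv)
        keep = np.ones(len(mzs), dtype=bool)
        if cfg.dropout > 0:
            keep = rng.random(len(mzs)) >= cfg.dropout
            keep[pattern.base_index] = True  # base peak always observed
        peaks.extend(zip(mzs[keep], ints[keep]))
        if cfg.contaminant and z == min(cfg.charges):
            base_mz, base_int = max(
                zip(mzs, ints), key=lambda p: p[1]
            )
            # co-eluting analyte overlapping the higher-mass isotopes
            step = 1.00335 / z
            for k in range(3, 7):
                peaks.append(
                    (
                        base_mz + k * step + rng.uniform(-0.05, 0.05),
                        base_int * cfg.contaminant_rel_intensity
                        * rng.uniform(0.5, 1.0),
                    )
                )
        scale *= 0.6
    truth = {"neutral_mass": mass, "envelopes": envelopes, "peptide": cfg.peptide}
    return Spectrum(peaks=tuple(peaks), source="synthetic-precursor"), truth


def simulate_fragment_spectrum(
    cfg: SimulationConfig,
) -> Tuple[Spectrum, Dict]:
    """Render a singly-charged b/y product-ion spectrum with dropout/jitter.

    Fragment intensities are drawn uniformly (product-ion intensity is not
    modelled mechanistically); a ``dropout`` fraction of ions is removed at
    random and all m/z values receive uniform ppm jitter.  The cysteine
    correction is applied, matching a disulfide-bonded precursor.
    """
    rng = cfg.rng()
    pep = Peptide(cfg.peptide, cfg.n_disulfides)
    spec, ions = theoretical_spectrum(pep, cys_correction=True)
    mzs = spec.mz
    keep = rng.random(len(mzs)) >= cfg.dropout
    if not keep.any():
        keep[rng.integers(len(keep))] = True
    mzs = _jitter(rng, mzs[keep], cfg.mz_jitter_ppm)
    ints = rng.uniform(0.2, 1.0, size=len(mzs))
    truth = {
        "peptide": cfg.peptide,
        "n_ions_total": len(ions),
        "n_ions_kept": int(keep.sum()),
    }
    return Spectrum(peaks=tuple(zip(mzs, ints)), source="synthetic-msms"), truth


def simulate_genome_with_gene(
    cfg: SimulationConfig,
) -> Tuple[NucSeq, Optional[GenomicHit]]:
    """Random DNA with the peptide's coding sequence planted as exons.

    Codons are sampled uniformly per residue; the coding sequence is split
    per ``exon_plan`` (residue counts; empty plan plants nothing) and the
    exons are placed in order, separated by random gaps, on a random strand
    unless ``strand`` is fixed.  Returns the sequence and the ground-truth
    hit (exons in coding order, forward coordinates), or None when nothing
    was planted.
    """
    rng = cfg.rng()
    L = cfg.genome_length
    genome = rng.choice(list("ACGT"), size=L)
    if not cfg.exon_plan:
        return NucSeq(id="synthetic-genome", sequence="".join(genome)), None
    if sum(cfg.exon_plan) != len(cfg.peptide):
        raise ValueError("exon plan does not sum to peptide length")
    coding = "".join(
        _codons_for(aa)[rng.integers(len(_codons_for(aa)))]
        for aa in cfg.peptide
    )
    seg_lengths = [3 * n for n in cfg.exon_plan]
    total = sum(seg_lengths)
    n_gaps = len(seg_lengths) - 1
    slack = L - total
    gap_hi = min(cfg.max_intron, max(cfg.min_intron, slack // (n_gaps + 1)))
    if slack < n_gaps * cfg.min_intron + 1:
        raise ValueError("exon plan does not fit in the genome")
    gaps = [
        int(rng.integers(cfg.min_intron, gap_hi + 1)) for _ in range(n_gaps)
    ]
    start = int(rng.integers(0, slack - sum(gaps) + 1))
    segments_fwd: List[Tuple[int, int]] = []
    pos = start
    offset = 0
    for seg_len, gap in zip(seg_lengths, gaps + [0]):
        genome[pos:pos + seg_len] = list(coding[offset:offset + seg_len])
        segments_fwd.append((pos, pos + seg_len))
        offset += seg_len
        pos += seg_len + gap
    strand = cfg.strand or ("+" if rng.random() < 0.5 else "-")
    seq = "".join(genome)
    if strand == "-":
        # planted on the minus strand: reverse-complement the whole genome,
        # so the coding segments flip to the other strand and reverse order
        comp_map = str.maketrans("ACGT", "TGCA")
        seq = seq.translate(comp_map)[::-1]
        exons = tuple((L - e, L - s) for s, e in segments_fwd)
    else:
        exons = tuple(segments_fwd)
    nuc = NucSeq(id="synthetic-genome", sequence=seq)
    truth = GenomicHit(
        seq_id=nuc.id,
        strand=strand,
        exons=exons,
        frame=(exons[0][0] if strand == "+" else L - exons[0][1]) % 3,
        translated=cfg.peptide,
    )
    return nuc, truth


def simulate_quant_study(cfg: SimulationConfig) -> Dict:
    """Calibration series, IS QC areas, and the two serum time courses.

    Returns a dict with:

    - ``calibration``: DataFrame (conc_nm, response) — IS-normalised area
      ratio, linear in concentration with lognormal noise of the configured
      CV;
    - ``is_areas``: internal-standard areas across the injection sequence;
    - ``hepcidin`` / ``iron``: subjects x timepoints arrays following the
      configured median trajectories with lognormal subject noise;
    - ``truth``: the generating slope, planted IS concentration and
      trajectories.
    """
    rng = cfg.rng()
    slope = 0.08  # response units per nM; arbitrary instrument gain
    conc = np.asarray(cfg.calibration_levels, dtype=float)
    response = _lognoise(rng, slope * conc, cfg.calibration_cv)
    calibration = pd.DataFrame({"conc_nm": conc, "response": response})
    is_areas = _lognoise(
        rng,
        np.full(cfg.n_injections, cfg.is_area_mean),
        cfg.is_area_cv,
    )
    k = len(cfg.timepoints_h)
    hep = _lognoise(
        rng,
        np.tile(np.asarray(cfg.hepcidin_medians_nm), (cfg.n_subjects, 1)),
        _cv_from_sigma(cfg.subject_sigma),
    )
    iron = _lognoise(
        rng,
        np.tile(np.asarray(cfg.iron_medians_nm), (cfg.n_subjects, 1)),
        _cv_from_sigma(cfg.subject_sigma),
    )
    spike_response = _lognoise(
        rng, np.array([slope * cfg.internal_standard_nm]), cfg.calibration_cv
    )[0]
    return {
        "calibration": calibration,
        "is_areas": is_areas,
        "hepcidin": hep,
        "iron": iron,
        "spike_response": spike_response,
        "truth": {
            "slope": slope,
            "intercept": 0.0,
            "internal_standard_nm": cfg.internal_standard_nm,
            "hepcidin_medians_nm": cfg.hepcidin_medians_nm,
            "iron_medians_nm": cfg.iron_medians_nm,
            "timepoints_h": cfg.timepoints_h,
        },
    }


def _cv_from_sigma(sigma: float) -> float:
    """CV of a lognormal with the given log-scale sigma."""
    return float(np.sqrt(np.exp(sigma**2) - 1.0))
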