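"""Pipeline configuration: tolerances, constants mode, and reproducibility.

A single human-editable YAML file can override any default; unknown keys
are rejected so typos fail loudly rather than silently using defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Union

import yaml

from .chem import LEGACY_HYDROGEN_MASS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Tolerances and modes shared by the identification pipeline.

    ``constants_mode`` selects the hydrogen mass used for the per-cysteine
    fragment correction: 'modern' (monoisotopic H atom, 1.00783 Da) or
    'legacy-1.00794' for bit-compatibility with older web calculators.
    """

    precursor_tol_ppm: float = 20.0
    fragment_tol_ppm: float = 10.0
    envelope_tol_ppm: float = 10.0
    rt_tol_min: float = 0.10
    mz_tol_da: float = 0.05
    constants_mode: str = "modern"
    codon_table_id: int = 1
    max_exons: int = 3
    output_dir: str = "."
    seed: int = 0
    # recorded upstream-processing settings (profile-data peak integration;
    # not applied to centroided peak-list inputs)
    noise_threshold: float = 3.0
    min_spectral_width_da: float = 0.05

    def __post_init__(self):
        if self.constants_mode not in ("modern", "legacy-1.00794"):
            raise ValueError(
                f"unknown constants_mode {self.constants_mode!r}"
            )
        if self.codon_table_id != 1:
            raise ValueError("only the standard codon table (1) is supported")

    @property
    def cys_hydrogen(self) -> Optional[float]:
        """H mass override for the cysteine correction (None = modern)."""
        return (
            LEGACY_HYDROGEN_MASS
            if self.constants_mode == "legacy-1.00794"
            else None
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"{path}: unknown config keys {sorted(unknown)}"
            )
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
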