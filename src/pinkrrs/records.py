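"""Shared domain types for the RRS pipeline.

Carcass-survey samples, genotype panels/containers, and run configuration.
Sample collections are carried as pandas DataFrames with the column schema
of :data:`SAMPLE_COLUMNS`; :class:`SampleRecord` is the typed single-row
view used for validation and round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "Locus",
    "LocusPanel",
    "GenotypeSet",
    "Config",
    "SAMPLE_COLUMNS",
    "SchemaError",
    "ValidationError",
    "ConfigError",
]

#: column order of a sample table CSV (one row per fish)
SAMPLE_COLUMNS = [
    "sample_id",
    "stream",
    "year",
    "lineage",
    "origin",
    "hatchery_code",
    "sex",
    "length_mm",
    "sample_day",
    "distance_m",
    "intertidal",
    "genotyped",
]

LINEAGES = {"odd", "even"}
ORIGINS = {"hatchery", "natural", "unknown"}
SEXES = {"F", "M", "unknown"}


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an unusable layout."""


class ValidationError(ValueError):
    """A row or cell violates the domain invariants."""


class ConfigError(ValueError):
    """A configuration value is out of range or inconsistent."""


@dataclass
class SampleRecord:
    """One carcass-survey fish.

    ``length_mm`` is mideye-to-hypural length; ``sample_day`` is the day of
    year the carcass was sampled; ``distance_m`` is meters upstream of the
    stream mouth. ``origin`` comes from the thermal otolith mark and is
    ``hatchery`` iff ``hatchery_code`` is set.
    """

    sample_id: str
    stream: str
    year: int
    lineage: str
    origin: str
    hatchery_code: Optional[str]
    sex: str
    length_mm: float
    sample_day: int
    distance_m: float
    intertidal: bool
    genotyped: bool

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ValidationError(f"lineage {self.lineage!r} for {self.sample_id}")
        if self.origin not in ORIGINS:
            raise ValidationError(f"origin {self.origin!r} for {self.sample_id}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex {self.sex!r} for {self.sample_id}")
        if (self.origin == "hatchery") != (self.hatchery_code is not None):
            raise ValidationError(
                f"origin/hatchery_code mismatch for {self.sample_id}: "
                f"origin={self.origin}, code={self.hatchery_code}"
            )
        if np.isfinite(self.length_mm) and self.length_mm <= 0:
            raise ValidationError(f"length_mm must be > 0 for {self.sample_id}")
        if self.distance_m < 0:
            raise ValidationError(f"distance_m must be >= 0 for {self.sample_id}")


@dataclass
class Locus:
    locus_id: str
    kind: str  # "snp" | "microhap"
    alleles: list[str]
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        n = len(self.alleles)
        if self.kind == "snp" and n != 2:
            raise ValidationError(f"snp locus {self.locus_id} must have 2 alleles")
        if self.kind == "microhap" and not (2 <= n <= 8):
            raise ValidationError(f"microhap locus {self.locus_id} must have 2-8 alleles")
        if len(self.freqs) != n:
            raise ValidationError(f"freqs length mismatch at {self.locus_id}")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValidationError(f"freqs do not sum to 1 at {self.locus_id}")
        if np.any(self.freqs <= 0):
            raise ValidationError(f"zero/negative freq at {self.locus_id}")


@dataclass
class LocusPanel:
    """Ordered marker panel: biallelic SNP amplicons plus multi-allelic
    microhaplotypes, each with population allele frequencies."""

    loci: list[Locus]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def n_alleles(self) -> np.ndarray:
        return np.array([len(l.alleles) for l in self.loci])

    def __len__(self) -> int:
        return len(self.loci)


class GenotypeSet:
    """Unordered allele-pair genotypes for a set of individuals on a panel.

    Stored as an integer array ``alleles`` of shape (n_samples, n_loci, 2)
    holding allele indices into each locus' allele list, sorted within the
    pair; missing genotypes are (-1, -1). No half-called genotypes.
    """

    def __init__(self, sample_ids: Sequence[str], alleles: np.ndarray, panel: LocusPanel):
        alleles = np.asarray(alleles, dtype=np.int16)
        if alleles.shape != (len(sample_ids), panel.n_loci, 2):
            raise ValidationError(
                f"allele array shape {alleles.shape} != "
                f"({len(sample_ids)}, {panel.n_loci}, 2)"
            )
        n_all = panel.n_alleles()
        bad = (alleles >= n_all[None, :, None]) | (
            (alleles < 0) & (alleles != -1)
        )
        if np.any(bad):
            i, l, _ = np.argwhere(bad)[0]
            raise ValidationError(
                f"allele index out of range at sample {sample_ids[i]}, "
                f"locus {panel.loci[l].locus_id}"
            )
        half = (alleles == -1).sum(axis=2) == 1
        if np.any(half):
            i, l = np.argwhere(half)[0]
            raise ValidationError(
                f"half-called genotype at sample {sample_ids[i]}, "
                f"locus {panel.loci[l].locus_id}"
            )
        self.sample_ids = list(sample_ids)
        self.alleles = np.sort(alleles, axis=2)
        # sorting pushes -1 first; keep (-1,-1) canonical
        self.panel = panel
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def __len__(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._index

    def row(self, sample_id: str) -> np.ndarray:
        return self.alleles[self._index[sample_id]]

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean: genotype missing."""
        return self.alleles[:, :, 0] == -1

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of missing loci."""
        return self.missing_mask().mean(axis=1)

    def subset(self, sample_ids: Sequence[str]) -> "GenotypeSet":
        idx = [self._index[s] for s in sample_ids]
        return GenotypeSet(list(sample_ids), self.alleles[idx], self.panel)

    def genotyping_success(self) -> pd.Series:
        return pd.Series(1.0 - self.missing_fraction(), index=self.sample_ids)


@dataclass
class Config:
    """Run configuration with the study's defaults.

    ``genotyping_error_rate`` defaults to the background rate observed
    across streams and years (0.54%); ``posterior_threshold`` to the >90%
    assignment cutoff. ``n_fmax``/``n_mmax`` are the escapement-based
    maxima of potential parents by sex used as assignment priors.
    """

    seed: int = 0
    genotyping_error_rate: float = 0.0054
    missing_rate: float = 0.01
    posterior_threshold: float = 0.90
    n_fmax: Optional[int] = None  # None: use the number of sampled candidates
    n_mmax: Optional[int] = None
    stream_length_m: float = 1500.0
    intertidal_boundary_m: float = 450.0
    parent_sampling_fraction: float = 1.0
    offspring_sampling_fraction: float = 1.0
    pair_beam_width: int = 5
    n_permutations: int = 10_000
    glm_min_offspring_per_origin: int = 30
    power_alpha: float = 0.05
    power_n_reps: int = 2000
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("genotyping_error_rate", "missing_rate",
                     "parent_sampling_fraction", "offspring_sampling_fraction",
                     "power_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.posterior_threshold <= 1.0:
            raise ConfigError(
                f"posterior_threshold={self.posterior_threshold} outside (0, 1]"
            )
        for name in ("n_fmax", "n_mmax"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if self.stream_length_m <= 0:
            raise ConfigError("stream_length_m must be positive")
        if self.pair_beam_width < 1:
            raise ConfigError("pair_beam_width must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)
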