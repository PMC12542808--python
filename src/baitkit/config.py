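"""Design configuration.

Every numeric threshold used by the design and evaluation pipeline lives in
one :class:`DesignConfig` object.  Defaults reflect a published custom bait
set for the Astragalean legume clade: candidate genes of >= 500 bp covered
by at least three species, exons of >= 500 bp with mean pairwise identity
between 75% and 98%, 80-nt baits tiled at 2x density, recovery thresholds at
50%/75% of the target length, and occupancy trimming at 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class DesignConfig:
    """All tunable thresholds of the bait-design and evaluation pipeline.

    Parameters
    ----------
    min_gene_len : int
        Minimum ungapped length (bp) of the shortest sequence for a candidate
        gene to be retained.
    min_taxa : int
        Minimum number of distinct taxa in a candidate gene alignment.
    min_exon_len : int
        Minimum exon alignment length (bp).
    identity_lo, identity_hi : float
        Inclusive bounds (percent) on mean pairwise identity of an exon
        alignment.  The lower bound discards exons too divergent for reliable
        capture; the upper bound discards exons too conserved to be
        phylogenetically informative (and likely to cross-hybridize).
    bait_len : int
        Bait (probe) length in nucleotides.
    tiling_density : float
        How densely consecutive baits overlap; 2.0 means a new bait starts
        every ``bait_len / 2`` bases.
    recovery_thresholds : frozenset of float
        Fractions of the per-locus target length at which recovered loci are
        counted (strictly greater-than).
    min_col_occupancy : float
        Minimum fraction of sequences with an unambiguous residue for an
        alignment column to be kept when trimming.
    """

    min_gene_len: int = 500
    min_taxa: int = 3
    min_exon_len: int = 500
    identity_lo: float = 75.0
    identity_hi: float = 98.0
    bait_len: int = 80
    tiling_density: float = 2.0
    recovery_thresholds: frozenset = field(
        default_factory=lambda: frozenset({0.50, 0.75})
    )
    min_col_occupancy: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.identity_lo <= self.identity_hi <= 100):
            raise ConfigError(
                "identity bounds must satisfy 0 < lo <= hi <= 100, got "
                f"[{self.identity_lo}, {self.identity_hi}]"
            )
        if self.bait_len < 1:
            raise ConfigError(f"bait_len must be >= 1, got {self.bait_len}")
        if self.tiling_density <= 0:
            raise ConfigError(
                f"tiling_density must be positive, got {self.tiling_density}"
            )
        for frac in self.recovery_thresholds:
            if not (0 < frac <= 1):
                raise ConfigError(
                    f"recovery threshold {frac} outside (0, 1]"
                )
        if not (0 <= self.min_col_occupancy <= 1):
            raise ConfigError(
                f"min_col_occupancy {self.min_col_occupancy} outside [0, 1]"
            )
        object.__setattr__(
            self, "recovery_thresholds", frozenset(self.recovery_thresholds)
        )

    @property
    def tiling_step(self) -> int:
        """Bait start spacing, ``round(bait_len / tiling_density)``."""
        step = int(self.bait_len / self.tiling_density + 0.5)
        if step == 0:
            raise ConfigError(
                f"tiling step rounds to 0 for bait_len={self.bait_len}, "
                f"density={self.tiling_density}"
            )
        return step

    def to_dict(self) -> dict:
        d = asdict(self)
        d["recovery_thresholds"] = sorted(self.recovery_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        d = dict(d)
        if "recovery_thresholds" in d:
            d["recovery_thresholds"] = frozenset(d["recovery_thresholds"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "DesignConfig":
        """Load a config from a YAML (or JSON, a YAML subset) file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
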