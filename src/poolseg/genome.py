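"""Reference coordinate frame for the simulated cross.

A :class:`GenomeModel` holds the chromosome sizes and the genetic map
density used to convert physical distance into expected crossover counts.
The packaged default approximates the 16 nuclear chromosomes of the
*S. cerevisiae* S288c reference (~12.1 Mb total) with a uniform map
density of 0.4 cM/kb, the genome-wide average for yeast.
Coordinates are 1-based throughout, following VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# R64 nuclear chromosome lengths (bp), chrI..chrXVI.
SACCHAROMYCES_CHROM_LENGTHS: dict[str, int] = {
    "chrI": 230_218,
    "chrII": 813_184,
    "chrIII": 316_620,
    "chrIV": 1_531_933,
    "chrV": 576_874,
    "chrVI": 270_161,
    "chrVII": 1_090_940,
    "chrVIII": 562_643,
    "chrIX": 439_888,
    "chrX": 745_751,
    "chrXI": 666_816,
    "chrXII": 1_078_177,
    "chrXIII": 924_431,
    "chrXIV": 784_333,
    "chrXV": 1_091_291,
    "chrXVI": 948_066,
}

#: genome-wide average genetic map density for yeast, cM per kb
DEFAULT_CM_PER_KB = 0.4


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths (bp) and a uniform genetic map density.

    Parameters
    ----------
    chrom_lengths
        Mapping of chromosome name to physical length in bp, in genome order.
    cm_per_kb
        Genetic map density (centiMorgan per kilobase), applied uniformly.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(SACCHAROMYCES_CHROM_LENGTHS)
    )
    cm_per_kb: float = DEFAULT_CM_PER_KB

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("genome must have at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.cm_per_kb <= 0:
            raise ValueError(f"map density must be > 0, got {self.cm_per_kb}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def morgans(self, chrom: str) -> float:
        """Genetic length of a chromosome in Morgans."""
        return self.chrom_lengths[chrom] / 1000.0 * self.cm_per_kb / 100.0

    def length_fractions(self) -> np.ndarray:
        lengths = np.array(list(self.chrom_lengths.values()), dtype=float)
        return lengths / lengths.sum()
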