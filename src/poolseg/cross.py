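"""Synthetic haploid cross: markers, meiosis, trait model, pooled reads.

Emulates the mapping design of an EMS-mutagenized haploid (the *superior*
parent, carrying ~900 induced SNPs on an S288c-like background and a low
ethyl acetate phenotype) crossed to an unrelated haploid (the *inferior*
parent, contributing dense background SNPs and a high phenotype).  The
simulator produces:

* a :class:`MarkerMap` of induced + background SNP markers,
* haploid segregants from Poisson (Haldane, no interference) meioses,
* phenotypes from an additive trait model with optional epistatic
  conditions (functional mitochondria and/or a partner allele),
* pooled sequencing read counts at a target mean depth with a symmetric
  per-read allele-flip error.

All genotypes are coded 1 for the superior-parent allele and 0 for the
inferior-parent allele; pooled "variant" reads count the superior allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = [
    "MarkerMap",
    "CausativeLocus",
    "TraitModel",
    "SegregantSet",
    "build_parents",
    "simulate_meiosis",
    "assign_phenotypes",
    "sample_pool_reads",
    "parent_pool",
    "select_lowest",
    "default_trait_model",
    "as_rng",
]

_BASES = np.array(list("ACGT"))

INDUCED = "induced"
BACKGROUND = "background"


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a Generator; pass through if one is given."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class MarkerMap:
    """Segregating markers of the cross, sorted by genome position.

    ``df`` columns: ``chrom`` (str), ``pos`` (1-based int), ``klass``
    (``"induced"`` mutations private to the superior parent, or
    ``"background"`` differences between the unrelated parents), ``ref``,
    ``alt`` (allele labels; ``alt`` is the superior-parent allele by
    convention).
    """

    df: pd.DataFrame
    genome: GenomeModel

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "klass", "ref", "alt"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"marker table missing columns {sorted(missing)}")
        for chrom, sub in self.df.groupby("chrom", sort=False, observed=True):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> np.ndarray:
        return (self.df["chrom"].astype(str) + ":" + self.df["pos"].astype(str)).to_numpy()

    def index_of(self, marker_id: str) -> int:
        chrom, pos = marker_id.rsplit(":", 1)
        hit = np.flatnonzero(
            (self.df["chrom"].to_numpy() == chrom) & (self.df["pos"].to_numpy() == int(pos))
        )
        if hit.size == 0:
            raise KeyError(f"marker {marker_id!r} not in map")
        return int(hit[0])

    def nearest(self, chrom: str, pos: int, klass: str | None = None) -> str:
        """Id of the marker nearest a physical position, optionally by class."""
        sub = self.df[self.df["chrom"] == chrom]
        if klass is not None:
            sub = sub[sub["klass"] == klass]
        if sub.empty:
            raise KeyError(f"no {klass or 'any'}-class markers on {chrom}")
        i = (sub["pos"] - pos).abs().idxmin()
        row = self.df.loc[i]
        return f"{row['chrom']}:{row['pos']}"

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome (map is genome-sorted)."""
        out: dict[str, slice] = {}
        chroms = self.df["chrom"].to_numpy()
        start = 0
        for chrom in self.genome.chromosomes:
            n = int((chroms == chrom).sum())
            if n:
                out[chrom] = slice(start, start + n)
                start += n
        return out


@dataclass(frozen=True)
class CausativeLocus:
    """One causative allele: additive effect of the superior-parent allele.

    ``requires_mito`` gates the effect on functional mitochondria;
    ``requires_allele`` names a partner marker whose superior allele must
    also be present for the effect to be expressed (hidden epistatic
    partner).
    """

    marker_id: str
    effect: float  # mg/L; sign = effect of carrying the superior allele
    requires_mito: bool = False
    requires_allele: str | None = None


@dataclass(frozen=True)
class TraitModel:
    """Additive trait model on the mg/L ethyl acetate scale.

    Phenotype = midparent baseline + sum of expressed locus effects +
    N(0, residual_sd) noise.  An effect is expressed when the segregant
    carries the superior allele and every epistatic condition holds.
    """

    superior_baseline: float = 13.9
    inferior_baseline: float = 49.8
    loci: tuple[CausativeLocus, ...] = ()
    residual_sd: float = 1.5
    mito_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual sd must be >= 0")
        if not 0.0 <= self.mito_prob <= 1.0:
            raise ValueError("mitochondria probability must be in [0, 1]")

    @property
    def midparent(self) -> float:
        return 0.5 * (self.superior_baseline + self.inferior_baseline)


@dataclass
class SegregantSet:
    """Haploid segregants: genotypes over a MarkerMap, mito status, phenotype."""

    ids: np.ndarray  # str array, n
    genotypes: np.ndarray  # int8, n x n_markers; 1 = superior-parent allele
    mito: np.ndarray  # bool, n; True = functional mitochondria
    markers: MarkerMap
    phenotype: np.ndarray | None = None  # float, mg/L

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.ids), len(self.markers)):
            raise ValueError("genotype matrix shape does not match ids x markers")
        if self.phenotype is not None and not np.all(np.isfinite(self.phenotype)):
            raise ValueError("phenotypes must be finite")

    def __len__(self) -> int:
        return len(self.ids)

    def allele_frequency(self) -> np.ndarray:
        """Superior-allele fraction at every marker."""
        return self.genotypes.mean(axis=0)

    def subset(self, index: np.ndarray) -> "SegregantSet":
        return SegregantSet(
            ids=self.ids[index],
            genotypes=self.genotypes[index],
            mito=self.mito[index],
            markers=self.markers,
            phenotype=None if self.phenotype is None else self.phenotype[index],
        )

    def phenotype_frame(self) -> pd.DataFrame:
        if self.phenotype is None:
            raise ValueError("phenotypes not assigned")
        return pd.DataFrame(
            {"segregant": self.ids, "mito": np.where(self.mito, "functional", "deficient"),
             "phenotype": self.phenotype}
        )


def build_parents(
    genome: GenomeModel,
    n_induced: int = 900,
    n_background: int = 30_000,
    seed: int | np.random.Generator | None = None,
) -> MarkerMap:
    """Place induced and background SNP markers on the genome.

    Markers are placed uniformly at random, with per-chromosome counts
    proportional to physical length, deduplicated within and across
    classes, and sorted.
    """
    if n_induced < 0 or n_background < 0:
        raise ValueError("marker counts must be >= 0")
    rng = as_rng(seed)
    n_total = n_induced + n_background
    chroms = genome.chromosomes
    counts = rng.multinomial(n_total, genome.length_fractions())
    frames = []
    for chrom, k in zip(chroms, counts):
        length = genome.chrom_lengths[chrom]
        if k > length:
            raise ValueError(
                f"requested {k} markers on {chrom} but only {length} positions exist"
            )
        pos = np.sort(rng.choice(length, size=k, replace=False) + 1)  # 1-based
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    df = pd.concat(frames, ignore_index=True)
    # label a random subset of all markers as induced
    klass = np.full(n_total, BACKGROUND, dtype=object)
    klass[rng.choice(n_total, size=n_induced, replace=False)] = INDUCED
    df["klass"] = klass
    ref_idx = rng.integers(0, 4, size=n_total)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_total)) % 4
    df["ref"] = _BASES[ref_idx]
    df["alt"] = _BASES[alt_idx]
    return MarkerMap(df=df, genome=genome)


def simulate_meiosis(
    markers: MarkerMap,
    genome: GenomeModel | None = None,
    n_segregants: int = 386,
    mito_prob: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> SegregantSet:
    """Generate haploid segregants of the cross (phenotypes unset).

    Per segregant and chromosome the crossover count is Poisson with mean
    equal to the chromosome's genetic length in Morgans (Haldane model, no
    interference), crossover positions are uniform, and one of the two
    product chromatids is kept with equal probability.  Mitochondrial
    status is an independent Bernoulli draw with ``mito_prob``.
    """
    if n_segregants <= 0:
        raise ValueError("n_segregants must be > 0")
    genome = genome or markers.genome
    rng = as_rng(seed)
    n_markers = len(markers)
    genotypes = np.empty((n_segregants, n_markers), dtype=np.int8)
    slices = markers.chrom_slices()
    pos_by_chrom = {
        chrom: markers.df["pos"].to_numpy()[sl] for chrom, sl in slices.items()
    }
    for i in range(n_segregants):
        for chrom, sl in slices.items():
            morgans = genome.morgans(chrom)
            n_xo = rng.poisson(morgans)
            start = rng.integers(0, 2)
            pos = pos_by_chrom[chrom]
            if n_xo == 0:
                genotypes[i, sl] = start
            else:
                xo = np.sort(rng.uniform(0, genome.chrom_lengths[chrom], size=n_xo))
                genotypes[i, sl] = (start + np.searchsorted(xo, pos)) % 2
    mito = rng.random(n_segregants) < mito_prob
    ids = np.array([f"seg{i + 1:04d}" for i in range(n_segregants)])
    return SegregantSet(ids=ids, genotypes=genotypes, mito=mito, markers=markers)


def assign_phenotypes(
    segregants: SegregantSet,
    trait: TraitModel,
    seed: int | np.random.Generator | None = None,
) -> SegregantSet:
    """Assign phenotypes under the additive/epistatic trait model."""
    rng = as_rng(seed)
    n = len(segregants)
    phen = np.full(n, trait.midparent, dtype=float)
    for locus in trait.loci:
        idx = segregants.markers.index_of(locus.marker_id)  # KeyError if absent
        expressed = segregants.genotypes[:, idx] == 1
        if locus.requires_mito:
            expressed = expressed & segregants.mito
        if locus.requires_allele is not None:
            pidx = segregants.markers.index_of(locus.requires_allele)
            expressed = expressed & (segregants.genotypes[:, pidx] == 1)
        phen[expressed] += locus.effect
    if trait.residual_sd > 0:
        phen += rng.normal(0.0, trait.residual_sd, size=n)
    return replace(segregants, phenotype=phen)


def sample_pool_reads(
    pool: SegregantSet,
    mean_depth: float = 40.0,
    error_rate: float = 0.005,
    seed: int | np.random.Generator | None = None,
    qual: float = 100.0,
) -> pd.DataFrame:
    """Pooled sequencing read counts at every marker.

    Per marker the total depth is Poisson(``mean_depth``); each read comes
    from a uniformly chosen pool member (equal weighting, with
    replacement) and reports that member's allele, flipped with
    probability ``error_rate``.  Equivalently the variant-read count is
    Binomial(depth, f(1-e) + (1-f)e) with f the pool allele fraction.

    Returns a counts table with columns ``chrom, pos, depth, variant, qual``.
    """
    if len(pool) == 0:
        raise ValueError("pool is empty")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = as_rng(seed)
    f = pool.allele_frequency()
    p = f * (1.0 - error_rate) + (1.0 - f) * error_rate
    depth = rng.poisson(mean_depth, size=len(f))
    variant = rng.binomial(depth, p)
    df = pool.markers.df
    return pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "depth": depth,
            "variant": variant,
            "qual": float(qual),
        }
    )


def parent_pool(markers: MarkerMap, which: str) -> SegregantSet:
    """A one-member 'pool' holding a parent genome, for parent sequencing.

    The superior parent carries the variant (superior) allele at every
    marker under the polarized coding; the inferior parent carries none.
    """
    if which not in ("superior", "inferior"):
        raise ValueError("which must be 'superior' or 'inferior'")
    g = np.ones((1, len(markers)), dtype=np.int8) if which == "superior" else np.zeros(
        (1, len(markers)), dtype=np.int8
    )
    return SegregantSet(
        ids=np.array([f"{which}_parent"]),
        genotypes=g,
        mito=np.array([which == "inferior"]),  # the mutagenized parent lost respiration
        markers=markers,
    )


def select_lowest(segregants: SegregantSet, k: int) -> SegregantSet:
    """The k segregants with the lowest phenotype (the selected pool)."""
    if segregants.phenotype is None:
        raise ValueError("phenotypes not assigned")
    if not 0 < k <= len(segregants):
        raise ValueError("k must be in 1..n_segregants")
    order = np.argsort(segregants.phenotype, kind="stable")
    return segregants.subset(order[:k])


def default_trait_model(markers: MarkerMap, mito_prob: float = 1.0) -> TraitModel:
    """Three-locus default parameterization of the low ethyl acetate trait.

    Loci echo the mapped architecture: a plasma-membrane ATPase mutation
    (chrVII, -5 mg/L), a mitochondrial beta-keto-acyl synthase mutation
    (chrV, -3 mg/L) expressed only with functional mitochondria and a
    hidden induced partner allele (chrXIII), and a trehalose-pathway
    background allele on the superior parent's side (chrII, -16 mg/L).
    Each desired position is snapped to the nearest simulated marker of
    the matching class.
    """
    pma1_like = markers.nearest("chrVII", 482_216, INDUCED)
    cem1_like = markers.nearest("chrV", 278_369, INDUCED)
    partner = markers.nearest("chrXIII", 500_000, INDUCED)
    tps1_like = markers.nearest("chrII", 490_000, BACKGROUND)
    if len({pma1_like, cem1_like, partner, tps1_like}) < 4:
        warnings.warn("default causative loci collide on a sparse marker map")
    return TraitModel(
        loci=(
            CausativeLocus(tps1_like, -16.0),
            CausativeLocus(pma1_like, -5.0),
            CausativeLocus(cem1_like, -3.0, requires_mito=True, requires_allele=partner),
        ),
        mito_prob=mito_prob,
    )
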