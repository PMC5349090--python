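"""Marker count I/O, variant filters and the pooled frequency statistic.

A *counts table* (the in-memory form of one pool's or parent's sequencing
result) is a pandas DataFrame with columns::

    chrom    chromosome name (str)
    pos      1-based position (int)
    depth    total reads covering the site
    variant  reads supporting the superior-parent allele
    qual     site-level quality score (VCF QUAL)

Counts round-trip through VCF 4.2 with per-sample AD allele depths (one
pseudo-sample per pool or parent).  Filtering keeps sites covered by at
least 25 reads with quality at least 10; parent genotypes are called when
at least 90% of reads agree.  The SNP variant frequency is the exact
ratio variant/depth at each site.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeModel

logger = logging.getLogger("poolseg")

COUNT_COLUMNS = ["chrom", "pos", "depth", "variant", "qual"]

__all__ = [
    "read_counts",
    "write_counts",
    "filter_markers",
    "call_parent_variant",
    "compute_frequency",
    "informative_markers",
    "restrict_to_sites",
    "write_frequency_tsv",
]


class VcfFormatError(ValueError):
    """A VCF record lacks the fields this pipeline requires."""


def _check_counts(counts: pd.DataFrame) -> None:
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    if ((counts["variant"] < 0) | (counts["variant"] > counts["depth"])).any():
        raise ValueError("variant depth must satisfy 0 <= variant <= depth")


def read_counts(vcf_path: str) -> pd.DataFrame:
    """Read a counts table from a VCF with AD-style allele depths.

    One row per biallelic SNP record; multi-allelic records and indels are
    skipped with a logged tally (available as ``df.attrs['n_skipped']``).
    A record without a usable AD field raises :class:`VcfFormatError`
    naming the site.
    """
    rows: list[tuple] = []
    n_skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise VcfFormatError(f"{vcf_path}: no sample column with allele depths")
        sample = samples[0]
        for rec in vcf:
            alts = rec.alts or ()
            is_snp = (
                len(alts) == 1
                and rec.ref is not None
                and len(rec.ref) == 1
                and len(alts[0]) == 1
            )
            if not is_snp:
                n_skipped += 1
                continue
            ad = rec.samples[sample].get("AD")
            if ad is None or len(ad) < 2 or any(v is None for v in ad[:2]):
                raise VcfFormatError(
                    f"{vcf_path}: record {rec.chrom}:{rec.pos} has no AD allele depths"
                )
            ref_depth, var_depth = int(ad[0]), int(ad[1])
            rows.append(
                (rec.chrom, rec.pos, ref_depth + var_depth, var_depth,
                 float(rec.qual) if rec.qual is not None else 0.0)
            )
    if n_skipped:
        logger.info("read_counts(%s): skipped %d non-biallelic-SNP records", vcf_path, n_skipped)
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    df.attrs["n_skipped"] = n_skipped
    _check_counts(df)
    return df


def write_counts(
    counts: pd.DataFrame,
    vcf_path: str,
    genome: GenomeModel,
    sample: str = "pool",
    ref_alleles: np.ndarray | None = None,
    alt_alleles: np.ndarray | None = None,
) -> None:
    """Write a counts table as an uncompressed VCF 4.2 with one pseudo-sample.

    Allele labels default to A/T when the marker map is not supplied; the
    AD field carries (reference reads, variant reads).
    """
    _check_counts(counts)
    header = pysam.VariantHeader()
    for chrom, length in genome.chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("AD", "R", "Integer", "Allelic depths for the ref and alt alleles")
    header.add_sample(sample)
    n = len(counts)
    refs = ref_alleles if ref_alleles is not None else np.full(n, "A")
    alts = alt_alleles if alt_alleles is not None else np.full(n, "T")
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for i, row in enumerate(counts.itertuples(index=False)):
            rec = out.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,  # pysam is 0-based; file stays 1-based
                alleles=(str(refs[i]), str(alts[i])),
                qual=float(row.qual),
            )
            rec.samples[sample]["AD"] = (int(row.depth - row.variant), int(row.variant))
            out.write(rec)


def filter_markers(
    counts: pd.DataFrame, min_depth: int = 25, min_quality: float = 10.0
) -> pd.DataFrame:
    """Keep markers with depth >= min_depth and quality >= min_quality.

    Both boundaries are inclusive; row order is preserved.  Idempotent.
    """
    if min_depth < 0 or min_quality < 0:
        raise ValueError("filter thresholds must be >= 0")
    _check_counts(counts)
    keep = (counts["depth"] >= min_depth) & (counts["qual"] >= min_quality)
    out = counts.loc[keep].reset_index(drop=True)
    out.attrs["n_removed"] = int((~keep).sum())
    return out


def call_parent_variant(parent_counts: pd.DataFrame, min_fraction: float = 0.90) -> pd.DataFrame:
    """Call each marker in a parent sample as variant/reference/ambiguous.

    ``variant`` when at least ``min_fraction`` of reads carry the variant
    allele (boundary inclusive), ``reference`` when at most
    ``1 - min_fraction`` do, ``ambiguous`` otherwise (such markers are
    dropped from the informative set downstream).
    """
    _check_counts(parent_counts)
    if (parent_counts["depth"] <= 0).any():
        raise ValueError("parent counts must be depth-filtered before genotype calling")
    var_frac = parent_counts["variant"] / parent_counts["depth"]
    ref_frac = (parent_counts["depth"] - parent_counts["variant"]) / parent_counts["depth"]
    genotype = np.where(
        var_frac >= min_fraction, "variant",
        np.where(ref_frac >= min_fraction, "reference", "ambiguous"),
    )
    out = parent_counts.copy()
    out["genotype"] = genotype
    return out


def compute_frequency(counts: pd.DataFrame) -> pd.DataFrame:
    """SNP variant frequency: variant reads / total reads, per marker.

    Exact per-marker ratio, no smoothing.  Zero-depth rows reaching this
    stage violate the filtering contract and raise.
    """
    _check_counts(counts)
    if (counts["depth"] <= 0).any():
        raise RuntimeError("zero-depth marker reached compute_frequency; filter first")
    out = counts[["chrom", "pos", "variant", "depth"]].copy()
    out["freq"] = out["variant"] / out["depth"]
    return out


def informative_markers(
    superior_calls: pd.DataFrame, inferior_calls: pd.DataFrame
) -> pd.DataFrame:
    """Sites where the parents carry opposite homozygous alleles.

    Under the polarized coding (variant = superior-parent allele) a marker
    is informative when the superior parent is called ``variant`` and the
    inferior parent ``reference``.  Returns a (chrom, pos) site table.
    """
    sup = superior_calls.loc[superior_calls["genotype"] == "variant", ["chrom", "pos"]]
    inf = inferior_calls.loc[inferior_calls["genotype"] == "reference", ["chrom", "pos"]]
    return sup.merge(inf, on=["chrom", "pos"])


def restrict_to_sites(counts: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Subset a counts table to a (chrom, pos) site list, preserving order."""
    _check_counts(counts)
    merged = counts.merge(sites[["chrom", "pos"]], on=["chrom", "pos"])
    return merged.reset_index(drop=True)


def write_frequency_tsv(freq: pd.DataFrame, path: str) -> None:
    # %.17g keeps the exact variant/depth ratio round-trippable through text
    freq.to_csv(path, sep="\t", index=False, float_format="%.17g")
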