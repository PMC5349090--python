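"""End-to-end orchestration: simulate -> filter -> scan -> fine-map -> stats.

``run_pipeline`` drives the whole analysis from a :class:`RunConfig` and
persists every stage's inputs and outputs into a run directory:
parent/pool VCFs, frequency and smoothed-profile TSVs, the scan report,
the fine-mapping report, a ranked segregant table and a YAML summary.
All randomness flows from the single config seed through per-stage
substreams, so a run is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cross, finemap, markers as mio, scan, segstats
from .config import ConfigError, RunConfig, echo_config, validate_config
from .genome import GenomeModel

logger = logging.getLogger("poolseg")

__all__ = ["run_pipeline", "simulate_experiment", "analyze_experiment",
           "StageError", "SimulatedExperiment", "ScanResult"]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class SimulatedExperiment:
    """Everything the synthetic stage produces, before any filtering."""

    genome: GenomeModel
    markers: cross.MarkerMap
    trait: cross.TraitModel
    segregants: cross.SegregantSet  # phenotyped, all of them
    selected: cross.SegregantSet  # lowest-phenotype pool
    random: cross.SegregantSet  # random control pool
    counts: dict[str, pd.DataFrame]  # selected/random/superior_parent/inferior_parent


@dataclass
class ScanResult:
    """Filtered frequencies, smoothed profiles and QTL calls for both pools."""

    freq_selected: pd.DataFrame
    freq_random: pd.DataFrame
    smoothed_selected: pd.DataFrame
    smoothed_random: pd.DataFrame
    calls: pd.DataFrame
    report: pd.DataFrame
    n_informative: int


def _resolve_trait(cfg: RunConfig, marker_map: cross.MarkerMap) -> cross.TraitModel:
    t = cfg.trait
    if t.loci == "default":
        base = cross.default_trait_model(marker_map, mito_prob=t.mito_prob)
        loci = base.loci
    elif t.loci == "none":
        loci = ()
    else:
        loci = tuple(
            cross.CausativeLocus(
                marker_id=marker_map.nearest(l["chrom"], int(l["pos"]), l.get("klass")),
                effect=float(l["effect"]),
                requires_mito=bool(l.get("requires_mito", False)),
                requires_allele=(
                    marker_map.nearest(
                        l["partner"]["chrom"], int(l["partner"]["pos"]),
                        l["partner"].get("klass"),
                    )
                    if l.get("partner")
                    else None
                ),
            )
            for l in t.loci
        )
    return cross.TraitModel(
        superior_baseline=t.superior_baseline,
        inferior_baseline=t.inferior_baseline,
        loci=loci,
        residual_sd=t.residual_sd,
        mito_prob=t.mito_prob,
    )


def simulate_experiment(cfg: RunConfig) -> SimulatedExperiment:
    """Generate the full synthetic experiment for one seed."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_map, rng_meiosis, rng_phen, rng_pool, rng_seq = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    genome = GenomeModel(cm_per_kb=cfg.genome.cm_per_kb)
    marker_map = cross.build_parents(
        genome, cfg.markers.n_induced, cfg.markers.n_background, seed=rng_map
    )
    trait = _resolve_trait(cfg, marker_map)
    segregants = cross.simulate_meiosis(
        marker_map, genome, cfg.pools.n_segregants, trait.mito_prob, seed=rng_meiosis
    )
    segregants = cross.assign_phenotypes(segregants, trait, seed=rng_phen)
    selected = cross.select_lowest(segregants, cfg.pools.selected_size)
    random_idx = rng_pool.choice(
        len(segregants), size=cfg.pools.random_size, replace=False
    )
    random_pool = segregants.subset(np.sort(random_idx))
    counts = {
        "selected": cross.sample_pool_reads(
            selected, cfg.pools.pool_depth, cfg.pools.error_rate, seed=rng_seq
        ),
        "random": cross.sample_pool_reads(
            random_pool, cfg.pools.pool_depth, cfg.pools.error_rate, seed=rng_seq
        ),
        "superior_parent": cross.sample_pool_reads(
            cross.parent_pool(marker_map, "superior"),
            cfg.pools.parent_depth, cfg.pools.error_rate, seed=rng_seq,
        ),
        "inferior_parent": cross.sample_pool_reads(
            cross.parent_pool(marker_map, "inferior"),
            cfg.pools.parent_depth, cfg.pools.error_rate, seed=rng_seq,
        ),
    }
    return SimulatedExperiment(
        genome=genome, markers=marker_map, trait=trait, segregants=segregants,
        selected=selected, random=random_pool, counts=counts,
    )


def analyze_experiment(counts: dict[str, pd.DataFrame], cfg: RunConfig) -> ScanResult:
    """Filter markers, compute and smooth frequencies, call QTLs.

    ``counts`` maps selected/random/superior_parent/inferior_parent to
    counts tables (from the simulator or from VCFs).
    """
    f = cfg.filters
    filtered = {
        name: mio.filter_markers(c, f.min_depth, f.min_quality)
        for name, c in counts.items()
    }
    for name, c in filtered.items():
        logger.info("filter_markers(%s): %d markers retained (%d removed)",
                    name, len(c), c.attrs.get("n_removed", 0))
    sup_calls = mio.call_parent_variant(filtered["superior_parent"], f.parent_min_fraction)
    inf_calls = mio.call_parent_variant(filtered["inferior_parent"], f.parent_min_fraction)
    sites = mio.informative_markers(sup_calls, inf_calls)
    # informative markers must survive filters in both pools
    sites = sites.merge(filtered["selected"][["chrom", "pos"]], on=["chrom", "pos"])
    sites = sites.merge(filtered["random"][["chrom", "pos"]], on=["chrom", "pos"])
    logger.info("informative markers present in both pools and parents: %d", len(sites))
    freq_sel = mio.compute_frequency(mio.restrict_to_sites(filtered["selected"], sites))
    freq_rnd = mio.compute_frequency(mio.restrict_to_sites(filtered["random"], sites))
    sm_sel = scan.smooth_profile(freq_sel, cfg.scan.ci_level)
    sm_rnd = scan.smooth_profile(freq_rnd, cfg.scan.ci_level)
    calls = scan.call_qtls(
        sm_sel, cfg.scan.lower, cfg.scan.upper, cfg.scan.min_markers, cfg.scan.merge_gap
    )
    report = scan.report_linkage(calls, sm_sel, sm_rnd, cfg.scan.lower, cfg.scan.upper)
    return ScanResult(
        freq_selected=freq_sel, freq_random=freq_rnd,
        smoothed_selected=sm_sel, smoothed_random=sm_rnd,
        calls=calls, report=report, n_informative=len(sites),
    )


def _finemap_markers(result: ScanResult, per_region: int) -> list[str]:
    """Up to ``per_region`` evenly spaced informative markers per QTL call."""
    chosen: list[str] = []
    freq = result.freq_selected
    for call in result.calls.itertuples(index=False):
        sub = freq[
            (freq["chrom"] == call.chrom)
            & freq["pos"].between(call.start, call.end)
        ]
        take = min(per_region, len(sub))
        if take == 0:
            continue
        idx = np.unique(np.linspace(0, len(sub) - 1, take).round().astype(int))
        for row in sub.iloc[idx].itertuples(index=False):
            chosen.append(f"{row.chrom}:{row.pos}")
    return chosen


def _read_data_counts(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    d = cfg.data
    return {
        "selected": mio.read_counts(d.selected_vcf),
        "random": mio.read_counts(d.random_vcf),
        "superior_parent": mio.read_counts(d.superior_parent_vcf),
        "inferior_parent": mio.read_counts(d.inferior_parent_vcf),
    }


def run_pipeline(config: RunConfig | dict | None) -> Path:
    """Run every stage and persist results; returns the run directory."""
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"seed": cfg.seed, "mode": cfg.mode}
    try:
        echo_config(cfg, out / "config_echo.yaml")

        stage = "simulate"
        try:
            if cfg.mode == "synthetic":
                sim = simulate_experiment(cfg)
                counts = sim.counts
                sim.markers.df.to_csv(out / "markers.tsv", sep="\t", index=False)
                phen = sim.segregants.phenotype_frame()
                phen.to_csv(out / "segregants.tsv", sep="\t", index=False)
                mdf = sim.markers.df
                for name, fname in [
                    ("selected", "pool_selected.vcf"), ("random", "pool_random.vcf"),
                    ("superior_parent", "parent_superior.vcf"),
                    ("inferior_parent", "parent_inferior.vcf"),
                ]:
                    mio.write_counts(
                        counts[name], str(out / fname), sim.genome, sample=name,
                        ref_alleles=mdf["ref"].to_numpy(), alt_alleles=mdf["alt"].to_numpy(),
                    )
                summary["n_markers"] = len(sim.markers)
                summary["n_segregants"] = len(sim.segregants)
                summary["n_below_selection_cutoff"] = int(
                    (sim.segregants.phenotype < cfg.finemap.selection_cutoff).sum()
                )
                summary["causative_loci"] = [
                    {"marker": l.marker_id, "effect": l.effect,
                     "requires_mito": l.requires_mito, "partner": l.requires_allele}
                    for l in sim.trait.loci
                ]
            else:
                sim = None
                counts = _read_data_counts(cfg)
                phen = pd.read_csv(cfg.data.phenotypes_tsv, sep="\t")
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError(stage, exc) from exc

        stage = "scan"
        try:
            result = analyze_experiment(counts, cfg)
            mio.write_frequency_tsv(result.freq_selected, out / "freq_selected.tsv")
            mio.write_frequency_tsv(result.freq_random, out / "freq_random.tsv")
            result.smoothed_selected.to_csv(out / "smoothed_selected.tsv", sep="\t", index=False)
            result.smoothed_random.to_csv(out / "smoothed_random.tsv", sep="\t", index=False)
            result.report.to_csv(out / "scan_report.tsv", sep="\t", index=False)
            with open(out / "qtl_calls.bed", "w") as bed:
                for call in result.calls.itertuples(index=False):
                    bed.write(f"{call.chrom}\t{call.start - 1}\t{call.end}\t"
                              f"{call.direction}\t{call.peak_freq:.4f}\n")
            summary["n_informative_markers"] = result.n_informative
            summary["n_qtl_calls"] = int(len(result.calls))
            summary["thresholds"] = {"lower": cfg.scan.lower, "upper": cfg.scan.upper}
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        stage = "finemap"
        try:
            refined = finemap.refine_selection(
                phen[phen["segregant"].isin(
                    sim.selected.ids if sim is not None else phen["segregant"]
                )].reset_index(drop=True),
                cfg.finemap.refine_cutoff,
            )
            summary["n_refined_segregants"] = int(len(refined))
            summary["n_excluded_by_refinement"] = int(refined.attrs["n_excluded"])
            fm = pd.DataFrame()
            if sim is not None and len(result.calls) and len(refined):
                keep = np.isin(sim.selected.ids, refined["segregant"].to_numpy())
                subset = sim.selected.subset(np.flatnonzero(keep))
                marker_ids = _finemap_markers(result, cfg.finemap.markers_per_region)
                rng_score = np.random.default_rng(
                    np.random.SeedSequence(cfg.seed).spawn(6)[5]
                )
                matrix = finemap.score_alleles(
                    subset, marker_ids, cfg.finemap.missing_rate, seed=rng_score
                )
                matrix.to_csv(out / "allele_matrix.tsv", sep="\t")
                fm = finemap.finemap_region(matrix, cfg.finemap.alpha, cfg.finemap.bonferroni)
            fm.to_csv(out / "finemap.tsv", sep="\t", index=False)
            if len(fm):
                summary["top_finemap_marker"] = {
                    "marker": str(fm.iloc[0]["marker"]), "k": int(fm.iloc[0]["k"]),
                    "n": int(fm.iloc[0]["n"]), "p": float(fm.iloc[0]["p"]),
                }
                summary["n_significant_markers"] = int(fm["significant"].sum())
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        stage = "segstats"
        try:
            ranked = segstats.rank_segregants(phen)
            ranked.to_csv(out / "segregants_ranked.tsv", sep="\t", index=False)
            summary["lowest_segregant"] = {
                "id": str(ranked.iloc[0]["segregant"]),
                "phenotype": float(ranked.iloc[0]["phenotype"]),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        with open(out / "summary.yaml", "w") as fh:
            yaml.safe_dump(summary, fh, sort_keys=False)
        logger.info("run complete: %s", out)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
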