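"""Genotype-phenotype table analytics for individually scored segregants.

Works on a *segregant table*: one row per segregant with allele calls at
named loci (e.g. PMA1, CEM1), a phenotype mean (mg/L ethyl acetate) and a
replicate standard deviation.  The packaged fixture is the published
44-segregant table of the mutagenized-parent x S288c cross, scored at
PMA1 and CEM1 by Sanger sequencing, in which the five lowest producers
all carry both superior (mutant-parent) alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "load_table1",
    "rank_segregants",
    "crosstab_top",
    "compare_groups",
    "enrichment_test",
    "GroupComparison",
]

#: allele label of the low-ethyl-acetate (superior) parent in the fixture
SUPERIOR_LABEL = "TDA1(4)"

_FIXTURE = "table1_tda1_s288c_segregants.tsv"


def load_table1() -> pd.DataFrame:
    """Load the packaged 44-segregant PMA1/CEM1 genotype-phenotype table."""
    with resources.files("poolseg.data").joinpath(_FIXTURE).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df = df.rename(columns={"ethyl_acetate_mg_per_l": "phenotype"})
    df.attrs["superior_label"] = SUPERIOR_LABEL
    df.attrs["loci"] = ["PMA1", "CEM1"]
    return df


def rank_segregants(table: pd.DataFrame) -> pd.DataFrame:
    """Rows sorted by ascending phenotype mean; ties broken by segregant id."""
    if table["phenotype"].isna().any():
        raise ValueError("phenotype missing for some segregants")
    return table.sort_values(
        ["phenotype", "segregant"], kind="stable"
    ).reset_index(drop=True)


def crosstab_top(
    table: pd.DataFrame,
    k: int,
    loci: list[str],
    superior_label: str | None = None,
) -> int:
    """Among the k lowest producers, count carriers of the superior allele at ALL loci."""
    if k > len(table):
        raise ValueError(f"k={k} exceeds table size {len(table)}")
    label = superior_label or table.attrs.get("superior_label", SUPERIOR_LABEL)
    for locus in loci:
        if locus not in table.columns:
            raise KeyError(f"locus {locus!r} not scored in table")
    if k == 0:
        return 0
    top = rank_segregants(table).head(k)
    mask = np.ones(len(top), dtype=bool)
    for locus in loci:
        mask &= (top[locus] == label).to_numpy()
    return int(mask.sum())


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group t-test or a one-way ANOVA with Tukey post-hoc."""

    design: str  # "two-group" | "multi-group"
    statistic: float  # t or F
    pvalue: float
    tukey: pd.DataFrame | None = None  # pairwise adjusted p-values (multi-group)


def compare_groups(
    groups: list[np.ndarray], equal_var: bool = True
) -> GroupComparison:
    """Compare phenotype vectors: unpaired two-sided t-test or ANOVA + Tukey.

    Two groups: Student t-test (pooled variance by default; set
    ``equal_var=False`` for Welch).  Three or more: one-way ANOVA F-test
    plus Tukey HSD pairwise adjusted p-values.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    if len(arrays) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=equal_var)
        return GroupComparison("two-group", float(t), float(p))
    f, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([np.full(len(g), f"group{i}") for i, g in enumerate(arrays)])
    tk = pairwise_tukeyhsd(values, labels)
    tukey_df = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return GroupComparison("multi-group", float(f), float(p), tukey=tukey_df)


def enrichment_test(
    table: pd.DataFrame,
    locus: str,
    cutoff: float,
    superior_label: str | None = None,
) -> float:
    """Fisher exact two-sided p for superior-allele x sub-cutoff association.

    Formalizes the qualitative top-of-table argument as a 2x2 exact test
    (allele call x phenotype strictly below/at-or-above cutoff).  A
    degenerate margin (all rows on one side) returns p = 1 with a warning.
    """
    if locus not in table.columns:
        raise KeyError(f"locus {locus!r} not scored in table")
    if table[locus].isna().any():
        raise ValueError(f"locus {locus!r} not scored for every segregant")
    label = superior_label or table.attrs.get("superior_label", SUPERIOR_LABEL)
    superior = (table[locus] == label).to_numpy()
    below = (table["phenotype"] < cutoff).to_numpy()
    tab = np.array(
        [
            [int((superior & below).sum()), int((superior & ~below).sum())],
            [int((~superior & below).sum()), int((~superior & ~below).sum())],
        ]
    )
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 margin; association undefined, returning p=1")
        return 1.0
    return float(stats.fisher_exact(tab, alternative="two-sided")[1])
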