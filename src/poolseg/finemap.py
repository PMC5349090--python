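"""Fine-mapping: phenotype cutoffs and exact-binomial marker tests.

After the genome scan, individual segregants from the selected pool are
re-thresholded with a stricter phenotype cutoff and their genotypes at
markers inside called QTL regions are tested against the 1:1 Mendelian
segregation expectation with a two-sided exact binomial test.  The
two-sided p-value uses the minimum-likelihood convention: it sums the
probabilities of all outcomes no more probable than the observed one.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cross import SegregantSet

logger = logging.getLogger("poolseg")

__all__ = [
    "select_segregants",
    "refine_selection",
    "binomial_exact_test",
    "score_alleles",
    "finemap_region",
]

SUPERIOR, INFERIOR, MISSING = "S", "I", "NA"


def select_segregants(phenotypes: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Segregants with phenotype strictly below ``cutoff`` (mg/L).

    The returned table carries ``attrs['n_excluded']``, the number of
    input rows at or above the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if not np.all(np.isfinite(phenotypes["phenotype"])):
        raise ValueError("phenotypes must be finite")
    keep = phenotypes["phenotype"] < cutoff
    out = phenotypes.loc[keep].reset_index(drop=True)
    out.attrs["n_excluded"] = int((~keep).sum())
    if out.empty:
        logger.warning("selection cutoff %.3g mg/L retains no segregants", cutoff)
    return out


def refine_selection(phenotypes: pd.DataFrame, cutoff: float = 16.3) -> pd.DataFrame:
    """Tighten the selected set with a stricter phenotype cutoff.

    Identical contract to :func:`select_segregants`; kept as a named stage
    because the scan-pool cutoff (default 20 mg/L) and the fine-mapping
    cutoff (default 16.3 mg/L, the superior parent's highest measured
    value) are distinct tunables.
    """
    out = select_segregants(phenotypes, cutoff)
    logger.info(
        "refine_selection: cutoff %.3g mg/L excluded %d of %d segregants",
        cutoff, out.attrs["n_excluded"], len(phenotypes),
    )
    return out


def binomial_exact_test(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood convention).

    Sums Binomial(n, p0) point probabilities over every outcome whose
    probability does not exceed that of the observed ``k`` (with a tiny
    relative tolerance to keep exactly tied outcomes, e.g. the symmetric
    n-k at p0=1/2, in the rejection set).  Symmetric in k <-> n-k when
    p0 = 1/2; p(n, n) = 2 * p0**n there.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n and n >= 1, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if p0 == 0.5:
        # dyadic case: integer arithmetic keeps the tail sum exact
        from math import comb

        ck = comb(n, k)
        total = sum(comb(n, j) for j in range(n + 1) if comb(n, j) <= ck)
        return min(total / 2**n, 1.0)
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    p = float(pmf[pmf <= pmf[k] * (1.0 + 1e-7)].sum())
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def score_alleles(
    segregants: SegregantSet,
    marker_ids: list[str],
    missing_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Allele matrix (segregants x markers) with S/I/NA entries.

    Abstraction of allele-specific PCR scoring: entries are read off the
    simulated genotypes, then masked missing independently with
    ``missing_rate``.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    from .cross import as_rng

    rng = as_rng(seed)
    cols = {}
    for mid in marker_ids:
        idx = segregants.markers.index_of(mid)  # KeyError for unknown markers
        calls = np.where(segregants.genotypes[:, idx] == 1, SUPERIOR, INFERIOR)
        if missing_rate > 0:
            calls = np.where(rng.random(len(calls)) < missing_rate, MISSING, calls)
        cols[mid] = calls
    return pd.DataFrame(cols, index=pd.Index(segregants.ids, name="segregant"))


def finemap_region(
    matrix: pd.DataFrame, alpha: float = 0.01, bonferroni: bool = False
) -> pd.DataFrame:
    """Exact-binomial segregation test for every scored marker.

    For each marker, k = segregants carrying the superior allele among the
    n non-missing calls; markers with n = 0 are dropped with a warning.
    Returns one row per marker (chrom, pos, k, n, p, significant), ranked
    by ascending p-value.  ``bonferroni`` divides alpha by the marker
    count (off by default; the reference analysis uses a fixed line).
    """
    if matrix.empty:
        raise ValueError("allele matrix is empty")
    rows = []
    for mid in matrix.columns:
        col = matrix[mid]
        n = int((col != MISSING).sum())
        if n == 0:
            logger.warning("marker %s has no scored segregants; dropped", mid)
            continue
        k = int((col == SUPERIOR).sum())
        chrom, pos = str(mid).rsplit(":", 1)
        rows.append({"marker": mid, "chrom": chrom, "pos": int(pos), "k": k, "n": n,
                     "p": binomial_exact_test(k, n)})
    out = pd.DataFrame(rows, columns=["marker", "chrom", "pos", "k", "n", "p"])
    if out.empty:
        return out.assign(significant=pd.Series(dtype=bool))
    level = alpha / len(out) if bonferroni else alpha
    out["significant"] = out["p"] <= level
    return out.sort_values("p", kind="stable").reset_index(drop=True)
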