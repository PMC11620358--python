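"""Fold-change arithmetic tying localization scores to mutant stabilization.

Covers the bookkeeping around differential expression that does not require a
dispersion model: CPM-based log2 fold changes, maternal/zygotic
classification across the maternal-to-zygotic transition (MZT),
intron-adjusted fold changes that separate transcriptional from
post-transcriptional effects, gene-set fractions, 2x2 chi-square enrichment,
and two-sample Kolmogorov-Smirnov comparison of fold-change distributions.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: CPM threshold above which a gene counts as expressed in a condition.
EXPRESSED_CPM = 1.0


def cpm(counts: pd.Series | np.ndarray) -> np.ndarray:
    """Counts per million mapped reads for one sample."""
    counts = np.asarray(counts, dtype=float)
    libsize = counts.sum()
    if libsize <= 0:
        raise ValueError("zero library size")
    return 1e6 * counts / libsize


def cpm_log2fc(
    counts: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene log2 fold change B vs A on the CPM scale.

    Returns a DataFrame indexed by gene with columns ``cpmA``, ``cpmB``,
    ``lfc`` = log2((cpmB + pc) / (cpmA + pc)), and ``expressed`` (CPM >= 1 in
    the reference sample A).
    """
    cpm_a = cpm(counts[sample_a])
    cpm_b = cpm(counts[sample_b])
    lfc = np.log2((cpm_b + pseudocount) / (cpm_a + pseudocount))
    return pd.DataFrame(
        {"cpmA": cpm_a, "cpmB": cpm_b, "lfc": lfc,
         "expressed": cpm_a >= EXPRESSED_CPM},
        index=counts.index,
    )


def classify_mz(records: pd.DataFrame, lfc_col: str = "lfc") -> pd.DataFrame:
    """Classify expressed genes as maternal, zygotic, or maternal-zygotic.

    The fold change must be wild-type 6 hpf vs 1 hpf.  Genes changing more
    than 2-fold down (lfc < -1) are predominantly maternal, more than 2-fold
    up (lfc > +1) zygotic, all other expressed genes maternal-zygotic;
    boundaries are exclusive (|lfc| exactly 1 stays maternal-zygotic).
    Unexpressed genes get NA.
    """
    out = records.copy()
    lfc = out[lfc_col]
    cls = np.select(
        [lfc < -1.0, lfc > 1.0],
        ["maternal", "zygotic"],
        default="maternal-zygotic",
    )
    out["mz_class"] = np.where(out["expressed"], cls, None)
    return out


def intron_adjusted_lfc(
    transcript_level: pd.DataFrame,
    exon_level: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Mature-mRNA fold change corrected for the pre-mRNA (intron) fold change.

    Intron counts are transcript-level counts minus exon-level counts, floored
    at 0 (negative differences are counting-model noise and are flagged).
    The adjusted change is ``lfc_mature - lfc_intron`` on the log2 scale; a
    purely transcriptional change moves both terms equally and cancels.
    Genes whose intron coverage is below 1 CPM in the reference sample are
    reported NA: their intron fold change is too noisy to subtract.
    """
    common = transcript_level.index.intersection(exon_level.index)
    tx = transcript_level.loc[common, [sample_a, sample_b]]
    ex = exon_level.loc[common, [sample_a, sample_b]]
    diff = tx.to_numpy() - ex.to_numpy()
    floored = (diff < 0).any(axis=1)
    intron = pd.DataFrame(np.maximum(diff, 0), index=common, columns=[sample_a, sample_b])
    mature = cpm_log2fc(ex, sample_a, sample_b, pseudocount)
    intron_fc = cpm_log2fc(intron, sample_a, sample_b, pseudocount)
    adjusted = mature["lfc"] - intron_fc["lfc"]
    low_intron = intron_fc["cpmA"] < EXPRESSED_CPM
    adjusted[low_intron] = np.nan
    return pd.DataFrame(
        {
            "lfc_mature": mature["lfc"],
            "lfc_intron": intron_fc["lfc"],
            "adjusted_lfc": adjusted,
            "intron_low_coverage": low_intron,
            "intron_floored": floored,
        },
        index=common,
    )


def set_fraction(
    universe: Iterable[str],
    subset: Iterable[str],
    marked: Iterable[str],
) -> float:
    """Percentage of a gene subset that carries a mark.

    Returns ``100 * |subset & marked| / |subset|`` rounded to one decimal, or
    two decimals when the subset exceeds 10,000 genes (large denominators
    deserve the extra digit).
    """
    universe, subset, marked = set(universe), set(subset), set(marked)
    if not subset:
        raise ValueError("empty subset")
    if not subset <= universe:
        raise ValueError("subset is not contained in the universe")
    pct = 100.0 * len(subset & marked) / len(subset)
    decimals = 2 if len(subset) > 10_000 else 1
    return round(pct, decimals)


def enrichment_chisq(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def ecdf_ks(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
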