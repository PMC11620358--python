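"""mRNA half-life estimation from BRIC-Seq pulse-chase time courses.

BRIC-Seq follows the decay of bromouridine-labeled mRNA after a chase, with
samples at 0, 2, 4, 6, 10, and 24 h.  Per-gene log2 fold changes versus the
0 h sample are first renormalized to the mean change of spiked-in control
RNAs (removing global recovery drift), then fitted by ordinary least squares
in log2 space.  Because decay often slows at late chase times, the line is
fitted to every nested prefix of the time course (0-4 h, 0-6 h, 0-10 h,
0-24 h) and the prefix with the highest R^2 wins; the half-life is -1/slope
hours.  A fit is reliable when R^2 > 0.9 and 0 < t1/2 < 24 h (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_TIMEPOINTS = (0.0, 2.0, 4.0, 6.0, 10.0, 24.0)

#: two prefix R^2 values closer than this are treated as tied, and the longer
#: prefix wins the tie.
R2_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PrefixFit:
    """OLS fit of log2 fold change on time over one prefix of the course."""

    end_time: float
    n_points: int
    slope: float
    intercept: float
    r2: float
    half_life: float  # hours; NaN when slope >= 0

    @property
    def reliable(self) -> bool:
        return self.r2 > 0.9 and 0.0 < self.half_life < 24.0


@dataclass
class DecayFit:
    """All prefix fits for one gene plus the selected best fit."""

    gene: str
    fits: list[PrefixFit] = field(default_factory=list)
    selected: PrefixFit | None = None

    @property
    def reliable(self) -> bool:
        return self.selected is not None and self.selected.reliable


def spikein_renormalize(
    lfc: pd.DataFrame,
    is_spikein: pd.Series,
) -> pd.DataFrame:
    """Subtract the per-timepoint mean spike-in log2 fold change from all rows.

    The arithmetic mean of log2 changes (the geometric mean on the linear
    scale) of the spike-ins estimates the global recovery drift at each
    timepoint; subtracting it leaves the spike-in mean at 0 and preserves all
    between-gene differences.  Idempotent.
    """
    spike = lfc.loc[is_spikein.reindex(lfc.index, fill_value=False)]
    if spike.empty:
        raise ValueError("no spike-in rows to renormalize against")
    return lfc - spike.mean(axis=0)


def fit_halflife(
    gene: str,
    timepoints: Sequence[float],
    log2fc: Sequence[float],
    min_points: int = 3,
    hl_max: float = 24.0,
) -> DecayFit:
    """Fit nested-prefix decay lines and select the maximum-R^2 prefix.

    Every prefix with at least ``min_points`` timepoints (the 0 h point
    included as an ordinary observation, intercept free) is fitted by OLS.
    R^2 is the squared Pearson correlation of fitted versus observed values.
    On (numerically) tied R^2 the longest prefix is selected.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(log2fc, dtype=float)
    if t.size != y.size:
        raise ValueError("timepoints and log2fc lengths differ")
    if np.any(np.diff(t) <= 0) or t[0] != 0:
        raise ValueError("timepoints must be strictly increasing starting at 0")
    fit = DecayFit(gene)
    for end in range(min_points, t.size + 1):
        tt, yy = t[:end], y[:end]
        if np.ptp(yy) == 0:
            # a perfectly flat prefix: slope 0, correlation undefined -> R2 0
            slope, intercept, r2 = 0.0, float(yy[0]), 0.0
        else:
            res = stats.linregress(tt, yy)
            slope, intercept = float(res.slope), float(res.intercept)
            r2 = float(res.rvalue) ** 2
        half_life = -1.0 / slope if slope < 0 else float("nan")
        fit.fits.append(PrefixFit(float(tt[-1]), end, slope, intercept, r2, half_life))
    if not fit.fits:
        raise ValueError(f"{gene}: fewer than {min_points} timepoints")
    best = fit.fits[0]
    for pf in fit.fits[1:]:
        if pf.r2 >= best.r2 - R2_TIE_TOL:  # later prefixes are longer
            best = pf
    fit.selected = best
    return fit


def fit_halflife_table(
    lfc: pd.DataFrame,
    is_spikein: pd.Series | None = None,
    timepoints: Sequence[float] | None = None,
    renormalize: bool = True,
) -> pd.DataFrame:
    """Fit every gene in a course table; returns one row per gene.

    ``lfc`` is genes x timepoints (columns coercible to hours).  When
    ``is_spikein`` is given and ``renormalize`` is True, courses are spike-in
    renormalized first and the spike-in rows are excluded from the output.
    """
    if timepoints is None:
        timepoints = [float(c) for c in lfc.columns]
    if is_spikein is not None and renormalize:
        lfc = spikein_renormalize(lfc, is_spikein)
    rows = []
    for gene, row in lfc.iterrows():
        if is_spikein is not None and bool(is_spikein.get(gene, False)):
            continue
        fit = fit_halflife(str(gene), timepoints, row.to_numpy())
        sel = fit.selected
        rows.append({
            "gene": gene,
            "slope": sel.slope,
            "intercept": sel.intercept,
            "r2": sel.r2,
            "half_life": sel.half_life,
            "prefix_end_h": sel.end_time,
            "reliable": sel.reliable,
        })
    return pd.DataFrame(rows).set_index("gene")


def filter_reliable(fits: pd.DataFrame) -> pd.DataFrame:
    """Rows passing the reliability filter: R^2 > 0.9 and 0 < t1/2 < 24 h."""
    keep = (fits["r2"] > 0.9) & (fits["half_life"] > 0.0) & (fits["half_life"] < 24.0)
    return fits[keep.fillna(False)]


def halflife_fold_change(
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
) -> tuple[pd.Series, int]:
    """Per-gene log2(t1/2 B / t1/2 A) for genes reliable in both conditions.

    Returns the fold-change series and the number of genes excluded for being
    missing or unreliable in either condition.
    """
    rel_a = filter_reliable(fits_a)
    rel_b = filter_reliable(fits_b)
    common = rel_a.index.intersection(rel_b.index)
    n_excluded = len(fits_a.index.union(fits_b.index)) - len(common)
    ratio = np.log2(rel_b.loc[common, "half_life"] / rel_a.loc[common, "half_life"])
    return ratio.rename("log2_halflife_fc"), int(n_excluded)
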