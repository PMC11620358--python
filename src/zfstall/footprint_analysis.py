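"""Per-codon footprint tracks, disome occupancy, and the disome localization score.

Disome (collided-ribosome) footprints report where ribosomes stall.  Rather
than calling sharp single-codon peaks, the localization score asks what
fraction of a transcript's disome reads fall inside its C2H2-ZF domain
codons: a domain-wise measure that is high when collisions cluster on the
zinc fingers and low when they are scattered or domain-independent.

Conventions: coordinates are 0-based half-open; codon ``i`` covers
nucleotides ``[3i, 3i+3)``; disome counts are indexed by the A-site codon of
the leading (stalled) ribosome.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: the 61 sense codons (DNA alphabet), i.e. all codons minus the three stops.
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "TCAG" for b in "TCAG" for c in "TCAG"
    if a + b + c not in STOP_CODONS
)

#: default 5'-end -> A-site offsets in nucleotides.  The disome offset places
#: the A-site of the leading ribosome, which sits ~45 nt into the ~60 nt
#: two-ribosome footprint.
DEFAULT_ASITE_OFFSETS = {"monosome": 15, "disome": 45}


class ZeroCoverageError(ValueError):
    """The normalization region of a track has no reads."""


@dataclass
class CodonTrack:
    """Per-codon monosome and disome A-site counts for one ORF (stop included)."""

    transcript_id: str
    monosome: np.ndarray
    disome: np.ndarray

    def __post_init__(self) -> None:
        self.monosome = np.asarray(self.monosome, dtype=np.int64)
        self.disome = np.asarray(self.disome, dtype=np.int64)
        if self.monosome.shape != self.disome.shape or self.monosome.ndim != 1:
            raise ValueError(f"{self.transcript_id}: track vectors must be 1-D and equal length")
        if self.monosome.size == 0:
            raise ValueError(f"{self.transcript_id}: empty track")
        if (self.monosome < 0).any() or (self.disome < 0).any():
            raise ValueError(f"{self.transcript_id}: negative counts")

    @property
    def n_codons(self) -> int:
        return int(self.disome.size)


@dataclass(frozen=True)
class DomainMask:
    """Non-overlapping, sorted codon intervals covering C2H2-ZF frames.

    Protein coordinates map directly onto codons (amino acid i <-> codon i).
    """

    transcript_id: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        ivs = tuple((int(a), int(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        prev_end = -1
        for a, b in ivs:
            if not 0 <= a < b:
                raise ValueError(f"{self.transcript_id}: bad interval [{a}, {b})")
            if a < prev_end:
                raise ValueError(f"{self.transcript_id}: intervals overlap or are unsorted")
            prev_end = b

    def selector(self, n_codons: int) -> np.ndarray:
        """Boolean vector of length ``n_codons`` marking in-domain codons."""
        sel = np.zeros(n_codons, dtype=bool)
        for a, b in self.intervals:
            if b > n_codons:
                raise ValueError(
                    f"{self.transcript_id}: interval [{a}, {b}) exceeds ORF of {n_codons} codons"
                )
            sel[a:b] = True
        return sel


@dataclass
class LocalizationScore:
    """Fraction of a transcript's disome reads that fall on its ZF domains."""

    transcript_id: str
    domain_reads: int
    total_reads: int
    score: float
    group: str  # high | middle | low | unscored | ungrouped
    domain_free: bool = False


def assign_asite(
    read_5p_position: int,
    read_length: int,
    footprint_class: str,
    offsets: Mapping[str, int] = DEFAULT_ASITE_OFFSETS,
) -> int:
    """Map a read 5' position (nt into the ORF) to its A-site codon index.

    The caller is responsible for dropping (and tallying) indices that fall
    outside ``[0, n_codons)``.
    """
    if read_5p_position < 0 or read_length < 0:
        raise ValueError("negative read position or length")
    return (read_5p_position + offsets[footprint_class]) // 3


def disome_occupancy(
    track: CodonTrack,
    mask: DomainMask | None = None,
    region: str = "all",
) -> np.ndarray:
    """Per-codon disome occupancy: counts over the mean count in a region.

    ``region="all"`` normalizes by the mean over the whole ORF;
    ``region="domains"`` by the mean over the mask's codons.  The mean
    occupancy over the normalization region is 1 by construction.
    """
    if region == "all":
        sel = np.ones(track.n_codons, dtype=bool)
    elif region == "domains":
        if mask is None:
            raise ValueError("region='domains' requires a mask")
        sel = mask.selector(track.n_codons)
    else:
        raise ValueError(f"unknown region {region!r}")
    denom = track.disome[sel].mean() if sel.any() else 0.0
    if denom == 0:
        raise ZeroCoverageError(f"{track.transcript_id}: no reads in normalization region")
    return track.disome / denom


def localization_score(
    track: CodonTrack,
    mask: DomainMask,
    min_reads: int = 10,
) -> LocalizationScore:
    """Disome localization score: domain reads / total ORF reads.

    Transcripts with fewer than ``min_reads`` disome reads on the ORF are
    flagged ``unscored`` (their score is still reported when defined).  An
    empty mask gives score 0 with the ``domain_free`` flag set.
    """
    total = int(track.disome.sum())
    if not mask.intervals:
        return LocalizationScore(track.transcript_id, 0, total, 0.0,
                                 "unscored", domain_free=True)
    sel = mask.selector(track.n_codons)
    domain = int(track.disome[sel].sum())
    score = domain / total if total > 0 else 0.0
    group = "ungrouped" if total >= min_reads else "unscored"
    return LocalizationScore(track.transcript_id, domain, total, score, group)


def region_read_fraction(
    track: CodonTrack,
    interval: tuple[int, int],
    which: str = "disome",
) -> float:
    """Fraction of a track's reads falling inside one codon interval."""
    counts = getattr(track, which)
    a, b = interval
    if not 0 <= a <= b <= track.n_codons:
        raise ValueError(f"interval [{a}, {b}) outside ORF of {track.n_codons} codons")
    total = counts.sum()
    if total == 0:
        raise ZeroCoverageError(f"{track.transcript_id}: no {which} reads")
    return float(counts[a:b].sum() / total)


def group_by_score(
    scores: Sequence[LocalizationScore],
    n_groups: int = 3,
) -> list[LocalizationScore]:
    """Split scored transcripts into balanced rank groups (high/middle/low).

    Transcripts are ranked by descending score, ties broken by ascending
    transcript_id; group sizes differ by at most one, with the extra members
    going to the higher groups.  Unscored transcripts pass through unchanged.
    """
    labels3 = ("high", "middle", "low")
    if n_groups == 3:
        labels = labels3
    else:
        labels = tuple(f"g{i}" for i in range(n_groups))
    scored = [s for s in scores if s.group != "unscored"]
    if len(scored) < n_groups:
        raise ValueError(f"need at least {n_groups} scored transcripts, have {len(scored)}")
    order = sorted(scored, key=lambda s: (-s.score, s.transcript_id))
    base, extra = divmod(len(order), n_groups)
    out: dict[str, LocalizationScore] = {}
    idx = 0
    for g, label in enumerate(labels):
        size = base + (1 if g < extra else 0)
        for s in order[idx:idx + size]:
            out[s.transcript_id] = replace(s, group=label)
        idx += size
    return [out.get(s.transcript_id, s) for s in scores]


def call_peaks_simple(
    track: CodonTrack,
    z_threshold: float = 4.0,
    min_count: int = 5,
) -> list[int]:
    """Simplified disome peak caller: codons that are strong track outliers.

    A codon is a peak when its disome count is at least ``min_count`` and at
    least ``z_threshold`` track standard deviations above the track mean.
    This is a deliberately simple threshold rule, not a reimplementation of
    published peak-calling procedures, and is not claimed to be equivalent to
    them.
    """
    d = track.disome.astype(float)
    mean = d.mean()
    if mean <= 0:
        raise ZeroCoverageError(f"{track.transcript_id}: empty track")
    sd = d.std(ddof=0)
    if sd == 0:
        return []
    z = (d - mean) / sd
    return [int(i) for i in np.flatnonzero((track.disome >= min_count) & (z >= z_threshold))]


def site_occupancy_pairs(
    tracks: Mapping[str, CodonTrack],
    masks: Mapping[str, DomainMask],
    cds_sequences: Mapping[str, str],
    min_asite: int = 2,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Mean disome occupancy per sense codon at the A/P/E sites of the leader.

    For each of the 61 sense codons, the mean occupancy is computed over all
    codon positions decoded at the A-site (and, one and two codons behind, the
    P- and E-sites) of the leading ribosome, in two normalization regions:
    the whole ORF and the ZF domains.  Positions with A-site index below
    ``min_asite`` are excluded so the P/E sites stay inside the ORF.

    Returns a tidy table (codon, site, occ_all, occ_domain) and the Spearman
    rank correlation between the two regions per site, computed on codons
    observed in both.
    """
    sites = {"A": 0, "P": 1, "E": 2}
    acc: dict[tuple[str, str, str], list[float]] = {}
    for tid, track in tracks.items():
        seq = cds_sequences[tid].upper().replace("U", "T")
        codons = [seq[3 * i:3 * i + 3] for i in range(len(seq) // 3)]
        try:
            occ_all = disome_occupancy(track, region="all")
        except ZeroCoverageError:
            continue
        mask = masks.get(tid)
        occ_dom = None
        dom_sel = None
        if mask is not None and mask.intervals:
            try:
                occ_dom = disome_occupancy(track, mask, region="domains")
                dom_sel = mask.selector(track.n_codons)
            except ZeroCoverageError:
                pass
        for i in range(min_asite, min(len(codons), track.n_codons)):
            for site, back in sites.items():
                codon = codons[i - back]
                if codon not in SENSE_CODONS:
                    continue
                acc.setdefault((codon, site, "all"), []).append(occ_all[i])
                if occ_dom is not None and dom_sel[i]:
                    acc.setdefault((codon, site, "domain"), []).append(occ_dom[i])
    rows = []
    for codon in SENSE_CODONS:
        for site in sites:
            v_all = acc.get((codon, site, "all"))
            v_dom = acc.get((codon, site, "domain"))
            rows.append({
                "codon": codon,
                "site": site,
                "occ_all": float(np.mean(v_all)) if v_all else np.nan,
                "occ_domain": float(np.mean(v_dom)) if v_dom else np.nan,
            })
    table = pd.DataFrame(rows)
    rho: dict[str, float] = {}
    for site in sites:
        sub = table[table["site"] == site].dropna(subset=["occ_all", "occ_domain"])
        if len(sub) >= 2:
            rho[site] = float(stats.spearmanr(sub["occ_all"], sub["occ_domain"]).statistic)
        else:
            rho[site] = float("nan")
    return table, rho


def masks_from_hits(
    hits: Iterable,
    protein_to_transcript: Mapping[str, str] | None = None,
    canonical_only: bool = True,
) -> dict[str, DomainMask]:
    """Build codon-coordinate domain masks from protein-level domain hits.

    Amino acid i corresponds to codon i, so protein frames translate to codon
    intervals unchanged.  By default only canonical 28-aa frames are kept,
    matching the convention that localization scores use 28-aa domains only.
    """
    per_tx: dict[str, list[tuple[int, int]]] = {}
    for hit in hits:
        if canonical_only and not hit.is_canonical_28:
            continue
        tid = (protein_to_transcript or {}).get(hit.protein_id, hit.protein_id)
        per_tx.setdefault(tid, []).append((hit.frame_start, hit.frame_end))
    out: dict[str, DomainMask] = {}
    for tid, ivs in per_tx.items():
        # Adjacent raw matches can yield touching or overlapping 28-aa frames;
        # merge them so the mask stays a valid non-overlapping interval set.
        merged: list[tuple[int, int]] = []
        for a, b in sorted(ivs):
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        out[tid] = DomainMask(tid, tuple(merged))
    return out
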