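"""Seeded synthetic data with ground truth for every recoverable quantity.

The generator emulates the statistical structure the analysis assumes:

* transcriptomes in which zinc-finger transcripts carry tandem canonical
  28-aa C2H2 domains (invariant Cys/His coordination residues, Lys/Arg-rich
  linkers) while control transcripts contain no pattern match;
* per-codon footprint tracks with Poisson counts, disome rates elevated
  inside domains and optionally coupled to upstream nascent-chain charge;
* two-genotype (wild-type vs mutant) expression counts at two stages in
  which high-localization-score transcripts are stabilized in the mutant;
* exponential BRIC-Seq decay courses with spike-ins, a shared recovery
  drift, and multiplicative log-normal noise.

Every dataset is reproducible from its seed and ships a ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domain_annotation import CANONICAL_FRAME_LEN, LEHNINGER, ProteinRecord, net_charge
from .footprint_analysis import CodonTrack, DomainMask

#: residues sampled at unconstrained domain/linker positions.  C and H are
#: excluded so the only scanner matches are the planted ones; Lys/Arg are
#: up-weighted to give the positively charged character of real C2H2-ZF
#: proteins.
_BODY_RESIDUES = np.array(list("ADEFGIKLMNPQRSTVWYKRKR"))
#: hydrophobic-position choices (C excluded to keep interiors inert).
_PHI_RESIDUES = np.array(list("LIVMFYW"))
#: control proteins: no cysteine at all, so no match is possible.
_CONTROL_RESIDUES = np.array(list("ADEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    """Knobs of the simulated study, with the study's conditions as defaults."""

    seed: int
    n_zf_transcripts: int = 50
    n_control_transcripts: int = 50
    domains_per_transcript: tuple[int, int] = (3, 30)
    linker_length: tuple[int, int] = (5, 25)
    lambda_bg: float = 0.2          # background footprint rate, reads/codon
    disome_enrichment: float = 10.0  # in-domain over background disome rate
    charge_beta: float = 0.0         # stall-weight coupling to upstream charge
    mutant_delta_lfc: float = 0.75   # log2 stabilization of high-score genes
    halflife_grid: tuple[float, ...] = tuple(float(h) for h in range(1, 21))
    bric_timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 10.0, 24.0)
    noise_sigma_log2: float = 0.2
    spikein_drift_log2_24h: float = 0.5
    n_spikeins: int = 3
    nb_dispersion: float = 0.1
    base_mean: float = 200.0         # mean expression counts per gene/sample
    intron_fraction: float = 0.15    # intron over exon mean count ratio

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("lambda_bg", "disome_enrichment", "base_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _make_domain(rng: np.random.Generator) -> str:
    """One canonical 28-aa C2H2 domain conforming to the consensus pattern."""
    s1 = int(rng.integers(2, 5))
    s2 = int(rng.integers(3, 6))
    tail = CANONICAL_FRAME_LEN - 2 - (16 + s1 + s2)

    def body(n: int) -> str:
        return "".join(rng.choice(_BODY_RESIDUES, size=n))

    phi = str(rng.choice(_PHI_RESIDUES))
    return (body(2) + "C" + body(s1) + "C" + body(3) + phi + body(8)
            + "H" + body(s2) + "H" + body(tail))


def make_transcriptome(
    config: SimulationConfig,
    census: tuple[int, int] | None = None,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate ZF and control proteins plus a ground-truth frame table.

    ZF proteins are tandem arrays of canonical 28-aa domains separated by
    C/H-free linkers; controls contain no cysteine and hence no match.  With
    ``census=(n_canonical, n_total)`` the generator instead plants exactly
    that many canonical domains among ``n_total`` domains, realizing the
    remainder as boundary-clipped (hence non-canonical) matches at protein
    termini, spread over as many proteins as needed.
    """
    rng = config.rng(stream=1)
    proteins: list[ProteinRecord] = []
    truth_rows: list[dict] = []

    def linker(n: int | None = None) -> str:
        if n is None:
            n = int(rng.integers(*config.linker_length))
        return "".join(rng.choice(_BODY_RESIDUES, size=n))

    if census is not None:
        n_canonical, n_total = census
        if not 0 <= n_canonical <= n_total:
            raise ValueError("census must satisfy 0 <= canonical <= total")
        n_clipped = n_total - n_canonical
        # clipped domains sit at protein starts (no 2-residue lead), two-per
        # protein is avoided for simplicity: one clipped domain per protein.
        remaining_canonical, remaining_clipped = n_canonical, n_clipped
        pidx = 0
        while remaining_canonical + remaining_clipped > 0:
            parts: list[str] = []
            pos = 0
            rows: list[dict] = []
            if remaining_clipped > 0:
                dom = _make_domain(rng)[2:]  # drop the lead: match at residue 0
                parts.append(dom)
                rows.append({"frame_start": 0, "is_canonical": False})
                pos = len(dom)
                remaining_clipped -= 1
            n_here = int(min(remaining_canonical, rng.integers(4, 12)))
            for _ in range(n_here):
                lk = linker()
                parts.append(lk)
                pos += len(lk)
                dom = _make_domain(rng)
                rows.append({"frame_start": pos, "is_canonical": True})
                parts.append(dom)
                pos += len(dom)
            remaining_canonical -= n_here
            parts.append(linker())
            pid = f"zf{pidx:05d}"
            proteins.append(ProteinRecord(pid, "".join(parts), pid))
            for r in rows:
                fs = r["frame_start"]
                # the scanner's clipped frame is still [0, 28) on a protein
                # at least 28 residues long, so record that end for both kinds
                truth_rows.append({
                    "protein_id": pid,
                    "frame_start": fs,
                    "frame_end": fs + CANONICAL_FRAME_LEN,
                    "is_canonical": r["is_canonical"],
                })
            pidx += 1
    else:
        lo, hi = config.domains_per_transcript
        for i in range(config.n_zf_transcripts):
            n_dom = int(rng.integers(lo, hi + 1))
            parts = [linker()]
            pos = len(parts[0])
            pid = f"zf{i:05d}"
            for _ in range(n_dom):
                dom = _make_domain(rng)
                truth_rows.append({
                    "protein_id": pid,
                    "frame_start": pos,
                    "frame_end": pos + CANONICAL_FRAME_LEN,
                    "is_canonical": True,
                })
                parts.append(dom)
                pos += CANONICAL_FRAME_LEN
                lk = linker()
                parts.append(lk)
                pos += len(lk)
            proteins.append(ProteinRecord(pid, "".join(parts), pid))
        for i in range(config.n_control_transcripts):
            length = int(rng.integers(200, 600))
            seq = "".join(rng.choice(_CONTROL_RESIDUES, size=length))
            pid = f"ctrl{i:05d}"
            proteins.append(ProteinRecord(pid, seq, pid))

    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "frame_start", "frame_end", "is_canonical"]
    )
    return proteins, truth


def masks_from_truth(truth: pd.DataFrame, canonical_only: bool = True) -> dict[str, DomainMask]:
    """Ground-truth domain masks in codon coordinates (aa i <-> codon i)."""
    sub = truth[truth["is_canonical"]] if canonical_only else truth
    out = {}
    for pid, grp in sub.groupby("protein_id"):
        ivs = tuple(sorted((int(a), int(b)) for a, b in
                           zip(grp["frame_start"], grp["frame_end"])))
        out[pid] = DomainMask(pid, ivs)
    return out


def _charge_weights(seq: str, sel: np.ndarray, beta: float,
                    region: tuple[int, int] = (14, 29)) -> np.ndarray:
    """Per-codon stall weights inside domains: exp(beta * upstream charge).

    The charge is that of the exit-tunnel segment 14-29 residues upstream of
    the codon, so positively charged nascent segments in the tunnel raise the
    local collision rate across that whole band.  Weights are normalized to
    mean 1 over the selected codons: beta redistributes collisions without
    changing the total in-domain rate.
    """
    w = np.ones(sel.size)
    if beta == 0.0:
        return w
    near, far = region
    for i in np.flatnonzero(sel):
        start = i - far
        if start >= 0:
            q = net_charge(seq[start:i - near + 1], 7.0, LEHNINGER)
            w[i] = np.exp(beta * q)
    mean_in = w[sel].mean()
    if mean_in > 0:
        w[sel] /= mean_in
    return w


def simulate_footprints(
    proteins: list[ProteinRecord],
    masks: dict[str, DomainMask],
    config: SimulationConfig,
    enrichment: dict[str, float] | None = None,
) -> tuple[dict[str, CodonTrack], pd.DataFrame]:
    """Poisson footprint tracks with in-domain disome enrichment.

    Monosome counts are Poisson(lambda_bg) everywhere.  Disome counts are
    Poisson(lambda_bg) outside domains and Poisson(lambda_bg * enrichment *
    w_i) inside, where w_i is the (mean-1) charge-coupling weight.  The
    per-transcript ``enrichment`` mapping overrides the config default, which
    lets a run mix stall-prone and control transcripts.  Ground truth records
    each transcript's expected localization score.
    """
    rng = config.rng(stream=2)
    tracks: dict[str, CodonTrack] = {}
    truth_rows = []
    for rec in proteins:
        n_codons = len(rec.sequence) + 1  # stop codon included
        enr = (enrichment or {}).get(rec.protein_id, config.disome_enrichment)
        mask = masks.get(rec.protein_id)
        sel = mask.selector(n_codons) if mask is not None else np.zeros(n_codons, bool)
        rate = np.full(n_codons, config.lambda_bg)
        if sel.any():
            w = _charge_weights(rec.sequence + "G", sel, config.charge_beta)
            rate[sel] = config.lambda_bg * enr * w[sel]
        mono = rng.poisson(config.lambda_bg, size=n_codons)
        dis = rng.poisson(rate)
        tracks[rec.protein_id] = CodonTrack(rec.protein_id, mono, dis)
        truth_rows.append({
            "transcript_id": rec.protein_id,
            "enrichment": enr,
            "expected_score": float(rate[sel].sum() / rate.sum()),
            "domain_codon_fraction": float(sel.mean()),
        })
    return tracks, pd.DataFrame(truth_rows).set_index("transcript_id")


def simulate_expression(
    gene_labels: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Negative-binomial count tables for WT/mutant x 1 hpf/6 hpf x two levels.

    ``gene_labels`` is indexed by gene with a boolean ``stabilized`` column
    (genes whose decay the mutant abolishes) and an optional
    ``transcription_changed`` column (genes whose change is pre-mRNA driven
    and should cancel in the intron-adjusted fold change).  Stabilized genes
    have their mature (exon) mean multiplied by 2**mutant_delta_lfc in the
    mutant at 6 hpf only; transcription-changed genes have both exon and
    intron means doubled there.

    Returns ``{"transcript": ..., "exon": ...}`` count tables with samples
    wt_1hpf, wt_6hpf, mz_1hpf, mz_6hpf, plus the ground-truth table.
    """
    rng = config.rng(stream=3)
    genes = gene_labels.index
    n = len(genes)
    stabilized = gene_labels["stabilized"].to_numpy(dtype=bool)
    if "transcription_changed" in gene_labels:
        tx_changed = gene_labels["transcription_changed"].to_numpy(dtype=bool)
    else:
        tx_changed = np.zeros(n, dtype=bool)

    base = rng.lognormal(mean=np.log(config.base_mean), sigma=0.6, size=n)
    samples = ["wt_1hpf", "wt_6hpf", "mz_1hpf", "mz_6hpf"]
    exon_mean = {s: base.copy() for s in samples}
    intron_mean = {s: base * config.intron_fraction for s in samples}
    exon_mean["mz_6hpf"] = exon_mean["mz_6hpf"].copy()
    exon_mean["mz_6hpf"][stabilized] *= 2.0 ** config.mutant_delta_lfc
    exon_mean["mz_6hpf"][tx_changed] *= 2.0
    intron_mean["mz_6hpf"] = intron_mean["mz_6hpf"].copy()
    intron_mean["mz_6hpf"][tx_changed] *= 2.0

    def nb(mean: np.ndarray) -> np.ndarray:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mean / shape)
        return rng.poisson(lam)

    exon = pd.DataFrame({s: nb(exon_mean[s]) for s in samples}, index=genes)
    intron = pd.DataFrame({s: nb(intron_mean[s]) for s in samples}, index=genes)
    transcript = exon + intron
    truth = pd.DataFrame(
        {"stabilized": stabilized, "transcription_changed": tx_changed},
        index=genes,
    )
    return {"transcript": transcript, "exon": exon}, truth


def simulate_bric(
    config: SimulationConfig,
    n_genes: int = 500,
    true_halflife: float | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Exponential decay courses with spike-ins, shared drift, and noise.

    Gene log2 fold change at chase time t is ``-t / t_half + drift(t) +
    N(0, sigma)`` (exactly 0 at t = 0); spike-ins follow ``drift(t)`` plus
    the same noise.  The drift is linear in t, reaching
    ``spikein_drift_log2_24h`` at 24 h, and must be removed by spike-in
    renormalization for unbiased recovery.  True half-lives are drawn from
    the config grid unless ``true_halflife`` pins them all.
    """
    rng = config.rng(stream=4)
    times = np.array(config.bric_timepoints)
    if true_halflife is not None:
        hl = np.full(n_genes, float(true_halflife))
    else:
        hl = rng.choice(config.halflife_grid, size=n_genes)
    drift = config.spikein_drift_log2_24h * times / times[-1]

    def noisy(clean: np.ndarray) -> np.ndarray:
        noise = rng.normal(0.0, config.noise_sigma_log2, size=clean.shape)
        noise[:, 0] = 0.0  # fold change vs the 0 h sample is identically 0
        return clean + noise

    gene_clean = -np.outer(1.0 / hl, times) + drift
    spike_clean = np.tile(drift, (config.n_spikeins, 1))
    data = np.vstack([noisy(gene_clean), noisy(spike_clean)])
    index = [f"gene{i:05d}" for i in range(n_genes)] + \
            [f"spikein{i}" for i in range(config.n_spikeins)]
    lfc = pd.DataFrame(data, index=index, columns=[f"{t:g}" for t in times])
    is_spikein = pd.Series(
        [False] * n_genes + [True] * config.n_spikeins, index=index, name="is_spikein"
    )
    truth = pd.DataFrame({"true_halflife": hl}, index=index[:n_genes])
    return lfc, is_spikein, truth


_CODON_CHOICES: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODON_CHOICES:
        from Bio.Data.CodonTable import standard_dna_table
        for codon, aa in standard_dna_table.forward_table.items():
            _CODON_CHOICES.setdefault(aa, []).append(codon)
    return _CODON_CHOICES


def reverse_translate(protein_seq: str, rng: np.random.Generator) -> str:
    """A CDS encoding the protein, with uniformly random synonymous codons.

    Appends a random stop codon; used to exercise codon-identity analyses on
    synthetic data.
    """
    table = _codon_table()
    codons = [str(rng.choice(table[aa])) for aa in protein_seq]
    codons.append(str(rng.choice(["TAA", "TAG", "TGA"])))
    return "".join(codons)
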