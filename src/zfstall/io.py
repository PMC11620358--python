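"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are TSV with headers; coordinates are 0-based half-open.  FASTA
parsing goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .domain_annotation import DomainHit, ProteinRecord
from .footprint_analysis import CodonTrack
from .nascent_charge import ChargeProfile

DOMAIN_COLUMNS = ["protein_id", "match_start", "match_end",
                  "frame_start", "frame_end", "is_canonical_28"]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Protein records from a (wrapped or unwrapped) FASTA file.

    The record ID is the first whitespace-delimited token of the header.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), rec.id))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    df = pd.DataFrame(
        [(h.protein_id, h.match_start, h.match_end,
          h.frame_start, h.frame_end, h.is_canonical_28) for h in hits],
        columns=DOMAIN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_domain_table(path: str | Path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        DomainHit(row.protein_id, int(row.match_start), int(row.match_end),
                  int(row.frame_start), int(row.frame_end), bool(row.is_canonical_28))
        for row in df.itertuples()
    ]


def write_tracks(
    tracks: Mapping[str, CodonTrack],
    path: str | Path,
    lengths_path: str | Path,
) -> None:
    """Sparse track TSV (absent codons are zero) plus an ORF-length sidecar."""
    rows, lens = [], []
    for tid in sorted(tracks):
        tr = tracks[tid]
        lens.append((tid, tr.n_codons))
        nz = np.flatnonzero((tr.monosome != 0) | (tr.disome != 0))
        for i in nz:
            rows.append((tid, int(i), int(tr.monosome[i]), int(tr.disome[i])))
    pd.DataFrame(rows, columns=["transcript_id", "codon_index", "monosome", "disome"]) \
        .to_csv(path, sep="\t", index=False)
    pd.DataFrame(lens, columns=["transcript_id", "n_codons"]) \
        .to_csv(lengths_path, sep="\t", index=False)


def read_tracks(path: str | Path, lengths_path: str | Path) -> dict[str, CodonTrack]:
    counts = pd.read_csv(path, sep="\t")
    lengths = pd.read_csv(lengths_path, sep="\t").set_index("transcript_id")["n_codons"]
    tracks: dict[str, CodonTrack] = {}
    grouped = dict(iter(counts.groupby("transcript_id")))
    for tid, n in lengths.items():
        mono = np.zeros(int(n), dtype=np.int64)
        dis = np.zeros(int(n), dtype=np.int64)
        grp = grouped.get(tid)
        if grp is not None:
            idx = grp["codon_index"].to_numpy()
            mono[idx] = grp["monosome"].to_numpy()
            dis[idx] = grp["disome"].to_numpy()
        tracks[str(tid)] = CodonTrack(str(tid), mono, dis)
    return tracks


def write_profile(profile: ChargeProfile, path: str | Path) -> None:
    pd.DataFrame({
        "offset": profile.offsets,
        "mean_charge": profile.mean_charge,
        "n_windows": profile.n_windows,
        "provenance": profile.provenance,
        "seed": "" if profile.seed is None else profile.seed,
    }).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample count table: genes in rows, sample IDs in the header."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, genotype, stage, level."""
    return pd.read_csv(path, sep="\t").set_index("sample_id")


def read_courses(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Decay-course TSV: gene, is_spikein, then one lfc column per timepoint.

    Timepoint columns are named ``lfc_<T>h``; returns the lfc table (columns
    renamed to the hour values) and the spike-in flag series.
    """
    df = pd.read_csv(path, sep="\t").set_index("gene")
    is_spikein = df.pop("is_spikein").astype(bool)
    lfc = df.rename(columns=lambda c: c.removeprefix("lfc_").removesuffix("h"))
    return lfc, is_spikein


def write_courses(lfc: pd.DataFrame, is_spikein: pd.Series, path: str | Path) -> None:
    out = lfc.rename(columns=lambda c: f"lfc_{c}h")
    out.insert(0, "is_spikein", is_spikein.reindex(lfc.index).astype(bool))
    out.rename_axis("gene").to_csv(path, sep="\t")
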