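"""Detection of C2H2 zinc-finger (C2H2-ZF) domains and peptide charge chemistry.

The C2H2-ZF is the most abundant DNA-binding module in vertebrate proteomes: a
~21-25 residue motif with two invariant zinc-coordinating cysteines and two
histidines, usually repeated in tandem arrays.  This module detects the motif
with the classic consensus pattern

    C-x(2,4)-C-x(3)-[LIVMFYWC]-x(8)-H-x(3,5)-H

normalizes each raw match to a fixed 28-residue frame (the dominant domain
length in zebrafish), and provides the Henderson-Hasselbalch net-charge and
isoelectric-point machinery used downstream for nascent-chain analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in a scannable sequence; X is tolerated as an unknown
#: residue but never satisfies a constrained pattern position (C, H, or the
#: hydrophobic position).
ALLOWED_ALPHABET = frozenset(AMINO_ACIDS) | {"X"}

#: residues accepted at the hydrophobic position of the consensus pattern.
HYDROPHOBIC_CLASS = "LIVMFYWC"

#: length of the normalized domain frame (residues).
CANONICAL_FRAME_LEN = 28
#: the frame is anchored this many residues before the first cysteine.
FRAME_LEAD = 2

DEFAULT_SPACERS = ((2, 4), (3, 5))


class InvalidSequenceError(ValueError):
    """A protein sequence contains characters outside the amino-acid alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence, linked to the transcript encoding it."""

    protein_id: str
    sequence: str
    transcript_id: str = ""

    def validate(self) -> None:
        bad = set(self.sequence) - ALLOWED_ALPHABET
        if bad:
            raise InvalidSequenceError(
                f"{self.protein_id}: illegal residue(s) {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class DomainHit:
    """A C2H2-ZF occurrence: raw pattern match plus normalized 28-aa frame.

    Coordinates are 0-based, half-open, in amino acids.  ``is_canonical_28``
    is True only when the frame fits in the protein without clipping at either
    terminus.
    """

    protein_id: str
    match_start: int
    match_end: int
    frame_start: int
    frame_end: int
    is_canonical_28: bool


@dataclass(frozen=True)
class PkaTable:
    """Side-chain and terminal pKa values for one dissociation-constant scale."""

    sidechain: Mapping[str, float]
    n_term: float
    c_term: float
    name: str = "custom"

    def __post_init__(self) -> None:
        for res, pka in {**dict(self.sidechain),
                         "N-terminus": self.n_term,
                         "C-terminus": self.c_term}.items():
            if not 0.0 < pka < 14.0:
                raise ValueError(f"pKa for {res} out of (0, 14): {pka}")


#: residues whose side chain is positively charged when protonated.
POSITIVE_RESIDUES = frozenset("KRH")
#: residues whose side chain is negatively charged when deprotonated.
NEGATIVE_RESIDUES = frozenset("DECY")

LEHNINGER = PkaTable(
    sidechain={
        "K": 10.53, "R": 12.48, "H": 6.00,
        "D": 3.65, "E": 4.25, "C": 8.18, "Y": 10.07,
    },
    n_term=9.69,
    c_term=2.34,
    name="Lehninger",
)


def _build_pattern(spacers=DEFAULT_SPACERS) -> re.Pattern:
    (s1_min, s1_max), (s2_min, s2_max) = spacers
    if not (0 <= s1_min <= s1_max and 0 <= s2_min <= s2_max):
        raise ValueError(f"invalid spacer ranges: {spacers}")
    # Lazy quantifiers make the regex engine try spacer lengths in ascending
    # (s1, s2) lexicographic order, so the leftmost match is also the one with
    # the smallest spacers -- a fully deterministic convention.
    # Spacer positions are unconstrained and accept X; the C/H literals and
    # the hydrophobic class are constrained and do not.
    return re.compile(
        f"C[A-Z]{{{s1_min},{s1_max}}}?"
        f"C[A-Z]{{3}}"
        f"[{HYDROPHOBIC_CLASS}]"
        f"[A-Z]{{8}}"
        f"H[A-Z]{{{s2_min},{s2_max}}}?"
        f"H"
    )


def scan_c2h2(
    protein: ProteinRecord,
    spacers: tuple[tuple[int, int], tuple[int, int]] = DEFAULT_SPACERS,
) -> list[DomainHit]:
    """Scan one protein for C2H2-ZF motifs.

    Matching is left-greedy: the scan walks left to right, keeps the leftmost
    (smallest-spacer) match, and resumes after its end, so retained hits never
    overlap.  Each hit carries the normalized 28-aa frame anchored 2 residues
    before the first cysteine, clipped at the sequence boundaries.

    An empty sequence yields an empty list; an illegal character raises
    :class:`InvalidSequenceError`.
    """
    if protein.sequence == "":
        return []
    protein.validate()
    pattern = _build_pattern(spacers)
    seq = protein.sequence
    n = len(seq)
    hits: list[DomainHit] = []
    pos = 0
    while (m := pattern.search(seq, pos)) is not None:
        ms, me = m.start(), m.end()
        raw_frame_start = ms - FRAME_LEAD
        frame_start = max(0, raw_frame_start)
        frame_end = min(n, frame_start + CANONICAL_FRAME_LEN)
        canonical = raw_frame_start >= 0 and raw_frame_start + CANONICAL_FRAME_LEN <= n
        hits.append(
            DomainHit(
                protein_id=protein.protein_id,
                match_start=ms,
                match_end=me,
                frame_start=frame_start,
                frame_end=frame_end,
                is_canonical_28=canonical,
            )
        )
        pos = me
    return hits


def net_charge(
    peptide: str,
    ph: float = 7.0,
    table: PkaTable = LEHNINGER,
    include_termini: bool = False,
) -> float:
    """Net charge of a peptide at the given pH (Henderson-Hasselbalch).

    Each protonatable group contributes the expected charge of its
    dissociation equilibrium: ``+1/(1 + 10^(pH - pKa))`` for basic groups and
    ``-1/(1 + 10^(pKa - pH))`` for acidic groups.  Residues without a pKa
    entry (e.g. X) contribute zero.
    """
    if peptide == "":
        raise ValueError("net_charge of an empty peptide is undefined")
    if not 0.0 < ph < 14.0:
        raise ValueError(f"pH out of (0, 14): {ph}")
    charge = 0.0
    for res in peptide:
        pka = table.sidechain.get(res)
        if pka is None:
            continue
        if res in POSITIVE_RESIDUES:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pka))
        elif res in NEGATIVE_RESIDUES:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    if include_termini:
        charge += 1.0 / (1.0 + 10.0 ** (ph - table.n_term))
        charge -= 1.0 / (1.0 + 10.0 ** (table.c_term - ph))
    return charge


def isoelectric_point(
    peptide: str,
    table: PkaTable = LEHNINGER,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> float:
    """pH at which the peptide's net charge (termini included) is zero.

    The charge is strictly decreasing in pH because the termini always
    contribute one basic and one acidic group, so bisection on [0.1, 13.9]
    converges unconditionally.
    """
    lo, hi = 0.1, 13.9
    f_lo = net_charge(peptide, lo, table, include_termini=True)
    f_hi = net_charge(peptide, hi, table, include_termini=True)
    if f_lo < 0 or f_hi > 0:  # cannot happen with termini included
        raise RuntimeError("charge does not bracket zero on [0.1, 13.9]")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = net_charge(peptide, mid, table, include_termini=True)
        if abs(f_mid) < tol:
            return mid
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("isoelectric-point bisection did not converge")


def positional_aa_frequencies(
    hits: Iterable[DomainHit],
    proteins: Mapping[str, str] | Mapping[str, ProteinRecord],
) -> pd.DataFrame:
    """Per-position residue frequencies across canonical 28-aa frames.

    Returns a 28 x 20 DataFrame (rows: frame positions 0..27, columns: the 20
    canonical residues); each row sums to 1 over the residues observed at that
    position.  Only ``is_canonical_28`` hits contribute; zero canonical hits
    is an error.
    """
    counts = np.zeros((CANONICAL_FRAME_LEN, len(AMINO_ACIDS)))
    col = {aa: j for j, aa in enumerate(AMINO_ACIDS)}
    n_used = 0
    for hit in hits:
        if not hit.is_canonical_28:
            continue
        rec = proteins[hit.protein_id]
        seq = rec.sequence if isinstance(rec, ProteinRecord) else rec
        frame = seq[hit.frame_start:hit.frame_end]
        for i, res in enumerate(frame):
            if res in col:
                counts[i, col[res]] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no canonical 28-aa hits to tabulate")
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return pd.DataFrame(
        counts / totals,
        index=pd.RangeIndex(CANONICAL_FRAME_LEN, name="position"),
        columns=list(AMINO_ACIDS),
    )
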