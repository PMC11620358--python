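import numpy as np
import pytest

from zfstall import synthetic_data as sd


@pytest.fixture(scope="session")
def default_config():
    return sd.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def small_transcriptome(default_config):
    proteins, truth = sd.make_transcriptome(default_config)
    return proteins, truth


@pytest.fixture(scope="session")
def footprint_dataset(default_config, small_transcriptome):
    proteins, truth = small_transcriptome
    masks = sd.masks_from_truth(truth)
    tracks, score_truth = sd.simulate_footprints(proteins, masks, default_config)
    return proteins, masks, tracks, score_truth


def left_greedy_oracle(seq, spacers=((2, 4), (3, 5))):
    """Independent left-greedy C2H2 pattern matcher (pure nested loops).

    At each start position, spacer combinations are tried in ascending
    (s1, s2) order; the first full match is retained and scanning resumes at
    its end.  Returns (start, end) spans.
    """
    (s1_lo, s1_hi), (s2_lo, s2_hi) = spacers
    phi = set("LIVMFYWC")
    spans = []
    i = 0
    n = len(seq)
    while i < n:
        found = None
        if seq[i] == "C":
            for s1 in range(s1_lo, s1_hi + 1):
                for s2 in range(s2_lo, s2_hi + 1):
                    length = 16 + s1 + s2
                    if i + length > n:
                        continue
                    j = i + 1 + s1
                    k = j + 1 + 3
                    m = k + 1 + 8
                    if (seq[j] == "C" and seq[k] in phi
                            and seq[m] == "H" and seq[m + 1 + s2] == "H"):
                        found = (i, i + length)
                        break
                if found:
                    break
        if found:
            spans.append(found)
            i = found[1]
        else:
            i += 1
    return spans


def hh_charge_oracle(peptide, ph, pka_sidechain, positive="KRH", negative="DECY"):
    """Hand Henderson-Hasselbalch oracle (termini excluded)."""
    q = 0.0
    for res in peptide:
        if res in pka_sidechain:
            if res in positive:
                q += 1.0 / (1.0 + 10.0 ** (ph - pka_sidechain[res]))
            elif res in negative:
                q -= 1.0 / (1.0 + 10.0 ** (pka_sidechain[res] - ph))
    return q
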