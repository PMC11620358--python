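# zfstall

Tools for asking whether ribosomes collide while translating C2H2 zinc-finger
(C2H2-ZF) domains and whether those collisions feed into mRNA decay.

C2H2-ZFs are ~28-residue DNA-binding modules — two invariant cysteines and two
histidines coordinating a zinc ion — usually present as long tandem arrays.
In zebrafish embryos, mRNAs encoding tandem C2H2-ZFs are degraded in a
Znf598-dependent manner (no-go decay), and disome (collided-ribosome)
footprints accumulate broadly across the zinc-finger codons rather than at one
sharp stall site.  `zfstall` implements the computational side of that
analysis so it can be exercised end-to-end on synthetic data with known
ground truth:

- **Domain scanning** (`domain_annotation`): the consensus pattern
  `C-x(2,4)-C-x(3)-[LIVMFYWC]-x(8)-H-x(3,5)-H`, left-greedy and
  non-overlapping, with every raw match normalized to a 28-aa frame anchored
  two residues before the first cysteine.  Henderson–Hasselbalch net charge
  `q(pH) = Σ⁺ 1/(1+10^(pH−pKa)) − Σ⁻ 1/(1+10^(pKa−pH))` and isoelectric
  points by bisection.
- **Disome analysis** (`footprint_analysis`): per-codon disome occupancy
  (counts over the regional mean), A/P/E-site codon occupancy tables with
  Spearman correlation, and the **disome localization score** — the fraction
  of a transcript's disome reads falling on its 28-aa C2H2-ZF codons, with a
  ≥10-read filter and balanced high/middle/low tertile grouping.
- **Nascent-chain charge** (`nascent_charge`): mean net charge of 6-residue
  windows as a function of distance upstream of stalled A-sites, against a
  null that resamples the same number of A-site positions uniformly from the
  domain universe.
- **Expression integration** (`expression_compare`): CPM log2 fold changes,
  maternal/zygotic classification (>2-fold rules), intron-adjusted fold
  changes (mature minus pre-mRNA), gene-set fractions, 2×2 chi-square, and
  two-sample Kolmogorov–Smirnov ECDF comparisons.
- **Half-life estimation** (`bric_halflife`): pulse-chase (BRIC-Seq) courses
  at 0/2/4/6/10/24 h, spike-in renormalization, OLS fits of log2 fold change
  on time over every nested prefix, maximum-R² selection, `t½ = −1/slope`,
  and the strict reliability filter R² > 0.9, 0 < t½ < 24 h.
- **Synthetic data** (`synthetic_data`): seeded generators for all of the
  above, each dataset shipped with its ground truth.

## Worked example

```python
import numpy as np
import zfstall as z
from zfstall.domain_annotation import ProteinRecord
from zfstall.footprint_analysis import CodonTrack, DomainMask

seq = ("MAELSPR" * 6 +                      # 42-aa N-terminal linker
       "TGCRICGKAFSRSDHLTHHERTHN" + "EKPY" +
       "KACDICGKRFARSDELTRHMRIHT" +
       "GSGSGSG" * 4)                       # C-terminal tail
rec = ProteinRecord("znf_demo", seq, "znf_demo")
hits = z.scan_c2h2(rec)
for h in hits:
    print(f"{h.protein_id}: match [{h.match_start},{h.match_end}) "
          f"frame [{h.frame_start},{h.frame_end}) canonical={h.is_canonical_28}")

mask = DomainMask("znf_demo", tuple((h.frame_start, h.frame_end) for h in hits))
disome = np.zeros(len(seq) + 1, dtype=int)
disome[[50, 55, 61, 70, 80, 88]] = [3, 4, 2, 3, 3, 1]
disome[[10, 20, 120]] = [2, 2, 1]
track = CodonTrack("znf_demo", np.zeros(len(seq) + 1, int), disome)
s = z.localization_score(track, mask)
print(f"localization score = {s.score:.2f} "
      f"({s.domain_reads}/{s.total_reads} disome reads on domains)")

frame1 = seq[hits[0].frame_start:hits[0].frame_end]
print(f"ZF1 net charge at pH 7: {z.net_charge(frame1):+.2f}   "
      f"pI: {z.isoelectric_point(frame1):.2f}")

fit = z.fit_halflife("demo", [0, 2, 4, 6, 10, 24],
                     [0, -0.42, -0.81, -1.18, -2.05, -3.90])
sel = fit.selected
print(f"half-life {sel.half_life:.1f} h from the 0-{sel.end_time:g} h prefix "
      f"(R^2 = {sel.r2:.3f})")
```

prints

```
znf_demo: match [44,65) frame [42,70) canonical=True
znf_demo: match [72,93) frame [70,98) canonical=True
localization score = 0.76 (16/21 disome reads on domains)
ZF1 net charge at pH 7: +2.24   pI: 8.97
half-life 4.9 h from the 0-4 h prefix (R^2 = 1.000)
```

The two zinc fingers are found as canonical 28-aa frames; 16 of the 21 disome
reads sit on them, giving a localization score of 0.76 (well above the ≥10
read filter); the first finger carries a net positive charge, consistent with
the exit-tunnel electrostatics hypothesis; and the decay course is fitted
best by its earliest prefix, a 4.9 h half-life — the late 24 h point, where
decay slows, is excluded by the maximum-R² prefix rule.

A command-line interface mirrors the library
(`zfstall scan-domains | score-disomes | charge-profile |
compare-expression | halflife | simulate`); `zfstall simulate --seed 1
--out-dir sim/` writes a complete synthetic dataset (FASTA, count tracks,
decay courses) plus `truth_*.tsv` tables that the other commands can be
checked against.

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
conventions, and the limits of what the synthetic benchmarks demonstrate.
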