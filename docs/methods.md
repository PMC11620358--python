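# Methods

## Domain detection and the 28-aa convention

C2H2 zinc fingers are detected with the classic consensus pattern
`C-x(2,4)-C-x(3)-[LIVMFYWC]-x(8)-H-x(3,5)-H`, not with profile (position
weight matrix) scoring.  The pipeline uses domains only as coordinate masks
and as a length census, and the synthetic generator plants
pattern-conforming domains, so profile scores would add machinery without
adding testable behavior.  Profile-based detection of diverged fingers is a
known limitation: the scanner will miss domains whose coordination residues
deviate from the consensus.

Matching is left-greedy and deterministic: the scan keeps the leftmost match,
preferring the smallest spacer lengths in lexicographic `(s1, s2)` order, and
resumes after the match end, so retained hits never overlap.  Raw matches are
21–25 residues; each is normalized to a fixed 28-residue frame anchored two
residues before the first cysteine.  This anchor is a convention chosen for
determinism — the ~85% of fingers that are 28 residues long then occupy
exactly one frame, and frames clipped by a protein terminus are flagged
non-canonical.  Downstream statistics (localization scores, within-domain
histograms, the randomized charge null) use canonical 28-aa frames only,
because fixed-length frames make positions comparable across domains.
Unknown residues (`X`) are tolerated in sequences and may occupy spacer
positions, but never satisfy a constrained position.

## Peptide charge and pI

Net charge at a given pH follows Henderson–Hasselbalch: each basic group
(K, R, H, N-terminus) contributes `1/(1+10^(pH−pKa))`, each acidic group
(D, E, C, Y, C-terminus) contributes `−1/(1+10^(pKa−pH))`.  The default pKa
set is the Lehninger scale (K 10.53, R 12.48, H 6.0, D 3.65, E 4.25, C 8.18,
Y 10.07; termini 9.69/2.34), the default of the standard peptide-statistics
tooling in this field; other scales can be supplied as a `PkaTable`.
Nascent-chain windows are scored without termini (an internal window of a
longer chain has neither a free α-amino nor a free carboxyl group); pI is
computed with termini included, by bisection on pH ∈ [0.1, 13.9].  With the
termini present the charge is strictly decreasing in pH, so the root is
unique; bisection stops at |charge| < 1e-6, comfortably inside the 1e-4
post-condition the tests verify.

## Disome occupancy and the localization score

Coordinates are 0-based and half-open throughout; codon `i` covers
nucleotides `[3i, 3i+3)`; amino acid `i` corresponds to codon `i`.  Disome
counts are indexed by the A-site codon of the *leading* (stalled) ribosome;
when raw read positions must be converted, a single fixed 5′→A-site offset
per footprint class is applied (defaults 15 nt monosome, 45 nt disome) —
length-stratified offset calibration is out of scope.

Occupancy at a codon is its count divided by the mean count per codon over a
normalization region (whole ORF, or the domain codons), so the regional mean
occupancy is 1 by construction.  The localization score of a transcript is
`domain disome reads / total ORF disome reads`, defined for transcripts with
at least 10 disome reads on the ORF; the filter applies to the score's own
denominator.  Scored transcripts are split into high/middle/low groups by
balanced rank tertiles (sizes differ by at most one, extras to the higher
groups), with ties broken by transcript ID so the partition is reproducible.
Rank tertiles rather than score-value thirds guarantee three populated
groups regardless of the score distribution's shape.

`call_peaks_simple` flags codons with count ≥ 5 and z-score ≥ 4 against the
track mean.  It is a convenience outlier rule for synthetic data, explicitly
not a reimplementation of published disome peak-calling procedures.

## Nascent-chain charge profiles and the randomized null

For an A-site at residue `a` and offset `d`, the 6-residue window covers
residues `[a−d−6, a−d)`; windows extending before the first residue are
skipped for that pair.  Offsets 14–23 thus tile the segment 14–29 residues
upstream of the A-site — the portion of the nascent chain inside the
ribosomal exit tunnel.  Each A-site contributes windows weighted by its read
count (a codon with five disome reads contributes five windows): read counts
are the natural multiplicity of observed collisions.  The null profile draws
the same number of A-site positions uniformly, with replacement, over all
(canonical domain, within-domain position 0–27) pairs; with-replacement
sampling keeps the null defined when the draw count exceeds the position
universe.  Null profiles are deterministic given their seed, and on a
degenerate universe (one domain, uniform sequence) they reproduce the
observed profile exactly — a self-consistency check the tests enforce.

## Expression comparisons

Log2 fold changes are computed on counts-per-million with a pseudocount
(default 0.5); genes with ≥ 1 CPM in the reference sample count as
expressed.  This deliberately replaces dispersion-modeling differential
expression (out of scope); the reproducible surface is the direction and
shift of fold-change distributions, not absolute per-gene estimates.
Maternal/zygotic classes use the >2-fold rules on the wild-type 6 hpf vs
1 hpf change, with exclusive boundaries: |lfc| exactly 1 remains
maternal-zygotic.

Intron-adjusted changes subtract the pre-mRNA (intron) fold change from the
mature (exon) fold change; intron counts are transcript-level minus
exon-level counts, floored at zero and flagged when negative.  Genes with
intron coverage below 1 CPM in the reference are reported NA rather than
adjusted by a noise-dominated term.  Because single-library negative-binomial
noise at biological dispersion is comparable to a 2-fold signal per gene, the
cancellation of transcriptional changes is a distribution-level property;
the tests assert it on medians over ≥ 40 genes, not gene-by-gene.

Gene-set fractions are reported as percentages, one decimal by default and
two when the denominator exceeds 10,000.  The 2×2 enrichment chi-square is
Pearson's, without Yates continuity correction: the intended use has
expected counts in the hundreds, where the correction is immaterial, and
omitting it makes results bit-reproducible against the plain
`Σ(O−E)²/E` formula.  ECDF comparisons use the two-sample two-sided
Kolmogorov–Smirnov test with the asymptotic p-value.

## Half-life estimation

Decay courses are per-gene log2 fold changes versus the 0 h sample on the
0/2/4/6/10/24 h grid.  Renormalization subtracts, at each timepoint, the
arithmetic mean of the spike-in log2 changes (the geometric mean of their
linear fold changes) — this removes shared recovery drift, leaves the
spike-in mean at zero, is idempotent, and preserves every between-gene
difference.

Because decay often slows late in the chase, a line is fitted by OLS (with
intercept; the t = 0 point included as an ordinary observation) to every
nested prefix with ≥ 3 timepoints — 0–4, 0–6, 0–10, 0–24 h on the default
grid — and the prefix with the highest R² (squared Pearson correlation of
fitted vs observed) is selected; R² values within 1e-12 are treated as tied
and the longest prefix wins, so noiseless courses select the full course.
The half-life is `−1/slope` hours (log2 space makes −1/slope the halving
time); non-negative slopes yield no valid half-life.  Fits are reliable iff
R² > 0.9 and 0 < t½ < 24 h, both bounds strict.  A perfectly flat prefix is
assigned slope 0 and R² 0 rather than an undefined correlation.

## The synthetic generator

The generator's defaults encode the study conditions the pipeline assumes;
they are parameters of the simulated biology, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_zf_transcripts` / `n_control_transcripts` | 50 / 50 | transcripts with / without planted domains |
| `domains_per_transcript` | 3–30 | tandem array length (extreme arrays reach ~30 copies) |
| `linker_length` | 5–25 aa | inter-domain linkers, C/H-free |
| `lambda_bg` | 0.2 reads/codon | Poisson background footprint rate |
| `disome_enrichment` | 10 | in-domain over background disome rate |
| `charge_beta` | 0 | stall-weight coupling `exp(β·q)` to the charge 14–29 aa upstream |
| `mutant_delta_lfc` | 0.75 | log2 stabilization of high-score genes in the mutant |
| `noise_sigma_log2` | 0.2 | multiplicative noise on decay courses |
| `spikein_drift_log2_24h` | 0.5 | shared recovery drift the renormalization must remove |
| `nb_dispersion` | 0.1 | negative-binomial dispersion of expression counts |
| `n_spikeins` | 3 | spike-in rows per course table |

Planted domains conform to the consensus pattern with invariant C/C/H/H and
Lys/Arg-enriched unconstrained positions (giving the high isoelectric points
characteristic of real C2H2-ZF proteins); linkers and controls exclude the
residues that could create spurious matches, so scanner recall and false
positives are exactly measurable.  A census mode plants an exact number of
canonical frames among a total (clipped matches at protein starts supply the
non-canonical remainder), which the scanner must recover.  With
`charge_beta > 0` the in-domain disome rate is multiplied by a mean-one
weight `exp(β·q)` where `q` is the net charge of the segment 14–29 residues
upstream, reproducing the charge–collision coupling at the profile level.
Expression counts are gamma-Poisson (NB); decay courses are
`−t/t½ + drift + noise`.  All streams derive from a single seed (per-purpose
substreams), so every dataset is bit-reproducible.

What the generator does *not* emulate: nucleotide-level reads and mapping
artifacts, codon-usage structure (CDSs for codon-identity analyses are
random synonymous reverse-translations), isoform structure, replicate
designs, and profile-divergent domains.  Passing the end-to-end tests
therefore shows that the statistics recover planted effects of realistic
size under count noise — not that the biological effects exist in any real
dataset.

## Problem sizes

The default test and acceptance runs use 50–200 transcripts per condition,
500 genes per decay simulation, a 9,622-domain census transcriptome, and
1,000-iteration oracle comparisons — sizes chosen so the complete suite runs
in well under a minute while keeping Monte-Carlo assertions at ≥3-sigma
separation from their thresholds.

## Known limitations

- The consensus pattern misses non-canonical fingers a profile would score.
- Fixed A-site offsets ignore read-length heterogeneity.
- The fold-change machinery is single-library CPM arithmetic; it is not a
  substitute for replicate-aware differential expression when replicates
  exist.
- The 28-aa frame anchor (two residues before the first cysteine) is a
  convention; other anchors would shift within-domain positional statistics
  by a constant.
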