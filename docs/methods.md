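# Methods

This note documents the models, parameters and design choices behind
`phasekit`: what the pipeline computes, what the synthetic-data generator
does and does not emulate, and the numerical conventions used throughout.
All genomic coordinates are 0-based half-open internally; BED output is
0-based, GFF3 output 1-based.

## Phasing model

A phased locus is a genomic region whose 21-nt small RNAs start predominantly
on one residue class mod 21 (the *register*). Because Dicer products are
duplexes with 2-nt 3' overhangs, antisense reads map offset by 2 nt: a
plus-strand read is in phase when `start ≡ r (mod 21)` and a minus-strand
read when `leftmost + 2 ≡ r (mod 21)`.

The detection statistic is a hypergeometric upper tail over *distinct*
5'-start positions (abundance is deliberately ignored: one highly expressed
sequence must not create a locus). In a window of `c` cycles there are
`N = 2·21·c` eligible positions and `K = 2c` in-phase ones; observing `k`
in-phase among `n` distinct starts gives `p = P(X ≥ k)` with
`X ~ Hypergeometric(N, K, n)`. The tail is computed exactly as a rational
number (`fractions.Fraction` over binomial coefficients) and cached; float
conversion happens only at the comparison with `alpha`.

Windows slide on a 21-nt grid anchored at coordinate 0 (`step = 21`). All 21
registers are tested in any window holding at least `min_members` distinct
starts. Defaults: `cycles = 11` (231-nt window), `alpha = 1e-4`,
`min_members = 3`. These are conservative values consistent with loci of
3–5 phased sequences; all are configuration-exposed. Overlapping significant
windows are merged only when their registers are identical, so adjacent loci
in different registers stay distinct; the locus span is the extent of its
in-phase member alignments, and the best window p-value is retained.

With ~24,000 windows per megabase and 21 registers per window, a small
number of alpha-level false calls (3 distinct background reads landing in
one register of one window, `p ≈ 9.4e-5`) is expected and observed at high
background densities; the post-filters do not remove them because they are
statistically indistinguishable from weak true loci. Users needing fewer
false calls should raise `min_members` to 4 or lower `alpha`.

### Post-filters and recruitment

After detection, member sequences aligning to more than `max_genome_hits`
(default 10) genomic positions are removed; loci left with fewer than
`min_members` members, or overlapping a blacklist interval (telomere-like
regions in the synthetic bundle), are dropped and counted. Two recruitment
passes then extend loci with 21-nt sequences not originally detected as
phased, using the locus members as the match database: pass 1 requires 100 %
identity over ≥ max(16, ⌈0.85·len⌉) nt, pass 2 relaxes identity to 85 %.
Pass-1 recruits are excluded from pass 2; sequences matching members of
several loci are recruited into all of them and flagged ambiguous. Recruited
members contribute to locus abundance sums (disable with
`include_recruited=False`).

## Trigger-site scanning

Instead of de-novo motif discovery, locus flanks (± 500 bp, truncated at
chromosome ends) are scanned for complementarity to each 22-nt trigger
miRNA, in the style of plant miRNA target prediction: antiparallel pairing
of the trigger against the target site, penalty 1 per mismatch, 0.5 per G:U
wobble, both doubled within trigger positions 2–13 (the seed-proximal and
central region that determines cleavage), no gaps. The best site with
penalty ≤ 4.5 is reported with its distance to the nearest locus end, its
flank side, and the inferred cleavage position — the boundary between the
target bases pairing trigger positions 10 and 11, the canonical plant miRNA
cleavage geometry. Both the site edge distance and the cleavage coordinate
are reported because "distance to the motif" is ambiguous between the two.

## Differential analysis

The design is two bulked libraries, one per condition, with no replicates —
so no dispersion model is fitted. Each unit's raw counts `(count_A,
count_B)` are tested with a g-test (df = 1) against expectations
proportional to the library totals; RPM values are used only for the
reported fold ratio (with a 0.5 pseudocount on both sides when either count
is zero, to keep the ratio defined). `category` is `ns` when `p > alpha`
(default `1e-3`, fixed, no multiple-testing correction — a
Benjamini–Hochberg layer can be added on the returned p-values but is
deliberately not applied by default), otherwise `over_A`/`over_B` by RPM
direction; `fold5_flag` marks ratios ≥ 5 in either direction.

The chi-square approximation is conservative for small counts: the exact
type-I error at `alpha = 1e-3` is ≈ 4e-4 for a balanced null of 20 reads and
≈ 9e-4 by 50 reads. Calibration checks therefore mix unit sizes (20–500
reads), where the aggregate false-positive rate is alpha-consistent.

Class enrichment contrasts (e.g. the annotation classes of 5-fold
over-accumulated sequences against the whole population) are per-class 2×2
g-tests of subset versus rest, reporting the direction of deviation. miRNA
family profiles aggregate miRNA-class sequences by the family of their best
database match, take the family type (canonical / variant / siRNA-like)
from database metadata rather than re-deriving it, compute the modal length
as the read length with the highest summed RPM (ties to the shorter
length), and flag families whose annotated loci overlap a detected phased
locus — such overlaps suggest the annotation is really a phasiRNA locus.

## Annotation

Classification is first-hit-wins through ordered tiers: mature miRNA db →
ncRNA db → repeat db → CDS features → intron/UTR features → genome.
Database tiers use an ungapped all-offsets local matcher; feature tiers and
the genome tier use end-to-end genomic mapping plus interval overlap. A
sequence matching only the genome is `unannotated`; one matching nothing is
`unmapped`; CDS and intron/UTR hits are class `gene` with the subclass
recorded. Match thresholds: identity ≥ 0.85 over a window of ≥ max(16,
⌈0.85·query length⌉) nt. E-values are not computed — for 18–28-nt queries
the identity/coverage/length thresholds are the operative filter — and
gapped alignment is omitted (indels in ungapped 21-mers at 85 % coverage
have negligible effect).

The matcher reports, per strand and diagonal, the best admissible window
(maximising identities, then aligned length, then the leftmost start), which
makes results enumerable and brute-force checkable. Multi-record searches
use exact k-mer seeds with a pigeonhole-safe seed length derived from the
thresholds (k = 5 at the defaults), so the seeded search is provably
equivalent to scanning every diagonal; if a configuration drives the safe
seed below 3 nt the code falls back to the full scan. Identity-fraction
comparisons use a 1e-9 epsilon so that exact threshold cases (e.g. 17/20 ≥
0.85) are accepted regardless of floating-point representation.

Genome mapping defaults to exact matching on both strands (`max_mismatches =
0`), the common choice for short small-RNA reads; a vectorised full-length
mismatch scan is available via `max_mismatches > 0`. Reads carrying
sequencing errors therefore typically go unmapped rather than mismapped,
which matches how the collapsed singletons behave in real pipelines.

## The synthetic study

The generator emulates a two-condition experiment: two bulked total-RNA
pools sequenced once each, analysed against a single reference genome.

**Reference bundle.** Random chromosomes (default 2 × 500 kb, minimum
100 kb) with planted non-overlapping features: miRNA loci (copied into the
miRNA database, grouped into 8 families with canonical/variant/siRNA-like
types), ncRNAs, repeats (including one 12-copy family so that genuine
multi-mappers exist), CDS/intron/UTR features, and telomere-like 5-kb
blacklist intervals at every chromosome end. The trigger database holds one
22-nt trigger; databases are verbatim copies of planted intervals, so
feature-derived reads are guaranteed to match their tier.

**Phased loci.** Default 60 loci with 3–10 members each; 92.5 % produce
reads from both strands; ~60 % carry a trigger site; member abundance
weights follow a Zipf law (exponent 1.5), reproducing the dominance of one
or two sequences per locus. For trigger-carrying loci the reverse complement
of the trigger is written into the genome in the precursor 5' flank and the
register is anchored to the cleavage point between trigger positions 10 and
11; because members must stay in register, realised site-to-locus distances
are quantised to `21·j − 10` (j ≥ 1), within the configured 2–452 bp range.
Precursor orientation is random, so sites occur on either side and strand.

**Libraries.** Each library is one multinomial draw of exactly
`library_size` reads (default 50,000) over all species, so conservation is
exact. The read-level class mix is phased 33 %, miRNA 22 % (one family
configured to contribute 64 % of miRNA reads), gene 14 %, repeat 12 %
(24-nt), ncRNA 8 %, unphased 21-nt genomic noise 8 %, unmappable 3 %. A
configurable fraction of loci (default 70 %) over-accumulates in library A
with a fold drawn uniformly from [5, 10]; the planted fold is imposed on the
per-library sampling probabilities, and the background classes absorb the
compositional compensation — exactly as RPM normalisation redistributes a
large class shift in real data — so planted null loci remain exactly null.
Random noise is excluded from the planted precursor regions (± 250 bp):
21-mers inside an active precursor would be processed in phase and would
make the ground truth ambiguous. Reads are emitted as 36-nt FASTQ records
(insert + 3' adapter, uniform quality 'I'); sequencing errors are i.i.d.
substitutions at 0.001 per base across the whole read, so error reads can
also fail adapter trimming, as in real data.

**What it does not emulate.** Ligation and base-composition biases, true
repeat/transposon sequence structure (planted "repeats" are random
sequence, so only the explicit multi-copy family multi-maps), genuine
sequence divergence between the two conditions' genomes, within-pool
genotype heterogeneity (each library is a single pool), and 24-nt phasiRNA
loci. Passing tests therefore demonstrate correctness of the statistics and
the pipeline plumbing under the stated model — not robustness to mapping
bias or genome divergence.

## Problem sizes and determinism

The test suite and the acceptance script run the default study (2 × 500 kb,
60 loci, 2 × 50,000 reads) — large enough that every stage operates in its
intended regime while a full run completes in well under a minute — plus a
denser 2 × 100 kb fixture for unit tests. All randomness flows through
`numpy.random.default_rng` seeds carried in the configuration; identical
configuration and seed give byte-identical TSV/BED/FASTQ outputs (the JSON
run report additionally records wall-clock times and is excluded from
byte-identity checks).

## Known limitations

- Phasing p-values are not corrected for the number of windows and
  registers tested; `alpha` should be read as a per-test level.
- Locus spans extend to every in-phase distinct position inside the merged
  significant windows, so a single stray in-phase read can stretch a
  boundary by one or more cycles.
- The matcher is ungapped; a single indel in a member sequence prevents
  recruitment even when identity is otherwise high.
- Exact-match genome mapping discards error-bearing reads instead of
  placing them; at realistic error rates this loses ~2 % of member
  abundance and no member identities.
- The g-test is anti-conservative for neither direction but loses power
  below ~30 reads per unit; locus-level counts are usually far above this.
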