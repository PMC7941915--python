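# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Study design assumed throughout

Two conditions (low-Pi treatment vs. Pi-sufficient control), unpaired,
with three biological replicates each — the canonical design for plant
nutrient-starvation RNA studies. All coordinates are 1-based, fully
closed, on the transcript sense strand. Sequences are held in DNA
alphabet (T for U) in files and memory; duplex thermodynamics convert
implicitly (T is read as U).

## Synthetic data with planted truth

The generator (`pistarve.simulate`) produces a reference bundle (mature +
precursor miRNAs, class-labelled transcripts, 2-kb promoters, a GO map)
and a planted truth object, all deterministically from one seed: the same
`SimulationConfig` reproduces byte-identical outputs.

* **Counts** are negative binomial with variance μ + φμ², φ =
  `nb_dispersion` (default 0.1, a typical squared biological CV for
  replicated bulk libraries; the real studies do not report their
  dispersion, so this is an explicit free parameter).
* **Planted fold changes** have |log₂fc| drawn uniformly from
  `planted_log2fc_range` (default 3–4) with an 80% up-regulation bias,
  matching the observation that Pi starvation predominantly induces small
  RNAs. Planted features receive baseline means well above 50 counts so
  effects are estimable at n = 3 vs 3.
* **The sRNA population** mixes miRBase-exact matures, templated isomiR
  end-shift variants (±1–2 nt within the precursor), sense/antisense cDNA
  fragments of every class, and unannotatable random sequences. Reads are
  the sRNA plus the TruSeq small-RNA 3′ adapter at constant high quality
  (an optional low-quality 3′ tail exercises quality trimming); true
  per-sample counts are emitted alongside the FASTQ so preprocessing can
  be checked for exact count recovery.
* **Degradome tags** (20 nt) start uniformly along each transcript at
  density `degradome_background_per_position` (default 0.2/nt — a free
  parameter chosen so transcripts carry clear but sparse background);
  each planted target adds tags whose 5′ end is exactly the transcript
  position paired to guide nucleotide 10, at `signal_to_noise` (default
  50) times the per-position background mean. Background decay is uniform
  (the simplest null for peak-category tests); no 5′ bias is simulated.
* **Planted target sites** are exact reverse complements of the guide, so
  contiguous complementarity spans guide positions 9–11 by construction.
* **Promoters** are uniform random DNA with the configured number of
  exact P1BS/PHO instances written in at recorded TSS-relative positions
  on random strands; chance motif occurrences elsewhere are possible and
  the truth records planted positions only.
* **mRNA-seq is simulated at count level**, not read level: differential
  gene expression needs only counts and exon lengths, and read alignment
  is out of scope.

What the simulator does **not** emulate: sequencing errors, ligation and
PCR biases, 5′-biased degradome background, genomic multi-mapping beyond
transcript space, and correlated replicates. Passing tests therefore
demonstrate correctness of the statistics and bookkeeping under the
declared model, not robustness to those artefacts.

## Preprocessing

Adapter trimming removes the longest read suffix matching an adapter
prefix with at most one mismatch per ten aligned bases (minimum overlap 3
to avoid spurious single-base trims). Quality trimming is the
modified-Mott rule: each base contributes `limit − P_error` and the
maximal-sum contiguous segment is kept; the limit is an error
probability, default 0.02. Reads outside 18–25 nt are discarded and
tallied by reason. CPM uses the post-filter library size as denominator.

## Exact negative-binomial test

The two-group test follows the classic conditional construction: library
sizes are equalized by scaling every sample to the geometric-mean library
size and rounding ("pseudo-counts" — a moment-matching simplification of
quantile equalization that keeps the conditioning argument integral). A
common dispersion is estimated by maximizing the conditional
log-likelihood of the within-group splits given group totals, on the log
scale over φ ∈ [10⁻⁶, 10]; a boundary solution is reported as 0 (the
Poisson limit). For each feature the group-A total is tested against its
conditional distribution given the feature's overall total (NB splits
with size nₐ/φ; binomial in the Poisson limit), with the two-sided
p-value equal to the summed probability of all splits no more likely than
the observed one. Features that are zero in every sample are removed
before the number of tests m is fixed; Bonferroni is min(1, m·p) and FDR
is Benjamini–Hochberg. Selection uses strict inequality at α.

A closed-form NB likelihood-ratio test (group means are the ML fits for a
saturated two-group log-link model with fixed dispersion) backs the DEG
caller; it agrees with an iteratively fitted GLM to ~1e-5 on the LRT
statistic and reduces to the exact-test decision within simulation error.

**Known limitation — composition bias.** When induction is strong and
asymmetric (as planted here), treated libraries are larger and
per-library-size equalization shifts every null feature downward by the
composition factor (~2× at the defaults). Planted effects are recovered
with correct signs, but a tail of null features crosses the Bonferroni
threshold; the type-I calibration property is therefore stated on a
composition-free null simulation. Robust normalizers (TMM/median-ratio)
are deliberately not substituted, to keep the per-million convention.

## Duplex search and scoring

Candidate sites are located by an ungapped antiparallel complementarity
prescreen (match 1, G:U 0.5; threshold max(10, 0.55·L), configurable),
then refined by Needleman–Wunsch alignment of the sRNA against the
reverse complement of a window padded by `max_bulge` (default 2) with
free end gaps (match +1, G:U +0.5, mismatch 0, gap −2, ties prefer
pairing). The prescreen is a pragmatic bound: duplexes weak enough to be
missed by it also fail the score thresholds, and permutation nulls use
the identical enumeration path.

The Allen-rule score charges mismatches and bulged nucleotides 1 and G:U
wobbles 0.5, doubled at sRNA positions 2–13; with the position-10
relaxation a single mismatch/G:U exactly at position 10 is not doubled.
Unaligned sRNA end positions count as mismatches. Default acceptance
threshold 4.0.

Duplex free energies use a simplified built-in nearest-neighbour table:
pair strengths G:C 2.4, A:U 1.1, G:U 0.5 kcal/mol; stacking two adjacent
pairs contributes −(mean strength) − 0.8; bulges cost +3.0 plus 0.5 per
nucleotide, internal loops +1.5 plus 0.5 per nucleotide; duplex
initiation is taken as zero. Absolute energies are therefore
package-specific — only the MFE ratio (duplex MFE / perfect-complement
MFE, clamped to [0, 1]) and energy orderings are contractual, and printed
literature MFEs will not be reproduced numerically. The MFE track filters
at ratio ≥ 0.6, ≤ 3 bulged nucleotides, overhangs ≤ 2, then scores
2·mismatch + 1·G:U + 3·bulge-nt + 1·loop (weights configurable).

Peak categories follow the five-level convention: 0 unique transcript
maximum (> 1 read), 1 shared maximum, 2 above the mean of positions with
signal, 3 at or below it, 4 single read. A prediction requires signal at
the coordinate paired to guide nucleotide 10 and that coordinate within
±1 of the transcript's maximal peak (tolerance configurable); the
reported p-value is a permutation null — mononucleotide shuffles of the
guide (dinucleotide available), p = (1 + hits)/(n_perm + 1), seeded and
reproducible. This null is a defined replacement for the unspecified
p-values printed by degradome tools, not a reproduction of any of them.

## Motifs and GO

IUPAC consensi are compiled to overlapping-match regexes; ambiguous
reference bases never match. Both strands are scanned by default; because
the P1BS consensus is its own reverse complement, a footprint matching
both strands is reported once (plus strand) so gene-level tallies and
positional bins are not double-counted. Bins are 500 bp on the hit start,
[-500, −1] first. GO over-representation is an upper-tail binomial test
(k annotated in the input, n input genes, success probability term size /
background size) with Bonferroni over tested terms and fold enrichment
(k / term size) / (n / background size); zero-size terms are skipped.

## Problem sizes

Defaults were chosen as comfortable desk-scale versions of the design:
~30 miRNAs, ~80 transcripts across the eight cDNA classes, ~300 unique
sRNAs at a 50 000-read mean library, 10 planted cleavage targets, 2-kb
promoters. The null-calibration property uses 5000 simulated features;
oracle comparisons use 500 random duplexes and 200 random promoters.
The test suite and the acceptance script each complete in well under a
minute on a single core.

## Open choices made here

* CPM denominators use post-filter library sizes.
* Combined-mode cDNA class assignment uses the priority rRNA > tRNA >
  snoRNA > snRNA > SRP-RNA > non-translating > protein-coding >
  pseudogene (configurable); per-class mode reports all matching classes.
* Antisense cDNA matches are allowed and flagged; the miRNA annotation
  layer is strand-specific (sense only).
* Depth normalization of cleavage profiles is per 10⁷ mapped tags
  (configurable).
* TPM is computed per sample (the formula is per-sample).
* Bonferroni m counts all features passing the nonzero filter.
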