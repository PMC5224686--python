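# Methods

## Overview

trfkit implements an analysis of tRNA-derived fragments (tRFs) in an
aging-brain small-RNA setting: fragment discovery and classification
from collapsed sequencing reads, age-trajectory labelling over a
three-timepoint (young / mid-age / old) × three-replicate design, 7-mer
seed-region discovery against multi-species 3'UTR alignments with two
null models, and a resampling statistic for age-related down-regulation
of predicted target transcripts. Every stage can run on synthetic data
with planted ground truth, so the full pipeline is testable without any
external download.

## tRF discovery and classification

Mature tRNA references carry the post-transcriptional CCA tail; reads
are matched as **exact, full-length, sense-strand substrings** of these
CCA-appended sequences. Mismatch- or indel-tolerant alignment is
deliberately out of scope: the exactness requirement is itself part of
the method (decoy reads with one mismatch must not map).

Classification follows the anchoring of the placement on the mature
molecule (1-based inclusive coordinates, CCA included):

* **5' tRF** — starts at position 1;
* **3'CCA tRF** — ends at the CCA terminus;
* **internal** — anywhere else;
* a read equal to the whole molecule is excluded from fragment sets;
* **3'U tRFs** (from the U-rich precursor trailer) are only assignable
  when trailer sequences are supplied and are off by default, since
  trailer-derived reads are negligible in the data this models.

Reads shorter than 17 nt are dropped ("longer than 16 nt" read
strictly; configurable). Adapter clipping removes the leftmost exact
occurrence of an adapter prefix of at least 7 nt (configurable
overlap); clipping at the first occurrence is the standard choice for
3' adapters since everything downstream of it is adapter read-through.

Abundance is normalized to reads per million (RPM) of the library's
total detected reads (all reads after length filtering, not only
mapped ones — the closest literal reading of "total number of reads
detected"; a mapped-only denominator is available as an option).
A candidate fragment, accumulated per (tRNA gene, class), is reported
only when its read count **strictly exceeds 0.1 %** of total reads in
*every* one of the nine libraries. The representative fragment of a
(tRNA, class) pair is the modal distinct read (largest count summed
over libraries; ties broken lexicographically) — the source protocol
reports one coordinate pair per tRF without stating its rule, so this
is the package's own deterministic construction. Multi-mapping reads
count once per matching gene copy; records over tRNA genes with
identical mature sequences are merged into one record listing all gene
ids.

## Age patterns

For per-timepoint replicate-averaged abundances (y, m, o) and a
relative tolerance ε (default 0.05, applied to the grand mean):
monotone up/down require each step to exceed the ε band; a dip
(m below both ends — the "M < Y < O" shape) or a peak require m to
clear both ends by the band; everything else is flat. ε is explicit
and configurable because the reference analysis classifies patterns
visually. Under the default replicate noise (CV 0.2, 3 replicates) a
truly flat trajectory is occasionally labelled as a weak dip or peak;
the planted-recovery guarantees therefore target the monotone and dip
shapes.

## Seed discovery

Every tRF is scanned with a 7-nt window sliding 5'→3' by one
nucleotide (L−6 windows). Each window generates the three canonical
target-site types used for miRNA seeds:

* **7mer-m8** — site for the full 7-mer;
* **7mer-1a** — site for the first 6 window nucleotides followed by an
  A on the target;
* **8mer-1a** — the 7mer-m8 site followed by an A.

Under the default **complementary** orientation the site is the
reverse complement of the window (the sequence a transcript must carry
to base-pair with the tRF); a **direct** orientation (literal window
match) is provided because "exact match" protocols are ambiguous on
this point, and the choice is echoed in every output header. The two
dialects are strand-symmetric only for the m8 type: the 1a-A stays on
the target 3' side in both, so reverse-complementing the UTRs maps
direct m8 counts onto complementary m8 counts but not the 1a variants.

A site occurrence is anchored on the reference species (rat, taxonomy
ID 10116) and counts as **conserved** when at least 15 of the 23
aligned vertebrate species — always including human (9606), mouse
(10090) and rat — carry the same sequence over the same alignment
columns (a gap column must be a gap, a base column the same base). An
"anywhere in the species' UTR" mode is available since column
anchoring is not universal among published pipelines. Observed counts
are **per gene** (a gene counts once however many sites it has), which
keeps the counting consistent with target-set construction; 8mer-1a
occurrences contain both 7-mer site types and are covered
automatically.

Two nulls calibrate each window's observed count:

1. **background expectation** — the empirical per-position frequency
   of the 7mer-m8 site in a user-supplied background corpus times the
   number of 7-mer positions scanned in the reference UTRs;
2. **composition null** — the mean observed count over all *other*
   7-mers with the same nucleotide multiset, by full enumeration of
   distinct permutations (≤ 5040; a single-permutation composition
   falls back to including the window itself, with a warning).

A window is **called** a candidate seed when its observed count is at
least 2× both nulls and reaches 25 genes (both thresholds
configurable and reported in every output — the reference analysis
calls seeds by visual inspection, so explicit stand-ins are needed).
Predicted targets of a tRF are the union, over called windows, of
genes with at least one conserved 7mer-m8 or 7mer-1a site; all
supporting sites are emitted in the deposited 8-column format
(gene, window offset, MSA start/end, UTR start/end, match type,
ascending comma-joined taxonomy IDs).

For throughput, conserved 7-mer occurrences of all blocks are
pre-indexed once (per-column agreement with the reference row,
vectorized as windowed sums over a byte matrix), making each window
— and the thousands of counts a composition null needs — a dictionary
lookup. The index is validated against a naive per-species full scan.

## Regulation statistic

Expression libraries are normalized to their totals, replicates
averaged per timepoint, and each transcript's relative change computed
between the first and last timepoints ((O−Y)/Y; label mapping absorbs
differently gridded series). Transcripts with zero young-mean are
excluded and counted. At each threshold t ∈ {5 %, 10 %, 20 %} a
transcript is DOWN if its change < −t (strictly), UP if > +t, else
NEUTRAL. The statistic for a target set is the **down/up ratio**; a
set with no up-regulated member gets an infinity sentinel with counts
retained.

The null is the ratio distribution over 1,000 uniform
without-replacement draws of equal-size transcript sets from the same
transcriptome. Only a draw's label counts enter its ratio, so draws
are realized directly as multivariate-hypergeometric label counts — an
exact distributional equivalence that keeps large calibration runs
cheap (property-tested against literal draws). Significance is
reported two ways: a two-tailed one-sample t-test of the null ratios
against the observed value (the literal reading of the protocol this
models, which is statistically unusual for a single observation
against a resampled distribution) and a two-tailed empirical rank test
with add-one correction, 2·(min(tail ranks)+1)/(n+1) — the
recommended default. Degenerate (zero-variance) nulls reject the
t-test mode with a pointer to the empirical mode. Star tiers:
\*\*\* p<0.005, \*\* p<0.01, \* p<0.05, # otherwise.

Change distributions are reported as densities over half-open 2.5 %
bins aligned at multiples of the bin width; densities are
transcript-count based (not abundance weighted).

## Synthetic data

The generators emit exactly the formats the readers consume and a
ground-truth JSON. One master seed feeds named child streams (one per
artifact), so regenerating one file never perturbs the others; all
outputs are byte-identical under a fixed seed.

* **tRNA set** — 30 random gene bodies of 70–90 nt with anticodon
  labels, CCA appended, 2 marked mitochondrial; optional duplicate
  sequences to exercise multi-mapping.
* **Read libraries** — 3 timepoints × 3 replicates at 10⁶ reads each.
  Eight 3' tRFs (fragments ending at the CCA terminus, start jitter
  sd 0.5 nt) and eight 5' tRFs (starting at position 1, end jitter
  sd 3 nt) are planted at a base abundance of 0.4 % of the library,
  scaled per timepoint by an age trajectory (monotone ×2 per step,
  dip, flat) with multiplicative log-normal replicate noise (CV 0.2
  — a simple overdispersion model; the modelled protocol states
  none). An internal-fragment background (5 % of mapped reads) and
  non-mapping decoys — random sequences and single-mismatch tRNA
  fragments that exercise the perfect-match rule — fill each library
  to depth.
* **UTR alignments** — 300 genes × 23 species × 500 columns of i.i.d.
  background (GC 0.4, gap rate 0.02 per cell). Each planted window's
  site (cycling through the three match types) is written at one
  shared column span in exactly k species (default 16), always
  including the human/mouse/rat trio; non-carrying species are
  perturbed if they match by chance. Planting avoids windows whose
  5' flank or first base is T, where shifted-register site identity
  between neighbouring offsets would make single-offset recovery
  ill-defined. What this background does **not** model: real UTRs'
  phylogenetic correlation, indel structure and composition bias —
  passing tests demonstrate correctness of the counting machinery,
  not real-data seed yields.
* **Expression** — 2,000 transcripts; old/young ratios log-normal
  around 1 (σ = 0.15), planted targets scaled down by the configured
  effect (default 15 %); per-replicate multiplicative noise (CV 0.2).

## Problem sizes and numerical choices

Defaults were chosen once as a realistic desk-scale study: 9 × 10⁶
reads, 300 alignment blocks, 2,000 transcripts, 1,000 resamples; the
acceptance script uses 300 null simulations and 100 power simulations
for its calibration figures. Ties in modal-read selection break
lexicographically; RPM conservation holds to ~1e-9 relative; histogram
bins are half-open on the right; all randomness flows from a single
integer seed.

## Known limitations

* Exact matching only — chemically modified or edited bases that break
  exactness are invisible, as are fragments spanning intron-containing
  or precursor-only contexts.
* The seed-call thresholds (2× both nulls, ≥25 genes) are explicit
  stand-ins for a visual criterion; yields on real data depend on them.
* The background corpus for the genomic-frequency null is
  user-supplied; no attempt is made to match UTR composition
  automatically.
* 3'U tRF detection requires trailer input and is untested against
  real trailer annotation.
* The t-test significance mode is reported for fidelity to the
  modelled protocol, not recommended.
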