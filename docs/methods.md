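# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `holophage`, in the order the pipeline runs them.

## Synthetic holobiont communities

The generator exists so that every downstream stage has planted ground
truth. It emulates the *structure* of a host-associated virome study —
phage contigs, microbial host genomes, three kinds of phage→host evidence,
environment-structured abundance, temperate-phage marker genes — not the
composition of real genomes.

**Background model.** All background sequence is i.i.d. uniform over
{A,C,G,T}. This is deliberate: under a uniform background the false-positive
behaviour of every matcher is analytically predictable (e.g. the chance that
a random 13-mer recurs three times at a fixed period in a 3 kb contig is
negligible), so "no false links on unplanted pairs" is a meaningful test.
The cost is realism — no GC skew, no repeats, no genes — discussed under
*Limitations*.

**Planting.** Features overwrite background rather than being inserted, so
contig lengths and previously planted coordinates never shift. Positions
are rejection-sampled against an occupancy map (max 100 retries, then a
`PlacementError`); planted features therefore never overlap. Phage-side
source regions (protospacers, prophage donors) are also registered so a
later tRNA overwrite cannot corrupt an earlier channel's signal.

- *CRISPR*: an array `R S1 R ... Sn R` with an exact random repeat
  (default 30 bp, 3 spacers of 32 bp). Spacers sample random phage
  substrings on random strands and are substituted at exactly
  `spacer_mutations` positions (default 0 — a spacer is ordinarily a
  faithful record of the protospacer). The whole array lands on a random
  strand.
- *Prophage*: a random phage slice (default 2–5 kb) point-mutated i.i.d. to
  a target identity (default 0.92, comfortably above the 0.80 acceptance
  filter) and written on a random strand. Host contigs (20–50 kb) are
  always > 2× the prophage length, so the half-contig span filter can pass.
- *tRNA*: a 70–90 bp random gene written exactly into the phage and with an
  exact number of substitutions, `round((1−identity)·len)`, into the host
  (default identity 0.97), making the realised identity deterministic
  rather than binomial — thresholds at 0.95 then behave reproducibly.
- *Markers*: temperate phages (probability 0.4) receive the bundled
  integrase-like exemplar back-translated with uniformly random synonymous
  codons, packaged as `TAA + ATG…CDS…stop` so the planted ORF is exactly
  the maximal start-to-stop frame at its locus.

**Abundance.** Read counts are negative-binomial with mean
`base_cpk × length_kb × factor` and variance μ + 0.1·μ²; the fold factor
(default 8) applies in a phage's enriched environment, with 6 samples per
environment. These are the desk-scale study conditions used throughout the
tests; at fold 8 and n = 6 the enrichment labeller recovers ≥ 95% of
planted labels.

**Determinism.** Each concern (labels, phage sequence, host sequence, link
indicators, planting, abundance, markers) draws from its own child RNG
stream derived from the single community seed, so the Bernoulli link
indicators can be replayed independently of sequence generation, and a
fixed config yields byte-identical output.

## CRISPR channel

**Detection.** A simplified repeat–spacer detector: exact 13-mers recurring
at a consistent period seed a candidate; the repeat unit is extended
column-wise across copies (a column joins the repeat while at most
`n_copies − 2` copies dissent, with the final extent maximising a score of
+1 per unanimous column, −0.6/−0.8 per dissent); the copy chain is rebuilt
by stepping the period so copies whose seed k-mer was mutated are recovered;
and the result is validated against repeat length 21–48 bp, spacer length
17–60 bp, ≥ 3 copies, and ≥ 0.9 per-copy identity to the consensus.
Candidates are evaluated best-supported-first and accepted greedily without
overlaps.

A boundary column where *all* copies happen to agree with flanking sequence
is mathematically indistinguishable from a longer repeat (probability
4^−(copies−1) per column), so planted coordinates are recovered exactly in
most, not all, cases; tests assert a ±2 bp tolerance. An array planted on
the reverse strand is found as its forward-strand mirror — spacer matching
is strand-symmetric, so links are unaffected.

**Matching.** Spacers are compared to both phage strands full-length and
ungapped, tolerating at most `max_mismatch` (default 1) substitutions.
Hamming scans over every position make the channel trivially
oracle-checkable; the ≤ 1-mismatch budget makes gapped alignment
irrelevant. One link per (phage, host) pair keeps the best hit
(fewest mismatches, then leftmost, then + strand).

## Prophage homology channel

**Engine.** Seed-and-extend: exact 11-mer matches are chained into
co-diagonal clusters (diagonal gap ≤ 64, subject-position gap ≤ 2 kb, at
least 5 seeds — even the weakest acceptable signal, 1 kb at 80% identity,
seeds ~86 times), and each cluster is resolved by an exact affine-gap local
DP restricted to a band around the cluster's diagonals (±32). Small
problems (≤ 4 M cells) skip seeding and run the full DP. Scoring is match
+1 / mismatch −1, gap of length L costs 10 + 10·L (the first gap column
scores −20, each further −10). The DP is vectorised row-wise; horizontal
(subject-gap) moves are resolved with a running-maximum scan, exact because
re-opening a gap in the same row never beats extending it. Hits are
selected greedily by score with no subject overlap.

**Filter.** Identity strictly > 0.80, host-side span ≥ 1 kb and ≤ half the
host contig; one link per (phage, host genome) keeps the highest score. For
host contigs under 2 kb the window is empty — such hits are rejected and
logged, since it is unstated whether those contigs should be excluded
upstream. A raw score threshold (default 50, roughly a 50 bp exact match)
replaces a database-statistics e-value: the identity and span filters
dominate acceptance, and a raw threshold is deterministic.

## tRNA channel

tRNA *prediction* is an input (GFF3); extraction is strand-aware with 1-based
inclusive coordinates converted to 0-based half-open. Matching is end-free
(overlap) global alignment, match +1 / mismatch −1 / gap −2; identity is
matches over aligned columns of the overlap region and coverage is the
overlap's share of the shorter gene. The published acceptance rule is an
identity threshold only (≥ 0.95); the ≥ 0.9 coverage floor is this
package's addition to stop short spurious overlaps from becoming best hits,
and is configurable. "Best hit" is enforced per phage tRNA (per-tRNA rather
than per-contig, which is the stricter reading); ties break to the
lexicographically smaller host and are logged. Note that end-free alignment
always trims terminal mismatches (a mismatch costs −1, two free end gaps
cost 0), so identity is measured on the trimmed overlap.

## Infection network and stratification test

Links merge into a bipartite graph; duplicate (phage, host) pairs union
their channel evidence and isolated nodes are dropped (only matched phages
and hosts appear). Enrichment labels come from Cpk (count/(length/1000)):
"sponge" requires mean sponge Cpk ≥ 2× mean seawater Cpk and detection in
≥ half the sponge samples, symmetric for "seawater", otherwise "mixed"
("unknown" when absent everywhere). The partition table counts each phage
once per distinct host-niche category it reaches; a per-edge counting mode
would be a one-line change and is deliberately not the default, since
"once per phage per niche" keeps a phage with many hosts of one niche from
dominating a cell.

The stratification statistic `diffprop` is the difference between the
conditional probabilities that an edge lands on a sponge-symbiont host given
a sponge-enriched versus a seawater-enriched phage, over edges, with
mixed/unknown phages excluded. It is bounded in [−1, 1], antisymmetric
under label swap, and undefined (an error) when either label class has no
edges. The null distribution permutes phage labels uniformly among phage
nodes with edges fixed; the p-value uses the add-one rule, so its floor is
1/(n_perm + 1). The statistic is pluggable — any callable on the same edge
arrays can replace it. The choice of a difference of conditional
proportions is this package's own explicit definition; published analyses
of this design report only a helper library and a statistic value, which is
not reproducible without the underlying network table, so no attempt is
made to match any specific published statistic value.

Calibration: on 400 independent null networks (24 phages, 16 hosts, labels
independent of niche) the rejection rate at α = 0.05 with 500 permutations
sits inside the exact binomial 95% interval, and 50 completely stratified
networks (≥ 6 phages per label) are all detected at p ≤ 0.05 — both checks
run in the test suite.

## Lifestyle calling

ORFs are maximal start-to-stop frames (first ATG after the previous in-frame
stop, stop required inside the contig, ≥ 60 aa; the recorded interval
includes the stop codon). Marker detection aligns each ORF locally
(BLOSUM62, gap open −11 / extend −1) against exemplar proteins; a hit needs
identity ≥ 0.35 over ≥ 50% of the exemplar. The bundled exemplars in
`data/synthetic_markers.faa` are *synthetic stand-ins* with realistic
amino-acid composition, sufficient because the generator back-translates
the same exemplars; real integrase/excisionase sets can be supplied as
protein FASTA.

The ensemble rule is marker precedence: any marker hit ⇒ temperate,
regardless of the composition classifier — a marker is direct evidence and
the precedence can only move calls toward temperate. Otherwise a k-NN
(k = 5) on 256-dimensional tetranucleotide frequencies decides, with
confidence = vote fraction and an explicit *unclassified* class below 0.6;
with no reference set everything without a marker stays unclassified, which
mirrors the reality that most environmental phage contigs receive no call.

T:L ratios per environment are ΣCpk(temperate)/ΣCpk(lytic) over that
environment's samples (scale-invariant in the counts), plus the
temperate/lytic contig count ratio; zero lytic Cpk reports +∞ with a flag.

## Spot quantification

`find_maxima` implements prominence-thresholded maxima ("noise tolerance"
counting): a maximum is reported iff flooding down from its value by the
threshold never reaches a higher peak. Internally, equal-value plateaus are
condensed into nodes; plateaus activate from brightest down; a union-find
records the level at which each peak's basin merges into a higher peak —
that merge level fixes the peak's prominence, and the global maximum's
prominence is its height above the image minimum (hence a constant image
has no maxima). Determinism choices: equal-valued distinct peaks are
ordered by their row-major-smallest pixel; each plateau reports the member
pixel nearest its centroid; edge maxima are included by default
(configurable). The implementation is checked against an explicit
flood-enumeration oracle on random integer images.

`optimize_threshold` formalises control-driven threshold selection: over a
grid it maximises mean count(positive controls) − mean count(negative
controls) subject to the negative mean not exceeding 1 spot per image, ties
toward the larger (more conservative) threshold. The objective is a
stand-in for an unpublished optimisation procedure and is pluggable.

`compare_groups` uses `scipy.stats.kruskal` (tie-corrected) for the omnibus
test, Dunn's pairwise z from pooled mid-ranks with the standard tie term
Σ(t³−t)/(12(N−1)), and Benjamini–Hochberg step-up across all pairs
(statsmodels). Counts, not intensities, are the analysis unit.

## Pipeline

`run_pipeline` executes simulate → channels → network → lifestyle with a
single global seed; per-stage seeds derive from blake2s(seed:stage), so
toggling stages does not shift the randomness of the others. The report
carries per-channel precision/recall against planted truth, the partition
table, the stratification summary and lifestyle tallies, and is
byte-identical across reruns of the same config.

## Problem sizes

Defaults are desk-scale: 20 phages of 5–30 kb against 10 hosts of 20–50 kb,
6 samples per environment, 10,000 permutations for a single test and 500
per replicate in calibration sweeps, 1000 replicates for rank-test
calibration. These sizes keep the full suite in the minutes range on one
CPU while leaving every statistical check adequately powered; all of them
scale up through configuration without code changes.

## Limitations

- Uniform-background synthetic data cannot expose false-positive modes
  driven by low-complexity sequence, repeats or shared mobile elements;
  passing tests show correctness of the decision rules, not real-world
  specificity.
- The CRISPR detector assumes a near-constant repeat period within an
  array and does not model repeat degeneration at array ends, leader
  prediction or Cas genes; its sensitivity relative to dedicated detectors
  is unquantified.
- The homology engine's banded DP is exact only when the optimal path stays
  inside the seeded band — guaranteed for substitution-only divergence, and
  verified against full DP in tests, but long indels could in principle
  escape the band.
- Protein-level (translated) homology, prophage boundary refinement and
  attachment sites are out of scope.
- The composition classifier is only as good as its reference set; with
  the default empty reference everything without a marker is unclassified.
- Published network-stratification values from real sponge datasets are not
  reproducible here because the underlying data and the exact statistic are
  not available; the package instead demonstrates calibration and power of
  its own explicitly defined test.
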