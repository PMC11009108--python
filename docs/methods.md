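# Methods

This note documents the models, rules and numerical choices behind
`lncscreen`, the assumptions they rest on, and what the synthetic-data
suite does and does not demonstrate.

## Gene-model merging

The merge treats a lncRNA "gene" as a cluster of highly similar isoforms
occupying one strand of one locus. Three passes build the partition:

1. **Core rule + closure.** Two same-strand transcripts group when
   (a) their bodies (span start→end) overlap by ≥ 60 % of the *shorter*
   transcript and (b) at least one exon pair shares ≥ 60 % of the
   *longer* exon of the pair. Groups are the connected components of this
   relation (single linkage). Single linkage was chosen because it is
   order-independent and cheap to verify against a brute-force
   enumeration; any iterative pairwise merging scheme converges to the
   same components.
2. **Monoexonic attachment.** A transcript left single after pass 1 with
   one exon attaches to a multi-member group when ≥ 30 % of its genomic
   span lies inside the group's merged span.
3. **Multiexonic attachment.** A remaining multi-exon transcript attaches
   when ≥ 90 % of its exonic bases fall inside the group's merged exons.

Attachment decisions are evaluated against a *snapshot* of group geometry
(pass 2 against the pass-1 groups, pass 3 against the post-pass-2
groups) and applied afterwards; a transcript joining a group therefore
never changes another transcript's decision, which makes the result
invariant to input permutation (tested). Attachment targets are only
multi-member groups: two leftover singletons never merge in passes 2–3,
because the pass-1 rule already is the pairwise merge criterion.
Qualifying for several groups resolves to the largest base-pair overlap,
ties to the leftmost group start.

Upstream filters: an exon is dropped when its covered fraction (bases
with ≥ 1 read) is below `min_covered_fraction`. The default 0.10 reads
the exclusion rule literally — remove the exon when 90 % of its length is
uncovered; the stricter alternative (keep only ≥ 90 % covered) is the
same function at 0.90. Coding overlap removes exonic bases intersecting
coding exons on either strand or coding introns on the same strand;
"losing > 70 % of genomic coordinates" is counted over exonic bases, not
span, because the subtraction operates on exons. Gene *complexity* is
`n_exons × span_bp` with span = end − start (a 148-exon, 150 kb gene
scores 22.2 M); span, not summed exon length, is used because complexity
is meant to capture both splicing structure and genomic extent.

Coordinates are 0-based half-open internally; GTF I/O converts. Gene ids
are deterministic `chrom:start-end:strand` slugs. GTF/BED12 parsing is
implemented in-module so that malformed input fails with the offending
line number.

## Target prioritization

Selection operates on a gene × sample TPM matrix with tissue labels.
Four sequential steps, each ignoring genes already selected:

1. top `n₁` by mean TPM over all samples;
2. tissues cycled in sorted-name order, each contributing its next-best
   unselected gene by tissue-mean TPM, until `n₂` genes are gathered;
3. the same round-robin over individual samples (`n₃`);
4. conserved genes only: top `n₄ₐ` by global mean, then top `n₄ᵦ` by
   maximal tissue-mean TPM ("tissue-specific expression").

Round-robin was chosen for steps 2–3 because it equalizes representation
across tissues and cell lines — the stated purpose of those steps —
where cumulative top-lists would let large or highly expressed tissues
crowd out small ones. Ties in TPM break lexicographically by gene id, so
the selection is a pure function of the matrix. Default quotas are
9,300 / 9,306 / 8,892 / (2,000 + 1,012) = 30,510. Low-expressed-exon
flags use the population standard deviation and a strict comparison
(`value < mean − 2·sd`), so a gene whose exons are all equal flags
nothing even though sd = 0.

## Array design

Each library vector encodes two 30-nt spacers against the same gene;
CasRx processes the array into two guides, and cutting a transcript at
two sites leaves fragments lacking the cap or the poly-A tail.

*Candidates.* Every 23-nt window of the spliced gene sequence is a
candidate; windows within 7 nt of the 3′ end cannot be extended to 30 nt
and are dropped. Extension runs 3′ along the target (seq23 is a prefix of
seq30); the direction is a design choice, fixed for determinism. Spacers
whose 30-mer contains a BsmBI site are removed in both orientations
(CGTCTC and GAGACG) since Golden-Gate cloning is orientation-agnostic.
Windows on exons flagged low-expressed are skipped.

*Scoring.* The on-target efficiency model is pluggable (any callable
23-mer → [0, 1]). The default is a deterministic surrogate — a logistic
in GC-distance from 0.5 and longest homopolymer run — adequate for
exercising the design logic; it is not a trained efficiency predictor,
and real libraries should plug one in.

*Off-targets.* A candidate is removed when its exact 23-mer occurs, on
either strand, in any other gene of the indexed transcriptome (23 nt is
the homology length at which CasRx activity is considered optimal, hence
the filter unit).

*Quotas.* 2–7 arrays per gene by sextile of the library-wide complexity
distribution; a value equal to a sextile boundary falls in the upper bin
(so the median maps to quota 5). Sextiles make the six quota levels
equally populated, which matches scaling guide number with structural
heterogeneity without hand-set thresholds.

*Greedy rounds.* Four rounds of decreasing stringency: R1 score ≥ 0.75,
MLD ≥ 30 %, MGD ≥ 10 % of spliced length; R2 top-quartile score (per
gene, over its surviving candidates), 25 %/5 %; R3 top-quartile,
10 %/1 %; R4 any score, MLD ≥ 10 %, MGD = positional non-overlap
(≥ 23 nt). Distances are |start − start| on the spliced sequence. Within
a round, all position-1 spacers are chosen first (best score, subject to
MGD against everything chosen; ties to the leftmost position), then each
array's position-2 spacer (MGD plus MLD to its own partner). Any failed
pick restarts the gene at the next round; failing round 4 marks the gene
undesignable. The gene's round is thus the minimal feasible round *for
this greedy order* — a round a clairvoyant designer could satisfy may be
skipped, which is accepted for determinism and speed.

*Controls.* NT arrays: random 23-mers filtered against the genome at
Hamming ≤ 3 on either strand, extended with random 7-mers, paired
consecutively. The filter uses pigeonhole seed-and-verify (split into 4
chunks, one must match exactly), verified in tests against the quadratic
scan. Blacklisting flags spacers matching essential-gene sequence with a
23-nt window at ≤ 2 mismatches on either strand; the implied 21-nt
perfect-match subcase is covered by this more permissive rule.

## Screen analysis

*Counting.* Read 1 (30 cycles) reports spacer 2 reverse-complemented;
read 2 crosses 29 nt of vector and covers the first 27 nt of spacer 1.
The index keys position 1 by 27 nt and position 2 by 30 nt. A mate
resolves by exact lookup first, then by minimum-Hamming search at ≤ 2
substitutions; a pair counts only when both mates resolve uniquely to
the same array. Ambiguous pairs (two arrays at equal best distance, or a
duplicated key) are discarded and tallied rather than assigned randomly.

*Normalization and LFC.* Array LFCs are log2((sample + 0.5)/(baseline +
0.5)) on CPM-normalized counts with the plasmid library as baseline. The
0.5 pseudocount (stated for fraction LFCs) is adopted uniformly for
zero-safety and is exposed as a parameter. Arrays with < 30 plasmid
counts are removed; arrays in the top 1 % of |LFC| in ≥ 2 nuclease-free
control screens *and* ≥ 1 sample screen are removed as noise (the rule is
skipped with fewer than two controls). Surviving counts are re-normalized
by median-of-ratios (size factor = median over zero-free rows of the
ratio to the row geometric mean) before ranking.

*α-RRA.* Arrays are ranked ascending by mean screen-replicate LFC
(depletion first); rank ties break by array id. For a gene with m arrays
at normalized ranks r₍₁₎ ≤ … ≤ r₍ₘ₎, only ranks inside the top α
fraction (default α = 0.25) are informative and

  ρ = min over {k : r₍ₖ₎ ≤ α} of P( Beta(k, m−k+1) ≤ r₍ₖ₎ ),

the chance that the k-th order statistic of m uniforms lies at or below
the observed k-th rank. When no rank qualifies, k = 1 is used as a
fallback; this keeps ρ continuous under the null so permutation p-values
remain uniform (verified by KS test at 500 genes). Significance comes
from a permutation null (default 100,000 draws): for pools of ≤ 256
arrays, m ranks are drawn without replacement (a true random
assignment); for larger pools, with replacement, indistinguishable when
m ≪ N. p = (1 + #{null ≤ ρ}) / (n_perm + 1); FDR by Benjamini–Hochberg;
hit ⇔ FDR < 0.25.

*Per-array p-values* (used for blacklisting and the gene-unified LFC) are
the normalized one-sided depletion ranks r/N, uniform under the null. An
array is blacklisted when it matches essential-gene sequence *and* has
p < 0.05 in ≥ 2 screens; blacklisted arrays are removed before gene
aggregation. The gene-unified LFC is the mean LFC of the gene's two most
significant arrays, p-ties broken toward the more negative LFC.

*QC.* Control AUC is the rank-based probability that a random
always-essential array shows a lower LFC than a random neutral array
(ties ½) — depletion is the positive direction. Lorenz evenness is the
percentage of arrays (sorted by abundance) needed to accumulate 90 % of
reads; a perfectly even library gives 90 %. Localization LFC is
log2((cytoplasmic CPM + 0.5)/(nuclear CPM + 0.5)), nuclear-enriched at
≤ 0.75 (a raw-ratio mode is available, since the published quantity is
called an LFC but printed on a ratio-like scale). CasRx activity is
1 − GFP(targeting)/GFP(non-targeting), clipped to [0, 1] with a warning.
Transposon-insertion coverage is 100 × count/total, reliable strictly
above 2 when not flagged artifactual. Screen scale arithmetic:
cells = arrays × coverage / MOI.

## Synthetic data

The generators emit exactly the statistical structure each stage
consumes, with mandatory seeds and full determinism per seed:

- **Loci**: isoform families share an identical anchor exon and heavily
  overlapping bodies (safely above the 60/60 thresholds); "split" loci
  place two transcripts at 55 % body overlap (below threshold); a
  configured fraction of loci carries a coding gene covering ~75 % of the
  first isoform's exonic bases, bracketing the 70 % drop rule. Loci are
  separated by 10 kb so cross-locus grouping is impossible and the
  intended partition is unambiguous ground truth.
- **Expression**: log-normal gene baselines (σ = 1.5 on the log scale), a
  designated tissue-specific subset boosted in one tissue, small
  log-normal sample noise, columns normalized to valid TPM.
- **Screen counts**: per-array abundances log-normal around a mean
  plasmid count of 300 (the depth a screen at 300× coverage and 15–20 M
  mapped reads per sample implies, ~200–300 reads per array); counts are
  negative binomial with dispersion 0.1 (var = μ + 0.1 μ²); a spiked 5 %
  of lncRNA genes deplete 4-fold (all arrays of a gene share the fold
  times per-array log-normal noise, σ = 0.1); always-essential controls
  deplete 6-fold; never-essential, non-targeting and nuclease-free
  control samples are null. By default each lncRNA gene gets 2–7 arrays,
  cycling through the quota range exactly as the complexity-sextile rule
  distributes them.
- **FASTQ**: exact read pairs per count in the screen's read
  architecture, optional substitution errors, constant qualities,
  array ids in headers (ignored by the counter).

**What passing tests show — and don't.** Recovery of ≥ 90 % of spiked
genes at FDR < 0.25 with empirical FDR ≤ 0.1 demonstrates that the
counting, filtering and α-RRA machinery is correctly assembled and has
the expected power under negative-binomial noise at realistic depth. It
does not demonstrate performance on real screens, where guide efficacy
varies per spacer, depletion is not shared uniformly across a gene's
arrays, counts are overdispersed beyond a single global dispersion, and
off-target structure is sequence-driven rather than absent. Likewise the
clustering ground truth exercises the threshold logic, not the messiness
of real annotation (fragmented isoforms, retained introns, antisense
nests).

## Problem sizes used by the test suite

Oracle suites run at ≤ 20 transcripts (clustering), ≤ 1.5 kb sequences
(mismatch scans) and N = 20 arrays (exact α-RRA enumeration). The
end-to-end test uses 500 lncRNA genes plus 60 control genes and 50 NT
arrays (2,540 arrays), five samples counted from FASTQ (~3.8 M read
pairs), and 20,000 permutations; the library default is 100,000
permutations. The selection check runs at 50,000 genes × 120 samples.

## Known limitations

- The surrogate spacer scorer encodes composition heuristics only; round
  assignment on real sequence will differ from a trained model's.
- Greedy feasibility can skip a round a global optimizer could satisfy.
- The α-RRA permutation null is shared across genes of equal array count;
  gene-specific covariates (e.g., expression-dependent variance) are not
  modeled.
- Counting keys on the 27/30-nt read portions only; indels in spacers are
  not recovered (substitution-only matching).
- Pass-2/3 attachment never merges two existing groups via a bridging
  transcript; a bridge therefore attaches to its best group only.
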