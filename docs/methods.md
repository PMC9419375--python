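# Methods

`spacerscan` analyses CRISPR defense repertoires at the community level:
where spacers occur (assemblies and raw reads), how fast they turn over
between near-clonal strains, how their abundance relates to the abundance of
their targets, and how much of the known phage diversity a repertoire
covers. Because the interesting quantities (acquisition rates, read classes,
shared-spacer fractions) are unobservable in real data, the package ships a
simulator that generates communities with complete ground truth; every
estimator is validated by parameter recovery against it.

## The divergence and turnover model

Two strains descend from a common ancestor and evolve independently for `G`
generations. Per lineage:

- substitutions arrive as a Poisson process with rate `mu` per base pair per
  generation, at uniform positions, with no indels;
- spacer acquisitions arrive as a Poisson process with rate `rho` per cell
  per generation; each new spacer is a random substring of a random phage
  (length uniform on `spacer_length_range`, random strand) inserted at the
  leader end of the array together with a fresh repeat copy, so array order
  reflects acquisition order;
- spacer loss is an optional exponential decay at rate `loss` per spacer per
  generation. Real populations certainly lose spacers, but no loss rate is
  identifiable from the data the analyses emulate, so the default is 0 and
  the knob exists for sensitivity analysis only.

The turnover estimator chains four quantities for a strain pair:

1. **Fragment ANI.** Each genome is cut into 1-kb fragments; each fragment
   is placed at its best locus in the partner (exact 16-mer seeding at ten
   offsets per fragment, gapless comparison, both strands) and kept at
   >= 80% identity. ANI is the mean identity of kept fragments, in percent;
   `n_fragments` counts kept fragments over both directions.
2. **SNV estimate.** `snv = n_per_genome x 1000 x (100 - ANI)/100`, where
   `n_per_genome = n_fragments/2` is the fragment count covering the
   alignable length once. This is the pairwise (two-branch) SNV count over
   the aligned length; using the raw bidirectional total here would count
   every difference twice and bias the turnover rate low by exactly 2x.
3. **Unique spacers.** Spacers detected in the two genomes are grouped by
   100%-identity clusters; `unique` counts clusters present in exactly one
   genome, and the shared fraction uses the union of clusters as denominator
   (Jaccard-style: symmetric and bounded in [0,1]; the |A|+|B| denominator
   is available behind `denominator="total"`).
4. **Turnover.**
   `rate = N x mu x L_aligned x unique / snv`
   with `L_aligned = n_fragments x 1000 / 2` (per-genome aligned length) and
   community size `N` (default 1e7 cells; default `mu` 8.9e-11/bp/gen, the
   literature value for lactic acid bacteria). Both `snv` and `unique` are
   two-branch quantities, so the branch factor cancels; no factor-2
   correction is applied. The rate is only computed for pairs with
   ANI > 99 (near-clonal regime), and pairs with zero unique spacers or an
   undefined ANI are flagged and excluded from rate distributions.

Under simulation defaults (`L=200 kb`, `mu=1e-8`, `G=5e5`, `rho=2e-5`,
`N=1e7`) the chain recovers `rho x N` and `mu x L_aligned / rho` within a
few percent as the median over 50 pairs; per-pair scatter is dominated by
Poisson noise on the ~20 unique spacers per pair.

## Array detection in assemblies

Exact 13-mers that recur at least three times with consecutive gaps in
`[min_repeat + min_spacer, max_repeat + max_spacer] = [38, 96]` bp seed
candidate repeat sets, which are extended column-by-column while **all**
copies agree, bounded by the 47-bp repeat cap and by keeping every gap
>= 15 bp. Strict agreement is the right rule for assemblies (consensus
sequences with essentially identical repeat copies) and yields exact repeat
boundaries; diverged copies at the read level are instead handled by the
mismatch-tolerant read scanner. A built locus must additionally pass:

- pairwise repeat identity >= 0.9 between consecutive copies;
- adjacent-spacer identity <= 0.8. This guard rejects tandem repeats, whose
  "spacers" are near-identical. The threshold is deliberately far above the
  ~0.55 mean identity that *unrelated* 28-42-mers already reach under this
  package's identity score (glocal, strand-maximised, gap -2 over a short
  denominator): a stricter guard (e.g. 0.6) would reject ~15% of genuine
  random spacer pairs and therefore most real arrays. Checking adjacent
  pairs only keeps the cost linear; tandem repeats always betray themselves
  in adjacent gaps.

Overlapping candidates resolve in favour of more repeat units. The
retention filter then removes spacers shorter than 15 bp or of 50 bp and
longer, dropping arrays left empty; filtering removes entries from the
ordered spacer list, so the exact repeat/spacer interleave (and the
reconstruction identity `concat == genome[start:end]`) is guaranteed only
for unfiltered arrays.

A note on identifiability: if every spacer at an array's junctions began
with the same base, the repeat/spacer boundary would be genuinely ambiguous
for any detector. With the simulator's uniform-random spacers and the
default ten spacers per array (real arrays run to dozens; a published
median is ~26) the probability of such ambiguity is negligible
(~4^-10 per edge).

## Spacer extraction from raw reads

A read spanning repeat-spacer-repeat contains two near-identical substrings
at a shift of 38-96 bp. Detection is three-stage, per sample:

1. **Candidates.** Each read is compared to itself at every admissible
   shift; the longest exactly agreeing run that satisfies the repeat/gap
   bounds yields a candidate repeat. Candidate extraction is exact on
   purpose: a mismatch budget would let runs coast deterministically past
   the repeat boundary on every read of a junction.
2. **Consensus.** Candidates are strand-canonicalised and grouped into
   families by shared 13-mers. A single read cannot place the boundary when
   a flanking base coincides with a spacer base (probability 1/4 per
   column), but the artefactual extension differs between junctions while
   the true repeat is common to all, so members vote per column (weighted
   by read support) and only columns where one base carries more than half
   the family survive.
3. **Emission.** Reads are rescanned for occurrences of each consensus
   repeat with up to 2 mismatches (absorbing sequencing errors), on the
   orientation in which the repeat is lexicographically smallest; gaps of
   15-49 bp between consecutive occurrences are emitted as spacers,
   deduplicated exactly, with coverage = number of supporting reads.

The metagenomic retention filter removes coverage-1 spacers and spacers
under 15 bp. Normalisation is per million *reads* (not bases), optionally
divided by community richness.

## Clustering and the identity score

Identity between two sequences is the number of matches in the best global
alignment with free end gaps on the shorter sequence (match +1, mismatch
-1, gap -2), divided by the shorter length; both strands are tried and
sequences are first reduced to their lexicographically smaller strand, which
makes the value invariant under reverse-complementing either argument.
Among score-optimal alignments the match count of one canonical alignment
is reported (diagonal preferred over gaps, leftmost optimal end), so five
mismatches between 30-mers score exactly 25/30. The DP is row-vectorised;
the left-gap recurrence collapses to a prefix-max scan with score, end
column and match count bit-packed into one int64.

Clustering is greedy and CD-HIT-like: sequences sorted by length
(descending, ties lexicographic) join the earliest-founded cluster whose
representative they match at >= threshold (100% and 80% are the thresholds
used downstream), else found a new cluster. The sort makes the result
independent of input order; at 100% the clusters coincide with exact
strand-canonical groups for sequence sets without substring pairs.
Sub-identity (80%) clusters can be computed per source category (genomic vs
metagenomic) as well as pooled.

## Read classification into spacer vs protospacer evidence

Each dereplicated spacer becomes a repeat-spacer-repeat reference flanked by
its array's consensus repeat. Reads are recruited by exact 15-mer seeding
against both strands, then the maximal-scoring ungapped block (match +1,
mismatch -3) is taken; blocks with more than 2 mismatches are dropped and
one best hit is kept per read (ties: lower reference index, '+' strand,
leftmost). The mismatch penalty of -3 stops block extension from coasting
through chance matches at the spacer boundary: a run of k flank bases
matching the repeat extends the block only with probability 4^-k, which
keeps boundary noise to 1-2 bp.

Classification by the aligned interval on the reference layout
`[repeat | spacer | repeat]`:

- **protospacer**: block covers >= 90% of the spacer and extends < 3 bp
  into either repeat (the read comes from the target side);
- **array**: block covers >= 15 bp of spacer and >= 5 bp of a repeat;
- **ambiguous** otherwise - counted, excluded from abundances.

The thresholds are config-exposed; the 3-bp protospacer incursion allowance
exists precisely because of the chance-match boundary noise above, and the
two rules are mutually exclusive by construction. Counts are normalised to
cpm (`x 1e6 / total reads`); the spacer-protospacer abundance relation is
summarised by OLS in log10 space over references seen in both classes
(log-log is the scale on which a proportional planted relation is linear;
linear-space fitting of cpm values spanning orders of magnitude would be
dominated by the few largest references).

## Target matching and vOTU coverage

Spacers are searched against a target FASTA (headers may carry `vOTU=` and
`category=` keys) as ungapped, full-length matches with at most 2
mismatches, both strands, via pigeonhole seeding (split into 3 parts, any
exact part anchors a verification). This replaces a heuristic
BLAST-with-cutoffs step by the exact decision rule the 2-mismatch criterion
implies; gapped hits are out of scope. Hits within 2 kb of an annotated
CRISPR repeat on the target are removed as self-matches. Category
precedence when a spacer hits several databases' worth of targets is
phage > plasmid > chromosome. vOTU summaries report distinct vOTUs per
genome, the spacers-per-vOTU histogram, the fraction of the catalogue
targeted, and an accumulation curve over genomes whose plateau equals the
exact union coverage.

## Community summaries

Dominant species: prevalence (fraction of samples with nonzero abundance)
> 2% and median abundance over all samples (zeros included) > 0.1%.
Defense-system prevalence classes per species: core > 90% of strains,
cloud < 10%, accessory otherwise; boundary prevalences of exactly 10%/90%
fall into accessory because strict inequalities on both sides would leave
them undefined. Rarefaction/accumulation curves sample orderings without
replacement; all orderings are enumerated exactly when there are at most
`n_perm` of them (so the two-sample disjoint case gives means 7.5 and 15
exactly), and the final point always equals the exact union.

## Simulator scope and what passing tests show

The simulator emulates the statistical structure the estimators assume:
i.i.d. background sequence at a set GC, identical planted repeat copies,
uniform-random spacers, Poisson substitutions shielded from the planted
arrays (whole-array shielding is the default so that spacer identity stays
orthogonal to divergence; repeat-only shielding is available via
`shield_arrays=False`), phage pools grouped into vOTUs at ~2% template
divergence, and uniform shotgun reads with iid substitution errors and a
fixed FASTQ quality character. It does not model genome architecture,
repeat degeneracy within arrays, recombination, selection on spacers,
indels, coverage bias or realistic error profiles. Parameter-recovery
results therefore demonstrate estimator correctness under the stated model,
not performance on real libraries; on real data, array degeneracy and
coverage structure will loosen the exactness results first.

## Problem sizes and determinism

The validation battery (also run by `scripts/acceptance.py`) uses: 50
strain pairs at L=200 kb for turnover recovery; 100k error-free 150-bp
reads over 2 genomes + 5 phages for classification; 30 host/phage pairs
and 1M reads for the abundance correlation; ~350 sequences for the
clustering oracle; 20 planted arrays and 200 shuffled 100-kb controls for
detection; 500 spacers against 100 kb for the search oracle. These sizes
put every recovered quantity well inside its tolerance while the whole
battery completes in a few minutes on one CPU. All randomness flows from a
single seed through `numpy.random.SeedSequence` spawning; identical seeds
give byte-identical outputs.

## Known limitations

- Orientation of detected arrays is reported as `unknown`; leader calling
  and Cas-subtype assignment are inputs, not outputs.
- The read-level extractor reconstructs spacers, not array order; CRASS-style
  graph reconstruction is out of scope.
- Fragment ANI is gapless within fragments; indel-rich divergence would
  fragment alignments and bias ANI low (the divergence model is SNV-only).
- At 100% identity, substring-containment pairs would merge (CD-HIT
  convention); the exact-group equivalence holds for length-diverse spacer
  sets without containments.
- The greedy 80% clustering depends on the identity definition; other
  tools' word filters and denominators will disagree near the threshold.
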