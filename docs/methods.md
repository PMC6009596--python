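# Methods

`polyasm` implements the assembly-curation and pseudomolecule-construction
computations used when finishing an allotetraploid (AABB) genome from mixed
evidence: an optical genome map for chimera detection, mate-pair libraries
for scaffolding, Hi-C contacts for chromosome-scale ordering, and the two
diploid ancestors' genomes for subgenome partitioning.  This note records
the models, the parameters that matter, and the design choices made where
the procedure was genuinely open.

## The synthetic study system

Real inputs at this problem's native scale (a ~2.6-Gb genome, hundreds of
gigabases of molecules and reads) are not needed to exercise the
computation, so the package ships a seeded generator
(`polyasm.synthetic`) that emulates the *structure* of such data at desk
scale.  The default study conditions are:

- **Genome**: 2 subgenomes x 2 chromosomes x 500 kb.  Ancestor A is
  uniform random DNA; ancestor B diverges from it by 3 substitutions per
  100 bp; each subgenome diverges from its ancestor by 1 per 100 bp.
  Short indels (<= 5 bp) occur at 1e-4 per bp — enough to stress k-mer
  partitioning and map sizing without complicating coordinate lifting.
- **Draft**: chromosomes fragmented at ~80 kb (sd 15 kb, min 40 kb), each
  fragment randomly oriented; 5 chimeras are planted by fusing two
  non-adjacent fragments (cross-subgenome joins preferred with
  probability 0.5, since homoeologous similarity is the dominant chimera
  source in allopolyploids).  The fragment floor keeps each chimera arm
  long enough to carry a handful of nick labels, which is what any
  map-based method needs to see a junction.
- **Optical molecules**: sampled at 25x coverage, lengths ~N(220, 40) kb;
  labels are true Nt.BspQI sites (GCTCTTC, both strands) with 5% missed
  labels, ~1e-6/bp spurious labels, and interval sizing noise of 2% (the
  molecule error model is Normal with sd proportional to inter-label
  distance).  10% of molecules are drawn to fail the retention filters.
- **Mate pairs**: three libraries (3 kb +- 0.3, 8 kb +- 0.8, 17 kb +- 1.7;
  20k/10k/5k pairs), innie orientation, 100-bp reads, 5% non-unique.
  Reads crossing a fragment boundary in truth are dropped, so pairs never
  bridge a planted junction — the discordance signal is by construction.
- **Long reads**: 10x coverage, ~N(12, 3) kb.  Reads are simulated along
  each draft component's *source interval*; overhang beyond the interval
  cannot align and becomes a soft clip with ~30 bp boundary jitter, so
  every planted junction accumulates a clip cluster.
- **Hi-C**: 150k contacts; intra-chromosome distance d drawn with
  p(d) ~ (1+d)^-1, 10% uniform inter-chromosome background, 10% low-mapq
  and 5% duplicate records to exercise filtering.

Every simulator draws from `default_rng([seed, op_tag])` with one tag per
operation, so outputs are byte-identical under a fixed seed and stages can
be re-run independently.

**What this does not emulate**: base-level read errors (evidence is
emitted at alignment-record level), repeat-induced mapping ambiguity
beyond a flat non-unique rate, biological contact-matrix structure
(compartments, centromeres), chromosome-scale length heterogeneity, and
real optical-map assembly error.  Passing tests therefore demonstrate the
correctness of the decision logic and the recoverability of planted
structure under calibrated noise — not performance on real data, where
mapping and coverage artifacts dominate.

## Optical map alignment

Maps are ordered label positions.  `align_maps` maximizes, over monotone
label matchings in either orientation:

    sum over matched pairs of  [ match_reward - (residual/tol)^2 ]
      - miss_penalty * (skipped reference labels)
      - extra_penalty * (skipped query labels)
      - end_penalty * (unmatched query end labels)

with `tol = max(500 bp, 10% of the reference interval)`.  Defaults
(reward 3, miss/extra 3, end 0.5) are set so a spurious chain of
coincidental interval agreements cannot profit: an unmatched skip costs as
much as a match earns, and a random interval pair mis-sizes by far more
than the tolerance.  The DP restricts transitions to skipping at most
`max_skip = 4` labels — a speed bound, not part of the objective; on tiny
maps the tests raise it so the DP search space equals full enumeration,
and equality against a brute-force oracle is asserted on >= 100 random
pairs.  Ties prefer '+' orientation, then the leftmost reference
placement.  The kernel is JIT-compiled with numba when available and runs
as plain Python otherwise.

"Fully aligned" is not a standard term with a fixed definition; here a
query is fully aligned when every label is matched except at most one at
each end, which tolerates molecule-end sizing artifacts without letting
interior disagreement pass.

Molecule retention follows standard single-enzyme QC: length strictly
greater than 150 kb, at least 8 labels, label SNR >= 3.0 and average
intensity < 0.6 (the intensity bound is applied literally as an upper
bound).

## Conflict detection and the chimeric score

A draft sequence is digested in silico and aligned to the genome maps.  At
toy scale the genome map is the digest of the true chromosomes — de novo
optical-map assembly is a separate problem and out of scope here — so the
map plays the same role the assembled consensus map plays in practice.

A **split alignment** is flagged when the best placement leaves a terminal
run of >= 3 unmatched labels that itself places elsewhere
(non-colinearly).  Two refinements matter in an allopolyploid:

1. *Terminal trimming.*  The DP will happily extend one or two labels past
   a junction when a skip combination happens to mis-size by little.
   Correct placements of exact sequence digests have near-zero interval
   residuals, so terminal matched pairs with residuals > 250 bp are
   trimmed before the tails are measured.
2. *Optimal split point.*  When the two joined fragments come from
   homoeologous regions, labels continue to match across the junction
   (~70% of nick sites survive ~5% sequence divergence) and the junction
   cannot be read off the primary alignment.  The split point is therefore
   chosen as the label boundary maximizing the summed score of the prefix
   aligned to one placement's map plus the suffix aligned to the other's;
   crossing the junction always loses score because homoeologous
   continuation pays miss penalties that the true placement does not.

The junction is reported with its label-bounded uncertainty interval
`[lo, hi]` (the innermost matched labels of the two placements): between
two labels an optical map is blind, and in a label desert that interval
can span tens of kb.  All downstream evidence respects it.

A **sizing discordance** (>= 3 consecutive intervals each beyond
tolerance) is also flagged, covering scale errors that do not split.

The **chimeric score** of a junction is the percentage of molecules
overlapping the +-50-kb window on the genome map that fully align; with
zero local molecules the score is 0 and flagged "no evidence" — absence of
optical data never nominates a break.  A split junction disagrees with
*both* placements' maps, so the score is computed on whichever side
carries more molecule evidence (relevant when one fragment ends at a
chromosome terminus, where nothing can span).

## Decision rules and breakpoints

A junction is a **candidate** chimera iff its score is >= 30% and more
than two fully aligned molecules span it.  A candidate is **broken** iff
the mate-pair relationship of its 10-kb flanks disagrees, or fewer than 5
fully aligned long reads span the region; otherwise it is kept, with the
firing clause recorded as a rationale code.  MP "disagreement" is made
precise by reusing the link-validity rule: fewer than 3 unique pairs with
one mate in each flank, innie orientation, and implied insert within
+-5 SD of their library mean.  The flanks sit outside the junction's
uncertainty interval so a concordant pair genuinely bridges the two
placements.  Both rules are monotone by construction: raising long-read
span coverage or the chimeric score can never convert a keep into a break.

The executed breakpoint is the median boundary of the largest soft-clip
cluster (single-linkage, 100-bp tolerance, >= 3 reads) within the
uncertainty interval +- 10 kb, ties resolved toward the junction; clip
pileups within 1 kb of a sequence terminus are alignment-edge artifacts
and ignored.  Without any cluster the junction coordinate itself is used.
Broken sequences become `{id}.1, {id}.2, ...` with bases conserved and
every decision logged.  Junctions that fail the candidate or confirmation
clauses are kept and logged rather than resolved manually.

## Mate-pair scaffolding

Only pairs with both mates unique yield links; a link's joined ends follow
from mate strands (innie).  A link's implied insert is `d_a + d_b`, the
mates' distances to the joined ends — the gap is unobservable at filter
time, so this is the zero-gap insert; the +-5 SD window is inclusive at
its boundaries and uses the nominal library SD.  Two contig ends join only
when a *single* library contributes >= 3 reasonable links (a conservative,
literal reading of "in each fragment library"), and an end with two or
more competing supported partners joins nothing: ambiguity produces
singletons, not guesses.  Scaffolds are the maximal simple paths; gaps are
`round(mean(insert_mean - d_a - d_b))`, clamped to 10 bp and flagged when
smaller.  Output ordering is deterministic and independent of link order.

## Hi-C grouping, ordering, orientation

Contacts with mapq > 20 (strict) and no duplicate flag are binned at
50 kb; intra- and inter-sequence submatrices are normalized separately
(entry / product of its bins' submatrix coverage, rescaled to nonzero mean
1).  Scaffold-level similarity is the mean normalized contact per bin
pair.

Grouping is average-linkage agglomeration cut at k groups.  It is written
in-package (~40 lines) rather than delegated to scipy/sklearn because the
contract requires a documented deterministic tie-break — equal
similarities merge the pair whose smallest member names sort first — which
library implementations do not guarantee.  The published procedure's
"threshold of the contact frequency" for forming initial groups is never
quantified, so a fixed-k cut is used as the interpretation.

Within a group: scaffolds are subclustered into min(5, size) subgroups;
each subgroup is ordered by greedy adjacent-contact chaining (heaviest
pair first, degree <= 2, acyclic; remaining chains merged at their
best-matching ends); each scaffold is oriented by the sign of the
contact-weighted position gradient toward its chain neighbours — the bins
of a correctly oriented scaffold interact most with the neighbour they
face.  Each ordered subgroup then collapses into a super-bin; super-bins
are chained by the same rule and each super-bin's direction is set by its
scaffolds' gradient toward the neighbouring super-bins.  The concatenated
order is canonicalised so the lexicographically smaller terminal scaffold
comes first — order and orientation are only defined up to global
reversal, and a lexicographic convention is deterministic where a
"heaviest end inward" convention is not.

Pseudomolecules concatenate each group's ordered scaffolds with 100-N
spacers (gap length is unspecified in the source procedures; 100 is the
common AGP convention for unsized gaps), reverse-complementing '-'
scaffolds; AGP v2.1 output uses gap type "scaffold" with
"proximity_ligation" evidence, and an AGP-to-FASTA reconstruction is
asserted as a round-trip identity.  The heatmap counts links in 500-kb
nonoverlapping windows and reports log2(count), masking empty bins to
match a 0-10 display scale.

The ordering/orientation recovery test uses one 2-Mb chromosome cut into
~20 fragments with 10-kb bins, so each scaffold holds several bins and the
orientation gradient is defined; with 50-kb bins a 100-kb scaffold has too
few bins to orient, which is a resolution fact of the method, not an
implementation limit.

## Subgenome partitioning

Whole-genome alignment against the two ancestors is replaced by
diagnostic k-mer voting: canonical (strand-collapsed, hence odd k) 21-mers
unique to one ancestor form that ancestor's diagnostic set, and a scaffold
is labelled A when its diagnostic-A hits reach 10 votes and at least twice
the B votes (symmetrically for B); both sides high with an unmet margin is
"ambiguous" — reported, never forced — and anything else "unassigned".
The 2:1 margin with a 10-vote floor keeps false assignment near zero at
the toy divergences while leaving genuinely mixed (chimeric) scaffolds
visible; a 10-kb windowed vote track is retained for exactly that
diagnostic.  Voting is exactly symmetric under swapping the ancestors and
invariant under reverse complement, both asserted as tests.

## Reporting

N50/N90/L50 follow the cumulative-length definition on the
descending-sorted lengths; gaps are maximal runs of N (length >= 1); GC%
is computed over non-N bases.  Pseudochromosome tables report
gap ratio = 100 x gap_length / length and anchored percent = 100 x
length / total assembly length, rounded half-up to 2 decimals as printed
tables are; the totals row sums columns exactly and recomputes its ratio
from the sums.  Subgenome summaries consider only sequences strictly
longer than 10 kb.  Anchored percent counts named pseudochromosomes only;
subgenome-separated percent counts all A- and B-labelled entries including
unplaced ones.

## Numerical and degenerate-input choices

- Alignment requires >= 2 query labels; single-label maps are rejected.
- Score floor 6 (~2 clean matches) for reporting an alignment at all.
- Empty molecule sets, empty drafts, empty record tables all yield empty
  outputs rather than errors; invalid configuration (rates outside [0,1],
  non-positive lengths/SDs, more chimeras than fragment pairs) raises
  `ValueError` at construction.
- Breakpoints exactly at 0 or at sequence length are rejected by
  `apply_breaks`; upstream localisation clamps its fallback inside the
  sequence.
- All tie-breaks (orientation preference, leftmost placement, cluster
  merge order, chain merge order, canonical path direction) are
  deterministic and documented at the definition site.

## Problem sizes

Tests and the acceptance script run the full pipeline at the default toy
scale: 20 seeds for chimera recovery (100 planted junctions), 20 for
mate-pair and Hi-C ordering recovery, 20 for subgenome accuracy, 100
random map pairs for the DP-enumeration check.  These sizes give binomial
standard errors of a few percent on the reported rates, which is the
package's chosen balance between statistical resolution and a test suite
that runs in minutes.

## Known limitations

- The genome map stands in for an assembled optical consensus; errors of
  real map assembly (chimeric map contigs, collapsed repeats) are not
  modelled.
- Sizing-discordance junctions carry a single-point location (no split
  refinement), so their breakpoints rely entirely on soft-clip clusters.
- Chimeras whose two fragments join near-colinearly in homoeologous
  coordinates are fundamentally ambiguous to a single-enzyme map and may
  be kept; the simulator can produce such joins and the recovery targets
  (>= 0.9) budget for them.
- Greedy contact chaining is not an exact TSP solution; with very weak
  decay or very short scaffolds the order degrades before the clustering
  does.
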