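# Methods

`ervfossil` implements the comparative-genomic toolkit used to study an
endogenous retrovirus (ERV) family shared across distantly related
mammalian hosts: classifying proviruses and solo LTRs from repeat
annotation, calling orthologous insertions between two species, dating
insertions from LTR–LTR divergence, detecting inter-LTR gene conversion,
and quantifying selection and coding integrity on retroviral domains.
Every stage is exercised end to end on simulated two-species genomes
with fully known ground truth.

## The biological model

A retrovirus integrates as a provirus: 5' LTR — internal coding region
(*gag*, *pol*, *env*) — 3' LTR, flanked by a short target-site
duplication (TSD; 4 bp for gammaretroviruses). The two LTRs are
identical at integration. Afterwards the provirus evolves at the host's
neutral rate; ectopic recombination between the LTRs can delete the
internal region, leaving a solo LTR. These facts give three measuring
instruments:

* **copy classification** — two same-orientation LTR hits separated by
  3–10 kb of intervening sequence delimit a putative full-length
  provirus; an unpaired hit missing <150 bp at its consensus 5' end and
  <10 bp at its 3' end is a complete solo LTR;
* **the two-LTR clock** — the K2P-corrected divergence *d* between a
  provirus's LTRs dates its insertion as *t* = *d* / (2 *r*), where *r*
  is the host neutral substitution rate per site per year (defaults
  shipped: 2.7×10⁻⁹ for vespertilionid bats, 1.8×10⁻⁹ for felids,
  2.2×10⁻⁹ as a mammalian average) and the factor 2 reflects both LTRs
  mutating independently;
* **orthology** — because independent integration at the same host
  position is vanishingly unlikely, presence of an element at the
  orthologous position in two species proves insertion before their
  split, and a contiguous "empty" pre-integration site (single TSD copy)
  proves insertion after it.

## Annotation

`pair_ltrs` merges fragmented same-family hits (overlap >50% of the
shorter hit, or genomically adjacent rows with advancing consensus
coordinates), then pairs LTR hits whose intervening sequence — measured
between `ltr5.end` and `ltr3.start`, bounds inclusive — lies in
[3000, 10000] bp on the same contig and strand. Pairing is an **exact
maximum-cardinality matching** (blossom algorithm) over all eligible
pairs, tie-broken towards the smallest total intervening length and then
towards leftmost-first pairs. We chose exact matching over a greedy
left-to-right scan because greedy is not guaranteed to maximise the
number of proviruses on chains of ≥3 hits (counterexamples exist where
pairing the two leftmost hits blocks two other eligible pairs), and
maximum recovery is the property the classifier is asked to deliver; the
small-gap/leftmost tie-break keeps output deterministic and
order-independent. The completeness rule for unpaired hits uses strict
bounds ("missing less than"), applied on consensus coordinates, since
fragment hits carry exactly that information.

Two sequence-level screens are included: the cross-species hit filter
(≥80% identity over ≥80% of the query, both inclusive) and the
family-membership rule (≥80% global-alignment identity to at least one
member, terminal gaps excluded from the denominator so truncated copies
are not penalised; candidates under 50 bp are refused).

## LTR–LTR dating

LTR pairs are aligned globally (match +1, mismatch −1, gap open −5,
extend −1; a pluggable external alignment can be supplied). Divergence
is Kimura's two-parameter distance
d = −½·ln[(1−2P−Q)·√(1−2Q)], with P and Q the transition and
transversion proportions over usable columns (gap- and N-containing
columns are skipped). Results with <50 usable sites are flagged
low-confidence; a non-positive logarithm argument flags saturation and
leaves *d* undefined.

**CpG masking.** Methylated CpG sites are hypermutable and inflate
apparent divergence, so by default every alignment column that is part
of a CpG dinucleotide in *either* sequence (read on the ungapped
sequence, through gaps) is masked before counting. Either-sequence mode
is the conservative choice when the ancestral state is unknown: it
catches both the intact CpG and its decayed TpG/CpA partner. A
consequence worth knowing: on data with **no** CpG rate elevation, this
masking is not neutral — a substitution that *creates* a CpG context
gets its column masked while the corresponding unmutated columns mostly
do not, so masked divergence underestimates the true distance by
roughly 15–20% at these GC contents. The clean-clock recovery
experiment therefore runs unmasked (the generating model there has no
CpG effect), while the benefit of masking is measured directly: with
10× CpG hypermutation, the masked age is closer to truth than the
unmasked age in ≳99% of replicates. On real data, where CpG
hypermutation is the dominant distortion, masking remains the right
default; ages should nevertheless be read as mild underestimates, which
is also the direction gene conversion pushes them.

Sliding-window profiles split a pairwise alignment into 300-column
windows at 50-column steps (the trailing partial window is dropped;
alignments shorter than one window collapse to a single window with a
warning), reporting per-window identity and K2P-corrected identity.

## Orthology calling

For each donor locus, two probes are extracted: 200 bp of host flank
plus 200 bp of element terminus across each junction, emitted in
element orientation (minus-strand loci are reverse-complemented).
Probes are searched against the target genome by an internal
seed-and-extend aligner (exact 16-mer seeds grouped by diagonal, local
Smith–Waterman extension of each candidate window); externally produced
BLAST tabular hits can be adapted instead — the pairing logic only sees
the hit contract.

The discriminating signal is the **host flank**: the element half of a
probe matches every family member in the target, so hits are ranked and
pairs scored by flank-side matches (score as tie-break), hit lists are
capped only after flank-aware ranking, and a candidate pair whose
summed flank matches fall below 100 is rejected as uninformative
(yielding `unresolved` rather than a spurious presence call). The best
5'/3' pair on one contig, consistent orientation, within 20 kb, is
interpreted through the distance *g* between the element-side
junctions: *g* ≥ 0.8× the expected provirus length → `present_provirus`
(for solo-LTR donors the expectation falls back to 2·LTR + 3 kb, the
minimum provirus); |*g* − LTR| ≤ 0.2×LTR → `present_solo`; *g* ≤ 25 bp →
`absent_empty`, recording the duplicated target site when the flanks
overlap by 2–10 bp (a 4-bp TSD gives *g* = −4); anything else is
`unresolved`. The 20 kb cap, ±20% solo band and 25 bp contiguity bound
are this package's choices — tolerant of indels and assembly noise
while keeping the three states disjoint by construction.

Per-branch insertion counts use Dollo parsimony (one gain, no loss):
each locus is assigned to the branch above the MRCA of the species
carrying it; a pattern with an absent species inside that clade is
reported as a conflict, never silently assigned. Incomplete lineage
sorting is not modelled, which is why conflicts are surfaced rather
than resolved.

## Gene conversion

For a provirus orthologous in species A and B, the four LTRs form a
quartet whose unrooted topology separates two histories: grouping **by
LTR position** ({5'A,5'B}|{3'A,3'B}) is the speciation signal expected
without conversion, while grouping **by provirus** ({5'A,3'A}|{5'B,3'B})
indicates post-speciation homogenisation of the two LTRs within each
lineage. The quartet is resolved by the four-point condition on
CpG-masked K2P distances computed from a reference-anchored multiple
alignment (each LTR aligned to the first and projected onto its
columns; adequate for the highly similar sequences involved, and a
better external alignment can be substituted). Support is the
proportion of 1000 column-bootstrap replicates recovering the
point-estimate split; undefined (saturated) distances or ties give a
star topology with support 0. Distance quartets replace
maximum-likelihood trees with approximate-likelihood-ratio supports
here: the discriminating signal is purely topological and fully
captured by the four-point condition at this scale. Conversion calls
are topology-only; tract boundaries are not located. Single-lineage
conversions flip the topology only when the tract is large (≈70%+ of
the LTR under the default simulation times) — partial tracts in one
lineage are genuinely harder to see, a limitation shared with the
tree-based version of the test.

## Selection and integrity

dN/dS (ω) per coding domain is estimated by Nei–Gojobori counting:
synonymous/nonsynonymous site fractions per codon are computed from the
9 single-base neighbours (changes to stop codons excluded); observed
differences per codon pair are averaged over the equally weighted
shortest mutational paths avoiding stops (codon pairs with all paths
blocked, or containing gaps/Ns/stops, are skipped for that pair);
proportions are Jukes–Cantor corrected and pair distances averaged;
ω = d̄N/d̄S, undefined when d̄S = 0. Departure from ω = 1 is tested by
resampling codon columns (1000 replicates, two-sided percentile
p-value), which substitutes for a likelihood-ratio test against a
branch model: a full codon ML engine is out of scope, the counting
estimator recovers simulated ω ∈ {0.2, 0.5, 1.0} within 0.03 under the
matched generating model, and the bootstrap rejects a true ω = 1 at
close to the nominal 5% level. One pooled ω is reported per
domain/subfamily alignment; per-domain p-values are reported raw, with
no family-wise correction. An alignment must provide ≥2 sequences and
≥30 shared ungapped codons.

ORF integrity counts disruption events against an in-frame reference
row: in-frame stop codons (the natural terminator of an ORF-ending
domain can be exempted) plus frameshifts, where one maximal indel run
whose length is not a multiple of 3 is one event regardless of length.
The event frequency per codon carries an exact (Garwood) Poisson 95%
interval: chi-square quantiles χ²(α/2, 2k)/2 and χ²(1−α/2, 2k+2)/2 over
the codon exposure; for zero events the upper bound is −ln(0.025)/n.
Shared deletions ≥100 bp are clustered by breakpoint coordinates with
±10 bp tolerance; clusters of ≥2 members are reported.

## The simulator

The generator plants truth the pipeline must recover, under exactly the
assumptions that make the statistics valid — so parameter-recovery
results certify the estimators, not the realism of the data:

* host background is i.i.d. sequence at a set GC content (default
  0.42); after the species split each lineage's genome mutates
  independently for `split_time_years`;
* insertions place TSD–LTR–internal–LTR–TSD (solo loci: a single LTR)
  with identical LTRs at integration and a duplicated 4-bp target site;
  ancestral insertions appear at orthologous positions in both genomes,
  lineage-specific ones leave a single-copy empty site in the other;
* every sequence evolves under a per-site K2P process
  (transition:transversion 2:1 by default). Without a CpG effect,
  per-site event counts are Poisson and applied sequentially, so
  multiple hits and reversions occur exactly as the distance correction
  assumes. With `cpg_multiplier ≠ 1` the process is discretised into
  0.1 MY steps and the C and G of every *current* CpG mutate at the
  multiplied rate — the simplest context-dependent model producing the
  inflation the masking corrects;
* conversion events overwrite a random tract of one LTR with the other
  at a stated time (element histories are simulated piecewise around
  such events); envelope deletions remove a stated interval of the
  internal region from affected copies;
* emitted RepeatMasker-dialect tables carry the true consensus
  coordinates; `degrade_rm_out` optionally fragments hits and truncates
  consensus termini to exercise the merge and completeness logic.

Insertion sites are drawn with a guaranteed minimum separation
(element length + 11 kb by default) and a 500 bp edge margin, so no two
planted elements can masquerade as one provirus and every flank probe
is element-free; an impossible configuration raises immediately rather
than silently shrinking. Deliberately absent from the model: indels
outside explicit events, selection on the host, fixation dynamics,
assembly gaps beyond N-runs, and ambiguous element spacing. Passing
tests therefore demonstrate correctness of the measurement machinery on
clean signals; on real assemblies, fragmentary annotation, nested
insertions and segmental duplications will add failure modes the
simulator does not probe.

## Experiment scales

The end-to-end experiments in `ervfossil.experiments` (run by
`scripts/acceptance.py` and the acceptance-level tests) use: 50
proviruses + 200 solo LTRs for annotation recovery plus 1000 random
≤8-hit pairing instances against exhaustive enumeration; 500 LTR pairs
per true age in {1, 5, 10, 20} MY for clock recovery and 500 replicates
for the CpG-masking contrast; two 10+10+10-insertion genomes for
orthology; 500 quartets (half converted, tract ≥ 0.8) for conversion;
40 alignments per ω plus 200 neutral simulations for selection; 10⁴
draws per rate for Poisson coverage; and a 43-member family with 29
shared-deletion copies for breakpoint clustering. These sizes give
sub-percent Monte-Carlo error on the means being checked while keeping
a full run around a minute on one core.
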