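# Methods

This note records the models, parameter defaults and numerical choices
behind `nanoamp`, and what the simulation-based tests do and do not
establish about real sequencing data.

## Panel model

An amplicon is a genomic interval with a primer pair and an attached
reference sequence. Lengths follow the panel documentation convention
`end − start` (coordinate difference, half-open style) rather than the
inclusive `end − start + 1`: every declared length in the built-in
10-amplicon AML panel matches the former, so it is adopted package-wide.
Pileup and variant positions remain ordinary 1-based coordinates.

**Pooling.** Amplicons co-amplified in one multiplex pool must have similar
lengths; `partition_pools` groups them so the within-pool spread never
exceeds `max_len_diff` (default 400 bp). Without incompatibilities this is
fixed-width grouping of points on a line, for which the sorted greedy sweep
is provably minimal (a brute-force partition search doubles as the test
oracle). Primer–primer interactions are modelled only as an optional set of
forbidden pairs — interaction energetics are out of scope — and with such
pairs a first-fit heuristic is used with no minimality guarantee. On the
built-in panel the length rule alone yields 3 pools, the published pool
count; the published membership differs (it also weighed primer
interactions), which the model does not attempt to reproduce.

**Depth balance.** `balance_recommendation` proposes primer-concentration
multipliers `median_depth / depth`, snapped to powers of two and left at 1×
within √2 of the median — mirroring how under-amplified targets get their
primers doubled or quadrupled in practice.

## Read simulator

The simulator is the package's source of study data; its defaults are the
assay's published conditions.

**Error process.** Each amplicon has an error profile
(insertion/deletion/substitution rates in events per 100 alignment
columns — the convention error-assessment tools report). Generation walks
the haplotype: before each position an insertion event may fire (length
1 + geometric, mean 2.0 bp); the position itself either starts a deletion
event (length 1 + geometric, mean ≈ 1.43 bp), is substituted, or is copied.
Initiation probabilities are scaled by the mean event lengths so the
expected column composition equals the profile rates. Deletion probability
is weighted per position by `min(1 + 0.5·(run − 1), 5)` inside homopolymer
runs — the characteristic nanopore failure mode that produces recurrent,
high-VAF artifacts — with the weights renormalised so the aggregate
deletion rate is preserved.

**Measurement-space calibration.** Profile rates are defined as what the
error estimator measures on optimally realigned reads. Optimal realignment
absorbs a few percent of generated events (an inserted base can extend a
matching context; adjacent events collide), so raw generation at nominal
rates under-shoots on re-measurement. A pilot simulation (120 reads, fixed
internal seed, two rounds) inflates the raw generator rates until the
re-measured rates match the nominal ones; results are cached per profile
and reference. After calibration the re-measured CEBPA identity sits within
about 0.3 of its 86.0 nominal value.

**Haplotypes and barcodes.** Variants sharing a `phase_group` always ride
the same simulated haplotype; distinct groups are mutually exclusive
alleles drawn from one multinomial (their VAFs must sum to ≤ 1), which is
what makes cis/trans configurations exact pre-noise. Barcodes are 24-base
random sequences kept ≥ 8 edits apart. Reads are emitted in forward
orientation; the demultiplexer nonetheless checks both orientations.

**What the simulator does not emulate:** base-quality values (qualities are
placeholders), chimeric reads, context-dependent substitution spectra,
inter-pool depth imbalance, sample cross-talk. Tests passing on simulated
data therefore demonstrate the *algorithms* behave as specified under the
published error magnitudes, not that real flowcell idiosyncrasies are
handled.

## Alignment

Reads are assigned to samples by barcode-prefix edit distance (unique
minimum ≤ 3 edits, ties unassigned) and to amplicons by edit-distance
screening against all panel references, then aligned with an affine-gap
glocal dynamic program (numba kernel): match +2, mismatch −3, gap open −4,
gap extend −1, so a gap of length L costs 3 + L.

Two end conventions matter and were chosen deliberately:

* *Read overhangs cost −1 per base* (linear, no opening cost). Free
  overhangs would let a large insertion be traded for silently clipping a
  read prefix plus garbage-aligning the reference start — a near-tie that
  noise resolves the wrong way for tandem duplications. A mild linear
  penalty keeps barcode remnants cheap while making wholesale clipping
  uncompetitive.
* *The reference is paid for end to end*: unaligned reference ends are
  charged as deletion gaps, then stripped from the reported alignment (the
  read simply does not cover those positions). This likewise removes the
  free reference-clipping escape route.

Tie-breaking is deterministic (match > mismatch > del > ins at equal
score), and indel runs are left-normalized after traceback (VCF-style) so
variant coordinates are stable. The kernel is verified against an
exhaustive Python DP on all short sequence pairs and seeded random longer
pairs.

**Error statistics** pool alignment columns over reads; the denominator is
every column (match + mismatch + ins + del), the convention under which the
four percentages of the built-in panel's published rows sum to ≈ 100 (the
printed IDH1 row sums to 99.7; the fixture self-check allows
[99.6, 100.2]). Percentages are rounded to 0.1 with largest-remainder
correction so they total exactly 100.0. Depth profiles flag positions below
a configurable floor (default 50×, the depth below which a known real-world
NPM1 false negative occurred).

## Variant calling and filtering

Pileups count alleles per reference position: substitutions by base,
deletions by length at their first deleted position, insertions attached to
the preceding position and keyed by inserted sequence (a carrying read
supports the insertion allele instead of its anchor base, so counts never
exceed depth). Insertion keys within edit distance `1 + len/8` of a more
frequent insertion key are pooled: noise corrupts the inserted sequence in
a fraction of carrier reads and would otherwise scatter its support.

Candidates require VAF ≥ 10% (SNV) or ≥ 15% (indel); loci above threshold
but under 50× depth are emitted with a `low_depth` filter rather than
dropped, so depth failures are visible in reports. The somatic filter is
anchored on a negative control (NC) sequenced on the same panel:

* NC VAF ≤ 7% (the panel-wide maximum mean error rate): the candidate
  passes outright;
* NC VAF > 7%: the candidate must show tumor−NC ΔVAF > 10% *and* a
  one-sided Fisher exact p ≤ 0.01 on the allele counts (scipy
  hypergeometric; an enumeration oracle checks all margins ≤ 30 in tests).
  Failures are labelled `nc_shared` plus `low_delta`/`high_p`.

With two NCs a candidate must pass against each. No multiple-testing
correction is applied — the fixed p cut-off is part of the published
filtering recipe being reproduced. Recurrent homopolymer deletion artifacts
appear at similar VAF in tumor and NC and die on `low_delta`/`high_p`.

**Measured VAF attenuation.** Around 15% of carrier reads lose a small
variant's allele to an error at the locus or to realignment, so measured
VAFs sit ~15% (relative) below the simulated fraction — the same direction
of bias seen when nanopore VAFs are compared with a second platform on real
samples. Thresholded decisions are unaffected at the VAFs of interest.

**Hotspots.** Exact-locus SNV catalog (FLT3 p.D835 chr13:28592642, IDH1
p.R132 chr2:209113113, IDH2 p.R140 chr15:90631934, IDH2 p.R172
chr15:90631838, GRCh37) plus a rule for NPM1 p.W288fs: any 4-bp frameshift
insertion inside the exon-11 window chr5:170837530–170837560. Cohort
summaries count positive cases per category.

## ITD detection

A tandem duplication appears as a large insertion whose sequence copies
adjacent reference. The caller:

1. extracts insertion events ≥ 20 bp per read (below the 30-bp minimum of
   clinically reported ITDs, far above 1–3 bp insertion noise), **merging**
   within-read insertion parts whose anchors fall inside the accumulated
   insert length + 50 bp — against a duplication the optimal alignment is
   degenerate and errors split one big gap into several, but the total
   inserted length is invariant. Insertions hugging the alignment's
   reference edges are discarded as read-end remnants;
2. clusters events by single linkage (|Δpos| ≤ 15 bp, length ratio within
   25%), suppressing clusters under 3 reads;
3. builds a star consensus against the medoid member (per-column majority,
   ties A<C<G<T, majority-gap columns dropped) and, if that dips below the
   identity bar, falls back to the medoid itself (a consensus over mixed
   rotations of the same duplication can degrade even when every member
   copies reference);
4. verifies tandemness by infix-aligning the consensus against the
   reference window ±2 insert lengths around the cluster position
   (identity ≥ 0.80);
5. for verified calls, refines the duplicated interval by a per-member
   vote: each member insert's best reference match contributes its span and
   start, and the medians define the interval — independent errors cancel,
   and the vote is robust to rotation ambiguity. The final consensus is the
   reference copy itself, the call position its start. Support is recounted
   as reads whose inserted bases near the call sum to ≥ 40% of the call
   length (fragmented carriers still count), and residual fragment clusters
   inside a verified call's footprint are suppressed.

Zero-noise recovery is exact for lengths 30–165 bp; at the published FLT3
error rates the called length stays within ±2 bp and the VAF within ±0.1
of truth across seeded replicates. Composite ITD-plus-deletion events are
out of scope.

## Phasing

Two variants on one amplicon are phased from spanning reads: reads covering
`[locus_a − w, locus_b + w]` with no mismatch or deletion inside the two
`w`-bp flanks around each locus (variant positions excluded). The flank
default is `w = 5`: survival falls roughly as `0.9^(4w)` at nanopore error
rates, and `w = 10` would leave too few informative reads at desk-scale
depths (~0.8% of reads) while `w = 5` retains ~8%.

Each spanning read is tested for each variant's alt allele; large
insertions (≥ 20 bp) match with relaxed tolerance (position ±5 bp, length
within 25%) because noise blurs big-insert placement. Reads partition into
a-only / b-only / both / neither; fractions are over informative reads
(a+b+both) — the convention under which the published co-occurrence
percentages of real double-mutant cases add to 100.

The call requires ≥ 20 informative reads. `predominantly_trans` needs
both-fraction ≤ 0.20 with each variant individually at ≥ 10% of informative
reads; `predominantly_cis` needs both-fraction ≥ 0.65. The trans bound has
an empirical anchor (observed trans co-occurrence is ~7–8%, error-driven);
the cis bound is set below the detection-dropout ceiling
`(1−q)²/(1−q²) ≈ 0.72–0.82` at per-variant dropout q ≈ 0.10–0.15. Calls
are labelled "predominantly" because read-level phasing cannot exclude the
two variants residing in different cells.

## Workflow

`run_pipeline` chains demultiplexing, amplicon alignment, pooled error
statistics, per-sample depth profiles, NC pileups, candidate calling,
somatic filtering, hotspot annotation, ITD calling and phasing (for any
sample with ≥ 2 PASS variants on one amplicon), and writes per-sample VCF
4.2 (small variants with anchor bases; ITDs as `<DUP:TANDEM>` with SVLEN)
plus TSV reports. VCF bodies contain no timestamps, so identical inputs
give byte-identical files. A run requires ≥ 1 negative control and allows
≤ 12 samples (the native-barcoding limit); `evaluate` scores outputs
against the simulator's truth table (locus ± 2 bp and allele; ITDs by
length ± 2 bp), annotating depth-floor false negatives as `low_depth`.

## Problem sizes used in the test suite

Simulation scales were chosen to keep each check statistically meaningful
at desk scale: error-rate recovery uses 600–2,000 reads per amplicon, ITD
recovery 300 reads at 40% VAF, somatic-filter behaviour 20 replicates at
200 tumor + 200 NC reads, phasing 20 replicates at 1,000 reads. The
acceptance script re-runs the ITD (165 bp and 30 bp) and CEBPA
error-recovery measurements at exactly these scales.

## Known limitations

* Synthetic references: the built-in panel carries random sequences of the
  correct lengths, so genomic coordinates are display liftovers and
  sequence-context effects (GC, real homopolymer layout) differ from the
  genome.
* Measured insertion VAFs understate truth more than SNVs (allele-key
  fragmentation is only partly recovered by merging).
* The ITD caller reports a single dominant duplication per region;
  co-occurring distinct ITDs at similar positions and lengths would merge.
* The phasing decision is binary per pair; more than two variants on one
  amplicon are phased only as the top-VAF pair in the workflow.
* The error model is stationary along the amplicon apart from homopolymer
  weighting; real nanopore error is sequence-context dependent.
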