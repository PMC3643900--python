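# Methods

This note documents the models, conventions and numerical choices
behind `paleorrna`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## The synthetic-data generator

The generator (`paleorrna.simulate`) emulates a pyrosequenced
ancient-bone metagenome with per-read truth.  Its defaults are the
study conditions of the workflow.

**Community.** `simulate_community` evolves each gene from one random
ancestor on a star phylogeny.  The per-branch substitution rate `b` is
solved from the requested expected pairwise divergence `d` via
`d = 2b(1−b) + (2/3)b²` (two leaves differ where exactly one branch
mutated, or both mutated to different bases).  Lineages are complete
domain→genus paths spanning two phyla whenever there are at least two
taxa; abundance weights halve from taxon to taxon, mirroring a bone
community dominated by a single genus.

**Reads.** Read lengths are a two-component normal mixture with modes
44 bp and 255 bp (fractions 0.8/0.2 by default, s.d. 4 and 25,
truncated at 20 bp) — the bimodal profile of this kind of library.
Each template molecule receives a 4-bp sequencing key at its start and
an end adaptor that is complete (44 bp), partial (uniform 1–43 bp) or
absent, drawn per molecule: adaptor state is a property of the
bead-bound template, so emulsion duplicates share it.  Duplicate-group
sizes are geometric with mean `duplication_mean` (group sizes are not
printed anywhere authoritative; geometric is the simplest one-parameter
choice with support ≥ 1), and each group belongs to one of four
emulsion sets.  Per-base Phred qualities are normal(27, 4) clipped to
[2, 40], giving the observed mean quality of about 27.

**Damage model.** Deamination converts template cytosines to uracil,
read as C→T.  The per-cytosine rate at 1-based distance `pos` from the
enhanced end is

    rate(pos) = ct_interior · (1 + (terminal_factor − 1) · exp(−pos / decay_length))

a one-parameter geometric decay of the terminal enhancement
(`terminal_factor` defaults to 50, within the 50–60-fold terminal
enhancement reported for this material; `decay_length` 5 positions).
Because both strands of an ancient molecule deaminate, reads carry C→T
enhanced toward their 5′ end *and* the complementary G→A enhanced
toward their 3′ end.  This both-strand convention is the standard
end-asymmetric damage pattern for this platform, and it is what makes
the collapsed C→T/G→A class of the spectrum estimate `ct_interior`
directly (see below).  Damage is applied to the template molecule once,
before sequencing error, independently per site — deamination precedes
sequencing chemically, so duplicates share damage but not errors.

**Instrument noise.** Substitutions at `baseline_error` (default
4×10⁻⁴/site, the platform's estimated error rate) to a uniformly random
different base, then homopolymer indels: each run of ≥ 2 identical
bases gains or loses one base with probability 10⁻³ (a modest
stand-in for the platform's characteristic homopolymer miscalls; no
flowgram signal model is attempted).

**What the generator does not model:** flowgram signal processing and
quality–error correlation, paired ends, chimeras, contamination,
GC-coverage bias, and length-dependent quality decay.  Passing tests
therefore demonstrate correctness of the statistics under a clean
generative model, not robustness to every real-data pathology.

## Preprocessing conventions

* Mean-quality filter removes reads with mean Phred strictly below the
  threshold (default 20); a read at exactly the threshold is kept.
* `linkage` dedup: normalized distance = global (Needleman–Wunsch) edit
  distance divided by the longer read length; single linkage at cutoff
  0.03 within each emulsion set.  The published workflow's per-set
  cutoffs are not printed anywhere, so one default cutoff is exposed
  per run; 0.03 tolerates ~3% per-pair differences.
* `greedy` dedup processes reads longest-first; a read joins the first
  representative with identity ≥ 0.97 over ≥ 0.8 of the longer
  sequence (identity = matched columns / alignment columns, coverage
  measured against the longer sequence, matching the cited tool's
  `-c`/`-aL` semantics).  Cluster representatives are the longest
  member, ties broken by mean quality then id.
* Adaptor trimming removes the longest read suffix matching a prefix of
  the 44-bp end adaptor (mismatch fraction ≤ 0.1, overlap ≥ 6), in the
  forward orientation only — the adaptor is a known sequence at a known
  end, not an unknown insert.

## Classification

The built-in local search scores +1/−2 with gaps −3/−1 and converts
scores with the Karlin–Altschul form `E = K·m·2N·exp(−λS)` using fixed
constants λ = 1.33, K = 0.621 for this scheme (N = total reference
length; the factor 2 covers both strands).  These constants make the
e-value *threshold* behave sensibly at desk scale; no agreement with
any external search engine's e-values is claimed, and externally
produced 12-column tabular hits can be imported instead.

Majority-LCA: hits are tied at the best e-value after rounding to 3
significant figures (tabular hit files print rounded e-values, and
floating-point equality would make tie detection representation-
dependent).  Ranks are descended from the domain while a *unique* child
covers ≥ 50% of the tied hits; an exact two-way 50/50 split has no
unique winner and stops at the parent.  The cross-phylum rule is
applied unconditionally before descent (hits in more than one phylum →
domain level), because it is stated unconditionally; with it disabled,
majority 1.0 reduces exactly to the classical strict LCA.  Genus is the
deepest rank attempted.  Composition profiles roll reads assigned above
the requested rank into a bucket labelled with their deepest assigned
taxon.

## Consensus building

The layout is the seed reference when given; otherwise it is grown from
the longest read by end-extension with overlapping reads (scored local
alignment, +1/−2/−3/−1).  All reads are then placed on the final layout
by semi-global edit-distance alignment in both orientations; a read
whose best placement exceeds 25% divergence is left unplaced and
reported.  Per column, the consensus base is the Phred-weighted
majority of placed bases (ties broken alphabetically for determinism),
column quality is the summed Phred of agreeing bases minus disagreeing
bases floored at 0, and coverage is the number of placed bases.  The
consensus string spans exactly the covered columns.

## The substitution spectrum

Each placed read is scanned in its own 5′→3′ orientation.  Counting
starts after the first run of `skip_run` (default 5) consecutive
consensus-matching bases; an indel breaks the run.  This suppresses
leftover partial adaptor at read starts.  Reads with more than
`max_changes` (default 5) counted changes are discarded entirely —
the discard is evaluated on post-skip changes, i.e. after the rule
those changes are defined by.  Indel columns are excluded from both
numerator and denominator (homopolymer indels are platform error, not
substitutions) and reported as a diagnostic count.  A symmetric variant
applying the skip rule from both ends is available behind a flag but
off by default: the motivating artifact (adaptor remnants) affects one
end.

Two rates are reported per class:

* `frequencies` — counts over all counted bases, the contig-level
  statistic ("changes per site").  Its expectation under the damage
  model is `ct_interior · (f_C + f_G)` ≈ half the per-cytosine rate at
  balanced composition, because only C/G columns can contribute.
* `conditional_rates` — counts over the counted bases whose consensus
  base is a source of the class (C/G columns for C→T/G→A).  This is the
  convention of positional damage profilers and recovers `ct_interior`
  directly (plus `baseline_error/3`); the parameter-recovery tests
  assert on it.  The denominator choice for the per-site statistic
  (post-skip bases rather than all aligned bases) is an interpretation
  made for internal consistency: the skip rule excludes those bases
  from the numerator, so they are excluded from the denominator too.

## Digestion and benchmark

Cuts are placed at motif start positions; since only mean fragment
lengths are of interest, any consistent within-site cut offset is
equivalent.  Overlapping occurrences count as distinct cuts; identical
positions from different motifs collapse.  `N` never matches (real
genomes contain assembly gaps; a gap should not create cuts).  All
seven recognition motifs of the two mixes are IUPAC reverse-complement
palindromes, so forward-strand scanning is complete — asserted as a
test.  The closed-form expectation sums per-motif match probabilities
(first order, motif overlap ignored); for these mixes no two motifs can
match at the same position, so the first-order expectation is exact for
the cut density.

The detection benchmark scores a read with a hit as TP when its true
interval overlaps an rRNA gene by ≥ 50 bp, FP when it lies entirely
outside every gene ± 1 kb, and ignores reads in between; FN are true
rRNA reads without a hit.  Precision = TP/(TP+FP), recall = TP/(TP+FN).

## Problem sizes

The packaged analyses run at desk scale by design: communities of 1–4
taxa with 1.5-kb SSU genes, 150–2000 reads per experiment, 1 Mb of
i.i.d. sequence for digestion checks, and 1000 random cases for the
oracle-equality checks.  These sizes give the parameter-recovery tests
3×10⁵ or more counted bases, enough to separate a 5×10⁻³ signal from a
4×10⁻⁴ floor with wide margin.

## Known limitations

* Duplicate clustering at cutoff 0.03 needs headroom over the expected
  normalized distance between duplicate copies (twice the per-copy
  error rate).  At 0.5% error the margin is threefold and group
  recovery is near-perfect (ARI ≥ 0.99); right at 1% error the margin
  is only 1.5-fold and duplicate pairs of ≤ 255 bp reads split at a
  noticeable rate (ARI ≈ 0.94–0.99 depending on the draw).  Very short
  (44 bp) reads are the worst case: the cutoff then tolerates a single
  edit.  This is a resolution limit of normalized-distance clustering,
  not an implementation artifact — the all-pairs oracle agrees exactly.
* The linkage mode is O(n²) alignments per emulsion set and is meant
  for the deduplicated-scale inputs used here, not raw 10⁷-read runs.
* E-values of the built-in search are internally consistent but not
  calibrated against external engines; import external tabular hits
  when comparability matters.
* De novo layout growth assumes the bin is a single locus with
  overlapping reads; repeat structure or mixed bins can truncate the
  layout.  Reference-guided assembly is preferred whenever a reference
  is available (as in the pipeline's simulated runs).
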