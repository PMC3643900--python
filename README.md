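# paleorrna

Taxonomic profiling and ancient-DNA damage analysis for pyrosequenced
bone and sediment metagenomes.

Ancient bones are dominated by microbial DNA, and a central question
about any taxon found in such a sample is whether its DNA is ancient
(deposited when the organism colonised the decaying bone) or recent.
`paleorrna` implements the computational workflow for answering this
from 454-style shotgun reads:

1. **Preprocessing** — mean-quality filtering, removal of artificially
   multiplied reads from emulsion PCR (single-linkage clustering of
   globally aligned reads per emulsion set, or greedy cd-hit-style
   clustering at 97% identity / 80% coverage), and trimming of the
   44-bp end adaptor that may be present fully, partially or not at
   all.
2. **rRNA classification** — curation of a taxonomy-annotated SSU/LSU
   rRNA reference table (alignment quality ≥ 75, pintail ≥ 100,
   domain-consistent taxonomies, informative entries only), local
   similarity search at E ≤ 10⁻¹⁰, and a majority
   lowest-common-ancestor assignment: among hits tied at the best
   e-value, ranks are descended while one child taxon covers ≥ 50% of
   the hits; reads whose best hits span several phyla are truncated to
   the domain.
3. **Consensus and damage** — reads binned per taxon and per rRNA
   subunit (bit score > 75) are assembled into a consensus, and every
   read is compared back to it. Nucleotide changes are collapsed into
   the 6 complementary classes; cytosine deamination in ancient DNA
   produces a large C→T/G→A excess over the sequencing-error floor
   (4×10⁻⁴/site), while the other five classes stay at the floor.  To
   avoid counting leftover adaptor, only changes after the first 5
   consecutive consensus-matching bases are counted, and reads with
   more than 5 counted changes are discarded.
4. **Restriction digestion and benchmarking** — in silico digestion
   with the GC-rich-cutting enzyme mixes used to deplete bacterial DNA
   (Mix1: CGCG, CGRYCG, CGWCG; Mix2: those plus TCGA, CCGG, GCSGC,
   GCGC), closed-form fragment-length expectations for i.i.d. sequence,
   and a precision/recall benchmark for rRNA read detection (≥ 50 bp
   gene overlap, ±1 kb ignore zone).

A synthetic-data generator produces mock communities and 454-style
reads with full per-read truth (source, coordinates, duplicate group,
adaptor state, damaged and error positions), so the whole pipeline is
testable end to end without downloads.

## The damage statistic

For a contig with consensus $c$ and placed reads $r_1,\dots,r_n$, let
$m_i$ be the set of post-skip aligned positions of read $i$ (positions
after its first run of 5 consecutive matches, scanning from the 5′
end), and drop reads with more than 5 mismatches in $m_i$.  For each
complementary change class $k$ (e.g. C→T/G→A),

$$f_k \;=\; \frac{\sum_i \#\{j \in m_i : (c_j \to r_{ij}) \in k\}}{\sum_i |m_i|}$$

is the per-site change frequency.  The package additionally reports the
*conditional* rate $\tilde f_k$, dividing by only those positions whose
consensus base can undergo the class (C or G columns for C→T/G→A) — the
convention of positional damage profilers, and the quantity that
directly estimates the per-cytosine deamination probability.

## Worked example

Simulate a single damaged taxon (2% per-cytosine deamination, 50-fold
end enhancement, 4×10⁻⁴ error floor), assemble its reads and measure
the spectrum:

```python
from paleorrna import (DamageModel, ReadLengthModel, build_consensus,
                       simulate_community, simulate_reads,
                       substitution_spectrum)
from paleorrna.consensus import spectrum_table
from paleorrna.simulate import NO_ADAPTORS

ancient = DamageModel(baseline_error=4e-4, ct_interior=0.02,
                      terminal_factor=50, decay_length=5)
community = simulate_community(seed=1, n_taxa=1, gene_lengths={"SSU": 1500})
reads, truth = simulate_reads(
    community, 1500, length_model=ReadLengthModel(100, 250, 0.5),
    adaptor_config=NO_ADAPTORS, damage_model=ancient, seed=1)

contig = build_consensus(reads, community.entries[0].sequence)
spectrum = substitution_spectrum(contig, skip_run=5, max_changes=5)
print(spectrum_table(spectrum))
```

which prints

```
  class  count  bases  frequency  conditional_rate
C>T/G>A   3421 106304   1.60e-02          3.22e-02
T>C/A>G     11 108078   5.13e-05          1.02e-04
C>A/G>T      9 106304   4.20e-05          8.47e-05
A>C/T>G     13 108078   6.06e-05          1.20e-04
C>G/G>C     16 106304   7.46e-05          1.51e-04
A>T/T>A     11 108078   5.13e-05          1.02e-04
```

The C→T/G→A class sits two orders of magnitude above every other class
— the signature of deaminated, ancient DNA.  Re-running with
`ct_interior=0` puts all six classes at the 10⁻⁴ error floor.  The same
contrast is produced end to end by the pipeline:

```
paleorrna run-all --seed 11 --out run/
```

which simulates a four-taxon, two-phylum community with damage confined
to the dominant genus, preprocesses and classifies the reads, writes a
phylum-level composition profile, and emits one consensus and one
spectrum per (taxon, gene) bin plus a machine-readable `report.json`.

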