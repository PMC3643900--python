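"""Taxon-binned consensus building and the substitution-spectrum statistic.

Classified reads are binned per taxon and per rRNA subunit (SSU/LSU),
assembled against a reference-guided or read-seeded layout, and each
read is then compared back to the consensus.  Nucleotide changes are
collapsed into the 6 complementary change classes (C→T/G→A, T→C/A→G,
C→A/G→T, A→C/T→G, C→G/G→C, A→T/T→A).  Ancient, deamination-damaged DNA
shows a strong excess of the C→T/G→A class over the sequencing-error
floor, while undamaged DNA shows all classes at the error floor.

To avoid counting leftover adaptor sequence, only changes after the
first run of ``skip_run`` contiguous consensus-matching bases (scanned
from the read's 5' end) are counted, and reads with more than
``max_changes`` counted changes are discarded entirely.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from .preprocess import Read
from .taxonomy import Assignment, HitRecord, revcomp

logger = logging.getLogger(__name__)

#: the 6 complementary change classes, keyed by name.
CLASS_NAMES = ("C>T/G>A", "T>C/A>G", "C>A/G>T", "A>C/T>G", "C>G/G>C", "A>T/T>A")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: map a directed change (consensus base, read base) to its class name.
CLASS_OF: dict[tuple[str, str], str] = {}
for _name in CLASS_NAMES:
    _x, _y = _name.split("/")[0].split(">")
    CLASS_OF[(_x, _y)] = _name
    CLASS_OF[(_COMP[_x], _COMP[_y])] = _name

#: source bases of each class (for the per-opportunity denominators).
CLASS_SOURCES = {name: frozenset({name.split(">")[0], _COMP[name.split(">")[0]]})
                 for name in CLASS_NAMES}


@dataclass
class Placement:
    """One read aligned onto the contig layout.

    ``events`` is the alignment walk in layout order: ``("M", col, base)``
    for an aligned read base, ``("I", None, base)`` for a read base with
    no layout column (insertion), ``("D", col, None)`` for a layout
    column the read deletes.  Bases are as placed (reverse-complemented
    for ``orientation == "-"``).
    """

    read_id: str
    orientation: str
    start: int
    events: list[tuple[str, int | None, str | None]]


@dataclass
class Contig:
    """A per-bin consensus with per-column coverage and quality."""

    id: str
    taxon: str
    gene: str
    column_bases: list[str]  # per layout column; "" where uncovered
    coverage: np.ndarray
    quality: np.ndarray
    placements: list[Placement]
    unplaced: list[str] = field(default_factory=list)

    @property
    def consensus(self) -> str:
        return "".join(b for b in self.column_bases if b)

    @property
    def covered(self) -> np.ndarray:
        return self.coverage >= 1

    @property
    def mean_coverage(self) -> float:
        return float(self.coverage[self.covered].mean())

    @property
    def min_coverage(self) -> int:
        return int(self.coverage[self.covered].min())

    @property
    def mean_quality(self) -> float:
        return float(self.quality[self.covered].mean())

    @property
    def min_quality(self) -> int:
        return int(self.quality[self.covered].min())


@dataclass
class SubstitutionSpectrum:
    """Counts and rates for the 6 complementary change classes.

    ``frequencies`` follow the contig statistic (counts over all counted
    bases).  ``conditional_rates`` divide each class by the counted
    bases whose consensus base could undergo that change (e.g. C or G
    columns for C→T/G→A) — the convention of positional damage tools,
    and the quantity that estimates the underlying per-cytosine
    deamination probability.
    """

    counts: dict[str, int]
    total_bases: int
    opportunities: dict[str, int]
    error_floor: float
    n_used: int
    n_discarded: int
    n_no_anchor: int = 0
    n_indels: int = 0

    @property
    def frequencies(self) -> dict[str, float]:
        t = self.total_bases
        return {k: (v / t if t else 0.0) for k, v in self.counts.items()}

    @property
    def conditional_rates(self) -> dict[str, float]:
        return {k: (self.counts[k] / self.opportunities[k]
                    if self.opportunities[k] else 0.0) for k in self.counts}


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_and_filter_reads(assignments: list[Assignment], hits: list[HitRecord],
                         taxon: str, gene: str,
                         ref_genes: dict[str, str],
                         score_min: float = 75.0) -> list[str]:
    """Select reads for one (taxon, gene) assembly bin.

    A read qualifies when its assigned lineage contains ``taxon`` (i.e.
    it was assigned at or below that rank), its best hit against a
    reference of the requested gene has bit score strictly above
    ``score_min``, and that gene matches the bin.
    """
    if score_min < 0:
        raise ValueError("score_min must be >= 0")
    best: dict[str, float] = defaultdict(float)
    for h in hits:
        if ref_genes.get(h.subject) == gene:
            best[h.query] = max(best[h.query], h.bitscore)
    out = []
    for a in assignments:
        if a.path is None or taxon not in a.path.labels:
            continue
        if a.read_id in best and best[a.read_id] > score_min:
            out.append(a.read_id)
    if not out:
        logger.warning("bin %s/%s: no qualifying reads (unknown taxon label?)",
                       taxon, gene)
    return sorted(out)


# ---------------------------------------------------------------------------
# consensus building
# ---------------------------------------------------------------------------

def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _place_on_layout(read: Read, layout: str, max_divergence: float) -> Placement | None:
    """Semi-global (infix) edit-distance placement, better orientation wins."""
    best = None
    for orient, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        res = edlib.align(seq, layout, mode="HW", task="path")
        d = res["editDistance"]
        if d >= 0 and (best is None or d < best[0]):
            best = (d, orient, seq, res)
    if best is None:
        return None
    d, orient, seq, res = best
    if d / max(1, len(read)) > max_divergence:
        return None
    tpos = res["locations"][0][0]
    start = tpos
    qpos = 0
    events: list[tuple[str, int | None, str | None]] = []
    for n, op in _parse_cigar(res["cigar"]):
        if op in "=X":
            for _ in range(n):
                events.append(("M", tpos, seq[qpos]))
                qpos += 1
                tpos += 1
        elif op == "I":  # read base absent from layout
            for _ in range(n):
                events.append(("I", None, seq[qpos]))
                qpos += 1
        elif op == "D":  # layout column absent from read
            for _ in range(n):
                events.append(("D", tpos, None))
                tpos += 1
    return Placement(read.id, orient, start, events)


def _grow_layout(reads: list[Read], min_score: float, max_divergence: float) -> str:
    """Determine the layout de novo: seed with the longest read and extend
    it with reads that overlap an end (scored local alignment)."""
    from Bio import Align
    from .taxonomy import GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH
    aligner = Align.PairwiseAligner(mode="local", match_score=MATCH,
                                    mismatch_score=MISMATCH,
                                    open_gap_score=GAP_OPEN,
                                    extend_gap_score=GAP_EXTEND)
    order = sorted(reads, key=lambda r: (-len(r), r.id))
    layout = order[0].sequence
    pending = list(order[1:])
    progress = True
    while progress and pending:
        progress = False
        remaining = []
        for read in pending:
            res = edlib.align(read.sequence, layout, mode="HW")
            res_rc = edlib.align(revcomp(read.sequence), layout, mode="HW")
            d = min(x["editDistance"] for x in (res, res_rc) if x["editDistance"] >= 0)
            if d / max(1, len(read)) <= max_divergence:
                progress = True  # contained; consumes no growth
                continue
            grown = False
            for seq in (read.sequence, revcomp(read.sequence)):
                score = aligner.score(layout, seq)
                if score < min_score:
                    continue
                aln = aligner.align(layout, seq)[0]
                tb, qb = aln.aligned
                t0, t1 = int(tb[0][0]), int(tb[-1][-1])
                q0, q1 = int(qb[0][0]), int(qb[-1][-1])
                if q0 > 0 and t0 == 0:
                    layout = seq[:q0] + layout
                    grown = True
                if q1 < len(seq) and t1 == len(layout):
                    layout = layout + seq[q1:]
                    grown = True
                if grown:
                    break
            if grown:
                progress = True
            else:
                remaining.append(read)
        pending = remaining
    return layout


def build_consensus(reads: list[Read], seed_reference: str | None = None, *,
                    contig_id: str = "contig", taxon: str = "", gene: str = "",
                    min_score: float = 20.0,
                    max_divergence: float = 0.25) -> Contig:
    """Build a consensus from a bin of reads.

    The layout is the seed reference when given, else it is grown from
    the longest read by end-extension with overlapping reads.  Every
    read is then aligned to the layout in both orientations; reads whose
    best placement diverges more than ``max_divergence`` are left
    unplaced and reported.  The consensus base per column is the
    Phred-weighted majority of the placed bases; the column quality is
    the summed Phred of agreeing bases minus that of disagreeing bases,
    floored at 0; coverage is the number of placed bases at the column.
    """
    if not reads:
        raise ValueError("a consensus needs at least one read")
    layout = seed_reference if seed_reference else _grow_layout(
        reads, min_score, max_divergence)
    ncol = len(layout)
    votes: list[dict[str, int]] = [defaultdict(int) for _ in range(ncol)]
    placements, unplaced = [], []
    for read in reads:
        p = _place_on_layout(read, layout, max_divergence)
        if p is None:
            unplaced.append(read.id)
            continue
        placements.append(p)
        qual = read.quality if p.orientation == "+" else read.quality[::-1]
        qpos = 0
        for op, col, base in p.events:
            if op == "M":
                votes[col][base] += qual[qpos] if qpos < len(qual) else 20
                qpos += 1
            elif op == "I":
                qpos += 1
    column_bases = []
    coverage = np.zeros(ncol, dtype=int)
    quality = np.zeros(ncol, dtype=int)
    cov_counts = np.zeros(ncol, dtype=int)
    for p in placements:
        for op, col, base in p.events:
            if op == "M":
                cov_counts[col] += 1
    for col in range(ncol):
        v = votes[col]
        if not v:
            column_bases.append("")
            continue
        best_base = max(sorted(v), key=lambda b: v[b])
        agree = v[best_base]
        disagree = sum(v.values()) - agree
        column_bases.append(best_base)
        coverage[col] = cov_counts[col]
        quality[col] = max(0, agree - disagree)
    if unplaced:
        logger.info("contig %s: %d reads unplaced", contig_id, len(unplaced))
    return Contig(contig_id, taxon, gene, column_bases, coverage, quality,
                  placements, unplaced)


# ---------------------------------------------------------------------------
# substitution spectrum
# ---------------------------------------------------------------------------

def _oriented_events(p: Placement):
    """Alignment events in read orientation (5'→3' of the original read)."""
    return p.events if p.orientation == "+" else list(reversed(p.events))


def substitution_spectrum(contig: Contig, skip_run: int = 5,
                          max_changes: int | None = 5,
                          error_floor: float = 4e-4,
                          symmetric: bool = False) -> SubstitutionSpectrum:
    """Read-versus-consensus change counts in the 6 complementary classes.

    Each placed read is scanned from its 5' end; counting starts after
    the first run of ``skip_run`` consecutive consensus-matching bases
    (mismatches at or before the end of that run are ignored — they are
    typically leftover adaptor).  A read with more than ``max_changes``
    counted changes is discarded entirely and contributes to neither
    numerator nor denominator; ``max_changes=None`` disables the
    discard.  Gap (indel) columns are excluded from both counts and
    reported as a diagnostic.  With ``symmetric`` the skip rule is also
    applied from the 3' end.
    """
    if skip_run < 0:
        raise ValueError("skip_run must be >= 0")
    if max_changes is not None and max_changes < 0:
        raise ValueError("max_changes must be >= 0")
    counts = {k: 0 for k in CLASS_NAMES}
    opportunities = {k: 0 for k in CLASS_NAMES}
    total_bases = 0
    n_used = n_discarded = n_no_anchor = n_indels = 0

    def anchor_index(events) -> int | None:
        """Index of the event completing the first ``skip_run``-long run of
        matches; ``-1`` when ``skip_run == 0`` (count everything)."""
        if skip_run == 0:
            return -1
        run = 0
        for i, (op, col, base) in enumerate(events):
            if op == "M" and contig.column_bases[col] == base:
                run += 1
                if run == skip_run:
                    return i
            else:
                run = 0
        return None

    for p in contig.placements:
        events = _oriented_events(p)
        a = anchor_index(events)
        if a is None:
            n_no_anchor += 1
            continue
        stop = len(events)
        if symmetric:
            a_rev = anchor_index(list(reversed(events)))
            if a_rev is None:
                n_no_anchor += 1
                continue
            stop = len(events) - 1 - a_rev
        read_counts = {k: 0 for k in CLASS_NAMES}
        read_bases = 0
        read_indels = 0
        for op, col, base in events[a + 1:stop]:
            if op != "M":
                read_indels += 1
                continue
            cons = contig.column_bases[col]
            if not cons:
                continue
            read_bases += 1
            if base != cons and (cons, base) in CLASS_OF:
                read_counts[CLASS_OF[(cons, base)]] += 1
        n_changes = sum(read_counts.values())
        if max_changes is not None and n_changes > max_changes:
            n_discarded += 1
            continue
        n_used += 1
        total_bases += read_bases
        n_indels += read_indels
        for k in CLASS_NAMES:
            counts[k] += read_counts[k]
        # second pass for per-class opportunity denominators
        for op, col, base in events[a + 1:stop]:
            if op != "M":
                continue
            cons = contig.column_bases[col]
            if not cons or cons not in _COMP:
                continue
            for k in CLASS_NAMES:
                if cons in CLASS_SOURCES[k]:
                    opportunities[k] += 1
    return SubstitutionSpectrum(counts, total_bases, opportunities, error_floor,
                                n_used, n_discarded, n_no_anchor, n_indels)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def spectrum_table(spectrum: SubstitutionSpectrum):
    import pandas as pd
    freq = spectrum.frequencies
    cond = spectrum.conditional_rates
    return pd.DataFrame(
        [(k, spectrum.counts[k], spectrum.opportunities[k], freq[k], cond[k])
         for k in CLASS_NAMES],
        columns=["class", "count", "bases", "frequency", "conditional_rate"])


def write_spectrum(spectrum: SubstitutionSpectrum, path) -> None:
    spectrum_table(spectrum).to_csv(path, sep="\t", index=False)


def write_contig(contig: Contig, fasta_path, stats_path=None) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{contig.id} taxon={contig.taxon} gene={contig.gene}\n")
        seq = contig.consensus
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    if stats_path is not None:
        with open(stats_path, "w") as fh:
            fh.write("column\tbase\tcoverage\tquality\n")
            for col, base in enumerate(contig.column_bases):
                if base:
                    fh.write(f"{col}\t{base}\t{contig.coverage[col]}\t"
                             f"{contig.quality[col]}\n")


def write_alignment(contig: Contig, path) -> None:
    """Padded-alignment text export of the read placements."""
    ncol = len(contig.column_bases)
    with open(path, "w") as fh:
        fh.write("consensus  " + "".join(b or "-" for b in contig.column_bases) + "\n")
        for p in contig.placements:
            row = ["."] * ncol
            for op, col, base in p.events:
                if op == "M":
                    row[col] = base
                elif op == "D":
                    row[col] = "-"
            fh.write(f"{p.read_id}({p.orientation}) " + "".join(row) + "\n")


def plot_spectrum(spectrum: SubstitutionSpectrum, path, title: str = "") -> None:
    """Bar plot of the 6 class frequencies with the error-floor line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    freq = spectrum.frequencies
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(CLASS_NAMES)), [freq[k] for k in CLASS_NAMES],
           color=["#c0392b" if k == "C>T/G>A" else "#7f8c8d" for k in CLASS_NAMES])
    ax.axhline(spectrum.error_floor, color="black", linestyle="--", linewidth=1,
               label=f"error floor {spectrum.error_floor:g}")
    ax.set_xticks(range(len(CLASS_NAMES)))
    ax.set_xticklabels(CLASS_NAMES, rotation=45, ha="right")
    ax.set_ylabel("changes per site")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
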