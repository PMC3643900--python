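"""rRNA reference curation, similarity search and majority-LCA assignment.

Reads are classified by comparison against a curated table of SSU/LSU
rRNA reference sequences carrying ranked lineages from several taxonomy
sources.  Curation removes poorly aligned entries (alignment quality
below 75), potentially chimeric entries (pintail score below 100),
entries whose taxonomy sources disagree at the domain level, and
taxonomically uninformative entries.

Assignment uses an abundance-aware lowest-common-ancestor rule: among
all hits tied at the best e-value, ranks are descended from the domain
while a single child taxon accounts for at least a majority (default
50%) of the tied hits.  Reads whose tied hits span more than one phylum
are truncated to the domain level regardless of majority.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: scoring scheme of the built-in local search (+1 match, -2 mismatch,
#: -3 gap open, -1 gap extend) and the Karlin-Altschul constants used to
#: convert raw scores into e-values and bit scores.
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -3, -1
KA_LAMBDA, KA_K = 1.33, 0.621

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TaxonPath:
    """A ranked lineage domain→genus; trailing ranks may be absent."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.labels) <= len(RANKS):
            raise ValueError(f"lineage must span 1..{len(RANKS)} ranks")
        if any(not lab for lab in self.labels):
            raise ValueError("lineage contains an empty rank label (gap)")

    @classmethod
    def parse(cls, text: str) -> "TaxonPath":
        return cls(tuple(t.strip() for t in text.strip().strip(";").split(";")))

    def __str__(self) -> str:
        return ";".join(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def rank(self) -> str:
        return RANKS[len(self.labels) - 1]

    @property
    def domain(self) -> str:
        return self.labels[0]

    def at(self, rank: str) -> str | None:
        i = RANKS.index(rank)
        return self.labels[i] if i < len(self.labels) else None


@dataclass
class ReferenceEntry:
    """One rRNA reference sequence with curation metadata."""

    accession: str
    gene: str  # SSU or LSU
    sequence: str
    align_quality: int | None = None
    pintail: int | None = None
    taxonomies: dict[str, TaxonPath] = field(default_factory=dict)
    informative: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        for name, score in (("align_quality", self.align_quality),
                            ("pintail", self.pintail)):
            if score is not None and not 0 <= score <= 100:
                raise ValueError(f"{self.accession}: {name} out of range")

    @property
    def taxonomy(self) -> TaxonPath | None:
        """Primary lineage (the ``silva`` source when present)."""
        if "silva" in self.taxonomies:
            return self.taxonomies["silva"]
        return next(iter(self.taxonomies.values()), None)


@dataclass
class HitRecord:
    """One query→reference local-alignment hit (tabular hit dialect)."""

    query: str
    subject: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")

    @property
    def strand(self) -> str:
        return "+" if self.send >= self.sstart else "-"


@dataclass
class Assignment:
    """Taxonomic assignment of one read (possibly truncated lineage)."""

    read_id: str
    path: TaxonPath | None
    n_best: int

    @property
    def rank(self) -> str | None:
        return self.path.rank if self.path else None


# ---------------------------------------------------------------------------
# reference curation
# ---------------------------------------------------------------------------

def curate_reference_db(entries: list[ReferenceEntry],
                        trna_blacklist: frozenset[str] | set[str] = frozenset(),
                        *, min_align_quality: int = 75,
                        min_pintail: int = 100) -> list[ReferenceEntry]:
    """Apply the curation rules; rejected entries are logged with a reason.

    Retained entries have alignment quality >= 75, pintail >= 100, a
    domain on which all taxonomy sources agree, are taxonomically
    informative and are not on the tRNA-contamination blacklist.
    Curation is idempotent.
    """
    kept = []
    for e in entries:
        reason = None
        if e.accession in trna_blacklist:
            reason = "blacklisted (tRNA contamination)"
        elif e.align_quality is None or e.pintail is None or not e.taxonomies:
            reason = "missing curation metadata"
        elif e.align_quality < min_align_quality:
            reason = f"align_quality {e.align_quality} < {min_align_quality}"
        elif e.pintail < min_pintail:
            reason = f"pintail {e.pintail} < {min_pintail}"
        elif len({t.domain for t in e.taxonomies.values()}) > 1:
            reason = "taxonomy sources disagree at domain level"
        elif not e.informative:
            reason = "taxonomically uninformative"
        if reason:
            logger.info("curation: dropped %s: %s", e.accession, reason)
        else:
            kept.append(e)
    return kept


# ---------------------------------------------------------------------------
# built-in local similarity search
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="local", match_score=MATCH,
                              mismatch_score=MISMATCH,
                              open_gap_score=GAP_OPEN,
                              extend_gap_score=GAP_EXTEND)
    return a


def _evalue(score: float, qlen: int, db_len: int) -> float:
    # both strands are searched, hence the factor 2 on the search space
    return KA_K * qlen * 2 * db_len * math.exp(-KA_LAMBDA * score)


def _bitscore(score: float) -> float:
    return (KA_LAMBDA * score - math.log(KA_K)) / math.log(2)


def search_local(queries, references: list[ReferenceEntry],
                 evalue_cutoff: float = 1e-10) -> list[HitRecord]:
    """Local-alignment search of reads against the reference entries.

    Both strands are searched with a fixed scoring scheme (+1/-2, gap
    -3/-1); e-values follow the Karlin-Altschul form with fixed constants
    over the total searched database size.  Hits above ``evalue_cutoff``
    are suppressed; the best strand is reported per query/reference pair.

    ``queries`` may be ``preprocess.Read`` objects or ``(id, sequence)``
    pairs.
    """
    if not references:
        raise ValueError("empty reference set")
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    db_len = sum(len(r.sequence) for r in references)
    aligner = _aligner()
    hits: list[HitRecord] = []
    for q in queries:
        qid, qseq = (q.id, q.sequence) if hasattr(q, "sequence") else q
        qlen = len(qseq)
        if qlen == 0:
            continue
        rc = revcomp(qseq)
        for ref in references:
            best = None  # (score, strand, oriented query)
            for strand, oriented in (("+", qseq), ("-", rc)):
                score = aligner.score(ref.sequence, oriented)
                if best is None or score > best[0]:
                    best = (score, strand, oriented)
            score, strand, oriented = best
            if score <= 0:
                continue
            ev = _evalue(score, qlen, db_len)
            if ev > evalue_cutoff:
                continue
            aln = aligner.align(ref.sequence, oriented)[0]
            counts = aln.counts()
            length = counts.identities + counts.mismatches + counts.gaps
            tblocks, qblocks = aln.aligned
            s0, s1 = int(tblocks[0][0]), int(tblocks[-1][-1])  # 0-based half-open
            a0, a1 = int(qblocks[0][0]), int(qblocks[-1][-1])
            gapopen = (len(tblocks) - 1)
            if strand == "+":
                qstart, qend = a0 + 1, a1
                sstart, send = s0 + 1, s1
            else:
                qstart, qend = qlen - a1 + 1, qlen - a0
                sstart, send = s1, s0 + 1
            hits.append(HitRecord(
                query=qid, subject=ref.accession,
                pident=round(100.0 * counts.identities / length, 3),
                length=length, mismatch=counts.mismatches, gapopen=gapopen,
                qstart=qstart, qend=qend, sstart=sstart, send=send,
                evalue=ev, bitscore=round(_bitscore(score), 1)))
    return hits


# ---------------------------------------------------------------------------
# majority-LCA assignment
# ---------------------------------------------------------------------------

def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (tabular files print rounded
    e-values, so ties are detected after rounding)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def assign_taxonomy_mlca(hits: list[HitRecord],
                         taxonomy: dict[str, TaxonPath],
                         majority: float = 0.5,
                         strict_phylum: bool = True) -> Assignment | None:
    """Majority lowest-common-ancestor assignment for one read's hits.

    Only hits tied at the minimum e-value (after rounding to 3
    significant figures) are considered.  Ranks are descended from the
    domain; at each rank the child taxon covering at least ``majority``
    of the tied hits is selected, provided it is the unique such child
    (an exact two-way split produces no winner and the descent stops).
    With ``strict_phylum`` the lineage is truncated to the domain
    whenever the tied hits span more than one phylum.

    Returns ``None`` for an empty hit list (no assignment, which is
    distinct from a domain-level assignment).
    """
    if not hits:
        return None
    if not 0.5 <= majority <= 1.0:
        raise ValueError("majority must be in [0.5, 1.0]")
    rounded = [round_sig(h.evalue) for h in hits]
    best_e = min(rounded)
    tied = [h for h, e in zip(hits, rounded) if e == best_e]
    paths = [taxonomy[h.subject] for h in tied]
    n = len(tied)

    max_depth = len(RANKS)
    if strict_phylum:
        phyla = {p.labels[1] for p in paths if len(p) >= 2}
        if len(phyla) > 1:
            max_depth = 1

    best: tuple[str, ...] = ()
    for depth in range(1, max_depth + 1):
        counts = Counter(p.labels[:depth] for p in paths
                         if len(p) >= depth and p.labels[:depth - 1] == best)
        winners = [pref for pref, c in counts.items()
                   if c >= majority * n - 1e-9]
        if len(winners) != 1:
            break
        best = winners[0]
    path = TaxonPath(best) if best else None
    return Assignment(tied[0].query, path, n)


def assign_all(hits: list[HitRecord], taxonomy: dict[str, TaxonPath],
               majority: float = 0.5, strict_phylum: bool = True) -> list[Assignment]:
    """Group hits per read and assign each read."""
    by_read: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        by_read[h.query].append(h)
    out = []
    for read_hits in by_read.values():
        a = assign_taxonomy_mlca(read_hits, taxonomy, majority, strict_phylum)
        if a is not None:
            out.append(a)
    return out


# ---------------------------------------------------------------------------
# composition profiles
# ---------------------------------------------------------------------------

def compose_profile(assignments: list[Assignment], level: str = "phylum") -> pd.DataFrame:
    """Tabulate counts and percentages at a taxonomic rank.

    Reads assigned above the requested rank roll into a bucket labelled
    by their deepest assigned taxon (e.g. domain-only reads appear under
    the domain name in a phylum-level profile).
    """
    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}")
    depth = RANKS.index(level) + 1
    counter: Counter[str] = Counter()
    for a in assignments:
        if a.path is None:
            counter["Unassigned"] += 1
        elif len(a.path) >= depth:
            counter[a.path.labels[depth - 1]] += 1
        else:
            counter[a.path.labels[-1]] += 1  # roll-up bucket
    total = sum(counter.values())
    rows = [(taxon, c, 100.0 * c / total if total else 0.0)
            for taxon, c in counter.most_common()]
    return pd.DataFrame(rows, columns=["taxon", "count", "percent"])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TAX_SOURCES = ("silva", "embl", "greengenes", "rdp")


def write_reference_table(entries: list[ReferenceEntry], path) -> None:
    cols = ["accession", "gene", "align_quality", "pintail",
            *[f"taxonomy_{s}" for s in _TAX_SOURCES], "sequence"]
    rows = []
    for e in entries:
        row = {"accession": e.accession, "gene": e.gene,
               "align_quality": e.align_quality, "pintail": e.pintail,
               "sequence": e.sequence}
        for s in _TAX_SOURCES:
            row[f"taxonomy_{s}"] = str(e.taxonomies[s]) if s in e.taxonomies else ""
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_reference_table(path) -> list[ReferenceEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = []
    for _, row in df.iterrows():
        taxonomies = {s: TaxonPath.parse(row[f"taxonomy_{s}"])
                      for s in _TAX_SOURCES if row.get(f"taxonomy_{s}", "")}
        entries.append(ReferenceEntry(
            accession=row["accession"], gene=row["gene"],
            sequence=row["sequence"],
            align_quality=int(row["align_quality"]) if row["align_quality"] else None,
            pintail=int(row["pintail"]) if row["pintail"] else None,
            taxonomies=taxonomies))
    return entries


def write_hits(hits: list[HitRecord], path) -> None:
    """Write the standard 12-column tabular hit format."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(v) for v in (
                h.query, h.subject, h.pident, h.length, h.mismatch, h.gapopen,
                h.qstart, h.qend, h.sstart, h.send, f"{h.evalue:.3g}",
                h.bitscore)) + "\n")


def read_hits(path) -> list[HitRecord]:
    hits = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not f or not f[0]:
                continue
            hits.append(HitRecord(f[0], f[1], float(f[2]), int(f[3]), int(f[4]),
                                  int(f[5]), int(f[6]), int(f[7]), int(f[8]),
                                  int(f[9]), float(f[10]), float(f[11])))
    return hits
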