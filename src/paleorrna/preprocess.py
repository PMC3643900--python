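"""Read quality filtering, duplicate clustering and end-adaptor trimming.

Pyrosequencing libraries contain artificially multiplied reads produced
during emulsion PCR: the same bead-bound template is sequenced several
times, so the copies are near-identical apart from sequencing errors and
homopolymer miscalls.  Two de-duplication strategies are provided:

* ``linkage`` — pairwise global alignment followed by single-linkage
  clustering at a normalized edit-distance cutoff, run separately within
  each emulsion set (duplicates can only arise within a set);
* ``greedy`` — longest-first greedy clustering at an identity threshold
  over a minimum fraction of the longer sequence (cd-hit style
  ``-c``/``-aL`` semantics).

End-of-read library adaptors (a 44-bp adaptor that may be present fully,
partially or not at all) are detected by suffix–prefix comparison and
trimmed together with their qualities.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ADAPTOR_STATES = ("full", "partial", "none", "unknown")


@dataclass
class Read:
    """A single-end read with per-base Phred qualities.

    ``emulsion_set`` labels the library partition within which PCR
    duplicates can arise; ``adaptor_state`` records what the trimmer
    found at the 3' end (``unknown`` until trimming has run).
    """

    id: str
    sequence: str
    quality: list[int] = field(default_factory=list)
    emulsion_set: str = ""
    adaptor_state: str = "unknown"

    def __post_init__(self) -> None:
        if self.quality and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.quality and min(self.quality) < 0:
            raise ValueError(f"read {self.id}: negative Phred score")
        if self.adaptor_state not in ADAPTOR_STATES:
            raise ValueError(f"read {self.id}: bad adaptor_state {self.adaptor_state!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        if not self.quality:
            return 0.0
        return sum(self.quality) / len(self.quality)


@dataclass
class ClusterSet:
    """A partition of read ids into duplicate clusters.

    ``clusters`` maps a cluster id to its member read ids; the cluster id
    is the id of the representative, which is always a member.
    """

    clusters: dict[str, list[str]]

    @property
    def representatives(self) -> list[str]:
        return list(self.clusters)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict[str, str]:
        """Map every read id to its cluster id."""
        return {m: rep for rep, members in self.clusters.items() for m in members}


# ---------------------------------------------------------------------------
# quality filtering
# ---------------------------------------------------------------------------

def filter_mean_quality(reads: list[Read], threshold: float = 20.0) -> list[Read]:
    """Keep reads whose mean Phred quality is at or above ``threshold``.

    A read with mean quality exactly at the threshold is retained: the
    filter removes reads *below* the threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept = [r for r in reads if r.mean_quality >= threshold]
    logger.info("quality filter: %d in, %d kept, %d removed",
                len(reads), len(kept), len(reads) - len(kept))
    return kept


# ---------------------------------------------------------------------------
# duplicate clustering
# ---------------------------------------------------------------------------

def _normalized_distance(a: str, b: str) -> float:
    """Global (Needleman-Wunsch) edit distance over the longer length."""
    if not a and not b:
        return 0.0
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return d / max(len(a), len(b))


def _representative(members: list[Read]) -> Read:
    """Longest member; ties broken by mean quality, then lexicographic id."""
    return max(members, key=lambda r: (len(r), r.mean_quality, [-ord(c) for c in r.id]))


def _cluster_linkage(reads: list[Read], cutoff: float) -> ClusterSet:
    """All-pairs single linkage within each emulsion set (union-find)."""
    parent = {r.id: r.id for r in reads}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_set: dict[str, list[Read]] = defaultdict(list)
    for r in reads:
        by_set[r.emulsion_set].append(r)
    for group in by_set.values():
        for a, b in itertools.combinations(group, 2):
            # cheap lower bound: length difference alone can exceed the cutoff
            if abs(len(a) - len(b)) > cutoff * max(len(a), len(b)):
                continue
            if _normalized_distance(a.sequence, b.sequence) <= cutoff:
                ra, rb = find(a.id), find(b.id)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[str, list[Read]] = defaultdict(list)
    for r in reads:
        groups[find(r.id)].append(r)
    clusters = {}
    for members in groups.values():
        rep = _representative(members)
        clusters[rep.id] = [m.id for m in members]
    return ClusterSet(clusters)


def _greedy_match(read: Read, rep: Read, identity: float, coverage: float) -> bool:
    """cd-hit style test of ``read`` against a (longer or equal) representative."""
    shorter, longer = (read, rep) if len(read) <= len(rep) else (rep, read)
    res = edlib.align(shorter.sequence, longer.sequence, mode="HW", task="path")
    if res["editDistance"] < 0:
        return False
    cigar = res["cigar"]
    matches = columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    loc = res["locations"][0]
    span = loc[1] - loc[0] + 1
    return (matches / columns >= identity) and (span / len(longer) >= coverage)


def _cluster_greedy(reads: list[Read], identity: float, coverage: float) -> ClusterSet:
    """Longest-first greedy clustering against accumulated representatives."""
    order = sorted(reads, key=lambda r: (-len(r), -r.mean_quality, r.id))
    reps: list[Read] = []
    clusters: dict[str, list[str]] = {}
    for read in order:
        for rep in reps:
            if _greedy_match(read, rep, identity, coverage):
                clusters[rep.id].append(read.id)
                break
        else:
            reps.append(read)
            clusters[read.id] = [read.id]
    return ClusterSet(clusters)


def cluster_duplicates(reads: list[Read], mode: str = "linkage", *,
                       cutoff: float = 0.03,
                       identity: float = 0.97,
                       coverage: float = 0.8) -> ClusterSet:
    """Cluster emulsion-PCR duplicate reads.

    Parameters
    ----------
    mode:
        ``"linkage"`` — single-linkage at normalized global edit distance
        ``cutoff``, within each emulsion set separately.
        ``"greedy"`` — longest-first greedy clustering: a read joins the
        first representative with identity >= ``identity`` over at least
        ``coverage`` of the longer sequence, else founds a new cluster.
    """
    if mode == "linkage":
        if not 0 <= cutoff <= 1:
            raise ValueError("cutoff must be in [0, 1]")
        cs = _cluster_linkage(reads, cutoff)
    elif mode == "greedy":
        if not 0 < identity <= 1 or not 0 < coverage <= 1:
            raise ValueError("identity and coverage must be in (0, 1]")
        cs = _cluster_greedy(reads, identity, coverage)
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")
    assert sum(len(m) for m in cs.clusters.values()) == len(reads)
    logger.info("dedup (%s): %d reads -> %d clusters", mode, len(reads), cs.n_clusters)
    return cs


# ---------------------------------------------------------------------------
# adaptor trimming
# ---------------------------------------------------------------------------

def trim_end_adaptor(read: Read, end_adaptor: str, *,
                     min_overlap: int = 6,
                     max_mismatch_frac: float = 0.1) -> Read:
    """Trim a (possibly partial) 3'-end adaptor from a read.

    The longest suffix of the read matching a prefix of ``end_adaptor``
    with at most ``max_mismatch_frac`` mismatches and length at least
    ``min_overlap`` is removed; qualities are trimmed in lockstep.  The
    returned read's ``adaptor_state`` is ``full`` when the entire adaptor
    was found, ``partial`` for a shorter prefix, else ``none``.
    Only the forward orientation is searched.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq = read.sequence
    for k in range(min(len(seq), len(end_adaptor)), min_overlap - 1, -1):
        suffix = seq[-k:]
        prefix = end_adaptor[:k]
        mism = sum(1 for x, y in zip(suffix, prefix) if x != y)
        if mism <= int(max_mismatch_frac * k):
            state = "full" if k == len(end_adaptor) else "partial"
            return replace(read, sequence=seq[:-k],
                           quality=read.quality[:-k], adaptor_state=state)
    return replace(read, adaptor_state="none")


def trim_key_adaptor(read: Read, key_adaptor: str) -> Read:
    """Remove the short sequencing key from the read start if present verbatim."""
    if key_adaptor and read.sequence.startswith(key_adaptor):
        n = len(key_adaptor)
        return replace(read, sequence=read.sequence[n:], quality=read.quality[n:])
    return read


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fastq(path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        es, st = "", "unknown"
        for tok in rec.description.split():
            if tok.startswith("ES="):
                es = tok[3:]
            elif tok.startswith("AD="):
                st = tok[3:]
        reads.append(Read(rec.id, str(rec.seq),
                          list(rec.letter_annotations["phred_quality"]),
                          emulsion_set=es, adaptor_state=st))
    return reads


def write_fastq(reads: list[Read], path) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id,
                        description=f"ES={r.emulsion_set} AD={r.adaptor_state}")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def write_fasta(reads: list[Read], path) -> None:
    recs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in reads]
    SeqIO.write(recs, str(path), "fasta")


def write_clusters(cs: ClusterSet, path) -> None:
    """Two-column tab-separated membership table (read_id, cluster_id)."""
    with open(path, "w") as fh:
        fh.write("read_id\tcluster_id\n")
        for rep, members in cs.clusters.items():
            for m in members:
                fh.write(f"{m}\t{rep}\n")
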