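"""Synthetic bone-community and 454-style read generation with known truth.

The generator emulates the salient artifacts of a pyrosequenced
ancient-bone metagenome:

* a mock reference community with ranked lineages spanning several
  phyla, pairwise sequence divergence set by a star phylogeny;
* bimodal read lengths (peaks at 44 bp and 255 bp);
* a 4-bp sequencing key at every read start and a 44-bp end adaptor
  present fully, partially or not at all (drawn per template molecule,
  as on a real bead);
* emulsion-PCR duplicate reads: geometric group sizes, copies sharing
  one damaged template but differing at sequencing-error positions;
* a sequencing-error floor of 4e-4 substitutions per site plus
  homopolymer indels;
* cytosine-deamination damage: every template C is read as T with an
  interior per-C probability that is enhanced up to ~50-60-fold toward
  the 5' end of the molecule (geometric decay), and — because both
  strands of the ancient molecule deaminate — the complementary G→A
  change appears with the mirrored enhancement toward the 3' end.

Every emitted read has exactly one truth row recording its source,
coordinates, duplicate group, adaptor state and the damaged and
error positions, so downstream stages can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import Read
from .taxonomy import RANKS, TaxonPath, revcomp

BASES = np.array(list("ACGT"))

#: default 454-style adaptors: the 4-bp key and a fixed 44-bp end adaptor.
DEFAULT_KEY = "TCAG"
DEFAULT_END_ADAPTOR = "ATCACCGACTGCCCATAGAGAGGCTGAGACTGCCAAGGCACACA"


@dataclass
class DamageModel:
    """Deamination and instrument-error model.

    ``ct_interior`` is the probability that a template cytosine away
    from the molecule ends is read as T.  At 1-based position ``pos``
    from the 5' end the rate is
    ``ct_interior * (1 + (terminal_factor - 1) * exp(-pos / decay_length))``;
    the complementary G→A change uses the mirrored distance from the 3'
    end.  ``baseline_error`` is the per-site instrument substitution
    rate and ``homopolymer_indel_rate`` the per-run indel probability.
    """

    baseline_error: float = 4e-4
    ct_interior: float = 0.0
    terminal_factor: float = 1.0
    decay_length: float = 5.0
    homopolymer_indel_rate: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("baseline_error", "ct_interior", "homopolymer_indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.terminal_factor < 1.0:
            raise ValueError("terminal_factor must be >= 1")
        if self.rate_at(1) > 1.0:
            raise ValueError("effective terminal deamination rate exceeds 1")

    def rate_at(self, pos: int | np.ndarray) -> float | np.ndarray:
        """Deamination rate at 1-based distance ``pos`` from the enhanced end."""
        return self.ct_interior * (
            1.0 + (self.terminal_factor - 1.0) * np.exp(-np.asarray(pos) / self.decay_length))


#: damage defaults for an ancient (damaged) taxon: interior per-C
#: deamination 0.02, ~50-fold end enhancement, 4e-4 error floor.
ANCIENT_DAMAGE = DamageModel(baseline_error=4e-4, ct_interior=0.02,
                             terminal_factor=50.0, decay_length=5.0)
#: undamaged modern DNA: instrument error only.
NO_DAMAGE = DamageModel(baseline_error=4e-4, ct_interior=0.0)


@dataclass
class ReadLengthModel:
    """Bimodal read-length mixture (short and long normal components)."""

    short_mode: int = 44
    long_mode: int = 255
    short_fraction: float = 0.8
    short_sd: float = 4.0
    long_sd: float = 25.0

    def __post_init__(self) -> None:
        if self.short_mode <= 0 or self.long_mode <= 0:
            raise ValueError("length modes must be positive")
        if not 0.0 <= self.short_fraction <= 1.0:
            raise ValueError("short_fraction must be in [0, 1]")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        short = rng.random(n) < self.short_fraction
        mode = np.where(short, self.short_mode, self.long_mode)
        sd = np.where(short, self.short_sd, self.long_sd)
        return np.maximum(20, np.rint(rng.normal(mode, sd)).astype(int))


@dataclass
class AdaptorConfig:
    """Key and end-adaptor sequences and the end-adaptor presence model."""

    key_adaptor: str = DEFAULT_KEY
    end_adaptor: str = DEFAULT_END_ADAPTOR
    p_full: float = 0.4
    p_partial: float = 0.3
    p_absent: float = 0.3

    def __post_init__(self) -> None:
        if len(self.key_adaptor) != 4:
            raise ValueError("key adaptor must be exactly 4 bases")
        if len(self.end_adaptor) != 44:
            raise ValueError("end adaptor must be exactly 44 bases")
        if not math.isclose(self.p_full + self.p_partial + self.p_absent, 1.0):
            raise ValueError("presence probabilities must sum to 1")


NO_ADAPTORS = AdaptorConfig(p_full=0.0, p_partial=0.0, p_absent=1.0)


@dataclass
class CommunityEntry:
    accession: str
    taxonomy: TaxonPath
    gene: str  # SSU, LSU or genomic
    sequence: str


@dataclass
class ReferenceCommunity:
    """Mock community: reference entries plus normalized abundance weights."""

    entries: list[CommunityEntry]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("community must contain at least one entry")
        if any(not e.sequence for e in self.entries):
            raise ValueError("community entries must have non-empty sequences")
        if self.weights is None:
            self.weights = np.full(len(self.entries), 1.0 / len(self.entries))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.entries) or (self.weights < 0).any():
            raise ValueError("weights must be non-negative, one per entry")
        self.weights = self.weights / self.weights.sum()


# ---------------------------------------------------------------------------
# community simulation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each site with probability ``rate`` to a different base."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _branch_rate(divergence: float) -> float:
    """Per-branch substitution rate on a star tree such that the expected
    observed pairwise mismatch fraction equals ``divergence``.

    Two leaves differ at a site if exactly one branch mutated, or both
    mutated to different bases (2/3 of double hits):
    ``d = 2 b (1 - b) + (2/3) b^2``.
    """
    if divergence == 0:
        return 0.0
    # (-4/3) b^2 + 2 b - d = 0
    return (2 - math.sqrt(4 - (16.0 / 3.0) * divergence)) / (8.0 / 3.0)


def simulate_community(seed: int, n_taxa: int,
                       gene_lengths: dict[str, int] | None = None,
                       divergence: float = 0.1,
                       gc: float = 0.5) -> ReferenceCommunity:
    """Simulate a mock community of rRNA genes with known lineages.

    Taxa evolve on a star phylogeny from one random ancestor per gene,
    with per-branch rates chosen so that the expected pairwise
    divergence matches the request.  Lineages span two phyla whenever
    ``n_taxa >= 2``; abundance weights decay geometrically (the dominant
    taxon mirrors a bone community dominated by one genus).
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if not 0.0 <= divergence <= 0.3:
        raise ValueError("divergence must be in [0, 0.3]")
    gene_lengths = gene_lengths or {"SSU": 1500}
    rng = np.random.default_rng(seed)
    b = _branch_rate(divergence)
    entries = []
    for gene, length in gene_lengths.items():
        ancestor = _random_seq(rng, length, gc)
        for i in range(n_taxa):
            lineage = TaxonPath((
                "Bacteria",
                f"Phylum_{i % 2 + 1:02d}",
                f"Class_{i + 1:02d}",
                f"Order_{i + 1:02d}",
                f"Family_{i + 1:02d}",
                f"Genus_{i + 1:02d}",
            ))
            seq = _mutate(rng, ancestor, b)
            entries.append(CommunityEntry(f"REF{i + 1:03d}_{gene}", lineage, gene, seq))
    taxon_w = np.array([0.5 ** i for i in range(n_taxa)])
    taxon_w /= taxon_w.sum()
    weights = np.array([taxon_w[int(e.accession[3:6]) - 1] / len(gene_lengths)
                        for e in entries])
    return ReferenceCommunity(entries, weights)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _apply_damage(rng: np.random.Generator, frag: str, dm: DamageModel):
    """Deaminate one template molecule (both strands): C→T enhanced toward
    the 5' end, G→A enhanced toward the 3' end.  Returns the damaged
    fragment and the list of damaged positions (0-based)."""
    if dm.ct_interior == 0.0:
        return frag, []
    arr = np.array(list(frag))
    L = len(arr)
    pos5 = np.arange(1, L + 1)
    c_sites = arr == "C"
    g_sites = arr == "G"
    hit_c = c_sites & (rng.random(L) < dm.rate_at(pos5))
    hit_g = g_sites & (rng.random(L) < dm.rate_at(pos5[::-1]))
    arr[hit_c] = "T"
    arr[hit_g] = "A"
    damaged = sorted(np.nonzero(hit_c | hit_g)[0].tolist())
    return "".join(arr), damaged


def _apply_errors(rng: np.random.Generator, seq: str, dm: DamageModel):
    """Instrument noise on one sequencing pass: random substitutions at the
    baseline rate, then homopolymer indels.  Returns (sequence,
    substitution positions, indel count)."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < dm.baseline_error
    err_pos = np.nonzero(hit)[0].tolist()
    for i in err_pos:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    out = "".join(arr)
    n_indels = 0
    if dm.homopolymer_indel_rate > 0:
        pieces = []
        i = 0
        while i < len(out):
            j = i
            while j < len(out) and out[j] == out[i]:
                j += 1
            run = out[i:j]
            if j - i >= 2 and rng.random() < dm.homopolymer_indel_rate:
                n_indels += 1
                run = run + out[i] if rng.random() < 0.5 else run[:-1]
            pieces.append(run)
            i = j
        out = "".join(pieces)
    return out, err_pos, n_indels


def _qualities(rng: np.random.Generator, n: int,
               mean: float = 27.0, sd: float = 4.0) -> list[int]:
    q = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    return np.clip(q, 2, 40).tolist()


def simulate_reads(community: ReferenceCommunity, n_reads: int,
                   length_model: ReadLengthModel | None = None,
                   adaptor_config: AdaptorConfig | None = None,
                   damage_model: DamageModel | None = None,
                   duplication_mean: float = 1.0,
                   seed: int = 0, *,
                   damage_by_taxon: dict[str, DamageModel] | None = None,
                   n_emulsion_sets: int = 4) -> tuple[list[Read], pd.DataFrame]:
    """Simulate 454-style reads with a complete truth table.

    Duplicate-group sizes are geometric with mean ``duplication_mean``;
    copies in a group share one damaged template molecule (and its
    adaptor state, as on a real bead) and differ only at
    sequencing-error positions.  ``damage_by_taxon`` optionally
    overrides the damage model per genus label, so a community can mix
    ancient (damaged) and recent (undamaged) taxa.  Fixing the seed
    fixes every emitted byte.
    """
    if not community.entries:
        raise ValueError("empty community")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if duplication_mean < 1:
        raise ValueError("duplication_mean must be >= 1")
    length_model = length_model or ReadLengthModel()
    adaptor_config = adaptor_config or AdaptorConfig()
    damage_model = damage_model or NO_DAMAGE
    damage_by_taxon = damage_by_taxon or {}

    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    truth_rows = []
    group = 0
    while len(reads) < n_reads:
        group += 1
        size = int(min(rng.geometric(1.0 / duplication_mean), n_reads - len(reads)))
        ei = int(rng.choice(len(community.entries), p=community.weights))
        entry = community.entries[ei]
        dm = damage_by_taxon.get(entry.taxonomy.labels[-1], damage_model)
        L = int(min(length_model.draw(rng, 1)[0], len(entry.sequence)))
        start = int(rng.integers(0, len(entry.sequence) - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = entry.sequence[start:start + L]
        if strand == "-":
            frag = revcomp(frag)
        frag, damaged = _apply_damage(rng, frag, dm)
        # adaptor state is a property of the bead-bound template
        u = rng.random()
        if u < adaptor_config.p_full:
            state, tail = "full", adaptor_config.end_adaptor
        elif u < adaptor_config.p_full + adaptor_config.p_partial:
            k = int(rng.integers(1, len(adaptor_config.end_adaptor)))
            state, tail = "partial", adaptor_config.end_adaptor[:k]
        else:
            state, tail = "none", ""
        eset = f"ES{int(rng.integers(n_emulsion_sets)) + 1}"
        for _ in range(size):
            seq, err_pos, n_indels = _apply_errors(rng, frag, dm)
            full = adaptor_config.key_adaptor + seq + tail
            rid = f"read{len(reads) + 1:06d}"
            reads.append(Read(rid, full, _qualities(rng, len(full)),
                              emulsion_set=eset))
            truth_rows.append({
                "read_id": rid, "accession": entry.accession,
                "taxon": str(entry.taxonomy), "gene": entry.gene,
                "strand": strand, "start": start, "end": start + L,
                "dup_group": group, "adaptor_state": state,
                "damaged_positions": ";".join(map(str, damaged)),
                "error_positions": ";".join(map(str, err_pos)),
                "n_indels": n_indels,
            })
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def community_reference_entries(community: ReferenceCommunity):
    """View the community as curated-quality rRNA reference entries."""
    from .taxonomy import ReferenceEntry
    return [ReferenceEntry(e.accession, e.gene, e.sequence,
                           align_quality=100, pintail=100,
                           taxonomies={"silva": e.taxonomy})
            for e in community.entries if e.gene in ("SSU", "LSU")]


def simulate_host_genome(community: ReferenceCommunity, seed: int,
                         flank: int = 5000, spacer: int = 500,
                         divergence: float = 0.02, gc: float = 0.5):
    """Embed slightly diverged copies of the first taxon's rRNA genes in a
    random host genome: ``[flank] SSU [spacer] LSU [flank]``.

    Returns ``(genome, genes)`` with ``genes`` a list of 0-based
    half-open ``(start, end, gene_class)`` intervals — the truth for the
    rRNA-detection benchmark.
    """
    rng = np.random.default_rng(seed)
    by_gene = {e.gene: e for e in community.entries
               if e.accession.startswith("REF001")}
    parts = [_random_seq(rng, flank, gc)]
    genes = []
    pos = flank
    for gene in ("SSU", "LSU"):
        if gene not in by_gene:
            continue
        seq = _mutate(rng, by_gene[gene].sequence, divergence)
        parts.append(seq)
        genes.append((pos, pos + len(seq), gene))
        pos += len(seq)
        parts.append(_random_seq(rng, spacer, gc))
        pos += spacer
    parts.append(_random_seq(rng, flank - spacer, gc))
    return "".join(parts), genes


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       dtype={"damaged_positions": str, "error_positions": str})


def write_config(config: dict, path) -> None:
    """Flat key=value file."""
    with open(path, "w") as fh:
        for k in sorted(config):
            fh.write(f"{k}={config[k]}\n")
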