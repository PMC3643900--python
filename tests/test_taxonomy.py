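"""Reference curation rules, the built-in local search, and the
majority-LCA assignment checked against a brute-force tree oracle."""

import numpy as np
import pytest

from paleorrna.simulate import (
    NO_ADAPTORS,
    DamageModel,
    ReadLengthModel,
    community_reference_entries,
    simulate_community,
    simulate_reads,
)
from paleorrna.taxonomy import (
    RANKS,
    Assignment,
    HitRecord,
    ReferenceEntry,
    TaxonPath,
    assign_all,
    assign_taxonomy_mlca,
    compose_profile,
    curate_reference_db,
    read_hits,
    read_reference_table,
    round_sig,
    search_local,
    write_hits,
    write_reference_table,
)


def entry(acc="X1", aq=90, pintail=100, domains=("Bacteria",), informative=True):
    taxonomies = {src: TaxonPath((dom, "Actinobacteria"))
                  for src, dom in zip(("silva", "embl", "greengenes"), domains)}
    return ReferenceEntry(acc, "SSU", "ACGT" * 100, align_quality=aq,
                          pintail=pintail, taxonomies=taxonomies,
                          informative=informative)


def hit(acc, evalue=1e-30, query="q1"):
    return HitRecord(query, acc, 100.0, 50, 0, 0, 1, 50, 1, 50, evalue, 100.0)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_majority_descent(paths, majority, strict_phylum):
    """Literal tree-descent oracle: build the taxon tree with hit counts
    and walk down while a unique child holds a majority."""
    n = len(paths)
    # count hits passing through every prefix of the tree
    counts = {}
    for p in paths:
        for d in range(1, len(p) + 1):
            counts[p[:d]] = counts.get(p[:d], 0) + 1
    if strict_phylum:
        phyla = {p[1] for p in paths if len(p) > 1}
        if len(phyla) > 1:
            doms = [pref for pref in counts if len(pref) == 1
                    and counts[pref] >= majority * n - 1e-9]
            return doms[0] if len(doms) == 1 else ()
    out = ()
    while True:
        children = [pref for pref in counts
                    if len(pref) == len(out) + 1 and pref[:len(out)] == out
                    and counts[pref] >= majority * n - 1e-9]
        if len(children) != 1:
            return out
        out = children[0]


def oracle_strict_lca(paths):
    """Classical lowest common ancestor: longest shared prefix."""
    out = []
    for labs in zip(*paths):
        if len(set(labs)) == 1:
            out.append(labs[0])
        else:
            break
    shortest = min(len(p) for p in paths)
    return tuple(out[:shortest])


def random_paths(rng, n):
    """Random ragged lineages over a small random taxonomy."""
    paths = []
    for _ in range(n):
        depth = int(rng.integers(1, 7))
        labs = [f"D{rng.integers(2)}"]
        for d in range(1, depth):
            labs.append(f"{RANKS[d][0].upper()}{rng.integers(3)}")
        paths.append(tuple(labs))
    return paths


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

class TestCuration:
    @pytest.mark.parametrize("e,kept", [
        (entry(aq=74), False),                       # poorly aligned
        (entry(aq=75), True),                        # boundary kept
        (entry(pintail=99), False),                  # potential chimera
        (entry(pintail=100), True),                  # boundary kept
        (entry(domains=("Bacteria", "Eukaryota")), False),  # domain conflict
        (entry(informative=False), False),           # metagenome read etc.
    ])
    def test_rules(self, e, kept):
        assert (len(curate_reference_db([e])) == 1) is kept

    def test_blacklist_and_missing_metadata(self):
        assert curate_reference_db([entry("TRNA1")], {"TRNA1"}) == []
        bad = ReferenceEntry("Y1", "SSU", "ACGT", align_quality=None,
                             pintail=100, taxonomies={"silva": TaxonPath(("B",))})
        assert curate_reference_db([bad]) == []

    def test_idempotent(self):
        entries = [entry("A", aq=90), entry("B", aq=60), entry("C", pintail=50)]
        once = curate_reference_db(entries)
        assert curate_reference_db(once) == once


class TestTaxonPath:
    def test_gap_rejected(self):
        with pytest.raises(ValueError):
            TaxonPath(("Bacteria", "", "Clostridia"))

    def test_parse_and_rank(self):
        p = TaxonPath.parse("Bacteria;Actinobacteria;Actinomycetia")
        assert p.rank == "class"
        assert p.at("phylum") == "Actinobacteria"
        assert p.at("genus") is None


# ---------------------------------------------------------------------------
# built-in search
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def refs():
    rng = np.random.default_rng(99)
    seqs = ["".join(rng.choice(list("ACGT"), 1500)) for _ in range(3)]
    return [ReferenceEntry(f"R{i}", "SSU", s, align_quality=100, pintail=100,
                           taxonomies={"silva": TaxonPath(("Bacteria",))})
            for i, s in enumerate(seqs)]


class TestSearch:

    def test_exact_substring_is_unique_best_hit(self, refs):
        q = refs[1].sequence[200:300]
        hits = search_local([("q", q)], refs, 1e-10)
        assert len(hits) == 1
        h = hits[0]
        assert h.subject == "R1" and h.pident == 100.0
        assert (h.qstart, h.qend) == (1, 100)
        assert (h.sstart, h.send) == (201, 300)

    def test_reverse_strand_hit_found(self, refs):
        from paleorrna.taxonomy import revcomp
        q = revcomp(refs[0].sequence[400:520])
        hits = search_local([("q", q)], refs, 1e-10)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].pident == 100.0

    def test_shared_substring_ties_two_references(self, refs):
        shared = refs[0].sequence[:120]
        twins = [ReferenceEntry(f"T{i}", "SSU", shared + refs[i].sequence[120:],
                                align_quality=100, pintail=100,
                                taxonomies={"silva": TaxonPath(("Bacteria",))})
                 for i in range(2)]
        hits = search_local([("q", shared)], twins, 1e-10)
        assert len(hits) == 2
        assert round_sig(hits[0].evalue) == round_sig(hits[1].evalue)

    def test_random_queries_yield_no_hits_at_cutoff(self, refs):
        """Empirical null: unrelated 60-bp queries against a 10-kb
        reference never reach e <= 1e-10."""
        rng = np.random.default_rng(7)
        ref = [ReferenceEntry("BIG", "SSU", "".join(rng.choice(list("ACGT"), 10_000)),
                              align_quality=100, pintail=100,
                              taxonomies={"silva": TaxonPath(("Bacteria",))})]
        queries = [(f"q{i}", "".join(rng.choice(list("ACGT"), 60)))
                   for i in range(50)]
        assert search_local(queries, ref, 1e-10) == []

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="empty reference"):
            search_local([("q", "ACGT")], [], 1e-10)


# ---------------------------------------------------------------------------
# majority-LCA assignment
# ---------------------------------------------------------------------------

class TestMajorityLCA:
    def _assign(self, paths, majority=0.5, strict_phylum=True):
        taxonomy = {f"A{i}": TaxonPath(p) for i, p in enumerate(paths)}
        hits = [hit(f"A{i}") for i in range(len(paths))]
        a = assign_taxonomy_mlca(hits, taxonomy, majority, strict_phylum)
        return a.path.labels if a.path else ()

    def test_unanimous_hits_reach_genus(self):
        p = ("Bacteria", "Actinobacteria", "Actinomycetia", "Streptomycetales",
             "Streptomycetaceae", "Streptomyces")
        assert self._assign([p] * 10) == p

    def test_cross_phylum_hits_truncate_to_domain(self):
        actino = ("Bacteria", "Actinobacteria", "Actinomycetia",
                  "Streptomycetales")
        firmi = ("Bacteria", "Firmicutes")
        labels = self._assign([actino] * 9 + [firmi], strict_phylum=True)
        assert labels == ("Bacteria",)

    def test_majority_descends_past_plain_lca(self):
        base = ("Bacteria", "P1", "C1", "O1")
        a = base + ("FamilyA",)
        b = base + ("FamilyB",)
        labels = self._assign([a, a, a, b])
        assert labels == a                      # 3/4 >= 50%
        assert oracle_strict_lca([a, a, a, b]) == base  # plain LCA is shallower

    def test_even_split_stops_at_parent(self):
        base = ("Bacteria", "P1", "C1", "O1")
        a = base + ("FamilyA",)
        b = base + ("FamilyB",)
        assert self._assign([a, a, b, b]) == base

    def test_no_hits_returns_none(self):
        assert assign_taxonomy_mlca([], {}, 0.5, True) is None

    def test_only_tied_best_evalue_hits_count(self):
        taxonomy = {"A": TaxonPath(("Bacteria", "P1")),
                    "B": TaxonPath(("Bacteria", "P2"))}
        hits = [hit("A", 1e-40), hit("B", 1e-12)]
        a = assign_taxonomy_mlca(hits, taxonomy, 0.5, True)
        assert a.path.labels == ("Bacteria", "P1")
        assert a.n_best == 1

    def test_evalue_ties_detected_after_rounding(self):
        taxonomy = {"A": TaxonPath(("Bacteria", "P1")),
                    "B": TaxonPath(("Bacteria", "P1", "C1"))}
        hits = [hit("A", 1.2341e-30), hit("B", 1.2339e-30)]
        a = assign_taxonomy_mlca(hits, taxonomy, 0.5, True)
        assert a.n_best == 2

    def test_matches_descent_oracle_on_random_cases(self):
        """1000 random taxonomies/hit sets against the brute-force
        tree-descent oracle, across majority settings."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            paths = random_paths(rng, int(rng.integers(1, 9)))
            majority = float(rng.choice([0.5, 0.6, 0.75, 1.0]))
            strict = bool(rng.integers(2))
            got = self._assign(paths, majority, strict)
            want = oracle_majority_descent(paths, majority, strict)
            assert got == want, (paths, majority, strict)

    def test_full_majority_equals_classical_lca(self):
        rng = np.random.default_rng(321)
        for _ in range(1000):
            paths = random_paths(rng, int(rng.integers(1, 7)))
            got = self._assign(paths, majority=1.0, strict_phylum=False)
            assert got == oracle_strict_lca(paths), paths

    def test_raising_majority_never_deepens(self):
        rng = np.random.default_rng(55)
        for _ in range(300):
            paths = random_paths(rng, int(rng.integers(1, 8)))
            depths = [len(self._assign(paths, m, False))
                      for m in (0.5, 0.6, 0.8, 1.0)]
            assert depths == sorted(depths, reverse=True)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

class TestProfile:
    def _assignment(self, rid, labels):
        return Assignment(rid, TaxonPath(labels) if labels else None, 1)

    def test_phylum_percentages(self):
        a = [self._assignment(f"r{i}", ("Bacteria", "Actinobacteria"))
             for i in range(80)]
        b = [self._assignment(f"s{i}", ("Bacteria", "Proteobacteria"))
             for i in range(20)]
        prof = compose_profile(a + b, "phylum")
        assert prof.set_index("taxon").percent.to_dict() == {
            "Actinobacteria": 80.0, "Proteobacteria": 20.0}

    def test_domain_only_reads_roll_up(self):
        a = [self._assignment(f"r{i}", ("Bacteria", "Actinobacteria"))
             for i in range(5)]
        b = [self._assignment(f"s{i}", ("Bacteria",)) for i in range(5)]
        prof = compose_profile(a + b, "phylum")
        assert prof.set_index("taxon").loc["Bacteria", "count"] == 5

    def test_counts_conserved_and_percents_sum_100(self):
        rng = np.random.default_rng(2)
        assigns = [self._assignment(f"r{i}", tuple(p))
                   for i, p in enumerate(random_paths(rng, 57))]
        prof = compose_profile(assigns, "order")
        assert prof["count"].sum() == 57
        assert prof.percent.sum() == pytest.approx(100.0)


def test_synthetic_reads_recover_true_phylum():
    """Classification accuracy: with 10% community divergence and low
    error, nearly every read with a hit lands in its true phylum."""
    c = simulate_community(77, 4, {"SSU": 1500}, divergence=0.1)
    dm = DamageModel(baseline_error=0.005, ct_interior=0.0)
    reads, truth = simulate_reads(
        c, 120, length_model=ReadLengthModel(100, 255, 0.3),
        adaptor_config=NO_ADAPTORS, damage_model=dm, seed=78)
    refs = curate_reference_db(community_reference_entries(c))
    hits = search_local(reads, refs, 1e-10)
    taxonomy = {r.accession: r.taxonomy for r in refs}
    assignments = assign_all(hits, taxonomy)
    true_phylum = dict(zip(truth.read_id,
                           truth.taxon.str.split(";").str[1]))
    ok = total = 0
    for a in assignments:
        total += 1
        ok += (a.path is not None and len(a.path) >= 2
               and a.path.labels[1] == true_phylum[a.read_id])
    assert total > 0
    assert ok / total >= 0.95


def test_reference_table_and_hits_roundtrip(tmp_path):
    entries = [entry("A1"), entry("B2", domains=("Bacteria", "Bacteria"))]
    p = tmp_path / "refs.tsv"
    write_reference_table(entries, p)
    back = read_reference_table(p)
    assert [e.accession for e in back] == ["A1", "B2"]
    assert back[0].taxonomies["silva"] == entries[0].taxonomies["silva"]

    hits = [hit("A1", 1.23e-30), hit("B2", 4.5e-12)]
    hp = tmp_path / "hits.tsv"
    write_hits(hits, hp)
    back = read_hits(hp)
    assert [h.subject for h in back] == ["A1", "B2"]
    assert back[0].evalue == pytest.approx(1.23e-30, rel=1e-2)
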