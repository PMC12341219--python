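"""Dereplication, UNOISE-style denoising, chimeras, OTU clustering, taxonomy."""

import numpy as np
import pytest

from darkamp.denoise import (TaxonomyReference, UniqueSeq, Zotu, beta_skew,
                             classify_taxonomy, cluster_otus, dereplicate,
                             flag_chimeras, pairwise_identity, unoise_denoise)


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _mutate(seq, positions, rng):
    s = list(seq)
    for p in positions:
        s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s)


class TestDereplicate:
    def test_counts_and_singleton_removal(self):
        seqs = ["AAA"] * 3 + ["CCC"] + ["GGG"] * 2
        uniques = dereplicate(seqs, "s1")
        assert {(u.seq, u.count) for u in uniques} == {("AAA", 3), ("GGG", 2)}

    def test_all_singletons_empty(self):
        assert dereplicate(["AAA", "CCC", "GGG"]) == []

    def test_sorted_by_descending_count(self):
        uniques = dereplicate(["A"] * 2 + ["C"] * 5 + ["G"] * 3)
        assert [u.count for u in uniques] == [5, 3, 2]


class TestUnoise:
    @pytest.mark.parametrize("d,count,centroid_count,merged", [
        (1, 10, 100, True),    # 0.10 <= beta(1) = 0.125
        (1, 20, 100, False),   # 0.20 >  0.125 -> new ZOTU
        (2, 3, 100, True),     # 0.03 <= beta(2) = 0.03125
        (2, 4, 100, False),
        (3, 2, 300, True),     # 2/300 <= beta(3) = 1/128
        (3, 3, 300, False),
    ])
    def test_abundance_skew_boundary(self, d, count, centroid_count, merged):
        rng = np.random.default_rng(d * 1000 + count)
        seq = _rand_seq(rng, 200)
        var = _mutate(seq, rng.choice(200, d, replace=False), rng)
        zotus, member_map = unoise_denoise(
            [UniqueSeq(seq, centroid_count, "s"), UniqueSeq(var, count, "s")])
        if merged:
            assert len(zotus) == 1
            assert zotus[0].total == centroid_count + count
            assert member_map[var] == seq
        else:
            assert len(zotus) == 2

    def test_beta_curve(self):
        assert beta_skew(1) == 1 / 8
        assert beta_skew(2) == 1 / 32
        assert beta_skew(1, alpha=3) == 1 / 16

    def test_recovers_planted_templates_under_errors(self):
        """Reads from 5 templates at 0.1% per-base error denoise to 5 ZOTUs."""
        rng = np.random.default_rng(7)
        templates = [_rand_seq(rng, 250) for _ in range(5)]
        reads = []
        for t in templates:
            for _ in range(1500):
                n_err = rng.binomial(len(t), 0.001)
                reads.append(_mutate(t, rng.choice(len(t), n_err, replace=False),
                                     rng) if n_err else t)
        uniques = dereplicate(reads, "s1")
        zotus, _ = unoise_denoise(uniques)
        assert sorted(z.centroid_seq for z in zotus) == sorted(templates)
        # count conservation: members accumulate to centroids
        assert sum(z.total for z in zotus) == sum(u.count for u in uniques)

    def test_idempotence(self):
        rng = np.random.default_rng(11)
        templates = [_rand_seq(rng, 150) for _ in range(4)]
        uniques = [UniqueSeq(t, 100 * (i + 1), "s")
                   for i, t in enumerate(templates)]
        zotus, _ = unoise_denoise(uniques)
        again, _ = unoise_denoise(
            [UniqueSeq(z.centroid_seq, z.total, "s") for z in zotus])
        assert {z.centroid_seq for z in again} == {z.centroid_seq for z in zotus}


class TestChimeras:
    def test_constructed_chimera_flagged(self):
        rng = np.random.default_rng(3)
        a, b = _rand_seq(rng, 200), _rand_seq(rng, 200)
        chimera = a[:100] + b[100:]
        zotus = [Zotu("Z1", a, {"s": 50}), Zotu("Z2", b, {"s": 40}),
                 Zotu("Z3", chimera, {"s": 10})]
        flag_chimeras(zotus)
        assert [z.chimera_flag for z in zotus] == [False, False, True]

    def test_prefix_only_match_not_flagged(self):
        rng = np.random.default_rng(4)
        a = _rand_seq(rng, 200)
        child = a[:100] + _rand_seq(rng, 100)  # right half matches nothing
        zotus = [Zotu("Z1", a, {"s": 50}), Zotu("Z3", child, {"s": 10})]
        flag_chimeras(zotus)
        assert not zotus[1].chimera_flag

    def test_low_parent_abundance_not_flagged(self):
        rng = np.random.default_rng(5)
        a, b = _rand_seq(rng, 200), _rand_seq(rng, 200)
        chimera = a[:100] + b[100:]
        zotus = [Zotu("Z1", a, {"s": 15}), Zotu("Z2", b, {"s": 40}),
                 Zotu("Z3", chimera, {"s": 10})]  # parent a < 2x child
        flag_chimeras(zotus)
        assert not zotus[2].chimera_flag

    def test_planted_chimera_recall(self):
        """Recall >= 0.9 on exact two-parent chimeras at known rate."""
        rng = np.random.default_rng(6)
        parents = [_rand_seq(rng, 300) for _ in range(8)]
        zotus = [Zotu(f"P{i}", p, {"s": int(rng.integers(200, 500))})
                 for i, p in enumerate(parents)]
        planted = []
        for i in range(10):
            ia, ib = rng.choice(8, 2, replace=False)
            k = int(rng.integers(50, 250))
            planted.append(Zotu(f"C{i}", parents[ia][:k] + parents[ib][k:],
                                {"s": int(rng.integers(2, 20))}))
        flag_chimeras(zotus + planted)
        recall = sum(z.chimera_flag for z in planted) / len(planted)
        assert recall >= 0.9
        assert not any(z.chimera_flag for z in zotus)


class TestClusterOtus:
    def test_identical_zotus_one_otu(self):
        z = [Zotu("Z1", "ACGT" * 50, {"s": 10}), Zotu("Z2", "ACGT" * 50, {"s": 5})]
        otus = cluster_otus(z)
        assert len(otus.members) == 1

    def test_below_cutoff_two_otus(self):
        rng = np.random.default_rng(8)
        a = _rand_seq(rng, 418)
        b = _mutate(a, rng.choice(418, 13, replace=False), rng)  # 96.9%
        assert pairwise_identity(a, b) < 0.97
        otus = cluster_otus([Zotu("Z1", a, {"s": 10}), Zotu("Z2", b, {"s": 5})])
        assert len(otus.members) == 2

    def test_membership_identity_invariant(self):
        rng = np.random.default_rng(9)
        bases = [_rand_seq(rng, 300) for _ in range(6)]
        zotus = []
        for i, b in enumerate(bases):
            for j in range(4):
                seq = _mutate(b, rng.choice(300, int(rng.integers(0, 6)),
                                            replace=False), rng)
                zotus.append(Zotu(f"Z{i}_{j}", seq,
                                  {"s": int(rng.integers(2, 500))}))
        otus = cluster_otus(zotus)
        seq_of = {z.zotu_id: z.centroid_seq for z in zotus}
        for otu_id, members in otus.members.items():
            centroid = seq_of[members[0]]
            for m in members:
                assert pairwise_identity(seq_of[m], centroid) >= 0.97

    def test_matches_exhaustive_oracle(self):
        """Greedy clustering equals the all-pairs oracle partition."""
        rng = np.random.default_rng(10)
        bases = [_rand_seq(rng, 200) for _ in range(12)]
        zotus, counts = [], rng.permutation(np.arange(100, 200))
        for i in range(60):
            b = bases[i % 12]
            seq = _mutate(b, rng.choice(200, int(rng.integers(0, 8)),
                                        replace=False), rng)
            zotus.append(Zotu(f"Z{i}", seq, {"s": int(counts[i])}))
        got = cluster_otus(zotus)
        # oracle: hamming identity matrix (equal lengths, substitutions only)
        ordered = sorted(zotus, key=lambda z: (-z.total, z.zotu_id))
        arr = np.array([[ord(c) for c in z.centroid_seq] for z in ordered])
        ident = 1.0 - (arr[:, None, :] != arr[None, :, :]).mean(axis=2)
        centroids, assign = [], {}
        for i, z in enumerate(ordered):
            hit = next((c for c in centroids if ident[i, c] >= 0.97), None)
            if hit is None:
                centroids.append(i)
                assign[z.zotu_id] = i
            else:
                assign[z.zotu_id] = hit
        oracle = {}
        for zid, c in assign.items():
            oracle.setdefault(c, set()).add(zid)
        got_partition = {frozenset(v) for v in got.members.values()}
        assert got_partition == {frozenset(v) for v in oracle.values()}


@pytest.fixture()
def toy_reference():
    rng = np.random.default_rng(21)
    entries = {}
    lin = {
        "wolb": {"domain": "Bacteria", "phylum": "Proteobacteria",
                 "class": "Alphaproteobacteria", "order": "Rickettsiales",
                 "family": "Anaplasmataceae", "genus": "Wolbachia"},
        "serr": {"domain": "Bacteria", "phylum": "Proteobacteria",
                 "class": "Gammaproteobacteria", "order": "Enterobacterales",
                 "family": "Yersiniaceae", "genus": "Serratia"},
        "carn": {"domain": "Bacteria", "phylum": "Firmicutes",
                 "class": "Bacilli", "order": "Lactobacillales",
                 "family": "Carnobacteriaceae", "genus": "Carnobacterium"},
    }
    for name, lineage in lin.items():
        entries[name] = (_rand_seq(rng, 250), lineage)
    return TaxonomyReference.from_dict(entries)


class TestClassifyTaxonomy:
    def test_identical_query_full_lineage(self, toy_reference):
        seq = toy_reference.records["wolb"]
        lineage, conf = classify_taxonomy(seq, toy_reference,
                                          rng=np.random.default_rng(0))
        assert lineage["genus"] == "Wolbachia"
        assert all(c == 1.0 for c in conf.values())

    def test_no_shared_kmers_unclassified(self, toy_reference):
        lineage, conf = classify_taxonomy("A" * 250, toy_reference,
                                          rng=np.random.default_rng(0))
        assert lineage == {} and conf == {}

    def test_query_shorter_than_k_unclassified(self, toy_reference):
        lineage, _ = classify_taxonomy("ACGTA", toy_reference,
                                       rng=np.random.default_rng(0))
        assert lineage == {}

    def test_confidence_monotone_and_seeded_rerun_identical(self, toy_reference):
        rng = np.random.default_rng(13)
        base = toy_reference.records["serr"]
        query = _mutate(base, rng.choice(250, 20, replace=False), rng)
        out1 = classify_taxonomy(query, toy_reference, cutoff=0.0,
                                 rng=np.random.default_rng(55))
        out2 = classify_taxonomy(query, toy_reference, cutoff=0.0,
                                 rng=np.random.default_rng(55))
        assert out1 == out2
        ranks = ["domain", "phylum", "class", "order", "family", "genus"]
        confs = [out1[1][r] for r in ranks if r in out1[1]]
        assert confs == sorted(confs, reverse=True) or \
            all(confs[i] >= confs[i + 1] for i in range(len(confs) - 1))

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            classify_taxonomy("ACGT" * 30, TaxonomyReference({}, {}))
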