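"""Barcode designation, species clustering, naming, and the sex-ratio test."""

import numpy as np
import pytest
from scipy.stats import chi2

from darkamp.denoise import OtuMap, Zotu
from darkamp.hostbarcode import (assign_name, dereplicate_genotypes,
                                 p_distance, propose_species_clusters,
                                 select_barcode, sex_ratio_test)


def _rand_seq(rng, n=418):
    return "".join(rng.choice(list("ACGT"), n))


def _mutate(seq, k, rng):
    pos = rng.choice(len(seq), k, replace=False)
    s = list(seq)
    for p in pos:
        s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s)


@pytest.fixture()
def coi_setup():
    rng = np.random.default_rng(31)
    host = _rand_seq(rng)
    other = _rand_seq(rng)
    zotus = [Zotu("Z1", host, {"s1": 0}), Zotu("Z2", _mutate(host, 2, rng), {"s1": 0}),
             Zotu("Z3", other, {"s1": 0})]
    otu_map = OtuMap({"Otu1": ["Z1", "Z2"], "Otu2": ["Z3"]})
    is_arth = {"Z1": True, "Z2": True, "Z3": True}
    return zotus, otu_map, is_arth


class TestSelectBarcode:
    def _set(self, zotus, counts):
        for z in zotus:
            z.counts = {"s1": counts.get(z.zotu_id, 0)}

    def test_below_300_dominant_reads_fails(self, coi_setup):
        zotus, otu_map, is_arth = coi_setup
        self._set(zotus, {"Z1": 299})
        rec = select_barcode("s1", zotus, otu_map, is_arth)
        assert not rec.passed and rec.reject_reason == "low_reads"

    def test_inclusive_thresholds_pass(self, coi_setup):
        """300 reads and a ratio of exactly 0.95 both pass."""
        zotus, otu_map, is_arth = coi_setup
        self._set(zotus, {"Z1": 285, "Z2": 15, "Z3": 300 // 19})
        # dominant OTU = 300 reads; total arthropod = 300 + 15 -> adjust Z3
        self._set(zotus, {"Z1": 285, "Z2": 15})
        rec = select_barcode("s1", zotus, otu_map, is_arth)
        assert rec.passed and rec.dominant_otu_reads == 300

    def test_ratio_below_95_fails(self, coi_setup):
        zotus, otu_map, is_arth = coi_setup
        self._set(zotus, {"Z1": 400, "Z3": 30})  # ratio 400/430 < 0.95
        rec = select_barcode("s1", zotus, otu_map, is_arth)
        assert not rec.passed and rec.reject_reason == "low_ratio"

    def test_barcode_is_most_abundant_zotu_of_dominant_otu(self, coi_setup):
        zotus, otu_map, is_arth = coi_setup
        self._set(zotus, {"Z1": 120 * 3, "Z2": 80 * 3})
        rec = select_barcode("s1", zotus, otu_map, is_arth)
        assert rec.passed and rec.barcode_seq == zotus[0].centroid_seq

    def test_no_arthropod_reads(self, coi_setup):
        zotus, otu_map, _ = coi_setup
        self._set(zotus, {"Z1": 500})
        rec = select_barcode("s1", zotus, otu_map, {z.zotu_id: False for z in zotus})
        assert not rec.passed and rec.reject_reason == "no_barcode"


class TestGenotypesAndClusters:
    def test_exact_dereplication(self):
        from darkamp.hostbarcode import BarcodeRecord

        recs = [BarcodeRecord(f"s{i}", "AAAA", 400, 1.0, True) for i in range(3)]
        recs += [BarcodeRecord("s9", "CCCC", 400, 1.0, True)]
        recs += [BarcodeRecord("s10", "GGGG", 100, 1.0, False, "low_reads")]
        geno = dereplicate_genotypes(recs)
        assert len(geno) == 2
        # numbering follows descending abundance
        assert set(geno["G0001"]) == {"s0", "s1", "s2"}

    def test_planted_species_recovered_exactly(self):
        """10 species at >=5% divergence, <=1% within, recovered exactly."""
        rng = np.random.default_rng(33)
        genotype_seqs, truth = {}, {}
        for sp in range(10):
            ancestor = _rand_seq(rng)
            for g in range(3):
                gid = f"sp{sp}_g{g}"
                genotype_seqs[gid] = ancestor if g == 0 else \
                    _mutate(ancestor, int(rng.integers(1, 5)), rng)
                truth[gid] = sp
        clusters = propose_species_clusters(genotype_seqs)
        planted = {}
        for gid, sp in truth.items():
            planted.setdefault(sp, set()).add(gid)
        got = {}
        for gid, (cl, amb) in clusters.items():
            got.setdefault(cl, set()).add(gid)
            assert not amb
        assert {frozenset(v) for v in got.values()} == \
            {frozenset(v) for v in planted.values()}

    def test_cluster_with_two_named_references_flagged_ambiguous(self):
        rng = np.random.default_rng(34)
        seq = _rand_seq(rng)
        genotype_seqs = {"g1": seq}
        refs = {"refA": _mutate(seq, 4, rng), "refB": _mutate(seq, 5, rng)}
        ref_species = {"refA": "Megaselia alpha", "refB": "Megaselia beta"}
        clusters = propose_species_clusters(genotype_seqs, refs, ref_species)
        assert clusters["g1"][1] is True

    def test_p_distance_ignores_n(self):
        a = "ACGT" * 10
        b = "ACGA" + "ACGT" * 9  # one difference
        assert p_distance(a, b) == pytest.approx(1 / 40)
        masked = "N" + a[1:]  # N site dropped from the comparison
        assert p_distance(masked, a) == 0.0
        # excessive N overlap: pair excluded (NaN)
        assert np.isnan(p_distance("N" * 40, a))


class TestAssignName:
    def test_species_at_99_percent(self):
        rng = np.random.default_rng(35)
        ref = _rand_seq(rng)
        query = _mutate(ref, 4, rng)  # 99%
        name, level, ident = assign_name(query, {"r1": ref},
                                         {"r1": "Megaselia alpha"})
        assert (name, level) == ("Megaselia alpha", "species")
        assert ident >= 0.97

    def test_genus_fallback_below_97(self):
        rng = np.random.default_rng(36)
        ref = _rand_seq(rng)
        query = _mutate(ref, 21, rng)  # 95%
        name, level, _ = assign_name(query, {"r1": ref}, {"r1": "Megaselia alpha"},
                                     classifier_lineage={"genus": "Megaselia"})
        assert (name, level) == ("Megaselia", "genus")

    def test_matches_nearest_neighbor_oracle(self):
        rng = np.random.default_rng(37)
        refs = {f"r{i}": _rand_seq(rng) for i in range(5)}
        species = {k: f"sp_{k}" for k in refs}
        for trial in range(6):
            base = refs[f"r{trial % 5}"]
            query = _mutate(base, int(rng.integers(0, 30)), rng)
            name, level, ident = assign_name(query, refs, species)
            # oracle: exhaustive hamming identity to every reference
            def ham_ident(a, b):
                return np.mean([x == y for x, y in zip(a, b)])
            best = max(refs, key=lambda r: ham_ident(query, refs[r]))
            best_ident = ham_ident(query, refs[best])
            if best_ident >= 0.97:
                assert name == species[best]
            else:
                assert level != "species"


class TestSexRatio:
    @pytest.mark.parametrize("f,m,stat,p", [
        (50, 50, 0.0, 1.0),
        (88, 44, 14.666666, 1.28295e-4),
        (60, 40, 4.0, 0.04550),
    ])
    def test_examples(self, f, m, stat, p):
        got_stat, got_p = sex_ratio_test(f, m)
        assert got_stat == pytest.approx(stat, rel=1e-4)
        assert got_p == pytest.approx(p, rel=1e-3)

    def test_matches_chi2_tail_oracle(self):
        stat, p = sex_ratio_test(70, 30)
        assert p == pytest.approx(float(chi2.sf(stat, 1)))

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            sex_ratio_test(0, 0)
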