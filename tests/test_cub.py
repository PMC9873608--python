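import math

import numpy as np
import pandas as pd
import pytest

from metacodon.cub import (
    build_reference_set,
    cai_gene,
    codon_weights,
    dcbs_gene,
    enc_sample,
    positional_nt_freqs,
    sample_cub_summary,
)
from metacodon.profiles import FrequencyProfile, abs_cufs
from metacodon.seqcore import (
    CdsCollection,
    CdsRecord,
    CodonCountTable,
    count_codons,
    standard_code,
)

CODE = standard_code()


def _poly(codon, n):
    return codon * n


class TestReferenceSet:
    def _collection(self, n):
        return CdsCollection("s", [CdsRecord(f"g{i:03d}", "ATGTAA")
                                   for i in range(n)])

    def test_top_five_percent_of_hundred(self):
        coll = self._collection(100)
        ab = {f"g{i:03d}": i + 1 for i in range(100)}
        ref = build_reference_set(coll, ab, 0.05)
        assert sorted(ref.member_ids) == [f"g{i:03d}" for i in range(95, 100)]

    def test_full_fraction_takes_all(self):
        coll = self._collection(10)
        ref = build_reference_set(coll, {f"g{i:03d}": i for i in range(10)}, 1.0)
        assert len(ref.member_ids) == 10

    def test_ceiling_convention(self):
        coll = self._collection(10)
        ref = build_reference_set(coll, {f"g{i:03d}": i for i in range(10)}, 0.05)
        assert ref.member_ids == ("g009",)

    def test_missing_abundances_reported(self):
        coll = self._collection(3)
        with pytest.raises(KeyError, match="g002"):
            build_reference_set(coll, {"g000": 1, "g001": 2}, 0.5)


class TestCodonWeights:
    def test_pseudocount_arithmetic(self):
        ref = build_reference_set(
            CdsCollection("s", [CdsRecord("g", _poly("TTT", 30) + _poly("TTC", 10))]),
            {"g": 1.0}, 1.0)
        w = codon_weights(ref)
        assert w.w["TTT"] == pytest.approx(1.0)
        assert w.w["TTC"] == pytest.approx(10.5 / 30.5)

    def test_absent_family_gets_unit_weights(self):
        ref = build_reference_set(
            CdsCollection("s", [CdsRecord("g", "ATGATG")]), {"g": 1.0}, 1.0)
        w = codon_weights(ref)
        assert w.w["TTT"] == 1.0 and w.w["TTC"] == 1.0

    def test_family_maximum_is_one(self, rng):
        from conftest import random_cds
        coll = CdsCollection("s", [CdsRecord("g", random_cds(rng, 500))])
        w = codon_weights(build_reference_set(coll, {"g": 1.0}, 1.0))
        for _aa, codons in CODE.families.items():
            assert max(w.w[c] for c in codons) == pytest.approx(1.0)


class TestCai:
    def _weights(self):
        ref = build_reference_set(
            CdsCollection("s", [CdsRecord("g", _poly("TTT", 30) + _poly("TTC", 10))]),
            {"g": 1.0}, 1.0)
        return codon_weights(ref)

    def test_family_maximal_gene_scores_one(self):
        w = self._weights()
        assert cai_gene(_poly("TTT", 7), w) == pytest.approx(1.0)

    def test_geometric_mean_identity(self):
        w = self._weights()
        w.w["TTC"] = 0.5
        assert cai_gene(_poly("TTC", 11), w) == pytest.approx(0.5)

    def test_two_codon_arithmetic(self):
        w = self._weights()
        w.w["TTT"], w.w["TTC"] = 1.0, 0.25
        assert cai_gene("TTTTTC", w) == pytest.approx(0.5)  # sqrt(1 * 0.25)

    def test_stop_and_n_codons_excluded(self):
        w = self._weights()
        assert cai_gene("TTTNNTTAA", w) == pytest.approx(1.0)

    def test_no_countable_codons_is_error(self):
        with pytest.raises(ValueError):
            cai_gene("TAA", self._weights())


class TestEnc:
    def test_uniform_usage_attains_maximum(self):
        assert enc_sample(CodonCountTable(np.full(61, 100), CODE)) == 61.0

    def test_one_codon_per_family_attains_minimum(self):
        counts = {codons[0]: 100 for codons in CODE.families.values()}
        assert enc_sample(CodonCountTable(counts, CODE)) == 20.0

    def test_wright_estimator_arithmetic(self):
        # single two-fold family with counts (30, 10):
        # F = (40*(0.75^2+0.25^2)-1)/39
        f_hat = (40 * (0.75 ** 2 + 0.25 ** 2) - 1) / 39
        counts = {codons[0]: 30 if len(codons) == 2 else 100
                  for codons in CODE.families.values()}
        for codons in CODE.families.values():
            if len(codons) == 2:
                counts[codons[1]] = 10
            elif len(codons) > 2:
                counts[codons[0]] = 100  # single codon used: F=1
        enc = enc_sample(CodonCountTable(counts, CODE), cap=False)
        expected = 2 + 9 / f_hat + 1 / 1 + 5 / 1 + 3 / 1
        assert enc == pytest.approx(expected)

    def test_missing_threefold_class_imputed(self):
        # no isoleucine at all: F3 = (F2+F4)/2, here F2=F4=1
        counts = {}
        for aa, codons in CODE.families.items():
            if aa == "I":
                continue
            counts[codons[0]] = 50
        enc = enc_sample(CodonCountTable(counts, CODE))
        assert enc == pytest.approx(20.0)

    def test_concentration_never_increases_enc(self, rng):
        # moving counts from a minor codon onto the family's major codon
        # concentrates usage and must not raise ENC
        base = rng.integers(20, 80, 61)
        counts = CodonCountTable(base, CODE)
        enc0 = enc_sample(counts, cap=False)
        s = counts.as_series()
        for codons in CODE.families.values():
            if len(codons) < 2:
                continue
            fam = s[list(codons)]
            s[fam.idxmax()] += s[fam.idxmin()]
            s[fam.idxmin()] = 0
        enc1 = enc_sample(CodonCountTable(s.to_dict(), CODE), cap=False)
        assert enc1 <= enc0 + 1e-9

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            enc_sample(CodonCountTable(np.zeros(61, dtype=int), CODE))


def _nnt_counts():
    """One count for each of the 16 codons of the form N N T (all are sense)."""
    codons = {a + b + "T": 1 for a in "ACGT" for b in "ACGT"}
    return CodonCountTable(codons, CODE)


class TestPositionalFreqs:
    def test_nnt_construction(self):
        pos = positional_nt_freqs(_nnt_counts())
        assert np.allclose(pos.f1, 0.25) and np.allclose(pos.f2, 0.25)
        assert pos.f3[3] == pytest.approx(1.0)  # T

    def test_all_atg(self):
        pos = positional_nt_freqs(CodonCountTable({"ATG": 9}, CODE))
        assert pos.f1[0] == 1.0 and pos.f2[3] == 1.0 and pos.f3[2] == 1.0

    def test_uniform_sense_codons_show_stop_exclusion_asymmetry(self):
        pos = positional_nt_freqs(CodonCountTable(np.ones(61, dtype=int), CODE))
        # 16 codons end in A minus stops TAA, TGA
        assert pos.f3[0] == pytest.approx(14 / 61)
        # 16 end in G minus stop TAG
        assert pos.f3[2] == pytest.approx(15 / 61)


class TestDcbs:
    def test_independent_construction_gives_zero(self):
        counts = _nnt_counts()
        cufs = abs_cufs(counts)
        pos = positional_nt_freqs(counts)
        assert dcbs_gene("ACTGCT", cufs, pos) == pytest.approx(0.0, abs=1e-12)

    def test_doubled_frequency_gives_one(self):
        counts = _nnt_counts()
        pos = positional_nt_freqs(counts)
        cufs = abs_cufs(counts)
        cufs.values["ACT"] = 2 / 16  # f = 2 * f1 f2 f3
        assert dcbs_gene("ACT", cufs, pos) == pytest.approx(1.0)

    def test_hand_summed_toy(self):
        counts = _nnt_counts()
        pos = positional_nt_freqs(counts)
        cufs = abs_cufs(counts)
        cufs.values["ACT"] = 0.10
        cufs.values["GGT"] = 0.02
        d_act = 0.10 / (1 / 16) - 1
        d_ggt = 0.02 / (1 / 16) - 1
        expected = (2 * d_act + d_ggt) / 3
        assert dcbs_gene("ACTGGTACT", cufs, pos) == pytest.approx(expected)

    def test_geometric_variant(self):
        counts = _nnt_counts()
        pos = positional_nt_freqs(counts)
        cufs = abs_cufs(counts)
        cufs.values["ACT"] = 0.10
        cufs.values["GGT"] = 0.02
        ratios = [0.10 * 16, 0.02 * 16]
        expected = math.exp(np.mean(np.log(ratios))) - 1
        assert dcbs_gene("ACTGGT", cufs, pos, geometric=True) == pytest.approx(expected)


class TestSampleSummary:
    def _collection(self, rng, n=10):
        from conftest import random_cds
        return CdsCollection("s", [CdsRecord(f"g{i}", random_cds(rng, 60))
                                   for i in range(n)])

    def test_single_gene_sample(self, rng):
        coll = CdsCollection("s", [self._collection(rng).records[0]])
        scores = sample_cub_summary(coll, {coll.records[0].gene_id: 1.0})
        assert scores.mean_cai == pytest.approx(
            list(scores.cai.values())[0])

    def test_duplication_invariance(self, rng):
        # CAI and DCBS are exactly invariant under duplicating every gene
        # (CAI once the non-scale-invariant reference pseudocount is off);
        # ENC carries Wright's finite-sample correction, so doubling the
        # counts moves it only by O(1/n)
        from conftest import random_cds
        coll = CdsCollection("s", [CdsRecord(f"g{i}", random_cds(rng, 150))
                                   for i in range(40)])
        ab = {r.gene_id: float(i + 1) for i, r in enumerate(coll.records)}
        dup_records = coll.records + [CdsRecord(r.gene_id + "_copy", r.sequence)
                                      for r in coll.records]
        dup = CdsCollection("s2", dup_records)
        dup_ab = {**ab, **{k + "_copy": v for k, v in ab.items()}}
        s1 = sample_cub_summary(coll, ab, top_frac=1.0, pseudocount=0.0,
                                enc_cap=False)
        s2 = sample_cub_summary(dup, dup_ab, top_frac=1.0, pseudocount=0.0,
                                enc_cap=False)
        assert s2.mean_cai == pytest.approx(s1.mean_cai)
        assert s2.mean_dcbs == pytest.approx(s1.mean_dcbs)
        # near the uniform end ENC amplifies the O(1/n) correction by the
        # squared class degeneracy, so allow a wider (still sub-codon) band
        assert s2.enc == pytest.approx(s1.enc, abs=0.5)

    def test_gene_order_invariance(self, rng):
        coll = self._collection(rng, 8)
        ab = {r.gene_id: float(i + 1) for i, r in enumerate(coll.records)}
        rev = CdsCollection("s", list(reversed(coll.records)))
        s1 = sample_cub_summary(coll, ab)
        s2 = sample_cub_summary(rev, ab)
        assert (s1.mean_cai, s1.enc, s1.mean_dcbs) == pytest.approx(
            (s2.mean_cai, s2.enc, s2.mean_dcbs))

    def test_per_gene_scores_match_recomputation(self, rng):
        coll = self._collection(rng, 10)
        ab = {r.gene_id: float(i + 1) for i, r in enumerate(coll.records)}
        scores = sample_cub_summary(coll, ab, top_frac=0.2)
        ref = build_reference_set(coll, ab, 0.2)
        w = codon_weights(ref)
        counts = count_codons(coll)
        cufs = abs_cufs(counts)
        pos = positional_nt_freqs(counts)
        for rec in coll.records:
            assert scores.cai[rec.gene_id] == pytest.approx(
                cai_gene(rec.sequence, w), abs=1e-12)
            assert scores.dcbs[rec.gene_id] == pytest.approx(
                dcbs_gene(rec.sequence, cufs, pos), abs=1e-12)
        assert scores.mean_cai == pytest.approx(np.mean(list(scores.cai.values())))
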