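import numpy as np
import pytest

from piscape.comparative import (align_pair, all_vs_all_hits, compare_pair,
                                 compute_aai, compute_pocp,
                                 core_flexible_partition,
                                 reciprocal_best_hits)
from piscape.localization import LocalizationCall
from piscape.sequence_io import ProteinRecord
from piscape.synthetic import SyntheticSpec, generate_pair, generate_proteome

from conftest import random_protein


def truth_localizations(truth):
    return {row.protein_id: LocalizationCall(
        row.protein_id, row.category, "imported",
        int(row.n_tm_planted), row.category == "secreted")
        for row in truth.itertuples(index=False)}


@pytest.fixture(scope="module")
def small_proteome():
    rng = np.random.default_rng(9)
    records, _ = generate_proteome(SyntheticSpec(n_proteins=30, seed=9))
    return records


class TestAlignment:
    def test_single_substitution_in_100_gives_99_percent(self, rng):
        a = random_protein(rng, 100)
        pos = 50
        repl = "W" if a[pos] != "W" else "Y"
        b = a[:pos] + repl + a[pos + 1:]
        pident, coverage, _ = align_pair(a, b)
        assert pident == pytest.approx(99.0, abs=0.5)
        assert coverage == pytest.approx(1.0, abs=0.02)

    def test_score_matches_biotite_reference(self, rng):
        """Affine-gap SW scores agree with an independent DP implementation."""
        import biotite.sequence as bseq
        import biotite.sequence.align as balign

        matrix = balign.SubstitutionMatrix.std_protein_matrix()
        for _ in range(30):
            a = random_protein(rng, int(rng.integers(40, 120)))
            b = random_protein(rng, int(rng.integers(40, 120)))
            _, _, ours = align_pair(a, b)
            ref = balign.align_optimal(
                bseq.ProteinSequence(a), bseq.ProteinSequence(b), matrix,
                gap_penalty=(-11, -1), local=True, max_number=1)[0]
            assert ours == pytest.approx(ref.score, abs=1e-9)


class TestAllVsAll:
    def test_identical_proteomes_hit_themselves_perfectly(self, small_proteome):
        hits = all_vs_all_hits(small_proteome, small_proteome)
        best = {}
        for h in hits:
            if h.query_id not in best or h.score > best[h.query_id].score:
                best[h.query_id] = h
        for rec in small_proteome:
            h = best[rec.protein_id]
            assert h.subject_id == rec.protein_id
            assert h.percent_identity == 100.0
            assert h.alignable_fraction_of_query == pytest.approx(1.0)

    def test_disjoint_short_random_sequences_yield_no_hits(self, rng):
        a = [ProteinRecord(f"a{i}", "A", random_protein(rng, 50))
             for i in range(10)]
        b = [ProteinRecord(f"b{i}", "B", random_protein(rng, 50))
             for i in range(10)]
        hits = all_vs_all_hits(a, b)
        # the 5-mer prefilter leaves essentially nothing at this length
        assert len(hits) == 0


class TestAaiPocp:
    def test_self_comparison_is_100(self, small_proteome):
        hits = all_vs_all_hits(small_proteome, small_proteome)
        aai, n_rbh = compute_aai(hits, hits)
        assert aai == pytest.approx(100.0)
        assert n_rbh == len(small_proteome)
        assert compute_pocp(hits, hits, len(small_proteome),
                            len(small_proteome)) == pytest.approx(100.0)

    def test_empty_hit_lists_give_nan(self):
        aai, n_rbh = compute_aai([], [])
        assert np.isnan(aai)
        assert n_rbh == 0

    def test_pocp_toy_counts(self):
        from piscape.comparative import AlignmentHit

        def hit(q, s):
            return AlignmentHit(q, s, 80.0, 0.9, 500.0, 1e-30)

        hits_ab = [hit("a1", "b1"), hit("a2", "b2")]
        hits_ba = [hit("b1", "a1"), hit("b2", "a2")]
        assert compute_pocp(hits_ab, hits_ba, 3, 3) == pytest.approx(400 / 6)

    def test_aai_tracks_mutation_rate(self):
        """AAI within 2 points of 100*(1-r) on a rate-r synthetic pair."""
        spec = SyntheticSpec(n_proteins=100, seed=17, acid_shift_delta=1.0,
                             basic_shift_delta=1.0, mutation_rate=0.2,
                             proteome_id="mutpair")
        a, b, _ = generate_pair(spec, n_shared=60, n_unique_each=10)
        hits_ab = all_vs_all_hits(a, b)
        hits_ba = all_vs_all_hits(b, a)
        aai, n_rbh = compute_aai(hits_ab, hits_ba)
        assert n_rbh >= 55
        assert abs(aai - 80.0) <= 2.0

    def test_aai_symmetric_in_argument_order(self, small_proteome):
        spec = SyntheticSpec(n_proteins=40, seed=23, mutation_rate=0.1,
                             proteome_id="sym")
        a, b, _ = generate_pair(spec, n_shared=25, n_unique_each=5)
        ab = all_vs_all_hits(a, b)
        ba = all_vs_all_hits(b, a)
        assert compute_aai(ab, ba)[0] == pytest.approx(
            compute_aai(ba, ab)[0], abs=1e-9)


class TestCoreFlexible:
    def test_identical_proteomes_all_core(self, small_proteome):
        hits = all_vs_all_hits(small_proteome, small_proteome)
        rbh = reciprocal_best_hits(hits, hits)
        core_a, flex_a, core_b, flex_b = core_flexible_partition(
            rbh, small_proteome, small_proteome)
        assert len(core_a) == len(small_proteome)
        assert flex_a == () and flex_b == ()

    def test_partition_recovers_planted_split(self):
        spec = SyntheticSpec(n_proteins=100, seed=29, mutation_rate=0.2,
                             proteome_id="split")
        a, b, truth = generate_pair(spec, n_shared=50, n_unique_each=15)
        hits_ab = all_vs_all_hits(a, b)
        hits_ba = all_vs_all_hits(b, a)
        rbh = reciprocal_best_hits(hits_ab, hits_ba)
        core_a, flex_a, core_b, flex_b = core_flexible_partition(rbh, a, b)
        planted_a = set(truth[truth.proteome_id == a[0].proteome_id]
                        .dropna(subset=["ortholog"]).protein_id)
        planted_b = set(truth[truth.proteome_id == b[0].proteome_id]
                        .dropna(subset=["ortholog"]).protein_id)
        assert set(core_a) == planted_a
        assert set(core_b) == planted_b
        # partition property: core + flexible tile each proteome
        assert set(core_a) | set(flex_a) == {r.protein_id for r in a}
        assert set(core_a) & set(flex_a) == set()


class TestComparePair:
    def test_identical_proteomes_have_zero_deltas(self, small_proteome):
        copy = [ProteinRecord(r.protein_id + "_c", "copy", r.sequence)
                for r in small_proteome]
        locs = {}
        for rec in list(small_proteome) + copy:
            locs[rec.protein_id] = LocalizationCall(
                rec.protein_id, "cytoplasmic", "imported", 0, False)
        cmp = compare_pair(small_proteome, copy, locs)
        assert cmp.aai == pytest.approx(100.0)
        assert cmp.pocp == pytest.approx(100.0)
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in cmp.composition_delta.values())
        a, b = cmp.id_a, cmp.id_b
        assert cmp.per_category_spectra[a]["whole"].rel_freq == pytest.approx(
            cmp.per_category_spectra[b]["whole"].rel_freq)

    def test_marine_freshwater_pair_direction(self):
        """Marine side is more acidic in whole, core and flexible subsets."""
        from piscape.spectrum import acid_neutral_basic

        spec = SyntheticSpec(n_proteins=100, seed=41, acid_shift_delta=1.0,
                             basic_shift_delta=1.0, mutation_rate=0.2,
                             proteome_id="dir")
        a, b, truth = generate_pair(spec, n_shared=80, n_unique_each=20)
        cmp = compare_pair(a, b, truth_localizations(truth))
        marine, fresh = cmp.id_a, cmp.id_b
        assert cmp.higher_acid_fraction == marine
        for subset in ("core", "flexible"):
            assert (acid_neutral_basic(cmp.partition_spectra[marine][subset])
                    .acid_fraction >
                    acid_neutral_basic(cmp.partition_spectra[fresh][subset])
                    .acid_fraction)
        assert cmp.mean_pi[marine]["whole"] < cmp.mean_pi[fresh]["whole"]

    def test_secreted_extra_shift_orders_category_deltas(self):
        """|d mean pI| sharpest for secreted, then cytoplasmic, then TM.

        Measured as the signed per-category difference in mean pI pooled
        over several seeded pairs (pooling beats the large per-protein pI
        variance); ground-truth categories avoid heuristic noise.
        """
        from piscape.pi_engine import isoelectric_points

        deltas = {"secreted": [], "cytoplasmic": [], "transmembrane": []}
        for seed in range(8):
            spec = SyntheticSpec(n_proteins=1, seed=600 + seed,
                                 acid_shift_delta=1.0, basic_shift_delta=1.0,
                                 secreted_extra_delta=1.0, mutation_rate=0.2,
                                 frac_secreted=0.2, frac_tm=0.2,
                                 proteome_id="ord")
            a, b, truth = generate_pair(spec, n_shared=400, n_unique_each=100)
            pi_a = dict(zip((r.protein_id for r in a),
                            isoelectric_points([r.sequence for r in a])))
            pi_b = dict(zip((r.protein_id for r in b),
                            isoelectric_points([r.sequence for r in b])))
            cat_of = dict(zip(truth.protein_id, truth.category))
            for cat in deltas:
                mean_a = np.mean([pi_a[r.protein_id] for r in a
                                  if cat_of[r.protein_id] == cat])
                mean_b = np.mean([pi_b[r.protein_id] for r in b
                                  if cat_of[r.protein_id] == cat])
                deltas[cat].append(mean_a - mean_b)
        mean = {cat: abs(np.mean(v)) for cat, v in deltas.items()}
        assert mean["secreted"] > mean["cytoplasmic"] > mean["transmembrane"]
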