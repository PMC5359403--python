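"""The synthetic-genome generator: profiles, convergence, determinism."""

import numpy as np
import pytest

from codonclust import synthetic_data as sd
from codonclust.codon_metrics import count_codons, gc3, rscu, scuo
from codonclust.genetics import AA_TO_CODONS, DEGENERATE_AAS
from codonclust.pipeline import genome_metrics
from codonclust.seqio import coding_sequences, read_genbank


class TestProfiles:
    def test_uniform_profile_is_simplex(self):
        prof = sd.uniform_profile()
        for aa in DEGENERATE_AAS:
            assert prof.probs[aa].sum() == pytest.approx(1.0)
            assert np.allclose(prof.probs[aa], 1.0 / len(AA_TO_CODONS[aa]))

    def test_invalid_simplex_rejected(self):
        probs = sd.uniform_profile().probs
        probs["K"] = np.array([0.9, 0.2])
        with pytest.raises(ValueError):
            sd.CodonProfile(probs)

    def test_mix_profiles_endpoints(self, rng):
        a = sd.uniform_profile()
        b = sd.random_profile(rng)
        assert sd.profile_tv_distance(sd.mix_profiles(a, b, 0.0), a) < 1e-12
        assert sd.profile_tv_distance(sd.mix_profiles(a, b, 1.0), b) < 1e-12


class TestSampleProfile:
    def test_high_concentration_returns_base(self, rng):
        base = sd.random_profile(rng, alpha=1.0)
        drawn = sd.sample_profile(base, 1e6, rng)
        assert sd.profile_tv_distance(drawn, base) < 1e-2

    def test_dirichlet_mean_matches_base(self, rng):
        """Monte-Carlo mean of flat-prior draws is the uniform base."""
        base = sd.uniform_profile()
        draws = [sd.sample_profile(base, 2.0, rng) for _ in range(3000)]
        mean_k = np.mean([d.probs["K"] for d in draws], axis=0)
        assert np.allclose(mean_k, base.probs["K"], atol=0.02)

    def test_fixed_seed_reproducible(self):
        base = sd.uniform_profile()
        a = sd.sample_profile(base, 10.0, np.random.default_rng(3))
        b = sd.sample_profile(base, 10.0, np.random.default_rng(3))
        assert sd.profile_tv_distance(a, b) == 0.0

    def test_nonpositive_concentration_rejected(self, rng):
        with pytest.raises(ValueError):
            sd.sample_profile(sd.uniform_profile(), 0.0, rng)


class TestGenerateGenome:
    def test_uniform_profile_gives_rscu_near_one(self, rng):
        rec = sd.generate_genome(
            sd.uniform_profile(), 60, [300] * 60, 0, rng, genome_id="U"
        )
        table = count_codons(coding_sequences(rec), source_id="U")
        assert table.n_codons >= 15000
        vec = rscu(table)
        defined = ~vec.undefined_mask
        assert np.abs(vec.values[defined] - 1.0).max() < 0.35
        assert np.abs(vec.values[defined] - 1.0).mean() < 0.1

    def test_concentrated_profile_gives_scuo_near_one(self, rng):
        prof = sd.concentrated_profile(rng)
        rec = sd.generate_genome(prof, 30, [150] * 30, 0, rng, genome_id="C")
        table = count_codons(coding_sequences(rec), source_id="C")
        assert scuo(table).scuo == pytest.approx(1.0)

    def test_trna_roundtrip_through_genbank(self, rng, tmp_path):
        rec = sd.generate_genome(
            sd.uniform_profile(), 5, [60] * 5, 5, rng, genome_id="T"
        )
        sd.write_genbank([rec], tmp_path / "t.gb")
        back = read_genbank(tmp_path / "t.gb")[0]
        assert back.trna_count == 5
        assert len(back.cds_regions) == 5
        assert back.sequence == rec.sequence

    def test_empirical_frequencies_converge_to_profile(self, rng):
        """TV distance to the generating profile < 0.02 at ~10^5 codons."""
        prof = sd.random_profile(rng, alpha=2.0)
        rec = sd.generate_genome(prof, 100, [1000] * 100, 0, rng, genome_id="big")
        table = count_codons(coding_sequences(rec), source_id="big")
        emp = sd.empirical_profile(table.counts)
        assert sd.profile_tv_distance(emp, prof, weights=sd.AA_COMPOSITION) < 0.02

    def test_gc3_monotone_in_gc_ending_weight(self, rng):
        gc3_values = []
        for w in [0.2, 0.4, 0.6, 0.8]:
            prof = sd.gc3_biased_profile(w)
            rec = sd.generate_genome(prof, 30, [200] * 30, 0, rng, genome_id="g")
            gc3_values.append(gc3(coding_sequences(rec)))
        assert all(b > a for a, b in zip(gc3_values, gc3_values[1:]))

    def test_short_gene_rejected(self, rng):
        with pytest.raises(ValueError, match="2 codons"):
            sd.generate_genome(sd.uniform_profile(), 1, [1], 0, rng)


class TestGenerateCohort:
    def test_same_seed_byte_identical_genbank(self, tmp_path, rng):
        profiles = sd.separated_regime_profiles(2, 1.0, rng)
        regimes = [
            sd.RegimeSpec(label=p.label, profile=p, n_genomes=2, n_genes=10,
                          gene_length_mean=60, gene_length_sd=10)
            for p in profiles
        ]
        spec = sd.CohortSpec(regimes=regimes, seed=5)
        for sub in ("a", "b"):
            (tmp_path / sub).mkdir()
            records, _ = sd.generate_cohort(spec)
            sd.write_genbank(records, tmp_path / sub / "c.gb")
        assert (tmp_path / "a/c.gb").read_bytes() == (tmp_path / "b/c.gb").read_bytes()

    def test_truth_table_matches_records(self, small_cohort):
        records, truth = small_cohort
        assert {r.id for r in records} == set(truth)
        assert len(set(truth.values())) == 3
        for rec in records:
            assert rec.cluster_label == truth[rec.id]

    def test_single_regime_tighter_than_separated_regimes(self, rng):
        """All pairwise d within one regime sit below between-regime d."""
        from codonclust.clustering import distance_matrix

        def pairwise_d(records):
            vectors = [genome_metrics(r)[1] for r in records]
            dm = distance_matrix(vectors)
            return dm

        prof = sd.random_profile(rng, alpha=0.5, label="solo")
        one = sd.CohortSpec(
            regimes=[sd.RegimeSpec(label="solo", profile=prof, n_genomes=6,
                                   n_genes=25, gene_length_mean=90,
                                   gene_length_sd=20)],
            seed=2,
        )
        recs1, _ = sd.generate_cohort(one)
        within = pairwise_d(recs1)
        iu = np.triu_indices(len(recs1), k=1)
        max_within = within.d[iu].max()

        profiles = sd.separated_regime_profiles(2, 1.0, rng)
        two = sd.CohortSpec(
            regimes=[
                sd.RegimeSpec(label=p.label, profile=p, n_genomes=3, n_genes=25,
                              gene_length_mean=90, gene_length_sd=20)
                for p in profiles
            ],
            seed=2,
        )
        recs2, truth2 = sd.generate_cohort(two)
        between = pairwise_d(recs2)
        cross = [
            between.d[i, j]
            for i in range(len(recs2))
            for j in range(i + 1, len(recs2))
            if truth2[recs2[i].id] != truth2[recs2[j].id]
        ]
        assert max_within < min(cross)

    def test_genome_ids_stable_across_generation_order(self):
        """Counter-derived substreams: genome i is identical regardless of
        how many genomes precede it in other regimes."""
        prof = sd.uniform_profile("u")
        spec1 = sd.CohortSpec(
            regimes=[sd.RegimeSpec(label="u", profile=prof, n_genomes=2,
                                   n_genes=5, gene_length_mean=40,
                                   gene_length_sd=5)],
            seed=9,
        )
        recs_a, _ = sd.generate_cohort(spec1)
        recs_b, _ = sd.generate_cohort(spec1)
        assert recs_a[1].sequence == recs_b[1].sequence
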