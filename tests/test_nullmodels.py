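import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from songnet import nullmodels, seqnet, synthgen
from songnet.nullmodels import (
    EffectSize,
    cohens_d_one_vs_null,
    cohens_d_two_sample,
    freq_shift_effect,
    freq_shift_series,
    null_distribution,
    null_effects,
    pool_effect_sizes,
    recording_rng,
    shuffle_within_songs,
)
from songnet.song_data import recording_from_sequences

from .conftest import random_recording


class TestShuffle:
    def test_single_token_song_identity(self):
        rec = recording_from_sequences([["A"]])
        rng = np.random.default_rng(0)
        assert shuffle_within_songs(rec, rng) == rec

    @given(st.lists(st.lists(st.sampled_from("ABCD"), min_size=1, max_size=10),
                    min_size=1, max_size=5),
           st.integers(0, 2**30))
    def test_per_song_multisets_and_lengths_conserved(self, seqs, seed):
        rec = recording_from_sequences(seqs)
        shuf = shuffle_within_songs(rec, np.random.default_rng(seed))
        assert [len(s) for s in shuf.songs] == [len(s) for s in rec.songs]
        for orig, new in zip(rec.type_sequences(), shuf.type_sequences()):
            assert Counter(orig) == Counter(new)
        shuf.validate()  # shuffled recordings remain structurally valid

    def test_two_token_song_uniform(self):
        rec = recording_from_sequences([["A", "B"]])
        rng = np.random.default_rng(1234)
        ba = sum(
            shuffle_within_songs(rec, rng).type_sequences()[0] == ["B", "A"]
            for _ in range(10_000)
        )
        # binomial(10000, .5): 3 SD band
        assert abs(ba / 10_000 - 0.5) < 3 * 0.005

    def test_acoustics_travel_with_tokens(self):
        rec = recording_from_sequences([["A", "B", "C"]],
                                       mean_freqs={"A": 2000, "B": 5000, "C": 8000})
        shuf = shuffle_within_songs(rec, np.random.default_rng(5))
        by_type = {t.type_id: t.mean_freq for t in shuf.songs[0]}
        assert by_type == {"A": 2000, "B": 5000, "C": 8000}

    def test_reproducible_given_seed(self):
        rec = random_recording(np.random.default_rng(8))
        a = shuffle_within_songs(rec, recording_rng(5, rec.recording_id))
        b = shuffle_within_songs(rec, recording_rng(5, rec.recording_id))
        assert a == b


class TestCohensD:
    def test_one_vs_null_hand_values(self):
        d, var_d = cohens_d_one_vs_null(4.0, [1, 2, 3])
        assert d == pytest.approx(2.0)
        # (1+3)/3 + 4/(2*4) with n1=1, n2=3
        assert var_d == pytest.approx(4 / 3 + 0.5)
        d0, _ = cohens_d_one_vs_null(2.0, [1, 2, 3])
        assert d0 == 0.0

    def test_zero_spread_null_undefined(self):
        d, v = cohens_d_one_vs_null(1.0, [2, 2, 2])
        assert math.isnan(d) and math.isnan(v)

    def test_two_sample_hand_value(self):
        d, var_d = cohens_d_two_sample([2, 4], [1, 3])
        assert d == pytest.approx(1 / math.sqrt(2))
        assert var_d == pytest.approx(4 / 4 + d * d / 8)
        assert cohens_d_two_sample([1, 2, 3], [1, 2, 3])[0] == 0.0


class TestNullDistribution:
    def test_deterministic_cycle_grammar_directions(self):
        # perfectly ordered songs: always the same cycle A->B->...->H->A
        seqs = [["A", "B", "C", "D", "E", "F", "G", "H"] * 2 for _ in range(10)]
        rec = recording_from_sequences(seqs)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            effs = {e.variable_name: e for e in null_effects(
                rec, ["average_degree", "average_shortest_path"], 50, rng)}
            assert effs["average_shortest_path"].d > 0
            assert effs["average_degree"].d < 0

    def test_identical_seed_identical_nulls(self):
        rec = random_recording(np.random.default_rng(2), n_songs=5)
        e1 = null_distribution(rec, "average_degree", 30, recording_rng(9, rec.recording_id))
        e2 = null_distribution(rec, "average_degree", 30, recording_rng(9, rec.recording_id))
        assert e1 == e2

    def test_exchangeable_recording_null_covers_zero(self):
        # iid uniform types: the observed value is itself a draw from the null
        rng = np.random.default_rng(77)
        effects = []
        for k in range(50):
            rec = random_recording(rng, n_songs=8, max_types=10, rec_id=f"r{k}")
            effects.append(
                null_distribution(rec, "average_degree", 60,
                                  np.random.default_rng(1000 + k))
            )
        meta = pool_effect_sizes(effects)
        assert meta.ci_low < 0 < meta.ci_high


class TestPooling:
    def test_equal_effects_return_common_value(self):
        es = [EffectSize(f"r{i}", "x", 0, 0, 1, 100, 0.5, 0.02) for i in range(3)]
        meta = pool_effect_sizes(es)
        assert meta.pooled_d == pytest.approx(0.5)
        assert meta.tau2 == 0.0
        assert meta.ci_low <= meta.pooled_d <= meta.ci_high

    def test_symmetric_pair_pools_to_midpoint(self):
        es = [EffectSize("a", "x", 0, 0, 1, 100, 0.0, 0.1),
              EffectSize("b", "x", 0, 0, 1, 100, 1.0, 0.1)]
        assert pool_effect_sizes(es).pooled_d == pytest.approx(0.5)

    def test_dersimonian_laird_hand_fixture(self):
        # frozen from an independent step-by-step DL calculation:
        # w=(25,25,6.25), mu_FE=0.366667, Q=2.5, C=33.3333, tau2=0.015,
        # w*=(18.1818,18.1818,5.7143), mu=0.381481, se=0.154160
        es = [EffectSize("a", "x", 0, 0, 1, 100, d, v)
              for d, v in [(0.2, 0.04), (0.4, 0.04), (0.9, 0.16)]]
        meta = pool_effect_sizes(es)
        assert meta.tau2 == pytest.approx(0.015, abs=1e-9)
        assert meta.pooled_d == pytest.approx(0.381481, abs=1e-5)
        assert meta.se == pytest.approx(0.154160, abs=1e-5)

    def test_fixed_effect_mode_and_errors(self):
        es = [EffectSize("a", "x", 0, 0, 1, 100, 0.2, 0.04),
              EffectSize("b", "x", 0, 0, 1, 100, 0.9, 0.16)]
        fe = pool_effect_sizes(es, method="FE")
        assert fe.tau2 == 0.0
        with pytest.raises(ValueError):
            pool_effect_sizes(es[:1])

    def test_undefined_effects_dropped_with_warning(self):
        es = [EffectSize("a", "x", 0, 0, 1, 100, 0.2, 0.04),
              EffectSize("b", "x", 0, 0, 1, 100, 0.4, 0.04),
              EffectSize("c", "x", 0, 0, 0, 100, float("nan"), float("nan"))]
        with pytest.warns(UserWarning):
            meta = pool_effect_sizes(es)
        assert meta.k_studies == 2


class TestFreqShift:
    def test_series_arithmetic(self):
        rec = recording_from_sequences([["A", "B", "C"]],
                                       mean_freqs={"A": 1000, "B": 3000, "C": 2000})
        assert list(freq_shift_series(rec)) == [2000.0, 1000.0]

    def test_one_token_songs_empty(self):
        rec = recording_from_sequences([["A"], ["B"]])
        assert freq_shift_series(rec).size == 0

    @given(st.lists(st.lists(st.sampled_from("ABC"), min_size=1, max_size=8),
                    min_size=1, max_size=4))
    def test_series_length_conserved(self, seqs):
        rec = recording_from_sequences(seqs)
        assert freq_shift_series(rec).size == sum(len(s) - 1 for s in seqs)

    def test_alternation_bias_gives_positive_pooled_d(self):
        cfg = synthgen.SimulationConfig(n_individuals=20, songs_per_recording=12,
                                        freq_alternation_weight=0.8, seed=10)
        pop = synthgen.simulate_population(cfg)
        effects = [freq_shift_effect(r, recording_rng(3, r.recording_id))
                   for r in pop.recordings]
        assert pool_effect_sizes(effects).pooled_d > 0
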