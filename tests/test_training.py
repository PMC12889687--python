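"""Masking plans, Fourier prior, loss assembly and the training loop."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motiflm.corpus import SequenceRecord, annotate_repeat_runs
from motiflm.nn import ALPHABET, ModelConfig
from motiflm.synth import SyntheticCorpusSpec, generate_corpus
from motiflm.training import (FourierPriorConfig, MaskingPlan, TrainingConfig,
                              build_masking_plan, combined_loss,
                              fourier_prior_loss, inband_fraction, mlm_loss,
                              reference_probability_profile, spectral_weights,
                              train_model, write_metric_log)


def make_record(seq):
    return SequenceRecord("s", 0, len(seq), seq,
                          repeat_runs=annotate_repeat_runs(seq, 30))


class TestMaskingPlan:
    def test_all_n_sequence_gives_empty_plan(self):
        plan = build_masking_plan(make_record("N" * 50), np.random.default_rng(0))
        assert len(plan) == 0

    def test_repeat_run_excluded(self):
        seq = "ACGT" * 20 + "acgt" * 10 + "ACGT" * 20
        run = annotate_repeat_runs(seq, 30)[0]
        rng = np.random.default_rng(1)
        for _ in range(200):
            plan = build_masking_plan(make_record(seq), rng)
            assert not np.any((plan.loss_positions >= run[0])
                              & (plan.loss_positions < run[1]))

    def test_short_lowercase_run_not_excluded(self):
        seq = "ACGT" * 20 + "acgt" * 5 + "ACGT" * 20  # 20 < 30: eligible
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(200):
            plan = build_masking_plan(make_record(seq), rng)
            hits += np.any((plan.loss_positions >= 80)
                           & (plan.loss_positions < 100))
        assert hits > 0

    def test_exclude_all_repeats_mode(self):
        seq = "ACGT" * 20 + "acgt" * 5 + "ACGT" * 20
        rng = np.random.default_rng(3)
        for _ in range(200):
            plan = build_masking_plan(make_record(seq), rng,
                                      exclude_all_repeats=True)
            assert not np.any((plan.loss_positions >= 80)
                              & (plan.loss_positions < 100))

    def test_selection_and_action_statistics(self):
        """10,000 seeded plans on clean 350-bp sequences: selection rate in
        [0.145, 0.155]; action fractions within 3 binomial SDs of
        0.8/0.1/0.1; masked inputs only differ at mask/mutate positions."""
        rng = np.random.default_rng(4)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 350)])
        rec = make_record(seq)
        n_sel, acts = 0, np.zeros(3)
        n_plans = 10_000
        for _ in range(n_plans):
            plan = build_masking_plan(rec, rng)
            n_sel += len(plan)
            for a in range(3):
                acts[a] += (plan.actions == a).sum()
        frac = n_sel / (n_plans * 350)
        assert 0.145 < frac < 0.155
        for a, p in enumerate((0.8, 0.1, 0.1)):
            sd = np.sqrt(p * (1 - p) * n_sel)
            assert abs(acts[a] - p * n_sel) < 3 * sd

    def test_corruption_only_at_selected_positions(self):
        rng = np.random.default_rng(5)
        seq = "ACGT" * 30
        plan = build_masking_plan(make_record(seq), rng)
        diff = np.flatnonzero(plan.input_tokens != plan.original_tokens)
        assert set(diff) <= set(plan.loss_positions)
        masked = plan.loss_positions[plan.actions == 0]
        assert np.all(plan.input_tokens[masked] == ALPHABET.MASK)
        mutated = plan.loss_positions[plan.actions == 1]
        assert np.all(plan.input_tokens[mutated] != plan.original_tokens[mutated])
        assert np.all(plan.input_tokens[mutated] < 4)


class TestReferenceProfile:
    def test_perfect_model_gives_ones(self):
        toks = ALPHABET.encode("ACGT")
        probs = np.zeros((4, 4))
        probs[np.arange(4), toks] = 1.0
        np.testing.assert_allclose(
            reference_probability_profile(probs, toks), 1.0)

    def test_uniform_model_gives_quarter(self):
        toks = ALPHABET.encode("ACGTACGT")
        np.testing.assert_allclose(
            reference_probability_profile(np.full((8, 4), 0.25), toks), 0.25)

    def test_n_positions_mean_filled(self):
        toks = ALPHABET.encode("ANGT")
        probs = np.tile([0.1, 0.2, 0.3, 0.4], (4, 1))
        prof = reference_probability_profile(probs, toks)
        # non-N entries: p(A)=0.1, p(G)=0.3, p(T)=0.4; N filled with mean
        np.testing.assert_allclose(prof, [0.1, (0.1 + 0.3 + 0.4) / 3, 0.3, 0.4])


class TestSpectralWeights:
    def test_band_is_unit_weight(self):
        w = spectral_weights(350)
        # C_L=17.5, C_H=58.33: every integer i in [18, 58] has weight 1
        np.testing.assert_allclose(w[17:58], 1.0)
        assert w[16] < 1.0 and w[58] < 1.0

    def test_printed_weight_values(self):
        w = spectral_weights(350, FourierPriorConfig(smoothing=5.0))
        assert w[174] == pytest.approx(0.04110, abs=1e-5)  # i=175
        assert w[0] == pytest.approx(0.23256, abs=1e-5)    # i=1

    def test_weights_in_unit_interval(self):
        for L in (64, 127, 350):
            w = spectral_weights(L)
            assert np.all(w > 0) and np.all(w <= 1)


class TestFourierPrior:
    def test_constant_profile_maximally_penalized(self):
        latt, a, _ = fourier_prior_loss(np.full(350, 0.5))
        assert latt == pytest.approx(1.0, abs=1e-5)

    def test_inband_cosine_near_zero(self):
        t = np.arange(350)
        prof = 0.5 + 0.1 * np.cos(2 * np.pi * 30 * t / 350)
        latt, a, _ = fourier_prior_loss(prof)
        assert latt < 0.01
        assert a[29] == pytest.approx(1.0, abs=1e-6)  # all mass at index 30

    def test_nyquist_cosine_value(self):
        t = np.arange(350)
        prof = 0.5 + 0.1 * np.cos(2 * np.pi * 175 * t / 350)
        latt, _, _ = fourier_prior_loss(prof)
        assert latt == pytest.approx(0.95890, abs=1e-3)

    def test_band_ordering_of_cosine_periods(self):
        # periods 10 bp (in band), 3 bp (high freq), 60 bp (low freq)
        t = np.arange(350)
        latts = {
            period: fourier_prior_loss(
                0.5 + 0.1 * np.cos(2 * np.pi * t / period))[0]
            for period in (10, 3, 60)
        }
        assert latts[10] < latts[3] and latts[10] < latts[60]

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_latt_bounded_and_spectrum_normalized(self, seed):
        rng = np.random.default_rng(seed)
        prof = rng.random(64)
        latt, a, w = fourier_prior_loss(prof)
        assert 0.0 <= latt <= 1.0
        if np.abs(a).sum() > 0:
            assert a.sum() == pytest.approx(1.0, abs=1e-6)

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        prof = rng.random(64)
        _, _, _, grad = fourier_prior_loss(prof, with_grad=True)
        fd = np.zeros(64)
        for i in range(64):
            up, dn = prof.copy(), prof.copy()
            up[i] += 1e-6
            dn[i] -= 1e-6
            fd[i] = (fourier_prior_loss(up)[0] - fourier_prior_loss(dn)[0]) / 2e-6
        rel = np.abs(grad - fd).max() / np.abs(fd).max()
        assert rel < 1e-4

    def test_nan_profile_rejected(self):
        with pytest.raises(ValueError):
            fourier_prior_loss(np.array([1.0, np.nan, 0.5, 0.2]))

    def test_inband_fraction_of_pure_tones(self):
        t = np.arange(350)
        assert inband_fraction(0.5 + 0.1 * np.cos(2 * np.pi * t / 10)) > 0.99
        assert inband_fraction(0.5 + 0.1 * np.cos(2 * np.pi * t / 3)) < 0.1


class TestLosses:
    def test_mlm_loss_closed_forms(self):
        toks = ALPHABET.encode("ACGTACGT")
        plan = MaskingPlan(toks.copy(), toks, np.arange(8),
                           np.zeros(8, dtype=int))
        perfect = np.zeros((8, 4))
        perfect[np.arange(8), toks] = 1.0
        assert mlm_loss(perfect, plan) == pytest.approx(0.0, abs=1e-9)
        assert mlm_loss(np.full((8, 4), 0.25), plan) == \
            pytest.approx(np.log(4), rel=1e-9)

    def test_mlm_loss_matches_bruteforce_average(self):
        rng = np.random.default_rng(7)
        toks = rng.integers(0, 4, 20)
        probs = rng.random((20, 4))
        probs /= probs.sum(-1, keepdims=True)
        pos = np.array([1, 5, 7, 13])
        plan = MaskingPlan(toks.copy(), toks, pos, np.zeros(4, dtype=int))
        expected = np.mean([-np.log(probs[p, toks[p]]) for p in pos])
        assert mlm_loss(probs, plan) == pytest.approx(expected, rel=1e-9)

    def test_empty_plan_contributes_zero(self):
        toks = ALPHABET.encode("NNNN")
        plan = MaskingPlan(toks.copy(), toks, np.array([], dtype=int),
                           np.array([], dtype=int))
        assert mlm_loss(np.full((4, 4), 0.25), plan) == 0.0

    @pytest.mark.parametrize("lmlm,latt,lam,total", [
        (1.0, 0.5, 0.002, 1.001),
        (1.0, 0.7, 0.0, 1.0),
        (2.5, 0.0, 1.0, 2.5),
    ])
    def test_combined_loss_arithmetic(self, lmlm, latt, lam, total):
        br = combined_loss(lmlm, latt, lam)
        assert br.total == pytest.approx(total, rel=1e-12)


@pytest.fixture(scope="module")
def small_corpus():
    spec = SyntheticCorpusSpec(n_sequences=250, length=64,
                               motifs_per_seq=1.0, repeat_rate=0.0)
    return generate_corpus(spec, np.random.default_rng(0))[0]


class TestTrainingLoop:
    def micro_train(self, records, seed=0, epochs=3, no_prior=False):
        cfg = dataclasses.replace(ModelConfig.micro(), context_length=64)
        tcfg = TrainingConfig.tiny(seed=seed, epochs=epochs, no_prior=no_prior)
        return train_model(records, cfg, tcfg)

    def test_loss_decreases(self, small_corpus):
        res = self.micro_train(small_corpus, epochs=15)
        assert res.log[-1]["train_mlm"] < res.log[0]["train_mlm"] - 0.005

    def test_same_seed_identical_logs(self, small_corpus):
        a = self.micro_train(small_corpus, seed=5, epochs=2)
        b = self.micro_train(small_corpus, seed=5, epochs=2)
        assert a.log == b.log

    def test_no_prior_flag_zeroes_attribution_loss(self, small_corpus):
        res = self.micro_train(small_corpus, epochs=1, no_prior=True)
        assert res.log[0]["train_att"] == 0.0

    def test_requires_train_and_val_splits(self, small_corpus):
        only_train = [r for r in small_corpus if r.split == "train"]
        with pytest.raises(ValueError, match="split"):
            self.micro_train(only_train)

    def test_metric_log_round_trip(self, small_corpus, tmp_path):
        res = self.micro_train(small_corpus, epochs=2)
        path = tmp_path / "metrics.tsv"
        write_metric_log(res.log, path)
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "epoch\ttrain_mlm\ttrain_att\tval_mlm"
        assert len(lines) == len(res.log) + 1
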