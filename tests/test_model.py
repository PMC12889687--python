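"""Tokenizer, transformer forward/backward, embeddings and chunking."""

import dataclasses

import numpy as np
import pytest

from motiflm.nn import (ALPHABET, AlphabetError, Adam, MaskedLM, ModelConfig,
                        N_BASES, _softmax_last, backward, chunk_plan,
                        count_parameters, forward, init_params)


class TestAlphabet:
    def test_round_trip(self):
        assert ALPHABET.decode(ALPHABET.encode("ACGTN")) == "ACGTN"

    def test_case_fold(self):
        assert np.array_equal(ALPHABET.encode("acgt"), ALPHABET.encode("ACGT"))

    def test_invalid_character_named(self):
        with pytest.raises(AlphabetError, match="'X'"):
            ALPHABET.encode("ACGX")

    def test_mask_never_decodes(self):
        with pytest.raises(AlphabetError):
            ALPHABET.decode([0, 5, 1])


class TestConfig:
    def test_paper_scale_fields(self):
        cfg = ModelConfig.paper()
        assert (cfg.embed_dim, cfg.n_blocks, cfg.n_heads, cfg.ff_dim,
                cfg.context_length) == (768, 8, 8, 3072, 350)

    def test_tiny_preset(self):
        cfg = ModelConfig.tiny()
        assert (cfg.embed_dim, cfg.n_blocks, cfg.n_heads, cfg.ff_dim) == \
            (64, 2, 4, 128)

    def test_invalid_heads_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(embed_dim=64, n_heads=5)

    def test_parameter_count_stable_and_matches_arrays(self):
        for cfg in (ModelConfig.tiny(), ModelConfig.micro()):
            params = init_params(cfg, np.random.default_rng(0))
            assert sum(v.size for v in params.values()) == count_parameters(cfg)
        assert count_parameters(ModelConfig.paper()) == \
            count_parameters(ModelConfig.paper())


@pytest.fixture(scope="module")
def model():
    return MaskedLM(ModelConfig.micro(context_length=40), seed=3)


class TestForward:
    def test_probability_rows_sum_to_one(self, model):
        tokens = np.random.default_rng(0).integers(0, 6, (3, 40))
        probs = model.predict_probs(tokens)
        np.testing.assert_allclose(probs.sum(-1), 1.0, atol=1e-6)
        assert probs.min() >= 0 and probs.max() <= 1

    def test_eval_mode_deterministic(self, model):
        tokens = np.random.default_rng(1).integers(0, 6, (2, 40))
        a = model.predict_logits(tokens)
        b = model.predict_logits(tokens)
        assert np.array_equal(a, b)

    def test_n_token_embedding_is_zero(self, model):
        assert np.all(model.params["emb"][ALPHABET.N] == 0)

    def test_length_exceeding_context_rejected(self, model):
        with pytest.raises(ValueError, match="context"):
            model.predict_logits(np.zeros((1, 41), dtype=int))

    def test_empty_sequence_rejected(self, model):
        with pytest.raises(ValueError):
            forward(model.params, model.cfg, np.zeros((1, 0), dtype=int))

    def test_rotary_positions_break_translation_invariance(self, model):
        # same local content at different positions must produce different
        # outputs: the encoder is not position-blind
        base = np.array([0, 1, 2, 3] * 10)
        rolled = np.roll(base, 4)
        la = model.predict_logits(base[None])[0]
        lb = model.predict_logits(rolled[None])[0]
        # compare predictions for the same content at shifted positions
        assert not np.allclose(la[:20], lb[4:24], atol=1e-5)

    def test_n_row_gradient_frozen_under_optimizer(self):
        cfg = ModelConfig.micro(context_length=8)
        model = MaskedLM(cfg, seed=0)
        opt = Adam(model.params, lr=0.1)
        tokens = np.array([[0, 1, 4, 3, 4, 1, 2, 0]])
        logits, aux = forward(model.params, cfg, tokens, keep_cache=True)
        grads = backward(model.params, cfg, np.ones_like(logits), aux["cache"])
        assert np.all(grads["emb"][ALPHABET.N] == 0)
        opt.step(model.params, grads)
        assert np.all(model.params["emb"][ALPHABET.N] == 0)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Float64 finite-difference check of the full forward/backward."""
        cfg = ModelConfig.micro(context_length=10)
        params = {k: v.astype(np.float64) * 10
                  for k, v in init_params(cfg, np.random.default_rng(1)).items()}
        params["emb"][ALPHABET.N] = 0.0
        tokens = np.array([[0, 1, 2, 3, 4, 5, 0, 2, 1, 3]])
        targ = tokens % 4

        def loss_of():
            logits, _ = forward(params, cfg, tokens)
            p = _softmax_last(logits)
            return float(np.log(
                p[np.arange(1)[:, None], np.arange(10)[None, :], targ]).sum())

        logits, aux = forward(params, cfg, tokens, keep_cache=True)
        p = _softmax_last(logits)
        dlogits = -p.copy()
        for i in range(10):
            dlogits[0, i, targ[0, i]] += 1
        grads = backward(params, cfg, dlogits, aux["cache"])

        rng = np.random.default_rng(0)
        for key in ("emb", "b0.Wq", "b0.Wk", "b0.Wv", "b0.Wo", "b0.W1",
                    "b0.W2", "b0.ln1_g", "lnf_b", "Wh1", "Wh2", "bh2"):
            flat = params[key].reshape(-1)
            for ix in rng.choice(flat.size, size=min(4, flat.size),
                                 replace=False):
                if key == "emb" and ix // params[key].shape[1] == ALPHABET.N:
                    continue
                orig, eps = flat[ix], 1e-6
                flat[ix] = orig + eps
                lp = loss_of()
                flat[ix] = orig - eps
                lm = loss_of()
                flat[ix] = orig
                fd = (lp - lm) / (2 * eps)
                an = grads[key].reshape(-1)[ix]
                assert an == pytest.approx(fd, rel=1e-4, abs=1e-7), key


class TestEmbeddings:
    def test_shape_contract(self, micro_model):
        emb = micro_model.extract_embeddings("ACGTN" * 5)
        assert emb.shape == (25, micro_model.cfg.embed_dim)

    def test_last_six_layer_averaging(self):
        # with 8 blocks the mean covers layers 3..8 (1-indexed)
        cfg = ModelConfig(embed_dim=16, n_blocks=8, n_heads=2, ff_dim=32,
                          context_length=16)
        model = MaskedLM(cfg, seed=0)
        seq = "ACGTACGTACGTACGT"
        layers = model.layer_stack(ALPHABET.encode(seq)[None])
        assert len(layers) == 8
        expected = np.mean([lay[0] for lay in layers[2:]], axis=0)
        np.testing.assert_allclose(model.extract_embeddings(seq), expected,
                                   rtol=1e-6)

    def test_fewer_than_six_blocks_averages_all(self):
        cfg = ModelConfig.tiny()
        model = MaskedLM(dataclasses.replace(cfg, context_length=20), seed=0)
        seq = "ACGT" * 5
        layers = model.layer_stack(ALPHABET.encode(seq)[None])
        expected = np.mean([lay[0] for lay in layers], axis=0)  # both layers
        np.testing.assert_allclose(model.extract_embeddings(seq), expected,
                                   rtol=1e-6)

    def test_empty_sequence_rejected(self, micro_model):
        with pytest.raises(ValueError):
            micro_model.extract_embeddings("")


class TestChunking:
    def test_published_window_tiling(self):
        """2,114-bp inputs: 5 full chunks cover [182, 1932), ends filled
        from the first/last 350 bp."""
        plan = chunk_plan(2114, 350)
        full = [(w, lo, hi, d) for w, lo, hi, d in plan if hi - lo == 350]
        assert len(full) == 5
        assert full[0][3] == 182 and full[-1][3] + 350 == 1932
        assert plan[0][:2] == (0, 0) and plan[0][2] == 182  # 5' fill
        w, lo, hi, d = plan[-1]
        assert w == 2114 - 350 == 1764 and d == 1932 and hi == 350

    @pytest.mark.parametrize("M,context", [
        (2114, 350), (700, 350), (350, 350), (351, 350), (1000, 350),
        (97, 16), (64, 16),
    ])
    def test_plan_partitions_every_position_exactly_once(self, M, context):
        cover = np.zeros(M, dtype=int)
        for w, lo, hi, d in chunk_plan(M, context):
            assert 0 <= w and w + context <= M
            cover[d : d + (hi - lo)] += 1
        assert np.all(cover == 1)

    def test_exact_multiple_tiles_without_edge_fill(self):
        plan = chunk_plan(700, 350)
        assert plan == [(0, 0, 350, 0), (350, 0, 350, 350)]

    def test_single_chunk_reduces_to_direct_extraction(self, micro_model):
        import dataclasses as dc

        cfg = dc.replace(ModelConfig.micro(), context_length=16)
        model = MaskedLM(cfg, seed=1)
        seq = "ACGTACGTACGTACGT"
        np.testing.assert_allclose(model.embed_long_sequence(seq),
                                   model.extract_embeddings(seq))

    def test_long_embedding_rows(self):
        cfg = dataclasses.replace(ModelConfig.micro(), context_length=16)
        model = MaskedLM(cfg, seed=1)
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 53)])
        emb = model.embed_long_sequence(seq)
        assert emb.shape == (53, cfg.embed_dim)
        with pytest.raises(ValueError):
            model.embed_long_sequence(seq[:10])


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, micro_model):
        w, c = tmp_path / "w.npz", tmp_path / "c.json"
        micro_model.save(w, c)
        back = MaskedLM.load(w, c)
        tokens = np.random.default_rng(0).integers(0, 6, (2, 30))
        np.testing.assert_array_equal(micro_model.predict_logits(tokens),
                                      back.predict_logits(tokens))

    def test_config_hash_mismatch_rejected(self, tmp_path, micro_model):
        import json

        w, c = tmp_path / "w.npz", tmp_path / "c.json"
        micro_model.save(w, c)
        meta = json.loads(c.read_text())
        meta["config"]["n_heads"] = 1
        c.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="hash"):
            MaskedLM.load(w, c)
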