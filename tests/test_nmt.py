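import numpy as np
import pytest

from codetrans.corpus import ParallelPair
from codetrans.nmt import (NmtConfig, TranslationCandidates, Translator, Vocab,
                           train)
from codetrans.synthetic import make_catalog
from codetrans.corpus import normalize_target
from codetrans.transformer import Seq2SeqTransformer

TINY = NmtConfig(epochs=80, batch_size=16, seed=0)


def _distinct_pairs(n=25, seed=1):
    catalog = make_catalog(n, seed=seed)
    return [
        ParallelPair(source=" ".join(t.split()[2:7:2]),
                     target=normalize_target(t), code=c, case_id=f"p{i}")
        for i, (c, t) in enumerate(zip(catalog.codes, catalog.terms))
    ]


@pytest.fixture(scope="module")
def overfit_translator():
    return train(_distinct_pairs() * 2, TINY)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences on a tiny
        double-precision model (every parameter family sampled)."""
        m = Seq2SeqTransformer(src_vocab_size=9, tgt_vocab_size=8, d_model=8,
                               n_heads=2, n_enc_layers=1, n_dec_layers=1,
                               ffn_dim=12, max_len=10, seed=3, dtype=np.float64)
        rng = np.random.default_rng(0)
        src = np.array([[4, 5, 6, 0], [7, 8, 0, 0]])
        tgt_in = np.array([[1, 4, 5], [1, 6, 0]])
        labels = np.array([[4, 5, 2], [6, 2, 0]])
        m.params.zero_grad()
        m.loss_and_grad(src, tgt_in, labels)
        grads = {k: v.copy() for k, v in m.params.grads.items()}
        eps = 1e-6
        for name, g in grads.items():
            flat = m.params.values[name].ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = m.loss_and_grad(src, tgt_in, labels)
                flat[i] = orig - eps
                lm = m.loss_and_grad(src, tgt_in, labels)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = g.ravel()[i]
                assert abs(num - ana) / max(1.0, abs(num), abs(ana)) < 1e-6, name


class TestTraining:
    def test_loss_decreases_on_sanity_corpus(self, overfit_translator):
        h = overfit_translator.loss_history
        assert h[-1] < h[0] / 10

    def test_overfit_model_memorizes_targets(self, overfit_translator):
        pairs = _distinct_pairs()
        exact = sum(overfit_translator.translate(p.source, k=1).best == p.target
                    for p in pairs)
        assert exact / len(pairs) >= 0.95

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train([], TINY)

    def test_overlong_target_names_pair(self):
        pair = ParallelPair(source="x", target=" ".join(["tok"] * 100),
                            code="00100", case_id="toolong")
        with pytest.raises(ValueError, match="toolong"):
            train([pair], TINY)

    def test_training_is_deterministic(self):
        pairs = _distinct_pairs(8)
        cfg = NmtConfig(embed_dim=16, layers=1, heads=2, ffn_dim=16, epochs=5,
                        batch_size=4, seed=7)
        a, b = train(pairs, cfg), train(pairs, cfg)
        srcs = [p.source for p in pairs]
        outs_a = [a.translate(s, k=3).candidates for s in srcs]
        outs_b = [b.translate(s, k=3).candidates for s in srcs]
        assert outs_a == outs_b
        assert a.loss_history == b.loss_history


class TestTranslate:
    def test_top3_scores_non_increasing(self, overfit_translator):
        for p in _distinct_pairs()[:5]:
            cands = overfit_translator.translate(p.source, k=3)
            scores = [s for _, s in cands.candidates]
            assert scores == sorted(scores, reverse=True)
            assert len(cands.candidates) <= 3
            assert all(s for s, _ in cands.candidates)  # non-empty sentences

    def test_decoding_is_pure(self, overfit_translator):
        src = _distinct_pairs()[0].source
        assert (overfit_translator.translate(src, k=3)
                == overfit_translator.translate(src, k=3))

    def test_candidates_distinct_after_detokenization(self, overfit_translator):
        cands = overfit_translator.translate(_distinct_pairs()[0].source, k=3)
        assert len(set(cands.sentences)) == len(cands.sentences)

    def test_k_exceeding_beam_rejected(self, overfit_translator):
        with pytest.raises(ValueError, match="beam"):
            overfit_translator.translate("x", k=overfit_translator.config.beam_size + 1)

    def test_empty_source_rejected(self, overfit_translator):
        with pytest.raises(ValueError):
            overfit_translator.translate("   ", k=1)

    def test_k_below_one_rejected(self, overfit_translator):
        with pytest.raises(ValueError):
            overfit_translator.translate("x", k=0)

    def test_unknown_tokens_map_to_unk(self):
        v = Vocab.build(["alpha beta", "beta gamma"])
        ids = v.encode("alpha zzz")
        assert v.id_to_token[ids[1]] == "<unk>"
        assert v.decode(ids) == "alpha <unk>"


class TestConfigAndPersistence:
    def test_beam_must_cover_top3(self):
        with pytest.raises(ValueError):
            NmtConfig(beam_size=2)

    def test_candidate_score_order_enforced(self):
        with pytest.raises(ValueError):
            TranslationCandidates(source="s", candidates=(("a", -2.0), ("b", -1.0)),
                                  k=2)

    def test_checkpoint_round_trip(self, overfit_translator, tmp_path):
        overfit_translator.save(tmp_path / "ckpt")
        back = Translator.load(tmp_path / "ckpt")
        src = _distinct_pairs()[0].source
        assert back.translate(src, k=3) == overfit_translator.translate(src, k=3)
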