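"""Shared fixtures, including one session-scoped trained pipeline.

The heavy fixture runs the scaled-down study once (synthetic registry,
temporal holdout, translation model per input mode, matching step, SVM
baseline) and several tests read different aspects of its artifacts.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter

import pytest

from codetrans import corpus, nmt, synthetic, transform
from codetrans.baseline_svm import (MIN_COUNT_COMBINED, MIN_COUNT_PROCEDURE,
                                    SvmBaseline)
from codetrans.preprocess import default_stopwords

STUDY_SEED = 11
CUTOFF = dt.date(2019, 1, 1)


@pytest.fixture(scope="session")
def small_catalog():
    return synthetic.make_catalog(50, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study(small_catalog):
    """Scaled-down end-to-end study: 50 codes, 2,500 cases, moderate
    noise; translation + matching and the SVM baseline in input modes
    2 (curated) and 3 (curated + diagnosis)."""
    catalog = small_catalog
    config = synthetic.SynthConfig(
        n_codes=50, n_cases=2500, misspell_rate=0.1, token_dropout_rate=0.1,
        seed=STUDY_SEED)
    cases, truths = synthetic.simulate_cases(catalog, config)
    lexicons = synthetic.lexicons_from_truth(
        truths, catalog, stopwords=default_stopwords())
    dev, holdout = corpus.date_split(cases, CUTOFF)
    train_cases, val_cases = corpus.stratified_split(dev, 0.2, seed=STUDY_SEED)
    gold = [c.code for c in holdout]

    runs: dict[str, dict] = {}
    for mode, min_count in (("curated", MIN_COUNT_PROCEDURE),
                            ("curated+diagnosis", MIN_COUNT_COMBINED)):
        pairs_dev = corpus.build_pairs(dev, catalog, mode, lexicons)
        pairs_hold = corpus.build_pairs(holdout, catalog, mode, lexicons)
        translator = nmt.train(
            pairs_dev,
            nmt.NmtConfig(epochs=15, seed=STUDY_SEED, vocab_min_freq=2))
        cands = translator.translate_many([p.source for p in pairs_hold], k=3)
        matrix = transform.score_matrix(cands, catalog, "mean")
        preds = transform.predict(matrix)

        def texts(subset, mode=mode):
            return [p.source for p in corpus.build_pairs(subset, catalog,
                                                         mode, lexicons)]
        svm = SvmBaseline(min_count=min_count, seed=STUDY_SEED)
        svm.fit(texts(train_cases), [c.code for c in train_cases],
                texts(val_cases), [c.code for c in val_cases])
        svm_topk = [[c for c, _ in row]
                    for row in svm.predict_topk(texts(holdout), k=3)]
        runs[mode] = {
            "translator": translator,
            "candidates": cands,
            "predictions": preds,
            "topk": [p.top3 for p in preds],
            "references": [p.target for p in pairs_hold],
            "train_counts": Counter(p.code for p in pairs_dev),
            "svm_topk": svm_topk,
        }
    return {
        "catalog": catalog,
        "config": config,
        "cases": cases,
        "truths": truths,
        "lexicons": lexicons,
        "dev": dev,
        "holdout": holdout,
        "gold": gold,
        "runs": runs,
    }
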