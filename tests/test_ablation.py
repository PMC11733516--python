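"""Leave-one-word-out importance: vocabulary, scans, standardization, export."""

import numpy as np
import pandas as pd
import pytest

from qcla import HashingBowEncoder, remove_word, standardize_and_flag, vocabulary, wordcloud_data
from qcla.ablation import AblationResult, ablation_scan, word_counts
from qcla.predict import CVSpec, RidgeSpec

from conftest import make_text_dataset

SIGNAL = ["neglect", "conflict", "sleepless", "craving", "escape"]


def planted_marker_dataset(rng, n=200, fillers=120, words=8, a=-1.0, b=2.5):
    """One-question corpus where each respondent owns one of 5 marker words
    whose use probability rises with latent severity."""
    lex = [f"w{i:03d}" for i in range(fillers)]
    rows = []
    for i in range(n):
        theta = rng.lognormal(0.0888, 0.6674)
        my_marker = SIGNAL[rng.integers(len(SIGNAL))]
        seq = []
        for _ in range(words):
            p = 1.0 / (1.0 + np.exp(-(a + b * theta)))
            seq.append(my_marker if rng.random() < p else lex[rng.integers(fillers)])
        seq = list(dict.fromkeys(seq))
        items = np.clip(1 + np.floor(theta + rng.normal(0, 0.25, 4)), 1, 5).astype(int)
        rows.append(
            {"id": f"R{i}", "q1": " ".join(seq),
             **{f"gdt_{k + 1}": int(items[k]) for k in range(4)}}
        )
    return pd.DataFrame(rows)


def null_dataset(rng, n=100, vocab=250, words=8):
    lex = [f"w{i:03d}" for i in range(vocab)]
    rows = []
    for i in range(n):
        seq = rng.choice(lex, size=words, replace=False)
        items = rng.integers(1, 6, size=4)
        rows.append(
            {"id": f"R{i}", "q1": " ".join(seq),
             **{f"gdt_{k + 1}": int(items[k]) for k in range(4)}}
        )
    return pd.DataFrame(rows)


class TestVocabulary:
    def test_union_of_answer_words(self):
        ds = make_text_dataset([("a b", [1, 1, 1, 1]), ("b c", [2, 2, 2, 2])])
        assert set(vocabulary(ds, 1)) == {"a", "b", "c"}

    def test_frequency_filter(self):
        ds = make_text_dataset([("a b", [1, 1, 1, 1]), ("b c", [2, 2, 2, 2])])
        assert vocabulary(ds, 1, min_count=2) == ["b"]

    def test_counts_match_hand_tally(self):
        ds = make_text_dataset(
            [("time relax", [1] * 4), ("time fun", [1] * 4), ("relax time", [1] * 4),
             ("joy", [1] * 4), ("fun fun", [1] * 4)]
        )
        counts = word_counts(ds, 1)
        assert counts["time"] == 3
        assert counts["relax"] == 2
        assert counts["fun"] == 3  # dedup happens upstream; raw counts here
        assert counts["joy"] == 1

    def test_unknown_question_rejected(self):
        ds = make_text_dataset([("a", [1] * 4)])
        with pytest.raises(KeyError):
            vocabulary(ds, 3)


class TestRemoveWord:
    def test_absent_word_is_noop(self):
        ds = make_text_dataset([("time relax fun", [1] * 4)])
        out = remove_word(ds, 1, "zebra")
        assert out["q1"].tolist() == ["time relax fun"]

    def test_target_word_removed_everywhere(self):
        ds = make_text_dataset([("time relax fun", [1] * 4), ("relax joy", [2] * 4)])
        out = remove_word(ds, 1, "relax")
        assert out["q1"].tolist() == ["time fun", "joy"]

    def test_original_untouched(self):
        ds = make_text_dataset([("time relax", [1] * 4)])
        remove_word(ds, 1, "relax")
        assert ds["q1"].tolist() == ["time relax"]


class TestAblationScan:
    def test_planted_markers_rank_in_top_decile(self):
        """Severity-marker words outrank fillers by z in >= 90% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            ds = planted_marker_dataset(rng)
            enc = HashingBowEncoder(dim=128, seed=0)
            res = standardize_and_flag(
                ablation_scan(ds, enc, RidgeSpec(lam=1000.0), CVSpec(k=5, seed=seed), 1)
            )
            order = sorted(res, key=lambda r: -r.z)
            ranks = [1 + next(i for i, r in enumerate(order) if r.word == w) for w in SIGNAL]
            hits += np.mean(ranks) <= len(order) / 10
        assert hits >= 0.9 * n_seeds

    def test_single_signal_word_has_largest_delta(self):
        """A corpus where one word carries all the signal puts it on top."""
        rng = np.random.default_rng(3)
        rows = []
        for i in range(120):
            has_sig = rng.random() < 0.4
            fillers = [f"w{j:02d}" for j in rng.choice(40, size=5, replace=False)]
            seq = (["neglect"] if has_sig else []) + fillers
            item = 5 if has_sig else 1
            rows.append({"id": f"R{i}", "q1": " ".join(seq), **{f"gdt_{k}": item for k in range(1, 5)}})
        ds = pd.DataFrame(rows)
        enc = HashingBowEncoder(dim=64, seed=0)
        res = ablation_scan(ds, enc, RidgeSpec(lam=100.0), CVSpec(k=5, seed=0), 1)
        best = max(res, key=lambda r: r.delta)
        assert best.word == "neglect"

    def test_null_corpus_deltas_center_near_zero(self):
        rng = np.random.default_rng(7)
        ds = null_dataset(rng, n=60, vocab=120)
        enc = HashingBowEncoder(dim=32, seed=0)
        res = ablation_scan(ds, enc, RidgeSpec(lam=100.0), CVSpec(k=5, seed=7), 1)
        deltas = np.array([r.delta for r in res])
        assert abs(deltas.mean()) < 0.02

    def test_scan_is_deterministic(self):
        rng = np.random.default_rng(11)
        ds = null_dataset(rng, n=40, vocab=60, words=6)
        enc = HashingBowEncoder(dim=32, seed=0)
        kwargs = dict(ridge_spec=RidgeSpec(lam=100.0), cv_spec=CVSpec(k=4, seed=1), question=1)
        res1 = ablation_scan(ds, enc, **kwargs)
        res2 = ablation_scan(ds, enc, **kwargs)
        assert [(r.word, r.delta) for r in res1] == [(r.word, r.delta) for r in res2]

    def test_fixed_folds_reduce_delta_noise(self):
        """Re-randomizing folds per word inflates the delta spread on a null corpus."""
        from qcla.ablation import _encode_sequences
        from qcla.encoding import build_features
        from qcla.predict import kfold_split, oof_predict, pearson_with_p

        rng = np.random.default_rng(5)
        ds = null_dataset(rng, n=80, vocab=100, words=6)
        enc = HashingBowEncoder(dim=32, seed=0)
        spec = RidgeSpec(lam=100.0)
        fixed = ablation_scan(ds, enc, spec, CVSpec(k=5, seed=0), 1)
        sd_fixed = np.std([r.delta for r in fixed])

        # same scan but a fresh fold assignment per word
        y = ds[[f"gdt_{i}" for i in range(1, 5)]].to_numpy().sum(axis=1).astype(float)
        fm = build_features(ds, enc, (1,))
        base_folds = kfold_split(len(ds), CVSpec(k=5, seed=0))
        base = oof_predict(fm.values, y, spec, fold_assignment=base_folds)
        base_r, _ = pearson_with_p(base.predictions, y)
        sequences = [str(s) for s in ds["q1"]]
        deltas = []
        for w_i, word in enumerate(vocabulary(ds, 1)):
            affected = [i for i, s in enumerate(sequences) if word in s.split()]
            X = fm.values.copy()
            X[affected] = _encode_sequences(
                enc, [" ".join(t for t in sequences[i].split() if t != word) for i in affected]
            )
            oof = oof_predict(X, y, spec, CVSpec(k=5, seed=1000 + w_i))
            r, _ = pearson_with_p(oof.predictions, y)
            deltas.append(base_r - r)
        assert sd_fixed < np.std(deltas)


class TestStandardizeAndFlag:
    def test_hand_arithmetic_z(self):
        res = [AblationResult(w, 1, 0.5, 0.5 - d, d) for w, d in zip("abc", (-1.0, 0.0, 1.0))]
        out = standardize_and_flag(res)
        np.testing.assert_allclose([r.z for r in out], [-1.2247449, 0.0, 1.2247449], atol=1e-6)

    def test_degenerate_spread_rejected(self):
        res = [AblationResult(w, 1, 0.5, 0.4, 0.1) for w in "abc"]
        with pytest.raises(ValueError):
            standardize_and_flag(res)

    def test_flagging_respects_alpha(self):
        deltas = list(np.linspace(-1, 1, 100)) + [8.0]
        res = [AblationResult(f"w{i}", 1, 0.5, 0.5 - d, d) for i, d in enumerate(deltas)]
        out = standardize_and_flag(res, alpha=0.05)
        assert out[-1].significant
        assert not out[50].significant


class TestWordcloudData:
    def test_size_order_follows_z(self):
        res = [AblationResult(w, 1, 0.5, 0.5, 0.0, z=z, p=0.5) for w, z in zip("abc", (0.2, 1.5, 3.0))]
        data = wordcloud_data(res)
        sizes = {d.word: d.size for d in data}
        assert sizes["a"] < sizes["b"] < sizes["c"]

    def test_all_nonsignificant_bucket(self):
        res = [AblationResult(w, 1, 0.5, 0.5, 0.0, z=0.1, p=0.8) for w in "ab"]
        assert {d.bucket for d in wordcloud_data(res)} == {"ns"}

    def test_boundary_p_goes_to_less_significant_bucket(self):
        res = [
            AblationResult("a", 1, 0.5, 0.5, 0.0, z=2.0, p=0.05),
            AblationResult("b", 1, 0.5, 0.5, 0.0, z=2.5, p=0.01),
            AblationResult("c", 1, 0.5, 0.5, 0.0, z=3.0, p=0.009),
        ]
        buckets = {d.word: d.bucket for d in wordcloud_data(res)}
        assert buckets == {"a": "ns", "b": "p<.05", "c": "p<.01"}

    def test_negative_z_floored_to_smallest_size(self):
        res = [
            AblationResult("a", 1, 0.5, 0.5, 0.0, z=-2.0, p=0.05),
            AblationResult("b", 1, 0.5, 0.5, 0.0, z=3.0, p=0.003),
        ]
        data = {d.word: d.size for d in wordcloud_data(res, size_range=(10, 100))}
        assert data["a"] == 10.0
        assert data["b"] == 100.0
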