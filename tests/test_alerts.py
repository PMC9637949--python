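"""Alert mining: fragment statistics, thresholds, screening round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diadtox.alerts import (
    AlertMiner,
    AlertSet,
    fragment_counts,
    fscore_binary,
    mine_alerts,
    positive_rate,
    screen_structure,
)
from diadtox.fingerprints import (
    FingerprintMatrix,
    FingerprintScheme,
    UnsupportedSchemeError,
    featurize_dataset,
    make_dictionary_provider,
)


def _matrix_from_bits(bits, provider=None, width=None):
    bits = np.asarray(bits, dtype=np.uint8)
    width = width or bits.shape[1]
    if provider is None:
        provider = make_dictionary_provider("TOY", ["[#6]"] * width)
    return FingerprintMatrix(FingerprintScheme(provider.name, width, "dictionary"),
                             bits, [f"m{i}" for i in range(bits.shape[0])],
                             provider=provider)


class TestFragmentCounts:
    def test_toy_counts(self):
        bits = np.zeros((8, 3), dtype=np.uint8)
        bits[:3, 0] = 1  # set in exactly the 3 positives
        y = [1, 1, 1, 0, 0, 0, 0, 0]
        num_p, num_n = fragment_counts(bits, y)
        assert (num_p[0], num_n[0]) == (3, 0)
        assert (num_p[1], num_n[1]) == (0, 0)

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(0)
        bits = rng.integers(0, 2, size=(40, 17)).astype(np.uint8)
        y = rng.integers(0, 2, 40)
        num_p, num_n = fragment_counts(bits, y)
        for j in range(17):
            p = sum(int(bits[i, j]) for i in range(40) if y[i] == 1)
            n = sum(int(bits[i, j]) for i in range(40) if y[i] == 0)
            assert (num_p[j], num_n[j]) == (p, n)

    def test_misaligned_error(self):
        with pytest.raises(ValueError):
            fragment_counts(np.zeros((3, 2)), [1, 0])


class TestPositiveRate:
    @pytest.mark.parametrize("num_p,num_n,expected", [
        (12, 1, 0.92), (9, 3, 0.75), (0, 5, 0.0), (14, 0, 1.0),
    ])
    def test_values(self, num_p, num_n, expected):
        assert round(positive_rate(num_p, num_n), 2) == expected

    def test_zero_support_undefined(self):
        with pytest.raises(ValueError):
            positive_rate(0, 0)


def _fscore_bruteforce(num_p, num_n, n_pos, n_neg):
    """Generic two-class f-score on the expanded 0/1 occurrence vectors."""
    xs_pos = np.r_[np.ones(num_p), np.zeros(n_pos - num_p)]
    xs_neg = np.r_[np.ones(num_n), np.zeros(n_neg - num_n)]
    x_all = np.r_[xs_pos, xs_neg]
    mp, mn, m = xs_pos.mean(), xs_neg.mean(), x_all.mean()
    sp = np.sum((xs_pos - mp) ** 2) / (n_pos - 1)
    sn = np.sum((xs_neg - mn) ** 2) / (n_neg - 1)
    denom = sp + sn
    if denom == 0:
        return 0.0
    return ((mp - m) ** 2 + (mn - m) ** 2) / denom


class TestFscore:
    @pytest.mark.parametrize("num_p,num_n,expected", [
        (14, 0, 0.065), (17, 2, 0.072), (20, 5, 0.075), (6, 2, 0.019),
        (12, 1, 0.051), (8, 0, 0.036), (6, 0, 0.026), (9, 3, 0.029),
    ])
    def test_reference_values_at_study_class_sizes(self, num_p, num_n, expected):
        assert round(fscore_binary(num_p, num_n, 148, 450), 3) == expected

    def test_no_discrimination_is_zero_region(self):
        # identical within-class rates: between-class numerator nearly vanishes
        assert fscore_binary(10, 30, 50, 150) < 1e-12

    def test_constant_feature_zero_with_no_scatter(self):
        assert fscore_binary(0, 0, 10, 10) == 0.0
        assert fscore_binary(10, 10, 10, 10) == 0.0

    def test_small_class_errors(self):
        with pytest.raises(ValueError):
            fscore_binary(1, 0, 1, 10)

    @given(st.integers(2, 60), st.integers(2, 60), st.data())
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_closed_form_equals_bruteforce(self, n_pos, n_neg, data):
        num_p = data.draw(st.integers(0, n_pos))
        num_n = data.draw(st.integers(0, n_neg))
        closed = fscore_binary(num_p, num_n, n_pos, n_neg)
        assert closed == pytest.approx(
            _fscore_bruteforce(num_p, num_n, n_pos, n_neg), abs=1e-12)


class TestMineAlerts:
    def test_planted_bit_passes_published_thresholds(self):
        rng = np.random.default_rng(1)
        bits = (rng.random((200, 10)) < 0.3).astype(np.uint8)
        y = np.r_[np.ones(100, dtype=int), np.zeros(100, dtype=int)]
        bits[:, 4] = 0
        bits[rng.choice(100, 20, replace=False), 4] = 1      # 20 positives
        bits[100 + rng.choice(100, 2, replace=False), 4] = 1  # 2 negatives
        aset = mine_alerts(_matrix_from_bits(bits), y)
        mined_bits = {a.bit for a in aset}
        assert 4 in mined_bits
        a4 = next(a for a in aset if a.bit == 4)
        assert (a4.num_p, a4.num_n) == (20, 2)
        assert a4.pr == pytest.approx(20 / 22)

    def test_infinite_support_threshold_empty(self):
        bits = np.ones((20, 3), dtype=np.uint8)
        y = [1] * 10 + [0] * 10
        aset = mine_alerts(_matrix_from_bits(bits), y, min_support=10**9)
        assert len(aset) == 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        bits = (rng.random((100, 20)) < 0.4).astype(np.uint8)
        y = rng.integers(0, 2, 100)
        y[:5], y[-5:] = 1, 0
        base = mine_alerts(_matrix_from_bits(bits), y,
                           min_support=2, min_fscore=0.0, min_pr=0.4)
        base_bits = {a.bit for a in base}
        for kwargs in ({"min_support": 10}, {"min_fscore": 0.01}, {"min_pr": 0.6}):
            tighter = mine_alerts(_matrix_from_bits(bits), y,
                                  **{"min_support": 2, "min_fscore": 0.0,
                                     "min_pr": 0.4, **kwargs})
            assert {a.bit for a in tighter} <= base_bits

    def test_duplicate_columns_collapse_to_lowest_bit(self):
        bits = np.zeros((30, 4), dtype=np.uint8)
        bits[:10, 1] = 1
        bits[:10, 3] = 1  # identical to column 1
        y = [1] * 10 + [0] * 20
        aset = mine_alerts(_matrix_from_bits(bits), y,
                           min_support=2, min_fscore=0.0, min_pr=0.5)
        assert [a.bit for a in aset] == [1]

    def test_sorted_by_pr_then_fscore(self):
        rng = np.random.default_rng(3)
        bits = (rng.random((120, 15)) < 0.35).astype(np.uint8)
        y = np.r_[np.ones(40, dtype=int), np.zeros(80, dtype=int)]
        aset = mine_alerts(_matrix_from_bits(bits), y,
                           min_support=2, min_fscore=0.0, min_pr=0.0)
        keys = [(-a.pr, -a.fscore) for a in aset]
        assert keys == sorted(keys)

    def test_hashed_scheme_unsupported(self, separable_set):
        dataset, _, _ = separable_set
        fpm = featurize_dataset(dataset, "FP")
        with pytest.raises(UnsupportedSchemeError):
            mine_alerts(fpm, dataset.labels())

    def test_single_class_error(self):
        bits = np.ones((10, 2), dtype=np.uint8)
        with pytest.raises(ValueError):
            mine_alerts(_matrix_from_bits(bits), [1] * 10)


class TestMiningConsistencyAndScreening:
    def test_mined_counts_reproduced_by_rematching(self, study_shaped_set):
        from diadtox.synthdata import plant_scheme

        dataset, config = study_shaped_set
        provider = plant_scheme(config.plants)
        fpm = featurize_dataset(dataset, provider)
        aset = mine_alerts(fpm, dataset.labels())
        assert len(aset) >= 3
        for alert in aset:
            hits_p = hits_n = 0
            for rec in dataset:
                if screen_structure(rec, AlertSet([alert], {})):
                    if rec.label == 1:
                        hits_p += 1
                    else:
                        hits_n += 1
            assert (hits_p, hits_n) == (alert.num_p, alert.num_n)

    def test_every_counted_positive_is_flagged(self, small_planted_set):
        from diadtox.synthdata import plant_scheme

        dataset, config = small_planted_set
        provider = plant_scheme(config.plants)
        fpm = featurize_dataset(dataset, provider)
        aset = mine_alerts(fpm, dataset.labels())
        alert = aset.alerts[0]
        flagged = {rec.id for rec in dataset
                   if screen_structure(rec, AlertSet([alert], {}))}
        carrying = {rec.id for i, rec in enumerate(dataset.records)
                    if fpm.bits[i, alert.bit]}
        assert carrying <= flagged

    def test_methane_unflagged(self, small_planted_set):
        from diadtox.synthdata import plant_scheme

        _, config = small_planted_set
        provider = plant_scheme(config.plants)
        aset = AlertSet([], {})
        assert screen_structure("C", aset) == []

    def test_screen_reports_atom_indices(self):
        from diadtox.alerts import FragmentStat

        alert = FragmentStat("TOY", 0, "c1ccccc1", 1, 0, 1.0, 0.1)
        hits = screen_structure("Cc1ccccc1", AlertSet([alert], {}))
        assert len(hits) == 1
        _, matches = hits[0]
        assert len(matches[0]) == 6  # six ring atoms reported

    def test_unparseable_structure_errors(self):
        with pytest.raises(ValueError):
            screen_structure("((((", AlertSet([], {}))


class TestAlertSetIO:
    def test_save_load_roundtrip(self, tmp_path, small_planted_set):
        from diadtox.synthdata import plant_scheme

        dataset, config = small_planted_set
        fpm = featurize_dataset(dataset, plant_scheme(config.plants))
        aset = mine_alerts(fpm, dataset.labels())
        path = tmp_path / "alerts.tsv"
        aset.save(path)
        loaded = AlertSet.load(path)
        assert len(loaded) == len(aset)
        assert loaded.thresholds == aset.thresholds
        assert [a.pattern for a in loaded] == [a.pattern for a in aset]


class TestAlertMinerEstimator:
    def test_fit_transform_predict(self, small_planted_set):
        from diadtox.synthdata import plant_scheme

        dataset, config = small_planted_set
        miner = AlertMiner(scheme=plant_scheme(config.plants))
        miner.fit(dataset.smiles(), dataset.labels())
        assert len(miner.alerts_) >= 1
        hits = miner.transform(dataset.smiles()[:20])
        assert hits.shape == (20, len(miner.alerts_))
        flags = miner.predict(dataset.smiles()[:20])
        assert np.array_equal(flags, (hits.sum(axis=1) > 0).astype(int))
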