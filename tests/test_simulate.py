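import numpy as np
import pytest

import motifattn as ma
from motifattn.motifs import score_site
from motifattn.simulate import (GroundTruth, generate_background,
                                generate_negative, generate_positive, preset)


@pytest.fixture(scope="module")
def lib6():
    return ma.random_library(6, np.random.default_rng(21))


@pytest.fixture(scope="module")
def cfg6():
    return ma.SimulationConfig(n_sequences=200, seq_length=250, n_motifs=6,
                               n_pairs=3, seed=13)


@pytest.fixture(scope="module")
def truth6(lib6, cfg6):
    rng = np.random.default_rng(cfg6.seed)
    return ma.select_interacting_pairs(lib6, cfg6.n_motifs, cfg6.n_pairs, rng)


class TestPairSelection:
    def test_forced_single_pair(self, lib6):
        sub = ma.MotifLibrary(list(lib6.motifs[:2]))
        truth = ma.select_interacting_pairs(sub, 2, 1,
                                            np.random.default_rng(0))
        assert truth.pairs == {tuple(sorted(sub.names))}

    def test_counts_and_coverage(self, lib6):
        truth = ma.select_interacting_pairs(lib6, 5, 4,
                                            np.random.default_rng(1))
        assert len(truth.pairs) == 4
        assert len(truth.motif_pool) == 5
        covered = {m for p in truth.pairs for m in p}
        assert covered == truth.motif_pool

    def test_deterministic(self, lib6):
        a = ma.select_interacting_pairs(lib6, 4, 3, np.random.default_rng(5))
        b = ma.select_interacting_pairs(lib6, 4, 3, np.random.default_rng(5))
        assert a.pairs == b.pairs

    def test_infeasible_counts(self, lib6):
        with pytest.raises(ValueError):
            ma.select_interacting_pairs(lib6, 7, 1, np.random.default_rng(0))
        with pytest.raises(ValueError):
            ma.select_interacting_pairs(lib6, 3, 4, np.random.default_rng(0))
        with pytest.raises(ValueError):  # cannot cover 5 motifs with 2 pairs
            ma.select_interacting_pairs(lib6, 5, 2, np.random.default_rng(0))


class TestBackground:
    def test_length_and_alphabet(self, rng):
        s = generate_background(300, (0.25,) * 4, rng)
        assert len(s) == 300 and set(s) <= set("ACGT")

    def test_degenerate_frequencies(self, rng):
        assert generate_background(50, (1, 0, 0, 0), rng) == "A" * 50

    def test_empirical_frequencies(self):
        rng = np.random.default_rng(0)
        freqs = ma.simulate.HUMAN_BACKGROUND
        s = generate_background(1_000_000, freqs, rng)
        for base, f in zip("ACGT", freqs):
            assert s.count(base) / len(s) == pytest.approx(f, abs=0.01)
        gc = (s.count("G") + s.count("C")) / len(s)
        assert gc == pytest.approx(0.41, abs=0.01)


def _gaps(implants):
    """End-to-start gaps between the two members of each pair_id."""
    by_pair = {}
    for imp in implants:
        by_pair.setdefault(imp.pair_id, []).append(imp)
    gaps = []
    for members in by_pair.values():
        assert len(members) == 2
        first, second = sorted(members, key=lambda i: i.start)
        gaps.append(second.start - first.end)
    return gaps


class TestPositives:
    def test_pairing_gaps_and_bounds(self, cfg6, truth6, lib6):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq, implants = generate_positive(cfg6, truth6, lib6, rng)
            assert len(seq) == cfg6.seq_length
            k = len({i.pair_id for i in implants})
            assert cfg6.pairs_per_positive[0] <= k <= cfg6.pairs_per_positive[1]
            for g in _gaps(implants):
                assert cfg6.pair_gap[0] <= g <= cfg6.pair_gap[1]
            spans = sorted((i.start, i.end) for i in implants)
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                assert b1 <= a2  # non-overlapping
            assert all(0 <= i.start and i.end <= cfg6.seq_length
                       for i in implants)

    def test_sites_written_into_sequence(self, cfg6, truth6, lib6):
        seq, implants = generate_positive(cfg6, truth6, lib6,
                                          np.random.default_rng(8))
        for imp in implants:
            assert seq[imp.start:imp.end] == imp.site


class TestNegatives:
    def test_separation_count_and_pool(self, cfg6, truth6, lib6):
        rng = np.random.default_rng(4)
        for _ in range(20):
            seq, implants = generate_negative(cfg6, truth6, lib6, rng)
            assert 1 <= len(implants) <= 3
            assert {i.motif_name for i in implants} <= truth6.motif_pool
            assert all(i.pair_id is None for i in implants)
            spans = sorted((i.start, i.end) for i in implants)
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                assert a2 - b1 >= cfg6.neg_min_separation

    def test_small_pool_clamps_count(self, lib6):
        sub = ma.MotifLibrary(list(lib6.motifs[:2]))
        truth = GroundTruth({tuple(sorted(sub.names))}, set(sub.names))
        cfg = ma.SimulationConfig(n_sequences=10, seq_length=150, n_motifs=2,
                                  n_pairs=1, pairs_per_positive=(1, 1))
        _, implants = generate_negative(cfg, truth, sub,
                                        np.random.default_rng(0))
        assert 1 <= len(implants) <= 2


class TestDataset:
    def test_balance_and_shapes(self, tiny_dataset):
        ds, truth, lib, cfg = tiny_dataset
        assert len(ds) == cfg.n_sequences
        assert ds.labels.sum() == cfg.n_sequences // 2
        assert ds.seq_length == cfg.seq_length
        assert len(truth.pairs) == cfg.n_pairs

    def test_implanted_sites_pass_half_max(self, tiny_dataset):
        ds, truth, lib, cfg = tiny_dataset
        for implants in ds.implants[:100]:
            for imp in implants:
                pwm = lib[imp.motif_name]
                site = imp.site if imp.strand == "+" else \
                    ma.simulate.reverse_complement(imp.site)
                assert score_site(pwm, site) >= 0.5 * pwm.max_score

    def test_byte_identical_with_fixed_seed(self, lib6, cfg6):
        a, _ = ma.generate_dataset(cfg6, lib6)
        b, _ = ma.generate_dataset(cfg6, lib6)
        assert a.sequences == b.sequences
        assert np.array_equal(a.labels, b.labels)

    def test_presets_match_protocol(self):
        d60 = preset("data60")
        assert (d60.n_motifs, d60.n_pairs) == (25, 60)
        assert (d60.n_sequences, d60.seq_length) == (60_000, 300)
        assert d60.pair_gap == (8, 15)
        d40, d80 = preset("data40"), preset("data80")
        assert (d40.n_motifs, d40.n_pairs) == (20, 40)
        assert (d80.n_motifs, d80.n_pairs) == (30, 80)
        long = preset("long")
        assert (long.seq_length, long.n_motifs, long.n_pairs) == (1500, 40, 80)
        assert long.pairs_per_positive == (3, 5)
        assert long.pair_gap == (8, 80)


class TestSplit:
    def test_sizes_and_partition(self, tiny_dataset):
        ds, *_ = tiny_dataset
        tr, va, te = ma.split_dataset(ds, rng=1)
        assert (len(tr), len(va), len(te)) == (320, 40, 40)
        assert sorted(tr.ids + va.ids + te.ids) == sorted(ds.ids)

    def test_stratified_balance(self, tiny_dataset):
        ds, *_ = tiny_dataset
        tr, va, te = ma.split_dataset(ds, rng=2)
        for part in (tr, va, te):
            assert abs(part.labels.mean() - 0.5) <= 0.01

    def test_deterministic(self, tiny_dataset):
        ds, *_ = tiny_dataset
        a = ma.split_dataset(ds, rng=3)
        b = ma.split_dataset(ds, rng=3)
        assert a[0].ids == b[0].ids

    def test_bad_ratios_error(self, tiny_dataset):
        ds, *_ = tiny_dataset
        with pytest.raises(ValueError):
            ma.split_dataset(ds, ratios=(0.7, 0.2, 0.2))


def test_write_read_round_trip(tiny_dataset, tmp_path):
    ds, truth, *_ = tiny_dataset
    ma.write_dataset(ds, tmp_path, truth)
    back, truth2 = ma.read_dataset(tmp_path)
    assert back.ids == ds.ids
    assert back.sequences == ds.sequences
    assert np.array_equal(back.labels, ds.labels)
    assert truth2.pairs == truth.pairs
    orig = [(i.motif_name, i.start, i.pair_id) for i in ds.implants[0]]
    load = [(i.motif_name, i.start, i.pair_id) for i in back.implants[0]]
    assert sorted(orig, key=str) == sorted(load, key=str)
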