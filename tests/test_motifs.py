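import math

import numpy as np
import pytest

from motifattn.motifs import (PWM, MotifLibrary, MotifParseError,
                              cluster_motifs, filter_to_pwm, match_pwms,
                              random_library, read_motifs, reverse_complement,
                              sample_site, score_site, write_motifs)

UNIFORM = np.full((4, 4), 0.25)


def sharp_pwm(name, consensus, p=0.97):
    base = "ACGT"
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, base.index(b)] = p
    return PWM(name, mat)


class TestPWM:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            PWM("bad", np.array([[0.5, 0.5, 0.1, 0.1]] * 4))  # sums != 1
        with pytest.raises(ValueError):
            PWM("short", UNIFORM[:3])  # length < 4
        with pytest.raises(ValueError):
            PWM("neg", np.array([[1.2, -0.2, 0, 0]] * 4))

    def test_consensus_and_rc(self):
        p = sharp_pwm("x", "ACGT")
        assert p.consensus == "ACGT"
        assert p.reverse_complement().consensus == reverse_complement("ACGT")


class TestIO:
    def test_meme_round_trip(self, small_library, tmp_path):
        path = tmp_path / "lib.meme"
        write_motifs(small_library, path)
        back = read_motifs(path, "meme")
        assert back.names == small_library.names
        for a, b in zip(small_library, back):
            np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-4)

    def test_many_motif_round_trip_count(self, tmp_path):
        # block count in the written file matches the library size
        rng = np.random.default_rng(0)
        mats = rng.dirichlet(np.ones(4), size=(505, 6))
        lib = MotifLibrary([PWM(f"m{i}", mats[i]) for i in range(505)])
        path = tmp_path / "big.meme"
        write_motifs(lib, path)
        assert path.read_text().count("MOTIF ") == 505
        assert len(read_motifs(path, "meme")) == 505

    def test_jaspar_pseudocount(self, tmp_path):
        path = tmp_path / "lib.jaspar"
        path.write_text(">M1 tf1\n"
                        "A [ 10 10 0 0 ]\n"
                        "C [ 0 0 10 0 ]\n"
                        "G [ 0 0 0 10 ]\n"
                        "T [ 0 0 0 0 ]\n")
        lib = read_motifs(path, "jaspar")
        # counts column (10,0,0,0), pseudocount 0.25 per cell
        np.testing.assert_allclose(
            lib["tf1"].matrix[0],
            [10.25 / 11, 0.25 / 11, 0.25 / 11, 0.25 / 11])

    def test_format_sniffing(self, small_library, tmp_path):
        path = tmp_path / "x.meme"
        write_motifs(small_library, path)
        assert len(read_motifs(path)) == len(small_library)

    def test_empty_file_warns(self, tmp_path, caplog):
        path = tmp_path / "empty.meme"
        path.write_text("")
        with caplog.at_level("WARNING"):
            lib = read_motifs(path, "meme")
        assert len(lib) == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_malformed_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text("MEME version 4\n\nMOTIF broken\nnot a matrix\n")
        with pytest.raises(MotifParseError):
            read_motifs(path, "meme")

    def test_duplicate_names_rejected(self, tmp_path):
        lib = MotifLibrary([sharp_pwm("a", "ACGT")])
        path = tmp_path / "dup.meme"
        write_motifs(lib, path)
        text = path.read_text()
        block = text[text.index("MOTIF a"):]
        path.write_text(text + "\n" + block)
        with pytest.raises(MotifParseError):
            read_motifs(path, "meme")


class TestScoring:
    def test_uniform_pwm_scores_zero(self):
        p = PWM("u", UNIFORM)
        assert score_site(p, "ACGT") == pytest.approx(0.0)

    def test_consensus_attains_max_score(self, small_library):
        for p in small_library:
            assert score_site(p, p.consensus) == pytest.approx(p.max_score)

    def test_two_column_arithmetic(self):
        # direct oracle: 2 * log2(0.97 / 0.25)
        mat = np.array([[0.97, 0.01, 0.01, 0.01]] * 4)
        p = PWM("s", mat)
        expected = 4 * math.log2(0.97 / 0.25)
        assert score_site(p, "AAAA") == pytest.approx(expected, abs=1e-6)

    def test_any_substitution_lowers_score(self, small_library):
        p = small_library[0]
        best = score_site(p, p.consensus)
        for i in range(len(p)):
            for b in "ACGT":
                if b == p.consensus[i]:
                    continue
                site = p.consensus[:i] + b + p.consensus[i + 1:]
                assert score_site(p, site) < best

    def test_errors(self):
        p = PWM("u", UNIFORM)
        with pytest.raises(ValueError):
            score_site(p, "ACG")
        with pytest.raises(ValueError):
            score_site(p, "ACGX")


class TestSampling:
    def test_one_hot_pwm_always_consensus(self, rng):
        mat = np.zeros((5, 4))
        mat[:, 1] = 1.0
        p = PWM("c", mat)
        assert sample_site(p, rng) == "CCCCC"

    @pytest.mark.parametrize("seed", range(5))
    def test_half_max_constraint(self, small_library, seed):
        rng = np.random.default_rng(seed)
        for p in small_library:
            site = sample_site(p, rng)
            assert score_site(p, site) >= 0.5 * p.max_score

    def test_deterministic_given_seed(self, small_library):
        a = sample_site(small_library[0], np.random.default_rng(9))
        b = sample_site(small_library[0], np.random.default_rng(9))
        assert a == b


class TestFilterAnnotation:
    def test_constant_sites_give_sharp_pwm(self):
        p = filter_to_pwm(["ACGT"] * 10)
        assert p is not None
        assert p.consensus == "ACGT"
        assert p.matrix.max(axis=1).min() > 0.9

    def test_site_frequencies(self):
        p = filter_to_pwm(["AAAA", "AAAT"] * 5, pseudocount=0.0)
        np.testing.assert_allclose(p.matrix[3], [0.5, 0, 0, 0.5])

    def test_too_few_sites_returns_none(self):
        assert filter_to_pwm(["ACGTA"] * 5, min_sites=10) is None

    def test_self_match(self, small_library):
        ann = match_pwms(small_library[0], small_library)
        assert ann.motif_name == small_library[0].name
        assert ann.match_score == pytest.approx(1.0)
        assert ann.match_offset == 0

    def test_reverse_complement_match(self, small_library):
        q = small_library[1].reverse_complement()
        q.name = "rc"
        ann = match_pwms(q, small_library)
        assert ann.motif_name == small_library[1].name
        assert ann.orientation == "-"

    def test_uniform_query_below_threshold(self, small_library):
        q = PWM("flat", np.full((8, 4), 0.25))
        ann = match_pwms(q, small_library)
        assert ann.motif_name is None

    @pytest.mark.parametrize("seed", range(3))
    def test_stable_under_column_noise(self, small_library, seed):
        rng = np.random.default_rng(seed)
        src = small_library[2]
        noisy = src.matrix + rng.uniform(-0.05, 0.05, src.matrix.shape)
        noisy = np.clip(noisy, 1e-6, None)
        noisy /= noisy.sum(axis=1, keepdims=True)
        ann = match_pwms(PWM("noisy", noisy), small_library)
        assert ann.motif_name == src.name

    def test_short_query_errors(self, small_library):
        with pytest.raises(ValueError):
            match_pwms(PWM("q", UNIFORM), small_library, min_overlap=5)


class TestClustering:
    def test_dissimilar_library_identity(self, small_library):
        out = cluster_motifs(small_library, 0.8)
        assert out.names == small_library.names

    def test_duplicate_absorbed(self, small_library):
        dup = PWM("dup", small_library[0].matrix.copy())
        lib = MotifLibrary(list(small_library.motifs) + [dup])
        out = cluster_motifs(lib, 0.8)
        assert len(out) == len(small_library)

    def test_two_identical_triples(self):
        a, b = sharp_pwm("a", "ACGTAC"), sharp_pwm("b", "TTGACA")
        lib = MotifLibrary([
            PWM("a1", a.matrix), PWM("a2", a.matrix), PWM("a3", a.matrix),
            PWM("b1", b.matrix), PWM("b2", b.matrix), PWM("b3", b.matrix)])
        out = cluster_motifs(lib, 0.9)
        assert len(out) == 2

    def test_cluster_count_monotone_in_threshold(self, rng):
        lib = random_library(8, rng, max_similarity=0.9)
        counts = [len(cluster_motifs(lib, t)) for t in (0.5, 0.7, 0.9)]
        assert counts == sorted(counts)


def test_random_library_valid_and_distinct(rng):
    lib = random_library(10, rng)
    assert len({m.name for m in lib}) == 10
    for m in lib:
        np.testing.assert_allclose(m.matrix.sum(axis=1), 1.0, atol=1e-9)


class TestTomTomAdapter:
    def test_parse_synthetic_tomtom_output(self, small_library, tmp_path):
        # synthetic TomTom -text output covering two of the queries
        path = tmp_path / "tomtom.tsv"
        path.write_text(
            "Query_ID\tTarget_ID\tOptimal_offset\tp-value\tE-value\t"
            "q-value\tOverlap\tQuery_consensus\tTarget_consensus\t"
            "Orientation\n"
            f"{small_library[0].name}\tMA0001\t1\t1e-8\t1e-5\t1e-4\t8\tX\tY\t+\n"
            f"{small_library[0].name}\tMA0002\t0\t1e-3\t1.0\t0.2\t8\tX\tY\t-\n"
            f"{small_library[2].name}\tMA0003\t-2\t1e-5\t1e-2\t1e-2\t6\tX\tY\t-\n")
        from motifattn.motifs import parse_tomtom_output
        anns = parse_tomtom_output(path, small_library)
        assert anns[0].motif_name == "MA0001"  # smallest q wins
        assert anns[0].match_offset == 1
        assert anns[2].motif_name == "MA0003"
        assert anns[2].orientation == "-"
        assert anns[1].motif_name is None  # query absent from output

    def test_missing_binary_raises(self, small_library, tmp_path):
        from motifattn.motifs import tomtom_annotate
        with pytest.raises(FileNotFoundError):
            tomtom_annotate(small_library, tmp_path / "t.meme",
                            tomtom_executable="definitely-not-a-tool")
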