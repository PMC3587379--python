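"""K-mer composition profiles, hexamer Z-scores and over-represented oligos."""

import numpy as np
import pandas as pd
import pytest

from promin.kmer_features import (
    BackgroundModel,
    all_kmers,
    cluster_profiles,
    count_overlapping,
    hexamer_zscores,
    kmer_rate_profile,
    overrep_oligos,
    top_hexamers,
)
from promin.seqio import PromoterRecord

from conftest import random_dna


class TestCounting:
    def test_overlapping_occurrences(self):
        assert count_overlapping("AAAA", "AA") == 3
        assert count_overlapping("ACACAC", "ACA") == 2
        assert count_overlapping("ACGT", "TT") == 0


class TestBackgroundModel:
    def test_order0_product(self):
        bg = BackgroundModel.from_base_probs([0.1, 0.2, 0.3, 0.4])
        assert bg.prob("A") == pytest.approx(0.1)
        assert bg.prob("ACG") == pytest.approx(0.1 * 0.2 * 0.3)

    def test_fit_matches_empirical_frequencies(self):
        bg = BackgroundModel.fit(["AACC"], order=0)
        assert bg.prob("A") == pytest.approx(0.5)
        assert bg.prob("C") == pytest.approx(0.5)
        assert bg.prob("G") == pytest.approx(0.0)

    def test_order1_transitions(self):
        # "ACACAC": dimers AC x3, CA x2 -> P(C|A)=1, P(A|C)=1
        bg = BackgroundModel.fit(["ACACAC"], order=1)
        assert bg.prob("ACAC") == pytest.approx(bg.prob("A"))
        assert bg.prob("AA") == pytest.approx(0.0)

    def test_order_bounds(self):
        with pytest.raises(ValueError):
            BackgroundModel.fit(["ACGT"], order=3)


class TestRateProfile:
    def test_poly_a_mononucleotides(self):
        rec = PromoterRecord("r", "A" * 50, 25)
        prof = kmer_rate_profile([rec], k=1)
        assert np.allclose(prof.profile("A"), 1.0)
        assert np.allclose(prof.profile("C"), 0.0)

    def test_dimer_enumeration(self):
        # window "ACGT": overlapping dimers AC, CG, GT each once of 3
        prof = kmer_rate_profile(["ACGTACGT"], k=2, window=4)
        for d in ("AC", "CG", "GT"):
            assert prof.profile(d)[0] == pytest.approx(1 / 3)
        assert prof.profile("TA")[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_rates_sum_to_one(self, k, rng):
        recs = [PromoterRecord("r", random_dna(rng, 60), 30)]
        prof = kmer_rate_profile(recs, k=k)
        assert np.allclose(prof.rates.sum(axis=1), 1.0)

    def test_window_smaller_than_k(self):
        with pytest.raises(ValueError):
            kmer_rate_profile(["ACGTACGT"], k=3, window=2)


class TestClusterProfiles:
    def test_anchors_recover_themselves(self, rng):
        profiles = {
            "A": np.sin(np.linspace(0, 3, 50)),
            "G": np.cos(np.linspace(0, 3, 50)),
        }
        clusters = cluster_profiles(profiles)
        assert "A" in clusters.group_A and "G" in clusters.group_G

    def test_noisy_profiles_recover_anchor(self, rng):
        base_a = np.sin(np.linspace(0, 3, 80))
        base_g = np.cos(np.linspace(0, 3, 80))
        profiles = {"A": base_a, "G": base_g}
        truth = {}
        for i, kmer in enumerate(all_kmers(2) + all_kmers(3)):
            anchor = base_a if i % 2 == 0 else base_g
            truth[kmer] = "A" if i % 2 == 0 else "G"
            profiles[kmer] = anchor + rng.normal(0, 0.1, size=80)
        clusters = cluster_profiles(profiles)
        correct = sum(
            (kmer in clusters.group_A) == (truth[kmer] == "A")
            for kmer in truth
        )
        assert correct / len(truth) >= 0.95

    def test_constant_profile_assigned_by_gc(self):
        profiles = {
            "A": np.sin(np.linspace(0, 3, 30)),
            "G": np.cos(np.linspace(0, 3, 30)),
            "GC": np.ones(30),
        }
        with pytest.warns(UserWarning, match="constant"):
            clusters = cluster_profiles(profiles)
        assert "GC" in clusters.group_G


class TestHexamerZ:
    def test_brute_force_recount(self, rng):
        """Pooled counts and z agree with a naive per-window recount."""
        bg = BackgroundModel.from_base_probs([0.25] * 4)
        wins = [random_dna(rng, 200) for _ in range(5)]
        stats = hexamer_zscores(wins, bg)
        N = sum(len(w) - 5 for w in wins)
        for hexamer in rng.choice(all_kmers(6), size=30, replace=False):
            n = sum(count_overlapping(w, hexamer) for w in wins)
            assert stats.loc[hexamer, "n"] == n
            p = 0.25 ** 6
            z = (n - N * p) / np.sqrt(N * p * (1 - p))
            assert stats.loc[hexamer, "z"] == pytest.approx(z, abs=1e-9)

    def test_absent_hexamer_negative_z(self):
        bg = BackgroundModel.from_base_probs([0.25] * 4)
        stats = hexamer_zscores(["ACACACACACAC"], bg)
        assert stats.loc["TTTTTT", "z"] < 0

    def test_zero_probability_sentinel(self):
        bg = BackgroundModel.from_base_probs([0.5, 0.5, 0.0, 0.0])
        stats = hexamer_zscores(["AAGAAAAAAA"], bg)
        assert stats.loc["GGGGGG", "z"] == 0.0          # p=0, n=0
        assert np.isinf(stats.loc["AAGAAA", "z"])       # p=0, n>0
        assert stats.loc["AAGAAA", "p_zero"]


class TestTopHexamers:
    def _stats(self, zmap):
        hexamers = all_kmers(6)
        z = np.zeros(len(hexamers))
        for h, v in zmap.items():
            z[hexamers.index(h)] = v
        return pd.DataFrame({"z": z}, index=pd.Index(hexamers, name="hexamer"))

    def test_planted_ranks_first(self):
        stats = self._stats({"TATAAA": 20.0})
        assert top_hexamers(stats, n=1) == ["TATAAA"]

    def test_tie_breaks_lexicographic(self):
        stats = self._stats({"TTTTTT": 5.0, "AAAAAA": 5.0})
        assert top_hexamers(stats, n=2) == ["AAAAAA", "TTTTTT"]

    def test_n_zero_and_overflow(self):
        stats = self._stats({})
        assert top_hexamers(stats, n=0) == []
        with pytest.raises(ValueError):
            top_hexamers(stats.iloc[:10], n=11)

    def test_stable_under_input_permutation(self, rng):
        stats = self._stats({"CCCCCC": 9.0, "GGGGGG": 7.0, "ACGTAC": 8.0})
        shuffled = stats.sample(frac=1.0, random_state=1)
        assert top_hexamers(stats, 5) == top_hexamers(shuffled, 5)


class TestOverrepOligos:
    def test_planted_tandem_10mer(self):
        bg = BackgroundModel.from_base_probs([0.7, 0.1, 0.1, 0.1])
        word = "GCGTTCGGCT"  # rare under the A-rich background
        region = word * 50
        df = overrep_oligos([region], bg, kmin=6, kmax=12)
        assert word in set(df["oligo"])
        assert df.set_index("oligo").loc[word, "z"] > 5

    def test_null_background_near_empty(self, rng):
        """Background-matched regions yield (almost) no reported oligos in
        the regime where expected counts are not minuscule (k=6, 20 kb)."""
        probs = [0.25] * 4
        bg = BackgroundModel.from_base_probs(probs)
        regions = [random_dna(rng, 2000) for _ in range(10)]
        df = overrep_oligos(regions, bg, kmin=6, kmax=6)
        assert len(df) <= 3

    def test_infinite_threshold_empty(self, rng):
        bg = BackgroundModel.from_base_probs([0.25] * 4)
        df = overrep_oligos([random_dna(rng, 200)], bg, zthresh=np.inf)
        assert len(df) == 0

    def test_bad_k_range(self):
        bg = BackgroundModel.from_base_probs([0.25] * 4)
        with pytest.raises(ValueError):
            overrep_oligos(["ACGT"], bg, kmin=8, kmax=6)
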