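import numpy as np
import pandas as pd
import pytest

from metox.io_data import MetSite, ProteinRecord
from metox.seqenv import (
    OFFSETS,
    FreqMatrix,
    aa_aggregate_scores,
    env_frequencies,
    expected_outside,
    interval_counts,
    pair_resistant_sites,
    zscore_matrix,
)


def _protein(seq, pid="P1"):
    return ProteinRecord(id=pid, seq=seq)


def _site(pid, pos, oxidized=True):
    return MetSite(protein_id=pid, pos=pos, oxidized=oxidized)


class TestEnvFrequencies:
    def test_all_alanine_window(self):
        protein = _protein("A" * 10 + "M" + "A" * 10)
        fm = env_frequencies([_site("P1", 11)], [protein])
        assert fm.n == 1
        assert np.allclose(fm.f.loc["A"], 1.0)
        assert np.allclose(fm.f.drop(index="A"), 0.0)

    def test_truncated_window_excluded(self):
        protein = _protein("AAAA" + "M" + "A" * 25)  # only 4 N-terminal neighbours
        with pytest.raises(ValueError):
            env_frequencies([_site("P1", 5)], [protein])

    def test_two_sites_split_frequencies(self):
        pa = _protein("A" * 10 + "M" + "A" * 10, "PA")
        pc = _protein("C" * 10 + "M" + "C" * 10, "PC")
        fm = env_frequencies([_site("PA", 11), _site("PC", 11)], [pa, pc])
        assert np.allclose(fm.f.loc["A"], 0.5)
        assert np.allclose(fm.f.loc["C"], 0.5)

    def test_columns_sum_to_one(self, toy_proteome):
        proteome, sites = toy_proteome
        fm = env_frequencies([s for s in sites if s.oxidized], proteome)
        assert np.allclose(fm.f.sum(axis=0), 1.0, atol=1e-12)


class TestPairing:
    def test_single_eligible_partner_always_chosen(self):
        seq = "A" * 10 + "M" + "A" * 10 + "M" + "A" * 10
        protein = _protein(seq)
        ox = [_site("P1", 11, True)]
        for seed in range(5):
            kept, partners = pair_resistant_sites(ox, [protein], seed=seed)
            assert [s.pos for s in kept] == [11]
            assert [s.pos for s in partners] == [22]

    def test_no_partner_drops_pair(self):
        protein = _protein("A" * 10 + "M" + "A" * 10)
        kept, partners = pair_resistant_sites([_site("P1", 11)], [protein], seed=0)
        assert kept == [] and partners == []

    def test_deterministic_under_seed(self, toy_proteome):
        proteome, sites = toy_proteome
        ox = [s for s in sites if s.oxidized]
        a = pair_resistant_sites(ox, proteome, seed=4)
        b = pair_resistant_sites(ox, proteome, seed=4)
        assert a == b

    def test_partners_are_unique_resistant_mets(self, toy_proteome):
        proteome, sites = toy_proteome
        ox = [s for s in sites if s.oxidized]
        kept, partners = pair_resistant_sites(ox, proteome, seed=1)
        keys = [(s.protein_id, s.pos) for s in partners]
        assert len(keys) == len(set(keys))
        assert all(not s.oxidized for s in partners)


def _uniform_matrix(values: np.ndarray, n: int) -> FreqMatrix:
    from metox.io_data import CANONICAL_AA

    f = pd.DataFrame(values, index=list(CANONICAL_AA), columns=list(OFFSETS))
    return FreqMatrix(f=f, n=n)


class TestZScore:
    def test_identical_matrices_give_zero(self):
        f = np.full((20, 20), 0.05)
        zm = zscore_matrix(_uniform_matrix(f, 100), _uniform_matrix(f, 100))
        assert np.allclose(zm.z, 0.0)

    def test_hand_computed_value(self):
        # f_ox = 0.5, f_res = 0.3, n = 100 -> 0.2 / sqrt(0.46/100)
        fo = np.full((20, 20), 0.5)
        fr = np.full((20, 20), 0.3)
        zm = zscore_matrix(_uniform_matrix(fo, 100), _uniform_matrix(fr, 100))
        assert zm.z.iloc[0, 0] == pytest.approx(0.2 / np.sqrt(0.46 / 100))
        assert zm.z.iloc[0, 0] == pytest.approx(2.9488, abs=1e-3)

    def test_absent_in_both_defined_as_zero(self):
        fo = np.full((20, 20), 0.5)
        fr = np.full((20, 20), 0.5)
        fo[3, :] = 0.0
        fr[3, :] = 0.0
        zm = zscore_matrix(_uniform_matrix(fo, 50), _uniform_matrix(fr, 50))
        assert np.allclose(zm.z.iloc[3], 0.0)

    def test_mismatched_counts_rejected(self):
        f = np.full((20, 20), 0.05)
        with pytest.raises(ValueError):
            zscore_matrix(_uniform_matrix(f, 100), _uniform_matrix(f, 99))

    def test_antisymmetry_under_swap(self, rng):
        a = rng.random((20, 20)) * 0.5
        b = rng.random((20, 20)) * 0.5
        z1 = zscore_matrix(_uniform_matrix(a, 200), _uniform_matrix(b, 200))
        z2 = zscore_matrix(_uniform_matrix(b, 200), _uniform_matrix(a, 200))
        assert np.allclose(z1.z.to_numpy(), -z2.z.to_numpy())


class TestIntervalDiagnostics:
    def test_all_zero_matrix(self):
        zm = zscore_matrix(
            _uniform_matrix(np.full((20, 20), 0.05), 10),
            _uniform_matrix(np.full((20, 20), 0.05), 10),
        )
        counts = interval_counts(zm, (2.0,))
        assert counts[2.0]["outside"] == 0

    def test_single_extreme_entry(self):
        fo = np.full((20, 20), 0.05)
        fr = fo.copy()
        fo[0, 0] = 0.9  # one strongly enriched cell
        zm = zscore_matrix(_uniform_matrix(fo, 500), _uniform_matrix(fr, 500))
        counts = interval_counts(zm, (7.0,))
        assert counts[7.0]["outside"] == 1
        assert counts[7.0]["fraction_negative"] == 0.0

    def test_expected_outside_pm3_rounds_to_one(self):
        assert round(expected_outside(3.0)) == 1
        assert expected_outside(2.0) < 18.3


class TestAggregateScores:
    def test_zero_matrix(self):
        f = np.full((20, 20), 0.05)
        zm = zscore_matrix(_uniform_matrix(f, 10), _uniform_matrix(f, 10))
        assert (aa_aggregate_scores(zm) == 0).all()

    def test_single_entry(self):
        fo = np.full((20, 20), 0.05)
        fr = fo.copy()
        # push Y at offset -1 down in the oxidized environment
        fo[list("ACDEFGHIKLMNPQRSTVWY").index("Y"), list(OFFSETS).index(-1)] = 0.30
        zm = zscore_matrix(_uniform_matrix(fr, 100), _uniform_matrix(fo, 100))
        scores = aa_aggregate_scores(zm)
        assert scores["Y"] > 0
        assert (scores.drop("Y") == 0).all()

    def test_matches_brute_force_sum(self, rng):
        a = rng.random((20, 20)) * 0.4
        b = rng.random((20, 20)) * 0.4
        zm = zscore_matrix(_uniform_matrix(a, 300), _uniform_matrix(b, 300))
        brute = {
            aa: sum(abs(zm.z.at[aa, j]) for j in OFFSETS) for aa in zm.z.index
        }
        scores = aa_aggregate_scores(zm)
        for aa, val in brute.items():
            assert scores[aa] == pytest.approx(val)


def test_planted_glutamate_bias_detected(toy_proteome):
    proteome, sites = toy_proteome
    ox = [s for s in sites if s.oxidized]
    kept, partners = pair_resistant_sites(ox, proteome, seed=0)
    assert len(kept) >= 300
    zm = zscore_matrix(env_frequencies(kept, proteome), env_frequencies(partners, proteome))
    for j in (-3, -2, -1):
        assert zm.z.at["E", j] > 2.0
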