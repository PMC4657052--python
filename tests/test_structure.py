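import math

import numpy as np
import pytest

from metox.io_data import Atom, StructureModel
from metox.structure import (
    MOTIF_CUTOFF,
    dedup_chains,
    distance_histogram,
    linear_separations,
    ring_centroids,
    s_aromatic_calls,
    separation_summary,
)
from metox.synthetic import gen_toy_structure


def _phe(chain, resnum, centroid, missing=()):
    """Regular unit-radius hexagon ring at z = centroid plane."""
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    atoms = []
    for k, name in enumerate(names):
        if name in missing:
            continue
        ang = k * math.pi / 3
        atoms.append(
            Atom(chain, resnum, "PHE", name, "C",
                 centroid[0] + math.cos(ang), centroid[1] + math.sin(ang), centroid[2])
        )
    return atoms


def _trp(chain, resnum, origin):
    names = ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"]
    return [
        Atom(chain, resnum, "TRP", n, "N" if n.startswith("N") else "C",
             origin[0] + i * 0.5, origin[1], origin[2])
        for i, n in enumerate(names)
    ]


def _met_sd(chain, resnum, xyz):
    return Atom(chain, resnum, "MET", "SD", "S", *xyz)


class TestRingCentroids:
    def test_hexagon_centroid_at_centre(self):
        model = StructureModel(atoms=_phe("A", 1, (0.0, 0.0, 0.0)))
        rings = ring_centroids(model)
        assert len(rings) == 1
        assert np.allclose(rings[0].centroid, 0.0, atol=1e-12)

    def test_trp_contributes_two_rings(self):
        model = StructureModel(atoms=_trp("A", 2, (0.0, 0.0, 0.0)))
        rings = ring_centroids(model)
        assert sorted(r.label for r in rings) == ["benzene", "pyrrole"]

    def test_incomplete_ring_skipped(self, caplog):
        model = StructureModel(atoms=_phe("A", 1, (0.0, 0.0, 0.0), missing=("CZ",)))
        with caplog.at_level("WARNING"):
            rings = ring_centroids(model)
        assert rings == []
        assert "incomplete" in caplog.text


class TestMotifCalls:
    @pytest.mark.parametrize("z,expected", [(6.9, True), (7.0, True), (7.1, False)])
    def test_threshold(self, z, expected):
        model = StructureModel(atoms=[_met_sd("A", 10, (0.0, 0.0, z))] + _phe("A", 1, (0.0, 0.0, 0.0)))
        (call,) = s_aromatic_calls(model)
        assert call.nearest_distance == pytest.approx(z)
        assert call.forms_motif is expected

    def test_no_aromatics(self):
        model = StructureModel(atoms=[_met_sd("A", 1, (0.0, 0.0, 0.0))])
        (call,) = s_aromatic_calls(model)
        assert call.contacts == () and not call.forms_motif

    def test_met_without_sd_skipped(self, caplog):
        model = StructureModel(
            atoms=[Atom("A", 1, "MET", "CA", "C", 0, 0, 0)] + _phe("A", 2, (0, 0, 3))
        )
        with caplog.at_level("WARNING"):
            calls = s_aromatic_calls(model)
        assert calls == []
        assert "no resolved SD" in caplog.text

    def test_interchain_contacts_counted(self):
        model = StructureModel(atoms=[_met_sd("A", 1, (0, 0, 5.0))] + _phe("B", 1, (0, 0, 0)))
        (call,) = s_aromatic_calls(model)
        assert call.forms_motif

    def test_cutoff_monotonicity(self, toy_structure):
        lo = {c.resnum: c.forms_motif for c in s_aromatic_calls(toy_structure.model, cutoff=5.0)}
        hi = {c.resnum: c.forms_motif for c in s_aromatic_calls(toy_structure.model, cutoff=9.0)}
        for resnum, formed in lo.items():
            assert not formed or hi[resnum]

    def test_rigid_transform_invariance(self, toy_structure, rng):
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(scale=50.0, size=3)
        moved = StructureModel(
            atoms=[
                Atom(a.chain, a.resnum, a.resname, a.name, a.element,
                     *(q @ np.array(a.xyz) + t))
                for a in toy_structure.model.atoms
            ]
        )
        before = {c.resnum: (c.forms_motif, c.nearest_distance) for c in s_aromatic_calls(toy_structure.model)}
        after = {c.resnum: (c.forms_motif, c.nearest_distance) for c in s_aromatic_calls(moved)}
        assert before.keys() == after.keys()
        for resnum, (flag, dist) in before.items():
            assert after[resnum][0] == flag
            assert after[resnum][1] == pytest.approx(dist, abs=1e-8)

    def test_brute_force_distance_oracle(self):
        # recompute every SD-to-ring-mean distance with plain loops
        for seed in range(5):
            toy = gen_toy_structure(n_mets=12, motif_fraction=0.4, seed=seed)
            calls = {c.resnum: c for c in s_aromatic_calls(toy.model)}
            ring_atoms: dict[tuple[int, str], list] = {}
            for a in toy.model.atoms:
                if a.resname == "PHE" and a.name in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"):
                    ring_atoms.setdefault((a.resnum, "ring"), []).append(a.xyz)
            sds = {a.resnum: a.xyz for a in toy.model.atoms if a.name == "SD"}
            for resnum, sd in sds.items():
                best = min(
                    math.dist(sd, np.mean(coords, axis=0)) for coords in ring_atoms.values()
                )
                assert calls[resnum].nearest_distance == pytest.approx(best, abs=1e-9)
                assert calls[resnum].forms_motif == (best <= MOTIF_CUTOFF)


class TestDistanceHistogram:
    def test_single_occupied_bin(self):
        model = StructureModel(
            atoms=[_met_sd("A", 1, (0, 0, 5.0))] + _phe("A", 2, (0, 0, 0))
        )
        h = distance_histogram(s_aromatic_calls(model), bin_width=0.5)
        assert h.counts.sum() == 1
        assert h.counts[np.digitize(5.0, h.edges) - 1] == 1

    def test_empty_input(self):
        h = distance_histogram([], bin_width=0.5)
        assert h.counts.sum() == 0 and h.first_minimum is None

    def test_bimodal_minimum_between_modes(self, rng):
        # two Gaussian distance populations at 5 and 8.5 A
        atoms = []
        resnum = 0
        for mode, n in ((5.0, 150), (8.5, 150)):
            for _ in range(n):
                d = float(np.clip(rng.normal(mode, 0.35), 0.5, 19.5))
                resnum += 2
                base = resnum * 100.0
                atoms.append(_met_sd("A", resnum, (base, 0.0, d)))
                atoms.extend(_phe("A", resnum + 1, (base, 0.0, 0.0)))
        h = distance_histogram(s_aromatic_calls(StructureModel(atoms=atoms)), bin_width=0.5)
        assert h.first_minimum is not None
        assert 5.0 < h.first_minimum < 8.5

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            distance_histogram([], bin_width=0.0)


class TestDedupChains:
    def _chain(self, chain, seq3, offset=0.0):
        return [
            Atom(chain, i + 1, name, "CA", "C", float(i) + offset, offset, 0.0)
            for i, name in enumerate(seq3)
        ]

    def test_homodimer_collapses(self):
        model = StructureModel(atoms=self._chain("A", ["MET", "GLY"]) + self._chain("B", ["MET", "GLY"], 5.0))
        assert dedup_chains(model) == ["A"]

    def test_heterodimer_retained(self):
        model = StructureModel(atoms=self._chain("A", ["MET", "GLY"]) + self._chain("B", ["TRP", "GLY"], 5.0))
        assert dedup_chains(model) == ["A", "B"]

    def test_mixed(self):
        model = StructureModel(
            atoms=self._chain("A", ["MET"]) + self._chain("B", ["MET"], 3.0) + self._chain("C", ["TRP"], 6.0)
        )
        assert dedup_chains(model) == ["A", "C"]


class TestLinearSeparations:
    def test_same_chain_separation(self):
        model = StructureModel(atoms=[_met_sd("A", 10, (0, 0, 5.0))] + _phe("A", 25, (0, 0, 0)))
        pairs = linear_separations(s_aromatic_calls(model))
        assert list(pairs["separation"]) == [15]
        summary = separation_summary(pairs)
        assert summary.loc["PHE", "n"] == 1
        assert summary.loc["PHE", "median"] == 15

    def test_cross_chain_excluded(self):
        model = StructureModel(atoms=[_met_sd("A", 10, (0, 0, 5.0))] + _phe("B", 25, (0, 0, 0)))
        pairs = linear_separations(s_aromatic_calls(model))
        assert pairs.empty

    def test_trp_two_rings_one_pair(self):
        trp = _trp("A", 30, (0.0, 0.0, 0.0))
        # place SD within 7 A of both ring centroids
        model = StructureModel(atoms=[_met_sd("A", 10, (1.5, 3.0, 0.0))] + trp)
        calls = s_aromatic_calls(model)
        assert calls[0].forms_motif
        pairs = linear_separations(calls)
        assert len(pairs) == 1
        assert pairs["separation"].iloc[0] == 20
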