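"""Solvent accessibility via an internal Shrake–Rupley implementation.

Per-atom accessible surface area is estimated by placing a deterministic
quasi-uniform point set (golden-spiral lattice) on each atom's solvent-
expanded sphere (van der Waals radius + probe radius, probe 1.4 Å) and
counting the points that fall strictly outside every neighbouring atom's
expanded sphere. Heavy atoms only, matching crystal-structure practice.

Relative accessibility divides a residue's SASA by its theoretical maximum in
a Gly-X-Gly tripeptide (MET reference 224.0 Å²); residues are "exposed" at a
threshold t when relative accessibility strictly exceeds t. The analysis uses
the two extreme thresholds 5% and 20%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io_data import StructureModel, load_max_sasa_reference
from .stats import ContingencyTable2x2
from .structure import MotifCall

logger = logging.getLogger(__name__)

PROBE_RADIUS = 1.4  # Å, water
N_POINTS = 960

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.80

EXPOSURE_THRESHOLDS = (0.05, 0.20)


@dataclass(frozen=True)
class SasaRecord:
    chain: str
    resnum: int
    resname: str
    sasa: float  # Å²
    rel_accessibility: float

    @property
    def exposed_at_5(self) -> bool:
        return self.rel_accessibility > 0.05

    @property
    def exposed_at_20(self) -> bool:
        return self.rel_accessibility > 0.20

    def exposed_at(self, threshold: float) -> bool:
        return self.rel_accessibility > threshold


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit-sphere points (golden-spiral lattice)."""
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    model: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
) -> list[float]:
    """Per-atom accessible areas (Å², heavy atoms; hydrogens get 0).

    A surface point counts as accessible when it lies strictly outside every
    neighbour's expanded sphere, so exactly coincident spheres do not occlude
    each other.
    """
    heavy = [i for i, a in enumerate(model.atoms) if a.element not in ("H", "D")]
    coords = np.array([model.atoms[i].xyz for i in heavy])
    radii = np.array(
        [VDW_RADII.get(model.atoms[i].element, DEFAULT_RADIUS) + probe for i in heavy]
    )
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    areas = [0.0] * len(model.atoms)
    if len(heavy) == 0:
        return areas
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    r_max = radii.max()
    for idx, (center, r) in enumerate(zip(coords, radii)):
        pts = center + r * unit
        neighbours = [
            j for j in tree.query_ball_point(center, r + r_max) if j != idx
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            # strict "inside" occludes; the slack keeps points lying exactly
            # on a neighbour's surface accessible despite float rounding
            accessible &= d2 >= radii[j] ** 2 - 1e-9
        areas[heavy[idx]] = 4.0 * math.pi * r * r * accessible.mean()
    return areas


def residue_sasa(
    model: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
    reference: Mapping[str, float] | None = None,
) -> list[SasaRecord]:
    """Per-residue SASA and relative accessibility for every canonical residue.

    Residue types without a reference maximum (ligands, unknowns) are skipped
    with a warning.
    """
    if reference is None:
        reference = load_max_sasa_reference()
    atom_areas = shrake_rupley_sasa(model, probe=probe, n_points=n_points)
    totals: dict[tuple[str, int, str], float] = {}
    for atom, area in zip(model.atoms, atom_areas):
        key = (atom.chain, atom.resnum, "MET" if atom.resname == "MSE" else atom.resname)
        totals[key] = totals.get(key, 0.0) + area
    records = []
    for (chain, resnum, resname), sasa in totals.items():
        if resname not in reference:
            logger.warning("no reference area for %s %s/%d; skipped", resname, chain, resnum)
            continue
        records.append(
            SasaRecord(
                chain=chain,
                resnum=resnum,
                resname=resname,
                sasa=sasa,
                rel_accessibility=relative_accessibility(sasa, resname, reference),
            )
        )
    return records


def relative_accessibility(
    sasa: float, resname: str, reference: Mapping[str, float] | None = None
) -> float:
    """SASA divided by the residue type's Gly-X-Gly theoretical maximum."""
    if reference is None:
        reference = load_max_sasa_reference()
    resname = "MET" if resname == "MSE" else resname
    if resname not in reference:
        raise KeyError(f"no maximum-SASA reference for residue {resname!r}")
    return sasa / reference[resname]


def stratify_by_exposure(
    calls: Sequence[MotifCall],
    sasa: Sequence[SasaRecord],
    oxidized: Mapping[tuple[str, int], bool],
    threshold: float,
) -> ContingencyTable2x2:
    """Oxidation-by-motif 2x2 table restricted to exposed methionines.

    Rows: oxidized yes/no; columns: forms motif yes/no. Methionines whose
    accessibility exceeds ``threshold`` (strict) are retained; calls without
    a matching SASA record or oxidation label are dropped with a log entry.
    """
    acc = {(r.chain, r.resnum): r.rel_accessibility for r in sasa}
    a = b = c = d = 0
    n_dropped = 0
    for call in calls:
        key = (call.chain, call.resnum)
        if key not in acc or key not in oxidized:
            n_dropped += 1
            continue
        if acc[key] <= threshold:
            continue
        ox, motif = oxidized[key], call.forms_motif
        if ox and motif:
            a += 1
        elif ox:
            b += 1
        elif motif:
            c += 1
        else:
            d += 1
    if n_dropped:
        logger.info("stratify_by_exposure: dropped %d unmatched methionines", n_dropped)
    if a + b + c + d == 0:
        raise ValueError(f"no methionine exceeds accessibility threshold {threshold}")
    return ContingencyTable2x2(
        a, b, c, d, row_labels=("oxidized", "not-oxidized"), col_labels=("motif", "no-motif")
    )
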