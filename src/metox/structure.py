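"""S-aromatic motif geometry.

A methionine forms an S-aromatic motif when its SD sulphur lies within 7 Å of
the geometric centre of an aromatic ring (Phe, Tyr, or either of tryptophan's
two rings). Ring centroids are unweighted means of the ring member atoms;
contacts are measured across all chains, so inter-chain motifs in oligomers
count toward motif status (they are excluded only from the primary-structure
separation summary, where no linear distance is defined).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_data import ResidueMap, StructureModel

logger = logging.getLogger(__name__)

MOTIF_CUTOFF = 7.0  # Å, first minimum of the bimodal S-to-ring distance distribution

RING_ATOMS = {
    ("PHE", "ring"): ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    ("TYR", "ring"): ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    ("TRP", "pyrrole"): ("CG", "CD1", "CD2", "NE1", "CE2"),
    ("TRP", "benzene"): ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}


@dataclass(frozen=True)
class AromaticRing:
    chain: str
    resnum: int
    resname: str  # PHE | TYR | TRP
    label: str  # ring | pyrrole | benzene
    centroid: tuple[float, float, float]
    member_atoms: tuple[str, ...]


@dataclass(frozen=True)
class MotifCall:
    """Motif status of one methionine: nearest aromatic contacts, ascending."""

    chain: str
    resnum: int
    sd: tuple[float, float, float]
    contacts: tuple[tuple[AromaticRing, float], ...]
    forms_motif: bool

    @property
    def nearest_distance(self) -> float:
        return self.contacts[0][1] if self.contacts else math.inf

    @property
    def nearest_ring(self) -> AromaticRing | None:
        return self.contacts[0][0] if self.contacts else None


def ring_centroids(model: StructureModel) -> list[AromaticRing]:
    """All aromatic ring centroids; incomplete rings are skipped with a warning."""
    by_residue: dict[tuple[str, int, str], dict[str, tuple[float, float, float]]] = {}
    for a in model.atoms:
        if a.resname in ("PHE", "TYR", "TRP"):
            by_residue.setdefault((a.chain, a.resnum, a.resname), {})[a.name] = a.xyz
    rings = []
    for (chain, resnum, resname), atoms in by_residue.items():
        for (rn, label), members in RING_ATOMS.items():
            if rn != resname:
                continue
            if not all(m in atoms for m in members):
                logger.warning(
                    "skipping incomplete %s %s ring at %s/%d", resname, label, chain, resnum
                )
                continue
            coords = np.array([atoms[m] for m in members])
            centroid = tuple(float(v) for v in coords.mean(axis=0))
            rings.append(
                AromaticRing(
                    chain=chain,
                    resnum=resnum,
                    resname=resname,
                    label=label,
                    centroid=centroid,
                    member_atoms=members,
                )
            )
    return rings


def s_aromatic_calls(
    model: StructureModel,
    cutoff: float = MOTIF_CUTOFF,
    chains: Sequence[str] | None = None,
) -> list[MotifCall]:
    """Motif call for every methionine SD atom (optionally restricted to ``chains``).

    Distances are Euclidean from the SD sulphur to every ring centroid in the
    whole structure (inter-chain contacts allowed). Methionines whose SD atom
    is not resolved are skipped with a warning.
    """
    rings = ring_centroids(model)
    centroids = np.array([r.centroid for r in rings]) if rings else np.empty((0, 3))
    calls = []
    seen_met: dict[tuple[str, int], tuple[float, float, float] | None] = {}
    for a in model.atoms:
        if a.resname not in ("MET", "MSE"):
            continue
        if chains is not None and a.chain not in chains:
            continue
        key = (a.chain, a.resnum)
        seen_met.setdefault(key, None)
        if a.name == "SD" or (a.resname == "MSE" and a.name == "SE"):
            seen_met[key] = a.xyz
    for (chain, resnum), sd in seen_met.items():
        if sd is None:
            logger.warning("methionine %s/%d has no resolved SD atom; skipped", chain, resnum)
            continue
        if len(rings):
            d = np.linalg.norm(centroids - np.array(sd), axis=1)
            order = np.argsort(d, kind="stable")
            contacts = tuple((rings[i], float(d[i])) for i in order)
        else:
            contacts = ()
        calls.append(
            MotifCall(
                chain=chain,
                resnum=resnum,
                sd=sd,
                contacts=contacts,
                forms_motif=bool(contacts) and contacts[0][1] <= cutoff,
            )
        )
    return calls


@dataclass(frozen=True)
class DistanceHistogram:
    edges: np.ndarray
    counts: np.ndarray
    first_minimum: float | None  # left edge of the first local-minimum bin


def distance_histogram(
    calls: Sequence[MotifCall], bin_width: float = 0.5, max_distance: float = 20.0
) -> DistanceHistogram:
    """Histogram of nearest-ring distances over [0, max_distance].

    Reports the location of the first local minimum between occupied regions —
    the empirical basis for the 7 Å motif threshold.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    dists = [c.nearest_distance for c in calls if math.isfinite(c.nearest_distance)]
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    counts, _ = np.histogram(dists, bins=edges)
    first_min = None
    interior = np.flatnonzero(counts > 0)
    if interior.size >= 2:
        lo, hi = interior[0], interior[-1]
        for i in range(lo + 1, hi):
            if counts[i] <= counts[i - 1] and counts[i] < counts[i + 1]:
                # a flat valley counts once: report the plateau centre
                left = i
                while left - 1 > lo and counts[left - 1] == counts[i]:
                    left -= 1
                first_min = float((edges[left] + edges[i + 1]) / 2.0)
                break
    return DistanceHistogram(edges=edges, counts=counts, first_minimum=first_min)


def dedup_chains(model: StructureModel) -> list[str]:
    """Retain one chain per identical one-letter sequence (lowest chain id wins).

    Crystal forms of homooligomers otherwise contribute the same methionines
    several times over.
    """
    groups: dict[str, str] = {}
    for chain in sorted(model.chains()):
        seq = model.chain_sequence(chain)
        groups.setdefault(seq, chain)
    return sorted(groups.values())


def linear_separations(
    calls: Sequence[MotifCall],
    residue_map: ResidueMap | None = None,
) -> pd.DataFrame:
    """Primary-structure separations |Met pos - aromatic pos| per aromatic type.

    Considers every (methionine, contacting ring within the motif cutoff) pair
    of motif-forming calls; tryptophan's two rings collapse to one pair per
    residue. Cross-chain contacts carry no linear distance and are excluded
    (logged). When ``residue_map`` is given, author numbering is translated to
    sequence numbering first (both partners must be mapped).

    Returns a DataFrame with one row per pair (resname, separation) plus
    summary access via ``.groupby``.
    """
    rows = []
    n_cross = 0
    if residue_map is not None:
        to_seq = {v: k for k, v in residue_map.pairs.items()}
    for call in calls:
        if not call.forms_motif:
            continue
        seen_partner: set[tuple[str, int]] = set()
        for ring, dist in call.contacts:
            if dist > MOTIF_CUTOFF:
                break
            partner = (ring.chain, ring.resnum)
            if partner in seen_partner:
                continue  # TRP's second ring: same residue, one pair
            seen_partner.add(partner)
            if ring.chain != call.chain:
                n_cross += 1
                continue
            met_pos, aro_pos = call.resnum, ring.resnum
            if residue_map is not None:
                m = to_seq.get((call.chain, call.resnum))
                r = to_seq.get((ring.chain, ring.resnum))
                if m is None or r is None:
                    continue
                met_pos, aro_pos = m, r
            rows.append(
                {
                    "chain": call.chain,
                    "met_resnum": call.resnum,
                    "resname": ring.resname,
                    "separation": abs(met_pos - aro_pos),
                }
            )
    if n_cross:
        logger.info("linear_separations: excluded %d cross-chain contacts", n_cross)
    return pd.DataFrame(rows, columns=["chain", "met_resnum", "resname", "separation"])


def separation_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Median/mean/sd of separations grouped by aromatic residue type."""
    if pairs.empty:
        return pd.DataFrame(columns=["n", "median", "mean", "sd"])
    g = pairs.groupby("resname")["separation"]
    return pd.DataFrame(
        {"n": g.size(), "median": g.median(), "mean": g.mean(), "sd": g.std(ddof=1)}
    )
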