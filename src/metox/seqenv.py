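"""Differential sequence environments of oxidation-prone vs -resistant methionines.

For every retained methionine the 20 flanking positions (offsets -10..-1 and
+1..+10) are tallied into a residue-by-offset relative-frequency matrix. The
environments of oxidation-prone sites are compared to those of same-protein,
randomly paired oxidation-resistant sites through the standardized difference
of two proportions,

    Z_ij = (f_ij^ox - f_ij^res) / sqrt[(f^ox(1-f^ox) + f^res(1-f^res)) / n],

which under the null of identical environments is approximately standard
normal in every cell; 0/0 is defined as 0. Positive Z_ij means residue *i* is
more frequent at offset *j* around oxidation-prone methionines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_data import CANONICAL_AA, MetSite, ProteinRecord

logger = logging.getLogger(__name__)

OFFSETS = tuple(range(-10, 0)) + tuple(range(1, 11))
WINDOW = 10


@dataclass(frozen=True)
class FreqMatrix:
    """Relative frequencies of residues at each offset around central sites.

    ``f`` is a 20x20 DataFrame (rows: canonical residues, columns: offsets);
    ``n`` the number of central sites counted. Columns sum to 1 wherever all
    windows carry a canonical residue (X is excluded from the counts).
    """

    f: pd.DataFrame
    n: int


@dataclass(frozen=True)
class ZScoreMatrix:
    z: pd.DataFrame
    n: int

    def values(self) -> np.ndarray:
        return self.z.to_numpy().ravel()


def _lookup(proteins: Sequence[ProteinRecord] | Mapping[str, ProteinRecord]) -> Mapping[str, ProteinRecord]:
    if isinstance(proteins, Mapping):
        return proteins
    return {p.id: p for p in proteins}


def has_full_window(site: MetSite, protein: ProteinRecord) -> bool:
    """True when the site has >= 10 neighbours on both sides."""
    return site.pos - WINDOW >= 1 and site.pos + WINDOW <= len(protein.seq)


def env_frequencies(
    sites: Sequence[MetSite],
    proteins: Sequence[ProteinRecord] | Mapping[str, ProteinRecord],
) -> FreqMatrix:
    """Flanking-residue frequency matrix over sites with full +/-10 windows.

    Sites with fewer than ten neighbours on either side are excluded; the
    central position (offset 0) is never counted. Unknown residues (X) are
    excluded from both numerator and denominator.
    """
    lookup = _lookup(proteins)
    counts = pd.DataFrame(0.0, index=list(CANONICAL_AA), columns=list(OFFSETS))
    denom = pd.Series(0.0, index=list(OFFSETS))
    n_sites = 0
    for site in sites:
        protein = lookup[site.protein_id]
        if not has_full_window(site, protein):
            continue
        n_sites += 1
        for j in OFFSETS:
            aa = protein.seq[site.pos - 1 + j]
            if aa == "X":
                continue
            counts.at[aa, j] += 1
            denom[j] += 1
    if n_sites == 0:
        raise ValueError("no site retains a full +/-10 window")
    f = counts.div(denom.where(denom > 0, 1.0), axis=1)
    return FreqMatrix(f=f, n=n_sites)


def pair_resistant_sites(
    oxidized: Sequence[MetSite],
    proteins: Sequence[ProteinRecord] | Mapping[str, ProteinRecord],
    seed: int = 0,
) -> tuple[list[MetSite], list[MetSite]]:
    """Pair each eligible oxidized site with a same-protein resistant methionine.

    For every oxidized site with a full window, one non-oxidized methionine of
    the same protein — itself required to have a full window — is drawn
    uniformly at random. Each resistant methionine serves as a partner at
    most once, so no flanking window enters the resistant frequency matrix
    twice (duplicated windows inflate the variance of the z statistic).
    Oxidized sites without an eligible partner are dropped (logged). Returns
    the retained oxidized sites and their partners, index-aligned.
    """
    lookup = _lookup(proteins)
    rng = np.random.default_rng(seed)
    oxidized_positions: dict[str, set[int]] = {}
    for s in oxidized:
        oxidized_positions.setdefault(s.protein_id, set()).add(s.pos)

    kept_ox: list[MetSite] = []
    partners: list[MetSite] = []
    used: dict[str, set[int]] = {}
    n_dropped = 0
    for site in oxidized:
        protein = lookup[site.protein_id]
        if not has_full_window(site, protein):
            n_dropped += 1
            continue
        candidates = [
            pos
            for pos in protein.met_positions()
            if pos not in oxidized_positions[site.protein_id]
            and pos not in used.get(site.protein_id, set())
            and has_full_window(MetSite(site.protein_id, pos, False), protein)
        ]
        if not candidates:
            n_dropped += 1
            continue
        chosen = int(candidates[rng.integers(len(candidates))])
        used.setdefault(site.protein_id, set()).add(chosen)
        kept_ox.append(site)
        partners.append(MetSite(protein_id=site.protein_id, pos=chosen, oxidized=False))
    if n_dropped:
        logger.info("pair_resistant_sites: dropped %d oxidized sites", n_dropped)
    return kept_ox, partners


def zscore_matrix(fo: FreqMatrix, fr: FreqMatrix) -> ZScoreMatrix:
    """Standardized frequency difference between two environments.

    ``fo`` is the oxidation-prone matrix, ``fr`` the resistant one; both must
    count the same number n of central sites (the pairing guarantees this).
    Cells where both frequencies vanish are set to 0.
    """
    if fo.n != fr.n:
        raise ValueError(f"site counts differ: {fo.n} != {fr.n}")
    if fo.n == 0:
        raise ValueError("empty frequency matrices")
    a = fo.f.to_numpy()
    b = fr.f.to_numpy()
    var = (a * (1 - a) + b * (1 - b)) / fo.n
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (a - b) / np.sqrt(var)
    z[(a == 0) & (b == 0)] = 0.0
    # equal non-zero frequencies: zero difference over positive variance
    z[np.isnan(z) & (a == b)] = 0.0
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite z-score encountered")
    return ZScoreMatrix(z=pd.DataFrame(z, index=fo.f.index, columns=fo.f.columns), n=fo.n)


def interval_counts(
    zm: ZScoreMatrix, bounds: Sequence[float] = (2.0, 3.0)
) -> dict[float, dict[str, float]]:
    """How many of the 400 z values fall outside [-b, +b], per half-width b.

    Also reports the fraction of those extreme values that are negative
    (under-representation near oxidation-prone sites).
    """
    z = zm.values()
    out = {}
    for b in bounds:
        extreme = z[np.abs(z) > b]
        out[float(b)] = {
            "outside": int(extreme.size),
            "fraction_negative": float(np.mean(extreme < 0)) if extreme.size else 0.0,
        }
    return out


def expected_outside(bound: float, n_cells: int = 400) -> float:
    """Expected count of |Z| > bound among n_cells independent standard normals."""
    from scipy.stats import norm

    return float(n_cells * 2.0 * norm.sf(bound))


def aa_aggregate_scores(zm: ZScoreMatrix) -> pd.Series:
    """Per-residue relevance: sum over the 20 offsets of |z|."""
    return zm.z.abs().sum(axis=1)
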