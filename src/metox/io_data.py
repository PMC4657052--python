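"""Input/output layer: sequences, site tables, structures and packaged fixtures.

Sequence positions are 1-based throughout (UniProt convention); the N-terminal
initiator methionine is position 1. PDB author residue numbering is never
assumed to coincide with sequence numbering — :func:`map_sequence_to_structure`
builds the explicit correspondence by global alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import pandas as pd
from Bio import Align, SeqIO

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine, routinely modelled in crystal structures
}


class ParseError(ValueError):
    """Malformed input file (names the offending record)."""


class MappingError(ValueError):
    """Sequence/structure correspondence could not be established."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession; the universal sequence carrier."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("protein record with empty identifier")
        if not self.seq:
            raise ParseError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - set(CANONICAL_AA + "X")
        if bad:
            raise ParseError(
                f"record {self.id!r} contains non-canonical letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.seq):
            raise IndexError(f"position {pos} outside 1..{len(self.seq)}")
        return self.seq[pos - 1]

    def met_positions(self) -> list[int]:
        return [i + 1 for i, aa in enumerate(self.seq) if aa == "M"]


@dataclass(frozen=True)
class MetSite:
    """One methionine occurrence with its redox label.

    ``pct_oxidation`` is the fraction of the site found as methionine
    sulfoxide (MetO), when quantified; ``None`` otherwise.
    """

    protein_id: str
    pos: int
    oxidized: bool
    pct_oxidation: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("site positions are 1-based")
        if self.pct_oxidation is not None and not 0.0 <= self.pct_oxidation <= 1.0:
            raise ValueError("pct_oxidation must lie in [0, 1]")


@dataclass(frozen=True)
class ReactivityRecord:
    """One methionine from the in-vitro therapeutic-protein benchmark."""

    protein_name: str
    pdb_id: str
    met_pos: int
    reactivity_class: str  # "low" | "high"

    def __post_init__(self) -> None:
        if self.reactivity_class not in ("low", "high"):
            raise ValueError("reactivity_class must be 'low' or 'high'")
        if self.met_pos < 1:
            raise ValueError("met_pos must be positive")


@dataclass
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class StructureModel:
    """Flat atom list for one model of a crystal/NMR structure."""

    atoms: list[Atom] = field(default_factory=list)
    id: str = ""

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def chain_residues(self, chain: str) -> list[tuple[int, str]]:
        """(resnum, resname) pairs of a chain, in file order, deduplicated."""
        seen: dict[tuple[int, str], None] = {}
        for a in self.atoms:
            if a.chain == chain:
                seen.setdefault((a.resnum, a.resname), None)
        return list(seen)

    def chain_sequence(self, chain: str) -> str:
        """One-letter sequence of a chain; unknown residues become X."""
        return "".join(
            THREE_TO_ONE.get(resname, "X") for _, resname in self.chain_residues(chain)
        )


@dataclass(frozen=True)
class ResidueMap:
    """Correspondence between 1-based sequence positions and structure residues.

    ``pairs`` maps sequence position -> (chain id, author residue number) for
    residues aligned as identical; positions absent from the structure are
    simply missing from the mapping.
    """

    pairs: Mapping[int, tuple[str, int]]
    identity: float

    def to_structure(self, pos: int) -> tuple[str, int] | None:
        return self.pairs.get(pos)


# ---------------------------------------------------------------------------
# sequence I/O


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and trailing ``*`` stop symbols stripped.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i : i + 60] + "\n")


def read_sites(path: str | Path) -> list[MetSite]:
    """Read a per-site oxidation table.

    TSV columns: ``protein_id  pos  oxidized  pct_oxidation`` (last one
    optional / may be empty).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "pos", "oxidized"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: site table must have columns {sorted(required)}")
    sites = []
    for row in df.itertuples(index=False):
        pct = getattr(row, "pct_oxidation", None)
        if pct is not None and pd.isna(pct):
            pct = None
        oxidized = row.oxidized
        if isinstance(oxidized, str):
            oxidized = oxidized.strip().lower() in ("1", "true", "yes", "y")
        sites.append(
            MetSite(
                protein_id=str(row.protein_id),
                pos=int(row.pos),
                oxidized=bool(oxidized),
                pct_oxidation=None if pct is None else float(pct),
            )
        )
    return sites


def write_sites(sites: Iterable[MetSite], path: str | Path) -> None:
    rows = [
        {
            "protein_id": s.protein_id,
            "pos": s.pos,
            "oxidized": int(s.oxidized),
            "pct_oxidation": s.pct_oxidation,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=["protein_id", "pos", "oxidized", "pct_oxidation"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# structure I/O


def _select_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per atom name: highest occupancy, ties -> altloc 'A'."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in residue:
        by_name.setdefault(atom.name, []).append(atom)
    kept = []
    for variants in by_name.values():
        best = min(variants, key=lambda a: (-a.occ, a.altloc or "A"))
        kept.append(best)
    return kept


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file (dialect by extension, then content sniffing).

    Only model 1 is retained; for alternate locations the highest-occupancy
    conformer wins (ties broken toward altloc 'A'). Waters are dropped.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ParseError(f"{path}: no models / ATOM records found")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if residue.name == "HOH":
                continue
            for atom in _select_altlocs(residue):
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=residue.seqid.num,
                        resname=residue.name,
                        name=atom.name,
                        element=atom.element.name.upper(),
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                    )
                )
    if not atoms:
        raise ParseError(f"{path}: structure contains no atoms")
    return StructureModel(atoms=atoms, id=path.stem)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel to PDB format (via gemmi)."""
    # gemmi copies on add_residue/add_chain, so each level is completed
    # before being inserted into its parent
    grouped: dict[str, dict[tuple[int, str], list[Atom]]] = {}
    for a in model.atoms:
        grouped.setdefault(a.chain, {}).setdefault((a.resnum, a.resname), []).append(a)
    st = gemmi.Structure()
    st.name = model.id or "MODEL"
    gm = gemmi.Model("1")
    for chain_name, residues in grouped.items():
        chain = gemmi.Chain(chain_name)
        for (resnum, resname), atoms in residues.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            res.het_flag = "A"
            for a in atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(a.x, a.y, a.z)
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# sequence <-> structure correspondence


def map_sequence_to_structure(
    protein: ProteinRecord,
    structure: StructureModel,
    chain: str,
    min_identity: float = 0.9,
) -> ResidueMap:
    """Align a sequence to a structure chain and map identical positions.

    Global alignment (match +1, mismatch -1, gap -2). Raises
    :class:`MappingError` when identity over aligned columns falls below
    ``min_identity`` — almost always a wrong chain/protein pairing.
    """
    if chain not in structure.chains():
        raise MappingError(f"chain {chain!r} not present in structure {structure.id!r}")
    chain_res = structure.chain_residues(chain)
    chain_seq = structure.chain_sequence(chain)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    alignment = aligner.align(protein.seq, chain_seq)[0]

    pairs: dict[int, tuple[str, int]] = {}
    n_aligned = 0
    n_identical = 0
    for (s_start, s_end), (c_start, c_end) in zip(*alignment.aligned):
        for offset in range(s_end - s_start):
            si = s_start + offset
            ci = c_start + offset
            n_aligned += 1
            if protein.seq[si] == chain_seq[ci]:
                n_identical += 1
                pairs[si + 1] = (chain, chain_res[ci][0])
    identity = n_identical / n_aligned if n_aligned else 0.0
    if identity < min_identity:
        raise MappingError(
            f"sequence {protein.id!r} vs chain {chain!r}: identity "
            f"{identity:.2f} < {min_identity} over {n_aligned} aligned columns"
        )
    return ResidueMap(pairs=pairs, identity=identity)


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_path(name: str) -> Path:
    return Path(str(resources.files("metox").joinpath("data", name)))


def load_table2_fixture() -> list[ReactivityRecord]:
    """The 35-methionine in-vitro reactivity benchmark (8 therapeutic proteins)."""
    df = pd.read_csv(_data_path("table2_reactivity.tsv"), sep="\t")
    return [
        ReactivityRecord(
            protein_name=row.protein_name,
            pdb_id=row.pdb_id,
            met_pos=int(row.met_pos),
            reactivity_class=row.reactivity_class,
        )
        for row in df.itertuples(index=False)
    ]


def load_table2_confusion() -> pd.DataFrame:
    """Published per-protein confusion counts for the S-aromatic reactivity rule."""
    return pd.read_csv(_data_path("table2_confusion.tsv"), sep="\t")


def load_table4_summary() -> dict:
    """Summary of the E. coli glutamine synthetase (2GLS) validation.

    Only the printed aggregate survives in the source material: 15 empirically
    characterised methionines, 13 correctly assigned by the S-aromatic rule,
    compared against a Binomial(15, 0.5) random-guessing null.
    """
    row = pd.read_csv(_data_path("table4_summary.tsv"), sep="\t").iloc[0]
    return {
        "pdb_id": row["pdb_id"],
        "protein_name": row["protein_name"],
        "n_sites": int(row["n_sites"]),
        "n_correct": int(row["n_correct"]),
        "null_p": float(row["null_p"]),
    }


def load_max_sasa_reference() -> dict[str, float]:
    """Theoretical Gly-X-Gly maximum accessible areas (Å²) per residue type."""
    df = pd.read_csv(_data_path("max_sasa_gxg.tsv"), sep="\t")
    return dict(zip(df["resname"], df["max_sasa"]))
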