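"""Macromolecular structure I/O and C-alpha level views.

Structures are read with :mod:`gemmi` from fixed-column PDB or PDBx/mmCIF
files and converted into a light in-memory representation that the rest of
the pipeline consumes.  Only the first model of multi-model files is kept
(the biological-assembly and predicted-structure files the pipeline consumes
are single-model); all chains of the deposited assembly are retained.
Chains without any amino-acid residue (ligand/water-only chains) are
excluded from residue iteration but recorded as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

from abcconform.errors import (
    EmptySelectionError,
    EmptyStructureError,
    StructureParseError,
    TransformError,
)

__all__ = [
    "AtomRecord",
    "Residue",
    "ResidueLabel",
    "Structure",
    "CoordinateSet",
    "Selection",
    "read_structure",
    "write_mmcif",
    "extract_ca",
    "apply_transform",
]


@dataclass(frozen=True)
class ResidueLabel:
    """Identity of one residue: chain id + author residue number + icode."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.residue_number}{self.insertion_code}"

    def sort_key(self) -> tuple[int, str]:
        # insertion codes sort after the uninserted residue, alphabetically
        return (self.residue_number, self.insertion_code)


@dataclass
class AtomRecord:
    """One atom: name, coordinates in Angstrom and residue context."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    position: np.ndarray  # shape (3,), Angstrom
    model_number: int = 1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")
        if not self.residue_name:
            raise ValueError("residue_name must be non-empty")


@dataclass
class Residue:
    """One residue with its atoms keyed by atom name."""

    name: str
    number: int
    insertion_code: str = ""
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    label_seq: int | None = None  # 1-based position in the polymer sequence

    @property
    def ca(self) -> np.ndarray | None:
        return self.atoms.get("CA")

    def label(self, chain_id: str) -> ResidueLabel:
        return ResidueLabel(chain_id, self.number, self.insertion_code)


@dataclass
class Structure:
    """One biological unit or predicted model as ordered protein chains."""

    entry_id: str
    chains: dict[str, list[Residue]]
    source: str = "experimental"  # "experimental" | "predicted"
    assembly_id: str | None = None
    het_chains: list[str] = field(default_factory=list)
    n_het_residues: int = 0

    def __post_init__(self) -> None:
        if not self.chains:
            raise EmptyStructureError(
                f"{self.entry_id}: structure has no protein chains"
            )
        for cid, residues in self.chains.items():
            keys = [(r.number, r.insertion_code) for r in residues]
            if keys != sorted(keys):
                raise ValueError(f"chain {cid}: residues not ordered")

    def __iter__(self) -> Iterator[tuple[str, Residue]]:
        for cid, residues in self.chains.items():
            for res in residues:
                yield cid, res

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def copy(self) -> "Structure":
        chains = {
            cid: [
                Residue(
                    r.name,
                    r.number,
                    r.insertion_code,
                    {k: v.copy() for k, v in r.atoms.items()},
                    r.label_seq,
                )
                for r in residues
            ]
            for cid, residues in self.chains.items()
        }
        return Structure(
            self.entry_id,
            chains,
            self.source,
            self.assembly_id,
            list(self.het_chains),
            self.n_het_residues,
        )


@dataclass
class CoordinateSet:
    """Ordered, labelled C-alpha coordinates (N x 3, Angstrom)."""

    labels: list[ResidueLabel]
    coords: np.ndarray
    n_skipped: int = 0  # residues without a C-alpha atom in the source

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.labels) != len(self.coords):
            raise ValueError("labels and coords must have the same length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, indices: Sequence[int]) -> "CoordinateSet":
        idx = list(indices)
        return CoordinateSet([self.labels[i] for i in idx], self.coords[idx])

    def index_of(self, label: ResidueLabel) -> int:
        return self.labels.index(label)


@dataclass
class Selection:
    """Chain / residue-range filter for :func:`extract_ca`.

    ``residue_range`` is inclusive on both ends and uses author numbering.
    """

    chain_id: str | None = None
    residue_range: tuple[int, int] | None = None

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse ``"B"`` or ``"B:10-20"`` into a selection."""
        if ":" in text:
            cid, rng = text.split(":", 1)
            lo, hi = rng.split("-", 1)
            return cls(cid or None, (int(lo), int(hi)))
        return cls(text or None, None)

    def matches(self, chain_id: str, residue: Residue) -> bool:
        if self.chain_id is not None and chain_id != self.chain_id:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not (lo <= residue.number <= hi):
                return False
        return True


def _is_amino_acid(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None:
        return info.is_amino_acid()
    # unknown residue name: treat as protein if it has a backbone
    return res.find_atom("CA", "*") is not None and res.find_atom("N", "*") is not None


def _best_altloc(res: gemmi.Residue) -> dict[str, np.ndarray]:
    """Pick one position per atom name: highest occupancy, ties by altloc letter."""
    best: dict[str, tuple[float, str, np.ndarray]] = {}
    for atom in res:
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        key = atom.name
        cand = (-float(atom.occ), atom.altloc or "", pos)
        if key not in best or cand[:2] < best[key][:2]:
            best[key] = cand
    return {name: rec[2] for name, rec in best.items()}


def read_structure(
    path: str | Path,
    format: str = "auto",
    entry_id: str | None = None,
    source: str = "experimental",
) -> Structure:
    """Read a PDB or PDBx/mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path:
        Path to the structure file.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (detect from extension/content).
    entry_id:
        Identifier recorded on the result; defaults to the file's own name
        record, falling back to the file stem.
    source:
        ``"experimental"`` or ``"predicted"``; passed through as provenance.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif format == "auto":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    st.setup_entities()  # assigns label_seq where derivable
    model = st[0]  # first model only

    chains: dict[str, list[Residue]] = {}
    het_chains: list[str] = []
    n_het = 0
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if not _is_amino_acid(res):
                n_het += 1
                continue
            icode = res.seqid.icode.strip()
            residues.append(
                Residue(
                    name=res.name,
                    number=res.seqid.num,
                    insertion_code=icode,
                    atoms=_best_altloc(res),
                    label_seq=res.label_seq if res.label_seq else None,
                )
            )
        if residues:
            residues.sort(key=lambda r: (r.number, r.insertion_code))
            if any(r.label_seq is None for r in residues):
                for i, r in enumerate(residues, start=1):
                    r.label_seq = i
            chains[chain.name] = residues
        else:
            het_chains.append(chain.name)

    if not chains:
        raise EmptyStructureError(f"{path}: zero protein residues")

    eid = entry_id or (st.name.lower() if st.name else path.stem)
    return Structure(
        entry_id=eid,
        chains=chains,
        source=source,
        het_chains=het_chains,
        n_het_residues=n_het,
    )


def write_mmcif(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as PDBx/mmCIF (atom_site category).

    The emitted file re-reads into an equivalent structure: identical
    residue labels, coordinates preserved to well below 1e-3 A.
    """
    if structure.n_residues == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = structure.entry_id
    model = gemmi.Model(1)
    for cid, residues in structure.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            if res.label_seq is not None:
                gres.label_seq = res.label_seq
            for atom_name, pos in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(atom_name[:1])
                atom.pos = gemmi.Position(*pos)
                atom.occ = 1.0
                gres.add_atom(atom)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_mmcif_document()
    doc.write_file(str(path))


def extract_ca(
    structure: Structure, selection: Selection | str | None = None
) -> CoordinateSet:
    """Collect one C-alpha position per residue, in chain then residue order.

    Residues lacking a C-alpha atom are skipped; the skip count is recorded
    on the returned :class:`CoordinateSet`.
    """
    if isinstance(selection, str):
        selection = Selection.parse(selection)
    labels: list[ResidueLabel] = []
    coords: list[np.ndarray] = []
    n_skipped = 0
    matched_any = False
    for cid, res in structure:
        if selection is not None and not selection.matches(cid, res):
            continue
        matched_any = True
        ca = res.ca
        if ca is None:
            n_skipped += 1
            continue
        labels.append(res.label(cid))
        coords.append(ca)
    if selection is not None and not matched_any:
        raise EmptySelectionError(f"selection {selection} matched no residues")
    if not labels:
        raise EmptySelectionError("no residues with C-alpha atoms")
    return CoordinateSet(labels, np.array(coords), n_skipped=n_skipped)


def _check_rotation(rotation: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise TransformError("rotation must be a 3x3 matrix")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=tol):
        raise TransformError("rotation matrix is not orthonormal")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=tol):
        raise TransformError("rotation matrix determinant is not +1")
    return rotation


def apply_transform(
    structure: Structure, rotation: np.ndarray, translation: np.ndarray
) -> Structure:
    """Return a copy with every atom position x replaced by R.x + t."""
    rotation = _check_rotation(rotation)
    translation = np.asarray(translation, dtype=float).reshape(3)
    out = structure.copy()
    for _, res in out:
        for name in res.atoms:
            res.atoms[name] = rotation @ res.atoms[name] + translation
    return out


def structure_from_coordinates(
    entry_id: str,
    chains: dict[str, CoordinateSet] | Iterable[tuple[str, CoordinateSet]],
    source: str = "predicted",
    residue_name: str = "ALA",
) -> Structure:
    """Build a C-alpha-only :class:`Structure` from labelled coordinate sets.

    Convenience constructor used by the synthetic-fixture generators; each
    coordinate label becomes one residue whose only atom is its C-alpha.
    """
    if isinstance(chains, dict):
        items = chains.items()
    else:
        items = chains
    out: dict[str, list[Residue]] = {}
    for cid, cs in items:
        residues = []
        for i, (label, xyz) in enumerate(zip(cs.labels, cs.coords), start=1):
            residues.append(
                Residue(
                    name=residue_name,
                    number=label.residue_number,
                    insertion_code=label.insertion_code,
                    atoms={"CA": np.asarray(xyz, dtype=float).copy()},
                    label_seq=i,
                )
            )
        residues.sort(key=lambda r: (r.number, r.insertion_code))
        out[cid] = residues
    return Structure(entry_id=entry_id, chains=out, source=source)
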