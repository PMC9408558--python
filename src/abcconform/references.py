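"""Reference-structure library: class templates, conformation references,
and the annotated reference NBD used for motif anchoring.

The on-disk layout is one subdirectory per structural class holding
``reference.cif``, ``inward.cif`` and ``outward.cif``, plus an ``nbd/``
directory with the reference NBD structure and an ``anchors.json`` carrying
the two anchor residue labels (Walker-A lysine, signature glycine) and
their motif provenance.  :func:`build_synthetic_library` generates a fully
synthetic library in memory — deterministic mock assemblies standing in for
curated experimental references — so the pipeline runs without downloads;
real references can be dropped into the same layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from abcconform.errors import ReferenceLibraryError
from abcconform.structure_io import (
    CoordinateSet,
    ResidueLabel,
    Structure,
    extract_ca,
    read_structure,
    write_mmcif,
)

__all__ = [
    "NbdReference",
    "ClassReference",
    "ReferenceLibrary",
    "build_synthetic_library",
    "load_library",
    "write_library",
]


@dataclass
class NbdReference:
    """Reference NBD with annotated conftor anchor residues.

    ``walker_a_k`` is the Walker-A P-loop lysine (GXXXXG**K**T, motif
    position 7) and ``signature_g`` the ABC-signature central glycine
    (LS**G**GQ, motif position 3); anchors are stored as residue labels on
    the reference, not re-derived per run.
    """

    ca: CoordinateSet
    walker_a_k: ResidueLabel
    signature_g: ResidueLabel
    provenance: str = "synthetic"

    def anchor_labels(self) -> dict[str, ResidueLabel]:
        return {"walker_a_k": self.walker_a_k, "signature_g": self.signature_g}


@dataclass
class ClassReference:
    """Reference structures of one TMD structural class."""

    class_name: str
    structure: Structure  # canonical class reference (family assignment)
    inward_ref: Structure  # bottom-open conformation reference
    outward_ref: Structure  # bottom-closed conformation reference
    tmd: CoordinateSet | None = None  # TMD-only extract for tmd_only mode
    _ca_cache: dict = field(default_factory=dict, repr=False)

    def ca(self, which: str = "structure") -> CoordinateSet:
        if which not in self._ca_cache:
            st = getattr(self, {"structure": "structure", "inward": "inward_ref",
                                "outward": "outward_ref"}[which])
            self._ca_cache[which] = extract_ca(st)
        return self._ca_cache[which]


@dataclass
class ReferenceLibrary:
    """All class references plus the anchoring NBD reference."""

    classes: dict[str, ClassReference]
    nbd_reference: NbdReference
    synthetic: bool = True

    def __post_init__(self) -> None:
        if not self.classes:
            raise ReferenceLibraryError("reference library has no classes")

    def class_names(self) -> list[str]:
        return list(self.classes)


def build_synthetic_library(
    classes: list[str] | None = None, seed: int = 0
) -> ReferenceLibrary:
    """Deterministic synthetic reference library.

    For each class the bottom-open (inward) reference plants cross-NBD
    anchor distances staggered per class in the 22-30 A range and the
    bottom-closed (outward) reference in the 9-12 A range, mimicking how
    real classes differ in opening; the inward reference doubles as the
    canonical family-assignment reference.
    """
    from abcconform.synthetic import (
        STRUCTURAL_CLASSES,
        MockSpec,
        make_class_tmd_bundle,
        make_mock_transporter,
        make_reference_nbd,
    )

    classes = classes or STRUCTURAL_CLASSES
    out: dict[str, ClassReference] = {}
    for idx, name in enumerate(classes):
        d_open = 20.0 + 2.5 * idx
        d_closed = 8.5 + 0.5 * idx
        inward, _ = make_mock_transporter(
            MockSpec(
                planted_class=name,
                planted_state="open",
                planted_distances=(d_open, d_open),
                noise_sigma=0.0,
                n_chains=2,
                seed=seed * 1000 + idx,
                entry_id=f"ref_{name}_inward",
            )
        )
        outward, _ = make_mock_transporter(
            MockSpec(
                planted_class=name,
                planted_state="closed",
                planted_distances=(d_closed, d_closed),
                noise_sigma=0.0,
                n_chains=2,
                seed=seed * 1000 + 500 + idx,
                entry_id=f"ref_{name}_outward",
            )
        )
        out[name] = ClassReference(
            class_name=name,
            structure=inward,
            inward_ref=inward,
            outward_ref=outward,
            tmd=make_class_tmd_bundle(name),
        )
    nbd_ca, anchors = make_reference_nbd()
    nbd = NbdReference(
        ca=nbd_ca,
        walker_a_k=anchors["walker_a_k"],
        signature_g=anchors["signature_g"],
        provenance="synthetic reference NBD (generated five-helix bundle)",
    )
    return ReferenceLibrary(classes=out, nbd_reference=nbd, synthetic=True)


def write_library(library: ReferenceLibrary, directory: str | Path) -> None:
    """Write a library to the standard on-disk layout (mmCIF + JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    from abcconform.structure_io import structure_from_coordinates

    manifest = {"synthetic": library.synthetic, "classes": {}}
    for name, ref in library.classes.items():
        sub = directory / name
        sub.mkdir(exist_ok=True)
        write_mmcif(ref.structure, sub / "reference.cif")
        write_mmcif(ref.inward_ref, sub / "inward.cif")
        write_mmcif(ref.outward_ref, sub / "outward.cif")
        if ref.tmd is not None:
            tmd_st = structure_from_coordinates(f"{name}_tmd", {"T": ref.tmd})
            write_mmcif(tmd_st, sub / "tmd.cif")
        manifest["classes"][name] = {
            "reference": ref.structure.entry_id,
            "inward": ref.inward_ref.entry_id,
            "outward": ref.outward_ref.entry_id,
        }
    nbd_dir = directory / "nbd"
    nbd_dir.mkdir(exist_ok=True)
    nbd_st = structure_from_coordinates("reference_nbd", {"R": library.nbd_reference.ca})
    write_mmcif(nbd_st, nbd_dir / "reference_nbd.cif")
    anchors = {
        "walker_a_k": _label_to_json(library.nbd_reference.walker_a_k),
        "signature_g": _label_to_json(library.nbd_reference.signature_g),
        "provenance": library.nbd_reference.provenance,
        "motifs": {
            "walker_a_k": "Walker A GXXXXGKT, position 7 (K)",
            "signature_g": "ABC signature LSGGQ, position 3 (G)",
        },
    }
    (nbd_dir / "anchors.json").write_text(json.dumps(anchors, indent=2))
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _label_to_json(label: ResidueLabel) -> dict:
    return {
        "chain_id": label.chain_id,
        "residue_number": label.residue_number,
        "insertion_code": label.insertion_code,
    }


def _label_from_json(obj: dict) -> ResidueLabel:
    return ResidueLabel(
        obj["chain_id"], obj["residue_number"], obj.get("insertion_code", "")
    )


def load_library(directory: str | Path) -> ReferenceLibrary:
    """Load a reference library from the standard on-disk layout."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise ReferenceLibraryError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    classes: dict[str, ClassReference] = {}
    for name in manifest.get("classes", {}):
        sub = directory / name
        try:
            structure = read_structure(sub / "reference.cif", format="mmcif")
            inward = read_structure(sub / "inward.cif", format="mmcif")
            outward = read_structure(sub / "outward.cif", format="mmcif")
        except Exception as exc:
            raise ReferenceLibraryError(f"class {name}: {exc}") from exc
        tmd = None
        if (sub / "tmd.cif").exists():
            tmd = extract_ca(read_structure(sub / "tmd.cif", format="mmcif"))
        classes[name] = ClassReference(
            class_name=name,
            structure=structure,
            inward_ref=inward,
            outward_ref=outward,
            tmd=tmd,
        )
    nbd_dir = directory / "nbd"
    anchors = json.loads((nbd_dir / "anchors.json").read_text())
    nbd_st = read_structure(nbd_dir / "reference_nbd.cif", format="mmcif")
    nbd = NbdReference(
        ca=extract_ca(nbd_st),
        walker_a_k=_label_from_json(anchors["walker_a_k"]),
        signature_g=_label_from_json(anchors["signature_g"]),
        provenance=anchors.get("provenance", "unknown"),
    )
    return ReferenceLibrary(
        classes=classes,
        nbd_reference=nbd,
        synthetic=bool(manifest.get("synthetic", False)),
    )
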