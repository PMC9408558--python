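"""Batch classification, update detection and metadata emission.

``run_batch`` drives one entry through the whole pipeline: parse domain
hits -> filter -> categorize -> functional-unit call -> family assignment
-> NBD anchor location -> conftor measurement -> conformation labels ->
output record.  Per-entry failures become flagged rows, never batch aborts,
and entries are processed in sorted order so re-runs on identical inputs
are byte-identical.

Storage is deliberately flat: a TSV of records plus mmCIF structure files
aligned to their family/conformation reference.  Update scheduling is out
of scope — :func:`detect_updates` is a pure diff of content manifests that
any scheduler can call.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from abcconform.classification import (
    ClassificationRecord,
    assign_family,
    classify_conformation_conftor,
    classify_conformation_rmsd,
    compute_conftor,
    locate_anchors,
    pair_nbds,
)
from abcconform.domain_annotation import (
    call_functional_unit,
    categorize_hits,
    filter_hits,
    load_default_catalog,
    map_hit_to_structure,
    parse_domtblout,
)
from abcconform.errors import AbcConformError
from abcconform.references import ReferenceLibrary, build_synthetic_library, load_library
from abcconform.structure_io import (
    CoordinateSet,
    Structure,
    apply_transform,
    extract_ca,
    read_structure,
    write_mmcif,
)
from abcconform.superposition import AlignmentParams, structural_align

logger = logging.getLogger("abcconform.pipeline")

__all__ = [
    "RunConfig",
    "Manifest",
    "run_batch",
    "classify_entry",
    "detect_updates",
    "align_outputs_to_references",
    "emit_metadata",
    "manifest_from_dir",
    "plot_distance_histogram",
]

STRUCTURE_SUFFIXES = (".pdb", ".pdb1", ".ent", ".cif", ".mmcif")

METADATA_COLUMNS = [
    "entry_id",
    "source",
    "class",
    "conformation",
    "conftor_ab",
    "conftor_ba",
    "rmsd_inward",
    "rmsd_outward",
    "unit_verdict",
    "flags",
    "taxonomy",
    "gene",
    "protein",
    "release_date",
]


@dataclass
class RunConfig:
    """Run parameters mirroring the CLI flags; loadable from JSON."""

    structures_dir: str
    domtblout: str
    output_dir: str
    reference_library: str | None = None  # directory; None -> synthetic library
    cutoff: float = 14.0  # conftor open/closed cutoff, Angstrom
    tm_threshold: float = 0.6  # same-class TM-score threshold
    evalue: float = 0.001  # per-domain independent E-value ceiling
    coverage: float = 0.9  # minimum HMM-span fraction of profile length
    alignment_mode: str = "whole"  # "whole" | "tmd_only"
    metadata_sidecar: str | None = None  # optional pre-fetched TSV of metadata
    write_aligned: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cutoff", "tm_threshold", "evalue", "coverage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def load_reference_library(self) -> ReferenceLibrary:
        if self.reference_library:
            return load_library(self.reference_library)
        return build_synthetic_library()


def _discover_structures(directory: Path) -> dict[str, Path]:
    files: dict[str, Path] = {}
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() in STRUCTURE_SUFFIXES:
            files[path.stem] = path
    if not files:
        raise AbcConformError(f"no structure files in {directory}")
    return files


def _load_sidecar(path: str | None) -> dict[str, dict[str, str]]:
    if not path:
        return {}
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {row["entry_id"]: dict(row) for _, row in df.iterrows()}


def classify_entry(
    entry_id: str,
    structure: Structure,
    hits: list,
    library: ReferenceLibrary,
    config: RunConfig,
    params: AlignmentParams | None = None,
) -> ClassificationRecord:
    """Classify one assembly from its structure and filtered, annotated hits."""
    rec = ClassificationRecord(entry_id=entry_id, source=structure.source)
    unit = call_functional_unit(entry_id, hits)
    rec.unit_verdict = unit.verdict
    rec.n_nbd = unit.n_nbd
    rec.n_tmd = unit.n_tmd
    if unit.verdict == "needs_review":
        rec.add_flag("needs_review")
    if unit.verdict != "functional":
        return rec

    # Pfam class hint: best-E TMD hit with a hint
    tmd_hits = sorted(
        (h for h in unit.contributing_hits if h.category == "TMD"),
        key=lambda h: h.domain_ievalue,
    )
    hint = next((h.class_hint for h in tmd_hits if h.class_hint), None)

    # --- family assignment ---
    if config.alignment_mode == "tmd_only":
        tmd_labels = []
        for h in tmd_hits:
            chain = h.target_name.rsplit("_", 1)[-1]
            mapped = map_hit_to_structure(h, structure, chain)
            tmd_labels.extend(mapped.labels)
        qca = extract_ca(structure)
        keep = [i for i, lab in enumerate(qca.labels) if lab in set(tmd_labels)]
        query = qca.subset(keep)
    else:
        query = structure
    fam = assign_family(
        query,
        library,
        mode=config.alignment_mode,
        tm_threshold=config.tm_threshold,
        class_hint=hint,
        params=params,
    )
    rec.class_name = fam.class_name
    rec.best_tm = fam.best_tm
    for flag in fam.flags:
        rec.add_flag(flag)
    if fam.class_name is None:
        rec.add_flag("unclassified")
        return rec
    if fam.class_name == "EcfT-like":
        # atypical architecture: NBDs stay associated even without ATP
        rec.add_flag("ecf_special")

    # --- NBD extraction and pairing ---
    nbd_hits = [h for h in unit.contributing_hits if h.category == "NBD"]
    nbd_sets: list[tuple[str, CoordinateSet]] = []
    for h in nbd_hits:
        chain = h.target_name.rsplit("_", 1)[-1]
        mapped = map_hit_to_structure(h, structure, chain)
        if mapped.low_coverage:
            rec.add_flag("nbd_low_coverage")
        qca = extract_ca(structure, selection=None)
        keep = [i for i, lab in enumerate(qca.labels) if lab in set(mapped.labels)]
        if keep:
            nbd_sets.append((h.target_name, qca.subset(keep)))
    if len(nbd_sets) < 2:
        rec.add_flag("nbd_extraction_failed")
        return rec
    pairs, leftover, pair_flags = pair_nbds(nbd_sets)
    for flag in pair_flags:
        rec.add_flag(flag)
    i, j = pairs[0]

    # --- anchors and conftor ---
    anchors_a = locate_anchors(nbd_sets[i][1], library.nbd_reference, params)
    anchors_b = locate_anchors(nbd_sets[j][1], library.nbd_reference, params)
    for a in (anchors_a, anchors_b):
        for flag in a.flags:
            rec.add_flag(flag)
    m = compute_conftor(nbd_sets[i][1], nbd_sets[j][1], anchors_a, anchors_b)
    rec.conftor_ab = m.distance_ab
    rec.conftor_ba = m.distance_ba
    call = classify_conformation_conftor(m, cutoff=config.cutoff)
    rec.conformation = call.state
    for flag in call.flags:
        rec.add_flag(flag)

    # --- RMSD label as corroborating evidence ---
    ref = library.classes[fam.class_name]
    try:
        rmsd_call, rmsd_in, rmsd_out = classify_conformation_rmsd(
            structure, ref.inward_ref, ref.outward_ref, params
        )
        rec.conformation_rmsd = rmsd_call.state
        rec.rmsd_inward = rmsd_in
        rec.rmsd_outward = rmsd_out
        if (
            rmsd_call.state != "unassigned"
            and call.state != "unassigned"
            and rmsd_call.state != call.state
        ):
            rec.add_flag("rmsd_conftor_disagreement")
    except AbcConformError as exc:
        rec.add_flag(f"rmsd_label_failed:{exc}")
    return rec


def run_batch(
    config: RunConfig,
    params: AlignmentParams | None = None,
    library: ReferenceLibrary | None = None,
) -> tuple[list[ClassificationRecord], Path]:
    """Run the full pipeline over a directory of structures.

    Returns the records and the path of the written metadata TSV.  Output
    is a pure function of (inputs, config): entries are processed in sorted
    order and floats are emitted at fixed precision.
    """
    structures_dir = Path(config.structures_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = _discover_structures(structures_dir)
    catalog = load_default_catalog()
    all_hits = parse_domtblout(config.domtblout)
    kept = filter_hits(all_hits, max_evalue=config.evalue, min_profile_coverage=config.coverage)
    annotated, uncataloged = categorize_hits(kept, catalog)
    if uncataloged:
        logger.warning(
            "%d hits on uncataloged profiles ignored: %s",
            len(uncataloged),
            sorted({h.profile_name for h in uncataloged}),
        )
    sidecar = _load_sidecar(config.metadata_sidecar)
    if library is None:
        library = config.load_reference_library()

    records: list[ClassificationRecord] = []
    for entry_id in sorted(files):
        logger.info("entry=%s stage=start file=%s", entry_id, files[entry_id])
        entry_hits = [
            h
            for h in annotated
            if h.target_name.rsplit("_", 1)[0] == entry_id
        ]
        try:
            structure = read_structure(files[entry_id], entry_id=entry_id)
            rec = classify_entry(entry_id, structure, entry_hits, library, config, params)
        except AbcConformError as exc:
            logger.error("entry=%s stage=failed error=%s", entry_id, exc)
            rec = ClassificationRecord(entry_id=entry_id, error=str(exc))
            rec.add_flag("entry_error")
        meta = sidecar.get(entry_id, {})
        rec.taxonomy = meta.get("taxonomy", "")
        rec.gene = meta.get("gene", "")
        rec.protein = meta.get("protein", "")
        rec.release_date = meta.get("release_date", "")
        records.append(rec)
        logger.info(
            "entry=%s stage=done class=%s conformation=%s flags=%s",
            entry_id,
            rec.class_name,
            rec.conformation,
            ",".join(rec.flags),
        )
    tsv_path = out_dir / "classification.tsv"
    emit_metadata(records, tsv_path)
    if config.write_aligned:
        align_outputs_to_references(
            records, files, library, out_dir / "aligned", params
        )
    return records, tsv_path


def _fmt(value: float | None, digits: int = 3) -> str:
    return "" if value is None else f"{value:.{digits}f}"


def emit_metadata(records: list[ClassificationRecord], path: str | Path) -> Path:
    """Write records as a UTF-8 TSV with a stable column order.

    Missing values are empty fields (never a literal placeholder); numeric
    fields are fixed to three decimals so identical runs produce identical
    bytes.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "entry_id": rec.entry_id,
                "source": rec.source,
                "class": rec.class_name or "",
                "conformation": "" if rec.conformation == "unassigned" else rec.conformation,
                "conftor_ab": _fmt(rec.conftor_ab),
                "conftor_ba": _fmt(rec.conftor_ba),
                "rmsd_inward": _fmt(rec.rmsd_inward),
                "rmsd_outward": _fmt(rec.rmsd_outward),
                "unit_verdict": rec.unit_verdict,
                "flags": ";".join(rec.flags),
                "taxonomy": rec.taxonomy,
                "gene": rec.gene,
                "protein": rec.protein,
                "release_date": rec.release_date,
            }
        )
    df = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


@dataclass
class Manifest:
    """Content manifest: entry id -> (content hash, release date)."""

    entries: dict[str, dict[str, str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.entries, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Manifest":
        return cls(entries=json.loads(Path(path).read_text()))


def manifest_from_dir(directory: str | Path, release_date: str = "") -> Manifest:
    """Hash every structure file in a directory into a manifest."""
    directory = Path(directory)
    entries = {}
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() in STRUCTURE_SUFFIXES:
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            entries[path.stem] = {"hash": digest, "release_date": release_date}
    return Manifest(entries=entries)


def detect_updates(old: Manifest, new: Manifest) -> dict[str, set[str]]:
    """Set-exact partition of entry ids into added / changed / removed."""
    old_ids = set(old.entries)
    new_ids = set(new.entries)
    changed = {
        eid
        for eid in old_ids & new_ids
        if old.entries[eid]["hash"] != new.entries[eid]["hash"]
    }
    return {
        "added": new_ids - old_ids,
        "changed": changed,
        "removed": old_ids - new_ids,
    }


def align_outputs_to_references(
    records: list[ClassificationRecord],
    files: dict[str, Path],
    library: ReferenceLibrary,
    out_dir: str | Path,
    params: AlignmentParams | None = None,
) -> list[Path]:
    """Superpose each classified structure onto its family+conformation
    reference and write the transformed structure as mmCIF.

    Records without an assigned family (or unassigned conformation) are
    skipped with a log note.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for rec in records:
        if rec.class_name is None or rec.conformation == "unassigned":
            logger.info("entry=%s stage=align skipped (unassigned)", rec.entry_id)
            continue
        ref = library.classes[rec.class_name]
        target = ref.inward_ref if rec.conformation == "open" else ref.outward_ref
        structure = read_structure(files[rec.entry_id], entry_id=rec.entry_id)
        res = structural_align(extract_ca(structure), extract_ca(target), params)
        moved = apply_transform(structure, res.rotation, res.translation)
        path = out_dir / f"{rec.entry_id}.cif"
        write_mmcif(moved, path)
        written.append(path)
    return written


def plot_distance_histogram(
    tsv_path: str | Path,
    out_path: str | Path,
    bin_width: float = 2.0,
    d_range: tuple[float, float] = (0.0, 90.0),
    cutoff: float = 14.0,
) -> Path:
    """Histogram of all conftor distances in a classification TSV.

    Both per-structure distances are pooled (each NBD pair contributes two
    composite-site distances); 2 A bins over 0-90 A with the open/closed
    cutoff marked.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.read_csv(tsv_path, sep="\t")
    values = (
        pd.concat([df["conftor_ab"], df["conftor_ba"]])
        .dropna()
        .astype(float)
        .to_numpy()
    )
    bins = np.arange(d_range[0], d_range[1] + bin_width, bin_width)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(values, bins=bins, color="#4878a8", edgecolor="white")
    ax.axvline(cutoff, color="crimson", linestyle="--", label=f"cutoff {cutoff:g} A")
    ax.set_xlabel("Walker-A to signature C-alpha distance (A)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
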