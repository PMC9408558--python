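"""Structural-family assignment and conformational-state classification.

Family assignment aligns a query against every class reference and accepts
the best TM-score if it exceeds 0.6 (same structural class); below that
the entry is unclassified.  A disagreement between the Pfam-derived class
hint and the structure-based winner is flagged rather than resolved — that
is exactly how a novel fold announces itself (a MacB Pfam hit aligning
poorly to the MacB reference is how the Bce-like class was recognized).

Conformation is classified two ways:

* ``conftor`` rule — the two cross-NBD Walker-A -> signature C-alpha
  distances; *bottom-closed* requires BOTH below the 14 A cutoff (both
  composite ATP sites formed), otherwise *bottom-open*.  Distances within
  14 +/- 2 A raise a boundary flag for visual inspection.
* RMSD rule — nearer of the bottom-open (inward) and bottom-closed
  (outward) family references.  The conftor label takes precedence when
  they disagree; the RMSD label is retained as evidence.

Anchors are located by structural alignment of each NBD against the
annotated reference NBD, never by sequence motif search: many ABC proteins
carry degenerate, non-conserved ATP-binding sites, so the motif residues
are found by where they sit in the fold, not by what they read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from abcconform.errors import AbcConformError, AlignmentError, ReferenceLibraryError
from abcconform.references import NbdReference, ReferenceLibrary
from abcconform.structure_io import (
    CoordinateSet,
    ResidueLabel,
    Structure,
    extract_ca,
)
from abcconform.superposition import (
    AlignmentParams,
    matched_rmsd,
    structural_align,
)

__all__ = [
    "FamilyAssignment",
    "AnchorResult",
    "ConftorMeasurement",
    "ConformationCall",
    "ClassificationRecord",
    "assign_family",
    "locate_anchors",
    "compute_conftor",
    "classify_conformation_conftor",
    "classify_conformation_rmsd",
    "pair_nbds",
]

TM_CLASS_THRESHOLD = 0.6
CONFTOR_CUTOFF = 14.0  # Angstrom
BOUNDARY_BAND = 2.0  # Angstrom; 14 +/- 2 flags a boundary case
LOW_ANCHOR_TM = 0.45
RMSD_TIE_TOL = 0.01  # Angstrom


@dataclass
class FamilyAssignment:
    """Outcome of TM-score family assignment for one query."""

    class_name: str | None  # None = unclassified (best TM <= threshold)
    best_tm: float
    runner_up_tm: float
    mode: str  # "whole" | "tmd_only"
    tm_by_class: dict[str, float] = field(default_factory=dict)
    class_hint: str | None = None
    flags: list[str] = field(default_factory=list)


def assign_family(
    query: Structure | CoordinateSet,
    library: ReferenceLibrary,
    mode: str = "whole",
    tm_threshold: float = TM_CLASS_THRESHOLD,
    class_hint: str | None = None,
    params: AlignmentParams | None = None,
) -> FamilyAssignment:
    """Assign the query to the best-TM structural class, if convincing.

    ``mode="whole"`` aligns the full assembly C-alpha trace against each
    class's whole reference; ``mode="tmd_only"`` aligns a TMD extract (the
    caller supplies the extracted :class:`CoordinateSet`) against each
    class's TMD template.  TM-scores are normalized by reference length.
    """
    if not library.classes:
        raise ReferenceLibraryError("empty reference library")
    if mode not in ("whole", "tmd_only"):
        raise ValueError(f"unknown mode {mode!r}")
    qca = extract_ca(query) if isinstance(query, Structure) else query

    scores: dict[str, float] = {}
    for name, ref in library.classes.items():
        if mode == "whole":
            target = ref.ca("structure")
        else:
            if ref.tmd is None:
                continue
            target = ref.tmd
        try:
            res = structural_align(qca, target, params)
            scores[name] = res.tm_score
        except AlignmentError:
            scores[name] = 0.0
    if not scores:
        raise ReferenceLibraryError(f"no references usable in mode {mode!r}")

    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_name, best_tm = ordered[0]
    runner_up = ordered[1][1] if len(ordered) > 1 else 0.0
    flags: list[str] = []
    class_name = best_name if best_tm > tm_threshold else None
    if class_hint is not None and class_name is not None and class_hint != class_name:
        flags.append("hint_structure_disagreement")
    if class_hint is not None and class_name is None:
        flags.append("hint_without_structural_support")
    return FamilyAssignment(
        class_name=class_name,
        best_tm=best_tm,
        runner_up_tm=runner_up,
        mode=mode,
        tm_by_class=scores,
        class_hint=class_hint,
        flags=flags,
    )


@dataclass
class AnchorResult:
    """Anchors located on one NBD by alignment to the reference NBD."""

    walker_a_k: ResidueLabel | None
    signature_g: ResidueLabel | None
    tm: float
    flags: list[str] = field(default_factory=list)

    @property
    def found(self) -> bool:
        return self.walker_a_k is not None and self.signature_g is not None


def locate_anchors(
    nbd_ca: CoordinateSet,
    nbd_reference: NbdReference,
    params: AlignmentParams | None = None,
) -> AnchorResult:
    """Transfer the reference anchors onto a query NBD by structure alignment.

    The anchor is the query residue paired with the reference anchor
    residue; if that reference position fell in a gap, the nearest paired
    reference position within +/- 2 residues substitutes (flagged).  An
    alignment TM below 0.45 flags low anchor quality; outright alignment
    failure returns an empty result with an error flag instead of raising,
    so one bad entry cannot abort a batch.
    """
    flags: list[str] = []
    if len(nbd_ca) < 80:
        flags.append("short_nbd")
    try:
        res = structural_align(nbd_ca, nbd_reference.ca, params)
    except AlignmentError as exc:
        return AnchorResult(None, None, 0.0, flags + [f"anchor_alignment_failed:{exc}"])
    if res.tm_score < LOW_ANCHOR_TM:
        flags.append("low_anchor_quality")
    ref_to_query = {r: q for q, r in res.paired_labels}

    def _find(ref_label: ResidueLabel, name: str) -> ResidueLabel | None:
        if ref_label in ref_to_query:
            return ref_to_query[ref_label]
        for offset in (1, -1, 2, -2):
            neighbor = ResidueLabel(
                ref_label.chain_id,
                ref_label.residue_number + offset,
                ref_label.insertion_code,
            )
            if neighbor in ref_to_query:
                flags.append(f"{name}_anchor_neighbor")
                return ref_to_query[neighbor]
        flags.append(f"{name}_anchor_not_found")
        return None

    wa = _find(nbd_reference.walker_a_k, "walker_a")
    sig = _find(nbd_reference.signature_g, "signature")
    return AnchorResult(wa, sig, res.tm_score, flags)


@dataclass
class ConftorMeasurement:
    """The two cross-NBD Walker-A -> signature C-alpha distances.

    ``distance_ab`` runs from the Walker-A anchor of NBD A to the signature
    anchor of NBD B; ``distance_ba`` the reverse.  Each composite ATP site
    contributes one distance, so every NBD pair yields two values.
    """

    distance_ab: float | None
    distance_ba: float | None
    anchors: dict[str, ResidueLabel | None]
    alignment_quality: tuple[float, float] = (1.0, 1.0)
    flags: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return self.distance_ab is not None and self.distance_ba is not None


def compute_conftor(
    nbd_a: CoordinateSet,
    nbd_b: CoordinateSet,
    anchors_a: AnchorResult,
    anchors_b: AnchorResult,
) -> ConftorMeasurement:
    """Euclidean C-alpha distances across the NBD dimer, both directions."""
    flags = []
    anchors = {
        "wa_a": anchors_a.walker_a_k,
        "sig_a": anchors_a.signature_g,
        "wa_b": anchors_b.walker_a_k,
        "sig_b": anchors_b.signature_g,
    }

    def _pos(cs: CoordinateSet, label: ResidueLabel | None) -> np.ndarray | None:
        if label is None:
            return None
        try:
            return cs.coords[cs.index_of(label)]
        except ValueError:
            return None

    wa_a = _pos(nbd_a, anchors["wa_a"])
    sig_a = _pos(nbd_a, anchors["sig_a"])
    wa_b = _pos(nbd_b, anchors["wa_b"])
    sig_b = _pos(nbd_b, anchors["sig_b"])
    d_ab = d_ba = None
    if wa_a is not None and sig_b is not None:
        d_ab = float(np.linalg.norm(wa_a - sig_b))
    if wa_b is not None and sig_a is not None:
        d_ba = float(np.linalg.norm(wa_b - sig_a))
    if d_ab is None or d_ba is None:
        flags.append("incomplete_measurement")
    return ConftorMeasurement(
        distance_ab=d_ab,
        distance_ba=d_ba,
        anchors=anchors,
        alignment_quality=(anchors_a.tm, anchors_b.tm),
        flags=flags,
    )


@dataclass
class ConformationCall:
    """Open/closed verdict with boundary and quality flags."""

    state: str  # "open" | "closed" | "unassigned"
    flags: list[str] = field(default_factory=list)


def classify_conformation_conftor(
    measurement: ConftorMeasurement, cutoff: float = CONFTOR_CUTOFF
) -> ConformationCall:
    """Bottom-closed iff BOTH cross distances are strictly below the cutoff.

    Closure of a single composite ATP site does not close the transporter
    bottom; a distance exactly at the cutoff counts as open.  Either
    distance within ``cutoff +/- 2 A`` raises a boundary flag.
    """
    if not measurement.complete:
        return ConformationCall("unassigned", ["incomplete_measurement"])
    d1, d2 = measurement.distance_ab, measurement.distance_ba
    state = "closed" if (d1 < cutoff and d2 < cutoff) else "open"
    flags = []
    if any(abs(d - cutoff) <= BOUNDARY_BAND for d in (d1, d2)):
        flags.append("boundary_case")
    return ConformationCall(state, flags)


def classify_conformation_rmsd(
    query: Structure | CoordinateSet,
    inward_ref: Structure | CoordinateSet,
    outward_ref: Structure | CoordinateSet,
    params: AlignmentParams | None = None,
) -> tuple[ConformationCall, float, float]:
    """Label by the nearer of the two conformation references.

    Returns the call plus both RMSD values so a downstream conftor label
    can override while keeping the evidence.  Near-equal RMSDs (within
    0.01 A) are left unassigned with a tie flag.
    """

    def _ca(x) -> CoordinateSet:
        return extract_ca(x) if isinstance(x, Structure) else x

    qca = _ca(query)

    def _rmsd(ref) -> float:
        rca = _ca(ref)
        common = set(qca.labels) & set(rca.labels)
        if len(common) >= 0.5 * min(len(qca), len(rca)):
            return matched_rmsd(qca, rca).rmsd
        res = structural_align(qca, rca, params)
        return matched_rmsd(qca, rca, pairing=res.paired_labels).rmsd

    rmsd_in = _rmsd(inward_ref)
    rmsd_out = _rmsd(outward_ref)
    if abs(rmsd_in - rmsd_out) < RMSD_TIE_TOL:
        return ConformationCall("unassigned", ["rmsd_tie"]), rmsd_in, rmsd_out
    state = "open" if rmsd_in < rmsd_out else "closed"
    return ConformationCall(state), rmsd_in, rmsd_out


def pair_nbds(
    nbds: list[tuple[str, CoordinateSet]]
) -> tuple[list[tuple[int, int]], list[int], list[str]]:
    """Pair NBD ranges by greedy minimal centroid distance.

    Returns (pairs of indices, unpaired leftover indices, flags).  Exactly
    two NBDs form the single pair; more are greedily matched into disjoint
    closest-centroid pairs and flagged ``multi_unit``; an odd leftover is
    flagged ``unpaired_nbd``.
    """
    if len(nbds) < 2:
        raise AbcConformError("need at least 2 NBDs to pair")
    flags: list[str] = []
    if len(nbds) == 2:
        return [(0, 1)], [], flags
    flags.append("multi_unit")
    centroids = [cs.coords.mean(axis=0) for _, cs in nbds]
    remaining = set(range(len(nbds)))
    pairs: list[tuple[int, int]] = []
    while len(remaining) >= 2:
        best = None
        for i in sorted(remaining):
            for j in sorted(remaining):
                if j <= i:
                    continue
                d = float(np.linalg.norm(centroids[i] - centroids[j]))
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        pairs.append((i, j))
        remaining -= {i, j}
    leftover = sorted(remaining)
    if leftover:
        flags.append("unpaired_nbd")
    return pairs, leftover, flags


@dataclass
class ClassificationRecord:
    """Final per-entry output row of the pipeline."""

    entry_id: str
    source: str = ""
    class_name: str | None = None
    conformation: str = "unassigned"  # conftor label (takes precedence)
    conformation_rmsd: str = "unassigned"  # RMSD-rule label, kept as evidence
    conftor_ab: float | None = None
    conftor_ba: float | None = None
    rmsd_inward: float | None = None
    rmsd_outward: float | None = None
    best_tm: float | None = None
    unit_verdict: str = ""
    n_nbd: int = 0
    n_tmd: int = 0
    flags: list[str] = field(default_factory=list)
    taxonomy: str = ""
    gene: str = ""
    protein: str = ""
    release_date: str = ""
    error: str = ""

    def add_flag(self, flag: str) -> None:
        if flag and flag not in self.flags:
            self.flags.append(flag)
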