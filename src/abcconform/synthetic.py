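"""Synthetic structures, domain-hit tables and cohorts with planted truth.

Every pipeline stage is testable without downloading anything: the
generators here emit mock transporter assemblies whose conformational
geometry is planted exactly.  A mock assembly consists of

* two transmembrane pseudo-domains — ideal-helix bundles whose helix count,
  length, ring radius and tilt are specific to the structural class being
  emulated (the nine TMD classes differ in exactly these architectural
  features in real structures); and
* two pseudo-NBDs — copies of the shipped synthetic reference NBD, the
  second placed so that the two cross-domain Walker-A -> signature C-alpha
  distances equal the planted values to machine precision (two-sphere
  constraint solved in closed form).

All generators are pure functions of their spec and seed.  Gaussian
coordinate noise (sigma, Angstrom) and a global random rigid transform are
applied last, so planted distances are exact at sigma = 0 and perturbed by
~sqrt(2)*sigma otherwise; the realized post-noise distances are recorded in
the ground truth alongside the planted ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from abcconform.domain_annotation import PfamHit, render_domtblout
from abcconform.errors import FixtureSpecError
from abcconform.structure_io import (
    CoordinateSet,
    ResidueLabel,
    Structure,
    structure_from_coordinates,
)

__all__ = [
    "STRUCTURAL_CLASSES",
    "CLASS_TMD_PROFILE",
    "NBD_PROFILE",
    "MockSpec",
    "MockGroundTruth",
    "make_ideal_helix",
    "make_reference_nbd",
    "make_class_tmd_bundle",
    "make_mock_transporter",
    "make_mock_domtblout",
    "hits_for_mock",
    "make_cohort",
]

# The nine TMD structural classes, named after a well-known representative.
STRUCTURAL_CLASSES = [
    "Pgp-like",
    "ABCG2-like",
    "MacB-like",
    "Bce-like",
    "MalFG-like",
    "LptFG-like",
    "EcfT-like",
    "BtuCD-like",
    "MlaE-like",
]

# Profile used when emitting synthetic domain hits for a mock of each class.
CLASS_TMD_PROFILE = {
    "Pgp-like": ("ABC_membrane", "PF00664"),
    "ABCG2-like": ("ABC2_membrane", "PF01061"),
    "MacB-like": ("FtsX", "PF02687"),
    "Bce-like": ("DUF717", "PF05232"),
    "MalFG-like": ("BPD_transp_1", "PF00528"),
    "LptFG-like": ("LptF_LptG", "PF04239"),
    "EcfT-like": ("ECF_trnsprt", "PF12822"),
    "BtuCD-like": ("FecCD", "PF01032"),
    "MlaE-like": ("MlaE", "PF02405"),
}
NBD_PROFILE = ("ABC_tran", "PF00005")

_HELIX_RISE = 1.5  # Angstrom per residue
_HELIX_TURN = 100.0  # degrees per residue
_HELIX_RADIUS = 2.3  # Angstrom

OPEN_CLOSED_CUTOFF = 14.0  # Angstrom; bottom-open vs bottom-closed


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180 deg about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = v / np.linalg.norm(v)
    angle = math.acos(np.clip(c, -1.0, 1.0))
    return Rotation.from_rotvec(angle * axis).as_matrix()


def make_ideal_helix(
    n_residues: int,
    origin=(0.0, 0.0, 0.0),
    axis=(0.0, 0.0, 1.0),
    chain_id: str = "A",
    start_res: int = 1,
    phase: float = 0.0,
) -> CoordinateSet:
    """C-alpha trace of an ideal alpha helix.

    1.5 A rise and 100 degrees turn per residue at 2.3 A radius, giving the
    canonical ~3.8 A consecutive C-alpha spacing.  ``axis`` orients the
    helix; ``phase`` (radians) rotates the first residue about it.
    """
    if n_residues < 4:
        raise ValueError("a helix needs at least 4 residues")
    i = np.arange(n_residues)
    theta = np.deg2rad(_HELIX_TURN) * i + phase
    local = np.stack(
        [
            _HELIX_RADIUS * np.cos(theta),
            _HELIX_RADIUS * np.sin(theta),
            _HELIX_RISE * i,
        ],
        axis=1,
    )
    R = _rotation_between(np.array([0.0, 0.0, 1.0]), np.asarray(axis, dtype=float))
    coords = local @ R.T + np.asarray(origin, dtype=float)
    labels = [ResidueLabel(chain_id, start_res + k) for k in range(n_residues)]
    return CoordinateSet(labels, coords)


def _connect_segments(segments: list[np.ndarray]) -> np.ndarray:
    """Join C-alpha segments with straight loop residues ~3.5 A apart."""
    out = [segments[0]]
    for seg in segments[1:]:
        prev_end = out[-1][-1]
        start = seg[0]
        gap = np.linalg.norm(start - prev_end)
        n_loop = max(0, int(math.ceil(gap / 3.5)) - 1)
        if n_loop:
            ts = np.linspace(0, 1, n_loop + 2)[1:-1]
            out.append(prev_end + ts[:, None] * (start - prev_end))
        out.append(seg)
    return np.vstack(out)


def _relabel(coords: np.ndarray, chain_id: str, start_res: int = 1) -> CoordinateSet:
    labels = [ResidueLabel(chain_id, start_res + i) for i in range(len(coords))]
    return CoordinateSet(labels, coords)


# ---------------------------------------------------------------------------
# synthetic reference NBD
# ---------------------------------------------------------------------------

def make_reference_nbd(chain_id: str = "R") -> tuple[CoordinateSet, dict[str, ResidueLabel]]:
    """Synthetic compact reference NBD with annotated anchor residues.

    A deterministic five-helix two-layer bundle (~90 residues) standing in
    for an experimentally derived nucleotide-binding domain.  Two residues
    are annotated as the conftor anchors: ``walker_a_k`` (the Walker-A
    P-loop lysine, GXXXXG**K**T position 7) at the end of helix 2 and
    ``signature_g`` (the ABC-signature central glycine, LS**G**GQ position
    3) at the end of helix 4, both on the same (y ~ 0) face so the partner
    NBD's anchors can face them across the dimer interface.
    """
    hel_len = 16
    specs = [
        ((0.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
        ((9.0, hel_len * _HELIX_RISE, 0.0), (0.0, -1.0, 0.0)),
        ((18.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
        ((13.5, hel_len * _HELIX_RISE, 8.5), (0.0, -1.0, 0.0)),
        ((4.5, 0.0, 8.5), (0.0, 1.0, 0.0)),
    ]
    segments = []
    for origin, axis in specs:
        seg = make_ideal_helix(hel_len, origin=origin, axis=axis).coords
        segments.append(seg)
    coords = _connect_segments(segments)
    cs = _relabel(coords, chain_id)
    # anchor indices: last residue of helix 2 and of helix 4 in the final trace
    idx_h2_end = _segment_end_index(segments, 1)
    idx_h4_end = _segment_end_index(segments, 3)
    anchors = {
        "walker_a_k": cs.labels[idx_h2_end],
        "signature_g": cs.labels[idx_h4_end],
    }
    return cs, anchors


def _segment_end_index(segments: list[np.ndarray], k: int) -> int:
    """Index (into the connected trace) of the last residue of segment k.

    Loop insertion between segments is prefix-stable, so the end of segment
    k sits at the last position of the trace built from segments 0..k.
    """
    return len(_connect_segments(segments[: k + 1])) - 1


# ---------------------------------------------------------------------------
# class-specific TMD bundles
# ---------------------------------------------------------------------------

# (n_helices, helix_len, arrangement, scale_A, tilt_deg, z_stagger_A)
# The nine classes are given strongly distinct gross architectures: helix
# count 4-10, helix length 13-30 and ring / row / grid / vee footprints, so
# that TM-scores between different class templates stay below the 0.6
# same-class threshold the way real TMD scaffolds do.
_CLASS_TMD_PARAMS = {
    "Pgp-like": (6, 24, "ring", 9.0, 10.0, 0.0),
    "ABCG2-like": (8, 16, "row", 9.0, 0.0, 0.0),
    "MacB-like": (4, 30, "ring", 6.5, 0.0, 0.0),
    "Bce-like": (7, 14, "grid", 12.0, 25.0, 4.0),
    "MalFG-like": (8, 22, "ring", 15.5, 5.0, 2.5),
    "LptFG-like": (6, 20, "vee", 8.5, 15.0, 0.0),
    "EcfT-like": (6, 13, "row", 7.5, 30.0, 5.0),
    "BtuCD-like": (10, 18, "ring", 12.5, 0.0, 3.0),
    "MlaE-like": (7, 15, "grid", 8.0, 12.0, 0.0),
}


def make_class_tmd_bundle(
    class_name: str, origin=(0.0, 0.0, 0.0), chain_id: str = "T"
) -> CoordinateSet:
    """Ideal-helix TM bundle with the architecture of one structural class.

    Classes differ in helix count, helix length, footprint (ring, linear
    row, staggered grid, or two rows meeting at an angle), tilt and
    per-helix vertical stagger, mirroring how the real TMD classes differ
    in scaffold.  Helices alternate direction and are joined by short loops
    into one continuous C-alpha trace.
    """
    if class_name not in _CLASS_TMD_PARAMS:
        raise FixtureSpecError(f"unknown structural class {class_name!r}")
    n_hel, hel_len, arrangement, scale, tilt_deg, z_stagger = _CLASS_TMD_PARAMS[
        class_name
    ]
    origin = np.asarray(origin, dtype=float)
    segments = []
    tilt = np.deg2rad(tilt_deg)
    for k in range(n_hel):
        if arrangement == "ring":
            phi = 2.0 * np.pi * k / n_hel
            base = np.array([scale * np.cos(phi), scale * np.sin(phi), 0.0])
            radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        elif arrangement == "row":
            base = np.array([scale * k, 0.0, 0.0])
            radial = np.array([0.0, 1.0, 0.0])
        elif arrangement == "vee":
            half = (n_hel + 1) // 2
            arm, pos = divmod(k, half)
            ang = np.deg2rad(30.0 if arm == 0 else 150.0)
            base = np.array(
                [scale * (pos + 1) * np.cos(ang), scale * (pos + 1) * np.sin(ang), 0.0]
            )
            radial = np.array([np.cos(ang), np.sin(ang), 0.0])
        else:  # grid: two staggered rows
            row, col = divmod(k, max(2, (n_hel + 1) // 2))
            base = np.array([scale * col + scale / 2 * row, 8.0 * row, 0.0])
            radial = np.array([1.0, 0.0, 0.0])
        up = k % 2 == 0
        axis = np.array([0.0, 0.0, 1.0 if up else -1.0])
        if tilt_deg:
            R_tilt = Rotation.from_rotvec(tilt * radial).as_matrix()
            axis = R_tilt @ axis
        z0 = z_stagger * (k % 2)
        start = base + np.array([0.0, 0.0, z0])
        if not up:
            start = start + np.array([0.0, 0.0, hel_len * _HELIX_RISE])
        seg = make_ideal_helix(hel_len, origin=start + origin, axis=axis).coords
        segments.append(seg)
    coords = _connect_segments(segments)
    return _relabel(coords, chain_id)


# ---------------------------------------------------------------------------
# planted placement of the second NBD
# ---------------------------------------------------------------------------


def _solve_second_nbd_placement(
    nbd_coords: np.ndarray,
    p_w: np.ndarray,
    p_s: np.ndarray,
    d_ab: float,
    d_ba: float,
    rng: np.random.Generator,
    min_clearance: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t for NBD B so the two cross distances hold.

    NBD A sits at ``nbd_coords`` with Walker-A anchor ``p_w`` and signature
    anchor ``p_s``.  NBD B is the same fold transformed by (R, t); the
    constraints |p_w - (R p_s + t)| = d_ab and |(R p_w + t) - p_s| = d_ba
    put t on the intersection circle of two spheres, solved in closed form
    for each candidate rotation.  Among feasible placements the one with
    the best steric clearance from NBD A is kept.
    """
    candidates: list[np.ndarray] = []
    # canonical axes at several angles, then seeded random rotations
    for angle in (180.0, 120.0, 90.0, 60.0, 150.0):
        for ax in (
            (0.0, 0.0, 1.0),
            (1.0, 0.0, 0.0),
            (0.0, 1.0, 0.0),
            (1.0, 1.0, 1.0),
        ):
            axis = np.asarray(ax) / np.linalg.norm(ax)
            candidates.append(
                Rotation.from_rotvec(np.deg2rad(angle) * axis).as_matrix()
            )
    candidates.append(np.eye(3))
    for _ in range(12):
        candidates.append(Rotation.random(random_state=rng).as_matrix())

    sub = nbd_coords[:: max(1, len(nbd_coords) // 40)]
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for R in candidates:
        c1 = p_w - R @ p_s  # |t - c1| = d_ab
        c2 = p_s - R @ p_w  # |t - c2| = d_ba
        dvec = c2 - c1
        d = float(np.linalg.norm(dvec))
        if d < 1e-9:
            if abs(d_ab - d_ba) > 1e-9:
                continue
            # concentric spheres of equal radius: any direction works
            u = np.array([0.0, -1.0, 0.0])
            center = c1
            h = d_ab
            n_hat = np.array([0.0, 0.0, 1.0])
        else:
            a = (d * d + d_ab * d_ab - d_ba * d_ba) / (2.0 * d)
            h_sq = d_ab * d_ab - a * a
            if h_sq < 0.0 or d > d_ab + d_ba or d < abs(d_ab - d_ba):
                continue
            h = math.sqrt(max(h_sq, 0.0))
            n_hat = dvec / d
            center = c1 + a * n_hat
            u = np.array([0.0, -1.0, 0.0])
            u = u - np.dot(u, n_hat) * n_hat
            if np.linalg.norm(u) < 1e-9:
                u = np.array([1.0, 0.0, 0.0])
                u = u - np.dot(u, n_hat) * n_hat
            u /= np.linalg.norm(u)
        v = np.cross(n_hat, u)
        for theta in np.linspace(0.0, 2.0 * np.pi, 24, endpoint=False):
            t = center + h * (math.cos(theta) * u + math.sin(theta) * v)
            placed = sub @ R.T + t
            clearance = float(cdist(sub, placed).min())
            if best is None or clearance > best[0]:
                best = (clearance, R, t)
        if best is not None and best[0] >= min_clearance + 2.0:
            break
    if best is None:
        raise FixtureSpecError(
            f"no feasible NBD placement for distances ({d_ab}, {d_ba})"
        )
    _, R, t = best
    return R, t


# ---------------------------------------------------------------------------
# mock transporters
# ---------------------------------------------------------------------------


@dataclass
class MockSpec:
    """Specification of one mock transporter assembly."""

    planted_class: str = "Pgp-like"
    planted_state: str = "open"  # "open" | "closed" | "boundary"
    planted_distances: tuple[float, float] = (25.0, 25.0)
    noise_sigma: float = 0.0
    n_chains: int = 2  # 1 (full transporter), 2 (half-transporter dimer) or 4
    seed: int = 0
    entry_id: str | None = None

    def __post_init__(self) -> None:
        if self.planted_class not in STRUCTURAL_CLASSES:
            raise FixtureSpecError(f"unknown class {self.planted_class!r}")
        if self.n_chains not in (1, 2, 4):
            raise FixtureSpecError("n_chains must be 1, 2 or 4")
        if self.noise_sigma < 0:
            raise FixtureSpecError("noise_sigma must be >= 0")
        d1, d2 = self.planted_distances
        if d1 <= 0 or d2 <= 0:
            raise FixtureSpecError("planted distances must be positive")
        both_below = d1 < OPEN_CLOSED_CUTOFF and d2 < OPEN_CLOSED_CUTOFF
        if self.planted_state == "closed" and not both_below:
            raise FixtureSpecError(
                "closed state requires both distances below the 14 A cutoff"
            )
        if self.planted_state == "open" and both_below:
            raise FixtureSpecError(
                "open state requires at least one distance >= 14 A"
            )
        if self.planted_state == "boundary":
            lo, hi = sorted((d1, d2))
            if not (12.0 <= lo < OPEN_CLOSED_CUTOFF <= hi <= 16.0):
                raise FixtureSpecError(
                    "boundary state plants one distance below and one above "
                    "14 A, both within 14 +/- 2 A"
                )
        if self.planted_state not in ("open", "closed", "boundary"):
            raise FixtureSpecError(f"unknown state {self.planted_state!r}")


@dataclass
class MockGroundTruth:
    """Planted truth accompanying one mock assembly."""

    entry_id: str
    class_name: str
    state: str  # expected open/closed label under the both-below rule
    planted_distances: tuple[float, float]
    realized_distances: tuple[float, float]
    anchors: dict[str, ResidueLabel]  # wa_a, sig_a, wa_b, sig_b
    nbd_ranges: list[tuple[str, int, int]]  # (chain_id, first_res, last_res)
    tmd_ranges: list[tuple[str, int, int]]
    seed: int

    @property
    def expected_label(self) -> str:
        """open/closed label the classifier should produce."""
        d1, d2 = self.planted_distances
        return (
            "closed"
            if d1 < OPEN_CLOSED_CUTOFF and d2 < OPEN_CLOSED_CUTOFF
            else "open"
        )


def make_mock_transporter(spec: MockSpec) -> tuple[Structure, MockGroundTruth]:
    """Generate one mock transporter assembly with planted geometry.

    Deterministic in ``spec`` (byte-identical structures for equal specs).
    At ``noise_sigma = 0`` the conftor distances measured on the output
    equal the planted values to machine precision.
    """
    rng = np.random.default_rng(spec.seed)
    d_ab, d_ba = (float(d) for d in spec.planted_distances)

    # --- two TMD bundles side by side in the "membrane" region ---
    bundle1 = make_class_tmd_bundle(spec.planted_class).coords
    width = bundle1[:, 0].max() - bundle1[:, 0].min() + 8.0
    bundle2 = bundle1 + np.array([width, 0.0, 0.0])

    # --- NBD A below TMD1 ---
    nbd_ref, ref_anchors = make_reference_nbd()
    ref_coords = nbd_ref.coords
    wa_idx = nbd_ref.index_of(ref_anchors["walker_a_k"])
    sig_idx = nbd_ref.index_of(ref_anchors["signature_g"])
    # class-specific NBD depth decorrelates the NBD placement across classes
    class_idx = STRUCTURAL_CLASSES.index(spec.planted_class)
    nbd_depth = ref_coords[:, 2].max() + 6.0 + 2.0 * class_idx
    shift_a = np.array(
        [
            bundle1[:, 0].mean() - ref_coords[:, 0].mean(),
            bundle1[:, 1].mean() - ref_coords[:, 1].mean(),
            -nbd_depth,
        ]
    )
    nbd_a = ref_coords + shift_a
    # class-specific azimuth of NBD A further decorrelates classes
    R_az = Rotation.from_rotvec(np.deg2rad(40.0 * class_idx) * np.array([0.0, 0.0, 1.0])).as_matrix()
    centroid_a = nbd_a.mean(axis=0)
    nbd_a = (nbd_a - centroid_a) @ R_az.T + centroid_a
    p_w = nbd_a[wa_idx]
    p_s = nbd_a[sig_idx]

    # --- NBD B placed so both cross anchor distances are exact ---
    R_b, t_b = _solve_second_nbd_placement(nbd_a, p_w, p_s, d_ab, d_ba, rng)
    nbd_b = nbd_a @ R_b.T + t_b

    # --- assemble chains ---
    domains = [("TMD", bundle1), ("NBD", nbd_a), ("TMD", bundle2), ("NBD", nbd_b)]
    if spec.n_chains == 1:
        chain_of = ["A", "A", "A", "A"]
    elif spec.n_chains == 2:
        chain_of = ["A", "A", "B", "B"]
    else:
        chain_of = ["A", "B", "C", "D"]

    entry_id = spec.entry_id or f"mock{spec.seed:05d}"
    per_chain: dict[str, list[np.ndarray]] = {}
    ranges: list[tuple[str, str, int, int]] = []  # (kind, chain, lo, hi)
    counters: dict[str, int] = {}
    for (kind, coords), cid in zip(domains, chain_of):
        start = counters.get(cid, 0) + 1
        stop = start + len(coords) - 1
        counters[cid] = stop
        per_chain.setdefault(cid, []).append(coords)
        ranges.append((kind, cid, start, stop))

    # anchor labels in final numbering: NBD domains are ranges[1], ranges[3]
    def _anchor_label(domain_index: int, ref_idx: int) -> ResidueLabel:
        _, cid, lo, _ = ranges[domain_index]
        return ResidueLabel(cid, lo + ref_idx)

    anchors = {
        "wa_a": _anchor_label(1, wa_idx),
        "sig_a": _anchor_label(1, sig_idx),
        "wa_b": _anchor_label(3, wa_idx),
        "sig_b": _anchor_label(3, sig_idx),
    }

    # --- noise + global rigid transform (rigid part preserves distances) ---
    stacked = {cid: np.vstack(parts) for cid, parts in per_chain.items()}
    if spec.noise_sigma > 0:
        for cid in stacked:
            stacked[cid] = stacked[cid] + rng.normal(
                0.0, spec.noise_sigma, stacked[cid].shape
            )
    R_g = Rotation.random(random_state=rng).as_matrix()
    t_g = rng.uniform(-30.0, 30.0, 3)
    for cid in stacked:
        stacked[cid] = stacked[cid] @ R_g.T + t_g

    chain_sets = {
        cid: _relabel(stacked[cid], cid) for cid in sorted(stacked)
    }
    structure = structure_from_coordinates(entry_id, chain_sets, source="predicted")

    # realized distances after noise (rigid transform does not change them)
    def _pos(label: ResidueLabel) -> np.ndarray:
        cs = chain_sets[label.chain_id]
        return cs.coords[cs.index_of(label)]

    realized = (
        float(np.linalg.norm(_pos(anchors["wa_a"]) - _pos(anchors["sig_b"]))),
        float(np.linalg.norm(_pos(anchors["wa_b"]) - _pos(anchors["sig_a"]))),
    )

    truth = MockGroundTruth(
        entry_id=entry_id,
        class_name=spec.planted_class,
        state=spec.planted_state,
        planted_distances=(d_ab, d_ba),
        realized_distances=realized,
        anchors=anchors,
        nbd_ranges=[(c, lo, hi) for k, c, lo, hi in ranges if k == "NBD"],
        tmd_ranges=[(c, lo, hi) for k, c, lo, hi in ranges if k == "TMD"],
        seed=spec.seed,
    )
    return structure, truth


# ---------------------------------------------------------------------------
# synthetic domain-hit tables
# ---------------------------------------------------------------------------


@dataclass
class HitSpec:
    """Compact description of one synthetic domain hit."""

    target_name: str
    profile_name: str
    profile_accession: str
    ali_from: int
    ali_to: int
    ievalue: float = 1e-20
    profile_length: int = 200
    coverage: float = 1.0
    target_length: int = 0

    def to_hit(self) -> PfamHit:
        span = max(1, int(round(self.coverage * self.profile_length)))
        return PfamHit(
            target_name=self.target_name,
            profile_name=self.profile_name,
            profile_accession=self.profile_accession,
            profile_length=self.profile_length,
            full_seq_evalue=self.ievalue,
            domain_ievalue=self.ievalue,
            hmm_from=1,
            hmm_to=span,
            ali_from=self.ali_from,
            ali_to=self.ali_to,
            target_length=self.target_length or self.ali_to,
        )


def make_mock_domtblout(hit_specs: list[HitSpec]) -> str:
    """Well-formed HMMER3 per-domain table text for the given hit specs."""
    return render_domtblout([s.to_hit() for s in hit_specs])


def hits_for_mock(truth: MockGroundTruth) -> list[HitSpec]:
    """Domain-hit specs consistent with a mock assembly's planted domains.

    Target names follow the pipeline convention ``<entry_id>_<chain_id>``.
    """
    tmd_name, tmd_acc = CLASS_TMD_PROFILE[truth.class_name]
    nbd_name, nbd_acc = NBD_PROFILE
    specs = []
    for cid, lo, hi in truth.tmd_ranges:
        specs.append(
            HitSpec(
                target_name=f"{truth.entry_id}_{cid}",
                profile_name=tmd_name,
                profile_accession=tmd_acc,
                ali_from=lo,
                ali_to=hi,
                profile_length=hi - lo + 1,
            )
        )
    for cid, lo, hi in truth.nbd_ranges:
        specs.append(
            HitSpec(
                target_name=f"{truth.entry_id}_{cid}",
                profile_name=nbd_name,
                profile_accession=nbd_acc,
                ali_from=lo,
                ali_to=hi,
                profile_length=hi - lo + 1,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def _state_counts(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Exact integer allocation of n over the state mix (largest remainders)."""
    states = sorted(mix)
    raw = {s: n * mix[s] for s in states}
    counts = {s: int(math.floor(raw[s])) for s in states}
    rem = n - sum(counts.values())
    by_frac = sorted(states, key=lambda s: (-(raw[s] - counts[s]), s))
    for s in by_frac[:rem]:
        counts[s] += 1
    return counts


def _sample_distances(state: str, rng: np.random.Generator) -> tuple[float, float]:
    # the two composite-site distances are strongly correlated in real
    # structures (both track NBD separation), so sample a base separation
    # plus a small asymmetry
    if state == "closed":
        base = rng.uniform(8.5, 11.0)
        delta = rng.uniform(-0.8, 0.8)
        return (float(base), float(base + delta))
    if state == "open":
        # floor keeps even the asymmetric partner clear of the 14 +/- 2
        # boundary band, which is the preserve of the "boundary" state
        base = rng.uniform(21.5, 75.0)
        delta = rng.uniform(-5.0, 5.0)
        return (float(base), float(base + delta))
    # boundary: one side just below, one just above the cutoff
    return (float(rng.uniform(12.2, 13.8)), float(rng.uniform(14.2, 15.8)))


def make_cohort(
    n: int,
    mix: dict[str, float] | None = None,
    seed: int = 0,
    classes: list[str] | None = None,
    noise_sigma: float = 0.3,
) -> list[tuple[Structure, MockGroundTruth]]:
    """Deterministic cohort of mock transporters with planted states.

    ``mix`` gives open/closed/boundary proportions (default 60% open, 40%
    closed, matching the experimental predominance of bottom-open
    structures); counts are exact.  Structural classes cycle over
    ``classes`` (default: the first three to keep family variety cheap).
    """
    if n < 1:
        raise FixtureSpecError("n must be >= 1")
    mix = mix or {"open": 0.6, "closed": 0.4}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise FixtureSpecError("mix proportions must sum to 1")
    classes = classes or STRUCTURAL_CLASSES[:3]
    counts = _state_counts(n, mix)
    rng = np.random.default_rng(seed)
    states: list[str] = []
    for s in sorted(counts):
        states.extend([s] * counts[s])
    # deterministic interleave so entry order does not encode the state
    order = rng.permutation(len(states))
    cohort = []
    for i, idx in enumerate(order):
        state = states[idx]
        spec = MockSpec(
            planted_class=classes[i % len(classes)],
            planted_state=state,
            planted_distances=_sample_distances(state, rng),
            noise_sigma=noise_sigma,
            n_chains=2,
            seed=int(rng.integers(0, 2**31 - 1)),
            entry_id=f"mock{seed:03d}_{i:04d}",
        )
        cohort.append(make_mock_transporter(spec))
    return cohort
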