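"""Rigid-body superposition, TM-score and sequence-independent alignment.

Three layers build on each other:

1. :func:`kabsch` — optimal least-squares superposition of two pre-paired
   point sets (SVD formulation, reflections corrected).
2. :func:`tm_score` — the length-normalized structural similarity score
   ``TM = (1/L) * sum 1/(1+(d_i/d0)^2)`` with ``d0 = 1.24*(L-15)^(1/3) - 1.8``
   clamped from below for short chains.
3. :func:`structural_align` — a TM-score-maximizing, sequence-independent
   aligner: gapless-threading seeds, then iterated (superpose -> score
   matrix -> dynamic-programming re-alignment) until the residue pairing is
   stable; the best-TM result over all seeds is reported.

The aligner is the workhorse for structural-family assignment (TM-score
against class references) and for motif anchoring on the reference NBD; it
trades the published TM-align binary's exhaustive seeding for speed, which
is sufficient for the single-domain and assembly-scale alignments used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from abcconform.errors import AlignmentError
from abcconform.structure_io import CoordinateSet, ResidueLabel

__all__ = [
    "AlignmentParams",
    "SuperpositionResult",
    "kabsch",
    "tm_score",
    "tm_d0",
    "structural_align",
    "matched_rmsd",
]


@dataclass
class AlignmentParams:
    """Tunable constants of the iterative aligner."""

    gap_open_penalty: float = 0.6  # charged once per gap segment, score units
    d0_floor: float = 0.5  # Angstrom; lower clamp of the TM normalization
    max_iterations: int = 30
    convergence_tol: float = 0.0  # pairing must be exactly stable
    n_seed_offsets: int = 21  # gapless threading seeds (evenly subsampled)
    n_window_starts: int = 5  # fragment-window seeds per axis (5x5 grid)
    window_length: int = 24  # fragment-window seed length, residues
    n_refine_seeds: int = 3  # seeds carried into full iteration

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.d0_floor <= 0:
            raise ValueError("d0_floor must be positive")


@dataclass
class SuperpositionResult:
    """Outcome of one rigid superposition / structural alignment.

    ``rotation`` and ``translation`` map *query* coordinates onto the
    reference frame: ``x_aligned = R @ x + t``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    paired_labels: list[tuple[ResidueLabel, ResidueLabel]]
    rmsd: float
    tm_score: float | None = None  # normalized by reference length
    tm_score_query_norm: float | None = None
    normalization_length: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.paired_labels)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def _as_coords(x) -> tuple[np.ndarray, list[ResidueLabel] | None]:
    if isinstance(x, CoordinateSet):
        return x.coords, x.labels
    arr = np.asarray(x, dtype=float).reshape(-1, 3)
    return arr, None


def _kabsch_core(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rotation+translation mapping P onto Q; returns (R, t, rmsd)."""
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


def kabsch(P, Q) -> SuperpositionResult:
    """Least-squares superposition of pre-paired point sets (P onto Q).

    Parameters
    ----------
    P, Q:
        :class:`CoordinateSet` or (N, 3) arrays, paired by index, N >= 3.

    Returns
    -------
    SuperpositionResult
        The proper rotation and translation minimizing the RMSD of
        ``R @ P + t`` against ``Q`` over all rigid transforms; collinear or
        otherwise rank-deficient inputs are flagged ``"degenerate"``.
    """
    Pc, plabels = _as_coords(P)
    Qc, qlabels = _as_coords(Q)
    if len(Pc) != len(Qc):
        raise AlignmentError(f"point counts differ: {len(Pc)} vs {len(Qc)}")
    if len(Pc) < 3:
        raise AlignmentError("need at least 3 paired points")
    R, t, rmsd = _kabsch_core(Pc, Qc)
    flags = []
    if np.linalg.matrix_rank(Pc - Pc.mean(axis=0), tol=1e-8) < 2:
        flags.append("degenerate")
    if plabels is None:
        plabels = [ResidueLabel("P", i + 1) for i in range(len(Pc))]
    if qlabels is None:
        qlabels = [ResidueLabel("Q", i + 1) for i in range(len(Qc))]
    return SuperpositionResult(
        rotation=R,
        translation=t,
        paired_labels=list(zip(plabels, qlabels)),
        rmsd=rmsd,
        flags=flags,
    )


def tm_d0(L_target: int, d0_floor: float = 0.5) -> float:
    """TM-score normalization distance for a target of ``L_target`` residues."""
    if L_target < 1:
        raise ValueError("L_target must be >= 1")
    d0 = 1.24 * np.cbrt(L_target - 15.0) - 1.8 if L_target > 15 else d0_floor
    return max(float(d0), d0_floor)


def tm_score(paired_distances, L_target: int, d0_floor: float = 0.5) -> float:
    """TM-score of a set of paired residue distances, normalized by L_target."""
    d = np.asarray(paired_distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    d0 = tm_d0(L_target, d0_floor)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_target)


@njit(cache=True)
def _dp_align(S, gap_open):  # pragma: no cover - exercised via structural_align
    """Semi-global affine DP (gap extension free) over score matrix S.

    Terminal gaps are free.  Returns (qi, ri, n) index pairs of the best
    monotonic alignment.
    """
    n, m = S.shape
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in reference (query advances)
    Iy = np.full((n + 1, m + 1), NEG)
    tb = np.zeros((n + 1, m + 1, 3), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = 0.0  # free leading gaps
    for j in range(1, m + 1):
        Iy[0, j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # match state
            best = M[i - 1, j - 1]
            src = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                src = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                src = 2
            M[i, j] = best + S[i - 1, j - 1]
            tb[i, j, 0] = src
            # gap in reference
            open_x = M[i - 1, j] - gap_open
            ext_x = Ix[i - 1, j]
            if open_x >= ext_x:
                Ix[i, j] = open_x
                tb[i, j, 1] = 0
            else:
                Ix[i, j] = ext_x
                tb[i, j, 1] = 1
            # gap in query
            open_y = M[i, j - 1] - gap_open
            ext_y = Iy[i, j - 1]
            if open_y >= ext_y:
                Iy[i, j] = open_y
                tb[i, j, 2] = 0
            else:
                Iy[i, j] = ext_y
                tb[i, j, 2] = 1
    # free trailing gaps: best over last row/column in any state
    best = NEG
    bi = n
    bj = m
    bs = 0
    for j in range(m + 1):
        for s in range(3):
            v = M[n, j] if s == 0 else (Ix[n, j] if s == 1 else Iy[n, j])
            if v > best:
                best = v
                bi, bj, bs = n, j, s
    for i in range(n + 1):
        for s in range(3):
            v = M[i, m] if s == 0 else (Ix[i, m] if s == 1 else Iy[i, m])
            if v > best:
                best = v
                bi, bj, bs = i, m, s
    qi = np.empty(min(n, m), dtype=np.int64)
    ri = np.empty(min(n, m), dtype=np.int64)
    k = 0
    i, j, s = bi, bj, bs
    while i > 0 and j > 0:
        if s == 0:
            qi[k] = i - 1
            ri[k] = j - 1
            k += 1
            s = tb[i, j, 0]
            i -= 1
            j -= 1
        elif s == 1:
            s = tb[i, j, 1]
            i -= 1
        else:
            s = tb[i, j, 2]
            j -= 1
    return qi[:k][::-1].copy(), ri[:k][::-1].copy(), k


def _tm_refine(
    qc: np.ndarray,
    rc: np.ndarray,
    qi: np.ndarray,
    ri: np.ndarray,
    L_norm: int,
    d0: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """TM-score of a pairing, maximized over inclusion-subset superpositions.

    Mirrors the TM-score protocol: superpose on the full pair set, then
    iteratively re-superpose on the pairs currently within a distance
    cutoff, keeping the best score seen.
    """
    P = qc[qi]
    Q = rc[ri]
    best_tm = -1.0
    best_R = np.eye(3)
    best_t = np.zeros(3)
    sel = np.arange(len(P))
    cutoff = max(d0, 4.5)
    for _ in range(6):
        if len(sel) < 3:
            break
        R, t, _ = _kabsch_core(P[sel], Q[sel])
        d = np.linalg.norm(P @ R.T + t - Q, axis=1)
        tm = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm)
        if tm > best_tm:
            best_tm, best_R, best_t = tm, R, t
        new_sel = np.where(d < cutoff)[0]
        if len(new_sel) >= 3 and not np.array_equal(new_sel, sel):
            sel = new_sel
        else:
            break
    if best_tm < 0:
        R, t, _ = _kabsch_core(P, Q)
        d = np.linalg.norm(P @ R.T + t - Q, axis=1)
        best_tm = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm)
        best_R, best_t = R, t
    return best_tm, best_R, best_t


def _iterate_alignment(
    qc: np.ndarray,
    rc: np.ndarray,
    qi: np.ndarray,
    ri: np.ndarray,
    params: AlignmentParams,
    d0: float,
    L_norm: int,
    n_iter: int,
):
    """Superpose -> score -> DP loop; returns (tm, R, t, qi, ri)."""
    best = None
    for _ in range(n_iter):
        if len(qi) < 3:
            break
        tm, R, t = _tm_refine(qc, rc, qi, ri, L_norm, d0)
        if best is None or tm > best[0]:
            best = (tm, R, t, qi, ri)
        moved = qc @ R.T + t
        diff = moved[:, None, :] - rc[None, :, :]
        S = 1.0 / (1.0 + (diff**2).sum(axis=2) / d0**2)
        new_qi, new_ri, k = _dp_align(S, params.gap_open_penalty)
        if k < 3:
            break
        if len(new_qi) == len(qi) and np.array_equal(new_qi, qi) and np.array_equal(
            new_ri, ri
        ):
            qi, ri = new_qi, new_ri
            tm, R, t = _tm_refine(qc, rc, qi, ri, L_norm, d0)
            if tm > best[0]:
                best = (tm, R, t, qi, ri)
            break
        qi, ri = new_qi, new_ri
    if best is None:
        raise AlignmentError("alignment collapsed below 3 pairs")
    return best


def structural_align(
    query: CoordinateSet,
    reference: CoordinateSet,
    params: AlignmentParams | None = None,
) -> SuperpositionResult:
    """Sequence-independent TM-score-maximizing alignment of two C-alpha sets.

    The reported TM-score is normalized by the *reference* length (family
    assignment asks how much of the canonical fold is present); the
    query-normalized score is stored alongside.
    """
    params = params or AlignmentParams()
    qc, qlabels = _as_coords(query)
    rc, rlabels = _as_coords(reference)
    n, m = len(qc), len(rc)
    if n == 0 or m == 0:
        raise AlignmentError("empty coordinate set")
    if n < 3 or m < 3:
        raise AlignmentError("need at least 3 residues on each side")
    flags = []
    if min(n, m) < 20:
        flags.append("short_alignment")
    L_norm = m
    d0 = tm_d0(L_norm, params.d0_floor)

    # --- seeds: gapless threading at evenly subsampled offsets ---
    min_overlap = max(8, min(20, min(n, m) // 2))
    offsets = np.arange(-(n - min_overlap), m - min_overlap + 1)
    if len(offsets) > params.n_seed_offsets:
        pick = np.linspace(0, len(offsets) - 1, params.n_seed_offsets).astype(int)
        offsets = offsets[np.unique(pick)]
    if 0 not in offsets:
        offsets = np.append(offsets, 0)

    seed_pairings: list[tuple[np.ndarray, np.ndarray, int]] = []
    for off in offsets:
        qlo = max(0, -off)
        rlo = max(0, off)
        k = min(n - qlo, m - rlo)
        if k < min_overlap:
            continue
        seed_pairings.append(
            (np.arange(qlo, qlo + k), np.arange(rlo, rlo + k), int(off))
        )
    # fragment-window seeds: short gapless windows superposed at a grid of
    # start positions, catching alignments whose rigid frame no full-length
    # threading reaches (different fold topologies)
    W = min(params.window_length, n, m)
    if W >= min_overlap:
        order = 10_000  # window seeds rank after threading seeds in ties
        for qs in np.linspace(0, n - W, params.n_window_starts).astype(int):
            for rs in np.linspace(0, m - W, params.n_window_starts).astype(int):
                seed_pairings.append(
                    (np.arange(qs, qs + W), np.arange(rs, rs + W), order)
                )
                order += 1

    seeds = []
    for qi0, ri0, order in seed_pairings:
        try:
            tm, R, t, qi2, ri2 = _iterate_alignment(
                qc, rc, qi0, ri0, params, d0, L_norm, n_iter=2
            )
        except AlignmentError:
            continue
        seeds.append((tm, len(qi2), order, qi2, ri2))
    if not seeds:
        raise AlignmentError("no viable alignment seed")
    # ties: higher TM, then more pairs, then earliest seed order
    seeds.sort(key=lambda s: (-s[0], -s[1], s[2]))

    best = None
    for tm0, _, _, qi, ri in seeds[: params.n_refine_seeds]:
        try:
            tm, R, t, qi2, ri2 = _iterate_alignment(
                qc, rc, qi, ri, params, d0, L_norm, n_iter=params.max_iterations
            )
        except AlignmentError:
            continue
        if best is None or tm > best[0]:
            best = (tm, R, t, qi2, ri2)
    if best is None:
        raise AlignmentError("alignment failed on all seeds")
    tm, R, t, qi, ri = best

    moved = qc[qi] @ R.T + t
    d = np.linalg.norm(moved - rc[ri], axis=1)
    rmsd = float(np.sqrt(np.mean(d**2)))
    tm_q = float(
        np.sum(1.0 / (1.0 + (d / tm_d0(n, params.d0_floor)) ** 2)) / n
    )
    if qlabels is None:
        qlabels = [ResidueLabel("Q", i + 1) for i in range(n)]
    if rlabels is None:
        rlabels = [ResidueLabel("R", i + 1) for i in range(m)]
    return SuperpositionResult(
        rotation=R,
        translation=t,
        paired_labels=[(qlabels[i], rlabels[j]) for i, j in zip(qi, ri)],
        rmsd=rmsd,
        tm_score=tm,
        tm_score_query_norm=tm_q,
        normalization_length=L_norm,
        flags=flags,
    )


@dataclass
class MatchedRmsd:
    """RMSD over a residue pairing, optionally after outlier rejection."""

    rmsd: float
    n_retained: int
    n_input: int
    rotation: np.ndarray
    translation: np.ndarray

    def __float__(self) -> float:
        return self.rmsd


def matched_rmsd(
    query: CoordinateSet,
    reference: CoordinateSet,
    pairing: list[tuple[ResidueLabel, ResidueLabel]] | None = None,
    outlier_rejection: bool = False,
) -> MatchedRmsd:
    """Superposition RMSD over paired residues.

    Without a ``pairing``, residues sharing the same label in both sets are
    paired.  With ``outlier_rejection``, pairs farther than twice the current
    RMSD are dropped and the remainder re-superposed, for at most 5 cycles.
    """
    if pairing is None:
        common = [lab for lab in query.labels if lab in set(reference.labels)]
        pairing = [(lab, lab) for lab in common]
    if not pairing:
        raise AlignmentError("empty pairing")
    qidx = {lab: i for i, lab in enumerate(query.labels)}
    ridx = {lab: i for i, lab in enumerate(reference.labels)}
    try:
        qi = np.array([qidx[a] for a, _ in pairing])
        ri = np.array([ridx[b] for _, b in pairing])
    except KeyError as exc:
        raise AlignmentError(f"pairing label {exc} not present") from exc
    P = query.coords[qi]
    Q = reference.coords[ri]
    n_input = len(P)
    keep = np.arange(n_input)
    R, t, rmsd = _kabsch_core(P, Q)
    if outlier_rejection:
        for _ in range(5):
            d = np.linalg.norm(P[keep] @ R.T + t - Q[keep], axis=1)
            new_keep = keep[d <= 2.0 * rmsd]
            if len(new_keep) == len(keep):
                break
            if len(new_keep) < 3:
                raise AlignmentError("outlier rejection removed all pairs")
            keep = new_keep
            R, t, rmsd = _kabsch_core(P[keep], Q[keep])
    return MatchedRmsd(
        rmsd=rmsd,
        n_retained=len(keep),
        n_input=n_input,
        rotation=R,
        translation=t,
    )
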