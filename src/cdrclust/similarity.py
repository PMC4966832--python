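"""Anchor-frame superposition and DTW structural distance between CDR loops.

All loops of one CDR type are first rigidly fitted, by their ten anchor
residues, onto a single reference anchor geometry: superposing anchors
(rather than the loops themselves) preserves how each loop sits relative to
the antibody framework.  The structural distance between two superposed
loops is then computed by dynamic time warping over their backbone, which
permits many-to-one residue matches and therefore compares loops of unequal
length.  For equal-length loops the path is the diagonal, and the score is
the plain backbone RMSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .extraction import AnchoredLoop

__all__ = [
    "AnchorFrame",
    "DTWResult",
    "DegenerateGeometryError",
    "LoopDistanceMatrix",
    "build_anchor_frame",
    "closest_partner_analysis",
    "dtw_score",
    "insertion_site_agreement",
    "kabsch",
    "pairwise_matrix",
    "superpose_to_frame",
]


class DegenerateGeometryError(ValueError):
    """Anchor geometry too close to collinear for a unique rigid fit."""


@dataclass
class AnchorFrame:
    """Reference coordinates for 10 anchor residues x 4 backbone atoms."""

    coords: np.ndarray  # (40, 3)
    provenance: str = "supplied"
    frame_id: str = "frame-0"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.shape[0] != 40 or not np.all(np.isfinite(self.coords)):
            raise ValueError("anchor frame needs 40 finite reference points")


@dataclass
class DTWResult:
    """Matched residue-index pairs and the pooled backbone RMSD in Å."""

    pairs: list[tuple[int, int]]
    score: float
    same_length_shortcut: bool = False


@dataclass
class LoopDistanceMatrix:
    """Symmetric pairwise DTW score matrix over loops of one CDR type."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")

    def submatrix(self, ids: list[str]) -> "LoopDistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return LoopDistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in self.values[i]) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "LoopDistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
        return cls(header, np.array(rows, dtype=float))


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``moving`` onto ``target`` (no scaling).

    Returns (rotation, translation, rmsd) such that moving @ R.T + t best
    matches target.  Reflections are excluded.  Near-collinear point sets
    (rank-deficient covariance) raise :class:`DegenerateGeometryError`.
    """
    P = np.asarray(moving, float)
    Q = np.asarray(target, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # a unique rotation needs at least two independent directions
    if np.linalg.svd(P0, compute_uv=False)[1] < 1e-8:
        raise DegenerateGeometryError("collinear anchor geometry; rigid fit is not unique")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return R, t, rmsd


def _anchor_points(loop: AnchoredLoop) -> np.ndarray:
    return loop.anchor_coords().reshape(40, 3)


def build_anchor_frame(loops: list[AnchoredLoop], mode: str = "medoid") -> AnchorFrame:
    """Build the common reference anchor geometry for one CDR type.

    ``medoid`` (default) picks the loop whose anchors have the smallest
    summed fit RMSD to all other anchors; ``first`` uses the first loop;
    ``mean`` averages the anchor coordinates as given (assumes inputs are
    already in one frame).
    """
    if not loops:
        raise ValueError("cannot build an anchor frame from zero loops")
    if mode == "first":
        return AnchorFrame(_anchor_points(loops[0]), provenance="first",
                           frame_id=f"first:{loops[0].source}")
    if mode == "mean":
        coords = np.mean([_anchor_points(lp) for lp in loops], axis=0)
        return AnchorFrame(coords, provenance="mean", frame_id=f"mean:{len(loops)}")
    if mode == "medoid":
        pts = [_anchor_points(lp) for lp in loops]
        n = len(pts)
        sums = np.zeros(n)
        for i in range(n):
            for j in range(i + 1, n):
                _, _, r = kabsch(pts[i], pts[j])
                sums[i] += r
                sums[j] += r
        best = int(np.lexsort(([lp.source for lp in loops], sums))[0])
        return AnchorFrame(pts[best], provenance="medoid",
                           frame_id=f"medoid:{loops[best].source}")
    raise ValueError(f"unknown anchor-frame mode {mode!r}")


def superpose_to_frame(loop: AnchoredLoop, frame: AnchorFrame) -> tuple[AnchoredLoop, float]:
    """Rigidly fit a loop's 40 anchor atoms onto the frame; move the whole loop.

    Returns the transformed copy (tagged with the frame id) and the anchor
    fit RMSD in Å.
    """
    if not loop.is_complete():
        raise ValueError(f"{loop.source}: incomplete backbone, cannot superpose")
    R, t, rmsd = kabsch(_anchor_points(loop), frame.coords)
    moved = loop.transformed(R, t)
    moved.frame_id = frame.frame_id
    return moved, rmsd


def _residue_cost(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """cost[i, j] = sum of squared distances over the 4 backbone atoms."""
    diff = coords_a[:, None, :, :] - coords_b[None, :, :, :]
    return np.sum(diff ** 2, axis=(2, 3))


def dtw_score(loop_a: AnchoredLoop, loop_b: AnchoredLoop,
              check_frame: bool = True) -> DTWResult:
    """DTW structural distance between two superposed loops.

    Dynamic programming over the residue-pair cost matrix (summed squared
    backbone-atom distances) with the classic three steps; every residue of
    both loops is matched at least once, the path starts at (0, 0) and ends
    at the last residue pair.  The score is the pooled RMSD over all matched
    backbone atom pairs.  Equal-length loops take the forced diagonal path,
    so the score is exactly the plain backbone RMSD.
    """
    if check_frame and (loop_a.frame_id is None or loop_a.frame_id != loop_b.frame_id):
        raise ValueError("loops must be superposed to the same anchor frame")
    A = loop_a.loop_coords()
    B = loop_b.loop_coords()
    la, lb = len(A), len(B)
    cost = _residue_cost(A, B)

    if la == lb:
        pairs = [(i, i) for i in range(la)]
        total = float(np.sum(cost[np.arange(la), np.arange(la)]))
        score = float(np.sqrt(total / (4 * la)))
        return DTWResult(pairs=pairs, score=score, same_length_shortcut=True)

    D = np.full((la, lb), np.inf)
    D[0, 0] = cost[0, 0]
    for i in range(1, la):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
    for j in range(1, lb):
        D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, la):
        D[i, 1:] = cost[i, 1:]  # filled incrementally below
        row_prev = D[i - 1]
        row = D[i]
        for j in range(1, lb):
            row[j] += min(row_prev[j - 1], row_prev[j], row[j - 1])

    # backtrack; ties prefer the diagonal, then a step in the longer loop
    pairs = [(la - 1, lb - 1)]
    i, j = la - 1, lb - 1
    if la >= lb:
        order = ((-1, -1), (-1, 0), (0, -1))
    else:
        order = ((-1, -1), (0, -1), (-1, 0))
    while (i, j) != (0, 0):
        if i == 0:
            i, j = 0, j - 1
        elif j == 0:
            i, j = i - 1, 0
        else:
            best = None
            for di, dj in order:
                cand = D[i + di, j + dj]
                if best is None or cand < best[0] - 1e-12:
                    best = (cand, di, dj)
            i, j = i + best[1], j + best[2]
        pairs.append((i, j))
    pairs.reverse()
    total = float(sum(cost[i, j] for i, j in pairs))
    score = float(np.sqrt(total / (4 * len(pairs))))
    return DTWResult(pairs=pairs, score=score, same_length_shortcut=False)


def pairwise_matrix(loops: list[AnchoredLoop], check_frame: bool = True) -> LoopDistanceMatrix:
    """Symmetric DTW score matrix over all unordered loop pairs."""
    n = len(loops)
    if n < 2:
        raise ValueError("need at least two loops for a distance matrix")
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = dtw_score(loops[i], loops[j], check_frame=check_frame).score
            values[i, j] = values[j, i] = s
    return LoopDistanceMatrix([lp.source for lp in loops], values)


@dataclass
class ClosestPartnerRecord:
    sequence: str
    own_length: int
    own_sources: list[str]
    partner_source: str
    partner_length: int
    distance: float
    different_length: bool


@dataclass
class ClosestPartnerSummary:
    records: list[ClosestPartnerRecord] = field(default_factory=list)

    @property
    def n_unique_sequences(self) -> int:
        return len(self.records)

    @property
    def n_different_length(self) -> int:
        return sum(r.different_length for r in self.records)

    @property
    def fraction_different_length(self) -> float:
        return self.n_different_length / max(self.n_unique_sequences, 1)


def closest_partner_analysis(matrix: LoopDistanceMatrix,
                             sequences: dict[str, str]) -> ClosestPartnerSummary:
    """For every unique sequence, find the nearest loop of a *different* sequence.

    The nearest neighbour is minimised over all loops carrying that sequence
    versus all loops carrying any other sequence; the record notes whether
    the partner has a different loop length.
    """
    seqs = [sequences[i] for i in matrix.ids]
    unique = sorted(set(seqs))
    if len(unique) < 2:
        raise ValueError("closest-partner analysis needs at least two unique sequences")
    summary = ClosestPartnerSummary()
    idx_by_seq = {s: [i for i, q in enumerate(seqs) if q == s] for s in unique}
    for seq in unique:
        own = idx_by_seq[seq]
        others = [i for i, q in enumerate(seqs) if q != seq]
        sub = matrix.values[np.ix_(own, others)]
        k = int(np.argmin(sub))
        oi, oj = divmod(k, len(others))
        partner = others[oj]
        rec = ClosestPartnerRecord(
            sequence=seq,
            own_length=len(seq),
            own_sources=[matrix.ids[i] for i in own],
            partner_source=matrix.ids[partner],
            partner_length=len(seqs[partner]),
            distance=float(sub[oi, oj]),
            different_length=len(seqs[partner]) != len(seq),
        )
        summary.records.append(rec)
    return summary


def insertion_site_agreement(dtw: DTWResult,
                             chothia_insertion_positions: list[int]) -> int | None:
    """Offset between the structural insertion site and the Chothia one.

    The structural insertion site is where the DTW path matches residues of
    the longer loop many-to-one onto the shorter loop.  The offset is the
    minimum residue distance between any structurally inserted residue and
    any declared Chothia insertion index (indices into the longer loop).
    Returns None for equal-length pairs (not applicable).
    """
    la = max(i for i, _ in dtw.pairs) + 1
    lb = max(j for _, j in dtw.pairs) + 1
    if la == lb:
        return None
    if la > lb:
        longer = [i for i, _ in dtw.pairs]
        shorter = [j for _, j in dtw.pairs]
    else:
        longer = [j for _, j in dtw.pairs]
        shorter = [i for i, _ in dtw.pairs]
    sites: set[int] = set()
    for k in range(1, len(dtw.pairs)):
        if shorter[k] == shorter[k - 1]:  # longer loop advanced alone
            sites.add(longer[k - 1])
            sites.add(longer[k])
    if not sites or not chothia_insertion_positions:
        warnings.warn("no many-to-one matches or no declared insertion positions")
        return None
    return min(abs(s - c) for s in sites for c in chothia_insertion_positions)


def superpose_all(loops: list[AnchoredLoop], mode: str = "medoid"
                  ) -> tuple[list[AnchoredLoop], AnchorFrame, list[float]]:
    """Convenience: build the frame and fit every loop to it."""
    frame = build_anchor_frame(loops, mode=mode)
    fitted, rmsds = [], []
    for lp in loops:
        moved, r = superpose_to_frame(lp, frame)
        fitted.append(moved)
        rmsds.append(r)
    return fitted, frame, rmsds
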