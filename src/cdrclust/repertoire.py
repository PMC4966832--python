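"""Score-to-precision calibration and large-scale repertoire classification.

The raw HMM score of a query says little on its own; what a repertoire
analyst needs is "if I accept every assignment scoring at least s, what
fraction will be structurally correct?".  That map is estimated from the
structural cross-validation records (where truth is known), made monotone
by isotonic regression, and then applied to deep-sequencing CDR sequence
sets: at a requested expected precision, a sequence is assigned to its
best-scoring cluster only if the score clears the calibrated threshold.

Running the same repertoire through a length-dependent and a
length-independent cluster set quantifies how many more sequences the
length-variable clusters can absorb.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prediction import HMMSet, ScoreRecord, classify

__all__ = [
    "PrecisionCalibration",
    "RepertoireResult",
    "calibrate",
    "classify_repertoire",
    "length_distribution_report",
    "read_fasta",
    "write_fasta",
]


def read_fasta(path) -> dict[str, str]:
    """Minimal FASTA reader (id -> sequence, first token of header)."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


@dataclass
class PrecisionCalibration:
    """Monotone map from raw score threshold to expected precision."""

    thresholds: np.ndarray  # ascending candidate thresholds
    precisions: np.ndarray  # isotonic (non-decreasing) expected precision

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, float)
        self.precisions = np.asarray(self.precisions, float)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.precisions[0]), float(self.precisions[-1])

    def expected_precision(self, score: float) -> float:
        """Linear interpolation between observed thresholds (clipped)."""
        return float(np.interp(score, self.thresholds, self.precisions))

    def threshold_for(self, precision: float) -> float | None:
        """Smallest score threshold achieving the requested precision.

        Returns None (with a warning) when the precision exceeds the
        calibration support.
        """
        if precision > self.precisions[-1]:
            warnings.warn(
                f"requested precision {precision:.2f} above calibration "
                f"support (max {self.precisions[-1]:.2f}); nothing assignable")
            return None
        k = int(np.searchsorted(self.precisions, precision, side="left"))
        return float(self.thresholds[k])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"thresholds": self.thresholds.tolist(),
                       "precisions": self.precisions.tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "PrecisionCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["thresholds"]), np.array(d["precisions"]))


def calibrate(cv_records: list[ScoreRecord], min_records: int = 20
              ) -> PrecisionCalibration:
    """Estimate expected precision as a function of the score threshold.

    For each candidate threshold s (every observed best score), the raw
    estimate is the fraction of cross-validation assignments with score >= s
    that were correct, pooled over the CDR type's clusters.  Isotonic
    regression then enforces that precision never decreases with the
    threshold, smoothing the non-monotone pockets that finite data produce.
    """
    usable = [r for r in cv_records if r.best is not None and np.isfinite(r.score)]
    if len(usable) < min_records:
        raise ValueError(
            f"calibration needs at least {min_records} scored records, "
            f"got {len(usable)}")
    scores = np.array([r.score for r in usable])
    correct = np.array([r.best == r.true for r in usable], dtype=float)
    order = np.argsort(scores)
    scores, correct = scores[order], correct[order]
    thresholds = np.unique(scores)
    raw = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        k = np.searchsorted(scores, t, side="left")
        raw[i] = correct[k:].mean()
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(thresholds, raw)
    return PrecisionCalibration(thresholds=thresholds, precisions=fitted)


@dataclass
class RepertoireResult:
    """Assignments of a (deduplicated) repertoire under both cluster sets."""

    n_unique: int
    records: dict[str, list[ScoreRecord]]  # mode -> per-sequence records
    counts: pd.DataFrame  # precision level x mode -> assigned count
    gain: dict[float, float] = field(default_factory=dict)  # relative gain


def classify_repertoire(
    sequences: list[str] | dict[str, str],
    hmm_sets: dict[str, HMMSet],
    calibrations: dict[str, PrecisionCalibration],
    precision_levels: tuple[float, ...] = (0.75, 0.80, 0.85, 0.90),
    nonstandard: str = "raise",
) -> RepertoireResult:
    """Classify a sequence repertoire at several expected-precision levels.

    ``hmm_sets`` and ``calibrations`` are keyed by mode (typically
    ``independent`` and ``dependent``).  Sequences are deduplicated first;
    at each precision level a sequence counts as assigned when its best
    cluster score clears that mode's calibrated threshold.
    """
    if isinstance(sequences, dict):
        sequences = list(sequences.values())
    unique = sorted(set(sequences))
    if not unique:
        raise ValueError("empty repertoire")
    records: dict[str, list[ScoreRecord]] = {}
    for mode, hmm_set in hmm_sets.items():
        records[mode] = [classify(s, hmm_set, nonstandard=nonstandard)
                         for s in unique]
    rows = []
    for level in precision_levels:
        row = {"precision": level}
        for mode in hmm_sets:
            thr = calibrations[mode].threshold_for(level)
            if thr is None:
                row[mode] = 0
            else:
                row[mode] = sum(
                    1 for r in records[mode]
                    if r.best is not None and r.score >= thr)
        rows.append(row)
    counts = pd.DataFrame(rows).set_index("precision")
    gain = {}
    if {"independent", "dependent"} <= set(hmm_sets):
        for level in precision_levels:
            dep = counts.loc[level, "dependent"]
            ind = counts.loc[level, "independent"]
            gain[level] = (ind - dep) / dep if dep else float("inf")
    return RepertoireResult(n_unique=len(unique), records=records,
                            counts=counts, gain=gain)


def length_distribution_report(
    repertoire: list[str] | dict[str, str],
    structural: list[str] | dict[str, str] | None = None,
) -> pd.DataFrame:
    """Length histogram of a repertoire versus the structural sequence set.

    Deep-sequencing repertoires and the crystallographic set can have very
    different loop-length profiles, which is exactly why length-dependent
    assignment leaves sequences stranded; this table makes that visible.
    """
    def lengths(seqs):
        if seqs is None:
            return []
        if isinstance(seqs, dict):
            seqs = list(seqs.values())
        return [len(s) for s in seqs]

    rep = lengths(repertoire)
    struct = lengths(structural)
    all_lengths = sorted(set(rep) | set(struct))
    rows = []
    for n in all_lengths:
        rc = rep.count(n)
        sc = struct.count(n)
        rows.append({
            "length": n,
            "repertoire_count": rc,
            "repertoire_fraction": rc / len(rep) if rep else 0.0,
            "structural_count": sc,
            "structural_fraction": sc / len(struct) if struct else 0.0,
        })
    return pd.DataFrame(rows).set_index("length")
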