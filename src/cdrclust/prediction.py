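"""Sequence-based canonical-class prediction with profile HMMs.

Each structural cluster gets a profile hidden Markov model trained on its
member sequences, aligned by Chothia position (insertion-code columns
included), plus a background model of identical architecture trained on all
out-of-cluster sequences of the same CDR type.  A query is scored by the
difference of forward log-likelihoods (cluster minus background, in nats) —
the "raw" log-odds against an empirical rather than a fixed background —
and assigned one-vs-all to the best-scoring cluster among those that
contain sequences of its length.

The model is deliberately global (no local/flanking alignment states):
CDR loops are scored end to end.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AA_ALPHABET",
    "ClusterMSA",
    "ClusterModel",
    "HMMSet",
    "ProfileHMM",
    "ROCData",
    "ScoreRecord",
    "bootstrap_auc_compare",
    "build_cluster_msa",
    "classify",
    "compute_precision_recall",
    "label_sequence",
    "leave_one_out_cv",
    "macro_roc",
    "precision_at_full_recall",
    "raw_score",
    "train_hmm_set",
    "train_profile_hmm",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
GAP = "-"

#: a labelled sequence: (Chothia position, insertion code, amino acid)
LabeledSequence = list[tuple[int, str, str]]


def label_sequence(sequence: str, start: int = 1) -> LabeledSequence:
    """Label a plain sequence with consecutive positions (no insertions)."""
    return [(start + i, "", aa) for i, aa in enumerate(sequence)]


def plain(seq: LabeledSequence) -> str:
    return "".join(aa for _, _, aa in seq)


@dataclass
class ClusterMSA:
    """Gapped alignment of a cluster's sequences over Chothia-position columns."""

    name: str
    columns: list[tuple[int, str]]
    rows: list[str]

    @property
    def n_columns(self) -> int:
        return len(self.columns)


def build_cluster_msa(name: str, sequences: list[LabeledSequence]) -> ClusterMSA:
    """Align cluster sequences on the union of their Chothia positions.

    Columns are the numbering-ordered union of (position, insertion code)
    labels present in the cluster; each sequence occupies its own positions
    and gaps elsewhere.  This makes the alignment of a length-variable
    cluster well-defined: an insertion-code column (say 30B) is simply
    gapped in the rows that lack it.
    """
    if not sequences:
        raise ValueError("cannot build an MSA from zero sequences")
    columns = sorted({(pos, icode) for seq in sequences for pos, icode, _ in seq})
    col_index = {c: i for i, c in enumerate(columns)}
    rows = []
    for seq in sequences:
        row = [GAP] * len(columns)
        for pos, icode, aa in seq:
            j = col_index[(pos, icode)]
            if row[j] != GAP:
                raise ValueError(f"conflicting residues at position {pos}{icode}")
            row[j] = aa
        rows.append("".join(row))
    return ClusterMSA(name=name, columns=columns, rows=rows)


@dataclass
class ProfileHMM:
    """Global profile HMM with match, insert and delete states.

    Transition arrays are indexed by source column k = 0..L, where column 0
    is the begin state and column L+1 the end state: ``t_mm[k]`` is
    M_k -> M_{k+1} (into End at k = L), ``t_md[L]`` is forced to zero, and
    insert states I_0..I_L emit from ``insert_emissions``.
    """

    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (20,)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    pseudocount: float = 1.0

    @property
    def n_columns(self) -> int:
        return self.match_emissions.shape[0]

    def check_normalized(self, tol: float = 1e-9) -> bool:
        ok = np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=tol)
        ok &= math.isclose(float(self.insert_emissions.sum()), 1.0, abs_tol=tol)
        ok &= np.allclose(self.t_mm + self.t_mi + self.t_md, 1.0, atol=tol)
        ok &= np.allclose(self.t_im + self.t_ii, 1.0, atol=tol)
        ok &= np.allclose((self.t_dm + self.t_dd)[1:], 1.0, atol=tol)
        return bool(ok)

    def forward(self, sequence: str, nonstandard: str = "raise") -> float:
        """Forward log-likelihood (nats) of emitting ``sequence`` end to end."""
        seq = _encode(sequence, nonstandard)
        n = len(seq)
        L = self.n_columns
        NEG = -np.inf
        with np.errstate(divide="ignore"):
            lmm, lmi, lmd = np.log(self.t_mm), np.log(self.t_mi), np.log(self.t_md)
            lim, lii = np.log(self.t_im), np.log(self.t_ii)
            ldm, ldd = np.log(self.t_dm), np.log(self.t_dd)
            lme = np.log(self.match_emissions)
            lie = np.log(self.insert_emissions)

        fM = np.full((L + 1, n + 1), NEG)
        fI = np.full((L + 1, n + 1), NEG)
        fD = np.full((L + 1, n + 1), NEG)
        fM[0, 0] = 0.0  # begin state
        for k in range(L + 1):
            for i in range(n + 1):
                if k > 0 and i > 0:
                    fM[k, i] = lme[k - 1, seq[i - 1]] + _lse3(
                        fM[k - 1, i - 1] + lmm[k - 1],
                        fI[k - 1, i - 1] + lim[k - 1],
                        fD[k - 1, i - 1] + ldm[k - 1],
                    )
                if i > 0:
                    fI[k, i] = lie[seq[i - 1]] + _lse3(
                        fM[k, i - 1] + lmi[k],
                        fI[k, i - 1] + lii[k],
                        NEG,
                    )
                if k > 0:
                    fD[k, i] = _lse3(
                        fM[k - 1, i] + lmd[k - 1],
                        fD[k - 1, i] + ldd[k - 1],
                        NEG,
                    )
        return float(_lse3(fM[L, n] + lmm[L], fI[L, n] + lim[L], fD[L, n] + ldm[L]))

    def to_dict(self) -> dict:
        return {
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": {
                name: getattr(self, name).tolist()
                for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
            },
            "pseudocount": self.pseudocount,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileHMM":
        return cls(
            match_emissions=np.array(d["match_emissions"], float),
            insert_emissions=np.array(d["insert_emissions"], float),
            pseudocount=d.get("pseudocount", 1.0),
            **{k: np.array(v, float) for k, v in d["transitions"].items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "ProfileHMM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _encode(sequence: str, nonstandard: str) -> list[int]:
    out = []
    for aa in sequence:
        if aa in AA_INDEX:
            out.append(AA_INDEX[aa])
        elif nonstandard == "skip":
            continue
        else:
            raise ValueError(f"non-standard residue {aa!r}")
    return out


def _lse3(a: float, b: float, c: float) -> float:
    m = max(a, b, c)
    if m == -np.inf:
        return -np.inf
    return m + math.log(math.exp(a - m) + math.exp(b - m) + math.exp(c - m))


def train_profile_hmm(msa: ClusterMSA, pseudocount: float = 1.0,
                      transition_pseudocount: float = 0.1,
                      insert_extend: float = 0.1) -> ProfileHMM:
    """Estimate a profile HMM from a Chothia-column MSA.

    Every column is a match column; a gap in a row traverses the column's
    delete state.  Match emissions are Laplace-smoothed observed counts,
    (count + pseudocount) / (n_observed + 20 * pseudocount).  Transitions
    are counted from the implied match/delete paths with their own
    pseudocount; insert states are never observed in training (insertions
    are columns here), so they keep a uniform emission and a fixed
    extension probability.
    """
    L = msa.n_columns
    n_rows = len(msa.rows)
    if n_rows == 0 or L == 0:
        raise ValueError("empty MSA")
    counts = np.zeros((L, 20))
    for row in msa.rows:
        for k, aa in enumerate(row):
            if aa != GAP:
                counts[k, AA_INDEX[aa]] += 1
    observed = counts.sum(axis=1, keepdims=True)
    match_emissions = (counts + pseudocount) / (observed + 20.0 * pseudocount)

    # transition counts over the implied state paths (M or D per column)
    c_mm = np.zeros(L + 1)
    c_md = np.zeros(L + 1)
    c_dm = np.zeros(L + 1)
    c_dd = np.zeros(L + 1)
    for row in msa.rows:
        states = ["M"] + ["M" if aa != GAP else "D" for aa in row] + ["M"]
        for k in range(L + 1):
            a, b = states[k], states[k + 1]
            if a == "M" and b == "M":
                c_mm[k] += 1
            elif a == "M" and b == "D":
                c_md[k] += 1
            elif a == "D" and b == "M":
                c_dm[k] += 1
            else:
                c_dd[k] += 1

    pt = transition_pseudocount
    t_mm = np.zeros(L + 1)
    t_mi = np.zeros(L + 1)
    t_md = np.zeros(L + 1)
    for k in range(L + 1):
        if k < L:
            tot = c_mm[k] + c_md[k] + 3 * pt
            t_mm[k] = (c_mm[k] + pt) / tot
            t_md[k] = (c_md[k] + pt) / tot
            t_mi[k] = pt / tot
        else:  # last column: no delete state to enter, only End or insert
            tot = c_mm[k] + 2 * pt
            t_mm[k] = (c_mm[k] + pt) / tot
            t_mi[k] = pt / tot
            t_md[k] = 0.0
    t_im = np.full(L + 1, 1.0 - insert_extend)
    t_ii = np.full(L + 1, insert_extend)
    t_dm = np.zeros(L + 1)
    t_dd = np.zeros(L + 1)
    for k in range(1, L + 1):
        if k < L:
            tot = c_dm[k] + c_dd[k] + 2 * pt
            t_dm[k] = (c_dm[k] + pt) / tot
            t_dd[k] = (c_dd[k] + pt) / tot
        else:
            t_dm[k] = 1.0
            t_dd[k] = 0.0
    return ProfileHMM(
        match_emissions=match_emissions,
        insert_emissions=np.full(20, 1.0 / 20.0),
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii, t_dm=t_dm, t_dd=t_dd,
        pseudocount=pseudocount,
    )


def raw_score(hmm: ProfileHMM, background: ProfileHMM, sequence: str,
              nonstandard: str = "raise") -> float:
    """Log-likelihood difference (nats): cluster model minus background model."""
    return hmm.forward(sequence, nonstandard) - background.forward(sequence, nonstandard)


@dataclass
class ClusterModel:
    name: str
    hmm: ProfileHMM
    background: ProfileHMM
    train_lengths: set[int]
    n_train: int


@dataclass
class HMMSet:
    models: dict[str, ClusterModel]

    def __iter__(self):
        return iter(self.models.values())


def train_hmm_set(clusters: dict[str, list[LabeledSequence]],
                  pseudocount: float = 1.0,
                  skip_empty_complement: bool = False) -> HMMSet:
    """Train one cluster model + out-of-cluster background per cluster."""
    models = {}
    for name in sorted(clusters):
        seqs = clusters[name]
        if not seqs:
            continue
        complement = [s for other, group in clusters.items() if other != name
                      for s in group]
        if not complement:
            if skip_empty_complement:
                logger.info("cluster %s has no background sequences this "
                            "round; skipped", name)
                continue
            raise ValueError(f"cluster {name} covers the whole dataset; "
                             "no background sequences available")
        hmm = train_profile_hmm(build_cluster_msa(name, seqs), pseudocount)
        background = train_profile_hmm(
            build_cluster_msa(f"bg:{name}", complement), pseudocount)
        models[name] = ClusterModel(
            name=name, hmm=hmm, background=background,
            train_lengths={len(plain(s)) for s in seqs}, n_train=len(seqs))
    return HMMSet(models=models)


@dataclass
class ScoreRecord:
    sequence: str
    true: str | None
    best: str | None
    score: float
    scores: dict[str, float] = field(default_factory=dict)


def classify(sequence: str, hmm_set: HMMSet, true: str | None = None,
             nonstandard: str = "raise") -> ScoreRecord:
    """One-vs-all assignment among length-eligible clusters.

    Eligible clusters are those whose training set contains at least one
    sequence of the query's length; with length-variable clusters this is
    what lets a single cluster accept more than one loop length.  Ties go
    to the larger cluster, then alphabetically.
    """
    n = len(sequence)
    scores: dict[str, float] = {}
    for model in hmm_set:
        if n in model.train_lengths:
            scores[model.name] = raw_score(model.hmm, model.background,
                                           sequence, nonstandard)
    if not scores:
        return ScoreRecord(sequence=sequence, true=true, best=None,
                           score=float("nan"), scores={})
    best = max(scores, key=lambda c: (scores[c], hmm_set.models[c].n_train,
                                      # reversed name for deterministic ties
                                      tuple(-ord(ch) for ch in c)))
    return ScoreRecord(sequence=sequence, true=true, best=best,
                       score=scores[best], scores=scores)


def leave_one_out_cv(clusters: dict[str, list[LabeledSequence]],
                     seed: int = 0, pseudocount: float = 1.0
                     ) -> tuple[list[ScoreRecord], dict[str, tuple[float, float]]]:
    """Leave-one-out cross-validation of cluster prediction from sequence.

    Identical sequences are first removed within each cluster.  Each round
    holds out one randomly chosen unclassified unique sequence per cluster,
    retrains every cluster and background model without the held-out
    sequences, classifies them, and repeats until every sequence has been
    classified.  A cluster reduced to a single unique sequence cannot be
    modelled in its own round; its sequence is scored against the other
    clusters only (and logged).

    Returns all score records plus per-cluster (precision, recall).
    """
    rng = np.random.default_rng(seed)
    dedup: dict[str, list[LabeledSequence]] = {}
    for name in sorted(clusters):
        seen: set[str] = set()
        dedup[name] = []
        for seq in clusters[name]:
            s = plain(seq)
            if s not in seen:
                seen.add(s)
                dedup[name].append(seq)
    remaining = {name: list(range(len(group))) for name, group in dedup.items()}
    records: list[ScoreRecord] = []
    while any(remaining.values()):
        held: list[tuple[str, LabeledSequence]] = []
        for name in sorted(remaining):
            if remaining[name]:
                pick = remaining[name].pop(int(rng.integers(len(remaining[name]))))
                held.append((name, dedup[name][pick]))
        held_strings = {plain(s) for _, s in held}
        training = {
            name: [s for s in group if plain(s) not in held_strings]
            for name, group in dedup.items()
        }
        empty = [name for name, group in training.items() if not group]
        for name in empty:
            logger.info("cluster %s has a single unique sequence; "
                        "scoring it against the other clusters only", name)
        hmm_set = train_hmm_set(
            {n: g for n, g in training.items() if g}, pseudocount,
            skip_empty_complement=True)
        for name, seq in held:
            records.append(classify(plain(seq), hmm_set, true=name))
    return records, compute_precision_recall(records)


def compute_precision_recall(records: list[ScoreRecord]
                             ) -> dict[str, tuple[float, float]]:
    names = sorted({r.true for r in records if r.true is not None})
    stats = {}
    for c in names:
        tp = sum(1 for r in records if r.true == c and r.best == c)
        fp = sum(1 for r in records if r.true != c and r.best == c)
        fn = sum(1 for r in records if r.true == c and r.best != c)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        stats[c] = (precision, recall)
    return stats


def precision_at_full_recall(cluster: str, records: list[ScoreRecord]) -> float:
    """Precision when the score threshold admits every true cluster member.

    The threshold is the weakest true member's score for the cluster;
    precision is computed over all sequences scoring at or above it.
    """
    true_scores = [r.scores[cluster] for r in records if r.true == cluster]
    if not true_scores:
        raise ValueError(f"no true members with scores for cluster {cluster}")
    threshold = min(true_scores)
    admitted = [r for r in records
                if cluster in r.scores and r.scores[cluster] >= threshold]
    correct = sum(1 for r in admitted if r.true == cluster)
    return correct / len(admitted)


@dataclass
class ROCData:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _roc_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    order = np.lexsort((tpr, fpr))
    x = np.concatenate([[0.0], fpr[order], [1.0]])
    y = np.concatenate([[0.0], tpr[order], [1.0]])
    return float(np.trapezoid(y, x))


def macro_roc(records: list[ScoreRecord],
              thresholds: np.ndarray | None = None) -> ROCData:
    """Macro-averaged ROC over clusters from per-cluster raw scores.

    At each threshold the per-cluster TPR and FPR are averaged with equal
    weight; clusters lacking positives or negatives at the score level are
    excluded from the mean (and logged once).  AUC is the trapezoidal area.
    """
    names = sorted({r.true for r in records if r.true is not None})
    per_cluster = {}
    for c in names:
        pos = np.array([r.scores[c] for r in records
                        if r.true == c and c in r.scores])
        neg = np.array([r.scores[c] for r in records
                        if r.true != c and c in r.scores])
        if pos.size == 0 or neg.size == 0:
            logger.info("cluster %s excluded from macro ROC "
                        "(no positives or no negatives)", c)
            continue
        per_cluster[c] = (pos, neg)
    if not per_cluster:
        raise ValueError("no cluster has both positives and negatives")
    if thresholds is None:
        allscores = np.concatenate([np.concatenate(v) for v in per_cluster.values()])
        thresholds = np.sort(np.unique(allscores))[::-1]
    tpr = np.zeros(len(thresholds))
    fpr = np.zeros(len(thresholds))
    for i, t in enumerate(thresholds):
        tprs = [np.mean(pos >= t) for pos, _ in per_cluster.values()]
        fprs = [np.mean(neg >= t) for _, neg in per_cluster.values()]
        tpr[i] = np.mean(tprs)
        fpr[i] = np.mean(fprs)
    return ROCData(thresholds=np.asarray(thresholds), tpr=tpr, fpr=fpr,
                   auc=_roc_auc(fpr, tpr))


def bootstrap_auc_compare(roc_a: ROCData, roc_b: ROCData,
                          n: int = 1000, seed: int = 0) -> dict[str, float]:
    """Bootstrap test of the AUC difference between two ROC curves.

    Each replicate resamples the (FPR, TPR) points of both curves with
    replacement and recomputes the trapezoidal AUC; the p-value comes from
    a normal approximation of the replicate AUC differences.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    diffs = np.zeros(n)
    na, nb = len(roc_a.fpr), len(roc_b.fpr)
    for i in range(n):
        ia = rng.integers(0, na, size=na)
        ib = rng.integers(0, nb, size=nb)
        diffs[i] = (_roc_auc(roc_a.fpr[ia], roc_a.tpr[ia])
                    - _roc_auc(roc_b.fpr[ib], roc_b.tpr[ib]))
    mean, sd = float(diffs.mean()), float(diffs.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        p = 1.0 if abs(mean) < 1e-12 else 0.0
    else:
        p = float(2.0 * norm.sf(abs(mean) / sd))
    return {"auc_a": roc_a.auc, "auc_b": roc_b.auc,
            "mean_diff": mean, "sd_diff": sd, "p_value": p}
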