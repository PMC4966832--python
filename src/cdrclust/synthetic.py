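"""Synthetic loop families and sequence repertoires with known ground truth.

Every pipeline stage is testable without any structure download: this
module builds families of loop backbones that share a smooth arc shape
(optionally across a one-residue length difference, mimicking the
length-variable canonical classes), attaches per-family sequence motifs
with tunable mutation rates, and produces background loops/sequences that
belong to no family.

The geometry is deliberately simple — a circular-arc CA trace with ideal
backbone-atom offsets between two fixed anchor stretches shared by all
families — which is sufficient to exercise anchor superposition, DTW
scoring and clustering, but makes no claim of physical realism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .extraction import CDR_DEFINITIONS, AnchoredLoop, ChothiaResidue
from .prediction import AA_ALPHABET, LabeledSequence

__all__ = [
    "FamilySpec",
    "SyntheticTruth",
    "generate_cluster_sequences",
    "generate_loop_families",
    "generate_loop_family",
    "generate_repertoire",
]

#: Chothia position at which insertion codes are placed, per CDR type.
INSERTION_POSITION = {"L1": 30, "L2": 52, "L3": 95, "H1": 31, "H2": 52, "H3": 100}

_CA_SPACING = 3.8
_HALF_GAP = 5.0  # loop chord runs from (-5, 0, 0) to (5, 0, 0)
_ANCHOR_AA = "G"
_DEFAULT_BFACTOR = 30.0


@dataclass
class FamilySpec:
    """Parameters of one synthetic loop/sequence family."""

    base_length: int
    n_members: int
    coordinate_noise_sd: float = 0.2
    length_variant_fraction: float = 0.0
    insertion_index: int = 3
    motif: str = ""
    mutation_rate: float = 0.0
    seed: int = 0
    arc_height: float | None = None
    arc_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if self.base_length < 3:
            raise ValueError("base_length must be at least 3")
        for rate in (self.length_variant_fraction, self.mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.motif and len(self.motif) != self.base_length:
            raise ValueError("motif length must equal base_length")


@dataclass
class SyntheticTruth:
    """Ground-truth labels attached to generated loops and sequences."""

    loop_families: dict[str, int] = field(default_factory=dict)
    sequence_families: dict[str, int] = field(default_factory=dict)
    insertion_sites: dict[str, int | None] = field(default_factory=dict)

    def merge(self, other: "SyntheticTruth") -> None:
        self.loop_families.update(other.loop_families)
        self.sequence_families.update(other.sequence_families)
        self.insertion_sites.update(other.insertion_sites)


def _frame_vectors(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(tangent, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    normal = ref - np.dot(ref, tangent) * tangent
    normal /= np.linalg.norm(normal)
    binormal = np.cross(tangent, normal)
    return normal, binormal


def _backbone_from_ca(ca: np.ndarray) -> np.ndarray:
    """(L, 4, 3) N, CA, C, O atoms from a CA trace with ideal-ish offsets."""
    n = len(ca)
    atoms = np.zeros((n, 4, 3))
    for i in range(n):
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        tangent = ca[hi] - ca[lo]
        tangent = tangent / np.linalg.norm(tangent)
        normal, binormal = _frame_vectors(tangent)
        atoms[i, 0] = ca[i] - 1.2 * tangent + 0.5 * normal  # N
        atoms[i, 1] = ca[i]                                  # CA
        atoms[i, 2] = ca[i] + 1.2 * tangent + 0.5 * normal   # C
        atoms[i, 3] = ca[i] + 1.6 * tangent + 1.2 * normal + 0.4 * binormal  # O
    return atoms


def _anchor_ca() -> tuple[np.ndarray, np.ndarray]:
    # helical wobble off the x-axis keeps the anchor point set well away
    # from collinearity, so the rigid anchor fit is rotationally stable
    xs_n = -_HALF_GAP - _CA_SPACING * np.arange(5, 0, -1)
    xs_c = _HALF_GAP + _CA_SPACING * np.arange(1, 6)
    phase_n = 2.1 * np.arange(5)
    phase_c = 2.1 * np.arange(5) + 0.7
    n = np.stack([xs_n, 1.8 * np.sin(phase_n), 1.8 * np.cos(phase_n)], axis=1)
    c = np.stack([xs_c, 1.8 * np.sin(phase_c), 1.8 * np.cos(phase_c)], axis=1)
    return n, c


def _arc_ca(ts: np.ndarray, height: float, angle_deg: float) -> np.ndarray:
    """Loop CA positions along a bulged arc between the anchor endpoints."""
    a = np.array([-_HALF_GAP, 0.0, 0.0])
    b = np.array([_HALF_GAP, 0.0, 0.0])
    theta = np.deg2rad(angle_deg)
    u = np.array([0.0, np.cos(theta), np.sin(theta)])
    return (a[None, :] + ts[:, None] * (b - a)[None, :]
            + height * np.sin(np.pi * ts)[:, None] * u[None, :])


def _chothia_labels(cdr_type: str, length: int) -> list[tuple[int, str]]:
    """Chothia (position, insertion code) labels for a loop of this length.

    Short loops drop positions from the middle of the span (as Chothia
    deletions do); long loops put lettered insertions at the type's
    canonical insertion position.
    """
    d = CDR_DEFINITIONS[cdr_type]
    span = d.end - d.start + 1
    if length <= span:
        head = (length + 1) // 2
        tail = length - head
        positions = list(range(d.start, d.start + head))
        positions += list(range(d.end - tail + 1, d.end + 1))
        return [(p, "") for p in positions]
    ins_pos = INSERTION_POSITION[cdr_type]
    labels: list[tuple[int, str]] = []
    for p in range(d.start, d.end + 1):
        labels.append((p, ""))
        if p == ins_pos:
            for k in range(length - span):
                labels.append((p, chr(ord("A") + k)))
    return labels


def _insert_label(labels: list[tuple[int, str]], index: int) -> list[tuple[int, str]]:
    """Insert one lettered label after position ``index - 1``."""
    pos, icode = labels[index - 1]
    nxt = "A" if icode == "" else chr(ord(icode) + 1)
    return labels[:index] + [(pos, nxt)] + labels[index:]


def _draw_sequence(spec: FamilySpec, rng: np.random.Generator) -> str:
    out = []
    for aa in (spec.motif or "X" * spec.base_length):
        if aa == "X" or rng.random() < spec.mutation_rate:
            out.append(AA_ALPHABET[rng.integers(20)])
        else:
            out.append(aa)
    return "".join(out)


def _make_loop(source: str, cdr_type: str, labels: list[tuple[int, str]],
               sequence: str, loop_atoms: np.ndarray,
               n_atoms: np.ndarray, c_atoms: np.ndarray) -> AnchoredLoop:
    def residues(atom_blocks, lbls, seq, chain="A"):
        out = []
        for (pos, icode), aa, atoms in zip(lbls, seq, atom_blocks):
            out.append(ChothiaResidue(
                chain_id=chain, position=pos, insertion_code=icode,
                amino_acid=aa, backbone_atoms=atoms,
                bfactors=np.full(4, _DEFAULT_BFACTOR)))
        return out

    d = CDR_DEFINITIONS[cdr_type]
    n_labels = [(p, "") for p in range(d.start - 5, d.start)]
    c_labels = [(p, "") for p in range(d.end + 1, d.end + 6)]
    return AnchoredLoop(
        loop_residues=residues(loop_atoms, labels, sequence),
        n_anchor=residues(n_atoms, n_labels, _ANCHOR_AA * 5),
        c_anchor=residues(c_atoms, c_labels, _ANCHOR_AA * 5),
        source=source,
        cdr_type=cdr_type,
        resolution=2.0,
        method="X-RAY DIFFRACTION",
    )


def generate_loop_family(spec: FamilySpec, family_index: int = 0,
                         cdr_type: str = "L1"
                         ) -> tuple[list[AnchoredLoop], SyntheticTruth]:
    """Generate one family of anchored loops sharing an arc conformation.

    Members are the family's base backbone plus iid Gaussian coordinate
    noise; a ``length_variant_fraction`` of members carry one extra residue,
    locally interpolated into the arc at ``insertion_index``, so the family
    spans two lengths while keeping its shape.
    """
    rng = np.random.default_rng(spec.seed)
    height = spec.arc_height if spec.arc_height is not None else 5.0 + 1.5 * family_index
    angle = spec.arc_angle_deg if spec.arc_angle_deg is not None else 90.0 * family_index

    L = spec.base_length
    ts = np.arange(1, L + 1) / (L + 1)
    base_ca = _arc_ca(ts, height, angle)
    k = spec.insertion_index
    if not 1 <= k <= L - 1:
        raise ValueError("insertion_index must be inside the loop")
    t_new = (ts[k - 1] + ts[k]) / 2.0
    variant_ts = np.sort(np.append(ts, t_new))
    variant_ca = _arc_ca(variant_ts, height, angle)
    n_anchor_ca, c_anchor_ca = _anchor_ca()
    n_atoms = _backbone_from_ca(n_anchor_ca)
    c_atoms = _backbone_from_ca(c_anchor_ca)
    base_labels = _chothia_labels(cdr_type, L)
    variant_labels = _insert_label(base_labels, k)

    n_variant = int(round(spec.length_variant_fraction * spec.n_members))
    variant_members = set(rng.permutation(spec.n_members)[:n_variant].tolist())

    loops: list[AnchoredLoop] = []
    truth = SyntheticTruth()
    for m in range(spec.n_members):
        source = f"S{family_index}{m:02d}_A"
        is_variant = m in variant_members
        ca = variant_ca if is_variant else base_ca
        labels = variant_labels if is_variant else base_labels
        seq = _draw_sequence(spec, rng)
        if is_variant:
            seq = seq[:k] + AA_ALPHABET[rng.integers(20)] + seq[k:]
        atoms = _backbone_from_ca(ca)
        atoms = atoms + rng.normal(0.0, spec.coordinate_noise_sd, atoms.shape)
        na = n_atoms + rng.normal(0.0, spec.coordinate_noise_sd, n_atoms.shape)
        ca_atoms = c_atoms + rng.normal(0.0, spec.coordinate_noise_sd, c_atoms.shape)
        loops.append(_make_loop(source, cdr_type, labels, seq, atoms, na, ca_atoms))
        truth.loop_families[source] = family_index
        truth.sequence_families[source] = family_index
        truth.insertion_sites[source] = k if is_variant else None
    return loops, truth


def generate_loop_families(specs: list[FamilySpec], cdr_type: str = "L1"
                           ) -> tuple[list[AnchoredLoop], SyntheticTruth]:
    """Generate several families with distinct arcs; warn if they crowd.

    Families without explicit arc parameters get spread directions and
    bulge heights; a warning is raised when the base arcs come closer than
    twice the 3-sigma noise radius, i.e. when clusters may overlap.
    """
    all_loops: list[AnchoredLoop] = []
    truth = SyntheticTruth()
    base_arcs = []
    for f, spec in enumerate(specs):
        loops, t = generate_loop_family(spec, family_index=f, cdr_type=cdr_type)
        all_loops.extend(loops)
        truth.merge(t)
        height = spec.arc_height if spec.arc_height is not None else 5.0 + 1.5 * f
        angle = spec.arc_angle_deg if spec.arc_angle_deg is not None else 90.0 * f
        ts = np.arange(1, spec.base_length + 1) / (spec.base_length + 1)
        base_arcs.append(_arc_ca(ts, height, angle))
    max_sd = max(s.coordinate_noise_sd for s in specs)
    for i in range(len(base_arcs)):
        for j in range(i + 1, len(base_arcs)):
            d = np.sqrt(((base_arcs[i][:, None, :] - base_arcs[j][None, :, :]) ** 2
                         ).sum(-1)).min()
            if d < 2 * 3 * max_sd:
                warnings.warn(
                    f"families {i} and {j} are only {d:.2f} Å apart; "
                    f"coordinate noise sd {max_sd} may make them overlap")
    return all_loops, truth


def generate_cluster_sequences(spec: FamilySpec, family_index: int = 0,
                               cdr_type: str = "L1", id_prefix: str = "seq"
                               ) -> tuple[list[tuple[str, LabeledSequence]], SyntheticTruth]:
    """Generate Chothia-labelled sequences for one motif family.

    Sequences follow the motif with per-position mutations at
    ``mutation_rate`` (wildcard 'X' positions are uniform); a
    ``length_variant_fraction`` of them carry one inserted residue at
    ``insertion_index``, labelled with an insertion code, mirroring a
    length-variable cluster.
    """
    rng = np.random.default_rng(spec.seed + 10_000)
    base_labels = _chothia_labels(cdr_type, spec.base_length)
    variant_labels = _insert_label(base_labels, spec.insertion_index)
    n_variant = int(round(spec.length_variant_fraction * spec.n_members))
    variant_members = set(rng.permutation(spec.n_members)[:n_variant].tolist())
    out: list[tuple[str, LabeledSequence]] = []
    truth = SyntheticTruth()
    for m in range(spec.n_members):
        name = f"{id_prefix}{family_index}_{m:03d}"
        seq = _draw_sequence(spec, rng)
        if m in variant_members:
            k = spec.insertion_index
            seq = seq[:k] + AA_ALPHABET[rng.integers(20)] + seq[k:]
            labels = variant_labels
        else:
            labels = base_labels
        labeled = [(p, ic, aa) for (p, ic), aa in zip(labels, seq)]
        out.append((name, labeled))
        truth.sequence_families[name] = family_index
        truth.insertion_sites[name] = (spec.insertion_index
                                       if m in variant_members else None)
    return out, truth


def generate_repertoire(specs: list[FamilySpec], background_fraction: float,
                        n: int, seed: int = 0,
                        background_lengths: tuple[int, ...] | None = None
                        ) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate a plain-sequence repertoire: family draws plus background.

    ``background_fraction`` of the n sequences are uniform-random over the
    20-letter alphabet at the given lengths (default: the family lengths);
    the rest are drawn from the family motifs in proportion, each family
    keeping its own length-variant fraction.
    """
    rng = np.random.default_rng(seed)
    n_background = int(round(background_fraction * n))
    n_family = n - n_background
    if background_lengths is None:
        background_lengths = tuple(sorted({s.base_length for s in specs}))
    sequences: dict[str, str] = {}
    truth = SyntheticTruth()
    counter = 0
    for i in range(n_family):
        f = i % len(specs)
        spec = specs[f]
        local = FamilySpec(
            base_length=spec.base_length, n_members=1,
            length_variant_fraction=0.0, insertion_index=spec.insertion_index,
            motif=spec.motif, mutation_rate=spec.mutation_rate,
            seed=int(rng.integers(2 ** 31)))
        seq = _draw_sequence(local, np.random.default_rng(local.seed))
        if rng.random() < spec.length_variant_fraction:
            k = spec.insertion_index
            seq = seq[:k] + AA_ALPHABET[rng.integers(20)] + seq[k:]
        name = f"rep{counter:06d}"
        counter += 1
        sequences[name] = seq
        truth.sequence_families[name] = f
    for _ in range(n_background):
        length = int(rng.choice(background_lengths))
        seq = "".join(AA_ALPHABET[rng.integers(20)] for _ in range(length))
        name = f"rep{counter:06d}"
        counter += 1
        sequences[name] = seq
        truth.sequence_families[name] = -1
    return sequences, truth
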