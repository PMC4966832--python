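"""Shared fixtures: toy PDB text, hand-built loops, synthetic families."""

from __future__ import annotations

import numpy as np
import pytest

from cdrclust.extraction import AnchoredLoop, ChothiaResidue
from cdrclust.synthetic import FamilySpec, generate_loop_families


def make_residue(position, icode="", aa="A", chain="L", coords=None, bfactors=None):
    if coords is None:
        rng = np.random.default_rng(position * 7 + len(icode))
        base = np.array([position * 3.8, 0.0, 0.0])
        coords = base + rng.normal(0, 0.5, (4, 3))
    if bfactors is None:
        bfactors = np.full(4, 30.0)
    return ChothiaResidue(chain_id=chain, position=position, insertion_code=icode,
                          amino_acid=aa, backbone_atoms=coords, bfactors=bfactors)


def make_chain(positions, aa="A", chain="L"):
    """Residues at the given (position, icode) labels with synthetic coords."""
    out = []
    for p in positions:
        pos, icode = p if isinstance(p, tuple) else (p, "")
        out.append(make_residue(pos, icode, aa=aa, chain=chain))
    return out


def make_loop_from_coords(loop_coords, anchor_coords, source="TEST_A",
                          sequence=None, cdr_type="L1", resolution=2.0):
    """AnchoredLoop from raw (L,4,3) loop and (10,4,3) anchor coordinates."""
    loop_coords = np.asarray(loop_coords, float)
    anchor_coords = np.asarray(anchor_coords, float)
    L = loop_coords.shape[0]
    seq = sequence or "A" * L
    loop = [
        ChothiaResidue("A", 24 + i, "", seq[i], loop_coords[i], np.full(4, 30.0))
        for i in range(L)
    ]
    n_anchor = [
        ChothiaResidue("A", 19 + i, "", "G", anchor_coords[i], np.full(4, 30.0))
        for i in range(5)
    ]
    c_anchor = [
        ChothiaResidue("A", 35 + i, "", "G", anchor_coords[5 + i], np.full(4, 30.0))
        for i in range(5)
    ]
    return AnchoredLoop(loop_residues=loop, n_anchor=n_anchor, c_anchor=c_anchor,
                       source=source, cdr_type=cdr_type, resolution=resolution)


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a random translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31)))
                        ).as_matrix()
    t = rng.normal(0, 10.0, 3)
    return R, t


@pytest.fixture
def toy_pdb_text():
    """A minimal 3-residue Chothia-numbered PDB chain (positions 24-26)."""
    lines = [
        "EXPDTA    X-RAY DIFFRACTION",
        "REMARK   2 RESOLUTION.    1.90 ANGSTROMS.",
    ]
    serial = 1
    for k, (pos, resname) in enumerate([(24, "ALA"), (25, "GLY"), (26, "SER")]):
        for i, atom in enumerate(["N", "CA", "C", "O"]):
            x, y, z = pos * 3.8 + i * 0.5, k * 1.0, i * 0.3
            lines.append(
                f"ATOM  {serial:5d}  {atom:<3} {resname} L{pos:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{25.0:6.2f}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def three_family_loops():
    """Three well-separated loop families, one spanning two lengths."""
    specs = [
        FamilySpec(base_length=11, n_members=10, coordinate_noise_sd=0.2,
                   length_variant_fraction=0.4, insertion_index=5,
                   motif="ASTDYGNSWLK", mutation_rate=0.05, seed=1),
        FamilySpec(base_length=11, n_members=8, coordinate_noise_sd=0.2,
                   motif="GYTFTNYGMNW", mutation_rate=0.05, seed=2),
        FamilySpec(base_length=9, n_members=8, coordinate_noise_sd=0.2,
                   motif="QQYNSYPLT", mutation_rate=0.05, seed=3),
    ]
    return generate_loop_families(specs, cdr_type="L1")


@pytest.fixture
def three_motif_clusters():
    """Labelled sequence clusters from three distinct motifs."""
    from cdrclust.synthetic import generate_cluster_sequences

    specs = [
        FamilySpec(base_length=10, n_members=20, motif="ASTDYGNSWL",
                   mutation_rate=0.05, length_variant_fraction=0.25,
                   insertion_index=5, seed=1),
        FamilySpec(base_length=10, n_members=20, motif="QQWWSYPPTT",
                   mutation_rate=0.05, seed=2),
        FamilySpec(base_length=9, n_members=20, motif="KLHRGYEDA",
                   mutation_rate=0.05, seed=3),
    ]
    clusters = {}
    for f, spec in enumerate(specs):
        seqs, _ = generate_cluster_sequences(spec, family_index=f)
        clusters[f"C{f}"] = [ls for _, ls in seqs]
    return specs, clusters
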