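"""Extraction of Chothia-numbered CDR loops from antibody PDB files.

Input structures are expected to carry Chothia numbering in their residue
ids (the SAbDab dialect: insertion codes such as 30A mark loop insertions).
A CDR loop is cut out by Chothia position range together with its anchors,
the five framework residues on either side, which are later used to place
all loops of one CDR type in a common reference frame.

Quality control follows the usual crystallographic criteria for loop work:
X-ray structures only, resolution no worse than 2.8 Å, complete backbone
for loop and anchors, and backbone B-factors in (0, 80].
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BACKBONE_ATOMS",
    "CDR_DEFINITIONS",
    "AnchoredLoop",
    "CDRDefinition",
    "ChothiaResidue",
    "ExtractionError",
    "FilterReport",
    "ParseError",
    "ParsedStructure",
    "extract_cdr",
    "loop_sequence",
    "parse_chothia_pdb",
    "quality_filter",
    "read_loops_jsonl",
    "write_loop_pdb",
    "write_loops_fasta",
    "write_loops_jsonl",
]

#: Backbone atom names, in storage order.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class ParseError(ValueError):
    """Raised when a PDB record cannot be interpreted (names the line)."""


class ExtractionError(ValueError):
    """Raised when a CDR or its anchors cannot be extracted from a chain."""

    def __init__(self, message: str, reason: str = "missing_atoms"):
        super().__init__(message)
        self.reason = reason


@dataclass
class ChothiaResidue:
    """One residue with Chothia number, insertion code and backbone atoms.

    ``backbone_atoms`` is a (4, 3) array in N, CA, C, O order; missing atoms
    are NaN rows and make the residue incomplete.
    """

    chain_id: str
    position: int
    insertion_code: str
    amino_acid: str
    backbone_atoms: np.ndarray
    bfactors: np.ndarray

    def __post_init__(self) -> None:
        self.backbone_atoms = np.asarray(self.backbone_atoms, dtype=float).reshape(4, 3)
        self.bfactors = np.asarray(self.bfactors, dtype=float).reshape(4)

    @property
    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.backbone_atoms)))

    @property
    def label(self) -> tuple[int, str]:
        return (self.position, self.insertion_code)

    def copy(self) -> "ChothiaResidue":
        return replace(
            self,
            backbone_atoms=self.backbone_atoms.copy(),
            bfactors=self.bfactors.copy(),
        )


@dataclass(frozen=True)
class CDRDefinition:
    """Chothia boundaries of one CDR type plus the anchor length."""

    cdr_type: str
    start: int
    end: int
    anchor_length: int = 5


#: Chothia CDR boundaries; H2 is pre-extended by two N-terminal residues
#: (50-56 instead of 52-56), which improves sequence-based class prediction.
CDR_DEFINITIONS: dict[str, CDRDefinition] = {
    "L1": CDRDefinition("L1", 24, 34),
    "L2": CDRDefinition("L2", 50, 56),
    "L3": CDRDefinition("L3", 89, 97),
    "H1": CDRDefinition("H1", 26, 32),
    "H2": CDRDefinition("H2", 50, 56),
    "H3": CDRDefinition("H3", 95, 102),
}


@dataclass
class AnchoredLoop:
    """A CDR loop with its five N- and C-terminal anchor residues."""

    loop_residues: list[ChothiaResidue]
    n_anchor: list[ChothiaResidue]
    c_anchor: list[ChothiaResidue]
    source: str
    cdr_type: str
    resolution: float | None = None
    method: str | None = "X-RAY DIFFRACTION"
    chain_class: str = "unknown"
    frame_id: str | None = None

    def __len__(self) -> int:
        return len(self.loop_residues)

    @property
    def sequence(self) -> str:
        return loop_sequence(self)

    @property
    def labels(self) -> list[tuple[int, str]]:
        return [r.label for r in self.loop_residues]

    @property
    def labeled_sequence(self) -> list[tuple[int, str, str]]:
        """(position, insertion_code, amino acid) triples for the loop."""
        return [(r.position, r.insertion_code, r.amino_acid) for r in self.loop_residues]

    def loop_coords(self) -> np.ndarray:
        """(L, 4, 3) backbone coordinates of the loop residues."""
        return np.stack([r.backbone_atoms for r in self.loop_residues])

    def anchor_coords(self) -> np.ndarray:
        """(10, 4, 3) backbone coordinates, N-anchor then C-anchor."""
        return np.stack([r.backbone_atoms for r in self.n_anchor + self.c_anchor])

    def all_residues(self) -> list[ChothiaResidue]:
        return self.n_anchor + self.loop_residues + self.c_anchor

    def backbone_bfactors(self) -> np.ndarray:
        return np.concatenate([r.bfactors for r in self.all_residues()])

    def is_complete(self) -> bool:
        return all(r.is_complete for r in self.all_residues())

    def copy(self) -> "AnchoredLoop":
        return replace(
            self,
            loop_residues=[r.copy() for r in self.loop_residues],
            n_anchor=[r.copy() for r in self.n_anchor],
            c_anchor=[r.copy() for r in self.c_anchor],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AnchoredLoop":
        """Return a rigidly moved copy (x -> R x + t applied to every atom)."""
        out = self.copy()
        for res in out.all_residues():
            res.backbone_atoms = res.backbone_atoms @ rotation.T + translation
        return out


@dataclass
class FilterReport:
    """Book-keeping of quality filtering; inputs = kept + rejections."""

    input_count: int = 0
    kept_count: int = 0
    rejections: list[tuple[str, str]] = field(default_factory=list)

    def is_consistent(self) -> bool:
        return self.input_count == self.kept_count + len(self.rejections)


@dataclass
class ParsedStructure:
    """Chains of Chothia residues plus header metadata."""

    chains: dict[str, list[ChothiaResidue]]
    resolution: float | None
    method: str | None


def _sort_key(position: int, icode: str) -> tuple[int, str]:
    # blank insertion code sorts before 'A' < 'B' < ...
    return (position, icode)


def parse_chothia_pdb(pdb_text: str) -> ParsedStructure:
    """Parse a Chothia-numbered PDB file into per-chain residue lists.

    Only ATOM records of the first model are used.  Alternate locations are
    resolved per atom by highest occupancy, ties going to altloc 'A' (then
    alphabetically).  Residues are ordered by (position, insertion code).
    Non-amino-acid residues are skipped with a warning; malformed ATOM
    records raise :class:`ParseError` naming the offending line.
    """
    resolution: float | None = None
    method: str | None = None
    # (chain, pos, icode) -> {"resname": str, atoms: {name: (occ, altloc, xyz, b)}}
    residues: dict[tuple[str, int, str], dict] = {}
    warned: set[str] = set()

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec == "EXPDTA":
            method = line[10:].strip()
        elif line.startswith("REMARK   2 RESOLUTION"):
            tokens = line[22:].replace("ANGSTROMS", " ").replace("ANGSTROM", " ").split()
            for tok in tokens:
                try:
                    resolution = float(tok)
                    break
                except ValueError:
                    continue
        elif rec in ("ENDMDL",):
            break  # first model only
        elif rec == "ATOM  ":
            try:
                name = line[12:16].strip()
                altloc = line[16].strip()
                resname = line[17:20].strip()
                chain = line[21]
                pos = int(line[22:26])
                icode = line[26].strip()
                xyz = np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
                occ = float(line[54:60]) if line[54:60].strip() else 1.0
                bfac = float(line[60:66]) if line[60:66].strip() else 0.0
            except (ValueError, IndexError) as exc:
                raise ParseError(f"malformed ATOM record at line {lineno}: {line!r}") from exc
            if resname not in THREE_TO_ONE:
                if resname not in warned:
                    warnings.warn(f"skipping non-standard residue {resname}", stacklevel=2)
                    warned.add(resname)
                continue
            if name not in BACKBONE_ATOMS:
                continue
            key = (chain, pos, icode)
            entry = residues.setdefault(key, {"resname": resname, "atoms": {}})
            prev = entry["atoms"].get(name)
            cand = (occ, altloc, xyz, bfac)
            if prev is None or _altloc_wins(cand, prev):
                entry["atoms"][name] = cand

    chains: dict[str, list[ChothiaResidue]] = {}
    for (chain, pos, icode) in sorted(residues, key=lambda k: (k[0], _sort_key(k[1], k[2]))):
        entry = residues[(chain, pos, icode)]
        coords = np.full((4, 3), np.nan)
        bfacs = np.full(4, np.nan)
        for i, atom in enumerate(BACKBONE_ATOMS):
            if atom in entry["atoms"]:
                _, _, xyz, bfac = entry["atoms"][atom]
                coords[i] = xyz
                bfacs[i] = bfac
        chains.setdefault(chain, []).append(
            ChothiaResidue(
                chain_id=chain,
                position=pos,
                insertion_code=icode,
                amino_acid=THREE_TO_ONE[entry["resname"]],
                backbone_atoms=coords,
                bfactors=bfacs,
            )
        )
    return ParsedStructure(chains=chains, resolution=resolution, method=method)


def _altloc_wins(cand: tuple, prev: tuple) -> bool:
    """Occupancy decides; ties prefer altloc 'A', then alphabetical."""
    occ_c, alt_c = cand[0], cand[1] or "A"
    occ_p, alt_p = prev[0], prev[1] or "A"
    if not math.isclose(occ_c, occ_p):
        return occ_c > occ_p
    return alt_c < alt_p


def extract_cdr(
    chain_residues: list[ChothiaResidue],
    cdr_def: CDRDefinition,
    source: str = "UNKN_?",
    resolution: float | None = None,
    method: str | None = "X-RAY DIFFRACTION",
    chain_class: str = "unknown",
) -> AnchoredLoop:
    """Cut out one CDR loop plus its 5+5 sequence-adjacent anchor residues.

    The loop is every residue with start <= Chothia position <= end
    (insertion codes included); anchors are the five residues immediately
    before and after the loop in chain order.  Missing residues or backbone
    atoms in the loop or anchor region raise :class:`ExtractionError`.
    """
    ordered = sorted(chain_residues, key=lambda r: _sort_key(r.position, r.insertion_code))
    idx = [i for i, r in enumerate(ordered) if cdr_def.start <= r.position <= cdr_def.end]
    if not idx:
        raise ExtractionError(
            f"{source}: no residues in Chothia range "
            f"{cdr_def.start}-{cdr_def.end} for {cdr_def.cdr_type}"
        )
    first, last = idx[0], idx[-1]
    k = cdr_def.anchor_length
    if first < k or last + k >= len(ordered):
        raise ExtractionError(
            f"{source}: incomplete anchors for {cdr_def.cdr_type} "
            f"(need {k} residues on each side)"
        )
    loop = [ordered[i].copy() for i in range(first, last + 1)]
    n_anchor = [ordered[i].copy() for i in range(first - k, first)]
    c_anchor = [ordered[i].copy() for i in range(last + 1, last + 1 + k)]
    out = AnchoredLoop(
        loop_residues=loop,
        n_anchor=n_anchor,
        c_anchor=c_anchor,
        source=source,
        cdr_type=cdr_def.cdr_type,
        resolution=resolution,
        method=method,
        chain_class=chain_class,
    )
    if not out.is_complete():
        bad = [r.label for r in out.all_residues() if not r.is_complete]
        raise ExtractionError(
            f"{source}: missing backbone atoms at {bad} in {cdr_def.cdr_type} loop/anchors"
        )
    return out


def loop_sequence(loop: AnchoredLoop) -> str:
    """One-letter sequence of the loop residues (anchors excluded)."""
    return "".join(r.amino_acid for r in loop.loop_residues)


def quality_filter(
    loops: list[AnchoredLoop],
    method: str | None = None,
    resolution_max: float = 2.8,
    bfactor_max: float = 80.0,
    include_anchor_bfactors: bool = True,
) -> tuple[list[AnchoredLoop], FilterReport]:
    """Apply the structural quality filters and report every rejection.

    Kept loops come from X-ray structures at resolution <= ``resolution_max``
    (boundary kept), are complete, and have every backbone B-factor b with
    0 < b <= ``bfactor_max``.  B-factors are checked over loop and anchor
    backbone by default.  Identical sequences are deliberately *not*
    deduplicated: the same sequence can adopt distinct conformations.
    """
    report = FilterReport(input_count=len(loops))
    kept: list[AnchoredLoop] = []
    for loop in loops:
        meth = method if method is not None else loop.method
        if meth is None or "X-RAY" not in meth.upper():
            report.rejections.append((loop.source, "not_xray"))
            continue
        if loop.resolution is None or loop.resolution > resolution_max:
            report.rejections.append((loop.source, "resolution"))
            continue
        if not loop.is_complete():
            report.rejections.append((loop.source, "missing_atoms"))
            continue
        if include_anchor_bfactors:
            bfacs = loop.backbone_bfactors()
        else:
            bfacs = np.concatenate([r.bfactors for r in loop.loop_residues])
        if np.any(~np.isfinite(bfacs)) or np.any(bfacs <= 0.0) or np.any(bfacs > bfactor_max):
            report.rejections.append((loop.source, "bfactor"))
            continue
        kept.append(loop)
    report.kept_count = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# serialization

def _residue_to_dict(res: ChothiaResidue) -> dict:
    return {
        "chain": res.chain_id,
        "pos": res.position,
        "icode": res.insertion_code,
        "aa": res.amino_acid,
        "xyz": np.where(np.isfinite(res.backbone_atoms), res.backbone_atoms, None).tolist(),
        "b": np.where(np.isfinite(res.bfactors), res.bfactors, None).tolist(),
    }


def _residue_from_dict(d: dict) -> ChothiaResidue:
    xyz = np.array(
        [[np.nan if v is None else v for v in row] for row in d["xyz"]], dtype=float
    )
    b = np.array([np.nan if v is None else v for v in d["b"]], dtype=float)
    return ChothiaResidue(d["chain"], d["pos"], d["icode"], d["aa"], xyz, b)


def loop_to_dict(loop: AnchoredLoop) -> dict:
    return {
        "source": loop.source,
        "cdr_type": loop.cdr_type,
        "sequence": loop.sequence,
        "resolution": loop.resolution,
        "method": loop.method,
        "chain_class": loop.chain_class,
        "loop": [_residue_to_dict(r) for r in loop.loop_residues],
        "n_anchor": [_residue_to_dict(r) for r in loop.n_anchor],
        "c_anchor": [_residue_to_dict(r) for r in loop.c_anchor],
    }


def loop_from_dict(d: dict) -> AnchoredLoop:
    return AnchoredLoop(
        loop_residues=[_residue_from_dict(r) for r in d["loop"]],
        n_anchor=[_residue_from_dict(r) for r in d["n_anchor"]],
        c_anchor=[_residue_from_dict(r) for r in d["c_anchor"]],
        source=d["source"],
        cdr_type=d["cdr_type"],
        resolution=d.get("resolution"),
        method=d.get("method"),
        chain_class=d.get("chain_class", "unknown"),
    )


def write_loops_jsonl(loops: list[AnchoredLoop], path) -> None:
    with open(path, "w") as fh:
        for loop in loops:
            fh.write(json.dumps(loop_to_dict(loop)) + "\n")


def read_loops_jsonl(path) -> list[AnchoredLoop]:
    with open(path) as fh:
        return [loop_from_dict(json.loads(line)) for line in fh if line.strip()]


def write_loops_fasta(loops: list[AnchoredLoop], path) -> None:
    with open(path, "w") as fh:
        for loop in loops:
            fh.write(f">{loop.source} {loop.cdr_type}\n{loop.sequence}\n")


def write_filter_report_csv(report: FilterReport, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "reason"])
        for source, reason in report.rejections:
            writer.writerow([source, reason])


def write_loop_pdb(loop: AnchoredLoop) -> str:
    """Serialize a loop (anchors included) back to PDB ATOM records."""
    lines = []
    if loop.method:
        lines.append(f"EXPDTA    {loop.method}")
    if loop.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {loop.resolution:.2f} ANGSTROMS.")
    serial = 1
    for res in loop.all_residues():
        resname = ONE_TO_THREE[res.amino_acid]
        for i, atom in enumerate(BACKBONE_ATOMS):
            x, y, z = res.backbone_atoms[i]
            if not np.isfinite([x, y, z]).all():
                continue
            b = res.bfactors[i] if np.isfinite(res.bfactors[i]) else 0.0
            name_fmt = f" {atom:<3}" if len(atom) < 4 else atom
            lines.append(
                f"ATOM  {serial:5d} {name_fmt} {resname} {res.chain_id}"
                f"{res.position:4d}{res.insertion_code or ' '}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
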