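"""Atom correspondences between initial and final structures.

The morph is driven by springs connecting atoms of the (semiflexible)
initial structure to the positions of their counterparts in the (rigid)
final structure.  Correspondence is established per chain pair either by
a global gapped sequence alignment ("gapped threading") or by an
explicit user residue map ("threading").  Watson-Crick distance
restraints between codon and anticodon bases are built the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from .model_io import (
    ChainModel,
    PolymerClass,
    Residue,
    StructureModel,
    extract_sequence,
    representative_atom_name,
)

__all__ = [
    "AlignmentScoring",
    "SequenceAlignment",
    "SpringSet",
    "DistanceRestraint",
    "gapped_align",
    "build_springs",
    "wc_restraints",
    "read_residue_map",
    "alignment_to_fasta",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class AlignmentScoring:
    """Affine-gap global alignment parameters.

    Protein pairs score by BLOSUM62; nucleic pairs by match/mismatch.
    A gap of length L costs ``gap_open + L * gap_extend`` (both negative).
    """

    polymer_class: PolymerClass = PolymerClass.PROTEIN
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def score_pair(self, a: str, b: str) -> float:
        if self.polymer_class is PolymerClass.PROTEIN:
            try:
                return float(_BLOSUM62[a, b])
            except (KeyError, IndexError):
                return float(self.mismatch)
        return float(self.match) if a == b else float(self.mismatch)


@dataclass
class SequenceAlignment:
    """Ordered aligned index pairs; None marks a gap on that side."""

    aligned_pairs: List[Tuple[Optional[int], Optional[int]]]
    score: float
    scoring: AlignmentScoring

    def matched_pairs(self) -> List[Tuple[int, int]]:
        return [(i, j) for i, j in self.aligned_pairs
                if i is not None and j is not None]


_NEG = -1e30


def gapped_align(seq_a: str, seq_b: str,
                 scoring: Optional[AlignmentScoring] = None) -> SequenceAlignment:
    """Optimal global alignment with affine gaps (Gotoh's algorithm).

    Ties are broken deterministically during traceback: prefer an
    aligned pair, then a gap in B (consuming A), then a gap in A,
    resolved from the alignment's right end leftwards.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or AlignmentScoring()
    n, m = len(seq_a), len(seq_b)
    go, ge = scoring.gap_open, scoring.gap_extend

    M = np.full((n + 1, m + 1), _NEG)   # seq_a[i-1] aligned to seq_b[j-1]
    X = np.full((n + 1, m + 1), _NEG)   # gap in B (A residue vs gap)
    Y = np.full((n + 1, m + 1), _NEG)   # gap in A
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + ge * i
    for j in range(1, m + 1):
        Y[0, j] = go + ge * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scoring.score_pair(seq_a[i - 1], seq_b[j - 1])
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] + go + ge,
                          X[i - 1, j] + ge,
                          Y[i - 1, j] + go + ge)
            Y[i, j] = max(M[i, j - 1] + go + ge,
                          Y[i, j - 1] + ge,
                          X[i, j - 1] + go + ge)

    # traceback, preferring M > X (gap in B) > Y (gap in A)
    i, j = n, m
    end = {"M": M[n, m], "X": X[n, m], "Y": Y[n, m]}
    score = float(max(end.values()))
    state = next(st for st in ("M", "X", "Y") if end[st] >= score - 1e-9)
    pairs: List[Tuple[Optional[int], Optional[int]]] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            s = scoring.score_pair(seq_a[i - 1], seq_b[j - 1])
            target = M[i, j] - s
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i, j] - target) < tol:
                    state = st
                    break
        elif state == "X":
            pairs.append((i - 1, None))
            here = X[i, j]
            i -= 1
            if abs(M[i, j] + go + ge - here) < tol:
                state = "M"
            elif abs(X[i, j] + ge - here) < tol:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            pairs.append((None, j - 1))
            here = Y[i, j]
            j -= 1
            if abs(M[i, j] + go + ge - here) < tol:
                state = "M"
            elif abs(Y[i, j] + ge - here) < tol:
                state = "Y"
            else:
                state = "X"
        if i == 0 and j == 0:
            break
    pairs.reverse()
    return SequenceAlignment(aligned_pairs=pairs, score=score, scoring=scoring)


@dataclass
class SpringSet:
    """Atom -> fixed-target-point springs with force constant F.

    ``atom_refs[k]`` is (chain_id, residue_number, insertion_code,
    atom_name) in the mobile (initial) structure; ``targets[k]`` is the
    corresponding point (angstrom) taken from the pre-aligned final
    structure.  The spring energy is sum over pairs of
    (1/2) F w |x - t|^2, in kJ/mol with F in kJ/mol/A^2.
    """

    atom_refs: List[Tuple[str, int, str, str]]
    targets: np.ndarray
    force_constant: float = 30.0
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float).reshape(-1, 3)
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        if len(self.atom_refs) != len(self.targets):
            raise ValueError("atom_refs and targets length mismatch")
        if len(set(self.atom_refs)) != len(self.atom_refs):
            raise ValueError("a mobile atom appears in more than one spring")
        if self.weights is None:
            self.weights = np.ones(len(self.atom_refs))

    def __len__(self) -> int:
        return len(self.atom_refs)


@dataclass
class DistanceRestraint:
    """Harmonic restraint between two mobile atoms at a target distance."""

    atom_i: Tuple[str, int, str, str]
    atom_j: Tuple[str, int, str, str]
    target: float
    stiffness: float

    def __post_init__(self) -> None:
        if self.atom_i == self.atom_j:
            raise ValueError("restraint endpoints must differ")
        if self.target <= 0:
            raise ValueError("restraint target distance must be > 0")


def _aligned_residue_pairs(chain_a: ChainModel, chain_b: ChainModel,
                           mode, scoring: Optional[AlignmentScoring]) -> List[Tuple[Residue, Residue]]:
    if mode == "gapped":
        if chain_a.polymer_class is not chain_b.polymer_class:
            raise ValueError(
                f"cannot align {chain_a.polymer_class.value} chain "
                f"{chain_a.chain_id} to {chain_b.polymer_class.value} chain "
                f"{chain_b.chain_id}")
        scoring = scoring or AlignmentScoring(polymer_class=chain_a.polymer_class)
        aln = gapped_align(extract_sequence(chain_a), extract_sequence(chain_b),
                           scoring)
        return [(chain_a.residues[i], chain_b.residues[j])
                for i, j in aln.matched_pairs()]
    # manual residue map: list of ((resnum_a, icode_a), (resnum_b, icode_b))
    pairs = []
    for (na, ia), (nb, ib) in mode:
        ra = chain_a.residue(na, ia)
        rb = chain_b.residue(nb, ib)
        if ra is None or rb is None:
            raise ValueError(
                f"manual map references absent residue "
                f"{chain_a.chain_id}:{na}{ia} or {chain_b.chain_id}:{nb}{ib}")
        pairs.append((ra, rb))
    return pairs


def build_springs(model_a: StructureModel, model_b: StructureModel,
                  chain_pairs: Sequence[Tuple[str, str]],
                  alignment_mode="gapped",
                  atom_policy: str = "representative",
                  force_constant: float = 30.0,
                  scoring: Optional[AlignmentScoring] = None) -> SpringSet:
    """Construct threading springs from model_a atoms to model_b points.

    ``alignment_mode`` is either the string 'gapped' (automatic gapped
    alignment per chain pair) or a dict mapping (chain_a, chain_b) to a
    manual residue map.  ``atom_policy`` 'representative' springs CA /
    P (C1' at the 5' end); 'all-shared-atoms' springs every atom name
    present in both matched residues.  Target points are the partner
    atoms' coordinates in ``model_b``, which the caller is expected to
    have rigidly pre-aligned onto ``model_a``'s frame.
    """
    if atom_policy not in ("representative", "all-shared-atoms"):
        raise ValueError(f"unknown atom policy {atom_policy!r}")
    refs: List[Tuple[str, int, str, str]] = []
    targets: List[np.ndarray] = []
    for ca_id, cb_id in chain_pairs:
        chain_a = model_a.chain(ca_id)
        chain_b = model_b.chain(cb_id)
        if isinstance(alignment_mode, str):
            if alignment_mode != "gapped":
                raise ValueError(f"unknown alignment mode {alignment_mode!r}")
            mode = "gapped"
        else:
            mode = alignment_mode[(ca_id, cb_id)]
        for ra, rb in _aligned_residue_pairs(chain_a, chain_b, mode, scoring):
            if atom_policy == "representative":
                names = []
                rep = representative_atom_name(chain_a.polymer_class, ra)
                if rep is not None and rb.has_atom(rep):
                    names = [rep]
            else:
                names_b = {a.name for a in rb.atoms}
                names = [a.name for a in ra.atoms if a.name in names_b]
            for name in names:
                refs.append((ca_id, ra.number, ra.insertion_code, name))
                targets.append(rb.atom(name).coords)
    if not refs:
        raise ValueError("no matched residues: cannot construct any spring")
    return SpringSet(atom_refs=refs, targets=np.array(targets),
                     force_constant=force_constant)


# Canonical Watson-Crick hydrogen-bond heavy-atom pairs and ideal
# donor-acceptor distances (angstrom); first atom on the purine.
_WC_PAIRS: Dict[Tuple[str, str], List[Tuple[str, str, float]]] = {
    ("G", "C"): [("O6", "N4", 2.91), ("N1", "N3", 2.95), ("N2", "O2", 2.86)],
    ("A", "U"): [("N1", "N3", 2.82), ("N6", "O4", 2.95)],
    ("A", "T"): [("N1", "N3", 2.82), ("N6", "O4", 2.95)],
}
_PURINES = {"A", "G", "DA", "DG"}


def _base_letter(res: Residue) -> str:
    name = res.name.strip().upper()
    return name[-1] if name.startswith("D") and len(name) == 2 else name


def wc_restraints(chain_x: ChainModel, residues_x: Sequence[Tuple[int, str]],
                  chain_y: ChainModel, residues_y: Sequence[Tuple[int, str]],
                  stiffness: float = 30.0) -> List[DistanceRestraint]:
    """Watson-Crick distance restraints between two antiparallel strands.

    ``residues_x`` pairs with ``residues_y`` reversed (5'->3' against
    3'->5'), as in a codon-anticodon duplex.  G-C pairs get three
    restraints, A-U/A-T two.  Non-complementary pairs raise a warning
    but still receive a single restraint between the Watson-Crick edge
    nitrogens, since the morph may need to form the pairing.
    """
    if len(residues_x) != len(residues_y):
        raise ValueError("codon and anticodon residue lists differ in length")
    out: List[DistanceRestraint] = []
    for (nx, ix), (ny, iy) in zip(residues_x, list(residues_y)[::-1]):
        rx = chain_x.residue(nx, ix)
        ry = chain_y.residue(ny, iy)
        if rx is None or ry is None:
            raise ValueError(f"residue {nx}{ix} or {ny}{iy} not found")
        bx, by = _base_letter(rx), _base_letter(ry)
        if rx.name.strip().upper() in _PURINES:
            pur, pyr, key = rx, ry, (bx, by)
            pur_id, pyr_id = (chain_x.chain_id, nx, ix), (chain_y.chain_id, ny, iy)
        else:
            pur, pyr, key = ry, rx, (by, bx)
            pur_id, pyr_id = (chain_y.chain_id, ny, iy), (chain_x.chain_id, nx, ix)
        pairs = _WC_PAIRS.get(key)
        if pairs is None:
            warnings.warn(
                f"non-complementary base pair {bx}-{by} at {nx}/{ny}; "
                "applying a single WC-edge restraint")
            pairs = [("N1", "N3", 2.90)]
        for a_pur, a_pyr, dist in pairs:
            if pur.has_atom(a_pur) and pyr.has_atom(a_pyr):
                out.append(DistanceRestraint(
                    atom_i=pur_id + (a_pur,),
                    atom_j=pyr_id + (a_pyr,),
                    target=dist, stiffness=stiffness))
    return out


def read_residue_map(path) -> List[Tuple[Tuple[int, str], Tuple[int, str]]]:
    """Read a two-column manual residue map: ``A:12  B:13`` per line."""
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 2:
                raise ValueError(f"{path}:{line_no}: expected two columns")

            def parse(token: str) -> Tuple[int, str]:
                _, _, res = token.partition(":")
                res = res or token
                icode = ""
                if res and res[-1].isalpha():
                    res, icode = res[:-1], res[-1]
                return int(res), icode

            out.append((parse(cols[0]), parse(cols[1])))
    return out


def alignment_to_fasta(aln: SequenceAlignment, seq_a: str, seq_b: str,
                       name_a: str = "A", name_b: str = "B") -> str:
    """Render an alignment as aligned FASTA for inspection."""
    row_a, row_b = [], []
    for i, j in aln.aligned_pairs:
        row_a.append(seq_a[i] if i is not None else "-")
        row_b.append(seq_b[j] if j is not None else "-")
    return f">{name_a}\n{''.join(row_a)}\n>{name_b}\n{''.join(row_b)}\n"
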