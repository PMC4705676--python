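"""Superposition and trajectory-quality statistics.

Provides weighted Kabsch superposition, representative-atom (Calpha /
P) RMSD, the interdomain sRMSD, per-frame RMSD profiles against
reference structures, and the intermediate-recapitulation improvement
score

    improvement = (min(rmsd(A,B), rmsd(C,B)) - min_i rmsd(i,B))
                  / min(rmsd(A,B), rmsd(C,B)) * 100%

where A and C are the morph endpoints, B a held-out experimentally
determined intermediate, and i runs over trajectory frames.  A score of
100% means some frame recapitulates B exactly; 0% means the trajectory
never gets closer to B than the better endpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .correspondence import AlignmentScoring, gapped_align
from .model_io import (
    PolymerClass,
    StructureModel,
    Trajectory,
    extract_sequence,
    representative_atom_name,
)

__all__ = [
    "MetricReport",
    "kabsch_superpose",
    "apply_transform",
    "calpha_rmsd",
    "srmsd",
    "improvement_score",
    "score_trajectory",
    "residue_correspondence",
    "representative_coords",
]


def kabsch_superpose(points_p: np.ndarray, points_q: np.ndarray,
                     weights: Optional[np.ndarray] = None
                     ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of Q onto P.

    Returns (rotation, translation, rmsd) such that ``R @ q + t``
    minimizes the (weighted) RMSD to P.  The rotation is always proper
    (determinant +1).  Degenerate (collinear or coincident) point sets
    raise a ValueError since the optimal rotation is not unique.
    """
    P = np.asarray(points_p, dtype=float)
    Q = np.asarray(points_q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    cp = wn @ P
    cq = wn @ Q
    Pc, Qc = P - cp, Q - cq
    cov = (Pc * wn[:, None]).T @ Qc
    sv = np.linalg.svd(cov, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) point set: rotation not unique")
    rot, _ = Rotation.align_vectors(Pc, Qc, weights=w)
    R = rot.as_matrix()
    t = cp - R @ cq
    diff = P - (Q @ R.T + t)
    rmsd = float(np.sqrt((w * np.sum(diff * diff, axis=1)).sum() / w.sum()))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ np.asarray(R).T + np.asarray(t)


ResidueKey = Tuple[str, int, str]  # (chain_id, number, insertion_code)
Correspondence = List[Tuple[ResidueKey, ResidueKey]]


def residue_correspondence(model_a: StructureModel, model_b: StructureModel,
                           chain_pairs: Optional[Sequence[Tuple[str, str]]] = None,
                           ) -> Correspondence:
    """Residue pairing between two models via gapped alignment per chain.

    Defaults to pairing chains with equal ids present in both models.
    """
    if chain_pairs is None:
        chain_pairs = [(c.chain_id, c.chain_id) for c in model_a.chains
                       if model_b.has_chain(c.chain_id)]
    out: Correspondence = []
    for ca_id, cb_id in chain_pairs:
        ca = model_a.chain(ca_id)
        cb = model_b.chain(cb_id)
        if ca.polymer_class is PolymerClass.OTHER or cb.polymer_class is PolymerClass.OTHER:
            continue
        aln = gapped_align(extract_sequence(ca), extract_sequence(cb),
                           AlignmentScoring(polymer_class=ca.polymer_class))
        for i, j in aln.matched_pairs():
            ra, rb = ca.residues[i], cb.residues[j]
            out.append(((ca_id, ra.number, ra.insertion_code),
                        (cb_id, rb.number, rb.insertion_code)))
    return out


def representative_coords(model: StructureModel, keys: Sequence[ResidueKey]
                          ) -> Tuple[np.ndarray, List[bool]]:
    """Representative-atom coordinates for the given residues.

    Returns the coordinate rows and a present/absent mask (a residue
    lacking its representative atom is reported absent).
    """
    coords, present = [], []
    for chain_id, num, icode in keys:
        chain = model.chain(chain_id)
        res = chain.residue(num, icode)
        name = representative_atom_name(chain.polymer_class, res) if res else None
        atom = res.atom(name) if (res and name) else None
        if atom is None:
            present.append(False)
            coords.append(np.zeros(3))
        else:
            present.append(True)
            coords.append(atom.coords)
    return np.asarray(coords), present


def _paired_rep_coords(model_a: StructureModel, model_b: StructureModel,
                       correspondence: Correspondence) -> Tuple[np.ndarray, np.ndarray]:
    keys_a = [p[0] for p in correspondence]
    keys_b = [p[1] for p in correspondence]
    ca, pa = representative_coords(model_a, keys_a)
    cb, pb = representative_coords(model_b, keys_b)
    mask = np.array(pa) & np.array(pb)
    if not mask.all():
        warnings.warn(
            f"{int((~mask).sum())} residue pair(s) skipped: missing "
            "representative atom")
    return ca[mask], cb[mask]


def calpha_rmsd(model_a: StructureModel, model_b: StructureModel,
                correspondence: Optional[Correspondence] = None) -> float:
    """RMSD over representative atoms after least-squares superposition.

    Uses Calpha for protein chains and P (C1' at the 5' end) for
    nucleic chains; pairs missing the representative atom are skipped
    with a warning.
    """
    if correspondence is None:
        correspondence = residue_correspondence(model_a, model_b)
    if not correspondence:
        raise ValueError("empty residue correspondence")
    ca, cb = _paired_rep_coords(model_a, model_b, correspondence)
    _, _, rmsd = kabsch_superpose(ca, cb)
    return rmsd


def srmsd(model_a: StructureModel, model_b: StructureModel,
          domain1: Sequence[ResidueKey], domain2: Sequence[ResidueKey]) -> float:
    """Interdomain sRMSD: superpose on domain1, measure RMSD on domain2.

    The two structures are aligned by least squares over domain1's
    representative atoms only; the reported value is the unweighted
    RMSD over domain2's representative atoms without re-superposition,
    so it emphasizes the relative motion of domain2 with respect to
    domain1.
    """
    d1, d2 = set(domain1), set(domain2)
    if not d1 or not d2:
        raise ValueError("both domain selections must be non-empty")
    if d1 & d2:
        raise ValueError("domain selections must be disjoint")
    c1a, p1a = representative_coords(model_a, list(domain1))
    c1b, p1b = representative_coords(model_b, list(domain1))
    mask1 = np.array(p1a) & np.array(p1b)
    R, t, _ = kabsch_superpose(c1a[mask1], c1b[mask1])
    c2a, p2a = representative_coords(model_a, list(domain2))
    c2b, p2b = representative_coords(model_b, list(domain2))
    mask2 = np.array(p2a) & np.array(p2b)
    moved = apply_transform(c2b[mask2], R, t)
    diff = c2a[mask2] - moved
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def improvement_score(rmsd_ab: float, rmsd_cb: float, min_rmsd_ib: float) -> float:
    """Percent improvement of the trajectory's closest approach to B.

    (min(rmsd_AB, rmsd_CB) - min_i rmsd(i,B)) / min(rmsd_AB, rmsd_CB)
    * 100.  Negative when the morph never approaches B as closely as
    the better endpoint; 100 for exact recapitulation.
    """
    for v in (rmsd_ab, rmsd_cb, min_rmsd_ib):
        if v < 0:
            raise ValueError("RMSD inputs must be >= 0")
    denom = min(rmsd_ab, rmsd_cb)
    if denom <= 0:
        raise ValueError("min(rmsd_AB, rmsd_CB) must be > 0")
    return (denom - min_rmsd_ib) / denom * 100.0


@dataclass
class MetricReport:
    """Trajectory-quality summary against intermediate B and endpoint C."""

    rmsd_profile_vs_B: np.ndarray
    rmsd_profile_vs_C: np.ndarray
    min_rmsd_iB: float
    rmsd_AB: float
    rmsd_CB: float
    improvement: float          # percent, unrounded
    srmsd_values: Dict[str, float] = field(default_factory=dict)

    @property
    def improvement_rounded(self) -> int:
        """Improvement rounded to the nearest integer percent."""
        return int(round(self.improvement))

    def to_table(self) -> str:
        """Per-frame RMSD profile as a TSV table."""
        lines = ["frame\trmsd_vs_B\trmsd_vs_C"]
        for k, (b, c) in enumerate(zip(self.rmsd_profile_vs_B,
                                       self.rmsd_profile_vs_C)):
            lines.append(f"{k}\t{b:.3f}\t{c:.3f}")
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        return (
            f"rmsd(A,B) = {self.rmsd_AB:.2f} A\n"
            f"rmsd(C,B) = {self.rmsd_CB:.2f} A\n"
            f"min rmsd(i,B) = {self.min_rmsd_iB:.2f} A\n"
            f"improvement = {self.improvement_rounded}%\n"
        )


def score_trajectory(traj: Trajectory, model_a: StructureModel,
                     model_b: StructureModel, model_c: StructureModel,
                     srmsd_domains: Optional[Tuple[Sequence[ResidueKey],
                                                   Sequence[ResidueKey]]] = None,
                     ) -> MetricReport:
    """Score a trajectory against a held-out intermediate B.

    The residue correspondence is established by gapped alignment of B
    and C to A (the trajectory's topology), so the common residue set
    runs through A.  All RMSDs use representative atoms with
    superposition per frame.
    """
    corr_ab = residue_correspondence(model_a, model_b)
    corr_ac = residue_correspondence(model_a, model_c)
    if not corr_ab or not corr_ac:
        raise ValueError("no residue correspondence to B or C")

    work = model_a.copy()
    prof_b, prof_c = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for frame in traj.frames:
            work.set_coords(frame)
            prof_b.append(calpha_rmsd(work, model_b, corr_ab))
            prof_c.append(calpha_rmsd(work, model_c, corr_ac))
        rmsd_ab = calpha_rmsd(model_a, model_b, corr_ab)
        # C-vs-B pairing composed through A so one common residue set is used
        a_to_b = dict(corr_ab)
        corr_cb = [(ck, a_to_b[ak]) for ak, ck in corr_ac if ak in a_to_b]
        rmsd_cb = calpha_rmsd(model_c, model_b, corr_cb)
    prof_b = np.asarray(prof_b)
    prof_c = np.asarray(prof_c)
    min_ib = float(prof_b.min()) if len(prof_b) else min(rmsd_ab, rmsd_cb)
    report = MetricReport(
        rmsd_profile_vs_B=prof_b,
        rmsd_profile_vs_C=prof_c,
        min_rmsd_iB=min_ib,
        rmsd_AB=rmsd_ab,
        rmsd_CB=rmsd_cb,
        improvement=improvement_score(rmsd_ab, rmsd_cb, min_ib),
    )
    if srmsd_domains is not None:
        d1, d2 = srmsd_domains
        work.set_coords(traj.frames[int(np.argmin(prof_b))])
        report.srmsd_values["best_frame_vs_B"] = srmsd(model_b, work, d1, d2)
    return report
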