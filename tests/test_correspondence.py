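import warnings

import numpy as np
import pytest

import springmorph as sm
from springmorph.correspondence import (
    AlignmentScoring,
    DistanceRestraint,
    SpringSet,
    alignment_to_fasta,
    build_springs,
    gapped_align,
    read_residue_map,
    wc_restraints,
)
from springmorph.model_io import PolymerClass

PROTEIN = AlignmentScoring(polymer_class=PolymerClass.PROTEIN)
NUCLEIC = AlignmentScoring(polymer_class=PolymerClass.RNA)


def brute_force_best_score(seq_a, seq_b, scoring):
    """Exhaustive enumeration of all global alignments (lengths <= 6)."""
    best = -np.inf

    def rec(i, j, state, score):
        nonlocal best
        if i == len(seq_a) and j == len(seq_b):
            best = max(best, score)
            return
        if i < len(seq_a) and j < len(seq_b):
            rec(i + 1, j + 1, "M", score + scoring.score_pair(seq_a[i], seq_b[j]))
        if i < len(seq_a):
            open_cost = scoring.gap_open if state != "X" else 0.0
            rec(i + 1, j, "X", score + open_cost + scoring.gap_extend)
        if j < len(seq_b):
            open_cost = scoring.gap_open if state != "Y" else 0.0
            rec(i, j + 1, "Y", score + open_cost + scoring.gap_extend)

    rec(0, 0, "start", 0.0)
    return best


def test_identical_sequences_align_without_gaps():
    aln = gapped_align("ACGU", "ACGU", NUCLEIC)
    assert aln.aligned_pairs == [(0, 0), (1, 1), (2, 2), (3, 3)]
    assert aln.score == 4 * NUCLEIC.match


def test_single_deletion_is_placed_on_the_deleted_residue():
    aln = gapped_align("ACDE", "ACE", PROTEIN)
    assert aln.aligned_pairs == [(0, 0), (1, 1), (2, None), (3, 2)]


def test_alignment_indices_strictly_increase_and_no_double_gap():
    aln = gapped_align("ACDEFG", "ADG", PROTEIN)
    last_i = last_j = -1
    for i, j in aln.aligned_pairs:
        assert (i, j) != (None, None)
        if i is not None:
            assert i > last_i
            last_i = i
        if j is not None:
            assert j > last_j
            last_j = j


def test_alignment_score_equals_exhaustive_enumeration(rng):
    """DP affine-gap optimum vs brute force for 200 random short pairs."""
    for trial in range(200):
        protein = trial % 2 == 0
        alphabet = list("ACDEFGHIKL") if protein else list("ACGU")
        scoring = PROTEIN if protein else NUCLEIC
        sa = "".join(rng.choice(alphabet, rng.integers(1, 7)))
        sb = "".join(rng.choice(alphabet, rng.integers(1, 7)))
        got = gapped_align(sa, sb, scoring).score
        want = brute_force_best_score(sa, sb, scoring)
        assert got == pytest.approx(want, abs=1e-9), (sa, sb)


def test_empty_sequence_errors():
    with pytest.raises(ValueError):
        gapped_align("", "ACD", PROTEIN)


def test_springs_one_per_matched_residue(toy_case):
    springs = build_springs(toy_case.initial, toy_case.final, [("A", "A")],
                            force_constant=30.0)
    assert len(springs) == len(toy_case.initial.chains[0].residues)
    assert springs.force_constant == 30.0


def test_springs_skip_unmatched_residues(toy_case):
    shorter = sm.make_indel_variant(toy_case.final, [("A", 3, 4)])
    springs = build_springs(toy_case.initial, shorter, [("A", "A")])
    # two residues of the final structure are gone, so two fewer springs;
    # with a homopolymer sequence the gap placement itself is degenerate
    assert len(springs) == len(toy_case.initial.chains[0].residues) - 2


def test_doubling_force_constant_doubles_spring_energy(toy_case):
    """Raising the threading force constant F from 30 to 60 doubles the
    stiffness of every spring (as used to free a stuck tRNA)."""
    from springmorph.energetics import CompiledSprings, spring_energy
    index_map = toy_case.initial.atom_index_map()
    coords = toy_case.initial.coords_array() + 1.0
    energies = []
    for f in (30.0, 60.0):
        s = build_springs(toy_case.initial, toy_case.final, [("A", "A")],
                          force_constant=f)
        compiled = CompiledSprings(
            atom_idx=np.array([index_map[r] for r in s.atom_refs]),
            targets=s.targets, force_constant=s.force_constant,
            weights=np.asarray(s.weights))
        energies.append(spring_energy(coords, compiled)[0])
    assert energies[1] == pytest.approx(2.0 * energies[0], rel=1e-12)


def test_gapped_mode_equals_manual_identity_map(toy_case):
    n = len(toy_case.initial.chains[0].residues)
    identity = {("A", "A"): [((k, ""), (k, "")) for k in range(1, n + 1)]}
    auto = build_springs(toy_case.initial, toy_case.final, [("A", "A")])
    manual = build_springs(toy_case.initial, toy_case.final, [("A", "A")],
                           alignment_mode=identity)
    assert auto.atom_refs == manual.atom_refs
    np.testing.assert_allclose(auto.targets, manual.targets)


def test_manual_map_with_absent_residue_errors(toy_case):
    bad = {("A", "A"): [((999, ""), (1, ""))]}
    with pytest.raises(ValueError, match="absent residue"):
        build_springs(toy_case.initial, toy_case.final, [("A", "A")],
                      alignment_mode=bad)


def test_all_shared_atoms_policy_springs_every_common_atom(toy_case):
    springs = build_springs(toy_case.initial, toy_case.final, [("A", "A")],
                            atom_policy="all-shared-atoms")
    assert len(springs) == toy_case.initial.n_atoms


def test_springs_depend_only_on_the_alignment(toy_case):
    """Permuting atom storage order within residues leaves the spring
    set (as a mapping atom -> target) unchanged."""
    shuffled = toy_case.initial.copy()
    for res in shuffled.chains[0].residues:
        res.atoms = list(reversed(res.atoms))
    base = build_springs(toy_case.initial, toy_case.final, [("A", "A")],
                         atom_policy="all-shared-atoms")
    perm = build_springs(shuffled, toy_case.final, [("A", "A")],
                         atom_policy="all-shared-atoms")
    as_map = lambda s: {r: tuple(t) for r, t in zip(s.atom_refs, s.targets)}
    assert as_map(base) == as_map(perm)


def test_spring_set_rejects_duplicate_mobile_atoms():
    with pytest.raises(ValueError):
        SpringSet(atom_refs=[("A", 1, "", "CA"), ("A", 1, "", "CA")],
                  targets=np.zeros((2, 3)))


def test_wc_restraint_counts_for_canonical_pairs():
    # G-C gives three hydrogen-bond restraints, A-U two
    x = sm.make_polymer(2, "rna", sequence="GA", chain_id="X")
    y = sm.make_polymer(2, "rna", sequence="UC", chain_id="Y")
    restraints = wc_restraints(x.chains[0], [(1, ""), (2, "")],
                               y.chains[0], [(1, ""), (2, "")])
    # antiparallel: G pairs with C (y residue 2), A pairs with U (y residue 1)
    assert len(restraints) == 5
    for r in restraints:
        assert r.target > 0 and r.stiffness > 0


def test_wc_restraints_edge_cases():
    x = sm.make_polymer(2, "rna", sequence="GA", chain_id="X")
    y = sm.make_polymer(3, "rna", sequence="UUC", chain_id="Y")
    assert wc_restraints(x.chains[0], [], y.chains[0], []) == []
    with pytest.raises(ValueError):
        wc_restraints(x.chains[0], [(1, "")], y.chains[0], [(1, ""), (2, "")])
    # non-complementary pair warns but still restrains
    with pytest.warns(UserWarning, match="non-complementary"):
        r = wc_restraints(x.chains[0], [(2, "")], y.chains[0], [(3, "")])
    assert len(r) == 1


def test_distance_restraint_validation():
    with pytest.raises(ValueError):
        DistanceRestraint(("A", 1, "", "N1"), ("A", 1, "", "N1"), 2.9, 30.0)
    with pytest.raises(ValueError):
        DistanceRestraint(("A", 1, "", "N1"), ("B", 1, "", "N3"), -1.0, 30.0)


def test_residue_map_file_and_fasta_export(tmp_path):
    path = tmp_path / "map.txt"
    path.write_text("# comment\nA:12 B:13\nA:14A B:15\n")
    pairs = read_residue_map(path)
    assert pairs == [((12, ""), (13, "")), ((14, "A"), (15, ""))]
    aln = gapped_align("ACDE", "ACE", PROTEIN)
    fasta = alignment_to_fasta(aln, "ACDE", "ACE")
    assert "ACDE" in fasta and "AC-E" in fasta
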