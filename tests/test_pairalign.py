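"""Rigid and flexible pairwise structural alignment.

Independent oracles: an SVD-free grid search over rotations for the
Kabsch solver, exhaustive fragment-pair scans for the AFP search, and
brute-force alignment enumeration for the global sequence aligner.
"""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from kac3d.geometry import DegenerateGeometryError, kabsch_superpose
from kac3d.model import StructureModel
from kac3d.pairalign import (
    align_all_chains,
    find_afps,
    flexible_align,
    global_align,
    rigid_align_chains,
    select_best_chain,
)
from kac3d.synthdata import build_ideal_chain

# ---------------------------------------------------------------------------
# oracles


def grid_search_rmsd(P, Q, rounds=7):
    """Derivative-free rotation search (no SVD): a full Euler-angle scan
    followed by iteratively refined grids around the best rotation."""
    P = np.asarray(P)
    Q = np.asarray(Q)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def score(angles):
        R = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        return float(np.sqrt(np.mean(np.sum((Pc - Qc @ R.T) ** 2, axis=1))))

    best_angles = np.zeros(3)
    best = np.inf
    for off in itertools.product(range(-6, 7), repeat=3):  # full ±180° scan
        angles = 30.0 * np.array(off)
        s = score(angles)
        if s < best:
            best, best_angles = s, angles
    step = 15.0
    for _ in range(max(rounds, 10)):
        for off in itertools.product(range(-3, 4), repeat=3):
            angles = best_angles + step * np.array(off)
            s = score(angles)
            if s < best:
                best, best_angles = s, angles
        step /= 2.0
    return best


def exhaustive_afp_scan(A, B, L, cutoff):
    """All fragment pairs (i, j) whose optimal-superposition RMSD is
    within the cutoff, by independent per-pair Kabsch."""
    hits = set()
    for i in range(len(A) - L + 1):
        for j in range(len(B) - L + 1):
            _, _, rmsd = kabsch_superpose(A[i : i + L], B[j : j + L])
            if rmsd <= cutoff:
                hits.add((i + 1, j + 1))
    return hits


def enumerate_global_alignments(a, b, matrix, gap_open, gap_extend):
    """Score of the best global alignment by exhaustive enumeration
    (affine gaps), for sequences of length <= 5."""

    def gap_cost(length):
        return -(gap_open + gap_extend * (length - 1)) if length else 0.0

    best = -np.inf
    # enumerate monotone pair sets
    n, m = len(a), len(b)
    positions = [
        pairs
        for k in range(min(n, m) + 1)
        for ia in itertools.combinations(range(n), k)
        for ib in itertools.combinations(range(m), k)
        for pairs in [list(zip(ia, ib))]
    ]
    for pairs in positions:
        score = sum(matrix[a[i], b[j]] for i, j in pairs)
        # affine gap cost from the gap run structure between aligned pairs
        prev_i, prev_j = -1, -1
        for i, j in pairs + [(n, m)]:
            score += gap_cost(i - prev_i - 1) + gap_cost(j - prev_j - 1)
            prev_i, prev_j = i, j
        best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# Kabsch


class TestKabsch:
    def test_identical_sets(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(12, 3)) * 4.0
        R_true = Rotation.from_euler("zyx", [31.0, -54.0, 112.0], degrees=True).as_matrix()
        t_true = np.array([1.0, -2.0, 3.5])
        Q = (P - t_true) @ R_true  # so that R_true^T maps Q back
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(R @ Q.T + t[:, None], P.T, atol=1e-6)

    def test_proper_rotation_always(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            P = rng.normal(size=(6, 3))
            Q = rng.normal(size=(6, 3))
            R, _, _ = kabsch_superpose(P, Q)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_search_oracle(self):
        """RMSD equals a dense-grid rotation search to 1e-3 Å on noisy
        random 10-point sets."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            P = rng.normal(size=(10, 3)) * 3.0
            R = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
            Q = P @ R + rng.normal(scale=0.4, size=(10, 3))
            _, _, rmsd = kabsch_superpose(P, Q)
            oracle = grid_search_rmsd(P, Q)
            assert rmsd <= oracle + 1e-9  # never worse than the search
            assert abs(rmsd - oracle) < 1e-3

    def test_never_exceeds_translation_only(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            P = rng.normal(size=(8, 3)) * 2.0
            Q = rng.normal(size=(8, 3)) * 2.0
            _, _, rmsd = kabsch_superpose(P, Q)
            Pc = P - P.mean(axis=0)
            Qc = Q - Q.mean(axis=0)
            translation_only = float(np.sqrt(np.mean(np.sum((Pc - Qc) ** 2, axis=1))))
            assert rmsd <= translation_only + 1e-9

    @given(st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_property_rotation_never_hurts(self, seed):
        """For any paired point sets, the optimal rotation does at least
        as well as centroid matching alone."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        P = rng.normal(size=(n, 3)) * 3.0
        Q = rng.normal(size=(n, 3)) * 3.0
        try:
            _, _, rmsd = kabsch_superpose(P, Q)
        except DegenerateGeometryError:
            return
        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)
        assert rmsd <= float(np.sqrt(np.mean(np.sum((Pc - Qc) ** 2, axis=1)))) + 1e-9

    def test_too_few_or_collinear_errors(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line[::-1])


# ---------------------------------------------------------------------------
# sequence alignment


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("MKVLAT", "MKVLAT")
        assert aln.percent_identity == 100.0
        assert aln.pairs == [(i, i) for i in range(1, 7)]

    def test_no_identity(self):
        assert global_align("AAAA", "GGGG").percent_identity == 0.0

    @pytest.mark.parametrize(
        "a,b", [("KATE", "KTE"), ("MK", "MRK"), ("WLS", "WS"), ("KATE", "KATE")]
    )
    def test_score_matches_enumeration(self, a, b):
        gap_open, gap_extend = 11.0, 1.0
        aln = global_align(a, b, gap_open=gap_open, gap_extend=gap_extend)
        blosum = substitution_matrices.load("BLOSUM62")
        oracle = enumerate_global_alignments(a, b, blosum, gap_open, gap_extend)
        assert aln.score == pytest.approx(oracle)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            global_align("", "KAT")


# ---------------------------------------------------------------------------
# AFPs


@pytest.fixture(scope="module")
def pair_30():
    """Two related 30-residue chains (mixed topology, mild noise)."""
    plan = [("C", 3), ("H", 8), ("C", 4), ("E", 6), ("C", 9)]
    a = build_ideal_chain(plan, seed=5).chains[0]
    b_model = build_ideal_chain(plan, seed=5)
    rng = np.random.default_rng(6)
    for res in b_model.chains[0].residues:
        for atom in res.atoms:
            atom.coords = atom.coords + rng.normal(scale=0.3, size=3)
    return a, b_model.chains[0]


class TestFindAfps:
    def test_exact_copy_has_diagonal_afp(self):
        chain = build_ideal_chain([("H", 10), ("C", 4), ("E", 6)], seed=7).chains[0]
        afps = find_afps(chain, chain)
        diag = [a for a in afps if a.start_a == 1 and a.start_b == 1]
        assert diag and diag[0].fragment_rmsd < 1e-6

    def test_reversed_coordinates_break_diagonal(self):
        model = build_ideal_chain([("C", 4), ("H", 12), ("C", 4)], seed=8)
        chain = model.chains[0]
        import copy

        rev = copy.deepcopy(model).chains[0]
        coords = [a.coords.copy() for r in rev.residues for a in r.atoms][::-1]
        flat = iter(coords)
        for res in rev.residues:
            for atom in res.atoms:
                atom.coords = next(flat)
        afps = find_afps(chain, rev)
        assert not any(
            a.start_a == a.start_b and a.fragment_rmsd < 0.5 for a in afps
        )

    def test_matches_exhaustive_scan(self, pair_30):
        """The AFP set equals an independent exhaustive scan over all
        fragment pairs at the same cutoff."""
        a, b = pair_30
        L, cutoff = 6, 1.5
        afps = find_afps(a, b, fragment_length=L, fragment_rmsd_cutoff=cutoff)
        got = {(f.start_a, f.start_b) for f in afps}
        A = a.ca_coords()
        B = b.ca_coords()
        want = exhaustive_afp_scan(A, B, L, cutoff)
        assert got == want

    def test_short_chains_empty(self):
        chain = build_ideal_chain([("H", 10)], seed=9).chains[0]
        assert find_afps(chain, chain, fragment_length=20) == []


# ---------------------------------------------------------------------------
# flexible vs rigid


class TestFlexibleAlign:
    def test_rigid_copy_no_twists(self, clean_family):
        target = clean_family.target.chains[0]
        aln = flexible_align(target, target)
        assert aln.twists == 0
        assert aln.opt_rmsd < 0.1
        assert all(t == h for t, h in aln.correspondence)

    def test_hinge_exactly_one_twist(self, hinge_family):
        target = hinge_family.target.chains[0]
        for homolog in hinge_family.homologs:
            aln = flexible_align(target, homolog.chains[0])
            assert aln.twists == 1
            assert aln.opt_rmsd < 0.5

    def test_hinge_per_domain_kabsch_oracle(self, hinge_family):
        """Construction check: each domain superposes rigidly (~0 RMSD)
        even though the whole chain does not."""
        target = hinge_family.target.chains[0]
        homolog = hinge_family.homologs[0].chains[0]
        A = {r.author_number: r.ca.coords for r in target.residues if r.ca}
        B = {r.author_number: r.ca.coords for r in homolog.residues if r.ca}
        for lo, hi in hinge_family.spec.domains:
            nums = [n for n in range(lo, hi + 1) if n in A and n in B]
            _, _, rmsd = kabsch_superpose(
                np.array([A[n] for n in nums]), np.array([B[n] for n in nums])
            )
            assert rmsd < 1e-6
        _, _, whole = kabsch_superpose(
            np.array([A[n] for n in sorted(A)]), np.array([B[n] for n in sorted(B)])
        )
        assert whole > 1.0

    def test_flexible_opt_below_rigid_on_hinge(self, hinge_family):
        target = hinge_family.target.chains[0]
        for homolog in hinge_family.homologs:
            rigid = rigid_align_chains(target, homolog.chains[0])
            flex = flexible_align(target, homolog.chains[0])
            assert flex.opt_rmsd < rigid.rmsd

    def test_opt_rmsd_bounded_by_single_transform(self, demo_family):
        """Length-weighted per-block RMSD never exceeds the one-transform
        RMSD over the same correspondence."""
        target = demo_family.target.chains[0]
        for homolog in demo_family.homologs:
            aln = flexible_align(target, homolog.chains[0])
            if not aln.is_empty:
                assert aln.opt_rmsd <= aln.rmsd + 1e-6

    def test_zero_twists_matches_rigid_on_rigid_family(self, clean_family):
        target = clean_family.target.chains[0]
        for homolog in clean_family.homologs:
            flex = flexible_align(target, homolog.chains[0], max_twists=0)
            rigid = rigid_align_chains(target, homolog.chains[0])
            assert abs(flex.rmsd - rigid.rmsd) < 0.2

    def test_no_afps_gives_flagged_empty(self):
        a = build_ideal_chain([("H", 12)], seed=10).chains[0]
        b_model = build_ideal_chain([("H", 12)], seed=11)
        rng = np.random.default_rng(12)
        for res in b_model.chains[0].residues:
            for atom in res.atoms:
                atom.coords = rng.normal(scale=30.0, size=3)
        aln = flexible_align(a, b_model.chains[0])
        assert aln.is_empty
        assert aln.score == 0.0


# ---------------------------------------------------------------------------
# all-chain comparison and selection


def _tetramer(chain_template):
    import copy

    model = StructureModel(entry_id="tet")
    for i, cid in enumerate("ABCD"):
        chain = copy.deepcopy(chain_template)
        chain.chain_id = cid
        offset = np.array([40.0 * i, 0.0, 0.0])
        for res in chain.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + offset
        model.chains.append(chain)
    return StructureModel(entry_id="tet", chains=model.chains)


class TestAllChains:
    def test_tetramer_of_identical_chains(self, clean_family):
        target = clean_family.target.chains[0]
        tet = _tetramer(clean_family.homologs[0].chains[0])
        alns = align_all_chains(target, tet)
        assert len(alns) == 4
        opts = [a.opt_rmsd for a in alns]
        assert max(opts) - min(opts) < 1e-6

    def test_single_chain(self, clean_family):
        target = clean_family.target.chains[0]
        alns = align_all_chains(target, clean_family.homologs[0])
        assert len(alns) == 1

    def test_no_polymer_chain_errors(self):
        with pytest.raises(ValueError):
            align_all_chains(
                build_ideal_chain([("H", 10)], seed=13).chains[0],
                StructureModel(entry_id="empty"),
            )


class _FakeChain:
    def __init__(self, chain_id, length):
        self.chain_id = chain_id
        self.atom_sequence = "A" * length


class _FakeAln:
    is_empty = False

    def __init__(self, chain_id, opt_rmsd, length, score):
        self.homolog_id = "h"
        self.homolog_chain = _FakeChain(chain_id, length)
        self.opt_rmsd = opt_rmsd
        self.rmsd = opt_rmsd
        self.score = score
        self.homolog_sequence_length = length


class TestSelectBestChain:
    def test_rule_table(self):
        # lowest opt_rmsd wins
        sel = select_best_chain([_FakeAln("A", 1.2, 100, 10), _FakeAln("B", 1.5, 100, 10)])
        assert (sel.chain_id, sel.criterion) == ("A", "opt_rmsd")
        # tie on opt_rmsd -> longest sequence
        sel = select_best_chain([_FakeAln("A", 1.0, 190, 10), _FakeAln("B", 1.0, 200, 10)])
        assert (sel.chain_id, sel.criterion) == ("B", "length")
        # tie on both -> highest score
        sel = select_best_chain([_FakeAln("A", 1.0, 200, 280), _FakeAln("B", 1.0, 200, 300)])
        assert (sel.chain_id, sel.criterion) == ("B", "score")
        # full tie -> smallest chain id
        sel = select_best_chain([_FakeAln("B", 1.0, 200, 300), _FakeAln("A", 1.0, 200, 300)])
        assert (sel.chain_id, sel.criterion) == ("A", "chain_id")

    def test_permutation_invariance(self):
        rng = np.random.default_rng(14)
        alns = [
            _FakeAln(cid, float(rng.choice([1.0, 1.5])), int(rng.choice([150, 200])), float(rng.integers(100, 300)))
            for cid in "ABCDEF"
        ]
        picks = set()
        for _ in range(20):
            rng.shuffle(alns)
            sel = select_best_chain(list(alns))
            picks.add(sel.chain_id)
        assert len(picks) == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_best_chain([])
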