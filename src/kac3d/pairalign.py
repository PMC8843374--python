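"""Pairwise structural alignment: rigid and flexible.

Two routes onto a common result type:

* **rigid** — residue correspondence from a Needleman–Wunsch global
  sequence alignment, one Kabsch superposition over all corresponding
  Cα, no outlier rejection. This mirrors superposing two conformers in
  a viewer and reading off the all-atom-pair Cα RMSD.

* **flexible** — aligned fragment pairs (AFPs: gapless equal-length Cα
  fragments that superpose within an RMSD cutoff) chained by dynamic
  programming, monotone in both sequences. A *twist* is charged when
  consecutive chained AFPs cannot share one rigid transform; maximal
  runs of mutually compatible AFPs form *blocks*, each with its own
  Kabsch transform. ``opt_rmsd`` is the length-weighted mean of
  per-block RMSDs, while ``rmsd`` is still reported from a single
  transform over the full correspondence, so hinge motions show up as
  ``opt_rmsd << rmsd``.

This is a simplified FATCAT-style aligner: fragment length, the
compatibility thresholds and the twist penalty are configurable, and
bit-compatibility with any particular FATCAT release is a non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .geometry import (
    batched_fragment_rmsd,
    kabsch_superpose,
    rotation_angle_deg,
)
from .model import Chain, Residue, StructureModel

# ---------------------------------------------------------------------------
# sequence alignment


@dataclass
class SequenceAlignment:
    pairs: list[tuple[int, int]]  # 1-based positions, strictly increasing
    gapped_a: str
    gapped_b: str
    score: float
    percent_identity: float


def global_align(
    seq_a: str,
    seq_b: str,
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> SequenceAlignment:
    """Optimal global alignment (Needleman–Wunsch, affine gaps).

    Percent identity is identical pairs over aligned (non-gap) pairs,
    times 100.
    """
    if not seq_a or not seq_b:
        raise ValueError("global_align: empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    pairs: list[tuple[int, int]] = []
    ident = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for k in range(a1 - a0):
            ia, ib = a0 + k, b0 + k
            pairs.append((ia + 1, ib + 1))
            if seq_a[ia].upper() == seq_b[ib].upper():
                ident += 1
    pid = 100.0 * ident / len(pairs) if pairs else 0.0
    return SequenceAlignment(
        pairs=pairs,
        gapped_a=str(aln[0]),
        gapped_b=str(aln[1]),
        score=float(aln.score),
        percent_identity=pid,
    )


# ---------------------------------------------------------------------------
# structural alignment result types


@dataclass
class AFP:
    """Aligned fragment pair; start indices are 1-based positions in the
    chains' Cα-bearing residue sequences."""

    start_a: int
    start_b: int
    length: int
    fragment_rmsd: float
    rotation: np.ndarray = field(repr=False)
    translation: np.ndarray = field(repr=False)


@dataclass
class Block:
    """A maximal run of chained AFPs sharing one rigid transform.

    A rigid alignment is represented as a single block whose pairs come
    from the sequence correspondence (``explicit_pairs``) instead of AFPs.
    """

    afps: list[AFP]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    explicit_pairs: Optional[list[tuple[int, int]]] = None

    @property
    def index_pairs(self) -> list[tuple[int, int]]:
        if self.explicit_pairs is not None:
            return self.explicit_pairs
        return [
            (a.start_a + k, a.start_b + k) for a in self.afps for k in range(a.length)
        ]

    @property
    def length(self) -> int:
        return len(self.index_pairs)


@dataclass
class PairwiseStructAlignment:
    target_id: str
    homolog_id: str
    target_chain: Chain
    homolog_chain: Chain
    mode: str  # "rigid" | "flexible"
    correspondence: list[tuple[int, int]]  # (target, homolog) author numbers
    blocks: list[Block]
    twists: int
    rmsd: float
    opt_rmsd: float
    score: float

    @property
    def aligned_length(self) -> int:
        return len(self.correspondence)

    @property
    def is_empty(self) -> bool:
        return not self.correspondence

    @property
    def homolog_sequence_length(self) -> int:
        return len(self.homolog_chain.atom_sequence)

    def homolog_partner(self, target_author_number: int) -> Optional[int]:
        """Homolog author number aligned to a target residue, or None."""
        for ta, ha in self.correspondence:
            if ta == target_author_number:
                return ha
        return None

    def block_for_target(self, target_author_number: int) -> Optional[Block]:
        """The block containing (or nearest in sequence to) a target residue."""
        if not self.blocks:
            return None
        resA = _ca_residues(self.target_chain)
        num_to_idx = {r.author_number: i + 1 for i, r in enumerate(resA)}
        idx = num_to_idx.get(target_author_number)
        if idx is None:
            return None
        best, best_dist = None, None
        for blk in self.blocks:
            lo = min(p[0] for p in blk.index_pairs)
            hi = max(p[0] for p in blk.index_pairs)
            dist = 0 if lo <= idx <= hi else min(abs(idx - lo), abs(idx - hi))
            if best_dist is None or dist < best_dist:
                best, best_dist = blk, dist
        return best

    def to_dict(self) -> dict:
        return {
            "target": self.target_id,
            "homolog": self.homolog_id,
            "target_chain": self.target_chain.chain_id,
            "homolog_chain": self.homolog_chain.chain_id,
            "mode": self.mode,
            "aligned_length": self.aligned_length,
            "twists": self.twists,
            "rmsd": None if np.isnan(self.rmsd) else round(self.rmsd, 4),
            "opt_rmsd": None if np.isnan(self.opt_rmsd) else round(self.opt_rmsd, 4),
            "score": round(self.score, 4),
            "correspondence": [list(p) for p in self.correspondence],
        }


def alignment_to_fasta(aln: "PairwiseStructAlignment") -> str:
    """Paired gapped FASTA for one alignment (target row + homolog row)."""
    res_a = {r.author_number: r for r in aln.target_chain.polymer_residues}
    res_b = {r.author_number: r for r in aln.homolog_chain.polymer_residues}
    rows_a, rows_b = [], []
    prev_a = prev_b = None
    for ta, hb in aln.correspondence:
        if prev_a is not None:
            for num in range(prev_a + 1, ta):
                if num in res_a:
                    rows_a.append(res_a[num].one_letter)
                    rows_b.append("-")
            for num in range(prev_b + 1, hb):
                if num in res_b:
                    rows_a.append("-")
                    rows_b.append(res_b[num].one_letter)
        rows_a.append(res_a[ta].one_letter)
        rows_b.append(res_b[hb].one_letter)
        prev_a, prev_b = ta, hb
    id_a = f"{aln.target_id}_{aln.target_chain.chain_id}"
    id_b = f"{aln.homolog_id}_{aln.homolog_chain.chain_id}"
    return f">{id_a}\n{''.join(rows_a)}\n>{id_b}\n{''.join(rows_b)}\n"


def write_superposed(
    aln: "PairwiseStructAlignment",
    target_path,
    homolog_path,
) -> None:
    """Write the target as-is and the homolog with each residue moved by
    its block's transform (two decoupled coordinate files)."""
    import copy

    from .model import StructureModel
    from .structio import write_pdb

    write_pdb(
        StructureModel(entry_id=aln.target_id, chains=[copy.deepcopy(aln.target_chain)]),
        target_path,
    )
    hchain = copy.deepcopy(aln.homolog_chain)
    res_b = _ca_residues(aln.homolog_chain)
    block_of: dict[int, Block] = {}
    for blk in aln.blocks:
        for _, j in blk.index_pairs:
            block_of[res_b[j - 1].author_number] = blk
    default = aln.blocks[0] if aln.blocks else None
    for res in hchain.residues:
        blk = block_of.get(res.author_number, default)
        if blk is None:
            continue
        for atom in res.atoms:
            atom.coords = blk.rotation @ atom.coords + blk.translation
    write_pdb(
        StructureModel(entry_id=aln.homolog_id, chains=[hchain]), homolog_path
    )


@dataclass
class ChainSelection:
    homolog_id: str
    chain_id: str
    criterion: str  # "opt_rmsd" | "length" | "score" | "chain_id"
    alignment: PairwiseStructAlignment


# ---------------------------------------------------------------------------
# helpers


def _ca_residues(chain: Chain) -> list[Residue]:
    return [r for r in chain.polymer_residues if r.ca is not None]


def _ca_coords(residues: list[Residue]) -> np.ndarray:
    return np.array([r.ca.coords for r in residues])


def _index_pairs_to_author(
    pairs: list[tuple[int, int]], res_a: list[Residue], res_b: list[Residue]
) -> list[tuple[int, int]]:
    return [(res_a[i - 1].author_number, res_b[j - 1].author_number) for i, j in pairs]


# ---------------------------------------------------------------------------
# rigid route


def rigid_align_chains(
    target: Chain,
    homolog: Chain,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    target_id: str = "target",
    homolog_id: str = "homolog",
) -> PairwiseStructAlignment:
    """Sequence-correspondence rigid alignment: one Kabsch transform over
    all corresponding Cα, RMSD over all of them (no outlier rejection)."""
    res_a = _ca_residues(target)
    res_b = _ca_residues(homolog)
    if not res_a or not res_b:
        raise ValueError("rigid_align_chains: a chain has no Cα atoms")
    seq_a = "".join(r.one_letter for r in res_a)
    seq_b = "".join(r.one_letter for r in res_b)
    seqaln = global_align(seq_a, seq_b, gap_open=gap_open, gap_extend=gap_extend)
    pairs = seqaln.pairs
    if len(pairs) < 3:
        raise ValueError("rigid_align_chains: fewer than 3 corresponding Cα pairs")
    P = np.array([res_a[i - 1].ca.coords for i, _ in pairs])
    Q = np.array([res_b[j - 1].ca.coords for _, j in pairs])
    R, t, rmsd = kabsch_superpose(P, Q)
    block = Block(
        afps=[], rotation=R, translation=t, rmsd=rmsd, explicit_pairs=list(pairs)
    )
    return PairwiseStructAlignment(
        target_id=target_id,
        homolog_id=homolog_id,
        target_chain=target,
        homolog_chain=homolog,
        mode="rigid",
        correspondence=_index_pairs_to_author(pairs, res_a, res_b),
        blocks=[block],
        twists=0,
        rmsd=rmsd,
        opt_rmsd=rmsd,
        score=seqaln.score,
    )


# ---------------------------------------------------------------------------
# flexible route


def find_afps(
    target: Chain,
    homolog: Chain,
    fragment_length: int = 8,
    fragment_rmsd_cutoff: float = 3.0,
) -> list[AFP]:
    """All gapless fragment pairs whose optimally superposed Cα RMSD is
    within the cutoff, sorted by (start_a, start_b).

    Fragments must be contiguous both in the resolved-residue sequence
    and in author numbering (a chain break interrupts fragments).
    """
    res_a = _ca_residues(target)
    res_b = _ca_residues(homolog)
    L = fragment_length
    if len(res_a) < L or len(res_b) < L:
        return []
    A = _ca_coords(res_a)
    B = _ca_coords(res_b)

    def window_ok(residues: list[Residue]) -> np.ndarray:
        nums = np.array([r.author_number for r in residues])
        contiguous = np.diff(nums) == 1
        n_win = len(residues) - L + 1
        ok = np.ones(n_win, dtype=bool)
        for s in range(n_win):
            ok[s] = bool(np.all(contiguous[s : s + L - 1]))
        return ok

    ok_a = window_ok(res_a)
    ok_b = window_ok(res_b)
    ia = np.nonzero(ok_a)[0]
    ib = np.nonzero(ok_b)[0]
    if ia.size == 0 or ib.size == 0:
        return []
    # all window pairs, batched Kabsch
    wa = np.stack([A[s : s + L] for s in ia])
    wb = np.stack([B[s : s + L] for s in ib])
    gi, gj = np.meshgrid(np.arange(ia.size), np.arange(ib.size), indexing="ij")
    gi = gi.ravel()
    gj = gj.ravel()
    rmsd, R, t = batched_fragment_rmsd(wa[gi], wb[gj])
    keep = rmsd <= fragment_rmsd_cutoff
    afps = [
        AFP(
            start_a=int(ia[gi[k]]) + 1,
            start_b=int(ib[gj[k]]) + 1,
            length=L,
            fragment_rmsd=float(rmsd[k]),
            rotation=R[k],
            translation=t[k],
        )
        for k in np.nonzero(keep)[0]
    ]
    afps.sort(key=lambda a: (a.start_a, a.start_b))
    return afps


def _transforms_compatible(
    afp_i: AFP,
    afp_j: AFP,
    ref_point: np.ndarray,
    max_angle_deg: float,
    max_translation: float,
) -> bool:
    ang = rotation_angle_deg(afp_i.rotation, afp_j.rotation)
    if ang > max_angle_deg:
        return False
    pi = afp_i.rotation @ ref_point + afp_i.translation
    pj = afp_j.rotation @ ref_point + afp_j.translation
    return float(np.linalg.norm(pi - pj)) <= max_translation


def flexible_align(
    target: Chain,
    homolog: Chain,
    fragment_length: int = 8,
    fragment_rmsd_cutoff: float = 3.0,
    max_twists: int = 5,
    twist_penalty: float = 12.0,
    gap_open: float = 8.0,
    gap_extend: float = 0.5,
    compat_angle_deg: float = 15.0,
    compat_translation: float = 3.0,
    max_afps: int = 2500,
    target_id: str = "target",
    homolog_id: str = "homolog",
) -> PairwiseStructAlignment:
    """Fragment-pair chaining with twists.

    The chaining score is the sum over chained AFPs of
    ``length × (cutoff − fragment_rmsd)`` minus affine gap costs minus
    ``twist_penalty`` per twist. If the AFP pool exceeds ``max_afps``
    the lowest-RMSD fragments are kept (the pool is dense for highly
    similar chains and pruning there is harmless).
    """
    res_a = _ca_residues(target)
    res_b = _ca_residues(homolog)
    afps = find_afps(target, homolog, fragment_length, fragment_rmsd_cutoff)
    if len(afps) > max_afps:
        afps = sorted(afps, key=lambda a: a.fragment_rmsd)[:max_afps]
        afps.sort(key=lambda a: (a.start_a, a.start_b))
    if not afps:
        return PairwiseStructAlignment(
            target_id=target_id,
            homolog_id=homolog_id,
            target_chain=target,
            homolog_chain=homolog,
            mode="flexible",
            correspondence=[],
            blocks=[],
            twists=0,
            rmsd=float("nan"),
            opt_rmsd=float("nan"),
            score=0.0,
        )

    m = len(afps)
    L = fragment_length
    starts_a = np.array([a.start_a for a in afps])
    starts_b = np.array([a.start_b for a in afps])
    ends_a = starts_a + L - 1
    ends_b = starts_b + L - 1
    frag_score = np.array(
        [a.length * (fragment_rmsd_cutoff - a.fragment_rmsd) for a in afps]
    )
    Rs = np.stack([a.rotation for a in afps])
    ts = np.stack([a.translation for a in afps])
    B = _ca_coords(res_b)
    ref_pts = np.stack([B[s - 1 : s - 1 + L].mean(axis=0) for s in starts_b])
    # transformed reference point under every AFP's own transform is used
    # for the translation-compatibility test between AFPs

    T = max_twists
    NEG = -1e18
    dp = np.full((T + 1, m), NEG)
    parent = np.full((T + 1, m), -1, dtype=np.int64)
    parent_t = np.full((T + 1, m), -1, dtype=np.int64)
    dp[0] = frag_score

    cos_max = np.cos(np.radians(compat_angle_deg))
    for j in range(m):
        pred = (ends_a < starts_a[j]) & (ends_b < starts_b[j])
        idx = np.nonzero(pred)[0]
        if idx.size == 0:
            continue
        ga = starts_a[j] - ends_a[idx] - 1
        gb = starts_b[j] - ends_b[idx] - 1
        gap_cost = np.where(ga > 0, gap_open + gap_extend * (ga - 1), 0.0) + np.where(
            gb > 0, gap_open + gap_extend * (gb - 1), 0.0
        )
        # compatibility of predecessor transforms with AFP j
        traces = np.einsum("mab,ab->m", Rs[idx], Rs[j])
        cosang = (traces - 1.0) / 2.0
        pj = Rs[j] @ ref_pts[j] + ts[j]
        pi = np.einsum("mab,b->ma", Rs[idx], ref_pts[j]) + ts[idx]
        trans_diff = np.linalg.norm(pi - pj, axis=1)
        compat = (cosang >= cos_max) & (trans_diff <= compat_translation)
        for t_used in range(T + 1):
            # extend without a twist
            cand = dp[t_used, idx] - gap_cost
            cand = np.where(compat, cand, NEG)
            if t_used > 0:
                cand_twist = dp[t_used - 1, idx] - gap_cost - twist_penalty
                cand_twist = np.where(~compat, cand_twist, NEG)
                use_twist = cand_twist > cand
                src_t = np.where(use_twist, t_used - 1, t_used)
                cand = np.maximum(cand, cand_twist)
            else:
                src_t = np.full(idx.size, t_used)
            best_k = int(np.argmax(cand))
            best = cand[best_k] + frag_score[j]
            if best > dp[t_used, j]:
                dp[t_used, j] = best
                parent[t_used, j] = idx[best_k]
                parent_t[t_used, j] = src_t[best_k]

    flat = int(np.argmax(dp))
    t_best, j_best = divmod(flat, m)
    chain_idx: list[int] = []
    t_cur, j_cur = t_best, j_best
    while j_cur >= 0:
        chain_idx.append(j_cur)
        j_prev = int(parent[t_cur, j_cur])
        t_cur = int(parent_t[t_cur, j_cur]) if j_prev >= 0 else -1
        j_cur = j_prev
    chain_idx.reverse()
    chained = [afps[k] for k in chain_idx]

    # blocks: maximal runs of consecutive chained AFPs with compatible
    # transforms (same criterion the DP charges twists by)
    A = _ca_coords(res_a)
    groups: list[list[AFP]] = [[chained[0]]]
    for prev, cur in zip(chained, chained[1:]):
        ref = B[cur.start_b - 1 : cur.start_b - 1 + cur.length].mean(axis=0)
        if _transforms_compatible(prev, cur, ref, compat_angle_deg, compat_translation):
            groups[-1].append(cur)
        else:
            groups.append([cur])
    blocks: list[Block] = []
    for grp in groups:
        pairs = [(a.start_a + k, a.start_b + k) for a in grp for k in range(L)]
        P = A[[i - 1 for i, _ in pairs]]
        Q = B[[j - 1 for _, j in pairs]]
        R, t, rmsd = kabsch_superpose(P, Q)
        blocks.append(Block(afps=grp, rotation=R, translation=t, rmsd=rmsd))

    all_pairs = [p for blk in blocks for p in blk.index_pairs]
    P = A[[i - 1 for i, _ in all_pairs]]
    Q = B[[j - 1 for _, j in all_pairs]]
    _, _, full_rmsd = kabsch_superpose(P, Q)
    total_len = sum(b.length for b in blocks)
    opt_rmsd = sum(b.rmsd * b.length for b in blocks) / total_len
    twists = len(blocks) - 1
    score = float(dp[t_best, j_best])
    return PairwiseStructAlignment(
        target_id=target_id,
        homolog_id=homolog_id,
        target_chain=target,
        homolog_chain=homolog,
        mode="flexible",
        correspondence=_index_pairs_to_author(all_pairs, res_a, res_b),
        blocks=blocks,
        twists=twists,
        rmsd=full_rmsd,
        opt_rmsd=float(opt_rmsd),
        score=score,
    )


# ---------------------------------------------------------------------------
# all-chain comparison and the chain-selection rule


def align_all_chains(
    target_chain: Chain,
    homolog: StructureModel,
    mode: str = "flexible",
    target_id: str = "target",
    **params,
) -> list[PairwiseStructAlignment]:
    """One alignment per homolog polymer chain against the fixed target
    chain, ordered by homolog chain id."""
    chains = sorted(homolog.polymer_chains, key=lambda c: c.chain_id)
    if not chains:
        raise ValueError(f"{homolog.entry_id}: no polymer chains")
    fn = flexible_align if mode == "flexible" else rigid_align_chains
    return [
        fn(
            target_chain,
            ch,
            target_id=target_id,
            homolog_id=f"{homolog.entry_id}",
            **params,
        )
        for ch in chains
    ]


def select_best_chain(alignments: list[PairwiseStructAlignment]) -> ChainSelection:
    """Lexicographic chain selection: lowest opt_rmsd, then longest
    homolog sequence, then highest score, then smallest chain id."""
    if not alignments:
        raise ValueError("select_best_chain: no alignments")
    usable = [a for a in alignments if not a.is_empty]
    pool = usable if usable else alignments

    def key(a: PairwiseStructAlignment):
        return (
            a.opt_rmsd if not np.isnan(a.opt_rmsd) else float("inf"),
            -a.homolog_sequence_length,
            -a.score,
            a.homolog_chain.chain_id,
        )

    ordered = sorted(pool, key=key)
    best = ordered[0]
    criterion = "chain_id"
    if len(ordered) == 1:
        criterion = "opt_rmsd"
    else:
        runner = ordered[1]
        if not np.isclose(
            best.opt_rmsd, runner.opt_rmsd, atol=1e-9, equal_nan=True
        ):
            criterion = "opt_rmsd"
        elif best.homolog_sequence_length != runner.homolog_sequence_length:
            criterion = "length"
        elif not np.isclose(best.score, runner.score, atol=1e-9):
            criterion = "score"
    return ChainSelection(
        homolog_id=best.homolog_id,
        chain_id=best.homolog_chain.chain_id,
        criterion=criterion,
        alignment=best,
    )
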