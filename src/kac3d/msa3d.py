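"""Structure-anchored multiple alignment (MSA3D).

Many pairwise target–homolog structural alignments are compiled into a
single multiple alignment whose columns are exactly the target chain's
resolved residues, in target order. Each homolog row places the residue
its pairwise alignment maps to that target residue; homolog residues
aligned to nothing in the target are *dropped* (not rendered as extra
columns) and only counted, so the projection is lossy in a measured way.

Anchoring is target-only: adding or removing a homolog never re-gaps
existing rows, and reading any row against the target row reproduces
that homolog's pairwise correspondence exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model import Chain
from .pairalign import PairwiseStructAlignment
from .structio import FastaRecord, read_fasta, write_fasta


@dataclass
class AnchoredMSA:
    target_id: str
    target_chain: Chain
    #: per-column (author_number, insertion_code, one_letter) of the target
    columns: list[tuple[int, str, str]]
    #: row id -> per-column cell: (one_letter, author_number) or None
    rows: dict[str, list[Optional[tuple[str, int]]]] = field(default_factory=dict)
    #: row id -> homolog residues aligned outside the target columns
    dropped_insertions: dict[str, int] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def column_index(self, author_number: int, insertion_code: str = "") -> int:
        for i, (num, icode, _) in enumerate(self.columns):
            if num == author_number and icode == insertion_code:
                return i
        raise KeyError(f"no target column for residue {author_number}{insertion_code}")

    def target_row(self) -> str:
        return "".join(code for _, _, code in self.columns)

    def gapped_row(self, row_id: str) -> str:
        return "".join(c[0] if c else "-" for c in self.rows[row_id])

    def correspondence(self, row_id: str) -> list[tuple[int, int]]:
        """Recover the pairwise (target, homolog) author-number pairs."""
        out = []
        for (num, _, _), cell in zip(self.columns, self.rows[row_id]):
            if cell is not None:
                out.append((num, cell[1]))
        return out


def build_anchored_msa(
    target: Chain,
    alignments: list[PairwiseStructAlignment],
    target_id: str = "target",
) -> AnchoredMSA:
    """Compile pairwise structural alignments into a target-anchored MSA.

    All alignments must share the target chain, one per homolog; a
    duplicate homolog row id or a foreign target is an error.
    """
    columns = [
        (r.author_number, r.insertion_code, r.one_letter)
        for r in target.polymer_residues
    ]
    msa = AnchoredMSA(target_id=target_id, target_chain=target, columns=columns)
    col_of = {(num, icode): i for i, (num, icode, _) in enumerate(columns)}
    for aln in alignments:
        if aln.target_chain is not target:
            raise ValueError(
                f"alignment {aln.homolog_id}: target chain differs from the anchor"
            )
        row_id = f"{aln.homolog_id}_{aln.homolog_chain.chain_id}"
        if row_id in msa.rows:
            raise ValueError(f"two alignments claim homolog row {row_id}")
        row: list[Optional[tuple[str, int]]] = [None] * len(columns)
        aligned_h: set[int] = set()
        for t_num, h_num in aln.correspondence:
            idx = col_of.get((t_num, ""))
            if idx is None:
                continue
            h_res = aln.homolog_chain.residue_by_number(h_num)
            row[idx] = (h_res.one_letter if h_res else "X", h_num)
            aligned_h.add(h_num)
        if aligned_h:
            lo, hi = min(aligned_h), max(aligned_h)
            dropped = sum(
                1
                for r in aln.homolog_chain.polymer_residues
                if lo <= r.author_number <= hi and r.author_number not in aligned_h
            )
        else:
            dropped = 0
        msa.rows[row_id] = row
        msa.dropped_insertions[row_id] = dropped
    return msa


def export_msa(
    msa: AnchoredMSA,
    fasta_path: Optional[Union[str, Path]] = None,
    table_path: Optional[Union[str, Path]] = None,
) -> tuple[str, pd.DataFrame]:
    """Write the MSA as gapped FASTA plus a per-row metadata table."""
    if msa.n_columns == 0:
        raise ValueError("empty MSA")
    if not msa.rows:
        warnings.warn(f"MSA for {msa.target_id} has no homolog rows")
    records = [FastaRecord(id=msa.target_id, seq=msa.target_row())]
    meta_rows = []
    for row_id in msa.rows:
        seq = msa.gapped_row(row_id)
        records.append(FastaRecord(id=row_id, seq=seq))
        n_aligned = sum(1 for c in msa.rows[row_id] if c is not None)
        meta_rows.append(
            {
                "row_id": row_id,
                "entry": row_id.rsplit("_", 1)[0],
                "chain": row_id.rsplit("_", 1)[1],
                "coverage": round(n_aligned / msa.n_columns, 4),
                "dropped_insertions": msa.dropped_insertions[row_id],
            }
        )
    text = write_fasta(records, fasta_path)
    meta = pd.DataFrame(
        meta_rows, columns=["row_id", "entry", "chain", "coverage", "dropped_insertions"]
    )
    if table_path is not None:
        meta.to_csv(table_path, sep="\t", index=False)
    return text, meta


def import_gapped_rows(source: Union[str, Path], target_id: str) -> dict[str, str]:
    """Read an externally produced gapped FASTA (equal-length rows) into
    ``{row_id: gapped_sequence}``; the target row must be present."""
    records = read_fasta(source)
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"gapped rows differ in length: {sorted(lengths)}")
    rows = {r.id: r.seq for r in records}
    if target_id not in rows:
        raise ValueError(f"target row {target_id!r} not found in imported MSA")
    return rows
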