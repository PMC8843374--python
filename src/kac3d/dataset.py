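"""Homolog metadata: loading, representative selection, identity filter.

The homolog cohort for each target protein is described by a TSV with
one row per structure (PDB id, UniProt accession, organism, taxon
group, resolution, wild-type flag, percent identity to the target).
Taxon grouping — including Gram status — is input metadata and never
inferred from sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

TAXON_GROUPS = {
    "Gram-negative",
    "Gram-positive",
    "Gram-variable",
    "Eukaryote",
    "Archaea",
    "synthetic",
}

#: spellings accepted on input, normalized to the closed set
_TAXON_ALIASES = {
    "gram-negative": "Gram-negative",
    "gram negative": "Gram-negative",
    "gram-positive": "Gram-positive",
    "gram positive": "Gram-positive",
    "gram-variable": "Gram-variable",
    "gram variable": "Gram-variable",
    "eukaryote": "Eukaryote",
    "archaea": "Archaea",
    "synthetic": "synthetic",
    "synthetic construct": "synthetic",
}

REQUIRED_COLUMNS = [
    "pdb_id",
    "uniprot_id",
    "organism",
    "taxon_group",
    "resolution",
    "is_wildtype",
]


@dataclass(frozen=True)
class HomologRecord:
    pdb_id: str
    uniprot_id: str
    organism: str
    taxon_group: str
    resolution: Optional[float]
    is_wildtype: bool
    chain_hint: str = ""
    percent_identity_to_target: Optional[float] = None

    def __post_init__(self):
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(f"{self.pdb_id}: unknown taxon group {self.taxon_group!r}")
        pid = self.percent_identity_to_target
        if pid is not None and not 0.0 <= pid <= 100.0:
            raise ValueError(f"{self.pdb_id}: percent identity {pid} outside [0, 100]")


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes", "wt", "y")


def load_homolog_table(source: Union[str, Path, pd.DataFrame]) -> list[HomologRecord]:
    """Read and validate a homolog metadata TSV."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"homolog table missing columns: {missing}")
    dupes = df["pdb_id"][df["pdb_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate pdb_id rows: {sorted(set(map(str, dupes)))}")
    records = []
    for _, row in df.iterrows():
        raw_taxon = str(row["taxon_group"]).strip()
        taxon = _TAXON_ALIASES.get(raw_taxon.lower())
        if taxon is None:
            raise ValueError(
                f"{row['pdb_id']}: unknown taxon group {raw_taxon!r} "
                f"(expected one of {sorted(TAXON_GROUPS)})"
            )
        resolution = row["resolution"]
        resolution = None if pd.isna(resolution) else float(resolution)
        pid = row.get("percent_identity_to_target")
        pid = None if pid is None or pd.isna(pid) else float(pid)
        records.append(
            HomologRecord(
                pdb_id=str(row["pdb_id"]),
                uniprot_id=str(row["uniprot_id"]),
                organism=str(row["organism"]),
                taxon_group=taxon,
                resolution=resolution,
                is_wildtype=_parse_bool(row["is_wildtype"]),
                chain_hint=str(row.get("chain_hint", "") or ""),
                percent_identity_to_target=pid,
            )
        )
    return records


def select_representative(records: Sequence[HomologRecord]) -> list[HomologRecord]:
    """One structure per UniProt accession: wild-type preferred, then the
    best (lowest) resolution, ties broken by smallest PDB id; records
    without a resolution compete last. Groups with no wild-type entry
    fall back to the best non-WT structure with a warning."""
    by_uniprot: dict[str, list[HomologRecord]] = {}
    for rec in records:
        by_uniprot.setdefault(rec.uniprot_id, []).append(rec)

    def sort_key(rec: HomologRecord):
        return (
            rec.resolution if rec.resolution is not None else float("inf"),
            rec.pdb_id,
        )

    chosen = []
    for uniprot_id in sorted(by_uniprot):
        group = by_uniprot[uniprot_id]
        wt = [r for r in group if r.is_wildtype]
        if not wt:
            warnings.warn(
                f"{uniprot_id}: no wild-type structure; using best-resolution mutant"
            )
        pool = wt if wt else group
        chosen.append(min(pool, key=sort_key))
    return chosen


def identity_filter(
    records: Sequence[HomologRecord], threshold: float = 30.0
) -> list[HomologRecord]:
    """Keep records with percent identity to the target >= threshold
    (boundary inclusive)."""
    out = []
    for rec in records:
        if rec.percent_identity_to_target is None:
            raise ValueError(
                f"{rec.pdb_id}: percent identity not populated; compute it "
                "from a global sequence alignment first"
            )
        if rec.percent_identity_to_target >= threshold:
            out.append(rec)
    return out


def tally_by_taxon(records: Sequence[HomologRecord]) -> pd.DataFrame:
    """Structure counts per taxon group plus distinct-organism counts,
    mirroring a dataset summary table (integer arithmetic, exactly
    reproducible)."""
    rows = []
    by_taxon: dict[str, list[HomologRecord]] = {}
    for rec in records:
        by_taxon.setdefault(rec.taxon_group, []).append(rec)
    for taxon in sorted(by_taxon):
        group = by_taxon[taxon]
        rows.append(
            {
                "taxon_group": taxon,
                "n_structures": len(group),
                "n_organisms": len({r.organism for r in group}),
            }
        )
    rows.append(
        {
            "taxon_group": "Total",
            "n_structures": len(records),
            "n_organisms": len({r.organism for r in records}),
        }
    )
    return pd.DataFrame(rows, columns=["taxon_group", "n_structures", "n_organisms"])


def records_to_frame(records: Sequence[HomologRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pdb_id": r.pdb_id,
                "uniprot_id": r.uniprot_id,
                "organism": r.organism,
                "taxon_group": r.taxon_group,
                "resolution": r.resolution,
                "is_wildtype": r.is_wildtype,
                "chain_hint": r.chain_hint,
                "percent_identity_to_target": r.percent_identity_to_target,
            }
            for r in records
        ]
    )
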