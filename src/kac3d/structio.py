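"""Reading and writing the formats the pipeline touches.

PDB and mmCIF parsing is delegated to :mod:`gemmi` and lifted into the
package's own hierarchical model (:class:`~kac3d.model.StructureModel`);
FASTA goes through Biopython. A minimal fixed-column PDB serializer is
provided so the synthetic generator can emit standard files (SEQRES +
ATOM records) that round-trip through the parser.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import gemmi
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import Atom, Chain, Residue, StructureModel, THREE_TO_ONE

ONE_TO_THREE = {v: k for k, v in reversed(list(THREE_TO_ONE.items()))}


class ParseError(ValueError):
    """Raised when a coordinate or sequence file cannot be interpreted."""


@dataclass(frozen=True)
class FastaRecord:
    id: str
    seq: str


# ---------------------------------------------------------------------------
# structure parsing


def _dedupe_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties broken by
    alphabetically first altloc."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for atoms in by_name.values():
        if len(atoms) == 1:
            kept.append(atoms[0])
        else:
            kept.append(min(atoms, key=lambda a: (-a.occ, a.altloc)))
    return kept


def _convert(st: gemmi.Structure, entry_id: str) -> StructureModel:
    st.setup_entities()
    seqres_by_subchain: dict[str, str] = {}
    for ent in st.entities:
        if ent.entity_type == gemmi.EntityType.Polymer and ent.full_sequence:
            seq = "".join(
                THREE_TO_ONE.get(item.split(",")[0], "X") for item in ent.full_sequence
            )
            for sub in ent.subchains:
                seqres_by_subchain[sub] = seq

    model = st[0]  # crystal structures only; NMR ensembles collapse to model 1
    out = StructureModel(entry_id=entry_id)
    resolution = float(st.resolution)
    out.resolution = resolution if resolution > 0 else None

    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        seen: set[tuple[int, str]] = set()
        for gres in gchain:
            icode = gres.seqid.icode.strip()
            is_het = gres.het_flag == "H"
            if gres.name not in THREE_TO_ONE and not is_het and gres.name not in ("HOH",):
                warnings.warn(
                    f"{entry_id}/{gchain.name}: unknown residue name "
                    f"{gres.name} {gres.seqid.num} mapped to 'X'"
                )
            key = (gres.seqid.num, icode)
            if gres.name in THREE_TO_ONE or gres.name == "UNK":
                if key in seen:
                    raise ParseError(
                        f"{entry_id}/{gchain.name}: duplicate residue number "
                        f"{gres.seqid.num}{icode}"
                    )
                seen.add(key)
            res = Residue(author_number=gres.seqid.num, name=gres.name, insertion_code=icode)
            for ga in _dedupe_altlocs(gres):
                altloc = ga.altloc if ga.altloc != "\x00" else ""
                res.add_atom(
                    Atom(
                        name=ga.name,
                        element=ga.element.name,
                        coords=(ga.pos.x, ga.pos.y, ga.pos.z),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        altloc=altloc,
                        is_hetero=is_het,
                    )
                )
            chain.add_residue(res)
        if not chain.seqres_sequence:
            for gres in gchain:
                if gres.subchain in seqres_by_subchain:
                    chain.seqres_sequence = seqres_by_subchain[gres.subchain]
                    break
        out.chains.append(chain)
    # re-validate chain id uniqueness
    return StructureModel(entry_id=out.entry_id, chains=out.chains, resolution=out.resolution)


def parse_structure(
    source: Union[str, Path],
    format_hint: Optional[str] = None,
    entry_id: Optional[str] = None,
) -> StructureModel:
    """Parse PDB or mmCIF content (text or path) into a StructureModel.

    Altloc conformers are collapsed to the highest-occupancy one, waters
    and het groups are kept but flagged, and the declared (SEQRES/entity)
    sequence is captured per chain when present.
    """
    path: Optional[Path] = None
    if isinstance(source, Path):
        path = source
    elif (
        isinstance(source, str)
        and source.strip()
        and "\n" not in source
        and Path(source).is_file()
    ):
        path = Path(source)

    if path is not None:
        text = path.read_text()
        if entry_id is None:
            entry_id = path.stem
        if format_hint is None:
            format_hint = "cif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    else:
        text = str(source)
        if format_hint is None:
            format_hint = "cif" if text.lstrip().startswith("data_") else "pdb"
    if entry_id is None:
        entry_id = "unknown"

    try:
        if format_hint == "cif":
            block = gemmi.cif.read_string(text).sole_block()
            st = gemmi.make_structure_from_block(block)
        elif format_hint == "pdb":
            st = gemmi.read_pdb_string(text)
        else:
            raise ParseError(f"unknown format hint {format_hint!r}")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{entry_id}: {exc}") from exc

    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise ParseError(f"{entry_id}: no atoms found")
    if st.name and entry_id in ("unknown",):
        entry_id = st.name.lower()
    return _convert(st, entry_id)


# ---------------------------------------------------------------------------
# chain sequences


def chain_sequence(chain: Chain, source: str = "atom"):
    """Sequence of a chain plus its residue-numbering map.

    source="atom"
        1-letter sequence of resolved polymer residues and the list of
        their ``(author_number, insertion_code)`` pairs.
    source="seqres"
        The full declared sequence; the map has one entry per declared
        position, ``None`` where the residue is absent from coordinates.
    """
    polymer = chain.polymer_residues
    if not polymer:
        raise ValueError(f"chain {chain.chain_id}: no polymer residues")
    if source == "atom":
        return chain.atom_sequence, chain.numbering_map
    if source != "seqres":
        raise ValueError(f"unknown sequence source {source!r}")
    seqres = chain.seqres_sequence
    if not seqres:
        raise ValueError(f"chain {chain.chain_id}: no declared sequence")
    mapping = _map_seqres(seqres, chain)
    return seqres, mapping


def _map_seqres(seqres: str, chain: Chain) -> list[Optional[tuple[int, str]]]:
    """Map declared-sequence positions to resolved residues by global
    alignment of the atom sequence into the declared one."""
    from Bio import Align

    atom_seq = chain.atom_sequence
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -0.5
    # gaps in the atom sequence are expected (unresolved residues);
    # gaps in seqres are not, keep them costly via the same scheme
    aln = aligner.align(seqres, atom_seq)[0]
    mapping: list[Optional[tuple[int, str]]] = [None] * len(seqres)
    numbering = chain.numbering_map
    for (s_start, s_end), (a_start, a_end) in zip(*aln.aligned):
        for off in range(s_end - s_start):
            mapping[s_start + off] = numbering[a_start + off]
    return mapping


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source: Union[str, Path]) -> list[FastaRecord]:
    """Read FASTA records; duplicate IDs are an error, lowercase letters
    are upper-cased with a warning. Gap characters '-' are preserved."""
    if isinstance(source, Path) or (
        isinstance(source, str)
        and source.strip()
        and "\n" not in source
        and Path(source).is_file()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq)
        if any(c.islower() for c in seq):
            warnings.warn(f"record {rec.id}: lowercase letters upper-cased")
            seq = seq.upper()
        records.append(FastaRecord(id=rec.id, seq=seq))
    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate FASTA ids: {', '.join(dupes)}")
    return records


def write_fasta(records: Iterable[FastaRecord], path: Optional[Union[str, Path]] = None) -> str:
    """Write records as FASTA wrapped at 60 columns; returns the text."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate record ids on write")
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    buf = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=60)
    writer.write_file(bio)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# minimal PDB serializer (synthetic generator output)


def write_pdb(model: StructureModel, path: Optional[Union[str, Path]] = None) -> str:
    """Serialize a StructureModel to minimal PDB text (SEQRES + ATOM/HETATM
    + TER + END). Coordinates are written to 3 decimals, the format's
    native precision."""
    lines: list[str] = []
    if model.resolution is not None:
        lines.append(
            "REMARK   2 RESOLUTION.    %5.2f ANGSTROMS." % model.resolution
        )
    for chain in model.chains:
        if chain.seqres_sequence:
            res_names = [ONE_TO_THREE.get(c, "UNK") for c in chain.seqres_sequence]
            n = len(res_names)
            for i in range(0, n, 13):
                ser = i // 13 + 1
                chunk = " ".join(f"{name:>3s}" for name in res_names[i : i + 13])
                lines.append(f"SEQRES {ser:>3d} {chain.chain_id:1s} {n:>4d}  {chunk}")
    serial = 1
    for chain in model.chains:
        last_polymer = None
        for res in chain.residues:
            record = "HETATM" if (not res.is_polymer and not res.is_nucleotide) else "ATOM  "
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial:>5d} {name:<4.4s}{atom.altloc or ' '}"
                    f"{res.name:>3s} {chain.chain_id:1s}{res.author_number:>4d}"
                    f"{res.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
            if res.is_polymer:
                last_polymer = res
        if last_polymer is not None:
            lines.append(
                f"TER   {serial:>5d}      {last_polymer.name:>3s} "
                f"{chain.chain_id:1s}{last_polymer.author_number:>4d}"
            )
            serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
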