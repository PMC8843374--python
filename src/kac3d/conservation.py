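"""1D and 3D conservation calls for acetyl-lysine sites, with
discrepancy classification, domain filtering and taxon summaries.

A site is *conserved in 3D* on a homolog when, after structural
superposition, a homolog lysine occupies the target site's position in
space. Three routes can establish that:

1. the structural alignment maps the site to a homolog residue that is
   lysine and spatially consistent (Cα within ``rescue_cutoff`` of the
   superposed target Cα under the containing block's transform);
2. the *rescue rule*: an unaligned homolog lysine whose Cα lies within
   ``rescue_cutoff`` of the superposed target site (codifies the manual
   inspection of structural overlays that catches lysines the alignment
   output misses);
3. the *disorder rule*: the site maps into a homolog coordinate gap and
   the declared (SEQRES) sequence shows a lysine within
   ``disorder_window`` of the gap-interpolated position (the residue is
   disordered in the crystal but present in the linear sequence).

*Conserved in 1D* means the homolog row of a sequence alignment has K
in the column holding the target site. Disagreements are starred: an
open star marks a site found by 1D only, a filled star one found by 3D
only. Conservation requires lysine identity exactly — conservative
substitutions (R/H) do not count, though they are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import Chain
from .msa3d import AnchoredMSA
from .pairalign import PairwiseStructAlignment, global_align
from .structio import chain_sequence

POSITIVE_RESIDUES = {"R", "H"}


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SiteAnnotation:
    protein_id: str
    residue: int  # author numbering
    mechanisms: frozenset[str]  # over {"KAT:YfiQ", "KAT:YiaC", "AcP"}

    def __post_init__(self):
        if not self.mechanisms:
            raise ValueError(f"site {self.protein_id}/K{self.residue}: empty mechanism set")

    @property
    def is_kat(self) -> bool:
        return any(m.startswith("KAT:") for m in self.mechanisms)

    @property
    def is_acp(self) -> bool:
        return "AcP" in self.mechanisms


@dataclass(frozen=True)
class DomainDefinition:
    protein_id: str
    name: str
    ranges: tuple[tuple[int, int], ...]  # author numbering, inclusive

    def __post_init__(self):
        spans = sorted(self.ranges)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError(f"domain {self.name}: overlapping ranges")

    def contains(self, residue: int) -> bool:
        return any(a <= residue <= b for a, b in self.ranges)

    def residues(self) -> list[int]:
        return [r for a, b in self.ranges for r in range(a, b + 1)]


@dataclass
class ConservationCall:
    site: SiteAnnotation
    homolog_id: str
    homolog_chain_id: str = ""
    aligned_residue: Optional[tuple[str, int]] = None  # (code, author number)
    conserved_3d: Optional[bool] = None
    rescue_flag: bool = False
    disorder_flag: bool = False
    conserved_1d: Optional[bool] = None
    positive_substitution: bool = False  # R/H at the position (reported, not conserved)
    discrepancy: Optional[str] = None  # agree | open_star | filled_star
    domain_present: Optional[bool] = None


@dataclass
class TaxonSummary:
    site: SiteAnnotation
    group: str
    conserved: int
    total: int  # homologs passing the domain filter

    @property
    def fraction(self) -> float:
        return self.conserved / self.total if self.total else float("nan")


# ---------------------------------------------------------------------------
# 3D call


def _superposed_target_ca(alignment, site_residue):
    """Target site Cα plus the block transform that carries it."""
    block = alignment.block_for_target(site_residue.author_number)
    if block is None or site_residue.ca is None:
        return None, None
    return site_residue.ca.coords, block


def call_site_3d(
    site: SiteAnnotation,
    alignment: PairwiseStructAlignment,
    homolog_chain: Optional[Chain] = None,
    rescue_cutoff: float = 5.0,
    disorder_window: int = 2,
) -> ConservationCall:
    """3D conservation call for one site against one homolog chain."""
    target_chain = alignment.target_chain
    site_residue = target_chain.residue_by_number(site.residue)
    if site_residue is None or not site_residue.is_polymer:
        raise ValueError(
            f"site K{site.residue} not found in target chain {target_chain.chain_id}"
        )
    if homolog_chain is None:
        homolog_chain = alignment.homolog_chain
    call = ConservationCall(
        site=site,
        homolog_id=alignment.homolog_id,
        homolog_chain_id=homolog_chain.chain_id,
    )
    if alignment.is_empty:
        call.conserved_3d = False
        return call

    target_ca, block = _superposed_target_ca(alignment, site_residue)
    aligned_num = alignment.homolog_partner(site.residue)
    aligned_res = (
        homolog_chain.residue_by_number(aligned_num) if aligned_num is not None else None
    )
    if aligned_res is not None:
        call.aligned_residue = (aligned_res.one_letter, aligned_res.author_number)
        call.positive_substitution = aligned_res.one_letter in POSITIVE_RESIDUES
        if aligned_res.one_letter == "K":
            # spatial consistency under the containing block's transform
            ok = True
            if target_ca is not None and block is not None and aligned_res.ca is not None:
                moved = block.rotation @ aligned_res.ca.coords + block.translation
                ok = float(np.linalg.norm(moved - target_ca)) <= rescue_cutoff
            call.conserved_3d = ok
            # an aligned lysine never triggers the rescue rule
            return call

    # rescue: unaligned homolog lysines near the superposed target site
    if target_ca is not None and block is not None:
        aligned_h = {h for _, h in alignment.correspondence}
        for res in homolog_chain.polymer_residues:
            if res.one_letter != "K" or res.author_number in aligned_h:
                continue
            if res.ca is None:
                continue
            moved = block.rotation @ res.ca.coords + block.translation
            if float(np.linalg.norm(moved - target_ca)) <= rescue_cutoff:
                call.conserved_3d = True
                call.rescue_flag = True
                return call

    # disorder: site maps into a homolog coordinate gap
    if aligned_res is None and _disordered_lysine(
        site.residue, alignment, homolog_chain, disorder_window
    ):
        call.conserved_3d = True
        call.disorder_flag = True
        call.aligned_residue = None
        return call

    call.conserved_3d = False
    return call


def _disordered_lysine(
    site_number: int,
    alignment: PairwiseStructAlignment,
    homolog_chain: Chain,
    window: int,
) -> bool:
    """True when the declared homolog sequence has an *unresolved* lysine
    within ``window`` of the gap-interpolated site position."""
    if not homolog_chain.seqres_sequence:
        return False
    corr = alignment.correspondence
    below = [(t, h) for t, h in corr if t < site_number]
    above = [(t, h) for t, h in corr if t > site_number]
    if not below and not above:
        return False
    seqres, mapping = chain_sequence(homolog_chain, source="seqres")
    pos_of_author = {m: i for i, m in enumerate(mapping) if m is not None}

    estimates = []
    if below:
        t_lo, h_lo = max(below)
        pos = pos_of_author.get((h_lo, ""))
        if pos is not None:
            estimates.append(pos + (site_number - t_lo))
    if above:
        t_hi, h_hi = min(above)
        pos = pos_of_author.get((h_hi, ""))
        if pos is not None:
            estimates.append(pos - (t_hi - site_number))
    for est in estimates:
        for off in range(-window, window + 1):
            idx = est + off
            if 0 <= idx < len(seqres) and seqres[idx] == "K" and mapping[idx] is None:
                return True
    return False


# ---------------------------------------------------------------------------
# 1D call


def build_sequence_msa(
    target_id: str,
    target_seq: str,
    homolog_seqs: dict[str, str],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> dict[str, str]:
    """Target-anchored sequence MSA: each homolog is globally aligned to
    the target and projected onto target positions (homolog insertions
    dropped). Columns are exactly the target residues, so the column
    holding any target position is independent of the other rows."""
    rows = {target_id: target_seq}
    for hid, seq in homolog_seqs.items():
        aln = global_align(target_seq, seq, gap_open=gap_open, gap_extend=gap_extend)
        row = ["-"] * len(target_seq)
        for i, j in aln.pairs:
            row[i - 1] = seq[j - 1]
        rows[hid] = "".join(row)
    return rows


def call_site_1d(
    site: SiteAnnotation,
    target_gapped: str,
    homolog_gapped: str,
    site_position: int,
) -> bool:
    """1D conservation: does the homolog row carry K in the column of the
    target site? ``site_position`` is the 1-based position of the site in
    the *ungapped* target sequence."""
    if len(target_gapped) != len(homolog_gapped):
        raise ValueError("gapped rows differ in length")
    count = 0
    for col, ch in enumerate(target_gapped):
        if ch != "-":
            count += 1
            if count == site_position:
                return homolog_gapped[col] == "K"
    raise ValueError(
        f"site position {site_position} beyond target row "
        f"({count} residues)"
    )


def site_position_in_chain(chain: Chain, author_number: int) -> int:
    """1-based position of an author-numbered residue in the chain's
    resolved (atom) sequence."""
    for i, (num, icode) in enumerate(chain.numbering_map):
        if num == author_number and icode == "":
            return i + 1
    raise KeyError(f"residue {author_number} not resolved in chain {chain.chain_id}")


def call_site_1d_msa(
    site: SiteAnnotation, msa: AnchoredMSA, row_id: str
) -> bool:
    """1D call read off an anchored MSA's column."""
    col = msa.column_index(site.residue)
    cell = msa.rows[row_id][col]
    return cell is not None and cell[0] == "K"


# ---------------------------------------------------------------------------
# discrepancy, domain filter, summaries


def classify_discrepancy(call: ConservationCall) -> str:
    """agree | open_star (1D only) | filled_star (3D only)."""
    if call.conserved_1d is None or call.conserved_3d is None:
        raise ValueError("both 1D and 3D fields must be set")
    if call.conserved_1d and not call.conserved_3d:
        label = "open_star"
    elif call.conserved_3d and not call.conserved_1d:
        label = "filled_star"
    else:
        label = "agree"
    call.discrepancy = label
    return label


def domain_present(
    domain: DomainDefinition,
    alignment: PairwiseStructAlignment,
    coverage_threshold: float = 0.7,
) -> bool:
    """True when the homolog alignment covers at least
    ``coverage_threshold`` of the target domain's residues."""
    targets = [
        r
        for r in domain.residues()
        if alignment.target_chain.residue_by_number(r) is not None
    ]
    if not targets:
        raise ValueError(f"domain {domain.name}: no residues in target chain")
    aligned = {t for t, _ in alignment.correspondence}
    frac = sum(1 for r in targets if r in aligned) / len(targets)
    return frac >= coverage_threshold


MATRIX_SYMBOLS = {
    "dot": "dot",
    "open_circle": "open_circle",
    "open_star": "open_star",
    "filled_star": "filled_star",
    "blank": "blank",
}


def matrix_cell(call: ConservationCall) -> str:
    """Per-homolog, per-site plot symbol: dot = conserved in both, open
    circle = conserved in 3D only via rescue/disorder (and in 1D), stars
    = 1D/3D disagreement, blank = not conserved."""
    if call.discrepancy == "open_star":
        return "open_star"
    if call.discrepancy == "filled_star":
        return "filled_star"
    if call.conserved_3d and call.conserved_1d:
        return "open_circle" if (call.rescue_flag or call.disorder_flag) else "dot"
    return "blank"


def summarize_conservation(
    calls: Sequence[ConservationCall],
    metadata: pd.DataFrame,
    group_by: str = "taxon_group",
    use_3d: bool = True,
) -> tuple[list[TaxonSummary], pd.DataFrame]:
    """Taxon-stratified conserved fractions plus the per-homolog matrix.

    Only calls with ``domain_present`` true enter the denominators.
    The matrix lists one row per homolog, ordered by percent identity
    when metadata provides it, one column per site, cells from
    :func:`matrix_cell`.
    """
    meta = metadata.set_index(metadata["uniprot_id"].astype(str))
    missing = sorted(
        {c.homolog_id for c in calls if str(c.homolog_id) not in meta.index}
    )
    if missing:
        raise ValueError(f"calls without metadata records: {', '.join(missing)}")

    summaries: list[TaxonSummary] = []
    sites = sorted({c.site for c in calls}, key=lambda s: s.residue)
    groups = sorted(meta[group_by].astype(str).unique())
    for site in sites:
        for group in groups:
            in_group = [
                c
                for c in calls
                if c.site == site
                and str(meta.loc[str(c.homolog_id), group_by]) == group
                and c.domain_present is not False
            ]
            if not in_group:
                continue
            conserved = sum(
                1 for c in in_group if (c.conserved_3d if use_3d else c.conserved_1d)
            )
            summaries.append(
                TaxonSummary(site=site, group=group, conserved=conserved, total=len(in_group))
            )

    ids = sorted({c.homolog_id for c in calls})
    if "percent_identity_to_target" in meta.columns:
        ids.sort(key=lambda h: -float(meta.loc[str(h), "percent_identity_to_target"]))
    records = []
    for hid in ids:
        row: dict[str, object] = {"homolog_id": hid}
        if "percent_identity_to_target" in meta.columns:
            row["percent_identity"] = float(
                meta.loc[str(hid), "percent_identity_to_target"]
            )
        for site in sites:
            match = [c for c in calls if c.homolog_id == hid and c.site == site]
            col = f"K{site.residue}"
            if not match:
                row[col] = "blank"
            elif match[0].domain_present is False:
                row[col] = "blank"
            else:
                row[col] = matrix_cell(match[0])
        records.append(row)
    matrix = pd.DataFrame(records)
    return summaries, matrix


# ---------------------------------------------------------------------------
# site / domain tables


def load_site_table(source) -> list[SiteAnnotation]:
    """Read a site-annotation TSV (protein_id, residue, mechanisms with
    ';'-separated tokens over {KAT:YfiQ, KAT:YiaC, AcP})."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    required = {"protein_id", "residue", "mechanisms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    valid = {"KAT:YfiQ", "KAT:YiaC", "AcP"}
    sites = []
    for _, row in df.iterrows():
        mechanisms = frozenset(t.strip() for t in str(row["mechanisms"]).split(";") if t.strip())
        bad = mechanisms - valid
        if bad:
            raise ValueError(
                f"{row['protein_id']}/K{row['residue']}: unknown mechanisms {sorted(bad)}"
            )
        sites.append(
            SiteAnnotation(
                protein_id=str(row["protein_id"]),
                residue=int(row["residue"]),
                mechanisms=mechanisms,
            )
        )
    return sites


def load_domain_table(source) -> list[DomainDefinition]:
    """Read a domain-definition TSV (protein_id, domain, ranges like
    '122-159' or '1-124,321-416')."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    required = {"protein_id", "domain", "ranges"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        ranges = []
        for token in str(row["ranges"]).split(","):
            a, b = token.strip().split("-")
            ranges.append((int(a), int(b)))
        out.append(
            DomainDefinition(
                protein_id=str(row["protein_id"]),
                name=str(row["domain"]),
                ranges=tuple(ranges),
            )
        )
    return out


def packaged_sites() -> list[SiteAnnotation]:
    """The packaged E. coli acetylation-site table (Adk, Icd, KatE, Fmt, YaaA)."""
    from importlib.resources import files

    return load_site_table(str(files("kac3d.data") / "sites.tsv"))


def packaged_domains() -> list[DomainDefinition]:
    from importlib.resources import files

    return load_domain_table(str(files("kac3d.data") / "domains.tsv"))
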