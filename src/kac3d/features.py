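"""Structural annotation of site residues.

Covers the four judgements made when inspecting an acetylation site on
a structure: what secondary structure carries it, whether it is surface
exposed, whether it sits at an oligomer interface, and what it hydrogen
bonds or contacts (protein, ligand, nucleic acid, bridging waters).

The criteria are explicit, configurable codifications of what is
usually judged by eye in a viewer: exposure is relative accessibility
>= 0.20 in monomer context, an interface is any heavy atom within
5.0 Å of another polymer chain, and an H-bond is an N/O donor–acceptor
pair within 3.5 Å (no angle term: crystal structures carry no
hydrogens).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import dihedral
from .model import BACKBONE_ATOMS, Atom, Chain, Residue, StructureModel

# ---------------------------------------------------------------------------
# secondary structure


@dataclass
class SSEAssignment:
    """Per-residue 3-class secondary structure for one chain.

    labels[i] is 'H' (helix), 'E' (strand) or 'C' (loop/other) for the
    i-th polymer residue; segments lists (label, start_idx, end_idx)
    for H/E runs (inclusive indices into the polymer residue list).
    """

    chain: Chain
    labels: list[str]
    segments: list[tuple[str, int, int]] = field(default_factory=list)

    def label_of(self, author_number: int, insertion_code: str = "") -> str:
        for i, r in enumerate(self.chain.polymer_residues):
            if r.author_number == author_number and r.insertion_code == insertion_code:
                return self.labels[i]
        raise KeyError(f"residue {author_number}{insertion_code} not in chain")

    def end_flag(self, author_number: int, insertion_code: str = "") -> bool:
        """True when the residue lies within 2 residues of its H/E
        segment's terminus (loops always False)."""
        residues = self.chain.polymer_residues
        idx = None
        for i, r in enumerate(residues):
            if r.author_number == author_number and r.insertion_code == insertion_code:
                idx = i
                break
        if idx is None:
            raise KeyError(f"residue {author_number}{insertion_code} not in chain")
        for label, start, end in self.segments:
            if start <= idx <= end:
                return idx - start <= 2 or end - idx <= 2
        return False


# phi/psi windows (degrees); ideal helix (-57, -47), ideal strand (-120, +120)
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_STRAND_PHI = (-170.0, -70.0)
_STRAND_PSI = (80.0, 180.0)

_MIN_LEN = {"H": 4, "E": 3}


def _in(window: tuple[float, float], value: Optional[float]) -> bool:
    return value is not None and window[0] <= value <= window[1]


def assign_sse(chain: Chain) -> SSEAssignment:
    """Dihedral/Cα-geometry secondary-structure assignment.

    Backbone φ/ψ windows propose H or E; a Cα(i)–Cα(i+3) distance check
    confirms helices (≈5.3 Å in an α-helix) and Cα(i)–Cα(i+2) confirms
    strands (≈6.7 Å extended). Runs shorter than 4 (helix) or 3
    (strand) collapse to loop. Residues with missing backbone atoms are
    labeled 'C' with a warning.
    """
    residues = chain.polymer_residues
    n = len(residues)
    if n == 0:
        raise ValueError(f"chain {chain.chain_id}: no polymer residues")

    def backbone(r: Residue):
        return r.atom("N"), r.atom("CA"), r.atom("C")

    phi: list[Optional[float]] = [None] * n
    psi: list[Optional[float]] = [None] * n
    for i, r in enumerate(residues):
        N, CA, C = backbone(r)
        if None in (N, CA, C):
            warnings.warn(
                f"chain {chain.chain_id} residue {r.label}: missing backbone atoms"
            )
            continue
        if i > 0 and residues[i - 1].author_number == r.author_number - 1:
            Cp = residues[i - 1].atom("C")
            if Cp is not None:
                phi[i] = dihedral(Cp.coords, N.coords, CA.coords, C.coords)
        if i < n - 1 and residues[i + 1].author_number == r.author_number + 1:
            Nn = residues[i + 1].atom("N")
            if Nn is not None:
                psi[i] = dihedral(N.coords, CA.coords, C.coords, Nn.coords)

    def ca(i: int) -> Optional[np.ndarray]:
        a = residues[i].ca
        return a.coords if a is not None else None

    raw = []
    for i in range(n):
        label = "C"
        if _in(_HELIX_PHI, phi[i]) and _in(_HELIX_PSI, psi[i]):
            label = "H"
            if i + 3 < n and ca(i) is not None and ca(i + 3) is not None:
                d = float(np.linalg.norm(ca(i) - ca(i + 3)))
                if not 4.2 <= d <= 6.6:
                    label = "C"
        elif _in(_STRAND_PHI, phi[i]) and _in(_STRAND_PSI, psi[i]):
            label = "E"
            if i + 2 < n and ca(i) is not None and ca(i + 2) is not None:
                d = float(np.linalg.norm(ca(i) - ca(i + 2)))
                if not 5.9 <= d <= 7.4:
                    label = "C"
        raw.append(label)

    # enforce minimum segment lengths
    labels = list(raw)
    segments: list[tuple[str, int, int]] = []
    i = 0
    while i < n:
        if labels[i] in ("H", "E"):
            j = i
            while j + 1 < n and labels[j + 1] == labels[i]:
                j += 1
            if j - i + 1 < _MIN_LEN[labels[i]]:
                for k in range(i, j + 1):
                    labels[k] = "C"
            else:
                segments.append((labels[i], i, j))
            i = j + 1
        else:
            i += 1
    return SSEAssignment(chain=chain, labels=labels, segments=segments)


def classify_site_sse(
    residue: Residue, sse: SSEAssignment
) -> tuple[str, bool]:
    """Secondary-structure class of a site and whether it sits at the
    end (within 2 residues of the terminus) of its H/E segment."""
    label = sse.label_of(residue.author_number, residue.insertion_code)
    end = sse.end_flag(residue.author_number, residue.insertion_code)
    return label, end


# ---------------------------------------------------------------------------
# solvent accessibility

#: van der Waals radii (Å) used for SASA; unknown elements fall back to
#: 1.8 Å with a warning.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85,
    "I": 1.98, "FE": 1.80, "ZN": 1.39, "MG": 1.73, "CA": 2.00,
    "MN": 1.80, "NA": 2.27, "K": 2.75, "CU": 1.40, "NI": 1.63,
}
DEFAULT_RADIUS = 1.8

#: theoretical maximum residue SASA (Ų) in a Gly-X-Gly tripeptide
#: (Tien et al. 2013, theoretical values)
MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    "X": 200.0,
}


@dataclass
class SASAResult:
    atoms: list[Atom]
    atom_sasa: np.ndarray
    #: (chain_id, author_number, insertion_code) -> residue SASA (Ų)
    residue_sasa: dict[tuple[str, int, str], float]
    #: same key -> SASA / tabulated Gly-X-Gly maximum, clipped to [0, 1.2]
    rel_accessibility: dict[tuple[str, int, str], float]
    probe_radius: float
    points_per_atom: int

    def residue_value(self, residue: Residue, relative: bool = False) -> float:
        key = (
            residue.chain.chain_id if residue.chain else "",
            residue.author_number,
            residue.insertion_code,
        )
        return (self.rel_accessibility if relative else self.residue_sasa)[key]


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden
    spiral quadrature, as in Shrake–Rupley implementations)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def compute_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    points_per_atom: int = 960,
    chains: Optional[Sequence[str]] = None,
    include_het: bool = False,
) -> SASAResult:
    """Shrake–Rupley solvent-accessible surface area.

    ``chains`` restricts the context (monomer vs assembly); waters are
    always excluded, het groups only included on request. Per-residue
    relative accessibility uses tabulated Gly-X-Gly maxima.
    """
    selected = []
    for chain in model.chains:
        if chains is not None and chain.chain_id not in chains:
            continue
        for res in chain.residues:
            if res.is_water:
                continue
            if not res.is_polymer and not res.is_nucleotide and not include_het:
                continue
            for atom in res.atoms:
                if atom.element != "H":
                    selected.append(atom)
    if not selected:
        raise ValueError("no atoms selected for SASA")

    coords = np.array([a.coords for a in selected])
    radii = np.empty(len(selected))
    for i, a in enumerate(selected):
        r = VDW_RADII.get(a.element.upper())
        if r is None:
            warnings.warn(
                f"unknown element {a.element!r}; using {DEFAULT_RADIUS} Å radius"
            )
            r = DEFAULT_RADIUS
        radii[i] = r
    extended = radii + probe_radius
    sphere = _sphere_points(points_per_atom)

    tree = cKDTree(coords)
    max_reach = 2.0 * extended.max()
    sasa = np.zeros(len(selected))
    for i in range(len(selected)):
        pts = coords[i] + extended[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        if neighbors:
            nb_coords = coords[neighbors]
            nb_r = extended[neighbors]
            d2 = np.sum((pts[:, None, :] - nb_coords[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < nb_r[None, :] ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        sasa[i] = 4.0 * np.pi * extended[i] ** 2 * frac

    residue_sasa: dict[tuple[str, int, str], float] = {}
    for a, s in zip(selected, sasa):
        res = a.residue
        key = (res.chain.chain_id if res.chain else "", res.author_number, res.insertion_code)
        residue_sasa[key] = residue_sasa.get(key, 0.0) + float(s)
    rel = {}
    res_by_key = {}
    for a in selected:
        res = a.residue
        key = (res.chain.chain_id if res.chain else "", res.author_number, res.insertion_code)
        res_by_key[key] = res
    for key, total in residue_sasa.items():
        res = res_by_key[key]
        denom = MAX_SASA.get(res.one_letter, MAX_SASA["X"])
        rel[key] = float(np.clip(total / denom, 0.0, 1.2))
    return SASAResult(
        atoms=selected,
        atom_sasa=sasa,
        residue_sasa=residue_sasa,
        rel_accessibility=rel,
        probe_radius=probe_radius,
        points_per_atom=points_per_atom,
    )


# ---------------------------------------------------------------------------
# hydrogen bonds and contacts


@dataclass
class HBond:
    donor: Atom
    acceptor: Atom
    distance: float  # donor–acceptor Å (water-mediated: donor–water leg)
    bridging_water: Optional[Residue] = None
    classification: str = "side chain"  # side chain|backbone|ligand|inter-subunit


@dataclass
class ContactRecord:
    site: Residue
    partner: str  # chain id or het-group label
    min_distance: float
    contact_type: str  # inter-subunit | ligand | nucleic acid


def _classify_partner(site: Residue, partner_atom: Atom) -> str:
    partner = partner_atom.residue
    if partner is None:
        return "ligand"
    if partner.is_polymer:
        site_chain = site.chain.chain_id if site.chain else ""
        partner_chain = partner.chain.chain_id if partner.chain else ""
        if partner_chain != site_chain:
            return "inter-subunit"
        return "backbone" if partner_atom.name in BACKBONE_ATOMS else "side chain"
    return "ligand"


def detect_hbonds(
    model: StructureModel,
    site: Residue,
    donor_atoms: Sequence[str] = ("NZ",),
    d_max: float = 3.5,
    water_leg_max: float = 3.5,
) -> list[HBond]:
    """Direct and water-mediated H-bonds from the site's donor atoms.

    Direct bonds are N/O donor–acceptor pairs within ``d_max``;
    water-mediated bonds require both donor–water-O and water-O–acceptor
    legs within ``water_leg_max``. No angle criterion is applied.
    """
    donors = []
    for name in donor_atoms:
        atom = site.atom(name)
        if atom is None:
            raise ValueError(f"site {site.label} lacks donor atom {name!r}")
        donors.append(atom)

    candidates: list[Atom] = []
    waters: list[Atom] = []
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                if atom.element not in ("N", "O"):
                    continue
                if res.is_water:
                    waters.append(atom)
                elif res is not site:
                    candidates.append(atom)

    bonds: list[HBond] = []
    for donor in donors:
        for acc in candidates:
            d = float(np.linalg.norm(donor.coords - acc.coords))
            if d <= d_max:
                bonds.append(
                    HBond(
                        donor=donor,
                        acceptor=acc,
                        distance=d,
                        classification=_classify_partner(site, acc),
                    )
                )
        for wat in waters:
            d1 = float(np.linalg.norm(donor.coords - wat.coords))
            if d1 > water_leg_max:
                continue
            for acc in candidates:
                d2 = float(np.linalg.norm(wat.coords - acc.coords))
                if d2 <= water_leg_max:
                    bonds.append(
                        HBond(
                            donor=donor,
                            acceptor=acc,
                            distance=d1,
                            bridging_water=wat.residue,
                            classification=_classify_partner(site, acc),
                        )
                    )
    return bonds


def contact_scan(
    model: StructureModel, site: Residue, cutoff: float = 5.0
) -> list[ContactRecord]:
    """Heavy-atom distance scan of a site residue against other polymer
    chains, het groups and nucleic-acid chains; one record per partner
    entity with the minimum distance."""
    site_coords = site.heavy_coords()
    if site_coords.size == 0:
        return []
    site_chain = site.chain.chain_id if site.chain else ""

    best: dict[tuple[str, str], float] = {}
    for chain in model.chains:
        for res in chain.residues:
            if res is site or res.is_water:
                continue
            coords = res.heavy_coords()
            if coords.size == 0:
                continue
            if res.is_nucleotide:
                key = ("nucleic acid", chain.chain_id)
            elif res.is_polymer:
                if chain.chain_id == site_chain:
                    continue
                key = ("inter-subunit", chain.chain_id)
            else:
                key = ("ligand", f"{chain.chain_id}/{res.label}")
            d = float(
                np.min(
                    np.linalg.norm(
                        site_coords[:, None, :] - coords[None, :, :], axis=2
                    )
                )
            )
            if d <= cutoff and (key not in best or d < best[key]):
                best[key] = d
    return [
        ContactRecord(site=site, partner=partner, min_distance=d, contact_type=ctype)
        for (ctype, partner), d in sorted(best.items(), key=lambda kv: kv[1])
    ]


# ---------------------------------------------------------------------------
# per-site report


def annotate_site(
    model: StructureModel,
    chain_id: str,
    author_number: int,
    sse: Optional[SSEAssignment] = None,
    sasa_monomer: Optional[SASAResult] = None,
    exposure_threshold: float = 0.20,
    hbond_d_max: float = 3.5,
    contact_cutoff: float = 5.0,
) -> dict:
    """Full structural feature report for one site residue."""
    chain = model.chain(chain_id)
    residue = chain.residue_by_number(author_number)
    if residue is None:
        raise KeyError(f"{model.entry_id}/{chain_id}: no residue {author_number}")
    if sse is None:
        sse = assign_sse(chain)
    sse_class, end_flag = classify_site_sse(residue, sse)
    if sasa_monomer is None:
        sasa_monomer = compute_sasa(model, chains=[chain_id])
    rel = sasa_monomer.residue_value(residue, relative=True)
    contacts = contact_scan(model, residue, cutoff=contact_cutoff)
    hbonds = (
        detect_hbonds(model, residue, d_max=hbond_d_max)
        if residue.atom("NZ") is not None
        else []
    )
    return {
        "chain": chain_id,
        "residue": author_number,
        "name": residue.name,
        "sse_class": sse_class,
        "sse_end": end_flag,
        "rel_accessibility": round(rel, 3),
        "surface_exposed": rel >= exposure_threshold,
        "interface": any(c.contact_type == "inter-subunit" for c in contacts),
        "interface_partners": sorted(
            {c.partner for c in contacts if c.contact_type == "inter-subunit"}
        ),
        "ligand_contacts": sorted(
            {c.partner for c in contacts if c.contact_type == "ligand"}
        ),
        "nucleic_contacts": sorted(
            {c.partner for c in contacts if c.contact_type == "nucleic acid"}
        ),
        "n_hbonds": len(hbonds),
        "hbond_partners": sorted(
            {
                f"{b.acceptor.residue.label}:{b.acceptor.name}"
                + ("(w)" if b.bridging_water else "")
                for b in hbonds
                if b.acceptor.residue is not None
            }
        ),
    }
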