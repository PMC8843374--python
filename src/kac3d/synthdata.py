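"""Synthetic homolog-structure families with planted ground truth.

Every pipeline stage is testable without downloads by generating
families of homolog structures from an ideal-geometry target chain:

* backbone built residue-by-residue from ideal φ/ψ per secondary
  structure segment (helix −57/−47, strand −120/+120, loops drawn from
  a fixed small set), bond lengths N–CA 1.458, CA–C 1.525, C–N 1.329 Å,
  ω = 180°; side chains are reduced to CB plus an idealized NZ for
  lysines (enough for alignment and conservation calls);
* homolog sequences mutated to a requested identity with site outcomes
  planted per homolog: ``conserved``, ``substituted`` (to residue X),
  ``sequence_shifted`` (lysine moved k positions in sequence but left
  in the target site's spatial position — the 3D-only case),
  ``displaced`` (lysine kept in sequence but its loop moved away in
  space — the 1D-only case) and ``disordered`` (coordinates deleted,
  declared sequence kept);
* optional inter-domain hinge rotations (open/closed conformers) and
  Gaussian coordinate noise.

Everything is deterministic under the spec's seed, and the generator
emits the same artifacts a real study would read: PDB files, FASTA,
a homolog metadata TSV and a truth table for recovery scoring.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .geometry import place_atom, rotation_about_axis
from .model import Atom, Chain, Residue, StructureModel
from .structio import ONE_TO_THREE, FastaRecord, write_fasta, write_pdb

# ideal geometry constants (Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.5
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

PHI_PSI = {"H": (-57.0, -47.0), "E": (-120.0, 120.0)}
#: loops sample deterministically from this fixed set; all four pairs sit
#: outside the helix and strand φ/ψ windows so loops never read as H/E
LOOP_ANGLES = [(-140.0, 60.0), (70.0, 40.0), (-100.0, 0.0), (-80.0, 60.0)]
SEGMENT_MIN = {"H": 4, "E": 3, "C": 1}

#: amino-acid alphabet used for random positions; lysine is excluded so
#: planted sites are the only lysines and truth stays unambiguous
ALPHABET_NO_K = list("ARNDCEQGHILMFPSTWYV")


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class SiteOutcome:
    """Planted fate of one target lysine site in one homolog."""

    kind: str  # conserved | substituted | sequence_shifted | displaced | disordered
    to_residue: str = "Q"  # substituted / sequence_shifted replacement
    shift: int = 2  # sequence_shifted offset (residues)
    mask: Optional[tuple[int, int]] = None  # disordered range (author numbers)

    def __post_init__(self):
        kinds = {"conserved", "substituted", "sequence_shifted", "displaced", "disordered"}
        if self.kind not in kinds:
            raise ValueError(f"unknown site outcome kind {self.kind!r}")
        if self.to_residue == "K":
            raise ValueError("substitution target cannot be lysine")


@dataclass
class HomologSpec:
    identity: float  # requested percent sequence identity to the target
    site_outcomes: dict[int, SiteOutcome] = field(default_factory=dict)
    hinges: list[tuple[int, float]] = field(default_factory=list)  # (domain index, angle°)
    noise_sigma: float = 0.0  # Å, Gaussian per coordinate
    taxon_group: str = "synthetic"
    organism: str = ""

    def __post_init__(self):
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        for _, angle in self.hinges:
            if not 0.0 <= angle <= 180.0:
                raise ValueError(f"hinge angle {angle} outside [0, 180]")


@dataclass
class FamilySpec:
    seed: int
    sse_plan: list[tuple[str, int]]  # (type H/E/C, length)
    domains: list[tuple[int, int]]  # author-number ranges
    sites: list[int]  # target lysine positions (author numbers)
    homologs: list[HomologSpec]

    @property
    def length(self) -> int:
        return sum(n for _, n in self.sse_plan)

    def __post_init__(self):
        n = self.length
        for site in self.sites:
            if not 1 <= site <= n:
                raise ValueError(f"site {site} outside chain 1..{n}")
        for a, b in self.domains:
            if not (1 <= a <= b <= n):
                raise ValueError(f"domain range {a}-{b} outside chain")
        for h in self.homologs:
            for site, outcome in h.site_outcomes.items():
                if site not in self.sites:
                    raise ValueError(f"outcome for unknown site {site}")
                if outcome.kind == "disordered" and outcome.mask is not None:
                    lo, hi = outcome.mask
                    if not (1 <= lo <= hi <= n):
                        raise ValueError(f"disorder mask {outcome.mask} outside chain")


@dataclass
class FamilyResult:
    spec: FamilySpec
    target: StructureModel
    homologs: list[StructureModel]
    metadata: pd.DataFrame
    truth: pd.DataFrame  # one row per homolog × site

    def homolog_by_id(self, entry_id: str) -> StructureModel:
        for m in self.homologs:
            if m.entry_id == entry_id:
                return m
        raise KeyError(entry_id)


# ---------------------------------------------------------------------------
# ideal chain construction


def _phi_psi_for_plan(
    plan: Sequence[tuple[str, int]], rng: np.random.Generator
) -> list[tuple[float, float]]:
    angles = []
    for sse, length in plan:
        if sse not in SEGMENT_MIN:
            raise ValueError(f"unknown segment type {sse!r}")
        if length < SEGMENT_MIN[sse]:
            raise ValueError(
                f"segment {sse}×{length} shorter than minimum {SEGMENT_MIN[sse]}"
            )
        for _ in range(length):
            if sse == "C":
                angles.append(LOOP_ANGLES[int(rng.integers(len(LOOP_ANGLES)))])
            else:
                angles.append(PHI_PSI[sse])
    return angles


def build_ideal_chain(
    sse_plan: Sequence[tuple[str, int]],
    seed: int,
    sequence: Optional[str] = None,
    entry_id: str = "ideal",
    chain_id: str = "A",
) -> StructureModel:
    """Build an ideal-geometry chain (N/CA/C/O + CB, + NZ on lysines)
    from a secondary-structure plan. Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    angles = _phi_psi_for_plan(sse_plan, rng)
    n = len(angles)
    if n < 8:
        raise ValueError(f"total length {n} < 8")
    if sequence is None:
        sequence = "".join(rng.choice(ALPHABET_NO_K, size=n))
    if len(sequence) != n:
        raise ValueError(f"sequence length {len(sequence)} != plan length {n}")

    # backbone by natural-extension placement
    N = [np.array([0.0, 0.0, 0.0])]
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    C0 = ca0 + BOND_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    CA = [ca0]
    C = [C0]
    for i in range(n - 1):
        psi = angles[i][1]
        phi_next = angles[i + 1][0]
        n_next = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi)
        ca_next = place_atom(CA[i], C[i], n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_next = place_atom(C[i], n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi_next)
        N.append(n_next)
        CA.append(ca_next)
        C.append(c_next)

    chain = Chain(chain_id=chain_id, seqres_sequence=sequence)
    for i in range(n):
        code = sequence[i]
        res = Residue(author_number=i + 1, name=ONE_TO_THREE.get(code, "UNK"))
        res.add_atom(Atom("N", "N", N[i]))
        res.add_atom(Atom("CA", "C", CA[i]))
        res.add_atom(Atom("C", "C", C[i]))
        psi = angles[i][1]
        O = place_atom(N[i], CA[i], C[i], BOND_C_O, 120.5, psi - 180.0)
        res.add_atom(Atom("O", "O", O))
        if code != "G":
            CB = place_atom(N[i], C[i], CA[i], BOND_CA_CB, 110.5, 122.6)
            res.add_atom(Atom("CB", "C", CB))
            if code == "K":
                direction = CB - CA[i]
                direction /= np.linalg.norm(direction)
                res.add_atom(Atom("NZ", "N", CB + 4.0 * direction))
        chain.add_residue(res)
    return StructureModel(entry_id=entry_id, chains=[chain])


# ---------------------------------------------------------------------------
# family generation


def _mutate_sequence(
    target_seq: str,
    spec: FamilySpec,
    hspec: HomologSpec,
    rng: np.random.Generator,
) -> tuple[str, set[int]]:
    """Apply site outcomes, then random mutations to hit the requested
    identity. Returns the homolog sequence and the set of author numbers
    whose letter changed."""
    n = len(target_seq)
    seq = list(target_seq)
    changed: set[int] = set()
    reserved: set[int] = set(spec.sites)
    for site, outcome in hspec.site_outcomes.items():
        if outcome.kind == "substituted":
            seq[site - 1] = outcome.to_residue
            changed.add(site)
        elif outcome.kind == "sequence_shifted":
            shifted = site + outcome.shift
            if not 1 <= shifted <= n or shifted in spec.sites:
                raise ValueError(f"shifted position {shifted} invalid for site {site}")
            seq[site - 1] = outcome.to_residue
            seq[shifted - 1] = "K"
            changed.update({site, shifted})
            reserved.add(shifted)

    requested_mut = round((1.0 - hspec.identity / 100.0) * n)
    extra = requested_mut - len(changed)
    free = [p for p in range(1, n + 1) if p not in reserved and p not in changed]
    if extra < 0:
        best = 100.0 * (1.0 - len(changed) / n)
        raise ValueError(
            f"identity {hspec.identity}% unreachable: planted outcomes already "
            f"mutate {len(changed)} positions (achievable at most {best:.1f}%)"
        )
    if extra > len(free):
        worst = 100.0 * (1.0 - (len(changed) + len(free)) / n)
        raise ValueError(
            f"identity {hspec.identity}% unreachable: only {len(free)} free "
            f"positions (achievable at least {worst:.1f}%)"
        )
    for p in rng.choice(free, size=extra, replace=False) if extra else []:
        current = seq[p - 1]
        options = [a for a in ALPHABET_NO_K if a != current]
        seq[p - 1] = str(rng.choice(options))
        changed.add(int(p))
    return "".join(seq), changed


def _copy_structure_with_sequence(
    target: StructureModel, sequence: str, entry_id: str
) -> StructureModel:
    model = copy.deepcopy(target)
    model = StructureModel(entry_id=entry_id, chains=model.chains, resolution=None)
    chain = model.chains[0]
    chain.seqres_sequence = sequence
    for res, code in zip(chain.residues, sequence):
        res.name = ONE_TO_THREE.get(code, "UNK")
        had_nz = res.atom("NZ") is not None
        if code == "K" and not had_nz:
            ca, cb = res.atom("CA"), res.atom("CB")
            if ca is not None and cb is not None:
                d = cb.coords - ca.coords
                d /= np.linalg.norm(d)
                res.add_atom(Atom("NZ", "N", cb.coords + 4.0 * d))
        elif code != "K" and had_nz:
            res.atoms = [a for a in res.atoms if a.name != "NZ"]
    return model


def _apply_hinge(
    model: StructureModel, domain: tuple[int, int], angle: float
) -> None:
    chain = model.chains[0]
    members = [r for r in chain.residues if domain[0] <= r.author_number <= domain[1]]
    if not members:
        return
    cas = np.array([r.ca.coords for r in members if r.ca is not None])
    pivot = members[0].ca.coords
    v = cas.mean(axis=0) - pivot
    axis = np.cross(v, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(axis) < 1e-6:
        axis = np.cross(v, np.array([0.0, 1.0, 0.0]))
    R, t = rotation_about_axis(axis, pivot, angle)
    for res in members:
        for atom in res.atoms:
            atom.coords = R @ atom.coords + t


def _scramble_region(
    chain: Chain,
    lo: int,
    hi: int,
    rng: np.random.Generator,
    keep: Sequence[int] = (),
    magnitude: float = 10.0,
) -> None:
    """Destroy local backbone geometry in [lo, hi] so no gapless fragment
    covering it can superpose; residues in ``keep`` are untouched."""
    for res in chain.residues:
        if not lo <= res.author_number <= hi or res.author_number in keep:
            continue
        offset = rng.normal(0.0, magnitude / 2.0, size=3) + np.array(
            [0.0, 0.0, magnitude]
        )
        jitter = rng.normal(0.0, 2.0, size=(len(res.atoms), 3))
        for atom, j in zip(res.atoms, jitter):
            atom.coords = atom.coords + offset + j


def generate_family(spec: FamilySpec) -> FamilyResult:
    """Generate the target, homolog structures, metadata and truth table."""
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    seq = [""] * n
    for i in range(n):
        seq[i] = "K" if (i + 1) in spec.sites else str(rng.choice(ALPHABET_NO_K))
    target_seq = "".join(seq)
    target = build_ideal_chain(
        spec.sse_plan, seed=spec.seed, sequence=target_seq, entry_id="target"
    )
    target_chain = target.chains[0]

    homologs: list[StructureModel] = []
    meta_rows = []
    truth_rows = []
    fragment_reach = 7  # residues a fragment window can extend past a position

    for i, hspec in enumerate(spec.homologs, start=1):
        entry_id = f"syn{i:03d}"
        hseq, changed = _mutate_sequence(target_seq, spec, hspec, rng)
        model = _copy_structure_with_sequence(target, hseq, entry_id)
        chain = model.chains[0]

        for domain_idx, angle in hspec.hinges:
            _apply_hinge(model, spec.domains[domain_idx], angle)

        masked: list[tuple[int, int]] = []
        for site, outcome in hspec.site_outcomes.items():
            if outcome.kind == "displaced":
                site_res = chain.residue_by_number(site)
                ca_all = np.array(
                    [r.ca.coords for r in chain.residues if r.ca is not None]
                )
                d = site_res.ca.coords - ca_all.mean(axis=0)
                d = d / np.linalg.norm(d) if np.linalg.norm(d) > 1e-9 else np.array([0.0, 0.0, 1.0])
                shift_vec = 15.0 * d
                lo, hi = site - fragment_reach, site + fragment_reach
                for res in chain.residues:
                    if lo <= res.author_number <= hi:
                        for atom in res.atoms:
                            atom.coords = atom.coords + shift_vec
                # scramble the displaced block's neighbors inside it so the
                # translated block cannot re-align as a rigid fragment
                _scramble_region(chain, lo, hi, rng, keep=(), magnitude=6.0)
            elif outcome.kind == "sequence_shifted":
                shifted = site + outcome.shift
                lo = min(site, shifted) - fragment_reach
                hi = max(site, shifted) + fragment_reach
                _scramble_region(chain, lo, hi, rng, keep=(shifted,))
                src = target_chain.residue_by_number(site)
                dst = chain.residue_by_number(shifted)
                by_name = {a.name: a for a in src.atoms}
                for atom in dst.atoms:
                    if atom.name in by_name:
                        atom.coords = by_name[atom.name].coords.copy()
            elif outcome.kind == "disordered":
                masked.append(outcome.mask or (site - 2, site + 2))

        for lo, hi in masked:
            chain.residues = [
                r for r in chain.residues if not lo <= r.author_number <= hi
            ]

        if hspec.noise_sigma > 0:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.coords = atom.coords + rng.normal(
                        0.0, hspec.noise_sigma, size=3
                    )

        realized = 100.0 * sum(a == b for a, b in zip(target_seq, hseq)) / n
        meta_rows.append(
            {
                "pdb_id": entry_id,
                "uniprot_id": f"SYNP{i:02d}",
                "organism": hspec.organism or f"Synthetica sp. {i}",
                "taxon_group": hspec.taxon_group,
                "resolution": round(1.5 + 0.1 * i, 2),
                "is_wildtype": True,
                "chain_hint": "A",
                "percent_identity_to_target": round(realized, 2),
            }
        )
        for site in spec.sites:
            outcome = hspec.site_outcomes.get(site, SiteOutcome("conserved"))
            expected = _expected_truth(outcome)
            truth_rows.append({"homolog_id": entry_id, "site": site, **expected})
        homologs.append(model)

    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    return FamilyResult(
        spec=spec, target=target, homologs=homologs, metadata=metadata, truth=truth
    )


def _expected_truth(outcome: SiteOutcome) -> dict:
    table = {
        "conserved": (True, True, "agree", False, False),
        "substituted": (False, False, "agree", False, False),
        "sequence_shifted": (True, False, "filled_star", True, False),
        "displaced": (False, True, "open_star", False, False),
        "disordered": (True, True, "agree", False, True),
    }
    c3, c1, disc, rescue, disorder = table[outcome.kind]
    return {
        "conserved_3d": c3,
        "conserved_1d": c1,
        "discrepancy": disc,
        "rescue_flag": rescue,
        "disorder_flag": disorder,
    }


#: two-domain target plan used by the demo family: 90 residues, an
#: α/β N-terminal domain (1–40) and a helical C-terminal domain (41–90)
DEMO_PLAN: list[tuple[str, int]] = [
    ("C", 3), ("H", 10), ("C", 4), ("E", 6), ("C", 4), ("E", 6), ("C", 7),
    ("H", 12), ("C", 5), ("H", 12), ("C", 4), ("E", 8), ("C", 9),
]
DEMO_DOMAINS = [(1, 40), (41, 90)]
DEMO_SITES = [25, 55]  # loop lysines, one per domain


def demo_family_spec(seed: int, n_homologs: int = 6) -> FamilySpec:
    """The standard synthetic study conditions: a two-domain target with
    loop lysine sites and homologs spanning 58–92% identity that cycle
    through the planted outcomes — plain conservation, a 30° inter-domain
    hinge (open/closed conformers), substitution to arginine, a
    sequence-shifted-but-spatially-conserved lysine, a spatially
    displaced loop lysine, and a disordered loop — plus mild coordinate
    noise on one homolog. Taxon labels cycle through the domain-of-life
    groups so stratified summaries are exercised."""
    templates = [
        HomologSpec(identity=92.0),
        HomologSpec(identity=85.0, hinges=[(1, 30.0)]),
        HomologSpec(
            identity=78.0, site_outcomes={DEMO_SITES[0]: SiteOutcome("substituted", to_residue="R")}
        ),
        HomologSpec(
            identity=70.0, site_outcomes={DEMO_SITES[1]: SiteOutcome("sequence_shifted", shift=2)}
        ),
        HomologSpec(
            identity=64.0, site_outcomes={DEMO_SITES[0]: SiteOutcome("displaced")}
        ),
        HomologSpec(
            identity=58.0,
            site_outcomes={DEMO_SITES[1]: SiteOutcome("disordered")},
            noise_sigma=0.15,
        ),
    ]
    taxa = ["Gram-negative", "Gram-positive", "Eukaryote", "Archaea", "Gram-negative", "Eukaryote"]
    homologs = []
    for i in range(n_homologs):
        t = templates[i % len(templates)]
        homologs.append(
            HomologSpec(
                identity=t.identity - 1.0 * (i // len(templates)),
                site_outcomes=dict(t.site_outcomes),
                hinges=list(t.hinges),
                noise_sigma=t.noise_sigma,
                taxon_group=taxa[i % len(taxa)],
            )
        )
    return FamilySpec(
        seed=seed,
        sse_plan=DEMO_PLAN,
        domains=DEMO_DOMAINS,
        sites=DEMO_SITES,
        homologs=homologs,
    )


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryMetrics:
    overall_accuracy: float
    field_accuracy: dict[str, float]
    confusion_3d: dict[str, int]  # tp / fp / fn / tn on conserved_3d
    n_cells: int


TRUTH_FIELDS = ["conserved_3d", "conserved_1d", "discrepancy", "rescue_flag", "disorder_flag"]


def evaluate_recovery(calls: pd.DataFrame, truth: pd.DataFrame) -> RecoveryMetrics:
    """Score pipeline calls against the planted truth table.

    Both frames need homolog_id, site and the truth fields; the
    homolog × site grids must match exactly.
    """
    key = ["homolog_id", "site"]
    calls_idx = calls.set_index(key).sort_index()
    truth_idx = truth.set_index(key).sort_index()
    if set(calls_idx.index) != set(truth_idx.index):
        only_calls = sorted(set(calls_idx.index) - set(truth_idx.index))
        only_truth = sorted(set(truth_idx.index) - set(calls_idx.index))
        raise ValueError(
            f"grid mismatch: calls-only {only_calls[:5]}, truth-only {only_truth[:5]}"
        )
    truth_idx = truth_idx.loc[calls_idx.index]
    field_acc = {}
    all_match = np.ones(len(calls_idx), dtype=bool)
    for fieldname in TRUTH_FIELDS:
        got = calls_idx[fieldname].to_numpy()
        want = truth_idx[fieldname].to_numpy()
        match = got == want
        field_acc[fieldname] = float(match.mean())
        all_match &= match
    got3 = calls_idx["conserved_3d"].to_numpy().astype(bool)
    want3 = truth_idx["conserved_3d"].to_numpy().astype(bool)
    confusion = {
        "tp": int(np.sum(got3 & want3)),
        "fp": int(np.sum(got3 & ~want3)),
        "fn": int(np.sum(~got3 & want3)),
        "tn": int(np.sum(~got3 & ~want3)),
    }
    return RecoveryMetrics(
        overall_accuracy=float(all_match.mean()),
        field_accuracy=field_acc,
        confusion_3d=confusion,
        n_cells=len(calls_idx),
    )


# ---------------------------------------------------------------------------
# on-disk emission


def write_family(result: FamilyResult, outdir: Union[str, Path]) -> dict[str, Path]:
    """Write the family as PDB files, FASTA, metadata TSV and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structures = outdir / "structures"
    structures.mkdir(exist_ok=True)
    write_pdb(result.target, structures / "target.pdb")
    for model in result.homologs:
        write_pdb(model, structures / f"{model.entry_id}.pdb")
    records = [
        FastaRecord(id="target", seq=result.target.chains[0].seqres_sequence)
    ] + [
        FastaRecord(id=m.entry_id, seq=m.chains[0].seqres_sequence)
        for m in result.homologs
    ]
    write_fasta(records, outdir / "sequences.fasta")
    result.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    result.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    sites = pd.DataFrame(
        {
            "protein_id": "target",
            "residue": result.spec.sites,
            "mechanisms": "KAT:YiaC",
        }
    )
    sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)
    domains = pd.DataFrame(
        {
            "protein_id": "target",
            "domain": [f"D{i+1}" for i in range(len(result.spec.domains))],
            "ranges": [f"{a}-{b}" for a, b in result.spec.domains],
        }
    )
    domains.to_csv(outdir / "domains.tsv", sep="\t", index=False)
    return {
        "structures": structures,
        "sequences": outdir / "sequences.fasta",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
        "sites": outdir / "sites.tsv",
        "domains": outdir / "domains.tsv",
    }
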