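"""End-to-end workflow: structures in, conservation report out.

Mirrors the study design: load the target and every homolog structure,
align all homolog chains to the target chain (flexible by default),
pick one chain per homolog by the opt-rmsd/length/score rule, compile
the anchored MSA, call each site in 3D and 1D, star the discrepancies,
apply the domain-presence filter, annotate target sites structurally
and summarize by taxon group.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import conservation as cons
from . import dataset, features, msa3d, pairalign, structio


class ConfigError(ValueError):
    """Bad or incomplete configuration (CLI exit code 2)."""


class DataError(ValueError):
    """A pipeline stage failed on its inputs (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    target: str
    homolog_dir: str
    metadata: str
    sites: str
    outdir: str
    domains: Optional[str] = None
    target_chain: str = "A"
    protein_id: str = "target"
    mode: str = "flexible"
    import_msa: Optional[str] = None
    identity_threshold: float = 30.0
    select_representatives: bool = False
    # aligner
    fragment_length: int = 8
    fragment_rmsd_cutoff: float = 3.0
    max_twists: int = 5
    twist_penalty: float = 12.0
    gap_open: float = 8.0
    gap_extend: float = 0.5
    compat_angle_deg: float = 15.0
    compat_translation: float = 3.0
    # conservation
    rescue_cutoff: float = 5.0
    disorder_window: int = 2
    coverage_threshold: float = 0.7
    # features
    exposure_threshold: float = 0.20
    hbond_d_max: float = 3.5
    contact_cutoff: float = 5.0
    sasa_points: int = 960
    seed: int = 0
    run_features: bool = True

    def __post_init__(self):
        if self.mode not in ("rigid", "flexible"):
            raise ConfigError(f"mode must be rigid|flexible, got {self.mode!r}")
        for name in (
            "fragment_rmsd_cutoff",
            "twist_penalty",
            "gap_open",
            "gap_extend",
            "compat_angle_deg",
            "compat_translation",
            "rescue_cutoff",
            "coverage_threshold",
            "exposure_threshold",
            "hbond_d_max",
            "contact_cutoff",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.fragment_length < 3:
            raise ConfigError("fragment_length must be >= 3")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(payload, dict):
            raise ConfigError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def validate_paths(self) -> None:
        for name in ("target", "homolog_dir", "metadata", "sites"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        if self.domains and not Path(self.domains).exists():
            raise ConfigError(f"domains path does not exist: {self.domains}")
        if self.import_msa and not Path(self.import_msa).exists():
            raise ConfigError(f"import_msa path does not exist: {self.import_msa}")


def _aligner_kwargs(config: PipelineConfig) -> dict:
    if config.mode == "rigid":
        return {"gap_open": 11.0, "gap_extend": 1.0}
    return {
        "fragment_length": config.fragment_length,
        "fragment_rmsd_cutoff": config.fragment_rmsd_cutoff,
        "max_twists": config.max_twists,
        "twist_penalty": config.twist_penalty,
        "gap_open": config.gap_open,
        "gap_extend": config.gap_extend,
        "compat_angle_deg": config.compat_angle_deg,
        "compat_translation": config.compat_translation,
    }


def _load_structures(config: PipelineConfig, records):
    hdir = Path(config.homolog_dir)
    models = {}
    for rec in records:
        candidates = [hdir / f"{rec.pdb_id}{ext}" for ext in (".pdb", ".cif", ".ent")]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise DataError(f"structure file for {rec.pdb_id} not found in {hdir}")
        models[rec.pdb_id] = structio.parse_structure(path, entry_id=rec.pdb_id)
    return models


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write the report bundle.

    Returns a dict of output paths plus the in-memory tables. Raises
    ConfigError for bad configuration and DataError when a stage fails
    on its inputs (message names the stage and entity).
    """
    t0 = time.time()
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name):
        log.append(f"[{time.time() - t0:7.2f}s] {name}")

    # ---- load inputs
    stage("load target structure")
    try:
        target_model = structio.parse_structure(Path(config.target))
        target_chain = target_model.chain(config.target_chain)
    except (structio.ParseError, KeyError) as exc:
        raise DataError(f"stage load-target: {exc}") from exc

    stage("load metadata")
    try:
        records = dataset.load_homolog_table(config.metadata)
    except ValueError as exc:
        raise DataError(f"stage load-metadata: {exc}") from exc
    if config.select_representatives:
        records = dataset.select_representative(records)

    stage("load site/domain tables")
    try:
        all_sites = cons.load_site_table(config.sites)
        sites = [s for s in all_sites if s.protein_id == config.protein_id]
        domains = (
            [
                d
                for d in cons.load_domain_table(config.domains)
                if d.protein_id == config.protein_id
            ]
            if config.domains
            else []
        )
    except ValueError as exc:
        raise DataError(f"stage load-sites: {exc}") from exc
    if not sites:
        raise DataError(
            f"stage load-sites: no sites for protein_id {config.protein_id!r}"
        )

    stage("load homolog structures")
    models = _load_structures(config, records)

    # ---- identity filter (compute from sequences when absent)
    stage("identity filter")
    target_seq = target_chain.seqres_sequence or target_chain.atom_sequence
    filled = []
    for rec in records:
        if rec.percent_identity_to_target is None:
            hchain = models[rec.pdb_id].polymer_chains[0]
            hseq = hchain.seqres_sequence or hchain.atom_sequence
            pid = pairalign.global_align(target_seq, hseq).percent_identity
            rec = dataclasses.replace(rec, percent_identity_to_target=round(pid, 2))
        filled.append(rec)
    records = dataset.identity_filter(filled, config.identity_threshold)
    if not records:
        log.append("warning: no homologs pass the identity threshold")

    # ---- alignment + chain selection
    stage(f"{config.mode} alignment of all chains")
    selections: list[pairalign.ChainSelection] = []
    for rec in records:
        try:
            alns = pairalign.align_all_chains(
                target_chain,
                models[rec.pdb_id],
                mode=config.mode,
                target_id=target_model.entry_id,
                **_aligner_kwargs(config),
            )
            selections.append(pairalign.select_best_chain(alns))
        except ValueError as exc:
            raise DataError(f"stage align ({rec.pdb_id}): {exc}") from exc

    # ---- anchored MSA
    stage("anchored MSA")
    msa = msa3d.build_anchored_msa(
        target_chain,
        [s.alignment for s in selections],
        target_id=target_model.entry_id,
    )
    msa_fasta, msa_meta = msa3d.export_msa(
        msa, outdir / "msa3d.fasta", outdir / "msa3d_rows.tsv"
    )

    # ---- 1D rows
    stage("1D sequence alignment")
    if config.import_msa:
        seq_rows = msa3d.import_gapped_rows(config.import_msa, target_model.entry_id)
        target_row_1d = seq_rows[target_model.entry_id]
        seq_by_id = {rec.pdb_id: seq_rows.get(rec.pdb_id, "") for rec in records}
    else:
        homolog_seqs = {}
        for rec in records:
            sel = next(s for s in selections if s.homolog_id == rec.pdb_id)
            hchain = sel.alignment.homolog_chain
            homolog_seqs[rec.pdb_id] = hchain.seqres_sequence or hchain.atom_sequence
        rows = cons.build_sequence_msa(target_model.entry_id, target_seq, homolog_seqs)
        target_row_1d = rows[target_model.entry_id]
        seq_by_id = {rec.pdb_id: rows[rec.pdb_id] for rec in records}

    # ---- conservation calls
    stage("conservation calls")
    uniprot_of = {rec.pdb_id: rec.uniprot_id for rec in records}
    calls: list[cons.ConservationCall] = []
    for rec in records:
        sel = next(s for s in selections if s.homolog_id == rec.pdb_id)
        aln = sel.alignment
        for site in sites:
            try:
                call = cons.call_site_3d(
                    site,
                    aln,
                    rescue_cutoff=config.rescue_cutoff,
                    disorder_window=config.disorder_window,
                )
                row = seq_by_id.get(rec.pdb_id, "")
                if row:
                    pos = _site_position_in_target(
                        target_chain, target_seq, site.residue
                    )
                    call.conserved_1d = cons.call_site_1d(
                        site, target_row_1d, row, pos
                    )
                else:
                    call.conserved_1d = False
                cons.classify_discrepancy(call)
                site_domain = next(
                    (d for d in domains if d.contains(site.residue)), None
                )
                call.domain_present = (
                    cons.domain_present(site_domain, aln, config.coverage_threshold)
                    if site_domain is not None
                    else True
                )
                # summaries join on uniprot accessions
                call.homolog_id = uniprot_of[rec.pdb_id]
                calls.append(call)
            except ValueError as exc:
                raise DataError(
                    f"stage conserve ({rec.pdb_id} K{site.residue}): {exc}"
                ) from exc

    calls_df = pd.DataFrame(
        [
            {
                "homolog_id": c.homolog_id,
                "site": c.site.residue,
                "mechanisms": ";".join(sorted(c.site.mechanisms)),
                "aligned_residue": (
                    f"{c.aligned_residue[0]}{c.aligned_residue[1]}"
                    if c.aligned_residue
                    else ""
                ),
                "conserved_3d": bool(c.conserved_3d),
                "conserved_1d": bool(c.conserved_1d),
                "rescue_flag": c.rescue_flag,
                "disorder_flag": c.disorder_flag,
                "positive_substitution": c.positive_substitution,
                "discrepancy": c.discrepancy,
                "domain_present": bool(c.domain_present),
            }
            for c in calls
        ]
    )
    calls_df.to_csv(outdir / "calls.tsv", sep="\t", index=False)

    # ---- summaries
    stage("taxon summaries")
    if calls:
        meta_df = dataset.records_to_frame(records)
        summaries, matrix = cons.summarize_conservation(calls, meta_df)
    else:
        summaries, matrix = [], pd.DataFrame(columns=["homolog_id"])
    pd.DataFrame(
        [
            {
                "site": f"K{s.site.residue}",
                "taxon_group": s.group,
                "conserved": s.conserved,
                "total": s.total,
                "fraction": round(s.fraction, 4),
            }
            for s in summaries
        ]
    ).to_csv(outdir / "taxon_summary.tsv", sep="\t", index=False)
    matrix.to_csv(outdir / "matrix.tsv", sep="\t", index=False)

    # ---- features
    features_df = pd.DataFrame()
    if config.run_features:
        stage("feature annotation of target sites")
        sse = features.assign_sse(target_chain)
        sasa = features.compute_sasa(
            target_model,
            chains=[config.target_chain],
            points_per_atom=config.sasa_points,
        )
        feature_rows = []
        for site in sites:
            try:
                feature_rows.append(
                    features.annotate_site(
                        target_model,
                        config.target_chain,
                        site.residue,
                        sse=sse,
                        sasa_monomer=sasa,
                        exposure_threshold=config.exposure_threshold,
                        hbond_d_max=config.hbond_d_max,
                        contact_cutoff=config.contact_cutoff,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise DataError(f"stage features (K{site.residue}): {exc}") from exc
        features_df = pd.DataFrame(feature_rows)
        features_df.to_csv(outdir / "features.tsv", sep="\t", index=False)

    # ---- run log
    stage("done")
    run_info = {
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if v is not None
        },
        "seed": config.seed,
        "n_homologs": len(records),
        "selections": [
            {
                "homolog": s.homolog_id,
                "chain": s.chain_id,
                "criterion": s.criterion,
                "opt_rmsd": None
                if pd.isna(s.alignment.opt_rmsd)
                else round(s.alignment.opt_rmsd, 3),
                "twists": s.alignment.twists,
            }
            for s in selections
        ],
        "log": log,
    }
    (outdir / "run.json").write_text(json.dumps(run_info, indent=2))

    return {
        "outdir": outdir,
        "calls": calls_df,
        "matrix": matrix,
        "summaries": summaries,
        "features": features_df,
        "msa": msa,
        "selections": selections,
        "run_info": run_info,
    }


def _site_position_in_target(target_chain, target_seq: str, author_number: int) -> int:
    """Position of a site in the sequence used for the 1D rows (declared
    sequence when present, else the resolved sequence)."""
    if target_chain.seqres_sequence and target_seq == target_chain.seqres_sequence:
        _, mapping = structio.chain_sequence(target_chain, source="seqres")
        for i, m in enumerate(mapping):
            if m == (author_number, ""):
                return i + 1
        raise DataError(f"site {author_number} not in declared target sequence")
    return cons.site_position_in_chain(target_chain, author_number)
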