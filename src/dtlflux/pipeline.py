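"""End-to-end pipeline: simulate -> infer -> profile / flux / thermo -> report.

Each stage reads its inputs from, and writes its outputs to, a run
directory, so stages can be re-run individually and composed from the
command line.  A :class:`RunManifest` with per-file SHA-256 checksums
is written at the end; identical configuration and seed reproduce
identical checksums for every deterministic stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, ancestral, flux, io, pathways, simulate, thermo
from .simulate import DTLRates
from .tree import SpeciesTree

__all__ = ["RunConfig", "RunManifest", "DependencyError", "run_pipeline",
           "STAGES", "STAGE_ORDER"]

logger = logging.getLogger("dtlflux")

HGT_CLADE = "hgt_influx"
LOSS_CLADE = "loss_prone"


class DependencyError(RuntimeError):
    """A stage input is missing; names the stage that produces it."""


@dataclass
class RunConfig:
    """Parameters of a full synthetic run.

    The defaults describe the study conditions the generator emulates:
    a small DPANN-like clade with a transfer-boosted lineage (gene
    influx) and a loss-dominated, hotter-adapted lineage (genome
    streamlining), proteomes with a planted IVYWREL-OGT slope, and
    annotations whose overlap fraction is elevated in the streamlined
    clade.
    """

    outdir: str = "dtlflux_run"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "infer", "profile", "flux",
                               "thermo", "report")
    log_level: str = "INFO"

    # species tree
    n_tips: int = 16
    birth_rate: float = 1.0
    death_rate: float = 0.2

    # gene content
    n_families: int = 500
    root_presence_prob: float = 0.35
    origination_rate: float = 0.02
    duplication_rate: float = 0.02
    transfer_rate: float = 0.12
    loss_rate: float = 0.35
    hgt_transfer_multiplier: float = 8.0
    loss_loss_multiplier: float = 5.0

    # inference
    min_members: int = 4
    gain_penalty: float = 2.0
    loss_penalty: float = 1.0
    event_table: Optional[str] = None  # ingest instead of inferring

    # profiling
    completeness_mode: str = "gene"
    genes_per_category: int = 8

    # flux
    top_k: int = 50
    gains_definition: str = "DTO"
    pseudocount: float = 1.0

    # proteomes / annotations
    ogt_low: float = 45.0
    ogt_high: float = 80.0
    loss_clade_ogt_offset: float = 15.0
    ogt_slope: float = 0.002
    n_residues: int = 30_000
    mean_gene_length: int = 800
    target_coding_density: float = 0.92
    overlap_fraction_background: float = 0.12
    overlap_fraction_streamlined: float = 0.39

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data = dict(data, stages=tuple(data["stages"]))
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(out["stages"])
        return out

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def base_rates(self) -> DTLRates:
        return DTLRates(
            origination=self.origination_rate,
            duplication=self.duplication_rate,
            transfer=self.transfer_rate,
            loss=self.loss_rate,
        )


@dataclass
class RunManifest:
    version: str
    config_hash: str
    stages_run: list[str]
    files: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _require(outdir: Path, filename: str, producer: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise DependencyError(
            f"missing input {filename!r}; run the {producer!r} stage first")
    return path


def _load_tree(outdir: Path, producer: str = "simulate") -> SpeciesTree:
    tree = io.read_newick(_require(outdir, "species_tree.nwk", producer))
    clade_path = outdir / "clades.tsv"
    if clade_path.exists():
        table = pd.read_csv(clade_path, sep="\t", comment="#")
        for label, grp in table.groupby("clade"):
            for nid in grp["node"]:
                if nid in tree:
                    tree.node(nid).clade = label
    return tree


def _clade_map(tree: SpeciesTree) -> dict[str, str]:
    return {
        nid: (tree.node(nid).clade or "background") for nid in tree.preorder()
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path) -> list[str]:
    seed = int(cfg.seed)
    tree = simulate.simulate_species_tree(
        cfg.n_tips, cfg.birth_rate, cfg.death_rate, seed=seed)
    simulate.pick_disjoint_clades(tree, [HGT_CLADE, LOSS_CLADE])
    base = cfg.base_rates()
    schedule = {}
    hgt_nodes = set(tree.clade_nodes(HGT_CLADE))
    loss_nodes = set(tree.clade_nodes(LOSS_CLADE))
    for nid in tree.preorder():
        if nid in hgt_nodes:
            schedule[nid] = base.scaled({"transfer": cfg.hgt_transfer_multiplier})
        elif nid in loss_nodes:
            schedule[nid] = base.scaled({"loss": cfg.loss_loss_multiplier})
        else:
            schedule[nid] = base
    matrix, log = simulate.simulate_gene_content(
        tree, schedule, cfg.n_families, cfg.root_presence_prob, seed=seed + 1)
    true_tally = ancestral.BranchEventTally.from_event_log(tree, log)

    ogts = simulate.assign_tip_ogts(
        tree, cfg.ogt_low, cfg.ogt_high, seed=seed + 2,
        clade_offsets={LOSS_CLADE: cfg.loss_clade_ogt_offset})
    proteomes = simulate.simulate_proteomes(
        tree, ogts, slope=cfg.ogt_slope, n_residues=cfg.n_residues,
        seed=seed + 3)

    pdefs = simulate.simulate_pathway_groupings(
        matrix.families, genes_per_category=cfg.genes_per_category,
        seed=seed + 4)

    files = []

    def _write(name, fn):
        fn(outdir / name)
        files.append(name)

    _write("species_tree.nwk", lambda p: io.write_newick(tree, p))
    clade_rows = [(nid, tree.node(nid).clade) for nid in tree.preorder()
                  if tree.node(nid).clade]
    _write("clades.tsv", lambda p: io.write_tsv(
        pd.DataFrame(clade_rows, columns=["node", "clade"]), p))
    _write("presence_matrix.tsv",
           lambda p: io.write_presence_matrix(matrix, p,
                                              metadata={"seed": str(seed)}))
    _write("event_log.tsv", lambda p: io.write_event_log(log, p))
    _write("true_tally.tsv", lambda p: io.write_tally(
        true_tally, p, metadata={"source": "ground-truth simulation"}))
    _write("proteomes.faa",
           lambda p: io.write_fasta_proteomes(proteomes.sequences, p))
    _write("true_ogt.tsv", lambda p: io.write_tsv(
        pd.DataFrame(sorted(ogts.items()), columns=["genome", "ogt"]), p))

    rows = []
    for pw in pdefs:
        for si, step in enumerate(pw.steps, start=1):
            rows.append((pw.pathway_id, pw.name, pw.category, si,
                         ",".join(sorted(step))))
    _write("pathways.tsv", lambda p: io.write_tsv(
        pd.DataFrame(rows, columns=["pathway_id", "name", "category",
                                    "step_index", "alternatives"]), p))

    ann_dir = outdir / "annotations"
    ann_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(seed + 5)
    binary = matrix.binary
    for j, tid in enumerate(tree.tips):
        n_genes = max(60, int(binary[tid].sum()) * 3)
        # intergenic budget varies between genomes, so gene count predicts
        # genome size strongly but not perfectly
        genome_length = int(
            n_genes * cfg.mean_gene_length / cfg.target_coding_density
            * rng.uniform(0.95, 1.10))
        streamlined = tree.node(tid).clade == LOSS_CLADE
        overlap = (cfg.overlap_fraction_streamlined if streamlined
                   else cfg.overlap_fraction_background)
        gc = float(rng.uniform(0.28, 0.40) if streamlined
                   else rng.uniform(0.33, 0.52))
        # the sampled gene lengths can overshoot the length budget;
        # grow the genome a little and retry (deterministic)
        for _ in range(8):
            try:
                ann = simulate.simulate_annotation(
                    genome_length, n_genes, overlap, gc,
                    seed=seed + 100 + j, genome_id=tid,
                    mean_gene_length=cfg.mean_gene_length)
                break
            except simulate.InfeasibleConfigurationError:
                genome_length = int(genome_length * 1.1)
        else:
            raise simulate.InfeasibleConfigurationError(
                f"could not lay out {n_genes} genes for {tid}")
        io.write_gff(ann, ann_dir / f"{tid}.gff3")
        files.append(f"annotations/{tid}.gff3")
    logger.info("simulate: %d tips, %d families, %d events",
                tree.n_tips, matrix.shape[0], len(log))
    return files


def stage_infer(cfg: RunConfig, outdir: Path) -> list[str]:
    tree = _load_tree(outdir)
    files = []
    if cfg.event_table:
        tally, report = ancestral.ingest_event_table(cfg.event_table, tree)
        report.insert(0, "node", report.index)
        io.write_tsv(report, outdir / "ingested_tally.tsv")
        io.write_tally(tally, outdir / "inferred_tally.tsv",
                       metadata={"source": f"ingested:{cfg.event_table}"})
        return ["ingested_tally.tsv", "inferred_tally.tsv"]
    matrix = io.read_presence_matrix(
        _require(outdir, "presence_matrix.tsv", "simulate"))
    filtered = ancestral.filter_families(matrix, cfg.min_members)
    states = ancestral.reconstruct_ancestral_states(
        tree, filtered, method="parsimony",
        gain_penalty=cfg.gain_penalty, loss_penalty=cfg.loss_penalty)
    tally, events = ancestral.extract_branch_events(states, tree)
    out_states = states.copy()
    out_states.insert(0, "node", out_states.index)
    io.write_tsv(out_states, outdir / "ancestral_states.tsv",
                 metadata={"method": "parsimony",
                           "gain_penalty": str(cfg.gain_penalty),
                           "loss_penalty": str(cfg.loss_penalty)})
    files.append("ancestral_states.tsv")
    io.write_tally(tally, outdir / "inferred_tally.tsv",
                   metadata={"source": "profile-approximated parsimony",
                             "note": "D indistinguishable from profiles"})
    files.append("inferred_tally.tsv")
    frame = pd.DataFrame(
        [(e.family, e.branch, e.type, e.donor or "") for e in events],
        columns=["family", "branch", "type", "donor"])
    io.write_tsv(frame, outdir / "inferred_events.tsv")
    files.append("inferred_events.tsv")
    logger.info("infer: %d/%d families kept, %d events",
                filtered.shape[0], matrix.shape[0], len(events))
    return files


def _load_pathways(outdir: Path) -> list:
    path = outdir / "pathways.tsv"
    if path.exists():
        return pathways.load_pathway_definitions(path)
    return pathways.default_pflag_definitions()


def stage_profile(cfg: RunConfig, outdir: Path) -> list[str]:
    tree = _load_tree(outdir)
    matrix = io.read_presence_matrix(
        _require(outdir, "presence_matrix.tsv", "simulate"))
    states_path = _require(outdir, "ancestral_states.tsv", "infer")
    states = pd.read_csv(states_path, sep="\t", comment="#",
                         index_col="node")
    pdefs = _load_pathways(outdir)
    report = pathways.ancestral_completeness_trajectory(
        states, tree, pdefs, mode=cfg.completeness_mode)
    io.write_tsv(report, outdir / "completeness.tsv",
                 metadata={"mode": cfg.completeness_mode})
    clades: dict[str, list[str]] = {}
    for tid in tree.tips:
        clades.setdefault(tree.node(tid).clade or "background", []).append(tid)
    pflag_sets = {p.category: p.genes for p in pdefs}
    occ = pathways.pflag_profile(matrix, clades, pflag_sets)
    io.write_tsv(occ, outdir / "occurrence.tsv")
    logger.info("profile: %d pathway categories, %d clades",
                len(pflag_sets), len(clades))
    return ["completeness.tsv", "occurrence.tsv"]


def stage_flux(cfg: RunConfig, outdir: Path) -> list[str]:
    tree = _load_tree(outdir)
    tally_path = _require(outdir, "inferred_tally.tsv", "infer")
    raw = pd.read_csv(tally_path, sep="\t", comment="#", index_col="node")
    tally = ancestral.BranchEventTally(raw)
    summary = flux.flux_summary(tally)
    io.write_tsv(summary.to_frame(), outdir / "flux_summary.tsv",
                 metadata={"total": str(summary.total)})
    gains = frozenset(cfg.gains_definition)
    ratios = flux.gain_loss_table(tally, gains, cfg.pseudocount)
    io.write_tsv(ratios, outdir / "gain_loss_ratio.tsv")
    hot = flux.hgt_hotspots(tally, cfg.top_k)
    io.write_tsv(hot, outdir / "hgt_hotspots.tsv")
    files = ["flux_summary.tsv", "gain_loss_ratio.tsv", "hgt_hotspots.tsv"]
    events_path = outdir / "inferred_events.tsv"
    if events_path.exists():
        table = pd.read_csv(events_path, sep="\t", comment="#",
                            keep_default_na=False)
        records = [
            (row["donor"], row["branch"], row["family"])
            for _, row in table.iterrows()
            if row["type"] == "T" and row["donor"]
        ]
        partners = flux.transfer_partner_summary(records, _clade_map(tree))
        partners.insert(0, "donor", partners.index)
        io.write_tsv(partners, outdir / "transfer_partners.tsv")
        files.append("transfer_partners.tsv")
    logger.info("flux: total %s events over %d nodes",
                summary.total, summary.n_nodes)
    return files


def stage_thermo(cfg: RunConfig, outdir: Path) -> list[str]:
    proteomes = io.read_fasta_proteomes(
        _require(outdir, "proteomes.faa", "simulate"))
    ogt_table = pd.read_csv(_require(outdir, "true_ogt.tsv", "simulate"),
                            sep="\t", comment="#")
    true_ogt = dict(zip(ogt_table["genome"], ogt_table["ogt"]))

    ivy = {g: thermo.ivywrel_fraction(seqs) for g, seqs in proteomes.items()}
    genomes = sorted(proteomes)
    coeffs = thermo.calibrate_ogt([ivy[g] for g in genomes],
                                  [true_ogt[g] for g in genomes])
    rows = []
    for g in genomes:
        m = thermo.thermo_metrics(g, proteomes[g], coefficients=coeffs)
        rows.append((g, m.ivywrel, m.cvp_bias, m.predicted_ogt,
                     m.residue_count))
    io.write_tsv(pd.DataFrame(
        rows, columns=["genome", "ivywrel", "cvp_bias", "predicted_ogt",
                       "residues"]),
        outdir / "thermo_metrics.tsv",
        metadata={"ogt_intercept": f"{coeffs[0]:.6g}",
                  "ogt_slope": f"{coeffs[1]:.6g}"})

    ann_dir = outdir / "annotations"
    stat_rows = []
    if ann_dir.exists():
        for path in sorted(ann_dir.glob("*.gff3")):
            ann = io.read_gff(path)
            st = thermo.genome_stats(ann)
            stat_rows.append((st.genome_id, st.total_length, st.gc,
                              st.coding_density, st.overlap_fraction,
                              st.gene_count, st.mean_gene_length))
    stats_frame = pd.DataFrame(
        stat_rows, columns=["genome", "length", "gc", "coding_density",
                            "overlap_fraction", "genes", "mean_gene_length"])
    io.write_tsv(stats_frame, outdir / "genome_stats.tsv")

    reg_rows = []
    if len(stats_frame) >= 3:
        fit = thermo.linear_fit(stats_frame["length"], stats_frame["genes"])
        reg_rows.append(("genes_vs_length", fit))
        merged = stats_frame.merge(
            pd.DataFrame({"genome": genomes,
                          "predicted_ogt": [
                              thermo.predict_ogt(ivy[g], coeffs)
                              for g in genomes]}),
            on="genome")
        if len(merged) >= 3:
            fit2 = thermo.linear_fit(merged["length"], merged["predicted_ogt"])
            reg_rows.append(("ogt_vs_length", fit2))
    fit3 = thermo.linear_fit([true_ogt[g] for g in genomes],
                             [ivy[g] for g in genomes])
    reg_rows.append(("ivywrel_vs_true_ogt", fit3))
    io.write_tsv(pd.DataFrame(
        [(name, f.slope, f.intercept, f.r_squared, f.adj_r_squared,
          f.p_value, f.n) for name, f in reg_rows],
        columns=["regression", "slope", "intercept", "r2", "adj_r2", "p",
                 "n"]),
        outdir / "regressions.tsv")
    logger.info("thermo: %d proteomes, %d annotations",
                len(genomes), len(stat_rows))
    return ["thermo_metrics.tsv", "genome_stats.tsv", "regressions.tsv"]


def stage_report(cfg: RunConfig, outdir: Path) -> list[str]:
    summary: dict = {}
    flux_path = outdir / "flux_summary.tsv"
    if flux_path.exists():
        table = pd.read_csv(flux_path, sep="\t", comment="#")
        summary["event_totals"] = {
            row["category"]: row["count"] for _, row in table.iterrows()}
        summary["event_total"] = float(table["count"].sum())
    hot_path = outdir / "hgt_hotspots.tsv"
    if hot_path.exists():
        hot = pd.read_csv(hot_path, sep="\t", comment="#")
        if len(hot):
            summary["top_hgt_hotspot"] = {
                "node": str(hot.iloc[0]["node"]), "T": float(hot.iloc[0]["T"])}
    reg_path = outdir / "regressions.tsv"
    if reg_path.exists():
        regs = pd.read_csv(reg_path, sep="\t", comment="#")
        summary["regressions"] = {
            row["regression"]: {"slope": row["slope"], "adj_r2": row["adj_r2"],
                                "p": row["p"]}
            for _, row in regs.iterrows()}
    comp_path = outdir / "completeness.tsv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path, sep="\t", comment="#")
        root_rows = comp[comp["node"] == comp["node"].iloc[0]]
        summary["root_completeness"] = {
            row["category"]: row["completeness"]
            for _, row in root_rows.iterrows()}
    (outdir / "report.json").write_text(json.dumps(summary, indent=2,
                                                   sort_keys=True))
    return ["report.json"]


STAGES = {
    "simulate": stage_simulate,
    "infer": stage_infer,
    "profile": stage_profile,
    "flux": stage_flux,
    "thermo": stage_thermo,
    "report": stage_report,
}
STAGE_ORDER = ("simulate", "infer", "profile", "flux", "thermo", "report")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config_hash=config.config_hash(),
        stages_run=[],
        started=_time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    # the run directory is implied by the file's location; leaving it out
    # keeps checksums identical across relocated but otherwise equal runs
    snapshot = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    io.write_config(snapshot, outdir / "config.yaml")
    all_files = ["config.yaml"]
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        logger.info("stage %s: start", stage)
        produced = STAGES[stage](config, outdir)
        all_files.extend(produced)
        manifest.stages_run.append(stage)
        logger.info("stage %s: done (%d files)", stage, len(produced))
    for name in all_files:
        manifest.files[name] = io.file_sha256(outdir / name)
    manifest.finished = _time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
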