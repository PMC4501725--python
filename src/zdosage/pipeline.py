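"""End-to-end orchestration: simulate or load inputs, assign chromosomes,
quantify ratio shifts per timepoint, sex individuals, build the homolog
tree, and write everything plus a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dosage, homology, io, phylo, sexing
from .errors import InvalidDesignError
from .simulate import (
    SimDesign,
    evolve_alignment,
    simulate_experiment,
    simulate_sexing_cohort,
)

log = logging.getLogger("zdosage")

__all__ = ["PipelineConfig", "PipelineResult", "run_full", "load_config"]


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from JSON."""

    seed: int = 0
    outdir: str = "zdosage_out"
    # either a simulation design...
    simulate: dict | None = None
    # ...or explicit input paths
    inputs: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=dict)
    evalue_threshold: float = 1e-9
    normalization: str = "median"
    pseudocount: float = 0.5
    min_abundance: float = 1.0
    n_permutations: int = 999
    alpha: float = 0.05
    sexing: dict = field(default_factory=lambda: {
        "efficiency": 1.0, "low": 0.7, "high": 0.85})
    bootstrap_replicates: int = 100
    domain_window: tuple[int, int] = (51, 122)

    def validate(self):
        if self.pseudocount <= 0:
            raise InvalidDesignError("pseudocount must be > 0")
        if not 0 < self.alpha < 1:
            raise InvalidDesignError("alpha must lie in (0, 1)")
        if self.evalue_threshold <= 0:
            raise InvalidDesignError("evalue_threshold must be > 0")
        if self.simulate is None and not self.inputs:
            raise InvalidDesignError(
                "config needs either a 'simulate' block or input paths")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = json.load(fh)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidDesignError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if isinstance(cfg.domain_window, list):
        cfg.domain_window = tuple(cfg.domain_window)
    cfg.validate()
    return cfg


@dataclass
class PipelineResult:
    assignments: pd.DataFrame
    ratios: dict[float, pd.DataFrame]
    summaries: dict[float, pd.DataFrame]
    z_shift: pd.DataFrame
    sex_calls: list[sexing.SexCall]
    brood_p: float
    tree: phylo.Tree
    manifest: dict


def _default_phylo_tree() -> phylo.Tree:
    """Fixed 6-taxon tree used when no alignment is supplied: two clades
    separated by a long internal branch."""
    newick = ("((tx1:0.05,tx2:0.05):0.3,(tx3:0.05,tx4:0.05):0.05,"
              "(tx5:0.1,tx6:0.1):0.05);")
    return phylo.read_newick(newick)


def run_full(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write outputs under ``config.outdir``.

    Reruns with the same config and seed are byte-identical (no
    timestamps are written).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed,
                      "config": _config_dict(config),
                      "outputs": {}}

    # ---- stage 0: inputs -------------------------------------------------
    if config.simulate is not None:
        design = SimDesign(**{**config.simulate, "seed": config.seed})
        counts_df, samples, ref = simulate_experiment(design)
        input_paths = io.write_reference(ref, outdir / "inputs")
        io.write_counts_tsv(outdir / "inputs" / "counts.tsv", counts_df)
        samples_out = samples.copy()
        samples_out["infected"] = samples_out["infected"].astype(int)
        io.write_tsv(outdir / "inputs" / "samples.tsv", samples_out)
        ct_table, _truth = simulate_sexing_cohort(
            n_individuals=60, male_fraction=0.5,
            efficiency=config.sexing.get("efficiency", 1.0),
            noise_sd=0.15, seed=config.seed + 17)
        io.write_tsv(outdir / "inputs" / "ct_table.tsv", ct_table)
        msa = evolve_alignment(_default_phylo_tree(), seq_length=240,
                               seed=config.seed + 29)
        io.write_fasta(outdir / "inputs" / "alignment.fasta",
                       list(zip(msa.taxa, msa.rows)))
        genes = ref.genes
        contigs = ref.contigs
        input_paths.update({
            "counts": str(outdir / "inputs" / "counts.tsv"),
            "samples": str(outdir / "inputs" / "samples.tsv"),
            "ct_table": str(outdir / "inputs" / "ct_table.tsv"),
            "alignment": str(outdir / "inputs" / "alignment.fasta"),
        })
        manifest["inputs"] = input_paths
        counts = dosage.CountTable(counts_df, samples)
        log.info("simulate: %d genes, %d contigs, %d samples",
                 len(genes), len(contigs), counts_df.shape[1])
    else:
        genes = io.read_reference(config.inputs["reference_proteins"],
                                  config.inputs["gene_table"])
        contigs = io.read_fasta(config.inputs["contigs"])
        counts_df = io.read_counts_tsv(config.inputs["counts"])
        samples = io.read_tsv(config.inputs["samples"],
                              required=["sample_id", "hpo", "infected"])
        samples = samples.set_index("sample_id", drop=False)
        samples["infected"] = samples["infected"].astype(bool)
        ct_table = io.read_tsv(config.inputs["ct_table"],
                               required=["individual_id", "gene", "ct"])
        msa = io.read_alignment_fasta(config.inputs["alignment"])
        manifest["inputs"] = dict(config.inputs)
        counts = dosage.CountTable(counts_df, samples)
        log.info("load: %d genes, %d contigs, %d samples",
                 len(genes), len(contigs), counts_df.shape[1])

    # ---- stage 1: chromosome assignment ----------------------------------
    scoring = homology.Scoring(**config.scoring)
    assignments = homology.assign_chromosomes(
        contigs, genes, scoring, config.evalue_threshold)
    io.write_tsv(outdir / "assignments.tsv", assignments)
    manifest["outputs"]["assignments"] = str(outdir / "assignments.tsv")
    n_assigned = int((assignments["chromosome"] != "unassigned").sum())
    log.info("assign: %d/%d contigs assigned", n_assigned, len(assignments))

    # ---- stage 2: dosage analysis per timepoint --------------------------
    chrom = assignments["chromosome"]
    chrom = chrom[chrom != "unassigned"]
    autosomal = list(chrom.index[chrom != "Z"])
    norm = dosage.normalize(counts, method=config.normalization,
                            reference_contigs=autosomal or None)
    ratios: dict[float, pd.DataFrame] = {}
    summaries: dict[float, pd.DataFrame] = {}
    shift_rows = []
    for hpo in sorted(counts.samples["hpo"].unique()):
        inf_ids = counts.sample_ids(True, hpo)
        ctl_ids = counts.sample_ids(False, hpo)
        if not inf_ids or not ctl_ids:
            log.warning("dosage: skipping %s hpo (missing group)", hpo)
            continue
        rt = dosage.compute_ratios(norm, chrom, inf_ids, ctl_ids,
                                   config.pseudocount, config.min_abundance)
        rt = rt[rt["chromosome"] != "unassigned"]
        ratios[hpo] = rt
        summaries[hpo] = dosage.summarize_by_chromosome(rt)
        zs = dosage.z_shift_test(rt, config.n_permutations,
                                 seed=config.seed + int(hpo))
        shift_rows.append({"hpo": hpo, "observed_shift": zs.observed_shift,
                           "p_value": zs.p_value, "n_z": zs.n_z,
                           "n_autosomal": zs.n_autosomal})
        io.write_tsv(outdir / f"ratios_{hpo:g}hpo.tsv", rt)
        io.write_tsv(outdir / f"summary_{hpo:g}hpo.tsv", summaries[hpo])
        manifest["outputs"][f"ratios_{hpo:g}hpo"] = \
            str(outdir / f"ratios_{hpo:g}hpo.tsv")
        manifest["outputs"][f"summary_{hpo:g}hpo"] = \
            str(outdir / f"summary_{hpo:g}hpo.tsv")
        log.info("dosage: %g hpo shift=%.3f p=%.4g",
                 hpo, zs.observed_shift, zs.p_value)
    z_shift = pd.DataFrame(shift_rows)
    if len(z_shift) > 0:
        z_shift["p_adjusted"] = dosage.bh_adjust(z_shift["p_value"])
        z_shift["significant"] = (z_shift["p_adjusted"]
                                  <= config.alpha).astype(int)
    io.write_tsv(outdir / "z_shift_tests.tsv", z_shift)
    manifest["outputs"]["z_shift_tests"] = str(outdir / "z_shift_tests.tsv")

    # ---- stage 3: molecular sexing ---------------------------------------
    calls = sexing.call_sex_table(
        ct_table,
        efficiency=config.sexing.get("efficiency", 1.0),
        low=config.sexing.get("low", 0.7),
        high=config.sexing.get("high", 0.85))
    calls_df = pd.DataFrame(
        [{"individual_id": c.individual_id,
          **{f"dose_{g}": d for g, d in sorted(c.doses.items())},
          "call": c.call} for c in calls])
    io.write_tsv(outdir / "sex_calls.tsv", calls_df)
    manifest["outputs"]["sex_calls"] = str(outdir / "sex_calls.tsv")
    n_f = sum(1 for c in calls if c.call == "female")
    n_m = sum(1 for c in calls if c.call == "male")
    brood_p = sexing.brood_test(n_f, n_m) if (n_f + n_m) else float("nan")
    log.info("sexing: %d female / %d male / %d ambiguous (brood p=%.3g)",
             n_f, n_m, len(calls) - n_f - n_m, brood_p)

    # ---- stage 4: phylogeny ----------------------------------------------
    start, end = config.domain_window
    if msa.n_columns >= end:
        msa = phylo.MsaBlock(
            msa.taxa,
            [phylo.extract_domain(r, start, end) for r in msa.rows])
    tree = phylo.bootstrap(msa, n_replicates=config.bootstrap_replicates,
                           seed=config.seed + 43)
    newick = phylo.write_newick(tree)
    (outdir / "tree.nwk").write_text(newick + "\n")
    manifest["outputs"]["tree"] = str(outdir / "tree.nwk")
    log.info("phylo: %d taxa, %d bootstrap replicates",
             len(tree.leaf_names()), config.bootstrap_replicates)

    manifest["sexing_counts"] = {"female": n_f, "male": n_m,
                                 "ambiguous": len(calls) - n_f - n_m,
                                 "brood_p": brood_p}
    io.write_manifest(outdir / "manifest.json", manifest)
    return PipelineResult(assignments, ratios, summaries, z_shift,
                          calls, brood_p, tree, manifest)


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["domain_window"] = list(config.domain_window)
    return d
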