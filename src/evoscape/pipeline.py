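"""End-to-end orchestration: rates -> disorder -> PTM -> variants ->
profiles -> expression, from one config, with a consolidated summary.

Every output is a pure function of (inputs, config): no timestamps or other
run-dependent state are written, and each output file carries the config
hash, so re-running the same config yields byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import formats_io, structure_disorder, ptm_conservation
from . import variant_annotation, phyloprofiling, expression_specificity
from . import site_rates as sr

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("evoscape")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the outputs written so far."""

    def __init__(self, stage: str, cause: Exception, manifest: list[str]):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.manifest = manifest


@dataclass
class PipelineConfig:
    # inputs
    alignment: str = "alignment.fasta"
    tree: str = "tree.nwk"
    disorder: str = "disorder.tsv"
    phospho: str = "phospho.tsv"
    variants: str = "variants.tsv"
    domains: str = "domains.tsv"
    orthologs: str = "orthologs.tsv"
    taxonomy: str = "taxonomy.tsv"
    expression: str = "expression.tsv"
    # parameters
    reference_id: str = "human"
    model: str = "jtt"               # jtt | jtt+f
    K: int = 16
    alpha: str | float = "auto"
    disorder_cutoff: float = 0.5
    consensus_majority: float = 0.5
    disorder_consensus: str = "consensus"   # consensus | reference_only
    ptm_cutoff: float = 0.75
    ptm_majority: float = 0.5
    ptm_denominator: str = "all"
    pathogenic_labels: list[str] = field(default_factory=lambda: ["pathogenic"])
    k_clusters: int = 4
    sw_score_threshold: float = 150.0
    ward_variant: str = "ward"
    specificity_factor: float = 1.65
    # output
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        """Hash of the analysis-relevant configuration (outdir excluded)."""
        d = asdict(self)
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stage(name: str, manifest: list[str]):
    """Decorator-free stage wrapper: run fn, convert failure to stage error."""
    class _Ctx:
        def __enter__(self):
            log.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineStageError(name, exc, list(manifest)) from exc
    return _Ctx()


def run_pipeline(config: PipelineConfig, indir: str | Path = ".") -> dict:
    """Run every stage; writes tables under ``config.outdir``; returns the
    summary dict (also written as summary.json)."""
    indir = Path(indir)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    manifest: list[str] = []
    summary: dict = {"config_hash": chash}
    warnings_log: list[str] = []

    def emit(name: str) -> Path:
        manifest.append(name)
        return out / name

    # -- site_rates ----------------------------------------------------------
    with _stage("site_rates", manifest):
        aln = formats_io.read_alignment(indir / config.alignment, config.reference_id)
        tree = formats_io.read_newick(indir / config.tree)
        model = sr.jtt_model(aln, plus_f=(config.model == "jtt+f"))
        if config.alpha == "auto":
            alpha = sr.estimate_alpha(aln, tree, model, K=config.K)
        else:
            alpha = float(config.alpha)
        gamma = sr.GammaCategories.discretize(alpha, config.K)
        result = sr.posterior_mean_rates(aln, tree, model, gamma)
        cmap = formats_io.build_column_map(aln)
        rate_table = sr.project_rates(result, cmap)
        sr.write_rates(rate_table, emit("rates.tsv"),
                       model=model.name, K=config.K, alpha=alpha)
        summary["site_rates"] = {
            "alpha": alpha,
            "log_likelihood": result.log_likelihood,
            "n_no_data_columns": int(result.no_data.sum()),
        }

    # -- structure_disorder --------------------------------------------------
    with _stage("structure_disorder", manifest):
        tracks = formats_io.read_track(indir / config.disorder, aln, kind="disorder")
        dmat = structure_disorder.build_disorder_matrix(aln, tracks, tree)
        dmat.to_frame().to_csv(emit("disorder_matrix.tsv"), sep="\t",
                               float_format="%.6g")
        structure: dict[int, str] = {}
        ref_track = tracks[config.reference_id]
        for pos, col in cmap.residue_to_column.items():
            if config.disorder_consensus == "reference_only":
                structure[pos] = ("disordered"
                                  if ref_track.scores[pos - 1] >= config.disorder_cutoff
                                  else "ordered")
            else:
                structure[pos] = structure_disorder.consensus_structure(
                    dmat, col, cutoff=config.disorder_cutoff,
                    majority=config.consensus_majority)
        z = {pos: rate_table.loc[rate_table["pos"] == pos, "z"].iloc[0]
             for pos in structure}
        classification = structure_disorder.classify_residues(structure, z)
        classification.table.to_csv(emit("classification.tsv"), sep="\t",
                                    index=False, float_format="%.6g")
        tab = classification.table
        comp = structure_disorder.compare_rate_distributions(
            tab["z"].to_numpy(), tab["structure"].to_numpy())
        summary["order_disorder"] = comp

    # -- ptm_conservation ----------------------------------------------------
    with _stage("ptm_conservation", manifest):
        ptracks = formats_io.read_track(indir / config.phospho, aln, kind="phospho")
        callset = ptm_conservation.conserved_columns(
            aln, ptracks, cutoff=config.ptm_cutoff,
            majority=config.ptm_majority, denominator=config.ptm_denominator)
        callset.table.to_csv(emit("ptm.tsv"), sep="\t", index=False,
                             float_format="%.6g")
        summary["ptm"] = {
            "n_reference_sites": int(len(callset.calls[config.reference_id])),
            "n_conserved_reference_sites": len(callset.conserved_ref_positions),
        }

    # -- variant_annotation --------------------------------------------------
    with _stage("variant_annotation", manifest):
        domains = variant_annotation.read_domains(indir / config.domains)
        report = formats_io.read_variants(
            indir / config.variants, aln,
            allowed_labels=set(config.pathogenic_labels))
        warnings_log.extend(report.rejected)
        contexts = variant_annotation.annotate_variants(
            report.records, domains, classification,
            callset.conserved_ref_positions)
        rows = [{
            "protein": c.variant.protein, "pos": c.variant.position,
            "ref": c.variant.ref_aa, "alt": c.variant.alt_aa,
            "n_cases": c.variant.n_cases, "in_domain": c.in_domain or "none",
            "structure": c.structure, "evolution": c.evolution,
            "category": c.structure_category, "z": c.z,
            "dist_to_ptm": (c.distance_to_nearest_conserved_ptm
                            if c.distance_to_nearest_conserved_ptm is not None
                            else "NA"),
        } for c in contexts]
        import pandas as pd

        pd.DataFrame(rows).to_csv(emit("variant_context.tsv"), sep="\t",
                                  index=False, float_format="%.6g")
        dist = variant_annotation.summarize_distribution(contexts)
        dist.to_csv(emit("variant_summary.tsv"), sep="\t", index=False)
        summary["variants"] = {
            "n_records": len(report.records),
            "n_rejected": len(report.rejected),
            "n_cases_total": int(sum(c.variant.n_cases for c in contexts)),
        }

    # -- phyloprofiling ------------------------------------------------------
    with _stage("phyloprofiling", manifest):
        groups = phyloprofiling.read_taxonomy_groups(indir / config.taxonomy)
        table = phyloprofiling.read_profile_table(indir / config.orthologs)
        profile = phyloprofiling.build_profile(
            table, score_threshold=config.sw_score_threshold,
            taxonomy_groups=groups)
        cluster = phyloprofiling.ward_cluster(
            profile, k=config.k_clusters, variant=config.ward_variant)
        phyloprofiling.assign_class_labels(cluster, profile)
        with open(emit("clusters.tsv"), "w") as fh:
            fh.write(f"# evoscape config={chash}\n")
            fh.write("protein\tcluster\tclass\n")
            for p, c in zip(profile.proteins, cluster.assignments):
                fh.write(f"{p}\t{c}\t{cluster.class_labels[int(c)]}\n")
        (out / "dendrogram.nwk").write_text(
            phyloprofiling.linkage_to_newick(cluster.linkage, profile.proteins)
            + "\n")
        manifest.append("dendrogram.nwk")
        sizes = {f"cluster{c}": int((cluster.assignments == c).sum())
                 for c in sorted(set(cluster.assignments.tolist()))}
        summary["profiles"] = {
            "class_sizes": sizes,
            "class_labels": {str(k): v for k, v in cluster.class_labels.items()},
            "all_zero_proteins": profile.all_zero_proteins,
        }

    # -- expression_specificity ----------------------------------------------
    with _stage("expression_specificity", manifest):
        expr = expression_specificity.read_expression(indir / config.expression)
        calls = expression_specificity.specificity_calls(
            expr, factor=config.specificity_factor)
        expression_specificity.write_calls(calls, emit("specificity.tsv"))
        flagged = [c for c in calls if c.flag]
        per_tissue: dict[str, int] = {}
        for c in flagged:
            per_tissue[c.tissue] = per_tissue.get(c.tissue, 0) + 1
        summary["expression"] = {
            "n_flagged": len(flagged),
            "flags_per_tissue": dict(sorted(per_tissue.items())),
        }

    summary["warnings"] = warnings_log
    summary["manifest"] = manifest + ["summary.json"]
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
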