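"""Pipeline orchestration: run the study's workflows from one YAML config.

A config names the stages to run (synthetic-panel simulation, SNP
filtering, PCA, the F_ST outlier scan, depth simulation, CNV profiling,
contig simulation and the LTR census) plus a single global seed.  Stages
run in dependency order inside a run directory; a manifest JSON records
the config hash, the per-stage seeds and the SHA-256 of every output, so
an identical rerun is byte-identical and verifiable.

The global seed is expanded into per-stage seeds by a fixed counter
scheme — ``stage_seed = (seed * 10007 + stage_index) % 2**31`` with the
stage index taken from the canonical stage order — so any stage can be
reproduced on its own.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rangexpand import cnv as cnv_mod
from rangexpand import fst as fst_mod
from rangexpand import ltr as ltr_mod
from rangexpand import pca as pca_mod
from rangexpand import synthetic
from rangexpand.filtering import FilterConfig, apply_preset
from rangexpand.genotypes import read_vcf_genotypes, write_vcf

__all__ = ["PipelineConfigError", "run_pipeline", "demo_config", "stage_seed"]

STAGE_ORDER = (
    "simulate_panel",
    "filter",
    "pca",
    "fst",
    "simulate_depth",
    "cnv",
    "simulate_contigs",
    "ltr",
)


class PipelineConfigError(ValueError):
    """Config fails validation; the message names the offending field."""


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 10007 + STAGE_ORDER.index(stage)) % 2**31


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(block: dict, stage: str, field: str):
    if field not in block:
        raise PipelineConfigError(f"stage {stage!r}: missing required field {field!r}")
    return block[field]


def validate_config(config: dict) -> None:
    if "seed" not in config:
        raise PipelineConfigError("missing required field 'seed'")
    stages = config.get("stages")
    if not isinstance(stages, dict) or not stages:
        raise PipelineConfigError("missing required field 'stages'")
    for name in stages:
        if name not in STAGE_ORDER:
            raise PipelineConfigError(f"unknown stage {name!r}")
    has_panel = "simulate_panel" in stages
    for dep in ("filter", "pca", "fst"):
        if dep in stages and not has_panel and "vcf" not in stages[dep]:
            raise PipelineConfigError(f"stage {dep!r}: missing required field 'vcf'")
    if "fst" in stages and not has_panel and "pops" not in stages["fst"]:
        raise PipelineConfigError("stage 'fst': missing required field 'pops'")
    if "cnv" in stages and "simulate_depth" not in stages and "depth" not in stages["cnv"]:
        raise PipelineConfigError("stage 'cnv': missing required field 'depth'")
    for stage, block in stages.items():
        for key in ("vcf", "pops", "depth", "hits"):
            if key in (block or {}) and not Path(block[key]).exists():
                raise PipelineConfigError(
                    f"stage {stage!r}: input file {block[key]!r} does not exist"
                )


def run_pipeline(config: dict, outdir: str) -> dict:
    """Run the configured stages; returns (and writes) the manifest."""
    validate_config(config)
    seed = int(config["seed"])
    stages: dict = config["stages"]
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    seeds_used: dict[str, int] = {}

    G = truth = pops = None
    depth = None
    cn_truth = None

    def record(name: str, path: Path):
        outputs[name] = _sha256(path)

    if "simulate_panel" in stages:
        blk = dict(stages["simulate_panel"] or {})
        s = stage_seed(seed, "simulate_panel")
        seeds_used["simulate_panel"] = s
        n_outliers = blk.pop("n_outliers", 0)
        delta = blk.pop("delta", 0.0)
        cfg = synthetic.SimPanelConfig(seed=s, **blk)
        G, truth = synthetic.simulate_genotype_panel(cfg)
        if n_outliers:
            G, truth = synthetic.plant_outlier_snps(G, truth, n_outliers, delta, seed=s + 1)
        write_vcf(G, out / "panel.vcf")
        pops = pd.Series(truth.pop_labels, index=G.sample_ids, name="population")
        pops.rename_axis("sample").to_csv(out / "pops.tsv", sep="\t")
        record("panel.vcf", out / "panel.vcf")
        record("pops.tsv", out / "pops.tsv")

    if "filter" in stages:
        blk = stages["filter"] or {}
        if G is None:
            G = read_vcf_genotypes(blk["vcf"])
        preset = blk.get("preset", "structure")
        G_f, log = apply_preset(G, preset, FilterConfig(**blk.get("thresholds", {})))
        write_vcf(G_f, out / "filtered.vcf")
        pd.DataFrame(log, columns=["stage", "snps_in", "snps_out"]).to_csv(
            out / "filter_log.tsv", sep="\t", index=False
        )
        record("filtered.vcf", out / "filtered.vcf")
        record("filter_log.tsv", out / "filter_log.tsv")
        G_for_pca = G_f
    else:
        G_for_pca = G

    if "pca" in stages:
        blk = stages["pca"] or {}
        Gp = G_for_pca if G_for_pca is not None else read_vcf_genotypes(blk["vcf"])
        model = pca_mod.fit_pca(Gp, n_components=blk.get("n_components", 5))
        pd.DataFrame(
            model.scores,
            index=model.sample_ids,
            columns=[f"PC{i+1}" for i in range(model.n_components)],
        ).rename_axis("sample").to_csv(out / "pca_scores.tsv", sep="\t")
        pd.DataFrame(
            model.loadings,
            columns=[f"PC{i+1}" for i in range(model.n_components)],
        ).assign(chrom=model.snps["chrom"].values, pos=model.snps["pos"].values).to_csv(
            out / "pca_loadings.tsv", sep="\t", index=False
        )
        record("pca_scores.tsv", out / "pca_scores.tsv")
        record("pca_loadings.tsv", out / "pca_loadings.tsv")

    if "fst" in stages:
        blk = stages["fst"] or {}
        s = stage_seed(seed, "fst")
        seeds_used["fst"] = s
        Gf = G if G is not None else read_vcf_genotypes(blk["vcf"])
        if pops is None:
            pops = pd.read_csv(blk["pops"], sep="\t", index_col=0).iloc[:, 0]
        Gr = fst_mod.remove_rare(Gf, blk.get("rare_threshold", 0.10))
        scan = fst_mod.outlier_scan(
            Gr, pops, n_perm=blk.get("n_perm", 999), fdr=blk.get("fdr", 0.01), seed=s
        )
        fst_mod.scan_table(Gr, scan).to_csv(out / "fst_scan.tsv", sep="\t", index=False)
        overall = fst_mod.weir_cockerham(Gr, pops).overall_theta
        summary = {
            "overall_theta": overall,
            "n_snps_tested": int(scan.theta[~np.isnan(scan.p_value)].size),
            "n_candidates": int(len(scan.candidates)),
            "fdr": scan.fdr,
            "n_permutations": scan.n_permutations,
            "seed": s,
        }
        (out / "fst_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        record("fst_scan.tsv", out / "fst_scan.tsv")
        record("fst_summary.json", out / "fst_summary.json")

    if "simulate_depth" in stages:
        blk = dict(stages["simulate_depth"] or {})
        s = stage_seed(seed, "simulate_depth")
        seeds_used["simulate_depth"] = s
        n_samples = blk.get("n_samples", 10)
        n_orfs = blk.get("n_orfs", 200)
        rng = np.random.default_rng(s)
        samples = [f"s{i+1:03d}" for i in range(n_samples)]
        orfs = [f"ORF{i+1:04d}" for i in range(n_orfs)]
        cn_truth = pd.DataFrame(
            rng.choice([0, 1, 1, 1, 2], size=(n_samples, n_orfs)).astype(float),
            index=samples, columns=orfs,
        )
        cfg = synthetic.DepthSimConfig(
            cn_truth=cn_truth,
            mean_depth=blk.get("mean_depth", 50.0),
            dispersion=blk.get("dispersion", 10.0),
            seed=s,
        )
        depth = synthetic.simulate_depth_table(cfg)
        depth.rename_axis("orf").to_csv(out / "depth.tsv", sep="\t")
        record("depth.tsv", out / "depth.tsv")

    if "cnv" in stages:
        blk = stages["cnv"] or {}
        D = depth if depth is not None else pd.read_csv(blk["depth"], sep="\t", index_col=0)
        cn = cnv_mod.compute_copy_number(D)
        cn.rename_axis("orf").to_csv(out / "copy_number.tsv", sep="\t")
        record("copy_number.tsv", out / "copy_number.tsv")
        pop_map = blk.get("pop_map")
        if pop_map is None and pops is not None:
            pop_map = pops[pops.index.isin(cn.columns)]
        if pop_map is not None and len(pd.Series(pop_map).unique()) >= 2:
            med = cnv_mod.population_median_cn(cn, pop_map)
            pops_sorted = sorted(pd.Series(pop_map).unique())
            rep = cnv_mod.enrichment_scan(
                med,
                focal=blk.get("focal", pops_sorted[0]),
                other=blk.get("other", pops_sorted[1]),
                factor=blk.get("factor", 2.0),
                presence_threshold=blk.get("presence", 0.5),
            )
            rep.enriched.rename_axis("orf").to_csv(out / "enriched.tsv", sep="\t")
            record("enriched.tsv", out / "enriched.tsv")
        if blk.get("plasmid_orfs"):
            ps = cnv_mod.plasmid_status(cn, blk["plasmid_orfs"], blk.get("presence", 0.5))
            ps.rename_axis("sample").to_csv(out / "plasmid.tsv", sep="\t")
            record("plasmid.tsv", out / "plasmid.tsv")

    contigs = hits = None
    if "simulate_contigs" in stages:
        s = stage_seed(seed, "simulate_contigs")
        seeds_used["simulate_contigs"] = s
        contigs, hits, truth_ltr = synthetic.simulate_strain_contigs(seed=s)
        contig_dir = out / "contigs"
        contig_dir.mkdir(exist_ok=True)
        for strain, ctgs in contigs.items():
            ltr_mod.write_contigs_fasta(ctgs, contig_dir / f"{strain}.fasta")
            record(f"contigs/{strain}.fasta", contig_dir / f"{strain}.fasta")
        ltr_mod.write_bed(hits, out / "ltr_hits.bed")
        record("ltr_hits.bed", out / "ltr_hits.bed")
        pd.DataFrame([vars(t) for t in truth_ltr]).to_csv(
            out / "ltr_truth.tsv", sep="\t", index=False
        )
        record("ltr_truth.tsv", out / "ltr_truth.tsv")

    if "ltr" in stages:
        blk = stages["ltr"] or {}
        if contigs is None:
            raise PipelineConfigError(
                "stage 'ltr': needs simulate_contigs or explicit contig inputs"
            )
        census = ltr_mod.run_census(
            contigs, hits, reference_panel_ids=blk.get("reference_panel", [])
        )
        rows = [
            {
                "strain": r.hit.strain, "contig": r.hit.contig,
                "start": r.hit.start, "end": r.hit.end, "family": r.hit.family,
                "tsd_up": r.tsd.upstream, "tsd_down": r.tsd.downstream,
                "context": r.context, "status": r.population_status,
                "shared_strains": ",".join(r.shared_strains),
            }
            for r in census.catalogue
        ]
        pd.DataFrame(rows).to_csv(out / "ltr_catalogue.tsv", sep="\t", index=False)
        (out / "ltr_census.json").write_text(json.dumps(census.summary, indent=2) + "\n")
        ltr_mod.export_fasta(census.catalogue, out / "ltr_catalogue.fasta")
        for name in ("ltr_catalogue.tsv", "ltr_census.json", "ltr_catalogue.fasta"):
            record(name, out / name)

    manifest = {
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "stage_seeds": seeds_used,
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def demo_config(seed: int = 1) -> dict:
    """Small end-to-end demo configuration (runs in seconds)."""
    return {
        "seed": seed,
        "stages": {
            "simulate_panel": {
                "n_pops": 2, "pop_sizes": [20, 20], "fst": [0.05, 0.05],
                "n_snps": 400, "n_outliers": 4, "delta": 0.8,
            },
            "filter": {"preset": "structure"},
            "pca": {"n_components": 4},
            "fst": {"n_perm": 199, "fdr": 0.01},
            "simulate_depth": {"n_samples": 8, "n_orfs": 150},
            "cnv": {},
            "simulate_contigs": {},
            "ltr": {},
        },
    }
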