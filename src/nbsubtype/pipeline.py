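"""End-to-end orchestration: discover -> classify -> geneset -> verify ->
project -> associate, with a reproducible run manifest.

A run consumes at least two discovery datasets and one verification dataset
(either user-supplied TSV paths or a synthetic study generated on the fly),
writes every stage's outputs as TSV under the output directory, and records
a JSON manifest (config snapshot, seed, input digests, per-stage outputs)
whose bytes are identical across reruns with the same config and seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (AnalysisConfig, align_common_genes, read_clinical,
                   read_expression, write_clinical, write_expression)
from .clinstats import (cluster_factor_enrichment, five_year_fisher,
                        genomic_subtypes, crosstab, km_by_cluster,
                        logrank_by_cluster, pearson, survival_at)
from .geneset import combine_z, overlap_and_rank, select_dataset_top
from .hierarchy import cut_k, gene_clusters, hcluster, rescue_by_pca_nn
from .pca import discover_subgroups, fit_pca, loo_stability
from .preprocess import filter_low_expression, standardize_genes
from .projection import fit_loadings, project
from .signature import classify_cohort, default_rules
from .simulate import CohortSpec, generate_datasets

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Inputs for a full run.

    Either ``synthetic`` (a :class:`CohortSpec`; its ``n_samples`` tuple
    decides the number of datasets, the last being the verification cohort)
    or ``dataset_paths`` (list of {"expression": ..., "clinical": ...}
    dicts, last entry = verification) must be given.
    """

    seed: int = 0
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    synthetic: CohortSpec | None = None
    dataset_paths: list[dict] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        seed = int(doc.get("seed", 0))
        analysis = AnalysisConfig.from_dict(doc.get("analysis", {}))
        synthetic = None
        if "synthetic" in doc:
            kwargs = dict(doc["synthetic"])
            if isinstance(kwargs.get("n_samples"), list):
                kwargs["n_samples"] = tuple(kwargs["n_samples"])
            kwargs.setdefault("seed", seed)
            synthetic = CohortSpec(**kwargs)
        return cls(seed=seed, analysis=analysis, synthetic=synthetic,
                   dataset_paths=doc.get("datasets"))

    def snapshot(self) -> dict:
        snap = {"seed": self.seed, "analysis": self.analysis.to_dict()}
        if self.synthetic is not None:
            d = dataclasses.asdict(self.synthetic)
            d["signature_effects"] = self.synthetic.effects().to_numpy().tolist()
            snap["synthetic"] = d
        if self.dataset_paths is not None:
            snap["datasets"] = [dict(p) for p in self.dataset_paths]
        return snap


@dataclass
class RunManifest:
    """Reproducibility record of one run (paths relative to the out dir)."""

    version: str
    seed: int
    config: dict
    inputs: dict
    stages: list

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def default_synthetic_config(seed: int = 0) -> PipelineConfig:
    """Three-dataset synthetic study: two discovery cohorts plus a larger
    verification cohort, all at the generator's default effect sizes."""
    return PipelineConfig(
        seed=seed,
        synthetic=CohortSpec(n_samples=(40, 60, 100), seed=seed))


def run_all(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute the full chain; outputs land under ``outdir``.

    Raises :class:`PipelineError` naming the failing stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.analysis
    stages: list[dict] = []
    inputs: dict[str, str] = {}

    def record(stage: str, outputs: list[Path], **counts) -> None:
        log.info("stage %s: %s", stage,
                 " ".join(f"{k}={v}" for k, v in counts.items()))
        stages.append({"name": stage,
                       "outputs": sorted(str(p.relative_to(outdir)) for p in outputs),
                       "counts": counts})

    # ---- inputs -----------------------------------------------------------
    try:
        if config.synthetic is not None:
            n_ds = len(config.synthetic.sizes(
                len(config.synthetic.n_samples)
                if isinstance(config.synthetic.n_samples, tuple) else 1))
            if n_ds < 3:
                raise ValueError(
                    "synthetic study needs 3 datasets (2 discovery + 1 verification)")
            datasets = generate_datasets(config.synthetic, n_ds)
        else:
            if not config.dataset_paths or len(config.dataset_paths) < 3:
                raise ValueError(
                    "need >= 2 discovery datasets and 1 verification dataset")
            datasets = []
            for i, paths in enumerate(config.dataset_paths):
                em = read_expression(paths["expression"])
                cl = read_clinical(paths["clinical"])
                datasets.append((em, cl, None))
        names = [f"ds{i + 1}" for i in range(len(datasets))]
        in_paths = []
        for name, (em, cl, truth) in zip(names, datasets):
            ep, cp = outdir / f"{name}_expression.tsv", outdir / f"{name}_clinical.tsv"
            write_expression(em, ep)
            write_clinical(cl, cp)
            in_paths += [ep, cp]
            if truth is not None:
                tp = outdir / f"{name}_truth.tsv"
                truth.to_tsv(tp)
                in_paths.append(tp)
        inputs = {str(p.relative_to(outdir)): _sha256(p) for p in in_paths}
        record("inputs", in_paths, datasets=len(datasets),
               samples=sum(em.n_samples for em, _, _ in datasets))
    except Exception as exc:
        raise PipelineError(f"stage inputs failed: {exc}") from exc

    discovery = datasets[:-1]
    verification = datasets[-1]

    # ---- preprocess -------------------------------------------------------
    try:
        filtered = []
        outs = []
        for name, (em, cl, truth) in zip(names, datasets):
            fm = filter_low_expression(em, cfg.expression_floor)
            filtered.append((fm, cl, truth))
            p = outdir / f"{name}_filtered.tsv"
            write_expression(fm, p)
            outs.append(p)
        record("preprocess", outs,
               genes_in=sum(em.n_genes for em, _, _ in datasets),
               genes_out=sum(fm.n_genes for fm, _, _ in filtered))
    except Exception as exc:
        raise PipelineError(f"stage preprocess failed: {exc}") from exc

    # ---- discover ---------------------------------------------------------
    try:
        outs = []
        p_assignments = []
        for name, (fm, _cl, _t) in zip(names[:-1], filtered[:-1]):
            assign, _pca = discover_subgroups(fm, cfg)
            p_assignments.append(assign)
            p = outdir / f"{name}_pca_assignments.tsv"
            assign.to_tsv(p)
            outs.append(p)
            if cfg.loo_enabled:
                rep = loo_stability(fm, cfg)
                sp = outdir / f"{name}_stability.tsv"
                rep.shift_fraction.rename("shift_fraction").to_csv(
                    sp, sep="\t", index_label="sample_id")
                outs.append(sp)
        record("discover", outs,
               clusters=sum(a.k for a in p_assignments))
    except Exception as exc:
        raise PipelineError(f"stage discover failed: {exc}") from exc

    # ---- classify (integrate discovery cohorts on the 6-gene rules) -------
    try:
        rules = default_rules(cfg.signature.threshold_sd, cfg.signature.min_agree)
        outs = []
        r_assignments = []
        for name, (fm, _cl, _t) in zip(names[:-1], filtered[:-1]):
            assign = classify_cohort(fm, rules)
            r_assignments.append(assign)
            p = outdir / f"{name}_r_assignments.tsv"
            assign.to_tsv(p)
            outs.append(p)
        record("classify", outs,
               assigned=sum(len(a.assigned()) for a in r_assignments),
               nd=sum(a.n_unassigned for a in r_assignments))
    except Exception as exc:
        raise PipelineError(f"stage classify failed: {exc}") from exc

    # ---- geneset ----------------------------------------------------------
    try:
        per_ds_stats, per_ds_lists, sizes = [], [], []
        from .geneset import CONTRASTS, permutation_pvalues
        for i, (name, (fm, _cl, _t), assign) in enumerate(
                zip(names[:-1], filtered[:-1], r_assignments)):
            stats = {}
            for c in CONTRASTS:
                try:
                    stats[c] = permutation_pvalues(
                        fm, assign, c, n_perm=cfg.sam.n_permutations,
                        seed=cfg.sam.seed + config.seed + 101 * i + c)
                except ValueError as exc:
                    log.warning("%s contrast %d skipped: %s", name, c, exc)
            lists = {c: select_dataset_top(df, cfg.sam.top_n_significant,
                                           cfg.sam.fc_log2_threshold)
                     for c, df in stats.items()}
            per_ds_stats.append(stats)
            per_ds_lists.append(lists)
            sizes.append(len(assign.assigned()))
        geneset = overlap_and_rank(per_ds_lists, per_ds_stats,
                                   cfg.sam.top_n_per_contrast)
        outs = []
        for c, genes in geneset.per_contrast.items():
            rows = {}
            with_c = [stats for stats in per_ds_stats if c in stats]
            for i, stats in enumerate(per_ds_stats):
                if c not in stats:
                    continue
                rows[f"d_ds{i + 1}"] = stats[c]["d"].reindex(genes)
                rows[f"p_ds{i + 1}"] = stats[c]["perm_p"].reindex(genes)
                rows[f"log2_fc_ds{i + 1}"] = stats[c]["log2_fc"].reindex(genes)
            tab = pd.DataFrame(rows, index=genes)
            tab["combined_log2_fc"] = geneset.combined_fc[c]
            if genes and len(with_c) == len(per_ds_stats):
                tab["combined_z"] = combine_z(
                    [stats[c]["perm_p"].reindex(genes).to_numpy()
                     for stats in with_c],
                    [stats[c]["log2_fc"].reindex(genes).to_numpy()
                     for stats in with_c],
                    sizes)
            p = outdir / f"contrast_{c}.tsv"
            tab.to_csv(p, sep="\t", index_label="gene", float_format="%.6g")
            outs.append(p)
        up = outdir / "union_genes.txt"
        up.write_text("\n".join(geneset.union) + "\n")
        outs.append(up)
        record("geneset", outs, union=len(geneset.union))
    except Exception as exc:
        raise PipelineError(f"stage geneset failed: {exc}") from exc

    # ---- verify -----------------------------------------------------------
    try:
        vm, vcl, vtruth = filtered[-1]
        present = [g for g in geneset.union if g in vm.data.index]
        if len(present) < max(2, cfg.n_components):
            raise ValueError(
                f"only {len(present)} discriminative genes present in the "
                "verification dataset")
        vsub = standardize_genes(vm.select_genes(present))
        dend = hcluster(vsub, axis="samples")
        cut = cut_k(dend, cfg.hier.k_samples, cfg.hier.min_cluster_size)
        vpca = fit_pca(vsub, cfg.n_components)
        h_assign = rescue_by_pca_nn(cut, vpca.scores)
        gclust = gene_clusters(vsub, cfg.hier.k_genes)
        outs = []
        p = outdir / f"{names[-1]}_h_assignments.tsv"
        h_assign.to_tsv(p)
        outs.append(p)
        dp = outdir / "sample_dendrogram.tsv"
        dend.to_tsv(dp)
        outs.append(dp)
        gp = outdir / "gene_clusters.tsv"
        gclust.to_tsv(gp)
        outs.append(gp)
        record("verify", outs, genes_used=len(present),
               assigned=len(h_assign.assigned()),
               rescued=int((h_assign.provenance == "nn_rescue").sum()))
    except Exception as exc:
        raise PipelineError(f"stage verify failed: {exc}") from exc

    # ---- project ----------------------------------------------------------
    try:
        aligned = align_common_genes([fm for fm, _, _ in filtered])
        std = [standardize_genes(a) for a in aligned]
        model = fit_loadings(std[1], cfg.n_components)  # second discovery cohort
        outs = []
        mp = outdir / "loadings.tsv"
        model.to_tsv(mp)
        outs.append(mp)
        for name, s in zip(names, std):
            scores = project(s, model)
            p = outdir / f"{name}_projected_scores.tsv"
            scores.to_csv(p, sep="\t", index_label="sample_id",
                          float_format="%.8g")
            outs.append(p)
        record("project", outs, common_genes=len(model.genes))
    except Exception as exc:
        raise PipelineError(f"stage project failed: {exc}") from exc

    # ---- associate --------------------------------------------------------
    try:
        outs = []
        final = list(zip(names[:-1], r_assignments,
                         [cl for _, cl, _ in filtered[:-1]])) + \
            [(names[-1], h_assign, vcl)]
        surv_rows, corr_rows = [], []
        for name, assign, cl in final:
            if assign.k >= 2 and len(assign.assigned()) >= 4:
                enr = cluster_factor_enrichment(assign, cl)
                p = outdir / f"{name}_enrichment.tsv"
                enr.to_csv(p, sep="\t", index_label="factor",
                           float_format="%.6g")
                outs.append(p)
                try:
                    chi2, lp = logrank_by_cluster(assign, cl, "os")
                    fy = five_year_fisher(assign, cl)
                    curves = km_by_cluster(assign, cl, "os")
                    for clus, curve in curves.items():
                        surv_rows.append({
                            "dataset": name, "cluster": clus,
                            "five_year_os": survival_at(curve, 60.0),
                            "five_year_fisher_p": fy.get(clus, np.nan),
                            "logrank_chi2": chi2, "logrank_p": lp})
                except ValueError as exc:
                    log.warning("%s survival skipped: %s", name, exc)
            em = dict(zip(names, [fm for fm, _, _ in filtered]))[name]
            if {"MYCN", "MYC"} <= set(em.data.index):
                r, pv = pearson(em.data.loc["MYCN"], em.data.loc["MYC"])
                corr_rows.append({"dataset": name, "pearson_r": r, "p": pv})
            sub = genomic_subtypes(cl)
            tab = crosstab(assign, sub)
            p = outdir / f"{name}_crosstab.tsv"
            tab.to_csv(p, sep="\t", index_label="subtype")
            outs.append(p)
        sp = outdir / "survival.tsv"
        pd.DataFrame(surv_rows).to_csv(sp, sep="\t", index=False,
                                       float_format="%.6g")
        outs.append(sp)
        cp = outdir / "correlation.tsv"
        pd.DataFrame(corr_rows).to_csv(cp, sep="\t", index=False,
                                       float_format="%.6g")
        outs.append(cp)
        record("associate", outs, datasets=len(final))
    except Exception as exc:
        raise PipelineError(f"stage associate failed: {exc}") from exc

    manifest = RunManifest(version=__version__, seed=config.seed,
                           config=config.snapshot(), inputs=inputs,
                           stages=stages)
    manifest.to_json(outdir / "manifest.json")
    return manifest
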