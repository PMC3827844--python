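"""End-to-end orchestration: consistency -> tiers -> enrichment -> semantic -> network.

A :class:`PipelineConfig` names the input files (primary and auxiliary
expression datasets, probe annotation, gene sets, optional corpus and
interaction network), the stage parameters and a mandatory seed.  The
stages communicate only through their written tables; a manifest records
every parameter and output checksum, so an identical config and seed
reproduces an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consistency, enrichment, io, network as netmod, semantic, tiers

log = logging.getLogger(__name__)

DEFAULT_DELIMITERS = {
    "disease_specific": "disease and neuro",
    "cancer": "cancer",
    "any_disease": "disease",
    "stress": "disease and stress",
}


@dataclass
class DatasetConfig:
    matrix: str
    metadata: str
    platform_id: str
    role: str = "primary"  # "primary" or "auxiliary"


@dataclass
class PipelineConfig:
    datasets: list[DatasetConfig]
    annotation: str
    output_dir: str
    seed: int
    gene_sets: str | None = None
    corpus: str | None = None
    network: str | None = None
    intensity_fraction: float = consistency.DEFAULT_INTENSITY_FRACTION
    top_fraction_primary: float = tiers.DEFAULT_TOP_FRACTION
    top_fraction_auxiliary: float = tiers.DEFAULT_TOP_FRACTION
    tier3_max_set_size: int = tiers.DEFAULT_TIER3_MAX_SET_SIZE
    fdr_cutoff: float = enrichment.DEFAULT_FDR_CUTOFF
    min_category_size: int = enrichment.DEFAULT_MIN_CATEGORY_SIZE
    cycles: int = enrichment.DEFAULT_CYCLES
    n_control_resamples: int = semantic.DEFAULT_N_CONTROL_RESAMPLES
    k_splits: int = 2
    delimiters: dict = field(default_factory=lambda: dict(DEFAULT_DELIMITERS))
    include_neighbors: bool = True
    max_subnetwork_size: int = netmod.DEFAULT_MAX_SIZE

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data, base=Path(path).parent)

    @classmethod
    def from_dict(cls, data: dict, base: Path | None = None) -> "PipelineConfig":
        data = dict(data)
        if "seed" not in data:
            raise ValueError("pipeline config requires a seed")
        datasets = [DatasetConfig(**d) for d in data.pop("datasets")]
        cfg = cls(datasets=datasets, **data)
        cfg.validate(base=base)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() or base is None else base / p

        paths = [self.annotation] + [d.matrix for d in self.datasets] \
            + [d.metadata for d in self.datasets]
        paths += [p for p in (self.gene_sets, self.corpus, self.network) if p]
        for p in paths:
            rp = resolve(p)
            if not rp.exists():
                raise FileNotFoundError(f"configured input does not exist: {rp}")
        if base is not None:
            self.annotation = str(resolve(self.annotation))
            for d in self.datasets:
                d.matrix, d.metadata = str(resolve(d.matrix)), str(resolve(d.metadata))
            self.gene_sets = str(resolve(self.gene_sets)) if self.gene_sets else None
            self.corpus = str(resolve(self.corpus)) if self.corpus else None
            self.network = str(resolve(self.network)) if self.network else None

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def gene_intensity_table(records: pd.DataFrame) -> pd.Series:
    """Gene-level mean intensity: max probe mean intensity per gene."""
    mapped = records.dropna(subset=["gene_symbol"])
    return mapped.groupby("gene_symbol")["mean_intensity"].max()


def report_intensity_summary(records: pd.DataFrame, tier_sets: dict[str, set],
                             rng: np.random.Generator) -> pd.DataFrame:
    """Per-tier mean/variance of gene intensity with size-matched random controls.

    Single-gene tiers have an undefined variance (NaN, flagged by
    ``variance_defined``); the control column is the mean intensity of a
    size-matched random gene draw from the measured background.
    """
    intens = gene_intensity_table(records)
    rows = []
    for tier in sorted(tier_sets):
        members = sorted(set(tier_sets[tier]) & set(intens.index))
        n = len(members)
        vals = intens.loc[members]
        if n == 0:
            rows.append({"tier": tier, "n_genes": 0, "mean_intensity": np.nan,
                         "variance": np.nan, "variance_defined": False,
                         "random_control_mean": np.nan})
            continue
        control = intens.iloc[rng.choice(len(intens), size=n, replace=False)]
        rows.append({
            "tier": tier, "n_genes": n,
            "mean_intensity": float(vals.mean()),
            "variance": float(vals.var(ddof=1)) if n > 1 else np.nan,
            "variance_defined": n > 1,
            "random_control_mean": float(control.mean()),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the run manifest."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    outputs: list[Path] = []
    warnings_: list[str] = []

    def stage(name):
        log.info("stage %-12s +%.1fs", name, time.time() - t0)

    try:
        stage("read")
        annotation = io.read_probe_annotation(config.annotation)
        datasets = {}
        roles = {}
        for d in config.datasets:
            ds = io.read_expression_matrix(d.matrix, d.metadata, platform_id=d.platform_id)
            datasets[d.platform_id] = ds
            roles[d.platform_id] = d.role
        gene_sets = io.read_gene_sets(config.gene_sets) if config.gene_sets else None

        stage("consistency")
        records = {}
        for pid, ds in datasets.items():
            rec = consistency.score_dataset(ds, annotation,
                                            intensity_fraction=config.intensity_fraction)
            records[pid] = rec
            path = outdir / f"consistency_{pid}.tsv"
            rec.to_csv(path, sep="\t", index=False)
            outputs.append(path)

        stage("tiers")
        primary = pd.concat([records[p] for p in records if roles[p] == "primary"],
                            ignore_index=True)
        flagged = tiers.select_high_pcs(primary, config.top_fraction_primary)
        assignments = tiers.assign_tiers(flagged, gene_sets,
                                         tier3_max_set_size=config.tier3_max_set_size)
        tier_sets = tiers.tier_gene_sets(assignments)
        tier12 = tier_sets.get("1", set()) | tier_sets.get("2", set())
        aux_ids = [p for p in records if roles[p] == "auxiliary"]
        if aux_ids:
            tier0 = tiers.assign_tier0(tier12, records[aux_ids[0]],
                                       config.top_fraction_auxiliary)
        else:
            tier0 = set()
            warnings_.append("no auxiliary dataset configured; Tier 0 stage skipped")
            log.warning(warnings_[-1])
        tier_sets["0"] = tier0
        venn = tiers.venn_difference(tier0, tier_sets.get("1", set()),
                                     tier_sets.get("2", set()), tier_sets.get("3", set()))

        combined = assignments.copy()
        combined.loc[combined["gene_symbol"].isin(tier0), "tier"] = "0"
        path = outdir / "tiers_genes.tsv"
        combined.sort_values(["tier", "gene_symbol"]).to_csv(path, sep="\t", index=False)
        outputs.append(path)
        path = outdir / "tiers_probes.tsv"
        flagged.to_csv(path, sep="\t", index=False)
        outputs.append(path)
        for label, members in [("tier0", tier0), *[(f"tier{t}", s)
                               for t, s in sorted(tier_sets.items()) if t != "0"],
                               *sorted(venn.items())]:
            p = outdir / f"genes_{label}.txt"
            p.write_text("".join(f"{g}\n" for g in sorted(members)))
            outputs.append(p)

        stage("enrichment")
        enrich_lists = {
            "tier0": tier0,
            "tier1": tier_sets.get("1", set()),
            "tier1+2": tier12,
            "tier1+2+3": tier12 | tier_sets.get("3", set()),
        }
        if gene_sets is not None:
            total = gene_intensity_table(primary)
            frames = []
            for label, members in enrich_lists.items():
                members = sorted(set(members) & set(total.index))
                if len(members) < 2:
                    continue
                background = enrichment.match_background_by_expression(total, members)
                table = enrichment.compute_enrichment(members, background, gene_sets)
                table = enrichment.permutation_fdr(
                    table, background, gene_sets, cycles=config.cycles, rng=rng)
                report = enrichment.filter_and_sort(
                    table, config.fdr_cutoff, config.min_category_size)
                report.insert(0, "list_label", label)
                frames.append(report)
            path = outdir / "enrichment.tsv"
            (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame()).to_csv(path, sep="\t", index=False)
            outputs.append(path)

        stage("semantic")
        if config.corpus:
            corpus = io.read_corpus(config.corpus)
            background_genes = sorted(gene_intensity_table(primary).index)
            sem_lists = {"tier0": tier0, **venn}
            rows = []
            for label, members in sem_lists.items():
                members = sorted(members)
                if not members:
                    continue
                for dname, expr in config.delimiters.items():
                    ctrl = semantic.control_ratio(
                        corpus, background_genes, len(members), expr,
                        n_resamples=config.n_control_resamples, rng=rng)
                    res = semantic.relative_enrichment(corpus, members, expr, ctrl,
                                                       list_label=label)
                    var = (semantic.subset_variance(corpus, members, expr,
                                                    config.k_splits, rng=rng)
                           if len(members) >= config.k_splits else np.nan)
                    rows.append({**res.__dict__, "delimiter_name": dname,
                                 "pooled_variance": var})
            path = outdir / "semantic.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            outputs.append(path)

        stage("network")
        if config.network:
            global_net = io.read_edge_list(config.network)
            focus = tier_sets.get("1", set()) or tier12
            if focus:
                induced = netmod.build_induced_network(
                    focus, global_net, include_neighbors=config.include_neighbors)
                partition = netmod.partition_subnetworks(
                    induced, max_size=config.max_subnetwork_size)
                scores = netmod.score_partition(
                    induced, partition, focus,
                    background_size=global_net.number_of_nodes())
                part_rows = [{"subnetwork_id": s.subnetwork_id, "gene": g,
                              "is_focus": g in focus}
                             for s in scores for g in sorted(s.nodes)]
                path = outdir / "subnetwork_membership.tsv"
                pd.DataFrame(part_rows).to_csv(path, sep="\t", index=False)
                outputs.append(path)
                path = outdir / "subnetwork_scores.tsv"
                pd.DataFrame([{
                    "subnetwork_id": s.subnetwork_id, "n_molecules": len(s.nodes),
                    "score": round(s.score, 3), "focus_molecules": s.focus_molecules,
                    "internal_edges": s.internal_edges,
                } for s in scores]).to_csv(path, sep="\t", index=False)
                outputs.append(path)
                path = outdir / "induced_network.graphml"
                import networkx as nx
                nx.write_graphml(induced, path)
                outputs.append(path)
            else:
                warnings_.append("no Tier 1/2 genes; network stage skipped")

        stage("report")
        summary = report_intensity_summary(primary, {**tier_sets}, rng)
        path = outdir / "intensity_summary.tsv"
        summary.to_csv(path, sep="\t", index=False)
        outputs.append(path)
    except Exception as exc:  # annotate stage failures with context
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    manifest = {
        "parameters": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        "warnings": warnings_,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    manifest_path = outdir / "manifest.json"
    stable = {k: v for k, v in manifest.items() if k != "elapsed_seconds"}
    manifest_path.write_text(json.dumps(stable, indent=2, sort_keys=True) + "\n")
    return manifest
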