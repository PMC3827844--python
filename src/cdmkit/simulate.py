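"""Seeded generators for every input the pipeline consumes.

The expression generator emulates the structure of the real multi-platform
case/control compendia the method was designed for: a multi-probe
oligonucleotide platform and a single-probe bead platform profiling the
same case/control cohort across tissue subsets (or condition-pure sample
splits), plus an auxiliary multi-disease platform sharing part of the
disease signal.  Signal structure, all in log2 space:

* gene baselines ~ N(8, 2) — intensities are log-normal with a wide
  dynamic range, so an upper-40% intensity cut is meaningful;
* per-sample measurement noise sd 0.5 (~40% CV, typical for arrays);
* gene x subset x condition hybridisation-batch offsets sd 0.25 — samples
  of one condition in one subset are processed together, the main source
  of false positives for naive pooled testing;
* probe affinity offsets sd 0.5 (constant per probe, cancel in tests);
* a fraction of *probes* cross-hybridise: a platform-consistent spurious
  differential signal, the failure mode that cross-platform and
  multi-probe concordance rules are designed to reject;
* a fraction of *genes* carry a sporadic artifact in a single random
  subset, the failure mode that consistency averaging rejects;
* planted disease genes are shifted by ``effect_size`` noise-sd units in
  disease samples in every subset, mostly downward, and are sampled with
  intensity-rank weighting (disease signal rides on expressed genes),
  which reproduces the intensity-consistency correlation seen on real
  compendia.

Every generator is deterministic given its seed and exports its ground
truth alongside the fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionDataset, GeneSetCollection


@dataclass
class PlatformSpec:
    """Design of one simulated platform."""

    platform_id: str
    probes_per_gene: tuple[int, ...] = (1,)  # choices, drawn uniformly per gene
    role: str = "primary"                    # "primary" or "auxiliary"
    design: str = "within"                   # "within" (tissue subsets) or "split"


DEFAULT_PLATFORMS = (
    PlatformSpec("AFFY1", probes_per_gene=(1, 2, 3), role="primary"),
    PlatformSpec("ILMN1", probes_per_gene=(1,), role="primary"),
    PlatformSpec("ILMN2", probes_per_gene=(1,), role="auxiliary"),
)


@dataclass
class GeneratorTruth:
    """Ground truth serialised alongside every generated fixture."""

    seed: int
    planted_disease_genes: list[str] = field(default_factory=list)
    planted_directions: dict[str, int] = field(default_factory=dict)
    effect_size: float = 0.0
    downregulated_fraction: float = 0.0
    aux_shared_genes: list[str] = field(default_factory=list)
    crosshyb_probes: dict[str, list[str]] = field(default_factory=dict)
    sporadic_genes: dict[str, list[str]] = field(default_factory=dict)
    planted_enriched_terms: list[str] = field(default_factory=list)
    planted_corpus_folds: dict = field(default_factory=dict)
    planted_module_nodes: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def gene_names(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n_genes + 1)]


def generate_multiplatform_study(
    n_genes: int = 5000,
    platforms: tuple[PlatformSpec, ...] = DEFAULT_PLATFORMS,
    n_subsets: int = 3,
    n_per_group: int = 10,
    planted_fraction: float = 0.02,
    effect_size: float = 1.5,
    downregulated_fraction: float = 0.8,
    baseline_log2_mean: float = 8.0,
    baseline_log2_sd: float = 2.0,
    noise_sd: float = 0.5,
    batch_sd: float = 0.25,
    probe_offset_sd: float = 0.5,
    crosshyb_fraction: float = 0.03,
    sporadic_fraction: float = 0.10,
    sporadic_scale: float = 1.5,
    aux_shared_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, ExpressionDataset], pd.DataFrame, GeneratorTruth]:
    """Simulate a multi-platform case/control expression study.

    Returns (datasets keyed by platform id, probe annotation table, truth).
    ``effect_size`` is in units of the per-sample noise sd.  At least two
    platforms are required and the auxiliary platform (if present) shares
    ``aux_shared_fraction`` of the planted genes.
    """
    if len(platforms) < 2:
        raise ValueError("need >=2 platforms")
    if not 0 <= planted_fraction < 1:
        raise ValueError("planted_fraction must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = gene_names(n_genes)
    baseline = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)

    # planted genes, sampled with intensity-rank weighting
    n_planted = round(planted_fraction * n_genes)
    rank = np.empty(n_genes)
    rank[np.argsort(baseline)] = np.arange(1, n_genes + 1)
    weights = rank / rank.sum()
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False, p=weights)
    directions = np.where(rng.random(n_planted) < downregulated_fraction, -1, 1)
    delta = effect_size * noise_sd
    gene_effect = np.zeros(n_genes)
    gene_effect[planted_idx] = delta * directions

    n_shared = round(aux_shared_fraction * n_planted)
    shared_idx = rng.choice(planted_idx, size=n_shared, replace=False) if n_planted else np.array([], int)
    aux_effect = np.zeros(n_genes)
    aux_effect[shared_idx] = gene_effect[shared_idx]

    truth = GeneratorTruth(
        seed=seed,
        planted_disease_genes=sorted(genes[i] for i in planted_idx),
        planted_directions={genes[i]: int(d) for i, d in zip(planted_idx, directions)},
        effect_size=effect_size,
        downregulated_fraction=downregulated_fraction,
        aux_shared_genes=sorted(genes[i] for i in shared_idx),
        params={
            "n_genes": n_genes, "n_subsets": n_subsets, "n_per_group": n_per_group,
            "planted_fraction": planted_fraction, "noise_sd": noise_sd,
            "batch_sd": batch_sd, "crosshyb_fraction": crosshyb_fraction,
            "sporadic_fraction": sporadic_fraction, "sporadic_scale": sporadic_scale,
            "aux_shared_fraction": aux_shared_fraction,
        },
    )

    datasets: dict[str, ExpressionDataset] = {}
    annotation_rows = []
    for spec in platforms:
        eff = aux_effect if spec.role == "auxiliary" else gene_effect

        # probes
        ppg = rng.choice(spec.probes_per_gene, size=n_genes)
        probe_gene = np.repeat(np.arange(n_genes), ppg)
        n_probes = len(probe_gene)
        probe_ids = []
        for gi, count in zip(range(n_genes), ppg):
            for k in range(count):
                probe_ids.append(f"{spec.platform_id}:{genes[gi]}:{k + 1}")
        probe_offset = rng.normal(0.0, probe_offset_sd, size=n_probes)

        # samples
        sample_ids, sample_subset, sample_cond = [], [], []
        if spec.design == "within":
            subset_labels = [f"S{j + 1}" for j in range(n_subsets)]
            for s in subset_labels:
                for cond in ("control", "disease"):
                    for r in range(n_per_group):
                        sample_ids.append(f"{spec.platform_id}:{s}:{cond[0]}{r + 1}")
                        sample_subset.append(s)
                        sample_cond.append(cond)
        elif spec.design == "split":
            for cond, prefix in (("control", "C"), ("disease", "D")):
                for j in range(n_subsets):
                    s = f"{prefix}{j + 1}"
                    for r in range(n_per_group):
                        sample_ids.append(f"{spec.platform_id}:{s}:{r + 1}")
                        sample_subset.append(s)
                        sample_cond.append(cond)
        else:
            raise ValueError(f"unknown design {spec.design!r}")
        sample_subset = np.asarray(sample_subset)
        is_disease = np.asarray([c == "disease" for c in sample_cond])
        n_samples = len(sample_ids)

        # batch offsets per gene x (subset, condition) hybridisation group
        group_keys = sorted({(s, c) for s, c in zip(sample_subset, sample_cond)})
        group_of_sample = np.array([group_keys.index((s, c))
                                    for s, c in zip(sample_subset, sample_cond)])
        batch = rng.normal(0.0, batch_sd, size=(n_genes, len(group_keys)))

        # cross-hybridising probes (platform-consistent spurious signal)
        n_ch = round(crosshyb_fraction * n_probes)
        ch_idx = rng.choice(n_probes, size=n_ch, replace=False)
        ch_amp = np.zeros(n_probes)
        ch_amp[ch_idx] = rng.normal(0.0, delta, size=n_ch)
        truth.crosshyb_probes[spec.platform_id] = sorted(probe_ids[i] for i in ch_idx)

        # sporadic single-subset artifacts (gene level, this platform only)
        n_sp = round(sporadic_fraction * n_genes)
        sp_idx = rng.choice(n_genes, size=n_sp, replace=False)
        sp_amp = np.zeros(n_genes)
        sp_amp[sp_idx] = rng.normal(0.0, sporadic_scale * delta, size=n_sp)
        disease_subsets = sorted({s for s, d in zip(sample_subset, is_disease) if d})
        sp_subset = rng.choice(disease_subsets, size=n_genes)
        truth.sporadic_genes[spec.platform_id] = sorted(genes[i] for i in sp_idx)

        log2 = (
            baseline[probe_gene][:, None]
            + probe_offset[:, None]
            + batch[probe_gene][:, group_of_sample]
            + eff[probe_gene][:, None] * is_disease[None, :]
            + ch_amp[:, None] * is_disease[None, :]
            + sp_amp[probe_gene][:, None]
            * (is_disease[None, :] & (sp_subset[probe_gene][:, None] == sample_subset[None, :]))
            + rng.normal(0.0, noise_sd, size=(n_probes, n_samples))
        )
        mat = pd.DataFrame(np.exp2(log2), index=pd.Index(probe_ids, name="probe_id"),
                           columns=sample_ids)
        datasets[spec.platform_id] = ExpressionDataset(
            platform_id=spec.platform_id,
            intensities=mat,
            condition=pd.Series(sample_cond, index=sample_ids),
            subset=pd.Series(sample_subset, index=sample_ids),
        )
        annotation_rows.extend(
            {"probe_id": pid, "gene_symbol": genes[gi], "platform": spec.platform_id}
            for pid, gi in zip(probe_ids, probe_gene)
        )

    annotation = pd.DataFrame(annotation_rows)
    return datasets, annotation, truth


def generate_gene_sets(universe, disease_genes, n_terms: int = 150,
                       size_range: tuple[int, int] = (5, 40),
                       n_planted_terms: int = 5,
                       planted_member_fraction: float = 0.8,
                       seed: int = 0) -> tuple[GeneSetCollection, GeneratorTruth]:
    """Random functional categories, a few enriched for the disease genes.

    Planted terms draw ``planted_member_fraction`` of their members from
    the disease gene pool, the rest uniformly; null terms draw uniformly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    universe = list(universe)
    disease_genes = [g for g in disease_genes if g in set(universe)]
    sets, names = {}, {}
    planted_terms = []
    for t in range(1, n_terms + 1):
        term_id = f"TERM{t:04d}"
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if t <= n_planted_terms and disease_genes:
            n_d = min(math.ceil(planted_member_fraction * size), len(disease_genes))
            members = set(rng.choice(disease_genes, size=n_d, replace=False))
            pool = [g for g in universe if g not in members]
            members |= set(rng.choice(pool, size=size - n_d, replace=False))
            planted_terms.append(term_id)
        else:
            members = set(rng.choice(universe, size=size, replace=False))
        sets[term_id] = {str(m) for m in members}
        names[term_id] = f"synthetic category {t}"
    truth = GeneratorTruth(seed=seed, planted_enriched_terms=planted_terms,
                           params={"n_terms": n_terms, "size_range": size_range,
                                   "planted_member_fraction": planted_member_fraction})
    return GeneSetCollection(sets=sets, names=names), truth


def generate_corpus(universe, n_documents: int = 2000,
                    tag_vocabulary: tuple[str, ...] = (
                        "disease", "cancer", "stress", "neuro",
                        "oncogene", "tumor_suppressor"),
                    gene_groups: dict[str, set] | None = None,
                    association_folds: dict[str, dict[str, float]] | None = None,
                    base_tag_rate: float = 0.08,
                    mean_extra_genes: float = 0.5,
                    seed: int = 0) -> tuple[pd.DataFrame, GeneratorTruth]:
    """Simulate a gene-document corpus with planted tag associations.

    Each document mentions one primary gene plus a small Poisson number of
    extra genes; a tag is attached with probability ``base_tag_rate`` times
    the largest association fold over the mentioned genes' groups (capped
    at 1).  Genes outside every group have fold 1 for every tag.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    universe = np.asarray(list(universe), dtype=object)
    gene_groups = gene_groups or {}
    association_folds = association_folds or {}
    fold_of_gene: dict[str, dict[str, float]] = {}
    for group, members in gene_groups.items():
        folds = association_folds.get(group, {})
        for g in members:
            slot = fold_of_gene.setdefault(str(g), {})
            for tag, f in folds.items():
                slot[tag] = max(slot.get(tag, 1.0), float(f))

    rows = []
    for d in range(1, n_documents + 1):
        primary = rng.choice(universe)
        n_extra = rng.poisson(mean_extra_genes)
        extra = rng.choice(universe, size=n_extra, replace=False) if n_extra else []
        doc_genes = frozenset({str(primary), *map(str, extra)})
        tags = set()
        for tag in tag_vocabulary:
            fold = max((fold_of_gene.get(g, {}).get(tag, 1.0) for g in doc_genes),
                       default=1.0)
            if rng.random() < min(1.0, base_tag_rate * fold):
                tags.add(tag)
        rows.append((f"DOC{d:06d}", doc_genes, frozenset(tags)))
    corpus = pd.DataFrame(rows, columns=["document_id", "genes", "tags"])
    truth = GeneratorTruth(seed=seed, planted_corpus_folds=association_folds,
                           params={"n_documents": n_documents,
                                   "base_tag_rate": base_tag_rate,
                                   "mean_extra_genes": mean_extra_genes})
    return corpus, truth


def generate_network(nodes=2000, degree_exponent: float = 2.5,
                     mean_degree: float = 6.0,
                     planted_module_size: int = 30,
                     planted_density: float = 0.6,
                     seed: int = 0) -> tuple[nx.Graph, GeneratorTruth]:
    """Scale-free-ish interaction network with a planted dense module.

    A Chung-Lu expected-degree graph whose weight sequence follows a power
    law with the requested tail exponent, rescaled to the requested mean
    degree; a random ``planted_module_size`` node subset then gets extra
    internal edges at density ``planted_density``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if isinstance(nodes, int):
        node_names = gene_names(nodes)
    else:
        node_names = list(nodes)
    n = len(node_names)
    # w_i ~ i^(-1/(gamma-1)) yields a degree tail exponent of gamma
    i = np.arange(1, n + 1, dtype=float)
    w = i ** (-1.0 / (degree_exponent - 1.0))
    w *= mean_degree * n / w.sum()
    w = np.minimum(w, math.sqrt(w.sum()))  # keep edge probabilities <= 1
    graph = nx.expected_degree_graph(w, seed=int(rng.integers(2**31 - 1)), selfloops=False)
    graph = nx.relabel_nodes(graph, dict(enumerate(node_names)))

    module = sorted(rng.choice(node_names, size=planted_module_size, replace=False))
    for a_i in range(len(module)):
        for b_i in range(a_i + 1, len(module)):
            if rng.random() < planted_density:
                graph.add_edge(module[a_i], module[b_i])
    truth = GeneratorTruth(seed=seed, planted_module_nodes=list(module),
                           params={"degree_exponent": degree_exponent,
                                   "mean_degree": mean_degree,
                                   "planted_density": planted_density})
    return graph, truth
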