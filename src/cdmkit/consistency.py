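"""Per-probe differential-expression consistency within one dataset.

The procedure, per platform: keep the upper fraction of probes by pooled
mean intensity (low-intensity signal is unlikely to exceed hybridisation
noise), run a two-tailed unequal-variance (Welch) t-test between control
and disease groups for every tissue subset (or every control-split x
disease-split pairing when the study ships condition-pure splits), convert
the p-values to negative decimal logarithms and average them.  That average
is the Primary Consistency Score (PCS).  The sign of the mean log ratio of
disease over control group averages gives the direction of change.

Intensities are treated throughout as *linear* arbitrary units: group
averages and their ratios are taken on the raw signal, and the t-tests run
on the linear values.

Also housed here are the two design-stage formulas of the approach: the
recall estimate REC = C(N, m) * P(m) over platform combinations, and the
probability PEC = q^n that an n-step mechanistic hypothesis built from a
list with true-positive fraction q is fully correct.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset

#: Floor applied to p-values before the -log10 transform, keeping PCS finite.
P_FLOOR = 1e-300

#: Default intensity cut: the upper 40% of probes by pooled mean intensity.
DEFAULT_INTENSITY_FRACTION = 0.40


def filter_top_intensity(dataset: ExpressionDataset,
                         fraction: float = DEFAULT_INTENSITY_FRACTION) -> list[str]:
    """Probe ids in the upper ``fraction`` by pooled mean intensity.

    The ranking key is each probe's mean over *all* samples (conditions
    pooled); ``ceil(fraction * n_probes)`` probes are retained, ties at the
    cutoff broken toward the lexicographically smaller probe id so the
    result is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if dataset.n_probes == 0:
        raise ValueError("empty dataset")
    means = dataset.intensities.mean(axis=1, skipna=True)
    order = sorted(means.index, key=lambda p: (-means[p], p))
    k = math.ceil(fraction * len(order))
    return order[:k]


def welch_test(control, disease) -> float:
    """Two-tailed p-value of the unequal-variance (Welch) t-test.

    Degenerate case: both groups with zero variance and equal means gives
    p = 1 (no evidence of change); zero variance with unequal means gives
    p = 0 under the limiting statistic.
    """
    control = np.asarray(control, dtype=float)
    disease = np.asarray(disease, dtype=float)
    control = control[np.isfinite(control)]
    disease = disease[np.isfinite(disease)]
    if len(control) < 2 or len(disease) < 2:
        raise ValueError("welch_test needs >=2 finite values per group")
    if control.var(ddof=1) == 0 and disease.var(ddof=1) == 0:
        return 1.0 if control.mean() == disease.mean() else 0.0
    return float(stats.ttest_ind(control, disease, equal_var=False).pvalue)


def _welch_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch p-values for two probes x samples matrices (NaN-aware)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: scipy yields NaN; equal means carry p=1
    nan = ~np.isfinite(p)
    if nan.any():
        eq = np.nanmean(a[nan], axis=1) == np.nanmean(b[nan], axis=1)
        p[nan] = np.where(eq, 1.0, 0.0)
    return p


def neg_log10(p) -> np.ndarray:
    """-log10 of p with the documented floor ``P_FLOOR``."""
    return -np.log10(np.maximum(np.asarray(p, dtype=float), P_FLOOR))


def compute_pcs(neg_log_p_values) -> float:
    """Primary Consistency Score: arithmetic mean of -log10 p over subsets."""
    vals = np.asarray(list(neg_log_p_values), dtype=float)
    if vals.size == 0:
        raise ValueError("compute_pcs needs >=1 subset result")
    return float(vals.mean())


def compute_direction(mean_controls, mean_diseases) -> int:
    """Direction of change: sign of the mean log ratio disease/control.

    One ratio per subset pairing; intensities must be positive for the
    ratio to exist.  Returns +1 (up in disease), -1 (down) or 0 when the
    mean log ratio is exactly zero.
    """
    mc = np.asarray(list(mean_controls), dtype=float)
    md = np.asarray(list(mean_diseases), dtype=float)
    if mc.size == 0 or mc.size != md.size:
        raise ValueError("need matching non-empty group-mean vectors")
    if (mc <= 0).any() or (md <= 0).any():
        raise ValueError("group means must be positive to take expression ratios")
    mean_log_ratio = float(np.mean(np.log(md / mc)))
    return int(np.sign(mean_log_ratio))


def test_pairs(dataset: ExpressionDataset) -> list[tuple[str, list[str], list[str]]]:
    """Enumerate the (label, control samples, disease samples) comparisons.

    Tissue-subset designs (every subset holds both conditions) yield one
    comparison per subset.  Split designs (condition-pure subsets) yield
    the full control-split x disease-split cross product — the 2x2 design
    gives four separate tests.
    """
    subsets = sorted(set(dataset.subset.loc[dataset.sample_ids]))
    comp = {s: {c: dataset.samples_where(c, s) for c in ("control", "disease")}
            for s in subsets}
    mixed = [s for s in subsets if comp[s]["control"] and comp[s]["disease"]]
    pure_c = [s for s in subsets if comp[s]["control"] and not comp[s]["disease"]]
    pure_d = [s for s in subsets if comp[s]["disease"] and not comp[s]["control"]]
    if mixed and (pure_c or pure_d):
        raise ValueError(
            f"{dataset.platform_id}: mixed within-subset and split designs"
        )
    if mixed:
        pairs = [(s, comp[s]["control"], comp[s]["disease"]) for s in mixed]
    else:
        pairs = [(f"{sc}|{sd}", comp[sc]["control"], comp[sd]["disease"])
                 for sc in pure_c for sd in pure_d]
    for label, ctl, dis in pairs:
        if len(ctl) < 2 or len(dis) < 2:
            raise ValueError(
                f"{dataset.platform_id}: comparison {label!r} needs >=2 samples per group"
            )
    if not pairs:
        raise ValueError(f"{dataset.platform_id}: no testable control/disease comparison")
    return pairs


def score_dataset(dataset: ExpressionDataset,
                  annotation: pd.DataFrame | None = None,
                  intensity_fraction: float = DEFAULT_INTENSITY_FRACTION) -> pd.DataFrame:
    """Consistency table for one dataset: one row per probe.

    Columns: probe_id, gene_symbol, platform, pcs, direction,
    mean_intensity, passed_intensity_filter, n_tests.  PCS and direction
    are computed only for probes passing the intensity filter (NaN
    otherwise).
    """
    retained = filter_top_intensity(dataset, intensity_fraction)
    pairs = test_pairs(dataset)

    mat = dataset.intensities
    sub = mat.loc[retained]
    neg_logs = np.zeros((len(retained), len(pairs)))
    log_ratios = np.zeros_like(neg_logs)
    for j, (_, ctl, dis) in enumerate(pairs):
        a = sub[ctl].to_numpy(dtype=float)
        b = sub[dis].to_numpy(dtype=float)
        neg_logs[:, j] = neg_log10(_welch_matrix(a, b))
        mc = np.nanmean(a, axis=1)
        md = np.nanmean(b, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_ratios[:, j] = np.log(md / mc)

    pcs = neg_logs.mean(axis=1)
    direction = np.sign(log_ratios.mean(axis=1)).astype(int)

    table = pd.DataFrame({
        "probe_id": mat.index,
        "platform": dataset.platform_id,
        "mean_intensity": mat.mean(axis=1, skipna=True).to_numpy(),
        "passed_intensity_filter": mat.index.isin(retained),
        "pcs": np.nan,
        "direction": 0,
        "n_tests": 0,
    }).set_index("probe_id")
    table.loc[retained, "pcs"] = pcs
    table.loc[retained, "direction"] = direction
    table.loc[retained, "n_tests"] = len(pairs)
    table = table.reset_index()

    if annotation is not None:
        mapping = annotation.set_index("probe_id")["gene_symbol"]
        table["gene_symbol"] = table["probe_id"].map(mapping)
    else:
        table["gene_symbol"] = pd.NA
    cols = ["probe_id", "gene_symbol", "platform", "pcs", "direction",
            "mean_intensity", "passed_intensity_filter", "n_tests"]
    return table[cols]


def estimate_recall(n_platforms: int, m: int, per_combination_yield: float) -> float:
    """REC = C(N, m) * P(m): recall over all m-platform combinations."""
    if not 1 <= m <= n_platforms:
        raise ValueError(f"need 1 <= m <= n_platforms, got m={m}, N={n_platforms}")
    return math.comb(n_platforms, m) * per_combination_yield


def compute_pec(q: float, n: int) -> float:
    """PEC = q^n: probability an n-step hypothesis from a q-pure list is correct."""
    if not 0 <= q <= 1:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    return q ** n
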