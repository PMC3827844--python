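"""Expression-matched functional enrichment with permutation FDR.

Because highly expressed genes are more likely to yield consistent
differential-expression calls, a changed gene list compared against the
full measured background would show spurious enrichment in categories of
highly expressed genes.  The background ("total file") is therefore
trimmed to its top-expression prefix until its mean intensity matches the
changed list before any category is tested.

For a category with ``TG`` genes in the background of size ``T``, of which
``CG`` appear in the changed list of size ``L``:

    ENR = (CG / L) / (TG / T)

with a one-sided Fisher (upper-tail hypergeometric) p-value and a
resampling FDR: random gene lists of size L are drawn from the background
and the expected number of categories at or below each observed p-value is
related to the observed number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection

DEFAULT_FDR_CUTOFF = 0.2
DEFAULT_MIN_CATEGORY_SIZE = 5
DEFAULT_CYCLES = 100


def match_background_by_expression(total: pd.Series, changed_genes) -> list[str]:
    """Expression-adjusted background: top-expression prefix matching L's mean.

    ``total`` maps gene symbol -> mean intensity for every measured gene.
    The background is the largest prefix of the intensity-descending total
    list whose mean intensity is at least the changed list's mean; the
    changed genes themselves are always included.  A changed list whose
    mean is below the global mean needs no adjustment and gets the full
    total list.
    """
    changed = list(dict.fromkeys(changed_genes))
    missing = [g for g in changed if g not in total.index]
    if missing:
        raise KeyError(f"changed gene(s) absent from total list: {missing[:5]}")
    if not changed:
        raise ValueError("empty changed gene list")
    target = float(total.loc[changed].mean())
    # intensity-descending, gene-symbol tie-break for determinism
    frame = total.rename("intensity").rename_axis("gene").reset_index()
    frame = frame.sort_values(["intensity", "gene"], ascending=[False, True])
    values = frame["intensity"].to_numpy(dtype=float)
    cummean = np.cumsum(values) / np.arange(1, len(values) + 1)
    # cummean is non-increasing on a descending sort
    k = int(np.searchsorted(-cummean, -target, side="right"))
    if k >= len(values) or cummean[-1] >= target:
        k = len(values)
    prefix = frame["gene"].iloc[:max(k, 1)].tolist()
    background = list(dict.fromkeys(prefix + changed))
    return background


def enrichment_coefficient(CG: int, L: int, TG: int, T: int) -> float:
    """ENR = (CG/L) / (TG/T)."""
    if TG <= 0 or L <= 0:
        raise ValueError("TG and L must be positive")
    if not (T >= TG and L >= CG >= 0):
        raise ValueError(f"impossible margins CG={CG}, L={L}, TG={TG}, T={T}")
    return (CG / L) / (TG / T)


def fisher_one_sided(CG: int, L: int, TG: int, T: int) -> float:
    """Upper-tail hypergeometric P(X >= CG), X ~ Hypergeom(T, TG, L)."""
    if CG > TG or CG > L or TG > T or L > T or CG < 0:
        raise ValueError(f"impossible margins CG={CG}, L={L}, TG={TG}, T={T}")
    return float(stats.hypergeom.sf(CG - 1, T, TG, L))


def _term_counts(membership: np.ndarray, in_list: np.ndarray) -> np.ndarray:
    """CG per term: membership is terms x genes boolean, in_list genes bool."""
    return membership @ in_list.astype(np.int64)


def compute_enrichment(changed_genes, background, gene_sets: GeneSetCollection) -> pd.DataFrame:
    """Per-category TG, CG, ENR and one-sided p over a fixed background.

    Genes absent from every category still count toward T (they dilute
    TG/T, the "Total file" semantics).  Categories with no background gene
    are dropped.
    """
    background = list(dict.fromkeys(background))
    bg_index = {g: i for i, g in enumerate(background)}
    changed = [g for g in dict.fromkeys(changed_genes) if g in bg_index]
    T = len(background)
    L = len(changed)
    if L == 0:
        raise ValueError("no changed gene lies in the background")
    term_ids = sorted(gene_sets.sets)
    membership = np.zeros((len(term_ids), T), dtype=bool)
    for i, tid in enumerate(term_ids):
        idx = [bg_index[g] for g in gene_sets[tid] if g in bg_index]
        membership[i, idx] = True
    in_list = np.zeros(T, dtype=bool)
    in_list[[bg_index[g] for g in changed]] = True

    TGs = membership.sum(axis=1)
    CGs = _term_counts(membership, in_list)
    keep = TGs > 0
    p = stats.hypergeom.sf(CGs[keep] - 1, T, TGs[keep], L)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = (CGs[keep] / L) / (TGs[keep] / T)
    return pd.DataFrame({
        "term_id": np.asarray(term_ids)[keep],
        "TG": TGs[keep].astype(int),
        "CG": CGs[keep].astype(int),
        "ENR": enr,
        "p_value": p,
        "list_size_L": L,
        "background_size_T": T,
    })


def permutation_fdr(observed: pd.DataFrame, background, gene_sets: GeneSetCollection,
                    cycles: int = DEFAULT_CYCLES, seed: int | None = None,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Resampling FDR for an observed enrichment table.

    For each of ``cycles`` randomisation rounds, a uniform random gene
    list of the observed size L is drawn from the background and every
    category's one-sided p recomputed.  For category c:

        FDR(c) = mean_cycles #{random p <= p_c} / #{observed p <= p_c}

    clipped to [0, 1].  Deterministic given the seed.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if rng is None:
        if seed is None:
            raise ValueError("permutation_fdr needs a seed (or an explicit rng)")
        rng = np.random.default_rng(seed)
    background = list(dict.fromkeys(background))
    T = len(background)
    L = int(observed["list_size_L"].iloc[0])
    term_ids = observed["term_id"].tolist()
    bg_index = {g: i for i, g in enumerate(background)}
    membership = np.zeros((len(term_ids), T), dtype=bool)
    for i, tid in enumerate(term_ids):
        idx = [bg_index[g] for g in gene_sets[tid] if g in bg_index]
        membership[i, idx] = True
    TGs = membership.sum(axis=1)

    random_ps = np.empty((cycles, len(term_ids)))
    for c in range(cycles):
        draw = rng.choice(T, size=L, replace=False)
        in_list = np.zeros(T, dtype=bool)
        in_list[draw] = True
        CGs = _term_counts(membership, in_list)
        random_ps[c] = stats.hypergeom.sf(CGs - 1, T, TGs, L)

    obs_p = observed["p_value"].to_numpy(dtype=float)
    flat = np.sort(random_ps.ravel())
    # expected false discoveries at threshold p_c, averaged over cycles
    expected = np.searchsorted(flat, obs_p, side="right") / cycles
    observed_counts = np.searchsorted(np.sort(obs_p), obs_p, side="right")
    fdr = np.clip(expected / observed_counts, 0.0, 1.0)
    out = observed.copy()
    out["fdr"] = fdr
    return out


def filter_and_sort(results: pd.DataFrame,
                    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
                    min_category_size: int = DEFAULT_MIN_CATEGORY_SIZE) -> pd.DataFrame:
    """Report: drop small categories, keep FDR < cutoff, sort.

    Primary sort ascending FDR, ties re-sorted by descending enrichment
    coefficient, then term id.
    """
    kept = results[(results["TG"] >= min_category_size)
                   & (results["fdr"] < fdr_cutoff)].copy()
    kept = kept.sort_values(["fdr", "ENR", "term_id"],
                            ascending=[True, False, True], kind="mergesort")
    return kept.reset_index(drop=True)
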