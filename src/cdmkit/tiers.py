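"""Gene-level Consistency Tiers from per-probe consistency tables.

Probes of each primary platform are ranked by PCS (within the
intensity-filtered population) and the top fraction flagged as high-PCS.
Gene-level tiers, strongest first:

* **Tier 0** — gene in Tier 1 or Tier 2 whose symbol is also among the
  high-PCS genes of the auxiliary multi-disease dataset (a shared
  neuropathy signal, in the original application).
* **Tier 1** — (a) high PCS on both platforms *and* >=2 high-PCS probes on
  the multi-probe platform, all probes concordant in direction; (b)
  simultaneous Tier 2 and Tier 3 qualification; (c) >=3 high-PCS probes on
  one platform, all concordant.
* **Tier 2** — (a) >=2 high-PCS probes on one platform, concordant; (b)
  high-PCS probes on both platforms, concordant.
* **Tier 3** — a high-PCS gene sharing a (not too large) functional
  category with at least one other high-PCS gene.
* **high_pcs_unconfirmed** — high PCS with no confirming rule.

Direction discordance (including a tied majority over a gene's high-PCS
probes) disqualifies the Tier 1/2 rules, never Tier 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .io import GeneSetCollection

#: Gene sets larger than this are ignored by the Tier 3 pathway rule
#: (vacuously large categories would link everything to everything).
DEFAULT_TIER3_MAX_SET_SIZE = 500

DEFAULT_TOP_FRACTION = 0.10

TIER_ORDER = ["0", "1", "2", "3", "high_pcs_unconfirmed", "none"]


def select_high_pcs(records: pd.DataFrame,
                    top_fraction: float = DEFAULT_TOP_FRACTION) -> pd.DataFrame:
    """Flag the top fraction of probes by PCS, ranked within each platform.

    Only probes that passed the intensity filter compete; ``ceil(fraction
    * n)`` probes are flagged per platform, ties broken toward the
    lexicographically smaller probe id.  Returns a copy with a boolean
    ``high_pcs`` column.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if len(records) == 0:
        raise ValueError("empty record list")
    out = records.copy()
    out["high_pcs"] = False
    eligible = out[out["passed_intensity_filter"] & out["pcs"].notna()]
    for _, plat in eligible.groupby("platform"):
        ranked = plat.sort_values(["pcs", "probe_id"],
                                  ascending=[False, True], kind="mergesort")
        k = math.ceil(top_fraction * len(ranked))
        out.loc[ranked.index[:k], "high_pcs"] = True
    return out


@dataclass
class TierAssignment:
    gene_symbol: str
    tier: str
    rules_fired: tuple[str, ...]
    supporting_probes: tuple[tuple[str, str, int], ...]  # (probe, platform, direction)
    consensus_direction: int


def _majority_sign(directions) -> int:
    up = sum(1 for d in directions if d > 0)
    down = sum(1 for d in directions if d < 0)
    if up > down:
        return 1
    if down > up:
        return -1
    return 0


def assign_tiers(records: pd.DataFrame,
                 gene_sets: GeneSetCollection | None = None,
                 multi_probe_platform: str | None = None,
                 tier3_max_set_size: int = DEFAULT_TIER3_MAX_SET_SIZE) -> pd.DataFrame:
    """Evaluate the tier rules over flagged records from >=2 primary platforms.

    ``records`` must carry a ``high_pcs`` column (see :func:`select_high_pcs`)
    and gene symbols.  ``multi_probe_platform`` names the platform whose
    probe redundancy backs the Tier 1a/1c rules; by default the platform
    with the highest mean probes-per-gene.  Returns one row per gene that
    has at least one high-PCS probe: gene_symbol, tier, rules_fired,
    consensus_direction, supporting_probes.
    """
    platforms = sorted(records["platform"].unique())
    if len(platforms) < 2:
        raise ValueError("tier assignment needs records from >=2 platforms")
    if multi_probe_platform is None:
        with_genes = records.dropna(subset=["gene_symbol"])
        ppg = with_genes.groupby("platform")["gene_symbol"].agg(
            lambda g: len(g) / max(g.nunique(), 1))
        multi_probe_platform = str(ppg.idxmax())
    elif multi_probe_platform not in platforms:
        raise ValueError(f"unknown platform id {multi_probe_platform!r}")

    high = records[records["high_pcs"]].copy()
    n_unmapped = high["gene_symbol"].isna().sum()
    if n_unmapped:
        import logging
        logging.getLogger(__name__).warning(
            "%d high-PCS probes lack a gene annotation and were dropped", n_unmapped)
        high = high.dropna(subset=["gene_symbol"])

    high_genes = set(high["gene_symbol"])

    # Tier 3: gene shares a (bounded-size) category with another high-PCS gene
    tier3_genes: set[str] = set()
    if gene_sets is not None:
        for _, members in gene_sets.items():
            if len(members) > tier3_max_set_size:
                continue
            hits = members & high_genes
            if len(hits) >= 2:
                tier3_genes |= hits

    rows = []
    for gene, probes in high.groupby("gene_symbol"):
        per_platform = {p: sub for p, sub in probes.groupby("platform")}
        directions = probes["direction"].tolist()
        all_concordant = len({d for d in directions if d != 0}) == 1 and 0 not in directions
        consensus = _majority_sign(directions)
        concordant_majority = consensus != 0

        rules = []
        t2a_platforms = [
            p for p, sub in per_platform.items()
            if len(sub) >= 2 and len(set(sub["direction"])) == 1 and sub["direction"].iloc[0] != 0
        ]
        both_platforms = len(per_platform) >= 2
        if t2a_platforms and concordant_majority:
            rules.append("T2a")
        if both_platforms and all_concordant:
            rules.append("T2b")
        if ("T2b" in rules
                and len(per_platform.get(multi_probe_platform, ())) >= 2
                and all_concordant):
            rules.append("T1a")
        t1c = any(
            len(sub) >= 3 and len(set(sub["direction"])) == 1 and sub["direction"].iloc[0] != 0
            for sub in per_platform.values()
        )
        if t1c and concordant_majority:
            rules.append("T1c")
        is_tier3 = gene in tier3_genes
        if is_tier3:
            rules.append("T3")
        if is_tier3 and ("T2a" in rules or "T2b" in rules):
            rules.append("T1b")

        if any(r in rules for r in ("T1a", "T1b", "T1c")):
            tier = "1"
        elif any(r in rules for r in ("T2a", "T2b")):
            tier = "2"
        elif is_tier3:
            tier = "3"
        else:
            tier = "high_pcs_unconfirmed"

        rows.append({
            "gene_symbol": gene,
            "tier": tier,
            "rules_fired": ",".join(rules) if rules else "",
            "consensus_direction": consensus,
            "supporting_probes": ";".join(
                f"{r.probe_id}|{r.platform}|{int(r.direction):+d}"
                for r in probes.itertuples()),
        })
    out = pd.DataFrame(rows, columns=["gene_symbol", "tier", "rules_fired",
                                      "consensus_direction", "supporting_probes"])
    return out.sort_values("gene_symbol").reset_index(drop=True)


def tier_gene_sets(assignments: pd.DataFrame) -> dict[str, set[str]]:
    """Tier label -> gene set from an assignment table."""
    return {t: set(sub["gene_symbol"]) for t, sub in assignments.groupby("tier")}


def assign_tier0(tier12_genes, auxiliary_records: pd.DataFrame,
                 top_fraction: float = DEFAULT_TOP_FRACTION) -> set[str]:
    """Tier 0: Tier 1/2 genes also high-PCS in the auxiliary dataset.

    The auxiliary (multi-disease) dataset is scored by the same PCS
    machinery; its top ``top_fraction`` by PCS defines the cross-disease
    confirmation set.
    """
    if len(auxiliary_records) == 0:
        raise ValueError("empty auxiliary record list")
    flagged = select_high_pcs(auxiliary_records, top_fraction)
    aux_genes = set(flagged.loc[flagged["high_pcs"], "gene_symbol"].dropna())
    return set(tier12_genes) & aux_genes


def venn_difference(tier0, tier1, tier2, tier3) -> dict[str, set[str]]:
    """Consecutive tier set differences: Tier 1-0, Tier 2-1, Tier 3-2."""
    return {
        "tier1_minus_0": set(tier1) - set(tier0),
        "tier2_minus_1": set(tier2) - set(tier1),
        "tier3_minus_2": set(tier3) - set(tier2),
    }
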