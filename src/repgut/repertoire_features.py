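"""Repertoire feature panel and group-comparison statistics.

Every categorical (feature, level) pair — V family, J gene, V–J pairing,
isotype, CDR3 charge/length class, plus D family and heavy–light
associations when a paired single-cell table supplies them — becomes one
testable parameter compared between groups with the two-sided 2x2 Fisher
exact test; continuous features (CDR_H3 length, mutation counts) are
compared with Welch's t. Volcano rows report the effect (first group
minus second) against -log10 p with the unadjusted p < 0.05 significance
flag used in repertoire volcano plots, plus a Benjamini–Hochberg column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .repertoire_io import Rearrangement, family_from_name, gene_from_name

logger = logging.getLogger(__name__)

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


def cdr3_charge_class(cdr3_aa: str) -> str:
    """Net-charge class at pH 7: (#R + #K) − (#D + #E); histidine excluded."""
    bad = set(cdr3_aa) - _AA20
    if bad:
        raise ValueError(f"non-amino-acid characters in CDR3: {sorted(bad)}")
    net = sum(cdr3_aa.count(a) for a in "RK") - sum(cdr3_aa.count(a) for a in "DE")
    if net > 0:
        return "positive"
    if net < 0:
        return "negative"
    return "neutral"


def cdr3_length_class(length_aa: int) -> str:
    if length_aa <= 10:
        return "short"
    if length_aa <= 17:
        return "medium"
    return "long"


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Uses the probability-mass rule (sum of hypergeometric probabilities of
    all tables with the same margins no more probable than the observed
    one). An all-zero table yields p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def welch_t(sample_x, sample_y) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: (t, Satterthwaite df, two-sided p)."""
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return np.inf * np.sign(x.mean() - y.mean()), float(len(x) + len(y) - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def benjamini_hochberg(p_values, q: float = 0.05):
    """BH step-up FDR: (adjusted p array, reject mask, largest rejected raw p)."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool), np.nan
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else np.nan
    return adjusted, reject, threshold


# ---------------------------------------------------------------------------
# Feature panel
# ---------------------------------------------------------------------------

CATEGORICAL_FEATURES = [
    "v_family",
    "j_gene",
    "d_family",
    "vj_pairing",
    "heavy_light_family",
    "isotype",
    "cdr3_charge_class",
    "light_cdr3_charge_class",
    "cdr3_length_class",
]
CONTINUOUS_FEATURES = ["cdr3_length_aa", "vh_mutation_count", "light_v_mutation_count"]


@dataclass
class FeaturePanel:
    """Per-sequence feature table for one group's repertoire."""

    group: str
    table: pd.DataFrame

    @classmethod
    def from_rearrangements(cls, records: Iterable[Rearrangement], group: str):
        rows = []
        for r in records:
            if r.v_call is None or r.j_call is None or r.cdr3_aa is None:
                continue
            rows.append(
                {
                    "sequence_id": r.sequence_id,
                    "v_family": r.v_family,
                    "j_gene": gene_from_name(r.j_call),
                    "d_family": r.metadata.get("d_family", np.nan),
                    "vj_pairing": f"{gene_from_name(r.v_call)}|{gene_from_name(r.j_call)}",
                    "heavy_light_family": np.nan,
                    "isotype": r.isotype,
                    "cdr3_charge_class": cdr3_charge_class(r.cdr3_aa),
                    "light_cdr3_charge_class": np.nan,
                    "cdr3_length_class": cdr3_length_class(len(r.cdr3_aa)),
                    "cdr3_length_aa": len(r.cdr3_aa),
                    "vh_mutation_count": r.vh_mutation_count,
                    "light_v_mutation_count": np.nan,
                }
            )
        return cls(group=group, table=pd.DataFrame(rows))

    @classmethod
    def from_single_cell_table(cls, df: pd.DataFrame, group: str):
        """Paired heavy/light single-cell table: expects heavy v_call/j_call/
        cdr3_aa/vh_mutation_count plus light_v_call, light_j_call,
        light_cdr3_aa, light_v_mutation_count and optional d_call, isotype."""
        rows = []
        for rec in df.to_dict("records"):
            heavy_fam = family_from_name(str(rec["v_call"]))
            light_fam = (
                family_from_name(str(rec["light_v_call"]))
                if pd.notna(rec.get("light_v_call"))
                else np.nan
            )
            rows.append(
                {
                    "sequence_id": rec["sequence_id"],
                    "v_family": heavy_fam,
                    "j_gene": gene_from_name(str(rec["j_call"])),
                    "d_family": (
                        family_from_name(str(rec["d_call"]))
                        if pd.notna(rec.get("d_call"))
                        else np.nan
                    ),
                    "vj_pairing": f"{gene_from_name(str(rec['v_call']))}|{gene_from_name(str(rec['j_call']))}",
                    "heavy_light_family": (
                        f"{heavy_fam}|{light_fam}" if pd.notna(light_fam) else np.nan
                    ),
                    "isotype": rec.get("isotype", "unknown"),
                    "cdr3_charge_class": cdr3_charge_class(str(rec["cdr3_aa"])),
                    "light_cdr3_charge_class": (
                        cdr3_charge_class(str(rec["light_cdr3_aa"]))
                        if pd.notna(rec.get("light_cdr3_aa"))
                        else np.nan
                    ),
                    "cdr3_length_class": cdr3_length_class(len(str(rec["cdr3_aa"]))),
                    "cdr3_length_aa": len(str(rec["cdr3_aa"])),
                    "vh_mutation_count": rec.get("vh_mutation_count", np.nan),
                    "light_v_mutation_count": rec.get("light_v_mutation_count", np.nan),
                }
            )
        return cls(group=group, table=pd.DataFrame(rows))

    def categorical_levels(self, feature: str) -> pd.Series:
        return self.table[feature].dropna().value_counts()

    @property
    def n(self) -> int:
        return len(self.table)


@dataclass
class FeatureComparison:
    feature: str
    level: Optional[str]
    test: str  # fisher_2x2 or welch_t
    counts: Optional[tuple]  # (a, b, c, d) for categorical features
    effect: float  # frequency or mean difference, first group minus second
    p_value: float
    bh_adjusted_p: float = np.nan
    significant: bool = False


def compare_repertoires(
    panel_a: FeaturePanel, panel_b: FeaturePanel, alpha: float = 0.05, bh_q: float = 0.05
) -> pd.DataFrame:
    """Test every panel parameter between two groups.

    Returns the volcano table: one row per (feature, level) with effect,
    p, -log10 p, the unadjusted significance flag at ``alpha`` and the
    BH-adjusted p at ``bh_q``.
    """
    comparisons: list[FeatureComparison] = []
    for feature in CATEGORICAL_FEATURES:
        counts_a = panel_a.categorical_levels(feature)
        counts_b = panel_b.categorical_levels(feature)
        n_a, n_b = int(counts_a.sum()), int(counts_b.sum())
        levels = sorted(set(counts_a.index) | set(counts_b.index))
        for level in levels:
            a = int(counts_a.get(level, 0))
            c = int(counts_b.get(level, 0))
            if a == 0 and c == 0:
                logger.info("feature %s level %s absent from both groups; skipped", feature, level)
                continue
            p = fisher_exact_2x2(a, n_a - a, c, n_b - c)
            effect = a / n_a - c / n_b if n_a and n_b else np.nan
            comparisons.append(
                FeatureComparison(
                    feature=feature,
                    level=str(level),
                    test="fisher_2x2",
                    counts=(a, n_a - a, c, n_b - c),
                    effect=effect,
                    p_value=p,
                )
            )
    for feature in CONTINUOUS_FEATURES:
        x = panel_a.table[feature].dropna().to_numpy(dtype=float)
        y = panel_b.table[feature].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            logger.info("continuous feature %s lacks data in a group; skipped", feature)
            continue
        _, _, p = welch_t(x, y)
        comparisons.append(
            FeatureComparison(
                feature=feature,
                level=None,
                test="welch_t",
                counts=None,
                effect=float(x.mean() - y.mean()),
                p_value=p,
            )
        )
    if comparisons:
        adjusted, _, _ = benjamini_hochberg([c.p_value for c in comparisons], q=bh_q)
        for comp, adj in zip(comparisons, adjusted):
            comp.bh_adjusted_p = float(adj)
            comp.significant = comp.p_value < alpha
    return pd.DataFrame(
        {
            "feature": [c.feature for c in comparisons],
            "level": [c.level for c in comparisons],
            "test": [c.test for c in comparisons],
            "effect": [c.effect for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "neg_log10_p": [-np.log10(c.p_value) if c.p_value > 0 else np.inf for c in comparisons],
            "significant": [c.significant for c in comparisons],
            "bh_adjusted_p": [c.bh_adjusted_p for c in comparisons],
        }
    )


def correlation_matrix(variables: pd.DataFrame, bh_q: float = 0.05):
    """Pairwise Pearson r and two-sided p over pairwise-complete
    observations, with a BH mask over all pairs.

    Returns (r matrix, p matrix, long-form table with bh_adjusted_p and
    bh_reject, largest raw p passing BH at ``bh_q``). Constant columns
    yield missing r/p.
    """
    cols = list(variables.columns)
    k = len(cols)
    r_mat = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p_mat = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            pair = variables[[cols[i], cols[j]]].dropna()
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if len(pair) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                r = p = np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, p = stats.pearsonr(x, y)
            r_mat.iloc[i, j] = r_mat.iloc[j, i] = r
            p_mat.iloc[i, j] = p_mat.iloc[j, i] = p
            rows.append({"var_x": cols[i], "var_y": cols[j], "r": r, "p_value": p, "n": len(pair)})
    table = pd.DataFrame(rows)
    tested = table["p_value"].notna()
    table["bh_adjusted_p"] = np.nan
    table["bh_reject"] = False
    threshold = np.nan
    if tested.any():
        adjusted, reject, threshold = benjamini_hochberg(table.loc[tested, "p_value"], q=bh_q)
        table.loc[tested, "bh_adjusted_p"] = adjusted
        table.loc[tested, "bh_reject"] = reject
    return r_mat, p_mat, table, threshold


def iga_igg_ratio(records: Iterable[Rearrangement], group: Optional[str] = None) -> float:
    """count(IGA) / count(IGG) among QC-passed records, optionally of one group."""
    n_iga = n_igg = 0
    for r in records:
        if not r.passes_qc:
            continue
        if group is not None and r.metadata.get("group") != group:
            continue
        if r.isotype == "IGA":
            n_iga += 1
        elif r.isotype == "IGG":
            n_igg += 1
    if n_igg == 0:
        warnings.warn("no IgG records; IgA/IgG ratio is infinite", stacklevel=2)
        return np.inf
    return n_iga / n_igg
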