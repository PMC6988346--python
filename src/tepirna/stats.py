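"""Cross-strain statistics: TE-vs-piRNA family correlations with BH
correction, piRNA variability (cv), insertion-class spectrum comparison
(Fisher's exact test), and expression fold changes at TE insertions."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

MIN_STRAINS = 4  # families observed in fewer strains are not tested


@dataclass
class FamilyMatrix:
    """TE copy numbers and antisense piRNA RPKM, families x strains."""

    copy_number: pd.DataFrame
    pirna_rpkm: pd.DataFrame
    family_class: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.copy_number.index.equals(self.pirna_rpkm.index) or \
                not self.copy_number.columns.equals(self.pirna_rpkm.columns):
            raise ValueError("matrices must share families and strains")


def correlate_families(fm: FamilyMatrix, method: str = "spearman",
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-family correlation between TE copy number and antisense piRNA
    abundance across strains, with Benjamini-Hochberg adjustment over all
    tested families.

    Families with fewer than 4 strains of paired data, or with a constant
    row, are reported with missing rho/P and excluded from the BH family.
    """
    if fm.copy_number.shape[1] < 3:
        raise ValueError("need at least 3 strains")
    rows = []
    for family in fm.copy_number.index:
        x = fm.copy_number.loc[family].astype(float)
        y = fm.pirna_rpkm.loc[family].astype(float)
        ok = x.notna() & y.notna()
        rho = pval = np.nan
        if ok.sum() >= MIN_STRAINS and x[ok].nunique() > 1 \
                and y[ok].nunique() > 1:
            if method == "spearman":
                rho, pval = sps.spearmanr(x[ok], y[ok])
            elif method == "pearson":
                rho, pval = sps.pearsonr(x[ok], y[ok])
            else:
                raise ValueError(f"unknown method {method!r}")
        rows.append(dict(family=family, n=int(ok.sum()), rho=rho, p=pval,
                         family_class=fm.family_class.get(family, "")))
    res = pd.DataFrame(rows).set_index("family")
    tested = res["p"].notna()
    res["p_adj"] = np.nan
    if tested.any():
        res.loc[tested, "p_adj"] = multipletests(
            res.loc[tested, "p"], method="fdr_bh")[1]
    res["significant"] = (res["p_adj"] < alpha) & (res["rho"] > 0)
    return res


def coefficient_of_variation(values: Sequence[float]) -> float:
    """cv = sample sd (ddof=1) / mean; raises on nonpositive mean."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("cv undefined for nonpositive mean")
    if arr.size < 2:
        return 0.0
    return float(arr.std(ddof=1) / mean)


def compare_spectra(occupancy_a: Sequence[int], occupancy_b: Sequence[int],
                    threshold: int = 5):
    """Compare how often two insertion classes segregate in at least
    ``threshold`` strains (2x2 Fisher's exact test, two-sided).

    Returns (table, odds_ratio, p); the table rows are classes A/B and the
    columns are [>= threshold, < threshold] counts.  A degenerate table
    can yield an infinite odds ratio.
    """
    a = np.asarray(occupancy_a)
    b = np.asarray(occupancy_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both classes must be nonempty")
    table = np.array([
        [int((a >= threshold).sum()), int((a < threshold).sum())],
        [int((b >= threshold).sum()), int((b < threshold).sum())],
    ])
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p)


def expression_fold_change(expression: pd.DataFrame,
                           genotype: pd.DataFrame,
                           categories: Mapping | None = None,
                           pseudocount: float = 1.0,
                           reference_category: str | None = None):
    """log2 fold change of gene expression in insertion carriers versus
    non-carriers, with optional per-category distribution comparison.

    ``expression``: genes x strains normalized expression.  ``genotype``:
    rows (insertion_id, gene, strain, carrier) as a DataFrame; every
    insertion needs at least one carrier and one non-carrier strain with
    expression.  ``categories`` maps insertion_id -> category label
    (e.g. CDS/UTR/intron/upstream).  When a non-carrier group mean is
    zero, ``pseudocount`` is added to both means and the row is flagged.

    Returns (per-insertion DataFrame, per-category KS DataFrame or None).
    """
    rows = []
    for ins, grp in genotype.groupby("insertion_id"):
        gene = grp["gene"].iloc[0]
        if gene not in expression.index:
            continue
        expr = expression.loc[gene]
        carriers = grp.loc[grp["carrier"], "strain"]
        noncar = grp.loc[~grp["carrier"].astype(bool), "strain"]
        carriers = [s for s in carriers if s in expr.index]
        noncar = [s for s in noncar if s in expr.index]
        if not carriers or not noncar:
            raise ValueError(
                f"insertion {ins}: needs >= 1 carrier and >= 1 non-carrier")
        mc = float(expr[carriers].mean())
        mn = float(expr[noncar].mean())
        flagged = mn == 0
        if flagged:
            mc += pseudocount
            mn += pseudocount
        rows.append(dict(
            insertion_id=ins, gene=gene,
            log2fc=float(np.log2(mc / mn)),
            carrier_mean=mc, noncarrier_mean=mn,
            pseudocount_applied=flagged,
            category=(categories or {}).get(ins, "")))
    per_ins = pd.DataFrame(rows)
    ks = None
    if categories and not per_ins.empty and reference_category is not None:
        ref = per_ins.loc[per_ins["category"] == reference_category,
                          "log2fc"]
        krows = []
        for cat, grp in per_ins.groupby("category"):
            if cat == reference_category or len(grp) == 0 or len(ref) == 0:
                continue
            stat, p = sps.ks_2samp(grp["log2fc"], ref)
            u_stat, u_p = sps.mannwhitneyu(grp["log2fc"], ref,
                                           alternative="two-sided")
            krows.append(dict(category=cat, n=len(grp), ks_stat=stat,
                              ks_p=p, mwu_p=u_p))
        ks = pd.DataFrame(krows)
    return per_ins, ks
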