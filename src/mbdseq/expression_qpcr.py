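"""qPCR relative quantification (ddCt) and group statistics.

Expression is quantified against a housekeeping reference gene
(default Hprt): dCt = Ct(target) - Ct(reference) per replicate,
ddCt = mean dCt(treated) - mean dCt(control), and the fold change is
2^-ddCt.  Two groups are compared by Student's t-test on replicate
dCt values; more groups by one-way ANOVA with Bonferroni-adjusted
pairwise tests after a significant omnibus.  The methylation-expression
concordance report cross-tabulates promoter methylation status against
expression direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_GENE = "Hprt"
ALPHA = 0.05


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    delta_ct_treated: float
    delta_ct_control: float
    sd_treated: float
    sd_control: float
    delta_delta_ct: float
    fold: float
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """dCt of one measurement: target Ct minus reference-gene Ct."""
    return ct_target - ct_reference


def validate_ct_table(table: pd.DataFrame, reference_gene: str = REFERENCE_GENE) -> None:
    missing = {"sample", "group", "gene", "replicate", "ct"} - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    samples = set(table["sample"])
    with_ref = set(table.loc[table["gene"] == reference_gene, "sample"])
    if samples - with_ref:
        raise ValueError(
            f"missing reference gene '{reference_gene}' for sample(s): "
            f"{sorted(samples - with_ref)}"
        )


def delta_ct_table(
    table: pd.DataFrame, reference_gene: str = REFERENCE_GENE
) -> pd.DataFrame:
    """Per-replicate dCt for every non-reference gene.

    Computed replicate-wise (each sample's target Ct minus that same
    sample's reference Ct) before any averaging, so replicate variance
    is preserved for the group tests.
    """
    validate_ct_table(table, reference_gene)
    ref = (
        table[table["gene"] == reference_gene]
        .set_index("sample")["ct"]
        .rename("ct_ref")
    )
    targets = table[table["gene"] != reference_gene].copy()
    targets = targets.join(ref, on="sample")
    targets["delta_ct"] = targets["ct"] - targets["ct_ref"]
    return targets[["sample", "group", "gene", "replicate", "delta_ct"]]


def fold_change(
    delta_ct_treated: np.ndarray,
    delta_ct_control: np.ndarray,
    gene: str = "",
    welch: bool = False,
) -> FoldChangeResult:
    """ddCt fold change between two replicate dCt vectors.

    ddCt = mean dCt(treated) - mean dCt(control); fold = 2^-ddCt.
    The attached p-value is a two-sided Student's t-test (pooled
    variance unless ``welch``).
    """
    t = np.asarray(delta_ct_treated, dtype=float)
    c = np.asarray(delta_ct_control, dtype=float)
    ddct = float(t.mean() - c.mean())
    p = None
    if len(t) >= 2 and len(c) >= 2:
        p = float(stats.ttest_ind(t, c, equal_var=not welch).pvalue)
    return FoldChangeResult(
        gene=gene,
        delta_ct_treated=float(t.mean()),
        delta_ct_control=float(c.mean()),
        sd_treated=float(t.std(ddof=1)) if len(t) > 1 else float("nan"),
        sd_control=float(c.std(ddof=1)) if len(c) > 1 else float("nan"),
        delta_delta_ct=ddct,
        fold=float(2.0 ** (-ddct)),
        p_value=p,
    )


def analyze_folds(
    table: pd.DataFrame,
    treated: str,
    control: str,
    reference_gene: str = REFERENCE_GENE,
    welch: bool = False,
) -> dict[str, FoldChangeResult]:
    """Fold change per gene between two named groups."""
    dct = delta_ct_table(table, reference_gene)
    out: dict[str, FoldChangeResult] = {}
    for gene, sub in dct.groupby("gene"):
        t = sub.loc[sub["group"] == treated, "delta_ct"].to_numpy()
        c = sub.loc[sub["group"] == control, "delta_ct"].to_numpy()
        if len(t) == 0 or len(c) == 0:
            continue
        out[str(gene)] = fold_change(t, c, gene=str(gene), welch=welch)
    return out


def compare_groups(
    table: pd.DataFrame,
    reference_gene: str = REFERENCE_GENE,
    welch: bool = False,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-gene group statistics on dCt values.

    Two groups: two-sided t-test.  More: one-way ANOVA; when the
    omnibus is significant at ``alpha``, Bonferroni-adjusted pairwise
    t-tests follow.  Returns one row per gene (and per pair for the
    post-hoc comparisons).
    """
    dct = delta_ct_table(table, reference_gene)
    rows = []
    for gene, sub in dct.groupby("gene"):
        groups = {g: s["delta_ct"].to_numpy() for g, s in sub.groupby("group")}
        if any(len(v) < 2 for v in groups.values()):
            small = [g for g, v in groups.items() if len(v) < 2]
            raise ValueError(f"gene {gene}: group(s) {small} have < 2 replicates")
        names = sorted(groups)
        if len(names) == 2:
            res = stats.ttest_ind(
                groups[names[0]], groups[names[1]], equal_var=not welch
            )
            rows.append(
                {
                    "gene": gene,
                    "test": "t-test",
                    "comparison": f"{names[0]} vs {names[1]}",
                    "statistic": float(res.statistic),
                    "p_value": float(res.pvalue),
                    "p_adjusted": float(res.pvalue),
                    "n_per_group": {g: len(groups[g]) for g in names},
                }
            )
        else:
            f = stats.f_oneway(*(groups[g] for g in names))
            rows.append(
                {
                    "gene": gene,
                    "test": "anova",
                    "comparison": "omnibus",
                    "statistic": float(f.statistic),
                    "p_value": float(f.pvalue),
                    "p_adjusted": float(f.pvalue),
                    "n_per_group": {g: len(groups[g]) for g in names},
                }
            )
            if f.pvalue < alpha:
                pairs = list(combinations(names, 2))
                m = len(pairs)
                for g1, g2 in pairs:
                    res = stats.ttest_ind(groups[g1], groups[g2], equal_var=not welch)
                    rows.append(
                        {
                            "gene": gene,
                            "test": "t-test (Bonferroni)",
                            "comparison": f"{g1} vs {g2}",
                            "statistic": float(res.statistic),
                            "p_value": float(res.pvalue),
                            "p_adjusted": min(1.0, float(res.pvalue) * m),
                            "n_per_group": {g: len(groups[g]) for g in (g1, g2)},
                        }
                    )
    return pd.DataFrame(rows)


def concordance_report(
    fold_changes: Mapping[str, FoldChangeResult | float],
    promoter_statuses: Mapping[str, str],
) -> pd.DataFrame:
    """Cross-tabulate promoter methylation status with expression
    direction.

    Concordant: promoter hypomethylation with upregulation (fold > 1)
    or hypermethylation with downregulation (fold < 1).  Genes with
    unchanged/mixed promoters, or present in only one input, are
    unscored.
    """
    genes = sorted(set(fold_changes) | set(promoter_statuses))
    rows = []
    for gene in genes:
        fc = fold_changes.get(gene)
        fold = fc.fold if isinstance(fc, FoldChangeResult) else fc
        status = promoter_statuses.get(gene)
        if fold is None or status is None:
            verdict = "unscored"
        elif status == "hypomethylated_in_b":
            verdict = "concordant" if fold > 1 else "discordant"
        elif status == "hypermethylated_in_b":
            verdict = "concordant" if fold < 1 else "discordant"
        else:
            verdict = "unscored"
        rows.append(
            {
                "gene": gene,
                "status": status,
                "fold": fold,
                "direction": (
                    None if fold is None else ("up" if fold > 1 else "down" if fold < 1 else "flat")
                ),
                "concordance": verdict,
            }
        )
    df = pd.DataFrame(rows)
    scored = df[df["concordance"].isin(["concordant", "discordant"])]
    df.attrs["concordant_fraction"] = (
        float((scored["concordance"] == "concordant").mean()) if len(scored) else float("nan")
    )
    return df
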