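"""Univariate statistics: t-test + fold-change screening, phenotype
correlation matrices, and the shear-force ANOVA summary.

The screening stage flags a protein as dysregulated when BOTH a
two-sided two-sample t-test gives p below the threshold AND the fold
change (ratio of raw class means, class_b / class_a) falls outside the
[lower, upper] band.  The default band (>1.3 up, <0.769 down, with
0.769 ~ 1/1.3) and p < 0.05 with no multiplicity correction follow
common chemometrics screening practice for label-free abundance data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UnivariateResult",
    "ttest_fc_screen",
    "correlate_with_phenotypes",
    "WBSRecord",
    "AnovaResult",
    "wbs_anova",
    "average_dwbs",
]


@dataclass
class UnivariateResult:
    """Per-protein screening table.

    ``table`` columns: ``p_value``, ``fold_change`` (class_b mean over
    class_a mean), ``direction`` (up/down/unchanged by the FC band) and
    ``significant`` (p AND FC rules both met).
    """

    table: pd.DataFrame
    p_threshold: float
    fc_upper: float
    fc_lower: float

    @property
    def significant_proteins(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def ttest_fc_screen(
    matrix: np.ndarray,
    labels: np.ndarray,
    protein_ids=None,
    p_threshold: float = 0.05,
    fc_upper: float = 1.3,
    fc_lower: float = 0.769,
    equal_var: bool = True,
) -> UnivariateResult:
    """Screen proteins by Student's t-test plus a fold-change band.

    Parameters
    ----------
    matrix : array, samples x proteins
        Raw (unscaled) positive abundances.
    labels : array of 0/1
        0 = class_a (reference, e.g. earlier timepoint), 1 = class_b.
    equal_var : bool
        Pooled-variance Student's t-test by default; set False for
        Welch's correction.

    Both FC thresholds are strict inequalities: a protein at exactly
    FC = 1.3 is not called.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    a, b = matrix[labels == 0], matrix[labels == 1]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"each class needs >= 2 samples (got {len(a)} and {len(b)})"
        )
    with np.errstate(invalid="ignore"):
        tstat, p = stats.ttest_ind(b, a, axis=0, equal_var=equal_var)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance columns: no evidence
    fc = b.mean(axis=0) / a.mean(axis=0)
    direction = np.where(fc > fc_upper, "up", np.where(fc < fc_lower, "down", "unchanged"))
    significant = (p < p_threshold) & (direction != "unchanged")
    if protein_ids is None:
        protein_ids = [f"var{i}" for i in range(matrix.shape[1])]
    table = pd.DataFrame(
        {
            "p_value": p,
            "fold_change": fc,
            "direction": direction,
            "significant": significant,
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )
    return UnivariateResult(table, p_threshold, fc_upper, fc_lower)


def correlate_with_phenotypes(
    abundance: pd.DataFrame, phenotypes: pd.DataFrame, p_threshold: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Pearson correlation of every protein with every phenotype variable.

    Rows of both frames are matched on their index (shared samples,
    typically at the biological-sample level).  Returns ``{"r": ...,
    "p": ..., "significant": ...}`` frames of shape proteins x
    phenotypes.  The p-value uses the exact t transform
    ``t = r sqrt(n-2) / sqrt(1-r^2)`` with n-2 degrees of freedom,
    two-sided.  Zero-variance vectors give a missing r with a warning.
    """
    shared = abundance.index.intersection(phenotypes.index)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared samples between abundances and phenotypes, got {len(shared)}"
        )
    X = abundance.loc[shared].to_numpy(dtype=float)
    Y = phenotypes.loc[shared].to_numpy(dtype=float)
    n = len(shared)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    xsd = np.sqrt((Xc**2).sum(axis=0))
    ysd = np.sqrt((Yc**2).sum(axis=0))
    if np.any(xsd == 0) or np.any(ysd == 0):
        warnings.warn("zero-variance column(s): correlations reported as missing")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ Yc) / np.outer(xsd, ysd)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    idx, cols = abundance.columns, phenotypes.columns
    return {
        "r": pd.DataFrame(r, index=idx, columns=cols),
        "p": pd.DataFrame(p, index=idx, columns=cols),
        "significant": pd.DataFrame(p < p_threshold, index=idx, columns=cols),
    }


# ---------------------------------------------------------------------------
# Shear-force (Warner-Bratzler) ANOVA


@dataclass(frozen=True)
class WBSRecord:
    """One shear-force measurement replicate (force in newtons)."""

    animal: str
    gender: str
    day: int
    replicate: int
    value: float


@dataclass
class AnovaResult:
    """Two-way fixed-effects ANOVA of shear force plus tenderization summary.

    ``anova`` has one row per effect (animal, day, animal x day) with F
    and p.  ``dwbs`` holds the per-animal difference of mean shear force
    between the late and early aging day (negative = meat got more
    tender) with its pooled within-animal standard deviation.  ``tukey``
    holds Tukey HSD comparisons for each significant main effect.
    """

    anova: pd.DataFrame
    dwbs: pd.DataFrame
    average_dwbs: float
    tukey: dict[str, pd.DataFrame]


def average_dwbs(per_animal_dwbs) -> float:
    """Mean of per-animal shear-force differences (plain average)."""
    return float(np.mean(np.asarray(per_animal_dwbs, dtype=float)))


def wbs_anova(records: list[WBSRecord], p_threshold: float = 0.05) -> AnovaResult:
    """Two-way ANOVA (animal, aging day, interaction) on replicate shear values.

    Requires >= 2 replicates in every animal x day cell.  When the
    omnibus test for an effect is significant, Tukey HSD comparisons
    are run over that effect's levels (standard HSD is used where the
    sequential "Tukey b" procedure would apply).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        raise ValueError("no records")
    counts = df.groupby(["animal", "day"]).size().unstack()
    if counts.isna().any().any() or (counts < 2).any().any():
        raise ValueError(
            "every animal x day cell needs >= 2 replicates; got\n" + counts.to_string()
        )
    model = smf.ols("value ~ C(animal) * C(day)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    anova = pd.DataFrame(
        {
            "F": [
                table.loc["C(animal)", "F"],
                table.loc["C(day)", "F"],
                table.loc["C(animal):C(day)", "F"],
            ],
            "p_value": [
                table.loc["C(animal)", "PR(>F)"],
                table.loc["C(day)", "PR(>F)"],
                table.loc["C(animal):C(day)", "PR(>F)"],
            ],
        },
        index=["animal", "day", "animal:day"],
    )

    days = sorted(df["day"].unique())
    early, late = days[0], days[-1]
    rows = []
    for animal, sub in df.groupby("animal", sort=False):
        ve = sub.loc[sub["day"] == early, "value"]
        vl = sub.loc[sub["day"] == late, "value"]
        n1, n2 = len(ve), len(vl)
        pooled_sd = np.sqrt(
            ((n1 - 1) * ve.var(ddof=1) + (n2 - 1) * vl.var(ddof=1)) / (n1 + n2 - 2)
        )
        rows.append(
            {
                "animal": animal,
                "gender": sub["gender"].iloc[0],
                "dwbs": vl.mean() - ve.mean(),
                "pooled_sd": pooled_sd,
            }
        )
    dwbs = pd.DataFrame(rows).set_index("animal")

    tukey: dict[str, pd.DataFrame] = {}
    for effect, column in (("animal", "animal"), ("day", "day")):
        if anova.loc[effect, "p_value"] < p_threshold and df[column].nunique() > 1:
            res = pairwise_tukeyhsd(df["value"], df[column].astype(str))
            tukey[effect] = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )

    return AnovaResult(
        anova=anova,
        dwbs=dwbs,
        average_dwbs=average_dwbs(dwbs["dwbs"]),
        tukey=tukey,
    )
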