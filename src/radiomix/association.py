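"""Association statistics linking clusters/features to clinical outcomes.

Cluster labels vs categorical outcomes are tested with the chi-square test of
independence and summarized by Cramér's V. Feature-outcome relationships use
Spearman's rank correlation for ordered outcomes and the proportion of
variance explained by a dummy-coded group regression (one-way ANOVA eta
squared) for unordered ones. Missing clinical values are dropped pairwise, so
each association uses its own complete-case N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "cramers_v_test",
    "spearman_assoc",
    "anova_r2",
    "zscore_table",
    "association_report",
    "SPEARMAN_DISPLAY_THRESHOLD",
    "R2_DISPLAY_THRESHOLD",
]

#: Report filters for the association heat-map tables (full matrices are
#: always computed; these only mark which entries clear the display cut).
SPEARMAN_DISPLAY_THRESHOLD = 0.2
R2_DISPLAY_THRESHOLD = 0.04


def _pairwise_complete(a, b):
    a = pd.Series(list(a)).reset_index(drop=True)
    b = pd.Series(list(b)).reset_index(drop=True)
    keep = a.notna() & b.notna()
    return a[keep], b[keep]


def cramers_v_test(labels, outcome) -> tuple[float, float, int, float]:
    """Chi-square test of independence and Cramér's V for two categoricals.

    V = sqrt(chi2 / (n * (min(r, c) - 1))) on the pairwise-complete
    contingency table, without continuity correction. Raises ``ValueError``
    if either variable has fewer than two observed levels.
    """
    a, b = _pairwise_complete(labels, outcome)
    table = pd.crosstab(a, b).to_numpy()
    r, c = table.shape
    if r < 2 or c < 2:
        raise ValueError("both variables need >= 2 observed levels")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    n = table.sum()
    v = float(np.sqrt(chi2 / (n * (min(r, c) - 1))))
    return float(chi2), float(p), int(dof), v


def spearman_assoc(features: pd.DataFrame, outcome) -> pd.Series:
    """Spearman's rho (midrank ties) of each feature column vs an ordered outcome.

    Constant features (or < 3 complete pairs) are reported as NaN.
    """
    outcome = pd.Series(list(outcome), index=features.index)
    out = {}
    for col in features.columns:
        x, y = _pairwise_complete(features[col], outcome)
        if len(x) < 3 or x.nunique() < 2 or y.nunique() < 2:
            out[col] = np.nan
            continue
        rho, _ = stats.spearmanr(x, y)
        out[col] = float(rho)
    return pd.Series(out, name="spearman_rho")


def anova_r2(feature, groups) -> float:
    """Proportion of a feature's variance explained by a categorical grouping.

    Equals the R-squared of a least-squares fit on dummy-coded groups:
    between-group SS / total SS. Zero total variance yields 0 with a warning.
    """
    x, g = _pairwise_complete(feature, groups)
    if g.nunique() < 2:
        raise ValueError("need >= 2 groups with observations")
    x = x.to_numpy(dtype=np.float64)
    grand = x.mean()
    sst = float(((x - grand) ** 2).sum())
    if sst == 0:
        logger.warning("zero total variance; r2 reported as 0")
        return 0.0
    ssb = 0.0
    for _, members in x_groupby(x, g):
        ssb += members.size * (members.mean() - grand) ** 2
    return float(ssb / sst)


def x_groupby(x: np.ndarray, g: pd.Series):
    for level in g.unique():
        yield level, x[(g == level).to_numpy()]


def anova_r2_table(features: pd.DataFrame, outcome) -> pd.Series:
    outcome = pd.Series(list(outcome), index=features.index)
    return pd.Series(
        {c: anova_r2(features[c], outcome) for c in features.columns}, name="r2_mreg"
    )


@dataclass(frozen=True)
class ZScaler:
    """Column means/SDs (population) fitted on one table, reusable on another."""

    mean: pd.Series
    sd: pd.Series
    constant_columns: tuple[str, ...]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy().astype(float)
        for col in table.columns:
            if col in self.constant_columns:
                continue
            out[col] = (table[col] - self.mean[col]) / self.sd[col]
        return out


def zscore_table(features: pd.DataFrame) -> tuple[pd.DataFrame, ZScaler]:
    """Standardize each column to mean 0, SD 1 (population SD, divisor n).

    Constant columns are flagged, left unscaled, and warned about. The
    returned scaler reapplies the fitted parameters to held-out rows.
    """
    mean = features.mean()
    sd = features.std(ddof=0)
    constant = tuple(features.columns[(sd == 0) | sd.isna()])
    if constant:
        logger.warning("constant columns left unscaled: %s", list(constant))
    scaler = ZScaler(mean=mean, sd=sd, constant_columns=constant)
    return scaler.transform(features), scaler


def association_report(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    cluster_labels,
    ordered_outcomes: dict[str, str],
    unordered_outcomes: dict[str, str],
) -> dict:
    """Cluster-outcome chi-square/V plus feature-outcome rho and r2 matrices.

    ``ordered_outcomes`` / ``unordered_outcomes`` map report names to clinical
    columns. Returns a dict with the cluster-association table (the shape of
    a per-outcome chi2/p/dof/V/N summary) and the two feature matrices.
    """
    labels = pd.Series(np.asarray(cluster_labels), index=clinical.index)
    cluster_rows = []
    for name, col in {**ordered_outcomes, **unordered_outcomes}.items():
        a, b = _pairwise_complete(labels, clinical[col])
        try:
            chi2, p, dof, v = cramers_v_test(a, b)
        except ValueError:
            logger.warning("outcome %s has < 2 levels; skipped", name)
            continue
        cluster_rows.append(
            {"outcome": name, "n": len(a), "chi2": chi2, "p": p, "dof": dof, "cramers_v": v}
        )
    rho = pd.DataFrame(
        {name: spearman_assoc(features, clinical[col]) for name, col in ordered_outcomes.items()}
    )
    r2 = pd.DataFrame(
        {name: anova_r2_table(features, clinical[col]) for name, col in unordered_outcomes.items()}
    )
    return {
        "cluster_association": pd.DataFrame(cluster_rows),
        "spearman_rho": rho,
        "r2_mreg": r2,
        "rho_display_mask": rho.abs() > SPEARMAN_DISPLAY_THRESHOLD,
        "r2_display_mask": r2 > R2_DISPLAY_THRESHOLD,
    }
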