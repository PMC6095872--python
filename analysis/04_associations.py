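#!/usr/bin/env python
"""Associate cluster labels and individual features with clinical outcomes.

For every clinical variable, the clustering setting with the highest Cramér's
V is reported together with the chi-square test of independence (the shape of
a per-outcome association summary table). Feature-level associations are
Spearman's rho for ordered outcomes and ANOVA variance explained for
unordered ones. Writes results/assoc/.
"""

import json
from pathlib import Path

import pandas as pd

from radiomix.association import (
    R2_DISPLAY_THRESHOLD,
    SPEARMAN_DISPLAY_THRESHOLD,
    anova_r2_table,
    cramers_v_test,
    spearman_assoc,
    zscore_table,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
ORDERED = ["grade", "t_stage", "n_stage", "overall_stage"]
UNORDERED = ["subtype", "recurrence_status", "recurrence_site", "histology"]


def main():
    features = pd.read_csv(ROOT / "features.csv", index_col=0)
    clinical = pd.read_csv(ROOT / "cohort" / "clinical.csv", index_col=0).loc[features.index]
    labels = pd.read_csv(ROOT / "cluster" / "labels.csv", index_col=0)
    z, _ = zscore_table(features)
    out = ROOT / "assoc"
    out.mkdir(exist_ok=True)

    rows = []
    for outcome in ORDERED + UNORDERED:
        if clinical[outcome].dropna().nunique() < 2:
            continue
        best = None
        for algorithm in labels.columns:
            chi2, p, dof, v = cramers_v_test(labels[algorithm], clinical[outcome])
            if best is None or v > best["cramers_v"]:
                best = {"outcome": outcome, "algorithm": algorithm,
                        "n": int(clinical[outcome].notna().sum()),
                        "chi2": round(chi2, 2), "p": float(f"{p:.3g}"),
                        "dof": dof, "cramers_v": round(v, 3)}
        rows.append(best)
        mark = "*" if best["p"] < 0.05 else " "
        print(f"{best['outcome']:>18}: best {best['algorithm']:>7}, "
              f"V={best['cramers_v']:.2f}, p={best['p']:.2g}{mark}")
    pd.DataFrame(rows).to_csv(out / "cluster_association.csv", index=False)

    rho = pd.DataFrame({o: spearman_assoc(z, clinical[o]) for o in ORDERED})
    r2 = pd.DataFrame({o: anova_r2_table(z, clinical[o]) for o in UNORDERED
                       if clinical[o].dropna().nunique() >= 2})
    rho.to_csv(out / "spearman_rho.csv")
    r2.to_csv(out / "r2_mreg.csv")
    n_rho = int((rho.abs() > SPEARMAN_DISPLAY_THRESHOLD).any(axis=1).sum())
    n_r2 = int((r2 > R2_DISPLAY_THRESHOLD).any(axis=1).sum())
    print(f"{n_rho} features pass |rho| > {SPEARMAN_DISPLAY_THRESHOLD}; "
          f"{n_r2} pass r2 > {R2_DISPLAY_THRESHOLD}")
    top = rho["grade"].abs().sort_values(ascending=False).head(5)
    print("strongest grade correlates:", {k: round(v, 2) for k, v in top.items()})


if __name__ == "__main__":
    main()
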