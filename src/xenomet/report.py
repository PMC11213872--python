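"""Aggregate stage outputs into human-readable run reports.

``model_summary_table`` mirrors the conventional chemometrics report layout
(Components, R2X(cum), R2Y(cum), Q2(cum), CV-ANOVA p per pairwise
comparison); ``discriminant_table`` lists selected features with m/z,
retention time, ion, VIP, p-value and direction of change.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .featuretable import FeatureTable
from .oplsda import OplsDaResults
from .stats import DiscriminantFeature


def model_summary_table(results: dict[str, OplsDaResults]) -> pd.DataFrame:
    """One row per pairwise comparison, named by the dict key."""
    rows = []
    for name, res in results.items():
        rows.append(
            {
                "Comparison": name,
                "Components": res.components,
                "R2X(cum)": round(res.r2x, 3),
                "R2Y(cum)": round(res.r2y, 3),
                "Q2(cum)": round(res.q2, 3),
                "CV-ANOVA P-value": (
                    "Not significant" if not res.significant
                    else f"{res.cv_anova_pvalue:.3g}"
                ),
            }
        )
    return pd.DataFrame(rows)


def discriminant_table(
    selected: dict[str, list[DiscriminantFeature]],
    table: FeatureTable | None = None,
) -> pd.DataFrame:
    """Selected features per comparison, decorated with feature metadata."""
    rows = []
    for name, feats in selected.items():
        for f in feats:
            row = {
                "Comparison": name,
                "Feature": f.feature_id,
                "VIP": round(f.vip, 2),
                "p(corr)": round(f.pcorr, 2),
                "P-value": f"{f.pvalue:.3g}",
                "Direction": {"up": "increase", "down": "decrease"}.get(
                    f.direction, f.direction
                ),
            }
            if table is not None and f.feature_id in table.feature_meta.index:
                meta = table.feature_meta.loc[f.feature_id]
                row["m/z"] = round(float(meta["mz"]), 4)
                row["t_R (min)"] = round(float(meta["rt"]), 2)
                row["Ion"] = meta.get("ion", "")
            rows.append(row)
    return pd.DataFrame(rows)


def write_markdown_report(
    path: str | Path,
    models: pd.DataFrame,
    discriminants: pd.DataFrame,
    stage_counts: list[dict] | None = None,
    extra: dict | None = None,
) -> None:
    parts = ["# Differential metabolomics run report", ""]
    if stage_counts:
        parts += ["## Feature-table processing", ""]
        parts.append(
            pd.DataFrame(
                [{"stage": s["stage"], "features": s["n_features"],
                  "samples": s["n_samples"]} for s in stage_counts]
            ).to_markdown(index=False)
        )
        parts.append("")
    parts += ["## Pairwise OPLS-DA models", "",
              models.to_markdown(index=False), ""]
    parts += ["## Discriminant features", ""]
    if discriminants.empty:
        parts.append("(none selected)")
    else:
        parts.append(discriminants.to_markdown(index=False))
    parts.append("")
    if extra:
        parts += ["## Additional results", ""]
        for title, frame in extra.items():
            parts += [f"### {title}", ""]
            if isinstance(frame, pd.DataFrame):
                parts.append(frame.to_markdown(index=False) if not frame.empty
                             else "(empty)")
            else:
                parts.append(str(frame))
            parts.append("")
    Path(path).write_text("\n".join(parts))
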