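"""Paper-style report tables and figures for a built cohort."""

from __future__ import annotations

import hashlib
import json
import sys
from datetime import datetime, timezone

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "characteristics_table",
    "score_distribution_table",
    "roc_figure",
    "provenance_record",
]


def _median_iqr(x) -> str:
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.0f} [{q1:.0f};{q3:.0f}]"


def characteristics_table(included: pd.DataFrame, excluded: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics, included vs excluded, with significance tests.

    Continuous rows use the two-sided rank-sum test, categorical rows the
    chi-square test.  Expects ``age_years``, ``sex``, ``died_7d`` and
    ``hospital`` columns in both frames.
    """
    rows = []

    def cat_row(label, inc_mask, exc_mask):
        a, b = int(inc_mask.sum()), int(exc_mask.sum())
        table = np.array(
            [[a, len(inc_mask) - a], [b, len(exc_mask) - b]], dtype=float
        )
        p = np.nan
        if len(exc_mask) and table.min() >= 0 and (table.sum(axis=1) > 0).all():
            try:
                p = stats.chi2_contingency(table)[1]
            except ValueError:
                p = np.nan
        rows.append(
            {
                "characteristic": label,
                "included": f"{a} ({100 * a / max(len(inc_mask), 1):.0f}%)",
                "excluded": f"{b} ({100 * b / max(len(exc_mask), 1):.0f}%)" if len(exc_mask) else "-",
                "p_value": p,
            }
        )

    rows.append(
        {
            "characteristic": "n",
            "included": str(len(included)),
            "excluded": str(len(excluded)),
            "p_value": np.nan,
        }
    )
    p_age = np.nan
    if len(excluded):
        p_age = stats.mannwhitneyu(
            included["age_years"], excluded["age_years"], alternative="two-sided"
        ).pvalue
    rows.append(
        {
            "characteristic": "median age [IQR]",
            "included": _median_iqr(included["age_years"]),
            "excluded": _median_iqr(excluded["age_years"]) if len(excluded) else "-",
            "p_value": p_age,
        }
    )
    cat_row(
        "female n (%)",
        included["sex"].eq("female"),
        excluded["sex"].eq("female") if len(excluded) else pd.Series(dtype=bool),
    )
    if "died_7d" in excluded.columns and len(excluded):
        cat_row("7-day mortality n (%)", included["died_7d"], excluded["died_7d"])
    for hosp in sorted(included["hospital"].unique()):
        cat_row(
            f"hospital {hosp}",
            included["hospital"].eq(hosp),
            excluded["hospital"].eq(hosp) if len(excluded) else pd.Series(dtype=bool),
        )
    return pd.DataFrame(rows)


def score_distribution_table(cohort: pd.DataFrame, score_names) -> pd.DataFrame:
    """Counts and observed 7-day mortality at each score value, per system."""
    rows = []
    for name in score_names:
        grp = cohort.groupby(name)["died_7d"]
        for value, sub in grp:
            rows.append(
                {
                    "system": name,
                    "score": int(value),
                    "n": int(sub.size),
                    "deaths": int(sub.sum()),
                    "mortality": float(sub.mean()),
                }
            )
    return pd.DataFrame(rows)


def roc_figure(curves: dict, path) -> None:
    """Overlaid ROC curves (one per score system) saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    for name, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{name} (AUROC {curve.area():.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def provenance_record(config: dict, seed, extra: dict | None = None) -> dict:
    """Machine-readable record sufficient to reproduce deterministic outputs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    rec = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "seed": seed,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "generated_at": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        rec.update(extra)
    return rec
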