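"""Natural-variation summaries and the genotype x culture variance
decomposition.

The decomposition is a two-way crossed fixed-effects ANOVA on
replicate-level data (genotype entered first, then culture, then their
interaction), with each term's *sequential* sum of squares expressed as a
percentage of the total sum of squares.  Sequential SS makes the four
percentages (genotype, culture, interaction, residual) sum to exactly 100.
Unbalanced designs run through the same decomposition; a warning is issued
when cell counts are more than 10% imbalanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["VarianceComponents", "variance_components", "trait_summary"]


@dataclass
class VarianceComponents:
    """Percent of total variation per source; entries sum to 100."""

    genotype_pct: float
    culture_pct: float
    interaction_pct: float
    residual_pct: float

    def __post_init__(self):
        parts = (
            self.genotype_pct,
            self.culture_pct,
            self.interaction_pct,
            self.residual_pct,
        )
        if any(p < -1e-9 for p in parts):
            raise ValueError("variance components must be >= 0")
        if abs(sum(parts) - 100.0) > 1e-6:
            raise ValueError("components must sum to 100")

    def as_dict(self) -> dict:
        return {
            "genotype_pct": self.genotype_pct,
            "culture_pct": self.culture_pct,
            "interaction_pct": self.interaction_pct,
            "residual_pct": self.residual_pct,
        }


def variance_components(values: pd.DataFrame) -> VarianceComponents:
    """Two-way fixed-effects decomposition of replicate-level trait values.

    ``values`` needs columns ``genotype``, ``culture``, ``value`` (one row
    per replicate).  Requires >= 2 genotypes and >= 2 cultures; the design
    may be unbalanced.  Raises when a term has no degrees of freedom (e.g.
    no replication leaves the interaction saturated with zero residual df).
    """
    df = values.copy()
    for col in ("genotype", "culture", "value"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    df["genotype"] = df["genotype"].astype(str)
    df["culture"] = df["culture"].astype(str)
    n_g = df["genotype"].nunique()
    n_c = df["culture"].nunique()
    if n_g < 2 or n_c < 2:
        raise ValueError("need >= 2 genotypes and >= 2 cultures")
    cells = df.groupby(["genotype", "culture"]).size()
    if len(cells) < n_g * n_c:
        raise ValueError("interaction term has no df: empty genotype x culture cells")
    residual_df = len(df) - n_g * n_c
    if residual_df <= 0:
        raise ValueError("residual term has no df: add replicates")
    if cells.max() > 1.1 * cells.min():
        warnings.warn("genotype x culture design imbalance exceeds 10%")
    model = smf.ols("value ~ C(genotype) + C(culture) + C(genotype):C(culture)", df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    ss = table["sum_sq"]
    total = float(ss.sum())
    if total == 0:
        raise ValueError("zero total variation")
    pct = 100.0 * ss / total
    return VarianceComponents(
        genotype_pct=float(pct["C(genotype)"]),
        culture_pct=float(pct["C(culture)"]),
        interaction_pct=float(pct["C(genotype):C(culture)"]),
        residual_pct=float(pct["Residual"]),
    )


def trait_summary(values: pd.DataFrame, n_bins: int = 10) -> dict:
    """Population summary of a trait over genotype means.

    ``values`` needs columns ``genotype`` and ``value`` (replicate level).
    Genotype means are computed first; the population mean/min/max/SD and
    histogram bins are then taken over those means, so each genotype counts
    once regardless of its replicate number.
    """
    if "genotype" not in values.columns or "value" not in values.columns:
        raise ValueError("need columns 'genotype' and 'value'")
    if len(values) < 1:
        raise ValueError("empty table")
    means = values.groupby("genotype")["value"].mean()
    counts, edges = np.histogram(means.to_numpy(), bins=n_bins)
    return {
        "n_genotypes": int(means.size),
        "mean": float(means.mean()),
        "min": float(means.min()),
        "max": float(means.max()),
        "sd": float(means.std(ddof=1)) if means.size > 1 else 0.0,
        "hist_counts": counts.tolist(),
        "hist_edges": edges.tolist(),
        "genotype_means": means,
    }
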