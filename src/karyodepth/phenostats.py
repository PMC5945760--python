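"""Trait comparisons between euploid and aneuploid plants.

Two layers, matching the two categories of aneuploidy-associated
phenotypes:

* :func:`compare_euploid_aneuploid` — per-trait two-sample t tests of
  all aneuploids against all euploids, detecting *general* effects shared
  across karyotypes;
* :func:`karyotype_association` — a per-(karyotype, trait) screen for
  *chromosome-specific* effects: each karyotype group with enough
  members is compared against the euploid group through a linear model
  with cross direction as a fixed covariate, with Benjamini–Hochberg
  adjustment across all tested pairs.  This is a deliberately plain
  fixed-covariate substitute for a full mixed-model association scan; it
  shares the group-size filter (≥ 3 members) but not the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TraitMatrix",
    "compare_euploid_aneuploid",
    "karyotype_association",
]

logger = logging.getLogger(__name__)


@dataclass
class TraitMatrix:
    """Individuals × traits values plus per-individual aneuploidy metadata.

    ``traits`` must be numeric, indexed by individual id;
    ``karyotype_label`` is the karyotype string ("WT" for euploids);
    ``cross_direction`` holds the reciprocal-cross origin of each plant.
    """

    traits: pd.DataFrame
    aneuploid: pd.Series  # bool per individual
    karyotype_label: pd.Series
    cross_direction: pd.Series

    def __post_init__(self) -> None:
        idx = self.traits.index
        for name, s in (
            ("aneuploid", self.aneuploid),
            ("karyotype_label", self.karyotype_label),
            ("cross_direction", self.cross_direction),
        ):
            if not s.index.equals(idx):
                raise ValueError(f"{name} index does not match traits index")
        if self.traits.isna().all().any():
            raise ValueError("trait matrix contains an all-missing trait")
        if self.aneuploid.isna().any():
            raise ValueError("aneuploidy status must be known for all individuals")

    @classmethod
    def from_population(cls, traits: pd.DataFrame, truth, cross_direction) -> "TraitMatrix":
        """Build from a simulated population's trait table and truth map."""
        from .karyotype import format_karyotype

        df = traits.set_index("individual_id")
        ids = df.index
        return cls(
            traits=df,
            aneuploid=pd.Series(
                [not truth[i].is_euploid for i in ids], index=ids, dtype=bool
            ),
            karyotype_label=pd.Series(
                [format_karyotype(truth[i]) for i in ids], index=ids
            ),
            cross_direction=pd.Series([cross_direction[i] for i in ids], index=ids),
        )


def compare_euploid_aneuploid(
    tm: TraitMatrix, alpha: float = 0.05, welch: bool = False
) -> pd.DataFrame:
    """Per-trait t test of aneuploid vs euploid group means.

    Pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption.  Traits with fewer than two observations
    in either group are skipped with a warning.  Returns one row per
    tested trait with group means, t, two-sided p, the direction of the
    aneuploid mean relative to the euploid mean, and a significance flag
    at ``alpha``.
    """
    rows = []
    for trait in tm.traits.columns:
        x = tm.traits.loc[~tm.aneuploid, trait].dropna()
        y = tm.traits.loc[tm.aneuploid, trait].dropna()
        if len(x) < 2 or len(y) < 2:
            logger.warning("trait %s skipped: fewer than 2 observations per group", trait)
            continue
        res = stats.ttest_ind(y, x, equal_var=not welch)
        diff = y.mean() - x.mean()
        rows.append(
            {
                "trait": trait,
                "mean_euploid": float(x.mean()),
                "mean_aneuploid": float(y.mean()),
                "t": float(res.statistic),
                "p": float(res.pvalue),
                "direction": "lower" if diff < 0 else "higher" if diff > 0 else "equal",
                "significant": bool(res.pvalue < alpha),
            }
        )
    return pd.DataFrame(rows)


def karyotype_association(
    tm: TraitMatrix, min_group: int = 3, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-(karyotype, trait) association screen against the euploid group.

    For every aneuploid karyotype with at least ``min_group`` members,
    each trait is regressed on a group indicator plus cross direction
    (fixed covariate) over the pooled euploid + group individuals.  The
    indicator's two-sided p-values are Benjamini–Hochberg adjusted across
    all (karyotype, trait) pairs tested.
    """
    euploid_mask = ~tm.aneuploid
    groups = (
        tm.karyotype_label[tm.aneuploid]
        .value_counts()
        .loc[lambda s: s >= min_group]
        .index.tolist()
    )
    if not groups:
        logger.warning("no karyotype group reaches min_group=%d", min_group)
        return pd.DataFrame(
            columns=["karyotype", "trait", "effect", "p", "p_adjusted", "significant"]
        )

    rows = []
    for label in groups:
        in_group = tm.karyotype_label == label
        subset = euploid_mask | in_group
        indicator = in_group[subset].astype(float)
        # Cross direction enters as a 0/1 fixed covariate (dropped if the
        # subset happens to be single-direction).
        directions = tm.cross_direction[subset]
        X = pd.DataFrame({"group": indicator})
        if directions.nunique() > 1:
            X["cross"] = (directions == directions.unique()[0]).astype(float)
        X = sm.add_constant(X)
        for trait in tm.traits.columns:
            y = tm.traits.loc[subset, trait]
            ok = y.notna()
            if indicator[ok].sum() < min_group or (1 - indicator[ok]).sum() < 2:
                continue
            fit = sm.OLS(y[ok], X[ok]).fit()
            rows.append(
                {
                    "karyotype": label,
                    "trait": trait,
                    "effect": float(fit.params["group"]),
                    "p": float(fit.pvalues["group"]),
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        result["p_adjusted"] = []
        result["significant"] = []
        return result
    reject, p_adj, _, _ = multipletests(result["p"], alpha=alpha, method="fdr_bh")
    result["p_adjusted"] = p_adj
    result["significant"] = reject
    return result
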