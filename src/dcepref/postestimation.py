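"""From estimates to headline outputs: attribute importance, care-model
ranking and split-sample subgroup comparisons.

The range method scores each attribute by the spread of its level
coefficients (reference level included at 0) as a share of the total spread.
Utility scores V = constant + sum(indicator * coefficient) rank every
full-factorial profile; the top-ranked profile is the preferred care model.
Subgroup analysis refits the mixed logit per stratum and compares
coefficients with independent-samples Wald z tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .dataset import ChoiceDataset
from .scheme import AttributeScheme, Profile

__all__ = [
    "UtilityEquation",
    "relative_importance",
    "importance_from_ranges",
    "utility_score",
    "rank_profiles",
    "subgroup_analysis",
    "SubgroupResult",
]


@dataclass(frozen=True)
class UtilityEquation:
    """Linear utility: constant plus one coefficient per indicator column."""

    constant: float
    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = [self.constant, *self.coefficients.values()]
        if not np.isfinite(vals).all():
            raise ValueError("utility equation must be finite")


def _level_coefficients(
    scheme: AttributeScheme, eq: UtilityEquation
) -> dict[str, dict[str, float]]:
    """Per attribute: level -> coefficient, reference included at 0."""
    out: dict[str, dict[str, float]] = {}
    for attr in scheme.attributes:
        coefs = {attr.reference: 0.0}
        for level in attr.nonreference_levels:
            col = attr.column(level)
            if col not in eq.coefficients:
                raise KeyError(f"equation is missing coefficient for column {col!r}")
            coefs[level] = float(eq.coefficients[col])
        out[attr.name] = coefs
    return out


def importance_from_ranges(
    level_coefficients: Mapping[str, Mapping[str, float]]
) -> pd.DataFrame:
    """Range-method relative importance from per-attribute level coefficients.

    range_k = max - min over the attribute's level coefficients (the
    reference must be present at 0); importance_k = 100 range_k / sum ranges.
    Returns a frame indexed by attribute with columns ``range`` and
    ``importance`` (percent, full precision; round to 1 decimal for display).
    """
    ranges = {
        name: max(coefs.values()) - min(coefs.values())
        for name, coefs in level_coefficients.items()
    }
    total = sum(ranges.values())
    if total == 0:
        raise ValueError("all attribute ranges are zero: relative importance undefined")
    return pd.DataFrame(
        {
            "range": pd.Series(ranges),
            "importance": pd.Series({k: 100.0 * v / total for k, v in ranges.items()}),
        }
    )


def relative_importance(scheme: AttributeScheme, eq: UtilityEquation) -> pd.DataFrame:
    """Range-method importance of each attribute under an estimated equation."""
    return importance_from_ranges(_level_coefficients(scheme, eq))


def utility_score(profile: Profile, eq: UtilityEquation, scheme: AttributeScheme) -> float:
    """V = constant + sum of the profile's indicator coefficients."""
    scheme.validate_profile(profile)
    v = eq.constant
    for attr, level in zip(scheme.attributes, profile.levels):
        if level != attr.reference:
            v += float(eq.coefficients[attr.column(level)])
    return v


def rank_profiles(scheme: AttributeScheme, eq: UtilityEquation) -> pd.DataFrame:
    """Score and rank every full-factorial profile (18 for the study scheme).

    Sorted by descending utility with dense ranks (exact ties share a rank);
    ties break deterministically by the lexicographic enumeration order.
    Columns: profile (label), one column per attribute, v_score, rank.
    """
    rows = []
    for i, profile in enumerate(scheme.full_factorial()):
        rows.append(
            {
                "profile": profile.label(),
                **{a.name: l for a, l in zip(scheme.attributes, profile.levels)},
                "v_score": utility_score(profile, eq, scheme),
                "_order": i,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["v_score", "_order"], ascending=[False, True], kind="stable"
    )
    df["rank"] = df["v_score"].rank(method="dense", ascending=False).astype(int)
    return df.drop(columns="_order").reset_index(drop=True)


@dataclass
class SubgroupResult:
    """Per-stratum mixed-logit fits and between-stratum coefficient tests.

    ``difference_tests`` has one row per compared mean coefficient with the
    Wald statistic z = (b1 - b2) / sqrt(se1^2 + se2^2) and its two-sided
    normal p-value.  ``n_excluded`` counts rows dropped for a missing
    covariate value.
    """

    covariate: str
    strata: tuple[str, str]
    results: dict
    importance: dict
    difference_tests: pd.DataFrame
    n_obs: dict
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "strata": list(self.strata),
            "results": {k: v.to_dict() for k, v in self.results.items()},
            "importance": {
                k: v["importance"].round(1).to_dict() for k, v in self.importance.items()
            },
            "difference_tests": self.difference_tests.to_dict(orient="records"),
            "n_obs": self.n_obs,
            "n_excluded": self.n_excluded,
        }


def subgroup_analysis(
    dataset: ChoiceDataset,
    covariate: str,
    estimator=None,
    **fit_kwargs,
) -> SubgroupResult:
    """Split-sample comparison of preferences across a binary covariate.

    Fits the mixed logit independently in each stratum (rows with a missing
    covariate are excluded and counted), derives per-stratum range-method
    importance from the attribute-level mean coefficients, and tests each
    attribute-level mean for a between-stratum difference.  If either
    stratum's fit does not converge the tests are suppressed (empty frame).
    """
    from .estimators import MixedLogit  # local import to avoid a cycle

    if covariate not in dataset.df.columns:
        raise ValueError(f"covariate {covariate!r} not in dataset")
    col = dataset.df[covariate]
    present = col.notna() & (col != "")
    strata = sorted(col[present].unique())
    if len(strata) != 2:
        raise ValueError(
            f"covariate {covariate!r} must have exactly 2 observed strata, found {strata}"
        )
    n_excluded = int((~present).sum())

    results, importance, n_obs = {}, {}, {}
    for s in strata:
        sub = dataset.subset(present & (col == s))
        est = (MixedLogit(**fit_kwargs) if estimator is None else estimator).fit(sub)
        results[s] = est.result_
        n_obs[s] = est.n_obs_
        eq = UtilityEquation(
            constant=float(est.mu_.get("asc", 0.0)),
            coefficients={c: float(est.mu_[c]) for c in est.spec_.random},
        )
        importance[s] = relative_importance(dataset.scheme, eq)

    r1, r2 = (results[s] for s in strata)
    ok = r1.converged and r2.converged
    rows = []
    if ok:
        t1 = r1.table.set_index("name")
        t2 = r2.table.set_index("name")
        shared = [
            n
            for n in t1.index
            if n in t2.index and t1.loc[n, "kind"] == "mean" and n != "asc"
        ]
        for name in shared:
            b1, se1 = t1.loc[name, ["estimate", "se"]]
            b2, se2 = t2.loc[name, ["estimate", "se"]]
            z = (b1 - b2) / np.sqrt(se1**2 + se2**2)
            rows.append(
                {
                    "name": name,
                    "b1": b1,
                    "b2": b2,
                    "z": z,
                    "p": 2 * ndtr(-abs(z)),
                }
            )
    tests = pd.DataFrame(rows, columns=["name", "b1", "b2", "z", "p"])
    return SubgroupResult(
        covariate=covariate,
        strata=tuple(strata),
        results=results,
        importance=importance,
        difference_tests=tests,
        n_obs=n_obs,
        n_excluded=n_excluded,
    )
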