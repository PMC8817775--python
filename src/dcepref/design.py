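"""Choice-set designs: construction, evaluation and the Orme sample-size rule.

A design is an ordered list of choice tasks; each task pairs two distinct
designed profiles and always carries an opt-out ("neither") alternative whose
utility is normalized to zero.  Design quality is summarized by D-efficiency
of the multinomial-logit information matrix at a coefficient prior (zero by
default, the utility-neutral case), plus level-balance and attribute-overlap
diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .scheme import AttributeScheme, Profile, study_scheme

__all__ = [
    "ChoiceTask",
    "Design",
    "DesignMetrics",
    "SampleSizeInputs",
    "DegenerateDesignError",
    "orme_sample_size",
    "build_design_matrix",
    "information_matrix",
    "d_efficiency",
    "search_efficient_design",
    "write_design_csv",
    "read_design_csv",
    "study_design",
]

#: Alternative-specific-constant column: 1 for designed alternatives, 0 for opt-out.
ASC_COLUMN = "asc"

#: Per-task information an ideal balanced orthogonal dummy column attains.
#: A 0/1 column over 3 alternatives under uniform probabilities has variance
#: m - m^2 with m the column mean; the maximum over m in {0, 1/3, 2/3, 1} is 2/9.
IDEAL_TASK_INFO = 2.0 / 9.0


class DegenerateDesignError(ValueError):
    """Raised when a design's information matrix is singular."""


@dataclass(frozen=True)
class ChoiceTask:
    """Two distinct designed profiles plus an always-present opt-out."""

    alternatives: tuple[Profile, ...]
    has_optout: bool = True

    def __post_init__(self) -> None:
        if len(self.alternatives) < 2:
            raise ValueError("a choice task needs at least 2 designed alternatives")
        if len(set(self.alternatives)) != len(self.alternatives):
            raise ValueError("within-task duplicate alternatives are not allowed")

    @property
    def n_alternatives(self) -> int:
        """Rows this task contributes in long format (including opt-out)."""
        return len(self.alternatives) + (1 if self.has_optout else 0)


@dataclass(frozen=True)
class Design:
    tasks: tuple[ChoiceTask, ...]
    scheme: AttributeScheme

    def __post_init__(self) -> None:
        if not self.tasks:
            raise ValueError("a design needs at least one task")
        for task in self.tasks:
            for p in task.alternatives:
                self.scheme.validate_profile(p)

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def n_designed_alternatives(self) -> int:
        return len(self.tasks[0].alternatives)


@dataclass(frozen=True)
class DesignMetrics:
    d_efficiency: float
    d_error: float
    level_balance: dict[str, dict[str, int]]
    overlap_count: int
    k_params: int

    def to_dict(self) -> dict:
        return {
            "d_efficiency": self.d_efficiency,
            "d_error": self.d_error,
            "level_balance": self.level_balance,
            "overlap_count": self.overlap_count,
            "k_params": self.k_params,
        }


@dataclass(frozen=True)
class SampleSizeInputs:
    """Inputs to the Orme rule N > 500 c / (t a).

    c: largest number of levels across attributes; t: tasks per respondent;
    a: designed alternatives per task (opt-out excluded); nonresponse_rate:
    anticipated nonresponse fraction used to inflate the base N.
    """

    c: int
    t: int
    a: int
    nonresponse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("c must be >= 2")
        if self.t < 1 or self.a < 1:
            raise ValueError("t and a must be >= 1 (t*a = 0 is rejected)")
        if not 0.0 <= self.nonresponse_rate < 1.0:
            raise ValueError("nonresponse_rate must lie in [0, 1)")


def orme_sample_size(inputs: SampleSizeInputs) -> int:
    """Smallest integer N satisfying the Orme rule, inflated for nonresponse.

    N_base = ceil(500 c / (t a)); N_final = ceil(N_base * (1 + r)).  Both
    stages round up so the returned N never undershoots the bound.  For the
    study inputs (c=3, t=8, a=2, r=0.10) this gives 104 respondents.
    """
    base = math.ceil(Fraction(500 * inputs.c, inputs.t * inputs.a))
    inflated = Fraction(base) * (1 + Fraction(inputs.nonresponse_rate).limit_denominator(10**6))
    return math.ceil(inflated)


def build_design_matrix(design: Design) -> pd.DataFrame:
    """Long-format dummy-coded matrix: one row per (task, alternative).

    Rows are task-major, alternative-minor, with the opt-out row last within
    each task.  Designed rows carry the profile's indicators plus asc=1; the
    opt-out row is all zeros (its utility is the normalization of the model).
    """
    scheme = design.scheme
    cols = [ASC_COLUMN] + scheme.columns
    rows, index = [], []
    for t, task in enumerate(design.tasks, start=1):
        for j, profile in enumerate(task.alternatives, start=1):
            rows.append(np.concatenate(([1.0], scheme.encode(profile))))
            index.append((t, j))
        if task.has_optout:
            rows.append(np.zeros(len(cols)))
            index.append((t, len(task.alternatives) + 1))
    return pd.DataFrame(
        rows,
        columns=cols,
        index=pd.MultiIndex.from_tuples(index, names=["task_id", "alt_id"]),
    )


def information_matrix(design: Design, prior_coefficients: np.ndarray | None = None) -> np.ndarray:
    """Multinomial-logit Fisher information at a prior, ASC excluded (K = 5).

    I(beta) = sum over tasks of X_t' (diag(p_t) - p_t p_t') X_t with p_t the
    logit choice probabilities of the task's alternatives (opt-out utility 0)
    evaluated at the prior.  The zero prior gives uniform probabilities.
    """
    k = design.scheme.n_params
    beta = np.zeros(k) if prior_coefficients is None else np.asarray(prior_coefficients, float)
    if beta.shape != (k,):
        raise ValueError(f"prior must have length {k}")
    X = build_design_matrix(design)[design.scheme.columns].to_numpy()
    info = np.zeros((k, k))
    offset = 0
    for task in design.tasks:
        n_alt = task.n_alternatives
        Xt = X[offset : offset + n_alt]
        offset += n_alt
        v = Xt @ beta
        p = np.exp(v - v.max())
        p /= p.sum()
        info += Xt.T @ (np.diag(p) - np.outer(p, p)) @ Xt
    return info


def _d_statistic(design: Design, prior: np.ndarray | None) -> float:
    """det(I/t)^(1/K); raises on singular information."""
    k = design.scheme.n_params
    info = information_matrix(design, prior) / design.n_tasks
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0 or not np.isfinite(logdet) or logdet < -50 * k:
        raise DegenerateDesignError(
            "singular information matrix: the design carries no information "
            "about at least one linear combination of the coefficients"
        )
    return float(np.exp(logdet / k))


def _level_balance(design: Design) -> dict[str, dict[str, int]]:
    balance: dict[str, dict[str, int]] = {
        a.name: {l: 0 for l in a.levels} for a in design.scheme.attributes
    }
    for task in design.tasks:
        for profile in task.alternatives:
            for attr, level in zip(design.scheme.attributes, profile.levels):
                balance[attr.name][level] += 1
    return balance


def _overlap_count(design: Design) -> int:
    """Tasks in which the designed alternatives share a level on some attribute."""
    n = 0
    for task in design.tasks:
        levels = list(zip(*(p.levels for p in task.alternatives)))
        if any(len(set(ls)) == 1 for ls in levels):
            n += 1
    return n


def d_efficiency(
    design: Design,
    prior_coefficients: np.ndarray | None = None,
    reference: Design | None = None,
) -> DesignMetrics:
    """D-efficiency plus balance/overlap diagnostics.

    The raw statistic det(I(prior)/t)^(1/K) is normalized by the same
    statistic of a reference: by default the utility-neutral balanced
    orthogonal ideal whose per-task information is diag(2/9) per dummy
    column, which bounds the statistic above at zero priors so the score
    lies in (0, 1].  Passing a reference design normalizes against that
    design instead (a design referenced to itself scores exactly 1).
    """
    stat = _d_statistic(design, prior_coefficients)
    ref_stat = (
        IDEAL_TASK_INFO if reference is None else _d_statistic(reference, prior_coefficients)
    )
    eff = stat / ref_stat
    return DesignMetrics(
        d_efficiency=eff,
        d_error=1.0 / stat,
        level_balance=_level_balance(design),
        overlap_count=_overlap_count(design),
        k_params=design.scheme.n_params,
    )


def _random_design(
    scheme: AttributeScheme, t: int, a: int, rng: np.random.Generator
) -> Design:
    profiles = scheme.full_factorial()
    tasks = []
    for _ in range(t):
        while True:
            picks = rng.choice(len(profiles), size=a, replace=False)
            alts = tuple(profiles[i] for i in picks)
            if len(set(alts)) == a:
                break
        tasks.append(ChoiceTask(alts))
    return Design(tuple(tasks), scheme)


def search_efficient_design(
    scheme: AttributeScheme,
    t: int,
    a: int = 2,
    iterations: int = 2000,
    seed: int = 0,
    prior_coefficients: np.ndarray | None = None,
) -> Design:
    """Coordinate-exchange search for a D-efficient design.

    Starts from a seeded random design and repeatedly proposes changing one
    alternative's level on one attribute, accepting the move only if it
    increases D-efficiency; deterministic given the seed.  Profiles may repeat
    across tasks; within-task duplicates are rejected.  Raises
    :class:`DegenerateDesignError` if no nonsingular design is found.
    """
    if t < 1 or a < 2:
        raise ValueError("need t >= 1 tasks and a >= 2 designed alternatives")
    rng = np.random.default_rng(seed)

    current = None
    for _ in range(200):
        cand = _random_design(scheme, t, a, rng)
        try:
            current_eff = d_efficiency(cand, prior_coefficients).d_efficiency
        except DegenerateDesignError:
            continue
        current = cand
        break
    if current is None:
        raise DegenerateDesignError(
            f"no nonsingular starting design found for t={t}, a={a}, "
            f"K={scheme.n_params}"
        )

    n_attr = len(scheme.attributes)
    for _ in range(iterations):
        ti = int(rng.integers(t))
        ai = int(rng.integers(a))
        attr_i = int(rng.integers(n_attr))
        attr = scheme.attributes[attr_i]
        new_level = attr.levels[int(rng.integers(len(attr.levels)))]
        task = current.tasks[ti]
        old = task.alternatives[ai]
        if old.levels[attr_i] == new_level:
            continue
        new_levels = list(old.levels)
        new_levels[attr_i] = new_level
        new_profile = Profile(tuple(new_levels))
        new_alts = list(task.alternatives)
        new_alts[ai] = new_profile
        if len(set(new_alts)) != a:
            continue
        new_tasks = list(current.tasks)
        new_tasks[ti] = ChoiceTask(tuple(new_alts))
        candidate = Design(tuple(new_tasks), scheme)
        try:
            eff = d_efficiency(candidate, prior_coefficients).d_efficiency
        except DegenerateDesignError:
            continue
        if eff > current_eff + 1e-12:
            current, current_eff = candidate, eff
    return current


# ---------------------------------------------------------------------------
# CSV round-trip and the shipped study design
# ---------------------------------------------------------------------------

def write_design_csv(design: Design, path: str | Path, header_comment: str | None = None) -> None:
    """Write task_id, alt_id and one level column per attribute.

    The opt-out is written as alt_id = a+1 with empty level fields.
    """
    df = design_to_frame(design)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def design_to_frame(design: Design) -> pd.DataFrame:
    attr_names = [a.name for a in design.scheme.attributes]
    rows = []
    for t, task in enumerate(design.tasks, start=1):
        for j, profile in enumerate(task.alternatives, start=1):
            rows.append([t, j, *profile.levels])
        if task.has_optout:
            rows.append([t, len(task.alternatives) + 1, *([""] * len(attr_names))])
    return pd.DataFrame(rows, columns=["task_id", "alt_id", *attr_names])


def read_design_csv(path: str | Path, scheme: AttributeScheme | None = None) -> Design:
    """Read a design CSV written by :func:`write_design_csv`.

    Rows with empty level fields are the opt-out; every task must have the
    same number of designed alternatives.
    """
    scheme = scheme or study_scheme()
    df = pd.read_csv(path, comment="#", dtype=str).fillna("")
    attr_names = [a.name for a in scheme.attributes]
    missing = [c for c in ["task_id", "alt_id", *attr_names] if c not in df.columns]
    if missing:
        raise ValueError(f"design file is missing columns: {missing}")
    tasks = []
    for task_id, grp in df.groupby(df["task_id"].astype(int), sort=True):
        grp = grp.sort_values("alt_id", key=lambda s: s.astype(int))
        alts, has_optout = [], False
        for _, row in grp.iterrows():
            levels = tuple(row[n] for n in attr_names)
            if all(l == "" for l in levels):
                has_optout = True
            else:
                alts.append(scheme.profile(*levels))
        tasks.append(ChoiceTask(tuple(alts), has_optout=has_optout))
    return Design(tuple(tasks), scheme)


def study_design() -> Design:
    """The study's eight shipped choice sets (two designed options + opt-out)."""
    path = resources.files("dcepref").joinpath("data/study_design.csv")
    with resources.as_file(path) as p:
        return read_design_csv(p, study_scheme())
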