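"""Synthetic respondents and choices under the random-coefficients logit DGP.

The generator emulates the study structure: each respondent answers every
task of the design; their preference weights are drawn from a normal
population (one mean and SD per dummy-coded attribute level, fixed
alternative-specific constant); choices follow the random-utility model with
i.i.d. Gumbel errors, i.e. multinomial-logit choice probabilities with the
opt-out utility normalized to zero.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import COVARIATE_COLUMNS, ChoiceDataset
from .design import ASC_COLUMN, Design, build_design_matrix

__all__ = [
    "PopulationPreferences",
    "draw_respondents",
    "draw_individual_coefficients",
    "shift_preferences",
    "simulate_choices",
]


@dataclass(frozen=True)
class PopulationPreferences:
    """Normal preference population: mean vector and heterogeneity SDs.

    ``mu`` and ``sigma`` are aligned with ``labels`` (ASC first, then the
    dummy-coded attribute levels).  The ASC is fixed across respondents, so
    ``sigma[0]`` must be 0; all SDs are non-negative.
    """

    mu: np.ndarray
    sigma: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, float)
        sigma = np.asarray(self.sigma, float)
        if mu.shape != sigma.shape or mu.shape != (len(self.labels),):
            raise ValueError("mu, sigma and labels must have equal length")
        if (sigma < 0).any():
            raise ValueError("sigma must be non-negative element-wise")
        if self.labels and self.labels[0] == ASC_COLUMN and sigma[0] != 0:
            raise ValueError("the ASC is fixed: sigma[0] must be 0")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)


def _apportion(n: int, weights: Mapping) -> dict:
    """Largest-remainder apportionment of n units to categories."""
    keys = list(weights)
    w = np.array([float(weights[k]) for k in keys])
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("marginal frequencies must be non-negative and sum > 0")
    quota = n * w / w.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    return dict(zip(keys, counts))


def draw_respondents(
    n: int,
    marginals: Mapping[str, Mapping] | None = None,
    seed: int = 0,
    method: str = "exact",
) -> pd.DataFrame:
    """Draw respondent covariates from marginal frequencies.

    ``marginals`` maps each covariate to ``{category: frequency}``; a ``None``
    category stands for a missing value.  ``method="exact"`` allocates
    categories in the exact apportioned counts (seeded shuffle), so at the
    study's n the observed strata are reproduced; ``method="independent"``
    draws each respondent independently from the marginal proportions.
    Covariates are drawn independently of each other in both modes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if method not in ("exact", "independent"):
        raise ValueError("method must be 'exact' or 'independent'")
    if marginals is None:
        from .studydata import STUDY_MARGINALS

        marginals = STUDY_MARGINALS
    rng = np.random.default_rng(seed)
    out = {"respondent_id": np.arange(1, n + 1)}
    for cov, freqs in marginals.items():
        cats = list(freqs)
        if method == "exact":
            counts = _apportion(n, freqs)
            values = [c for c in cats for _ in range(counts[c])]
            rng.shuffle(values)
        else:
            w = np.array([float(freqs[c]) for c in cats])
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("marginal frequencies must be non-negative and sum > 0")
            values = [cats[i] for i in rng.choice(len(cats), size=n, p=w / w.sum())]
        out[cov] = pd.array([v if v is not None else pd.NA for v in values],
                            dtype="string")
    return pd.DataFrame(out)


def draw_individual_coefficients(
    pop: PopulationPreferences, n: int, seed: int = 0
) -> pd.DataFrame:
    """Per-respondent preference weights beta_i = mu + sigma * z_i.

    z_i are independent standard normals; components with sigma = 0 (the ASC)
    are constant across respondents.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(pop.labels)))
    beta = pop.mu + pop.sigma * z
    df = pd.DataFrame(beta, columns=list(pop.labels))
    df.insert(0, "respondent_id", np.arange(1, n + 1))
    return df


def shift_preferences(
    coefficients: pd.DataFrame,
    respondents: pd.DataFrame,
    covariate: str,
    category: str,
    deltas: Mapping[str, float],
) -> pd.DataFrame:
    """Add ``deltas`` to the coefficients of respondents in one stratum.

    Hook for inducing subgroup preference differences in simulations (e.g.
    a stronger home preference among HIV-positive respondents).
    """
    out = coefficients.copy()
    mask = out["respondent_id"].map(
        respondents.set_index("respondent_id")[covariate].eq(category)
    ).fillna(False)
    for col, delta in deltas.items():
        out.loc[mask, col] = out.loc[mask, col] + delta
    return out


def _task_key(task) -> int:
    """Content hash of a task, so draws attach to task content not position."""
    payload = "||".join(p.label() for p in task.alternatives)
    return zlib.crc32(payload.encode("utf-8"))


def simulate_choices(
    design: Design,
    coefficients: pd.DataFrame,
    respondents: pd.DataFrame | None = None,
    seed: int = 0,
) -> ChoiceDataset:
    """Simulate one choice per respondent and task under the logit model.

    Utilities are x'beta_i for designed alternatives and 0 for the opt-out;
    the chosen alternative is drawn with probability exp(U_j)/sum exp(U_k)
    (equivalently argmax of U plus independent Gumbel noise).  The random
    stream is keyed per (respondent, task content), so reordering tasks
    within the design leaves each task's simulated choice unchanged.
    """
    cols = [ASC_COLUMN] + design.scheme.columns
    missing = [c for c in cols if c not in coefficients.columns]
    if missing:
        raise ValueError(f"coefficient labels do not match design columns: {missing}")
    X = build_design_matrix(design)
    beta = coefficients.set_index("respondent_id")[cols]

    # occurrence index disambiguates duplicated task contents
    keys, seen = [], {}
    for task in design.tasks:
        k = _task_key(task)
        occ = seen.get(k, 0)
        seen[k] = occ + 1
        keys.append((k, occ))

    Xmat = X[cols].to_numpy()
    task_slices, offset = [], 0
    for task in design.tasks:
        task_slices.append(slice(offset, offset + task.n_alternatives))
        offset += task.n_alternatives
    n_rows_per_resp = offset
    rids = beta.index.to_numpy()
    n = len(rids)
    B = beta.to_numpy(dtype=float)

    chosen = np.zeros((n, n_rows_per_resp), dtype=int)
    U = B @ Xmat.T  # (n, rows-per-respondent)
    for i in range(n):
        for t, sl in enumerate(task_slices):
            u = U[i, sl]
            p = np.exp(u - u.max())
            p /= p.sum()
            k, occ = keys[t]
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(seed), spawn_key=(i, k, occ))
            )
            choice = int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))
            chosen[i, sl.start + choice] = 1

    task_ids = np.concatenate(
        [np.full(task.n_alternatives, t + 1) for t, task in enumerate(design.tasks)]
    )
    alt_ids = np.concatenate(
        [np.arange(1, task.n_alternatives + 1) for task in design.tasks]
    )
    df = pd.DataFrame(
        {
            "respondent_id": np.repeat(rids, n_rows_per_resp),
            "task_id": np.tile(task_ids, n),
            "alt_id": np.tile(alt_ids, n),
            "chosen": chosen.ravel(),
        }
    )
    for ci, c in enumerate(cols):
        df[c] = np.tile(Xmat[:, ci].astype(int), n)
    if respondents is not None:
        covs = respondents.set_index("respondent_id")
        for cov in covs.columns:
            df[cov] = df["respondent_id"].map(covs[cov]).astype("string")
    return ChoiceDataset.from_frame(df, design.scheme)
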