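import numpy as np
import pandas as pd
import pytest

import dcepref as d
from dcepref.dataset import ChoiceDataValidationError
from dcepref.studydata import STUDY_MARGINALS


# --- respondents ------------------------------------------------------------

def test_exact_marginals_at_study_n():
    resp = d.draw_respondents(103, STUDY_MARGINALS, seed=3)
    assert resp["gender"].value_counts().to_dict() == {"male": 60, "female": 43}
    assert resp["age_group"].value_counts().to_dict() == {">=35": 61, "20-34": 42}
    assert resp["hiv_status"].value_counts().to_dict() == {"negative": 63, "positive": 40}
    assert resp["months_group"].value_counts().to_dict() == {">=6": 71, "<6": 31}
    assert resp["months_group"].isna().sum() == 1  # one missing duration value
    assert resp["respondent_id"].is_unique


def test_independent_draws_match_marginal_by_clt():
    n = 10000
    resp = d.draw_respondents(
        n, {"flag": {"yes": 0.5, "no": 0.5}}, seed=9, method="independent"
    )
    p_hat = (resp["flag"] == "yes").mean()
    assert abs(p_hat - 0.5) < 3 * np.sqrt(0.25 / n)


def test_respondent_draws_deterministic_and_validated():
    a = d.draw_respondents(50, STUDY_MARGINALS, seed=7)
    b = d.draw_respondents(50, STUDY_MARGINALS, seed=7)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ValueError):
        d.draw_respondents(0, STUDY_MARGINALS, seed=1)
    with pytest.raises(ValueError):
        d.draw_respondents(10, {"x": {"a": -1.0, "b": 2.0}}, seed=1)


# --- individual coefficients -------------------------------------------------

def test_zero_sigma_gives_mu_exactly(population):
    pop = d.PopulationPreferences(
        mu=population.mu, sigma=np.zeros_like(population.sigma), labels=population.labels
    )
    coefs = d.draw_individual_coefficients(pop, 20, seed=1)
    assert (coefs[list(pop.labels)].to_numpy() == pop.mu).all()


def test_coefficient_draws_recover_population_sd(population):
    coefs = d.draw_individual_coefficients(population, 50000, seed=2)
    sd_chw = coefs["c_chw"].std(ddof=1)
    assert abs(sd_chw - 1.85) / 1.85 < 0.02
    # the ASC is fixed across respondents
    assert coefs["asc"].nunique() == 1


def test_coefficient_draws_deterministic(population):
    a = d.draw_individual_coefficients(population, 30, seed=5)
    b = d.draw_individual_coefficients(population, 30, seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_negative_sigma_rejected(population):
    with pytest.raises(ValueError):
        d.PopulationPreferences(
            mu=population.mu, sigma=-population.sigma, labels=population.labels
        )


# --- choice simulation --------------------------------------------------------

def test_study_dataset_structure(study_dataset):
    assert study_dataset.n_obs == 2472  # 103 respondents x 8 tasks x 3 alternatives
    assert study_dataset.n_respondents == 103
    assert study_dataset.n_tasks == 8
    per_resp = study_dataset.df.groupby("respondent_id").size()
    assert (per_resp == 24).all()


def test_zero_coefficients_give_uniform_shares(design):
    n = 400
    coefs = pd.DataFrame(
        np.zeros((n, 6)), columns=["asc"] + design.scheme.columns
    )
    coefs.insert(0, "respondent_id", np.arange(1, n + 1))
    ds = d.simulate_choices(design, coefs, seed=21)
    shares = ds.df[ds.df["chosen"] == 1]["alt_id"].value_counts(normalize=True)
    n_choices = n * 8
    bound = 3 * np.sqrt((1 / 3) * (2 / 3) / n_choices)
    for alt in (1, 2, 3):
        assert abs(shares[alt] - 1 / 3) < bound


def test_saturating_voucher_coefficient(design):
    n = 300
    coefs = pd.DataFrame(
        np.zeros((n, 6)), columns=["asc"] + design.scheme.columns
    )
    coefs["s_tvouch"] = 20.0
    coefs.insert(0, "respondent_id", np.arange(1, n + 1))
    ds = d.simulate_choices(design, coefs, seed=22)
    df = ds.df
    # tasks whose two designed alternatives contain exactly one voucher
    picked = total = 0
    for (_, _), grp in df.groupby(["respondent_id", "task_id"]):
        voucher = grp["s_tvouch"] == 1
        if voucher.sum() == 1:
            total += 1
            picked += int(grp.loc[voucher, "chosen"].iloc[0])
    assert total > 0
    assert picked / total > 0.999


def test_simulation_invariant_to_task_order(scheme, design, population):
    coefs = d.draw_individual_coefficients(population, 40, seed=31)
    base = d.simulate_choices(design, coefs, seed=32).df
    perm = np.random.default_rng(0).permutation(8)
    shuffled = d.Design(tuple(design.tasks[i] for i in perm), scheme)
    moved = d.simulate_choices(shuffled, coefs, seed=32).df
    # choices depend only on the task's own alternatives: realign by content
    for new_pos, old_pos in enumerate(perm):
        a = base[base["task_id"] == old_pos + 1].reset_index(drop=True)
        b = moved[moved["task_id"] == new_pos + 1].reset_index(drop=True)
        assert (a["chosen"].to_numpy() == b["chosen"].to_numpy()).all()


def test_label_mismatch_rejected(design, population):
    coefs = d.draw_individual_coefficients(population, 5, seed=1)
    bad = coefs.rename(columns={"s_tvouch": "s_voucher"})
    with pytest.raises(ValueError, match="label"):
        d.simulate_choices(design, bad, seed=1)


def test_stratum_row_counts_follow_marginals(study_dataset):
    counts = study_dataset.df.groupby("hiv_status").size().to_dict()
    assert counts == {"negative": 63 * 24, "positive": 40 * 24}  # 1512 / 960
    by_months = study_dataset.df.groupby("months_group").size().to_dict()
    assert by_months == {"<6": 31 * 24, ">=6": 71 * 24}  # 744 + 1704 = 2448 < 2472


# --- CSV round-trip and validation ---------------------------------------------

def test_choice_csv_round_trip(tmp_path, study_dataset):
    path = tmp_path / "choices.csv"
    d.write_choice_csv(study_dataset, path)
    back = d.read_choice_csv(path, study_dataset.scheme)
    pd.testing.assert_frame_equal(back.df, study_dataset.df)
    assert back.n_respondents == 103 and back.n_tasks == 8 and back.n_obs == 2472


def test_two_chosen_rows_rejected(tmp_path, study_dataset):
    df = study_dataset.df.copy()
    grp = (df["respondent_id"] == df["respondent_id"].iloc[0]) & (df["task_id"] == 1)
    df.loc[grp, "chosen"] = 1  # all three rows chosen
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ChoiceDataValidationError, match="exactly one chosen"):
        d.read_choice_csv(path)


def test_indicator_domain_violation_rejected(tmp_path, study_dataset):
    df = study_dataset.df.copy()
    df.loc[df.index[0], "l_home"] = 2
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ChoiceDataValidationError):
        d.read_choice_csv(path)


def test_preference_shift_hook(population):
    resp = d.draw_respondents(200, seed=41)
    coefs = d.draw_individual_coefficients(population, 200, seed=42)
    shifted = d.shift_preferences(coefs, resp, "hiv_status", "positive", {"l_home": 1.0})
    pos = resp.loc[resp["hiv_status"] == "positive", "respondent_id"]
    mask = coefs["respondent_id"].isin(pos)
    assert np.allclose(
        shifted.loc[mask, "l_home"], coefs.loc[mask, "l_home"] + 1.0
    )
    assert np.allclose(shifted.loc[~mask, "l_home"], coefs.loc[~mask, "l_home"])
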