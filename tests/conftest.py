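import pytest

import sleeppi as sp


@pytest.fixture(scope="session")
def small_survey():
    """Artifact-free default-profile survey table, desk scale."""
    return sp.generate_population(sp.SyntheticConfig(n_respondents=600, seed=11))


@pytest.fixture(scope="session")
def small_scored(small_survey):
    return sp.score_table(small_survey)


@pytest.fixture(scope="session")
def medium_features():
    """Scored, filtered, split and encoded default data (training side)."""
    table = sp.generate_population(sp.SyntheticConfig(n_respondents=1500, seed=29))
    scored = sp.score_table(table)
    disturbed = sp.filter_sleep_disturbed(scored)
    split = sp.split(disturbed, 0.8, seed=29)
    fm_train, fm_test = sp.build_feature_matrix(disturbed, split)
    labels = (
        disturbed.set_index("respondent_id")
        .loc[list(split.train_ids), "true_cluster"]
        .to_numpy()
    )
    return {"train": fm_train, "test": fm_test, "true": labels, "split": split,
            "table": disturbed}


def best_psqi_items():
    """A complete PSQI response set scoring zero on every component."""
    items = {
        "psqi_latency_min": 5.0,
        "psqi_sleep_hours": 8.0,
        "psqi_bed_hours": 8.5,
        "psqi_q5a": 0,
        "psqi_quality": 0,
        "psqi_medication": 0,
        "psqi_daysleepy": 0,
        "psqi_enthusiasm": 0,
    }
    for name in sp.synthetic.PSQI_DISTURBANCE_ITEMS:
        items[name] = 0
    return items
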