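import numpy as np
import pandas as pd
import pytest

import drugmwas as dm
from drugmwas import reference


@pytest.fixture(scope="session")
def small_effects_dataset():
    """A small three-cohort dataset with 20 injected taxon effects."""
    cfg = dm.effects_preset(7, sizes=(200, 100, 80), n_taxa=80)
    return dm.generate(cfg)


@pytest.fixture()
def tiny_meta():
    """Hand-built two-cohort metadata: 6 samples, 2 drugs."""
    ids = [f"s{i}" for i in range(6)]
    frame = pd.DataFrame(
        {
            "cohort": ["A", "A", "A", "B", "B", "B"],
            "age": [30.0, 40, 50, 35, 45, 55],
            "sex": ["female", "male", "female", "male", "female", "male"],
            "bmi": [22.0, 25, 28, 21, 24, 27],
            "seq_depth": [2e7] * 6,
            "ibs_status": ["no"] * 6,
            "ibd_subtype": ["none"] * 6,
            "stoma_pouch": [False] * 6,
        },
        index=ids,
    )
    drugs = pd.DataFrame(
        {"d1": [1, 0, 1, 0, 1, 0], "d2": [0, 0, 1, 1, 0, 0]}, index=ids
    )
    return dm.SampleMetadata(frame, drugs)


def metadata_from_reference(rng_seed: int = 0) -> dm.SampleMetadata:
    """Cohort metadata whose drug matrix reproduces the published user counts.

    Within each cohort, the first n_users samples of each drug are marked as
    users — user counts and percentages are exact; the joint exposure
    pattern is arbitrary, which is irrelevant for usage summaries.
    """
    rng = np.random.default_rng(rng_seed)
    frames, drug_frames = [], []
    usage = reference.usage_table()
    for cohort, n in reference.COHORT_SIZES.items():
        ids = [f"{cohort}_{i:04d}" for i in range(n)]
        frames.append(
            pd.DataFrame(
                {
                    "cohort": cohort,
                    "age": rng.uniform(20, 80, n),
                    "sex": np.where(rng.random(n) < 0.6, "female", "male"),
                    "bmi": rng.uniform(18, 35, n),
                    "seq_depth": 2e7,
                    "ibs_status": "no",
                    "ibd_subtype": "none",
                    "stoma_pouch": False,
                },
                index=ids,
            )
        )
        cohort_usage = usage[usage["cohort"] == cohort]
        drugs = pd.DataFrame(0, index=ids, columns=list(cohort_usage["drug"]))
        for _, row in cohort_usage.iterrows():
            drugs.iloc[: row["n_users"], drugs.columns.get_loc(row["drug"])] = 1
        drug_frames.append(drugs)
    return dm.SampleMetadata(pd.concat(frames), pd.concat(drug_frames))


@pytest.fixture(scope="session")
def reference_meta():
    return metadata_from_reference()
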