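import numpy as np
import pandas as pd
import pytest

from glycometh.simulate import (
    ArraySimConfig,
    WgbsSimConfig,
    simulate_array_study,
    simulate_wgbs_counts,
)


@pytest.fixture(scope="session")
def planted_array_study():
    """Discovery-scale array study: 1000 probes, 8+8 subjects, 20 probes with
    an 0.11 case-only hypo-methylation effect planted at stage 5."""
    config = ArraySimConfig(
        n_probes=1000,
        n_subjects_per_arm=8,
        case_effect={i: -0.11 for i in range(20)},
        seed=7,
    )
    beta, sheet, truth = simulate_array_study(config)
    return config, beta, sheet, truth


@pytest.fixture(scope="session")
def islet_wgbs_study():
    """Islet-style WGBS cohort: 18 donors (2 T2D), ~±5 kb region, 30X,
    16-point planted control-minus-case difference."""
    config = WgbsSimConfig(seed=11)
    tables, donors, truth = simulate_wgbs_counts(config)
    return config, tables, donors, truth


@pytest.fixture
def toy_beta_matrix():
    """Tiny handmade paired study: 3 probes, 2 subjects per arm, one subgroup."""
    samples = []
    for arm in ("control", "case"):
        for s in range(3):
            subj = f"g_{arm}_{s}"
            for stage in (1, 5):
                samples.append({"sample_id": f"{subj}_s{stage}",
                                "subject_id": subj, "stage": stage,
                                "arm": arm, "subgroup": "g"})
    sheet = pd.DataFrame(samples)
    rng = np.random.default_rng(0)
    beta = pd.DataFrame(
        rng.uniform(0.2, 0.8, size=(3, len(sheet))),
        index=pd.Index([f"cg{i}" for i in range(3)], name="probe_id"),
        columns=sheet["sample_id"].tolist())
    return beta, sheet
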