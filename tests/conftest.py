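import numpy as np
import pandas as pd
import pytest

from nmrmetab import biomarkers as bm
from nmrmetab import preprocess as pp
from nmrmetab import synth
from nmrmetab.data import TABLE1, TABLE2, fixture_path


@pytest.fixture(scope="session")
def library():
    return synth.load_resonance_library()


@pytest.fixture(scope="session")
def table1():
    return bm.load_biomarker_table(fixture_path(TABLE1), "SHR-N_vs_WKY-N")


@pytest.fixture(scope="session")
def table2():
    return bm.load_biomarker_table(fixture_path(TABLE2), "SHR-H_vs_SHR-N")


@pytest.fixture(scope="session")
def disease_effects():
    return synth.load_effect_table(fixture_path(TABLE1), "SHR-N_vs_WKY-N")


@pytest.fixture(scope="session")
def treatment_effects():
    return synth.load_effect_table(fixture_path(TABLE2), "SHR-H_vs_SHR-N")


def small_design(**overrides) -> synth.CohortDesign:
    """Reduced-resolution cohort design for fast tests."""
    params = dict(n_points=4096, n_per_group=5, seed=0)
    params.update(overrides)
    return synth.CohortDesign(**params)


def noiseless_design(**overrides) -> synth.CohortDesign:
    """Deterministic forward model: no noise, baseline, dilution or
    biological variation."""
    params = dict(
        noise_sd=0.0,
        baseline_amplitude=0.0,
        dilution_sd=0.0,
        biological_cv=0.0,
        n_points=8192,
        n_per_group=3,
        seed=0,
    )
    params.update(overrides)
    return synth.CohortDesign(**params)


@pytest.fixture(scope="session")
def default_cohort(library, disease_effects):
    """One default-condition two-group cohort, preprocessed once and shared
    by read-only tests."""
    design = synth.CohortDesign(seed=7)
    sset = synth.simulate_cohort(library, disease_effects, design)
    trimmed = [pp.exclude_region(s) for s in sset.spectra]
    binned = pp.adaptive_bin(trimmed)
    normalized, report = pp.pqn_normalize(binned)
    scaled = pp.scale_features(normalized)
    return {
        "sset": sset,
        "binned": binned,
        "normalized": normalized,
        "scaled": scaled,
        "report": report,
    }


def groups_series(sset) -> pd.Series:
    return pd.Series(
        [s.group for s in sset.spectra],
        index=pd.Index([s.sample_id for s in sset.spectra], name="sample_id"),
    )


def matrix_from_array(X, groups, stage="scaled") -> pp.FeatureMatrix:
    """Wrap a plain ndarray as a FeatureMatrix for model-level tests."""
    df = pd.DataFrame(np.asarray(X, float),
                      index=[f"s{i:02d}" for i in range(len(X))])
    return pp.FeatureMatrix.from_dataframe(df, list(groups), stage)
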