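import numpy as np
import pandas as pd
import pytest

from riskaudit import (AdditiveRiskResults, ComponentFunction, DatasetSchema,
                       FeatureSpec, FitConfig, PatientTable)


def make_component(values, thresholds=None, counts=None, feature="x",
                   support=None, **kwargs) -> ComponentFunction:
    """Hand-built piecewise-constant component on a unit grid by default."""
    values = np.asarray(values, dtype=float)
    m = values.size
    if thresholds is None:
        thresholds = np.arange(1.0, m, 1.0)
    thresholds = np.asarray(thresholds, dtype=float)
    if counts is None:
        counts = np.full(m, 10, dtype=np.int64)
    if support is None:
        lo = thresholds[0] - 1.0 if m > 1 else 0.0
        hi = thresholds[-1] + 1.0 if m > 1 else 1.0
        support = (float(lo), float(hi))
    return ComponentFunction(feature=feature, kind="continuous",
                             thresholds=thresholds, values=values,
                             bin_counts=np.asarray(counts, dtype=np.int64),
                             support=support, **kwargs)


def make_results(components, intercept=0.0, outcome_name="outcome") -> AdditiveRiskResults:
    """Wrap hand-built components into a results object."""
    schema = DatasetSchema(
        outcome_name=outcome_name,
        features=tuple(FeatureSpec(c.feature, c.kind) for c in components))
    return AdditiveRiskResults(schema=schema, intercept=float(intercept),
                               components=list(components),
                               fit_config=FitConfig(), n_obs=0)


def table_for(results: AdditiveRiskResults, feature_arrays, outcomes) -> PatientTable:
    data = {results.schema.outcome_name: np.asarray(outcomes)}
    data.update(feature_arrays)
    return PatientTable.from_dataframe(pd.DataFrame(data), results.schema)


@pytest.fixture
def binary_feature_df():
    """10k patients, one binary feature with P(Y=1|x=1)=0.8, P(Y=1|x=0)=0.2."""
    rng = np.random.default_rng(7)
    n = 10_000
    x = rng.integers(0, 2, n).astype(float)
    y = (rng.random(n) < np.where(x == 1, 0.8, 0.2)).astype(int)
    return pd.DataFrame({"outcome": y, "x": x})


@pytest.fixture(scope="session")
def strict_pipeline():
    """One strict-adherence cohort fitted and scanned (shared across tests)."""
    import riskaudit as ra

    scn = ra.make_scenario("flattens_risk", "strict")
    cohort = ra.sample_cohort(scn, 20_000, n_nuisance=2, seed=11)
    table = cohort.to_table()
    res = ra.AdditiveRiskModel(table).fit(n_bags=20, n_rounds=150, max_bins=16,
                                          seed=13)
    report = ra.scan_artifacts(res, table)
    return scn, cohort, table, res, report
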