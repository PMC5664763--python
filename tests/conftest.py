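import numpy as np
import pandas as pd
import pytest

from noiselur.acoustics import AnalysisWindow, SoundLevelSeries
from noiselur.gis import FeatureMatrix, build_feature_matrix
from noiselur.simulate import LayoutConfig, generate_layout
from noiselur.variables import CandidateVariable


@pytest.fixture(scope="session")
def window() -> AnalysisWindow:
    # a Wednesday 06:00 within the austral-summer measurement season
    return AnalysisWindow.five_day("2015-11-11 06:00:00")


def constant_series(level: float, window: AnalysisWindow, site_id: str = "s") -> SoundLevelSeries:
    idx = pd.date_range(window.start, window.end, freq="s", inclusive="left")
    return SoundLevelSeries(site_id, pd.Series(np.full(len(idx), level), index=idx))


@pytest.fixture(scope="session")
def small_layout():
    """A compact settlement layout shared across GIS tests."""
    config = LayoutConfig(n_sites=25, extent_m=2200, n_households=600, seed=7)
    return generate_layout(config)


@pytest.fixture(scope="session")
def small_feature_matrix(small_layout) -> FeatureMatrix:
    sites, layers = small_layout
    return build_feature_matrix(sites, layers)


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """A six-site synthetic study written to disk in the pipeline formats."""
    from noiselur.pipeline import simulate_study
    from noiselur.simulate import SeriesConfig, TruthModel

    out = tmp_path_factory.mktemp("study")
    simulate_study(
        out,
        layout=LayoutConfig(n_sites=6, extent_m=2000, n_households=400, seed=12),
        truth=TruthModel(sigma=1.0),
        series_base=SeriesConfig(within_period_sd=2.0),
        seed=12,
    )
    return out


def toy_feature_matrix(values: dict[str, np.ndarray], signs: dict[str, int] | None = None) -> FeatureMatrix:
    """FeatureMatrix from plain columns, one variable type per column."""
    signs = signs or {}
    n = len(next(iter(values.values())))
    df = pd.DataFrame(values, index=[f"s{i}" for i in range(n)])
    variables = {
        name: CandidateVariable(name, name, "generic", None, signs.get(name, 0), "")
        for name in df.columns
    }
    return FeatureMatrix(df, variables)
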