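import numpy as np
import pandas as pd
import pytest

from metabopair import (
    Feature,
    FeatureTable,
    InjectionRecord,
    PipelineConfig,
    SimulationSpec,
    default_library_path,
    read_compound_library,
    simulate_study,
)


@pytest.fixture(scope="session")
def library():
    return read_compound_library(default_library_path())


@pytest.fixture(scope="session")
def small_study():
    """A modest simulated crossover study with known affected features."""
    spec = SimulationSpec(
        n_subjects=21, n_features=200, n_affected=10, fc_affected=2.5,
        noise_sd=0.15, seed=7,
    )
    return simulate_study(spec)


@pytest.fixture
def fast_config():
    """Default thresholds but a light permutation battery for unit tests."""
    return PipelineConfig(n_permutations=25)


def build_table(intensities: np.ndarray, injections: list[InjectionRecord],
                mz0: float = 100.0) -> FeatureTable:
    """Hand-build a FeatureTable from a matrix and injection records."""
    p = intensities.shape[0]
    features = [Feature(f"F{j:03d}", mz0 + j, 1.0 + 0.01 * j) for j in range(p)]
    df = pd.DataFrame(
        np.asarray(intensities, dtype=float),
        index=pd.Index([f.feature_id for f in features], name="feature_id"),
        columns=[r.injection_id for r in injections],
    )
    return FeatureTable(features=features, injections=injections, intensities=df)


def qc_study_records(n_qc: int, n_study: int, arm: str = "AD") -> list[InjectionRecord]:
    """n_qc leading QCs then n_study paired study injections (pre/post alternating)."""
    recs = [InjectionRecord(f"QC{k}", "qc", k + 1) for k in range(n_qc)]
    order = n_qc + 1
    for s in range(n_study):
        tp = "pre" if s % 2 == 0 else "post"
        subj = f"subj{s // 2:02d}"
        recs.append(InjectionRecord(f"S{s:03d}", "study", order, subj, tp, arm))
        order += 1
    return recs
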