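import numpy as np
import pytest

from bmecv import (
    AtomKind,
    GeneratorConfig,
    ObservableLabel,
    ObservableMatrix,
    TargetSet,
    align_by_tags,
    helix_bump_profile,
    make_benchmark_case,
    select_theta,
    theta_scan,
    uniform_weights,
)


def make_matrix(values, tags=None, frame_ids=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if tags is None:
        tags = [f"res{j + 2}_CA" for j in range(m)]
    labels = [ObservableLabel.from_tag(t) for t in tags]
    if frame_ids is None:
        frame_ids = list(range(1, n + 1))
    return ObservableMatrix(values=values, labels=labels, frame_ids=frame_ids)


def make_targets(values, sigmas, tags=None):
    values = np.asarray(values, dtype=float)
    if tags is None:
        tags = [f"res{j + 2}_CA" for j in range(len(values))]
    labels = [ObservableLabel.from_tag(t) for t in tags]
    return TargetSet(labels=labels, values=values, sigmas=np.asarray(sigmas, dtype=float))


def random_instance(rng, n_max=20, m_max=3):
    n = int(rng.integers(3, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    values = rng.normal(0, 1, (n, m))
    y = values.mean(axis=0) + rng.normal(0, 0.5, m)
    sig = rng.uniform(0.5, 2.0, m)
    return make_matrix(values), make_targets(y, sig)


@pytest.fixture(scope="session")
def default_benchmark():
    """The seeded default benchmark case (mismatched helix profiles,
    predictor-B systematic + random error on)."""
    return make_benchmark_case(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_benchmark_scan(default_benchmark):
    """Full 30-point theta scan of the default benchmark, benchmark mode."""
    case = default_benchmark
    matrix = align_by_tags(case.prior_cs, case.targets)
    target_matrix = align_by_tags(case.target_cs, case.targets)
    return theta_scan(
        matrix,
        case.targets,
        target_matrix=target_matrix,
        target_weights=uniform_weights(target_matrix.n_frames),
    )


@pytest.fixture(scope="session")
def default_selection(default_benchmark_scan):
    return select_theta(default_benchmark_scan, "min_chi2_v")


@pytest.fixture(scope="session")
def small_benchmark():
    """Desk-scale case for fast unit tests of the scan machinery."""
    config = GeneratorConfig(
        n_frames=240,
        n_residues=15,
        propensity_target=helix_bump_profile(15, bump=0.7, start=5, stop=10),
        propensity_prior=helix_bump_profile(15, bump=0.3, start=5, stop=10),
        cb_excluded=(7,),
        seed=7,
    )
    return make_benchmark_case(config)
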