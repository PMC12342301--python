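import numpy as np
import pytest

from budwormsync import dendro, pipeline, synthetic


@pytest.fixture(scope="session")
def default_config() -> synthetic.SyntheticSiteConfig:
    return synthetic.SyntheticSiteConfig()


@pytest.fixture(scope="session")
def default_truth(default_config):
    return synthetic.simulate_population(default_config)


@pytest.fixture(scope="session")
def default_trees(default_truth, default_config):
    return synthetic.simulate_tree_rings(default_truth, default_config)


@pytest.fixture(scope="session")
def default_rwi(default_trees):
    return [dendro.detrend_spline(t) for t in default_trees]


@pytest.fixture(scope="session")
def default_site_dir(tmp_path_factory, default_config):
    d = tmp_path_factory.mktemp("site")
    manifest = synthetic.write_site(d, default_config)
    return d, manifest


@pytest.fixture(scope="session")
def default_site_result(default_site_dir):
    """Full pipeline run on the default synthetic site (shared across tests)."""
    _, manifest = default_site_dir
    return pipeline.run_site(
        pipeline.SiteManifest.from_dict(manifest), seed=1, n_mc=200
    )


def episode_runs(years) -> list[tuple[int, int]]:
    """Maximal consecutive runs in a sorted collection of years."""
    runs: list[list[int]] = []
    prev = None
    for y in sorted(years):
        if prev is None or y > prev + 1:
            runs.append([y, y])
        else:
            runs[-1][1] = y
        prev = y
    return [tuple(r) for r in runs]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
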