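import numpy as np
import pytest

import wingmorph as wm
from wingmorph.synthetic import _RAW_TEMPLATE, _normalize_template, GroupSpec, Nuisance


@pytest.fixture(scope="session")
def template():
    return _normalize_template(_RAW_TEMPLATE)


@pytest.fixture(scope="session")
def default_dataset():
    return wm.generate(wm.default_spec(seed=1))


@pytest.fixture(scope="session")
def default_gpa(default_dataset):
    return wm.gpa(default_dataset)


def make_spec(
    template,
    groups,
    slope=None,
    noise=0.004,
    nuisance=None,
    seed=0,
):
    """Small helper for bespoke generator specs in tests.

    ``groups`` is a list of (name, n, offset-or-None, mean_log_cs, sd_log_cs).
    """
    k = template.shape[0]
    gs = tuple(
        GroupSpec(
            name=name,
            n=n,
            shape_offset=np.zeros((k, 2)) if off is None else off,
            mean_log_cs=mu,
            sd_log_cs=sd,
        )
        for name, n, off, mu, sd in groups
    )
    return wm.GeneratorSpec(
        template=template,
        groups=gs,
        allometric_slope=np.zeros((k, 2)) if slope is None else slope,
        landmark_noise_sd=noise,
        nuisance=nuisance or Nuisance(),
        seed=seed,
    )


def random_shape(rng, k=10):
    """A random non-degenerate centered configuration."""
    while True:
        pts = rng.normal(size=(k, 2))
        pts -= pts.mean(axis=0)
        if np.linalg.norm(pts) > 1e-3:
            return pts
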