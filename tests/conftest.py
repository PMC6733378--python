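import numpy as np
import pytest

import hipshape as hs


@pytest.fixture(scope="session")
def template58():
    template, base = hs.make_base_template(58)
    return template, base


@pytest.fixture(scope="session")
def ground_truth(template58):
    _, base = template58
    return hs.make_ground_truth(base, n_modes=3, mode_sds=[10.0, 5.0, 2.0],
                                seed=1)


@pytest.fixture(scope="session")
def population500(template58, ground_truth):
    """Low-noise 500-image population for parameter-recovery checks."""
    template, _ = template58
    spec = hs.SyntheticPopulationSpec(
        n_images=500, marking_noise_sd=0.1, seed=7, template=template)
    configs, true_scores = hs.simulate_population(ground_truth, spec)
    return configs, true_scores


@pytest.fixture(scope="session")
def fitted_model(template58, population500):
    """GPA + shape model fitted to the 500-image population."""
    template, _ = template58
    configs, _ = population500
    reduced = [hs.apply_template_exclusions(c, template) for c in configs]
    mean, aligned = hs.gpa(reduced)
    model = hs.build_ssm(aligned, template_id=template.template_id)
    return mean, aligned, model


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_similarity(rng, points):
    """Apply a random similarity transform to a point set."""
    theta = rng.uniform(-np.pi, np.pi)
    scale = rng.uniform(0.3, 3.0)
    shift = rng.uniform(-100.0, 100.0, 2)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    return scale * points @ R.T + shift
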