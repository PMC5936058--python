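import pytest

import foramtracer as ft


@pytest.fixture(scope="session")
def default_samples():
    """One seeded realisation of the default size-fraction feeding scenario."""
    samples, truth = ft.simulate_experiment(ft.default_scenario(), seed=11)
    return samples, truth


@pytest.fixture(scope="session")
def incorporation_table(default_samples, tmp_path_factory):
    """Validated samples run through the tracer transformer."""
    from foramtracer.io import read_samples

    samples, _ = default_samples
    path = tmp_path_factory.mktemp("data") / "samples.csv"
    samples.to_csv(path, index=False)
    validated = read_samples(path)
    return ft.TracerIncorporation().fit_transform(validated)
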