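import pytest

from nsclc_cea import load_model_config


@pytest.fixture(scope="session")
def config():
    """The bundled base-case parameter set (read once per session)."""
    return load_model_config()


@pytest.fixture(scope="session")
def settings(config):
    return config.settings


def collapse_to_point_masses(config):
    """Return a config whose every sampled parameter is a point mass."""
    from nsclc_cea import parameter_space, apply_override
    from nsclc_cea.config import HazardRatio

    out = config
    for name, ref in parameter_space(config).items():
        value = ref.get(config)
        if isinstance(value, HazardRatio):
            out = apply_override(
                out, name,
                {"mean": value.mean, "ci_low": value.mean, "ci_high": value.mean},
            )
        else:
            out = apply_override(
                out, name,
                {"mean": value.mean, "low": value.mean, "high": value.mean},
            )
    return out
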