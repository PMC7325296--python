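import pytest

from tehb import (SyntheticConfig, fit_wealth_index, fractional_rank,
                  generate_households, prepare_analysis_sample,
                  score_and_classify)


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def households(default_config):
    """10k households from the default generator configuration."""
    return generate_households(
        default_config.replace(n_households=10_000, seed=42))


@pytest.fixture(scope="session")
def scored_sample(households):
    """Analysis sample (positive tobacco spenders) with wealth score,
    quintile and fractional rank appended — the standard pipeline state."""
    sample, _ = prepare_analysis_sample(households)
    indicators = sorted((c for c in sample.columns
                         if c.startswith("asset_")),
                        key=lambda c: int(c.split("_")[1]))
    model = fit_wealth_index(sample, indicators)
    scored = score_and_classify(sample, model)
    scored["frac_rank"] = fractional_rank(scored["wealth_score"].to_numpy())
    return scored
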