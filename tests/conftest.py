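import pandas as pd
import pytest

from reeftherm import ingest
from reeftherm.synthetic import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def noise_free_config() -> SyntheticConfig:
    """Three months, all stochastic components off, satellite 0.58 C cool."""
    return SyntheticConfig(
        start_date="2018-01-01",
        end_date="2018-03-31",
        loggers_per_region=2,
        origin_bias=-0.58,
        ar1_sigma=0.0,
        jitter_sigma=0.0,
        logger_spread_sigma=0.0,
        latent_sigma_shared=0.0,
        latent_sigma_specific=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noise_free_dataset(noise_free_config):
    return simulate_dataset(noise_free_config)


@pytest.fixture(scope="session")
def noise_free_panel(noise_free_dataset):
    nightly = ingest.aggregate_nightlies(noise_free_dataset.loggers)
    return ingest.build_region_panel(nightly, noise_free_dataset.ssst, scope="all")


@pytest.fixture(scope="session")
def noisy_dataset():
    """Two noisy years with two field-season retrieval gaps."""
    cfg = SyntheticConfig(
        start_date="2018-01-01",
        end_date="2019-12-31",
        loggers_per_region=2,
        gap_schedule=(("2018-06-10", "2018-06-25"), ("2019-03-05", "2019-03-18")),
        seed=11,
    )
    return simulate_dataset(cfg)


def make_logger(records: list[tuple[str, float]], logger_id="L1", region="Northern",
                depth_m=3.0, deployment=None) -> ingest.LoggerSeries:
    """Hand-built LoggerSeries from (timestamp, temp) pairs."""
    rec = pd.DataFrame(
        {
            "timestamp": pd.to_datetime([t for t, _ in records]),
            "temp_c": [v for _, v in records],
        }
    )
    rec["qc_ok"] = True
    return ingest.LoggerSeries(
        logger_id=logger_id,
        region=region,
        depth_m=depth_m,
        records=rec,
        deployment_date=pd.Timestamp(deployment) if deployment else rec["timestamp"].iloc[0],
        retrieval_date=rec["timestamp"].iloc[-1],
    )
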