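import numpy as np
import pandas as pd
import pytest

from spermage import (
    GeneratorConfig,
    make_annotation,
    make_beta_matrix,
    make_covariates,
)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """63 subjects x 2,000 probes with clearly recoverable planted effects."""
    return GeneratorConfig(n_subjects=63, n_probes=2000,
                           effect_fraction=0.05, effect_size_mean=0.08,
                           seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    cov = make_covariates(config=small_config)
    ann, icrs = make_annotation(config=small_config)
    beta, truth = make_beta_matrix(ann, cov, small_config)
    return {"config": small_config, "covariates": cov, "annotation": ann,
            "icrs": icrs, "beta": beta, "truth": truth}


@pytest.fixture()
def toy_annotation():
    """Five hand-built probes covering flags and multi-gene annotation."""
    return pd.DataFrame(
        {
            "chr": ["1", "1", "2", "2", "X"],
            "pos": [100, 200, 300, 400, 500],
            "island_relation": ["island", "shore", "open_sea", "shelf",
                                "island"],
            "functional_region": ["promoter", "body", "intergenic",
                                  "multiple", "promoter"],
            "genes": ["GNAS;GNASAS", "MAGEL2", "", "KCNQ1", "GNAS"],
            "snp": [False, True, False, True, False],
            "crossreactive": [False, True, True, False, False],
        },
        index=pd.Index([f"cg{i:08d}" for i in range(1, 6)], name="probe_id"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
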