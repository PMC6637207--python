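import numpy as np
import pytest

from smatkit import synthetic


@pytest.fixture(scope="session")
def small_lineage():
    """Scaled-down lineage scenario for image-pipeline tests."""
    return synthetic.preset("lineage", seed=11).with_(
        frame_shape=(192, 192), cells_per_field=6,
        n_replicates=2, n_fields=2, times=np.arange(10) * 60.0,
        hcia_fields_per_condition=4,
    )


@pytest.fixture(scope="session")
def dual_stain_features(small_lineage):
    """Feature table of one mid-divergence dual-stain population."""
    from smatkit import hcia

    fields, _ = synthetic.generate_dual_stain_population(small_lineage, "24h")
    return hcia.extract_population(fields)
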