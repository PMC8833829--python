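import numpy as np
import pytest

from tnbcpet.imaging import SuvVolume, VolumeMeta


def suv_from_array(arr, spacing=(1.0, 1.0, 1.0), scanner="unknown"):
    """Wrap a plain array as an SuvVolume with dummy acquisition metadata."""
    meta = VolumeMeta(injected_activity_bq=1e8, body_weight_g=7e4, scanner=scanner)
    return SuvVolume(grid=np.asarray(arr, dtype=float), spacing=spacing, meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
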