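import numpy as np
import pytest

from dlsi import AcquisitionMeta

#: Acquisition conditions of the high-frame-rate protocol used throughout:
#: 22,881 fps, 4 s records.
FS = 22881.0
DURATION = 4.0


@pytest.fixture(scope="session")
def study_meta() -> AcquisitionMeta:
    return AcquisitionMeta(
        frame_rate=FS, exposure=0.5 / FS, black_level=0.0, total_duration=DURATION
    )


def make_curve(lags, values):
    """Build a G2Curve from arrays without caring about pair counts."""
    from dlsi import G2Curve

    lags = np.asarray(lags, dtype=float)
    return G2Curve(lags=lags, values=np.asarray(values, dtype=float),
                   n_pairs=np.ones(len(lags), dtype=int))
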