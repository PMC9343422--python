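import numpy as np
import pandas as pd
import pytest

from swayseg.synthetic import ClusterBlock, SegmentSpec, generate_recording
from swayseg.preprocess import preprocess_recording
from swayseg.sync import all_pairs_sync, sync_table


@pytest.fixture
def small_single_cluster_spec():
    """Noiseless, tilt-free: every sensor reads the same source. Small fs /
    duration keep module tests fast; physics does not depend on 1000 Hz."""
    return SegmentSpec(
        clusters=[ClusterBlock((1, 6))],
        n_sensors=6,
        fs=250.0,
        duration=10.0,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture
def two_cluster_spec():
    return SegmentSpec(
        clusters=[ClusterBlock((1, 3)), ClusterBlock((4, 6))],
        n_sensors=6,
        fs=250.0,
        duration=10.0,
        noise_sd=0.0,
        seed=3,
    )


def three_cluster_spec(seed: int, **kwargs) -> SegmentSpec:
    """22-sensor planted structure at full scale (20 s, 1000 Hz), SNR = 10."""
    defaults = dict(
        clusters=[ClusterBlock((1, 8)), ClusterBlock((9, 12)), ClusterBlock((13, 22))],
        noise_sd=1.0 / np.sqrt(10.0),
        seed=seed,
    )
    defaults.update(kwargs)
    return SegmentSpec(**defaults)


def adjacent_sync_table(spec: SegmentSpec, subject_id: str, condition: str = "EO",
                        trial_index: int = 1) -> pd.DataFrame:
    rec = generate_recording(spec, subject_id=subject_id, condition=condition,
                             trial_index=trial_index)
    pre = preprocess_recording(rec)
    return sync_table(all_pairs_sync(pre, pairs="adjacent"), pre)
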