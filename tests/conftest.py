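import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from focistat.foci_detection import DetectionParams
from focistat.synthetic_data import FieldSpec


@pytest.fixture
def detection_params() -> DetectionParams:
    """Detection settings used throughout the synthetic-field tests.

    abs_min=80 sits far above the filtered noise floor but well below the
    filtered response of a default-amplitude focus, mimicking the manual
    per-experiment tuning of the absolute-minimum criterion.
    """
    return DetectionParams(abs_min=80.0)


@pytest.fixture
def small_field_spec() -> FieldSpec:
    return FieldSpec(
        width=160,
        height=160,
        n_nuclei=2,
        nucleus_radius_range=(20.0, 26.0),
        foci_per_nucleus=[3, 1],
    )
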