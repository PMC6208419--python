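import numpy as np
import pytest

from nanopk.fitting import ConcentrationSeries
from nanopk.models import KineticParams, ModelVariant


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_series(variant, params, times, values=None, *, roi="heart",
                route="iv", subject="s1", group="g1",
                value_kind="concentration"):
    """Build a series directly from a model curve (optionally overridden)."""
    from nanopk.models import eval_variant
    times = np.asarray(times, dtype=float)
    if values is None:
        values = np.asarray(eval_variant(variant, params, times), dtype=float)
    return ConcentrationSeries(subject_id=subject, group_id=group, roi=roi,
                               route=route, times=times, values=values,
                               value_kind=value_kind)


@pytest.fixture
def double_exp_truth():
    return KineticParams(A=5.0, k_in=2.0, k_out=0.1)


@pytest.fixture
def mono_truth():
    return KineticParams(A=10.0, k_out=np.log(2) / 7.83)
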