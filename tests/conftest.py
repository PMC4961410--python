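import numpy as np
import pytest

from ctcgate.core import CHANNELS
from ctcgate.synthetic import (
    ImageParams,
    LogNormalParams,
    PopulationSpec,
    SampleScenario,
    render_sample,
    sample_events,
)


def make_population(name="CTC", frequency=1.0, truth_class="CTC",
                    radius=(8.0, 1.1), standard_positive=True, **medians):
    """Population with flat defaults; medians given as ch=(median, gsd)
    or ch=median (gsd 1.6)."""
    defaults = {"hoechst": (3000, 1.3), "cd45": (10, 1.6), "cd11b": (10, 1.6),
                "pck": (10, 1.6), "pdl1": (10, 1.6), "isotype": (10, 1.6),
                "capture": (10, 1.6)}
    for ch, v in medians.items():
        defaults[ch] = v if isinstance(v, tuple) else (v, 1.6)
    return PopulationSpec(
        name=name, frequency=frequency,
        channel_params={ch: LogNormalParams(*defaults[ch]) for ch in CHANNELS},
        size_params=LogNormalParams(*radius),
        truth_class=truth_class, standard_positive=standard_positive)


def make_two_pop_scenario(n_cells=10000, seed=1, pck_hi=130.0, pck_lo=10.0):
    """CTC-vs-OTHER mixture with planted pCK medians (hi, lo)."""
    pops = (
        make_population("CTC", 0.5, "CTC", pck=(pck_hi, 1.6)),
        make_population("OTHER", 0.5, "OTHER", pck=(pck_lo, 1.6),
                        standard_positive=False),
    )
    return SampleScenario(sample_id="twopop", capture_antibody="EpCAM",
                          populations=pops, n_cells=n_cells, seed=seed)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def rendered_sample():
    """A 120-cell field rendered at defaults, with its events and truth.

    Session-scoped: rendering is the slowest fixture and is reused by
    segmentation, feature-extraction and cross-mode tests.
    """
    from ctcgate.synthetic import make_scenario

    sc = make_scenario("fig2d_capture", seed=7, n_cells=120,
                       capture_antibody="Vim")[0]
    events, truth = sample_events(sc)
    params = ImageParams(field_shape=(768, 768))
    grid, truth = render_sample(events, truth, params)
    return sc, events, truth, grid, params
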