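import numpy as np
import pytest

from otolith_tracer import synthetic_data as sd
from otolith_tracer.transect_io import ElementalTransect


@pytest.fixture(scope="session")
def river_template():
    """Well-separated 3-site river (estuary, middle, upper)."""
    return sd.default_river_template(n_sites=3, separation_sd=10.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort(river_template):
    specs, sites = river_template
    scenarios = sd.default_scenarios(specs, sites)
    config = sd.CohortConfig(
        specs=specs,
        sites=sites,
        scenarios=[(s, 6) for s in scenarios],
        coreless_fraction=0.25,
        seed=23,
    )
    return sd.simulate_cohort(config)


def make_transect(
    values,
    fish_id="f1",
    site_id="s1",
    elements=None,
    positions=None,
    orientation="raw",
    below_dl=None,
):
    """Minimal transect builder for hand-constructed fixtures."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and values.shape[1] > 1 and elements is None:
        values = values.T
    n, k = values.shape
    if elements is None:
        elements = [f"E{i}" for i in range(k)] if k > 1 else ["Mn"]
    if positions is None:
        positions = np.arange(n, dtype=float)
    if below_dl is None:
        below_dl = np.zeros((n, k), dtype=bool)
    return ElementalTransect(
        fish_id=fish_id,
        capture_site_id=site_id,
        positions=np.asarray(positions, dtype=float),
        concentrations=values,
        elements=list(elements),
        below_dl=below_dl,
        orientation=orientation,
    )
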