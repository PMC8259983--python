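"""Shared fixtures: toy ME models, media, and a full panel scan.

Everything is generated programmatically from fixed seeds; the scan and the
auxotroph set are session-scoped because several test modules (and the
acceptance checks) interrogate the same optimum.
"""

import matplotlib

matplotlib.use("Agg")

import pytest

from me_allocate.conditions import composition_matrix, scan_conditions
from me_allocate.limitation import make_auxotroph
from me_allocate.synthetic import (
    ToyConfig,
    auxotroph_knockouts,
    base_media_for,
    generate_condition_panel,
    generate_toy_me_model,
)

TOY_SEED = 1


@pytest.fixture(scope="session")
def toy_model():
    """Respiratory toy ME model, all couplings applied."""
    return generate_toy_me_model(ToyConfig(seed=TOY_SEED))


@pytest.fixture(scope="session")
def toy_model_trna():
    """Toy model with the tRNA/synthetase layer enabled."""
    return generate_toy_me_model(ToyConfig(seed=TOY_SEED,
                                           include_trna_layer=True))


@pytest.fixture(scope="session")
def media_aerobic(toy_model):
    return base_media_for(toy_model, aerobic=True)


@pytest.fixture(scope="session")
def media_anaerobic(toy_model):
    return base_media_for(toy_model, aerobic=False)


@pytest.fixture(scope="session")
def scan_result(toy_model, media_aerobic):
    """Full nutrient-panel scan under both aerobicities."""
    panel = generate_condition_panel(toy_model)
    return scan_conditions(toy_model, toy_model.coenzymes, panel,
                           media_aerobic)


@pytest.fixture(scope="session")
def demand_table(scan_result):
    """Wide condition x component matrix of per-protein demands."""
    return composition_matrix(scan_result)


@pytest.fixture(scope="session")
def scan_metadata(scan_result):
    return (scan_result.demands.drop_duplicates("condition_id")
            .set_index("condition_id"))


@pytest.fixture(scope="session")
def toy_auxotrophs(toy_model):
    """Validated auxotroph models for every essential toy component."""
    return {met: make_auxotroph(toy_model, met, kos)
            for met, kos in auxotroph_knockouts(toy_model).items()}
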