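import numpy as np
import pytest

from spotassay import (
    DilutionSeries,
    PlateLayout,
    RenderConfig,
    ScavengingModel,
    layout_to_wells,
    render_plate,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_layout():
    """3x10 grid: 9 levels x 3 replicates + 3 reagent blanks."""
    return PlateLayout(
        n_rows=3, n_cols=10, origin=(24.0, 24.0),
        pitch_x=36.0, pitch_y=36.0, spot_radius=10.0,
    )


@pytest.fixture
def ladder():
    return DilutionSeries(top_concentration=3000.0, dilution_factor=2.0, n_levels=9)


@pytest.fixture
def model():
    return ScavengingModel(true_c50=200.0, hill=2.0, form="logistic_log")


@pytest.fixture
def populated_layout(small_layout, ladder):
    return layout_to_wells(small_layout, ladder, "s", 3, n_reagent_blanks=3)


@pytest.fixture
def noiseless_plate(model, small_layout, ladder):
    """Noiseless render: (image, truth table, populated layout)."""
    config = RenderConfig(layout=small_layout, noise_sd=0.0, seed=3)
    image, truth = render_plate(model, config, ladder, n_replicates=3, sample_id="s")
    populated = layout_to_wells(small_layout, ladder, "s", 3, n_reagent_blanks=3)
    return image, truth, populated
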