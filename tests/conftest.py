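import numpy as np
import pytest

from ricepheno.models import CultivarParams, ModelId, ResponseParams


@pytest.fixture(scope="session")
def schematic_params() -> dict[ModelId, ResponseParams]:
    """The four response functions with their canonical schematic values
    (Tb = 8 °C; To = 30 °C, Tc = 42 °C and TSEN where the family uses them)."""
    return {
        ModelId.GDD: ResponseParams(ModelId.GDD, tb=8.0),
        ModelId.EXPONENTIAL: ResponseParams(ModelId.EXPONENTIAL, tb=8.0, tsen=0.25),
        ModelId.BILINEAR: ResponseParams(ModelId.BILINEAR, tb=8.0, to=30.0, tc=42.0),
        ModelId.BETA: ResponseParams(
            ModelId.BETA, tb=8.0, to=30.0, tc=42.0, tsen=1.25
        ),
    }


@pytest.fixture(scope="session")
def schematic_cultivars(schematic_params) -> dict[ModelId, CultivarParams]:
    """Cultivar parameter sets on each family's own rate scale, chosen to
    give realistic 60–130 day stage durations in temperate rice climates."""
    thetas = {
        ModelId.GDD: (900.0, 1600.0),
        ModelId.EXPONENTIAL: (80.0, 130.0),
        ModelId.BILINEAR: (55.0, 95.0),
        ModelId.BETA: (50.0, 85.0),
    }
    return {
        m: CultivarParams(f"cv-{m.value}", p, *thetas[m])
        for m, p in schematic_params.items()
    }


@pytest.fixture(scope="session")
def temperature_grid() -> np.ndarray:
    """0.01 °C grid over 0–45 °C used for exhaustive response checks."""
    return np.round(np.arange(0.0, 45.0001, 0.01), 10)
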