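import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_field():
    """One simulated field at default settings, shared across tests."""
    from aggscreen.synthetic import SimulationSpec, simulate_field

    spec = SimulationSpec(seed=42)
    nuclear, protein, truth = simulate_field(spec)
    return spec, nuclear, protein, truth


@pytest.fixture(scope="session")
def toy_screen(tmp_path_factory):
    """A 3-compound screen (1 designed-active) written to disk."""
    from aggscreen.synthetic import (
        CompoundSpec,
        ScreenSpec,
        SimulationSpec,
        simulate_screen,
    )

    doses = (1e-8, 1e-7, 1e-6, 1e-5)
    compounds = (
        CompoundSpec(name="act", moa="moaA", doses=doses,
                     clustered_fractions=(0.2, 0.4, 0.6, 0.8)),
        CompoundSpec(name="null1", moa="moaA", doses=doses,
                     clustered_fractions=(0.0, 0.0, 0.0, 0.0)),
        CompoundSpec(name="null2", moa="moaB", doses=doses,
                     clustered_fractions=(0.0, 0.0, 0.0, 0.0)),
    )
    screen = ScreenSpec(
        compounds=compounds, n_fields=3, seed=11,
        base=SimulationSpec(image_shape=(192, 192), n_nuclei=8,
                            nucleus_radius_range=(10.0, 13.0), seed=0),
    )
    out = tmp_path_factory.mktemp("screen")
    fields, metadata_rows, truth_rows = simulate_screen(screen, out_dir=out)
    return {"dir": out, "fields": fields, "metadata": metadata_rows,
            "truth": truth_rows, "screen": screen}
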