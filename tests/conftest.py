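import numpy as np
import pytest

from cspws.optics import ACFParams, OpticsConfig, build_lut


@pytest.fixture(scope="session")
def optics():
    return OpticsConfig()


@pytest.fixture(scope="session")
def acf_params():
    return ACFParams(d=2.5)


@pytest.fixture(scope="session")
def ideal_lut(acf_params, optics):
    """Plain forward-curve LUT (exact round-trip identity)."""
    return build_lut(acf_params, optics)


@pytest.fixture(scope="session")
def calibrated_lut(acf_params, optics):
    """Pixel-calibrated LUT used by the D-map pipeline."""
    return build_lut(acf_params, optics, calibrate=True)


@pytest.fixture(scope="session")
def cube_factory(optics):
    """Simulate a small spectral cube at a given true D."""
    from cspws.synth import gen_density_field, simulate_spectral_cube

    def make(d_true, nxy=32, noise_sd=0.0, seed=0):
        params = ACFParams(d=d_true)
        nz = int(round(optics.depth_of_field / optics.axial_step))
        field = gen_density_field(
            params, (nxy, nxy, nz),
            (optics.coherence_xy, optics.coherence_xy, optics.axial_step),
            seed)
        return simulate_spectral_cube(field, optics, noise_sd=noise_sd,
                                      seed=seed + 1)

    return make
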