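import numpy as np
import pytest

import protonpbs as p


@pytest.fixture(scope="session")
def erm():
    return p.EnergyRangeModel()


@pytest.fixture(scope="session")
def hu_table():
    return p.build_hu_density_table(p.fixture_hu_density_curve())


@pytest.fixture(scope="session")
def water_density_coarse(hu_table):
    """30 cm water tank, 10 mm lateral / 1 mm depth voxels (IDD work)."""
    return p.densify(p.make_water_tank(30.0, (10.0, 10.0, 1.0)), hu_table)


@pytest.fixture(scope="session")
def water_density_fine(hu_table):
    """30 cm water tank, 2.5 mm lateral voxels (central-axis comparisons)."""
    return p.densify(p.make_water_tank(30.0, (2.5, 2.5, 1.0)), hu_table)


@pytest.fixture(scope="session")
def single_spot_source():
    return p.BeamSource(0.0, [0.0, 0.0, 0.0], [p.Spot(150.0, 1.0, fwhm_x_mm=8.0, fwhm_y_mm=8.0)])


@pytest.fixture(scope="session")
def mc_water_run(water_density_fine, single_spot_source):
    """One well-converged MC run in water shared by several checks."""
    return p.mc_dose(water_density_fine, single_spot_source, n_primaries=100_000, seed=11)


@pytest.fixture(scope="session")
def analytic_water_run(water_density_fine, single_spot_source):
    """Matching deterministic run (no extra lateral scattering term, like the MC)."""
    return p.analytic_dose(water_density_fine, single_spot_source, sigma_mcs=0.0)


def synthetic_calibration_table(noise_sigma: float = 0.0, seed: int = 0, n: int = 15):
    """Commissioning fixture: smooth declared curves over the energy interval."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    e = np.linspace(48.08, 221.07, n)
    sim = 0.998 * e + 0.3
    spread = 1.2 - 4.0e-3 * e + 1.5e-5 * e**2 - 2.0e-8 * e**3
    fx = 14.0 - 0.08 * e + 3.0e-4 * e**2 - 6.0e-7 * e**3 + 5.0e-10 * e**4
    fy = 15.0 - 0.09 * e + 3.5e-4 * e**2 - 7.0e-7 * e**3 + 6.0e-10 * e**4
    noise = lambda: rng.normal(0.0, noise_sigma, n) if noise_sigma else 0.0
    return pd.DataFrame(
        {
            "nominal_MeV": e,
            "simulated_MeV": sim + noise(),
            "spread_MeV": spread + noise(),
            "fwhm_x_mm": fx + noise(),
            "fwhm_y_mm": fy + noise(),
        }
    )
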