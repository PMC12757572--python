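"""Shared fixtures: toy parameters, synthetic clouds, and PDB helpers."""

import numpy as np
import pytest

from porescale.packing_model import PackingParameters, fit_packing, FitConfig
from porescale.pore_geometry import build_scale_grid, radial_profile
from porescale.synthetic import GeneratorConfig, sample_structure


def pdb_line(serial, name, res, chain, resseq, x, y, z, record="ATOM",
             altloc=" ", element=None):
    """Format one fixed-column PDB coordinate line."""
    if element is None:
        element = name[0]
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {name_field}{altloc}{res:>3s} "
            f"{chain}{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")


@pytest.fixture
def toy_params():
    """Reference packing parameters: ζ=5 Å, ξ=10 Å, K=1000, n0=10, l0=1 Å."""
    return PackingParameters(zeta=5.0, xi=10.0, capacity=1000.0,
                             n0=10.0, l0=1.0)


@pytest.fixture(scope="session")
def small_cloud():
    """10k-atom synthetic channel with known truth (seed 1)."""
    config = GeneratorConfig(n_total=10000, seed=1)
    structure, truth = sample_structure(config)
    return structure, truth


@pytest.fixture(scope="session")
def fitted_cloud(small_cloud):
    """Radial profile, scale grid, and packing fit of the small cloud."""
    structure, truth = small_cloud
    profile = radial_profile(structure, np.zeros(3))
    grid = build_scale_grid(profile)
    fit = fit_packing(profile, grid, FitConfig(seed=0))
    return structure, truth, profile, grid, fit
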