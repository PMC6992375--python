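import numpy as np
import pytest

from irmkit.optics import OpticalConfig
from irmkit.simulate import (
    CellScene,
    CellSpec,
    LensGeometry,
    cell_height_map,
    cell_optical_config,
    lens_height_map,
    lens_optical_config,
    render_irm,
    CELL_NA,
    LENS_NA,
    LENS_PIXEL_SIZE,
)


@pytest.fixture(scope="session")
def cell_cfg() -> OpticalConfig:
    """Bacteria in aqueous medium, imaged at 488 and 635 nm."""
    return cell_optical_config()


@pytest.fixture(scope="session")
def lens_cfg() -> OpticalConfig:
    """Lens-on-glass in air, imaged at 488 nm."""
    return lens_optical_config((488.0,))


@pytest.fixture(scope="session")
def lens_geom() -> LensGeometry:
    return LensGeometry(radius_of_curvature=20.0)


@pytest.fixture(scope="session")
def lens_frame(lens_geom, lens_cfg):
    """Noise-free rendered lens image, 488 nm, gap n = 1."""
    extent = 1030 * LENS_PIXEL_SIZE
    hm = lens_height_map(lens_geom, extent, LENS_PIXEL_SIZE)
    return render_irm(hm, lens_cfg, na=LENS_NA)


@pytest.fixture(scope="session")
def straight_line():
    """A 5-μm horizontal centerline used by the cell fixtures."""
    return np.array([[2.0, 5.0], [7.0, 5.0]])


def render_cell(cell: CellSpec, cfg: OpticalConfig, noise_sd: float = 0.0,
                seed: int = 0, shape=(100, 100), pixel_size: float = 0.1):
    hm = cell_height_map(CellScene([cell]), shape, pixel_size)
    return render_irm(hm, cfg, noise_sd=noise_sd, seed=seed, na=CELL_NA)


@pytest.fixture(scope="session")
def lift_frame(straight_line, cell_cfg):
    """Noise-free render of a cell attached at the leading pole and rising
    linearly to 180 nm at the lagging pole."""
    cell = CellSpec(straight_line, profile="single_lift", params={"lift_nm": 180.0})
    return render_cell(cell, cell_cfg)


@pytest.fixture(scope="session")
def undulating_frame(straight_line, cell_cfg):
    """Noise-free render of the undulating morphology (0 -> 180 -> 90 -> 180 nm)."""
    cell = CellSpec(straight_line, profile="undulating")
    return render_cell(cell, cell_cfg)
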