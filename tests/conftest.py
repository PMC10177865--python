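import numpy as np
import pytest

from emt_phenotyper.synthetic import CellSceneSpec, generate_cell_scene


@pytest.fixture(scope="session")
def mesenchymal_scene():
    """Spindle-cell scene targeting A_R 0.240 +/- 0.157, n = 60."""
    spec = CellSceneSpec(n_cells=60, phenotype="mesenchymal", seed=42)
    nuclei, actin, truth = generate_cell_scene(spec)
    return spec, nuclei, actin, truth


@pytest.fixture(scope="session")
def epithelial_scene():
    spec = CellSceneSpec(n_cells=50, phenotype="epithelial", seed=7)
    nuclei, actin, truth = generate_cell_scene(spec)
    return spec, nuclei, actin, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
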