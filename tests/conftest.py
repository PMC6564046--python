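import numpy as np
import pytest

from ccdrift.pedigree import Cell, Pedigree
from ccdrift.synthetic import SyntheticConfig, generate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def _cell(cid, pid, birth, tg1=4.0, tsg=6.0):
    return Cell(id=cid, parent_id=pid, birth_time=birth, t_g1=tg1, t_sg2m=tsg)


@pytest.fixture
def three_generation_pedigree():
    """A divides into (X, Y); X into (L, M); Y into (N, P): 7 cells."""
    cells = [
        _cell("A", None, 0.0, 4.0, 6.0),
        _cell("X", "A", 10.0, 3.0, 5.0),
        _cell("Y", "A", 10.0, 5.0, 7.0),
        _cell("L", "X", 18.0, 4.0, 4.0),
        _cell("M", "X", 18.0, 4.5, 5.5),
        _cell("N", "Y", 22.0, 3.5, 6.5),
        _cell("P", "Y", 22.0, 5.0, 5.0),
    ]
    return Pedigree(cells)


@pytest.fixture(scope="session")
def small_experiment():
    """One shared synthetic 72 h experiment (ground truth attached)."""
    cfg = SyntheticConfig(n_lineages=10, seed=7)
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def noiseless_experiment():
    cfg = SyntheticConfig(n_lineages=4, seed=11, noise_rel_sd=0.0)
    return generate_experiment(cfg)
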