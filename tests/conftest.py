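import numpy as np
import pytest

import pkpdcombo as pc


@pytest.fixture(scope="session")
def fx():
    return pc.reference_fixtures()


@pytest.fixture(scope="session")
def gem(fx):
    return fx["gemcitabine"]


@pytest.fixture(scope="session")
def fu(fx):
    return fx["fluorouracil"]


@pytest.fixture(scope="session")
def itz(fx):
    return fx["itraconazole"]


@pytest.fixture(scope="session")
def gem_regimen(fx):
    return fx["gemcitabine_regimen"]


@pytest.fixture(scope="session")
def fu_regimen(fx):
    return fx["fluorouracil_regimen"]


@pytest.fixture(scope="session")
def itz_regimen(fx):
    return fx["itraconazole_regimen_100"]


@pytest.fixture(scope="session")
def gem_trajectory(gem, gem_regimen):
    """Reference gemcitabine run: RK4, h=0.02, 400 min."""
    return pc.integrate_disposition(gem, gem_regimen, pc.SimulationGrid(400.0, 0.02))


@pytest.fixture(scope="session")
def fu_trajectory(fu, fu_regimen):
    """Reference 5-FU run: RK4, h=0.02, 200 min."""
    return pc.integrate_disposition(fu, fu_regimen, pc.SimulationGrid(200.0, 0.02))


def self_consistent(params: pc.PKParameters) -> pc.PKParameters:
    """Truth with the tissue volume implied by Vd2 = Vd1*k12/k21.

    Plasma data cannot identify an independent Vd2, so recovery studies
    use truths satisfying the same constraint the fitter reports under.
    """
    return pc.PKParameters(vd1=params.vd1, vd2=params.vd1 * params.k12 / params.k21,
                           cl=params.cl, k12=params.k12, k21=params.k21)


@pytest.fixture(scope="session")
def constant_tissue_trajectory():
    """Hand-built trajectory with constant tissue concentration."""
    def make(conc: float, t_end: float = 100.0, h: float = 0.5,
             params: pc.PKParameters | None = None) -> pc.DispositionTrajectory:
        params = params or pc.PKParameters(vd1=1000.0, vd2=1000.0, cl=10.0,
                                           k12=0.01, k21=0.01)
        n = round(t_end / h)
        times = np.arange(n + 1) * h
        tissue_amount = np.full(n + 1, conc * params.vd2 / 1000.0)
        zeros = np.zeros(n + 1)
        return pc.DispositionTrajectory(
            times=times, plasma_amount=zeros, tissue_amount=tissue_amount,
            eliminated_amount=zeros, administered=zeros + tissue_amount,
            plasma_conc=zeros, tissue_conc=np.full(n + 1, conc),
            auc_plasma=zeros, params=params, h=h)
    return make
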