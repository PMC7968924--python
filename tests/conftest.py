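import numpy as np
import pytest

from genedrive.genetics import DriveParams, FitnessModel, build_cube
from genedrive.inference import FitParameters
from genedrive.presets import preset_parameters


@pytest.fixture(scope="session")
def fitted_params() -> DriveParams:
    return preset_parameters("fitted_homer")


@pytest.fixture(scope="session")
def fitted_fit_params() -> FitParameters:
    p = preset_parameters("fitted_homer")
    return FitParameters(c_F=p.c_F, c_M=p.c_M, ch_F=p.ch_F, ch_M=p.ch_M,
                         cr=p.cr_F, s_F=p.s_F)


@pytest.fixture(scope="session")
def fitted_cube_1l(fitted_params):
    return build_cube("homer", "one_locus", fitted_params)


@pytest.fixture(scope="session")
def fitted_cube_2l(fitted_params):
    return build_cube("homer", "two_locus", fitted_params)


@pytest.fixture(scope="session")
def fitted_fitness_1l(fitted_params):
    return FitnessModel("homer", "one_locus", fitted_params)


@pytest.fixture(scope="session")
def mendelian_cube_1l():
    return build_cube("homer", "one_locus", DriveParams())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
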