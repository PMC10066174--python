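import pytest

from scrncmp import make_example


@pytest.fixture(scope="session")
def ek1():
    """Closed enzyme kinetics, S_tot=3, E_tot=2, base rates 1, k3_breve=2."""
    return make_example("ek1")


@pytest.fixture(scope="session")
def ek1_pair(ek1):
    return ek1.pair()


@pytest.fixture(scope="session")
def ek1_neg():
    """Negative control: the catalytic constant is *lowered* in the modified chain."""
    return make_example("ek1", kappa3_breve=0.5)


@pytest.fixture(scope="session")
def braess():
    """Braess-topology relay, S_tot=2, equal exit constants k2 = k4."""
    return make_example("braess", S_tot=2)


@pytest.fixture(scope="session")
def chromatin():
    """Reduced histone-modification circuit, D_tot=3, mu=1 vs mu_breve=2."""
    return make_example("chromatin")
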