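import numpy as np
import pytest

from tbpkinetics import KineticParameters, default_parameters


@pytest.fixture
def table2() -> KineticParameters:
    """Literature mammalian parameter set (basal synthesis on)."""
    return default_parameters()


@pytest.fixture
def table2_k0zero(table2) -> KineticParameters:
    """Same set without basal synthesis: the three-state configuration."""
    return table2.replace(k0=0.0)


def draw_parameters(rng: np.random.Generator, k6: float | None = None,
                    k0_zero: bool = True) -> KineticParameters:
    """Log-uniform random parameter set spanning the physiological decades."""
    def lu(lo, hi):
        return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))

    k5 = lu(1e-15, 1e-10)
    return KineticParameters(
        k0=0.0 if k0_zero else 0.01 * k5,
        k1=lu(1e3, 1e7),
        k2=lu(1e-5, 1e-1),
        k3=lu(1e3, 1e7),
        k4=lu(1e-6, 1e-2),
        k5=k5,
        k6=k6 if k6 is not None else lu(0.5, 4.0),
        k7=lu(1e-10, 1e-5),
        k8=lu(1e-6, 1e-3),
        D0=lu(1e-9, 1e-5),
    )
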