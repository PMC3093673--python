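import numpy as np
import pytest

from cleftflux import CleftGeometry, SeriesConfig, TransportParams


@pytest.fixture(scope="session")
def geometry():
    """Standard unit cell: 500x500 nm cell, 50 nm deep, R=20 nm, a=10 nm."""
    return CleftGeometry()


@pytest.fixture(scope="session")
def transport():
    """Anchor transport parameters: D = 1e5 nm^2/ms, t0 = 1 ms."""
    return TransportParams()


@pytest.fixture(scope="session")
def config():
    return SeriesConfig()


@pytest.fixture(scope="session")
def tables(geometry, config):
    """Source and sink coefficient tables at the default truncation."""
    from cleftflux.coefficients import cached_table

    q = cached_table(geometry.R, geometry, config.lmax, config.quad_order)
    p = cached_table(geometry.a, geometry, config.lmax, config.quad_order)
    return q, p


@pytest.fixture(scope="session")
def anchor_curve(geometry, transport, config):
    """Analytic J(t) at the anchor parameters on a grid covering the peak."""
    from cleftflux import response_curve

    times = np.geomspace(1e-3, 20.0, 300)
    return response_curve(times, geometry, transport, config)
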