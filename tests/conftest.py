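import numpy as np
import pytest

from crossvol import CrossSection, Slab


def random_frustum_slab(rng: np.random.Generator, n: int | None = None) -> Slab:
    """A random well-formed frustum slab with irregular interior d."""
    n = n or int(rng.integers(1, 9))
    L = float(rng.uniform(0.2, 3.0))
    start = float(rng.uniform(0.0, 2.0))
    d = rng.uniform(0.3, 2.0, size=n + 1)
    phi = rng.uniform(0.5, 1.0, size=2)   # within (pi/4-ish, square]
    # psi must respect the isoperimetric bound psi^2 >= 4 pi phi
    psi = np.array([
        rng.uniform(np.sqrt(4 * np.pi * p) * 1.01, 4.2) for p in phi
    ])
    ant = CrossSection(station=start, d=d[0], S=phi[0] * d[0] ** 2, C=psi[0] * d[0])
    post = CrossSection(station=start + L, d=d[-1], S=phi[1] * d[-1] ** 2,
                        C=psi[1] * d[-1])
    return Slab(anterior=ant, posterior=post, n=n,
                interior_d=tuple(d[1:-1]), mode="frustum")


def disk_mask(radius_px: int, pad: int = 10, scale: float = 1.0):
    """Rasterised disk: pixel centres inside the circle are foreground."""
    from crossvol import MaskImage

    n = 2 * radius_px + 2 * pad
    c = n / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    disk = (xx + 0.5 - c) ** 2 + (yy + 0.5 - c) ** 2 <= radius_px**2
    return MaskImage(pixels=disk, scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(1031)
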