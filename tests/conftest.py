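import numpy as np
import pytest

from gxesign import CellMeans, GxEDataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_cells(p00, p10, p01, p11):
    """Haploid cell-mean container from the four conditional means."""
    keys = [(0, 0), (1, 0), (0, 1), (1, 1)]
    return CellMeans(P=dict(zip(keys, [p00, p10, p01, p11])),
                     counts={k: 1 for k in keys})


def saturated_panel(rng, n=400, mu=1.0, alpha=2.0, beta=3.0, gamma=0.0,
                    noise_sd=0.0, p_e=0.5, maf=0.5):
    """Haploid single-variant panel with all four (E, G) cells populated."""
    while True:
        E = (rng.random(n) < p_e).astype(float)
        G = (rng.random(n) < maf).astype(np.int8)
        cells = {(a, b): ((E == a) & (G == b)).sum() for a in (0, 1) for b in (0, 1)}
        if min(cells.values()) > 0:
            break
    y = mu + alpha * E + beta * G + gamma * G * E
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, n)
    return GxEDataset(genotypes=G[:, None], exposure=E, phenotype=y, ploidy=1)
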