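import numpy as np
import pytest

from shapecomp import BlobParams, Contour, canonicalize, generate_blob
from shapecomp.descriptors import default_bank


def circle_contour(n: int = 384, r: float = 0.5, center=(0.5, 0.5)) -> Contour:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])
    return Contour(pts)


def square_contour(side: float = 1.0) -> Contour:
    return Contour(np.array([[0, 0], [side, 0], [side, side], [0, side]], float))


def star_contour(n_spikes: int = 5, r_out: float = 1.0, r_in: float = 0.4) -> Contour:
    t = np.linspace(0, 2 * np.pi, 2 * n_spikes, endpoint=False)
    r = np.where(np.arange(2 * n_spikes) % 2 == 0, r_out, r_in)
    return Contour(np.column_stack([r * np.cos(t), r * np.sin(t)]))


def ellipse_contour(a: float = 1.0, b: float = 0.5, n: int = 384) -> Contour:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(np.column_stack([a * np.cos(t), b * np.sin(t)]))


@pytest.fixture(scope="session")
def bank():
    return default_bank()


@pytest.fixture(scope="session")
def blob():
    return generate_blob(BlobParams(seed=7))


@pytest.fixture(scope="session")
def blobs5():
    """Five distinct category-exemplar blobs."""
    return [
        generate_blob(
            BlobParams(
                seed=i,
                elongation=1.0 + 0.3 * i,
                n_lobes=2 + i,
                lobe_amplitude=0.15 + 0.05 * i,
                spikiness=0.02 + 0.01 * i,
            )
        )
        for i in range(5)
    ]


@pytest.fixture()
def canonical_circle():
    return canonicalize(circle_contour(), n=384)
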