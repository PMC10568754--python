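import numpy as np
import pytest

from segscore import SceneSpec, generate_scene


def triangle_pair_image(width: int = 31, height: int = 9) -> np.ndarray:
    """Two flat isoceles triangles sharing their base line, labels 1 and 2.

    Each triangle's centroid sits ~height/3 from the shared base while its
    minor feret is ~height, so a prediction that merges the two regions has
    its centroid within half the minor feret of *both* ground-truth
    centroids — the canonical under-segmentation geometry.
    """
    img = np.zeros((2 * height + 2, width + 4), dtype=int)
    c0 = 2 + width // 2
    for d in range(height):
        half = int(round((width / 2) * (1 - d / height)))
        img[height - 1 - d, c0 - half : c0 + half + 1] = 1
        img[height + d, c0 - half : c0 + half + 1] = 2
    return img


@pytest.fixture(scope="session")
def scene():
    """One default synthetic scene (label image, intensity image)."""
    return generate_scene(SceneSpec(seed=7))


@pytest.fixture
def triangle_image():
    return triangle_pair_image()
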