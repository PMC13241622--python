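from __future__ import annotations

import numpy as np
import pytest

from nanocluster.io_formats import ROIMask, RenderedImage
from nanocluster.segmentation import AnalysisConfig, ClusterSet, Cluster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return AnalysisConfig()


def make_image(pixels, pixel_size_nm=5.0):
    return RenderedImage(np.asarray(pixels, dtype=np.uint16), pixel_size_nm=pixel_size_nm)


def full_roi(shape):
    return ROIMask(include=np.ones(shape, dtype=bool))


def block_cluster(cluster_id, i0, j0, height, width, pixel_size_nm=5.0):
    """A solid rectangular cluster with top-left pixel (i0, j0)."""
    ii, jj = np.mgrid[i0 : i0 + height, j0 : j0 + width]
    return Cluster(
        cluster_id=cluster_id,
        pixels=np.column_stack([ii.ravel(), jj.ravel()]),
        pixel_size_nm=pixel_size_nm,
    )


def make_cluster_set(clusters, analyzed_area_nm2=1e6, pixel_size_nm=5.0):
    return ClusterSet(
        clusters=clusters,
        analyzed_area_nm2=analyzed_area_nm2,
        pixel_size_nm=pixel_size_nm,
    )


def random_blob_image(rng, shape=(64, 64), n_spots=8, pixel_size_nm=5.0):
    """A random image with smooth blobs plus noise, for oracle-equivalence tests."""
    from scipy import ndimage

    img = np.zeros(shape)
    for _ in range(n_spots):
        i, j = rng.integers(0, shape[0]), rng.integers(0, shape[1])
        img[i, j] = rng.uniform(50, 400)
    img = ndimage.gaussian_filter(img, sigma=rng.uniform(1.0, 2.5))
    img += rng.poisson(0.3, size=shape)
    return make_image(np.round(img * 40).astype(np.uint16), pixel_size_nm=pixel_size_nm)
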