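"""Shared fixtures: small filter banks and cached synthetic image sets."""

from __future__ import annotations

import numpy as np
import pytest

from patchrec import frontend, synthetic_data as sd


@pytest.fixture(scope="session")
def small_bank():
    """Four-orientation bank with four kernel sides (two C1 bands)."""
    return frontend.build_gabor_bank(scale_table=(7, 9, 11, 13))


@pytest.fixture(scope="session")
def small_bands():
    return frontend.default_bands((7, 9, 11, 13))


@pytest.fixture(scope="session")
def full_bank():
    return frontend.build_gabor_bank()


def compute_c1_small(img, bank, bands):
    return frontend.c1_pool(frontend.s1_transform(img, bank), bands)


@pytest.fixture(scope="session")
def face_miniset(small_bank, small_bands):
    """Four identities with C1 pyramids under the reduced two-band front end."""
    faces = sd.generate_faces(sd.FaceGenSpec(n_identities=4, seed=11))
    c1 = {i: compute_c1_small(li.image, small_bank, small_bands)
          for i, li in enumerate(faces)}
    return faces, c1


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_c1(rng, shape=(20, 16), n_ori=4, n_bands=2):
    """A synthetic C1 pyramid of random values for oracle tests."""
    bands = frontend.default_bands((7, 9, 11, 13))[:n_bands]
    oris = frontend.DEFAULT_ORIENTATIONS[:n_ori]
    maps = {}
    for bi in range(n_bands):
        h = shape[0] - 3 * bi
        w = shape[1] - 3 * bi
        for o in oris:
            maps[(o, bi)] = rng.random((h, w))
    return frontend.C1Pyramid(maps=maps, orientations=oris, bands=bands)
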