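"""Random-patch dictionary model (HMAX): S2 Gaussian tuning and C2 global max.

At training time, square patches (side x side x orientations) are cut from
C1 pyramids at random positions to form the prototype dictionary.  At test
time each prototype acts as the center of a Gaussian radial-basis unit: the
S2 response at every position of every scale band is
``exp(-||window - patch||^2 / (2 sigma^2))`` and the C2 response is the
global maximum over positions and bands, giving one value per prototype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from patchrec.frontend import C1Pyramid

#: The six patch sides (in C1 grid units) used throughout the experiments.
PATCH_SIZES: tuple[int, ...] = (4, 8, 12, 16, 20, 24)

#: Sharpness of the Gaussian S2 tuning: sigma^2 = SIGMA_SCALE * element count,
#: normalizing by patch dimension so responses are comparable across sizes.
#: The default is calibrated so that C2 responses spread over (0, 1] instead
#: of saturating near 1 under the global max (an exact patch match is still
#: exactly 1): identical-image re-encodings give 1.0, unrelated images of the
#: same domain give best-match responses well below the vigilance band.
SIGMA_SCALE = 0.001


class EmptyDictionaryError(ValueError):
    """Raised when an encoding is requested against an empty dictionary."""


@dataclass
class Prototype:
    """An intermediate-complexity feature: a C1 patch and its provenance."""

    patch: np.ndarray            # (side, side, n_orientations), values in [0, 1]
    side: int
    source: tuple               # (image_id, band_index, row, col)
    model_tag: str = "hmax"

    def __post_init__(self) -> None:
        if self.patch.shape[0] != self.side or self.patch.shape[1] != self.side:
            raise ValueError("patch shape does not match side")


@dataclass
class PrototypeDictionary:
    """Ordered pool of prototypes; C2 vector index i corresponds to entry i."""

    prototypes: list[Prototype] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.prototypes)

    @property
    def per_size_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for p in self.prototypes:
            counts[p.side] = counts.get(p.side, 0) + 1
        return counts

    def of_size(self, side: int) -> list[int]:
        """Indices of prototypes with the given side, in dictionary order."""
        return [i for i, p in enumerate(self.prototypes) if p.side == side]

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            for i, p in enumerate(self.prototypes):
                g = f.create_group(f"prototype_{i:06d}")
                g.create_dataset("patch", data=p.patch)
                g.attrs["side"] = p.side
                g.attrs["model_tag"] = p.model_tag
                g.attrs["source"] = repr(p.source)

    @classmethod
    def load(cls, path: str) -> "PrototypeDictionary":
        import ast

        protos = []
        with h5py.File(path, "r") as f:
            for key in sorted(f.keys()):
                g = f[key]
                protos.append(Prototype(
                    patch=g["patch"][()],
                    side=int(g.attrs["side"]),
                    source=tuple(ast.literal_eval(g.attrs["source"])),
                    model_tag=str(g.attrs["model_tag"]),
                ))
        return cls(protos)


# ---------------------------------------------------------------------------
# random patch sampling
# ---------------------------------------------------------------------------

def _valid_placements(c1: C1Pyramid, side: int) -> list[tuple[int, int, int]]:
    """All (band, max_row+1, max_col+1) where a side x side patch fits."""
    out = []
    for bi in c1.band_indices:
        st = c1.band_stack(bi)
        if st is None:
            continue
        h, w = st.shape[:2]
        if h >= side and w >= side:
            out.append((bi, h - side + 1, w - side + 1))
    return out


def cut_patch(c1: C1Pyramid, band: int, row: int, col: int, side: int) -> np.ndarray:
    st = c1.band_stack(band)
    return st[row:row + side, col:col + side, :].copy()


def sample_random_patches(
    c1_set: list[C1Pyramid],
    sizes: tuple[int, ...] = PATCH_SIZES,
    n_per_size: int = 250,
    seed: int | np.random.Generator = 0,
    image_ids: list | None = None,
    model_tag: str = "hmax",
) -> PrototypeDictionary:
    """Sample ``n_per_size`` random C1 patches per size from a set of pyramids.

    Sampling is uniform over images, then over the bands/positions where the
    patch fits; duplicates are allowed.  Fully reproducible under ``seed``.

    Raises
    ------
    ValueError
        If a requested side fits in no map of any image.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if image_ids is None:
        image_ids = list(range(len(c1_set)))
    protos: list[Prototype] = []
    for side in sizes:
        usable = [(i, pl) for i, pl in ((i, _valid_placements(c1, side))
                                        for i, c1 in enumerate(c1_set)) if pl]
        if not usable and n_per_size > 0:
            raise ValueError(f"patch side {side} fits in no C1 map of any image")
        for _ in range(n_per_size):
            i, pl = usable[rng.integers(len(usable))]
            band, nr, nc = pl[rng.integers(len(pl))]
            r = int(rng.integers(nr))
            c = int(rng.integers(nc))
            protos.append(Prototype(
                patch=cut_patch(c1_set[i], band, r, c, side),
                side=side,
                source=(image_ids[i], band, r, c),
                model_tag=model_tag,
            ))
    return PrototypeDictionary(protos)


# ---------------------------------------------------------------------------
# S2 / C2
# ---------------------------------------------------------------------------

def _sigma2(side: int, n_ori: int) -> float:
    return SIGMA_SCALE * side * side * n_ori


def s2_response(c1: C1Pyramid, proto: Prototype) -> dict[int, np.ndarray]:
    """Gaussian S2 response map of one prototype in every band it fits.

    Returns a mapping band index -> 2-D response map whose entry at (r, c)
    is ``exp(-d2 / (2 sigma^2))`` with ``d2`` the squared Euclidean distance
    between the prototype and the C1 window with top-left corner (r, c).
    Bands too small for the patch are skipped.
    """
    out: dict[int, np.ndarray] = {}
    side = proto.side
    flat = proto.patch.ravel()
    s2v = _sigma2(side, proto.patch.shape[2])
    for bi in c1.band_indices:
        st = c1.band_stack(bi)
        if st is None or st.shape[0] < side or st.shape[1] < side:
            continue
        win = sliding_window_view(st, (side, side, st.shape[2]))[:, :, 0]
        w = win.reshape(win.shape[0], win.shape[1], -1)
        d2 = ((w - flat) ** 2).sum(axis=2)
        out[bi] = np.exp(-d2 / (2.0 * s2v))
    return out


def _band_windows(st: np.ndarray, side: int) -> np.ndarray:
    """(n_positions, side*side*n_ori) matrix of all patch windows in a band."""
    win = sliding_window_view(st, (side, side, st.shape[2]))[:, :, 0]
    return win.reshape(-1, side * side * st.shape[2])


def c2_encode(c1: C1Pyramid, dictionary: PrototypeDictionary) -> np.ndarray:
    """C2 vector: per prototype, the global max S2 response over bands/positions.

    Vectorized: for each (band, side) pair the squared distances of all
    windows to all same-size prototypes are computed with one matrix product.
    """
    if dictionary.n == 0:
        raise EmptyDictionaryError("cannot encode against an empty dictionary")
    c2 = np.zeros(dictionary.n)
    by_size: dict[int, list[int]] = {}
    for i, p in enumerate(dictionary.prototypes):
        by_size.setdefault(p.side, []).append(i)
    stacks = [c1.band_stack(bi) for bi in c1.band_indices]
    for side, idx in by_size.items():
        P = np.stack([dictionary.prototypes[i].patch.ravel() for i in idx])
        p_sq = (P**2).sum(axis=1)
        s2v = _sigma2(side, dictionary.prototypes[idx[0]].patch.shape[2])
        best = np.zeros(len(idx))
        for st in stacks:
            if st is None or st.shape[0] < side or st.shape[1] < side:
                continue
            W = _band_windows(st, side)
            d2 = (W**2).sum(axis=1)[:, None] - 2.0 * (W @ P.T) + p_sq[None, :]
            np.clip(d2, 0.0, None, out=d2)
            r = np.exp(-d2.min(axis=0) / (2.0 * s2v))
            best = np.maximum(best, r)
        c2[idx] = best  # sides that fit nowhere keep response 0
    return c2


def encode_set(c1_set: list[C1Pyramid], dictionary: PrototypeDictionary) -> np.ndarray:
    """Stack C2 vectors for a list of images into an (n_images, N) matrix."""
    return np.stack([c2_encode(c1, dictionary) for c1 in c1_set])


def save_c2_matrix(matrix: np.ndarray, image_ids: list, path: str) -> None:
    """Write a C2 matrix with an image-id row index (CSV, or HDF5 for .h5)."""
    if str(path).endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("c2", data=np.asarray(matrix))
            f.create_dataset("image_ids",
                             data=np.array([str(i) for i in image_ids],
                                           dtype=h5py.string_dtype()))
        return
    import pandas as pd

    pd.DataFrame(np.asarray(matrix), index=image_ids).to_csv(path)
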