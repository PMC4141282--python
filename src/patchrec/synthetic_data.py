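"""Synthetic face, object, and natural-image generators.

The generators produce grayscale image sets with the statistical structure
the study design assumes, so the whole pipeline is testable without any
external image database:

* **Faces** — parametric renderings of an identity-specific configuration of
  eye / nose / mouth blobs inside a head contour, rendered at nine yaw views
  (0, +-22.5, +-45, +-67.5, +-90 degrees) with a horizontal-compression view
  warp, a few expression variants per view, and pixel noise.  The spatial
  extent over which identity-diagnostic geometry varies is an explicit
  parameter (``identity_scale``), which ties the generator to the patch-size
  analysis: identity information lives at that scale, not in single edges.
* **Objects** — visually distinct shape/texture families (gratings, blob
  constellations, rings, bars, polygons, checkers) with within-category
  jitter in position, scale, orientation and phase.
* **Natural pool** — unlabeled composites of 1/f noise, oriented structure
  and object primitives, diverse enough to learn generic dictionaries from.

All images satisfy the front-end contract: single channel, height 140,
values in [0, 1]; everything is deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from patchrec.frontend import TARGET_HEIGHT

#: Default canvas width; height is the front-end target height (140).
DEFAULT_WIDTH = 112

#: Yaw views of the face grid (degrees); 0 is frontal, +-90 full profile.
DEFAULT_VIEWS: tuple[float, ...] = (0.0, 22.5, -22.5, 45.0, -45.0,
                                    67.5, -67.5, 90.0, -90.0)

TRAIN_VIEWS: tuple[float, ...] = (0.0, 45.0, -45.0, 90.0, -90.0)
TEST_VIEWS: tuple[float, ...] = (22.5, -22.5, 67.5, -67.5)


@dataclass
class LabelledImage:
    """A grayscale image with its class label and generator metadata."""

    image: np.ndarray
    label: object
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FaceGenSpec:
    """Parameters of the synthetic face-identity set.

    ``identity_scale`` is the spatial extent (pixels) of the feature
    configuration that differs between identities; at the default 48 px it
    spans 12 C1 grid units of the finest band, so identity-diagnostic
    structure is invisible to 4x4 patches but covered by intermediate ones.
    """

    n_identities: int = 10
    views: tuple[float, ...] = DEFAULT_VIEWS
    expressions_per_view: int = 3
    identity_scale: float = 48.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        need = set(TRAIN_VIEWS) | set(TEST_VIEWS)
        if not need <= set(self.views):
            raise ValueError("views must cover the train and test view sets")


@dataclass(frozen=True)
class ObjectGenSpec:
    """Parameters of the synthetic object-category set."""

    n_categories: int = 5
    images_per_category: int = 80
    within_category_variation: float = 1.0
    noise_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.images_per_category < 80:
            raise ValueError("images_per_category must be >= 80 to allow 30/50 splits")


# ---------------------------------------------------------------------------
# drawing primitives (vectorized on coordinate grids)
# ---------------------------------------------------------------------------

def _grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    return np.mgrid[0:h, 0:w].astype(np.float64)


def _blob(Y, X, cy, cx, sy, sx, amp, angle=0.0):
    """Anisotropic blob with a flat core and crisp boundary.

    The super-Gaussian profile gives the sharp material edges of
    photographs, so that small C1 patches see generic oriented edge
    fragments rather than generator-specific smooth ramps.
    """
    ca, sa = np.cos(angle), np.sin(angle)
    y0 = (Y - cy) * ca + (X - cx) * sa
    x0 = -(Y - cy) * sa + (X - cx) * ca
    q = y0**2 / (2 * sy**2) + x0**2 / (2 * sx**2)
    return amp * np.exp(-(q**2))


def _ring(Y, X, cy, cx, ry, rx, width, amp):
    """Elliptical ring with a crisp profile."""
    d = np.sqrt(((Y - cy) / ry) ** 2 + ((X - cx) / rx) ** 2)
    q = (d - 1.0) ** 2 / (2 * (width / min(ry, rx)) ** 2)
    return amp * np.exp(-(q**2))


def _bar(Y, X, cy, cx, length, thickness, angle, amp):
    ca, sa = np.cos(angle), np.sin(angle)
    u = (X - cx) * ca + (Y - cy) * sa
    v = -(X - cx) * sa + (Y - cy) * ca
    along = np.exp(-((u**2 / (2 * (length / 2) ** 2)) ** 2))
    across = np.exp(-((v**2 / (2 * thickness**2)) ** 2))
    return amp * along * across


# ---------------------------------------------------------------------------
# faces
# ---------------------------------------------------------------------------

def _identity_params(rng: np.random.Generator, s: float) -> dict:
    """Draw the identity-specific facial geometry.

    Identity is carried by the *configuration* — offsets (pixels, relative
    to the face center) of eyes, brows, nose and mouth, jittered at the
    identity scale ``s`` — while the local shapes of the features themselves
    are shared by all identities (and perturbed only by expression), so
    identity-diagnostic structure lives at scale ``s`` rather than in any
    single local edge.
    """
    j = lambda a: rng.uniform(-a, a)  # noqa: E731
    ref = 48.0   # feature sizes and head stay fixed at the reference scale,
    #              only the configural layout spans the identity scale s
    return {
        "eye_dy": -0.30 * s + j(0.12 * s),
        "eye_dx": 0.30 * s + j(0.12 * s),
        "eye_asym": j(0.06 * s),
        "eye_ry": 0.055 * ref,
        "eye_rx": 0.085 * ref,
        "brow_gap": 0.12 * ref + j(0.08 * s),
        "nose_dy": 0.06 * s + j(0.10 * s),
        "nose_len": 0.20 * ref,
        "nose_wid": 0.05 * ref,
        "mouth_dy": 0.38 * s + j(0.12 * s),
        "mouth_w": 0.24 * ref + j(0.08 * s),
        "mouth_th": 0.035 * ref,
        "mouth_curve": 0.0,
        "head_rx": 0.58 * ref,
        "head_ry": 0.80 * ref,
        "shade": 0.0,
    }


def _render_face(p: dict, view: float, expr: dict, h: int, w: int,
                 noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Render one identity at one yaw view with one expression perturbation."""
    Y, X = _grid(h, w)
    cy, cx = h / 2.0, w / 2.0
    th = np.deg2rad(view)
    compress = np.cos(th)            # horizontal foreshortening
    nose_shift = 0.35 * p["nose_len"] * np.sin(th)   # nose sticks out of the plane

    def vx(dx):                       # view-warped x offset
        return dx * compress + nose_shift * 0.3

    img = np.full((h, w), 0.78)
    img += p["shade"] * (X - cx) / w  # gentle identity-specific shading gradient
    # head contour (darker interior + outline ring)
    hrx = max(p["head_rx"] * abs(compress) + 0.18 * p["head_rx"], 6.0)
    d = np.sqrt(((Y - cy) / p["head_ry"]) ** 2 + ((X - (cx + nose_shift * 0.3)) / hrx) ** 2)
    img -= 0.12 * (d < 1.0)
    img -= _ring(Y, X, cy, cx + nose_shift * 0.3, p["head_ry"], hrx, 2.0, 0.25)

    eye_open = p["eye_ry"] * expr["eye_aperture"]
    for side_sign, vis in ((-1.0, view < 90), (1.0, view > -90)):
        if not vis:                   # far eye occluded at full profile
            continue
        ex = side_sign * (p["eye_dx"] + side_sign * p["eye_asym"])
        img -= _blob(Y, X, cy + p["eye_dy"], cx + vx(ex),
                     max(eye_open, 0.8), max(p["eye_rx"] * compress, 0.8), 0.45)
        img -= _bar(Y, X, cy + p["eye_dy"] - p["brow_gap"], cx + vx(ex),
                    2.6 * p["eye_rx"] * abs(compress) + 1.0, 1.1, 0.0, 0.30)
    # nose: vertical bar ending in a blob, shifted toward the leading edge
    nx = cx + nose_shift
    img -= _bar(Y, X, cy + p["nose_dy"], nx, p["nose_len"],
                max(p["nose_wid"], 0.8), np.pi / 2, 0.30)
    img -= _blob(Y, X, cy + p["nose_dy"] + 0.5 * p["nose_len"], nx,
                 max(p["nose_wid"], 1.0), max(1.4 * p["nose_wid"], 1.0), 0.25)
    # mouth: curved horizontal bar
    mw = max(p["mouth_w"] * expr["mouth_width"] * abs(compress), 1.5)
    curve = (p["mouth_curve"] + expr["mouth_curve"])
    my = cy + p["mouth_dy"] + curve * ((X - cx - nose_shift * 0.3) / max(mw, 1.0)) ** 2
    u = X - (cx + nose_shift * 0.3)
    img -= (0.40 * np.exp(-(u**2) / (2 * (mw / 1.6) ** 2))
            * np.exp(-((Y - my) ** 2) / (2 * p["mouth_th"] ** 2)))
    img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_faces(spec: FaceGenSpec, width: int = DEFAULT_WIDTH) -> list[LabelledImage]:
    """Generate the full identity x view x expression grid of face images.

    Returns ``n_identities * len(views) * expressions_per_view`` labelled
    images; ``label`` is the identity index and ``meta`` holds the view and
    expression indices.  Deterministic under ``spec.seed``.
    """
    master = np.random.default_rng(spec.seed)
    id_seeds = master.integers(0, 2**31 - 1, size=spec.n_identities)
    out: list[LabelledImage] = []
    for ident in range(spec.n_identities):
        id_rng = np.random.default_rng(id_seeds[ident])
        params = _identity_params(id_rng, spec.identity_scale)
        img_seeds = id_rng.integers(0, 2**31 - 1,
                                    size=len(spec.views) * spec.expressions_per_view)
        k = 0
        for view in spec.views:
            for e in range(spec.expressions_per_view):
                r = np.random.default_rng(img_seeds[k]); k += 1
                expr = {
                    "eye_aperture": r.uniform(0.7, 1.3),
                    "mouth_width": r.uniform(0.85, 1.15),
                    "mouth_curve": r.uniform(-1.5, 1.5),
                }
                img = _render_face(params, view, expr, TARGET_HEIGHT, width,
                                   spec.noise_sd, r)
                out.append(LabelledImage(img, ident,
                                         {"view": view, "expression": e}))
    return out


# ---------------------------------------------------------------------------
# objects
# ---------------------------------------------------------------------------

_N_FAMILIES = 6


def _render_object(family: int, cat: dict, jit: dict, h: int, w: int,
                   noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Render one object image of a category with within-category jitter."""
    Y, X = _grid(h, w)
    cy = h / 2.0 + jit["dy"]
    cx = w / 2.0 + jit["dx"]
    sc = cat["scale"] * jit["scale"]
    ang = cat["angle"] + jit["angle"]
    img = np.full((h, w), 0.72)
    if family == 0:       # grating inside a disc
        u = (X - cx) * np.cos(ang) + (Y - cy) * np.sin(ang)
        mask = np.exp(-(((Y - cy) ** 2 + (X - cx) ** 2) / (2 * (1.1 * sc) ** 2)))
        img -= 0.4 * mask * (0.5 + 0.5 * np.sin(2 * np.pi * u / cat["period"]
                                                + jit["phase"]))
    elif family == 1:     # constellation of blobs (fixed category layout)
        for (oy, ox, r) in cat["blobs"]:
            img -= _blob(Y, X, cy + oy * sc, cx + ox * sc,
                         r * sc, r * sc, 0.5)
    elif family == 2:     # concentric rings
        for i in range(cat["n_rings"]):
            rr = sc * (0.35 + 0.65 * i / max(cat["n_rings"] - 1, 1))
            img -= _ring(Y, X, cy, cx, rr, rr, 1.6, 0.45)
    elif family == 3:     # fan of bars
        for i in range(cat["n_bars"]):
            a = ang + i * cat["bar_step"]
            img -= _bar(Y, X, cy, cx, 2 * sc, cat["bar_th"], a, 0.5)
    elif family == 4:     # polygon contour
        k = cat["n_vertices"]
        vs = [(cy + sc * np.sin(ang + 2 * np.pi * i / k),
               cx + sc * np.cos(ang + 2 * np.pi * i / k)) for i in range(k)]
        for i in range(k):
            (y1, x1), (y2, x2) = vs[i], vs[(i + 1) % k]
            mcy, mcx = (y1 + y2) / 2, (x1 + x2) / 2
            seg = np.hypot(y2 - y1, x2 - x1)
            a = np.arctan2(y2 - y1, x2 - x1)
            img -= _bar(Y, X, mcy, mcx, seg, 1.3, a, 0.5)
    else:                 # checkerboard patch
        u = (X - cx) * np.cos(ang) + (Y - cy) * np.sin(ang)
        v = -(X - cx) * np.sin(ang) + (Y - cy) * np.cos(ang)
        mask = np.exp(-((u**2 + v**2) / (2 * (1.1 * sc) ** 2)))
        img -= 0.45 * mask * (np.sign(np.sin(2 * np.pi * u / cat["period"]
                                             + jit["phase"])
                                      * np.sin(2 * np.pi * v / cat["period"]
                                               + jit["phase"])) * 0.5 + 0.5)
    img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def _category_params(family: int, rng: np.random.Generator) -> dict:
    cat = {
        "scale": rng.uniform(24, 34),
        "angle": rng.uniform(0, np.pi),
        "period": rng.uniform(7, 14),
        "n_rings": int(rng.integers(2, 5)),
        "n_bars": int(rng.integers(2, 5)),
        "bar_step": rng.uniform(0.5, 1.2),
        "bar_th": rng.uniform(1.2, 2.5),
        "n_vertices": int(rng.integers(3, 7)),
    }
    n_blobs = int(rng.integers(3, 6))
    cat["blobs"] = [(rng.uniform(-0.8, 0.8), rng.uniform(-0.8, 0.8),
                     rng.uniform(0.08, 0.2)) for _ in range(n_blobs)]
    return cat


def generate_objects(spec: ObjectGenSpec, width: int = DEFAULT_WIDTH) -> list[LabelledImage]:
    """Generate labelled images for visually distinct shape-family categories.

    Categories cycle through six shape families and additionally differ in
    their drawn parameters; within-category images jitter in position,
    scale, orientation and texture phase (amplitude set by
    ``within_category_variation``).  Deterministic under ``spec.seed``.
    """
    master = np.random.default_rng(spec.seed)
    cat_seeds = master.integers(0, 2**31 - 1, size=spec.n_categories)
    out: list[LabelledImage] = []
    v = spec.within_category_variation
    for ci in range(spec.n_categories):
        crng = np.random.default_rng(cat_seeds[ci])
        family = ci % _N_FAMILIES
        cat = _category_params(family, crng)
        img_seeds = crng.integers(0, 2**31 - 1, size=spec.images_per_category)
        for k in range(spec.images_per_category):
            r = np.random.default_rng(img_seeds[k])
            jit = {
                "dy": r.uniform(-8, 8) * v,
                "dx": r.uniform(-8, 8) * v,
                "scale": 1.0 + r.uniform(-0.12, 0.12) * v,
                "angle": r.uniform(-0.18, 0.18) * v,
                "phase": r.uniform(0, 2 * np.pi),
            }
            img = _render_object(family, cat, jit, TARGET_HEIGHT, width,
                                 spec.noise_sd, r)
            out.append(LabelledImage(img, ci, {"family": family, "index": k}))
    return out


# ---------------------------------------------------------------------------
# natural pool
# ---------------------------------------------------------------------------

def _pink_noise(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """1/f spatial noise, rescaled to [0, 1]."""
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.sqrt(fy**2 + fx**2)
    f[0, 0] = 1.0
    spectrum = (rng.normal(size=(h, w)) + 1j * rng.normal(size=(h, w))) / f
    img = np.real(np.fft.ifft2(spectrum))
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) if hi > lo else np.full((h, w), 0.5)


def generate_natural_pool(n_images: int, seed: int = 0,
                          width: int = DEFAULT_WIDTH) -> list[LabelledImage]:
    """Generate a diverse unlabeled pool emulating generic natural scenes.

    Each image is a 1/f-noise background composited with a random number of
    oriented bars, grating patches and object primitives at random
    positions, so patch dictionaries sampled from the pool contain generic
    oriented and textured structure at every size.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=n_images)
    h = TARGET_HEIGHT
    out: list[LabelledImage] = []
    for k in range(n_images):
        r = np.random.default_rng(seeds[k])
        img = 0.55 * _pink_noise(h, width, r) + 0.22
        Y, X = _grid(h, width)
        for _ in range(int(r.integers(2, 7))):
            kind = int(r.integers(3))
            cy, cx = r.uniform(10, h - 10), r.uniform(10, width - 10)
            if kind == 0:
                img -= _bar(Y, X, cy, cx, r.uniform(15, 60), r.uniform(1, 3),
                            r.uniform(0, np.pi), r.uniform(0.2, 0.45))
            elif kind == 1:
                s = r.uniform(3, 14)
                img -= _blob(Y, X, cy, cx, s, s * r.uniform(0.5, 1.5),
                             r.uniform(0.2, 0.45), r.uniform(0, np.pi))
            else:
                u = (X - cx) * np.cos(r.uniform(0, np.pi)) \
                    + (Y - cy) * np.sin(r.uniform(0, np.pi))
                mask = np.exp(-(((Y - cy) ** 2 + (X - cx) ** 2)
                                / (2 * r.uniform(8, 22) ** 2)))
                img -= (r.uniform(0.2, 0.4) * mask
                        * np.sin(2 * np.pi * u / r.uniform(5, 15)) ** 2)
        img += r.normal(0.0, 0.02, size=img.shape)
        out.append(LabelledImage(np.clip(img, 0.0, 1.0), None, {"index": k}))
    return out


# ---------------------------------------------------------------------------
# convenience selectors
# ---------------------------------------------------------------------------

def images(collection: list[LabelledImage]) -> list[np.ndarray]:
    return [li.image for li in collection]


def labels(collection: list[LabelledImage]) -> list:
    return [li.label for li in collection]
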