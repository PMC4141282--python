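"""Image-collection and configuration I/O.

Collections live on disk in a ``<label>/<image>`` directory layout (PNG,
PGM or JPEG) with an optional ``manifest.csv`` carrying extra metadata
columns (e.g. ``view`` and ``expression`` for face sets).  Front-end
parameter tables (orientations, Gabor scales, C1 bands) can be overridden
from a YAML or JSON config file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from patchrec import frontend
from patchrec.synthetic_data import LabelledImage

IMAGE_EXTENSIONS = (".png", ".pgm", ".jpg", ".jpeg")


def load_image(path: str | Path) -> np.ndarray:
    """Read one image file and preprocess it to the 140-pixel-height contract."""
    with Image.open(path) as im:
        raw = np.asarray(im)
    return frontend.preprocess_image(raw)


def load_collection(root: str | Path) -> list[LabelledImage]:
    """Load a labelled collection from a ``<label>/<image>`` directory tree.

    If ``root/manifest.csv`` exists (columns ``label, file`` plus optional
    metadata), it defines the collection; otherwise every image file found
    under a first-level subdirectory is loaded with that subdirectory's
    name as its label.
    """
    root = Path(root)
    manifest = root / "manifest.csv"
    out: list[LabelledImage] = []
    if manifest.exists():
        df = pd.read_csv(manifest)
        meta_cols = [c for c in df.columns if c not in ("label", "file")]
        for _, row in df.iterrows():
            img = load_image(root / str(row["file"]))
            meta = {c: row[c] for c in meta_cols}
            out.append(LabelledImage(img, str(row["label"]), meta))
        return out
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(sub.iterdir()):
            if f.suffix.lower() in IMAGE_EXTENSIONS:
                out.append(LabelledImage(load_image(f), sub.name, {"file": f.name}))
    if not out:
        raise FileNotFoundError(f"no labelled images found under {root}")
    return out


def save_collection(collection: list[LabelledImage], root: str | Path) -> None:
    """Write a collection as ``<label>/<index>.png`` plus a manifest CSV."""
    root = Path(root)
    rows = []
    for i, li in enumerate(collection):
        label = "unlabelled" if li.label is None else str(li.label)
        d = root / label
        d.mkdir(parents=True, exist_ok=True)
        name = f"{i:05d}.png"
        arr = np.clip(li.image * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(d / name)
        rows.append({"label": label, "file": f"{label}/{name}", **li.meta})
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)


# ---------------------------------------------------------------------------
# front-end configuration
# ---------------------------------------------------------------------------

def load_frontend_config(path: str | Path) -> tuple[list, tuple]:
    """Build (Gabor bank, C1 band table) from a YAML/JSON config file.

    Recognized keys (all optional): ``orientations`` (degrees),
    ``scales`` (odd kernel sides), ``bands`` (list of
    ``{scales: [a, b], pool: n, stride: m}``).
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    cfg = cfg or {}
    orientations = tuple(cfg.get("orientations", frontend.DEFAULT_ORIENTATIONS))
    scales = tuple(cfg.get("scales", frontend.DEFAULT_SCALES))
    bank = frontend.build_gabor_bank(orientations, scales)
    if "bands" in cfg:
        bands = tuple(
            frontend.ScaleBand(tuple(b["scales"]), int(b["pool"]), int(b["stride"]))
            for b in cfg["bands"])
    else:
        bands = frontend.default_bands(scales)
    return bank, bands
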