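"""Representational dissimilarity matrices and the within/between selectivity index.

An RDM over a set of C2 feature vectors has entry (i, j) equal to
``1 - r(i, j)`` with ``r`` the Pearson correlation; rows are grouped
contiguously by class label so each class forms a square block on the
diagonal.  The selectivity index summarizes an RDM's block structure as the
mean *correlation* within the diagonal blocks (diagonal cells excluded)
divided by the mean correlation between blocks; perfectly identity-specific
representations give within = 1, between = 0, index = +infinity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class RDM:
    """Square dissimilarity matrix with labels grouped into diagonal blocks."""

    matrix: np.ndarray
    labels: list
    block_index: dict = field(default_factory=dict)  # label -> (start, stop)

    def __post_init__(self) -> None:
        m = self.matrix
        assert m.ndim == 2 and m.shape[0] == m.shape[1]
        assert np.allclose(m, m.T, atol=1e-10), "RDM must be symmetric"
        assert np.allclose(np.diag(m), 0.0, atol=1e-10), "RDM diagonal must be 0"
        assert m.min() >= -1e-10 and m.max() <= 2.0 + 1e-10, "entries in [0, 2]"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SelectivityIndex:
    """Mean within-block correlation over mean between-block correlation."""

    value: float                 # may be +inf
    n_within: int
    n_between: int
    mean_within: float
    mean_between: float


def build_rdm(features: np.ndarray, labels: list) -> RDM:
    """1 - Pearson-correlation dissimilarity matrix, rows sorted by label.

    Zero-variance feature vectors (for which correlation is undefined) are
    excluded with a warning.  Label order follows first appearance, so runs
    with the same label sequence produce aligned matrices.

    Parameters
    ----------
    features
        (n_images, n_features) matrix of C2 vectors.
    labels
        Per-row class or identity labels.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two feature vectors")
    if len(labels) != X.shape[0]:
        raise ValueError("labels must match the number of feature vectors")
    ok = X.std(axis=1) > 0
    if not ok.all():
        logger.warning("excluding %d zero-variance feature vector(s) from RDM",
                       int((~ok).sum()))
    label_order = list(dict.fromkeys(labels))
    keep = [i for lab in label_order for i, li in enumerate(labels)
            if li == lab and ok[i]]
    Xs = X[keep]
    labs = [labels[i] for i in keep]
    if Xs.shape[0] < 2:
        raise ValueError("fewer than two usable feature vectors")
    corr = np.corrcoef(Xs)
    m = 1.0 - corr
    np.fill_diagonal(m, 0.0)
    m = np.clip((m + m.T) / 2.0, 0.0, 2.0)
    blocks: dict = {}
    start = 0
    for lab in label_order:
        cnt = labs.count(lab)
        if cnt:
            blocks[lab] = (start, start + cnt)
            start += cnt
    return RDM(matrix=m, labels=labs, block_index=blocks)


def _block_masks(labels: list) -> tuple[np.ndarray, np.ndarray]:
    lab = np.asarray(labels, dtype=object)
    same = lab[:, None] == lab[None, :]
    off_diag = ~np.eye(len(lab), dtype=bool)
    return same & off_diag, (~same) & off_diag


def selectivity_index(features: np.ndarray, labels: list) -> SelectivityIndex:
    """Within-block over between-block mean correlation of the feature vectors.

    The diagonal (self-correlation) is excluded.  If the between-block mean
    is 0 and the within-block mean positive the index is ``+inf``; a
    negative denominator is reported as-is with a warning, since the ratio
    assumes non-negative correlations.
    """
    labs = list(labels)
    counts = {lab: labs.count(lab) for lab in set(labs)}
    eligible = [lab for lab, c in counts.items() if c >= 2]
    if len(eligible) < 2:
        raise ValueError("need >= 2 labels with >= 2 members each")
    rdm = build_rdm(features, labs)
    corr = 1.0 - rdm.matrix
    within_mask, between_mask = _block_masks(rdm.labels)
    mean_within = float(corr[within_mask].mean())
    mean_between = float(corr[between_mask].mean())
    if mean_between == 0.0:
        value = np.inf if mean_within > 0 else np.nan
    else:
        if mean_between < 0:
            logger.warning("negative mean between-block correlation %.4f; "
                           "selectivity ratio reported as-is", mean_between)
        value = mean_within / mean_between
    return SelectivityIndex(
        value=float(value),
        n_within=int(within_mask.sum()),
        n_between=int(between_mask.sum()),
        mean_within=mean_within,
        mean_between=mean_between,
    )


def average_rdms(rdms: list[RDM]) -> RDM:
    """Element-wise average of RDMs from runs with aligned label order."""
    if not rdms:
        raise ValueError("no RDMs to average")
    labels0 = rdms[0].labels
    for r in rdms[1:]:
        if r.labels != labels0:
            raise ValueError("RDM label orders are not aligned")
    m = np.mean([r.matrix for r in rdms], axis=0)
    return RDM(matrix=m, labels=labels0, block_index=dict(rdms[0].block_index))


def selectivity_to_jsonable(si: SelectivityIndex) -> dict:
    """JSON-safe dict; +infinity is serialized as the literal string 'inf'."""
    value = "inf" if np.isinf(si.value) else si.value
    return {"value": value, "n_within": si.n_within, "n_between": si.n_between,
            "mean_within": si.mean_within, "mean_between": si.mean_between}


def rdm_to_csv(rdm: RDM, path: str) -> None:
    """Write an RDM with label headers."""
    import pandas as pd

    df = pd.DataFrame(rdm.matrix, index=rdm.labels, columns=rdm.labels)
    df.to_csv(path)


def plot_rdm(rdm: RDM, path: str, title: str = "") -> None:
    """Render an RDM heatmap to PNG (optional visual output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.4))
    im = ax.imshow(rdm.matrix, vmin=0, vmax=2, cmap="viridis")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="1 - correlation")
    bounds = [b for (_, b) in rdm.block_index.values()][:-1]
    for b in bounds:
        ax.axhline(b - 0.5, color="w", lw=0.6)
        ax.axvline(b - 0.5, color="w", lw=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
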