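"""ART-inspired unsupervised prototype learning ("stable" dictionary model).

Each training image is presented once.  Its C2 activity against the current
prototype pool is the match signal: the P most active units form the
top-down expectation, and their mean activity is compared with a vigilance
threshold rho.  A match (resonance) leaves the pool untouched; a mismatch
(reset) extracts new candidate prototypes from the portions of the image
least covered by the current pool and admits them only if they are
sufficiently decorrelated from same-size prototypes already stored.

This is a functional implementation of the match/vigilance/reset contract:
C2 activity as the match signal, top-P expectation, mismatch-triggered
extraction.  The continuous on-center off-surround neural dynamics that
motivate it are not simulated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from patchrec.frontend import C1Pyramid
from patchrec.hmax_model import (
    PATCH_SIZES,
    EmptyDictionaryError,
    Prototype,
    PrototypeDictionary,
    c2_encode,
    cut_patch,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StableConfig:
    """Learning hyper-parameters of the stable model.

    Attributes
    ----------
    vigilance : float
        Match threshold rho in [0, 1]; the mean of the top-P C2 values must
        reach it for the image to resonate.
    top_p : int
        Number of most-active C2 units forming the expectation (default 5).
    dup_threshold : float
        Maximum Pearson correlation a candidate may have with any stored
        same-size prototype and still be admitted (decorrelation bar).
    per_reset : int
        Candidates extracted per patch size on each mismatch event.
    max_retries : int
        Mismatch/extraction rounds per image before it is flagged.
    """

    vigilance: float = 0.99
    top_p: int = 5
    dup_threshold: float = 0.7
    per_reset: int = 1
    max_retries: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.vigilance <= 1.0:
            raise ValueError("vigilance must be in [0, 1]")
        if self.top_p < 1:
            raise ValueError("top_p must be >= 1")
        if not 0.0 < self.dup_threshold <= 1.0:
            raise ValueError("dup_threshold must be in (0, 1]")


@dataclass
class TraceRecord:
    """Learning events for one image presentation."""

    image_id: object
    top_matches: list[float]
    match: float
    resonated: bool
    n_added: int
    flagged: bool = False


@dataclass
class LearningTrace:
    records: list[TraceRecord] = field(default_factory=list)
    per_size_counts: dict[int, int] = field(default_factory=dict)

    @property
    def total_added(self) -> int:
        return sum(r.n_added for r in self.records)

    def to_jsonl(self, path: str) -> None:
        with open(path, "w") as f:
            for r in self.records:
                f.write(json.dumps(asdict(r)) + "\n")


# ---------------------------------------------------------------------------
# match / vigilance
# ---------------------------------------------------------------------------

def top_p_select(c2: np.ndarray, p: int) -> list[int]:
    """Indices of the P largest C2 values, descending; ties go to the lower index."""
    if p < 1:
        raise ValueError("p must be >= 1")
    c2 = np.asarray(c2)
    if c2.size == 0:
        return []
    # stable sort on (-value, index): equal values keep ascending index order
    order = np.argsort(-c2, kind="stable")
    return [int(i) for i in order[:p]]


def vigilance_test(c2: np.ndarray | None, cfg: StableConfig) -> tuple[bool, float]:
    """Mean of the top-P C2 values vs. the vigilance threshold.

    An empty pool gives match 0 (no expectation can cover the input).
    Returns ``(resonated, match)``.
    """
    if c2 is None or np.asarray(c2).size == 0:
        match = 0.0
    else:
        c2 = np.asarray(c2)
        idx = top_p_select(c2, cfg.top_p)
        match = float(np.mean(c2[idx]))
    return match >= cfg.vigilance, match


# ---------------------------------------------------------------------------
# mismatch-triggered extraction
# ---------------------------------------------------------------------------

def _coverage_maps(
    c1: C1Pyramid, dictionary: PrototypeDictionary, side: int
) -> dict[int, np.ndarray]:
    """Per band: best S2 response of any stored same-size prototype at each
    candidate position (0 everywhere when none are stored)."""
    from patchrec.hmax_model import _band_windows, _sigma2

    same = [dictionary.prototypes[i] for i in dictionary.of_size(side)]
    P = np.stack([p.patch.ravel() for p in same]) if same else None
    cov: dict[int, np.ndarray] = {}
    for bi in c1.band_indices:
        st = c1.band_stack(bi)
        if st is None or st.shape[0] < side or st.shape[1] < side:
            continue
        shape = (st.shape[0] - side + 1, st.shape[1] - side + 1)
        if P is None:
            cov[bi] = np.zeros(shape)
            continue
        W = _band_windows(st, side)
        d2 = (W**2).sum(axis=1)[:, None] - 2.0 * (W @ P.T) + (P**2).sum(axis=1)[None, :]
        np.clip(d2, 0.0, None, out=d2)
        s2v = _sigma2(side, st.shape[2])
        cov[bi] = np.exp(-d2.min(axis=1) / (2.0 * s2v)).reshape(shape)
    return cov


#: RMS contrast below which a patch counts as empty: Pearson correlation of
#: near-constant patches reflects pixel noise, not structure, so two empty
#: patches are treated as exact duplicates (r = 1) and an empty patch never
#: correlates with a structured one (r = 0).
EMPTY_PATCH_RMS = 0.02


def _max_corr(candidate: np.ndarray, existing: list[np.ndarray]) -> float:
    """Largest Pearson correlation of the candidate with stored patches."""
    if not existing:
        return -np.inf
    a = candidate.ravel()
    a = a - a.mean()
    na = np.linalg.norm(a)
    rms_a = na / np.sqrt(a.size)
    best = -np.inf
    for e in existing:
        b = e.ravel()
        b = b - b.mean()
        nb = np.linalg.norm(b)
        rms_b = nb / np.sqrt(b.size)
        if rms_a < EMPTY_PATCH_RMS or rms_b < EMPTY_PATCH_RMS:
            r = 1.0 if max(rms_a, rms_b) < EMPTY_PATCH_RMS else 0.0
        else:
            r = float(a @ b / (na * nb))
        best = max(best, r)
    return best


def extract_new_prototypes(
    c1: C1Pyramid,
    dictionary: PrototypeDictionary,
    cfg: StableConfig,
    sizes: tuple[int, ...] = PATCH_SIZES,
    image_id: object = None,
    rng: np.random.Generator | None = None,
) -> list[Prototype]:
    """Cut candidate prototypes from the least-covered positions of an image.

    For each size, ``per_reset`` candidates are taken at the positions whose
    best S2 coverage by the current same-size pool is lowest (ties broken in
    band/row/column scan order).  A candidate is admitted to the dictionary
    only if its maximum Pearson correlation with stored same-size prototypes
    is below ``cfg.dup_threshold``.  Returns the admitted prototypes; zero
    admissions is legal.
    """
    added: list[Prototype] = []
    for side in sizes:
        cov = _coverage_maps(c1, dictionary, side)
        if not cov:
            continue
        # flatten candidate positions in deterministic scan order
        entries = []  # (coverage, order, band, row, col)
        order = 0
        for bi in sorted(cov):
            m = cov[bi]
            for r in range(m.shape[0]):
                for c in range(m.shape[1]):
                    entries.append((m[r, c], order, bi, r, c))
                    order += 1
        entries.sort(key=lambda t: (t[0], t[1]))
        existing = [dictionary.prototypes[i].patch
                    for i in dictionary.of_size(side)]
        n_taken = 0
        for covval, _, bi, r, c in entries:
            if n_taken >= cfg.per_reset:
                break
            patch = cut_patch(c1, bi, r, c, side)
            if _max_corr(patch, existing) < cfg.dup_threshold:
                proto = Prototype(patch=patch, side=side,
                                  source=(image_id, bi, r, c),
                                  model_tag="stable")
                dictionary.prototypes.append(proto)
                existing.append(patch)
                added.append(proto)
                n_taken += 1
            else:
                # correlated duplicate: skip to the next least-covered position
                n_taken += 1
    return added


# ---------------------------------------------------------------------------
# single-pass learning
# ---------------------------------------------------------------------------

def learn_dictionary(
    c1_images: list[C1Pyramid],
    cfg: StableConfig | None = None,
    sizes: tuple[int, ...] = PATCH_SIZES,
    seed: int = 0,
    image_ids: list | None = None,
    dictionary: PrototypeDictionary | None = None,
) -> tuple[PrototypeDictionary, LearningTrace]:
    """Single-pass ART-style learning over a sequence of C1 pyramids.

    Each image is encoded against the current pool and vigilance-tested; on
    mismatch new prototypes are extracted and the test repeats, up to
    ``cfg.max_retries`` rounds, after which the image is flagged in the
    trace.  Prototypes are never removed or modified once admitted.
    """
    if cfg is None:
        cfg = StableConfig()
    if not c1_images:
        raise ValueError("need at least one image")
    if image_ids is None:
        image_ids = list(range(len(c1_images)))
    rng = np.random.default_rng(seed)
    dictionary = dictionary if dictionary is not None else PrototypeDictionary()
    trace = LearningTrace()
    for img_id, c1 in zip(image_ids, c1_images):
        n_added = 0
        resonated, match, top = False, 0.0, []
        for _ in range(cfg.max_retries + 1):
            c2 = c2_encode(c1, dictionary) if dictionary.n else None
            resonated, match = vigilance_test(c2, cfg)
            top = ([float(c2[i]) for i in top_p_select(c2, cfg.top_p)]
                   if c2 is not None else [])
            if resonated:
                break
            new = extract_new_prototypes(c1, dictionary, cfg, sizes,
                                         image_id=img_id, rng=rng)
            if not new:   # nothing admissible left in this image
                break
            n_added += len(new)
        if not resonated:
            # re-test once more after the final extraction round
            c2 = c2_encode(c1, dictionary) if dictionary.n else None
            resonated, match = vigilance_test(c2, cfg)
        flagged = not resonated
        if flagged:
            logger.warning("image %r failed to resonate (match=%.3f)", img_id, match)
        trace.records.append(TraceRecord(
            image_id=img_id, top_matches=top, match=match,
            resonated=resonated and n_added == 0, n_added=n_added,
            flagged=flagged))
    trace.per_size_counts = dictionary.per_size_counts
    return dictionary, trace


def stable_c2_encode(c1: C1Pyramid, dictionary: PrototypeDictionary) -> np.ndarray:
    """Test-phase C2 encoding against a stable-learned dictionary.

    Identical computation to the HMAX C2 stage (shared code path).
    """
    if dictionary.n == 0:
        raise EmptyDictionaryError("cannot encode against an empty dictionary")
    return c2_encode(c1, dictionary)
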