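"""Study harness: splits, feature-learning modes, multi-run classification.

The harness reproduces the study design around the two dictionary models:

* **Tasks** — ``face_id`` (within-category: discriminate identities across
  unseen views) and ``object_cat`` (between-category: discriminate object
  classes).  Face splits train on views {0, +-45, +-90} and test on
  {+-22.5, +-67.5}; object splits use 30 train / 50 test images per class.
* **Feature-learning modes** — ``within`` (dictionary learned from the
  split's own training images), ``between`` (from held-out labels of the
  same domain), ``natural`` (from a generic natural-image pool).
* **Runs** — every experiment is repeated over random splits (defaults: 15
  for faces, 30 for objects); per-run accuracy is the percentage of correct
  linear-SVM classifications of test C2 vectors, and mean/SD over runs is
  reported per patch size.
* **Statistics** — patch sizes are compared pairwise with two-sided
  Wilcoxon rank-sum tests over the per-run accuracy samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from patchrec import frontend, hmax_model, stable_model
from patchrec.hmax_model import PATCH_SIZES
from patchrec.synthetic_data import TEST_VIEWS, TRAIN_VIEWS, LabelledImage

logger = logging.getLogger(__name__)

FACE_N_CLASSES = (10, 20, 30, 40)
OBJECT_N_CLASSES = (2, 5, 10, 20, 30, 40)
OBJECT_TRAIN_PER_CLASS = 30
OBJECT_TEST_PER_CLASS = 50
MIN_IMAGES_PER_CATEGORY = 80


@dataclass
class DataPools:
    """Image pools the harness draws from; any unused pool may be empty."""

    faces: list[LabelledImage] = field(default_factory=list)
    objects: list[LabelledImage] = field(default_factory=list)
    natural: list[LabelledImage] = field(default_factory=list)


@dataclass(frozen=True)
class ExperimentSpec:
    """Full specification of one experiment grid entry.

    ``n_runs`` defaults to the study design: 15 random splits for the face
    task, 30 for the object task.
    """

    task: str                           # "face_id" | "object_cat"
    mode: str                           # "within" | "between" | "natural"
    model: str = "hmax"                 # "hmax" | "stable"
    sizes: tuple[int, ...] = PATCH_SIZES
    n_classes: int = 10
    n_runs: int | None = None
    seed: int = 0
    n_per_size: int = 250               # hmax dictionary budget per size
    natural_n_per_size: int = 1000      # hmax budget per size in natural mode
    expressions_per_train_view: int = 3
    stable_config: stable_model.StableConfig = field(
        default_factory=stable_model.StableConfig)
    shuffle_labels: bool = False        # chance-level control
    combine_sizes: bool = False         # also report concatenated-size result

    def __post_init__(self) -> None:
        if self.task not in ("face_id", "object_cat"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.mode not in ("within", "between", "natural"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.model not in ("hmax", "stable"):
            raise ValueError(f"unknown model {self.model!r}")
        if not set(self.sizes) <= set(PATCH_SIZES):
            raise ValueError(f"sizes must be a subset of {PATCH_SIZES}")
        allowed = FACE_N_CLASSES if self.task == "face_id" else OBJECT_N_CLASSES
        if self.n_classes not in allowed:
            raise ValueError(
                f"n_classes for {self.task} must be one of {allowed}")

    @property
    def runs(self) -> int:
        if self.n_runs is not None:
            return self.n_runs
        return 15 if self.task == "face_id" else 30


@dataclass
class Split:
    """One train/test partition plus the image ids used for feature learning."""

    train: list[tuple[int, object]]      # (image id = pool index, label)
    test: list[tuple[int, object]]
    feature_learning_set: list[int] = field(default_factory=list)


@dataclass
class RunResult:
    """Per-run accuracies (%) for one (task, mode, model, size, n_classes)."""

    key: tuple
    accuracies: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    @property
    def size(self):
        return self.key[3]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def make_object_split(pool: list[LabelledImage], n_classes: int,
                      seed: int | np.random.Generator) -> Split:
    """Sample categories and a disjoint 30-train / 50-test split per category."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_classes < 2:
        raise ValueError("need at least two classes")
    by_label: dict = {}
    for i, li in enumerate(pool):
        by_label.setdefault(li.label, []).append(i)
    for lab, ids in by_label.items():
        if len(ids) < MIN_IMAGES_PER_CATEGORY:
            raise ValueError(
                f"category {lab!r} has {len(ids)} images, needs >= "
                f"{MIN_IMAGES_PER_CATEGORY}")
    labels = sorted(by_label, key=str)
    if n_classes > len(labels):
        raise ValueError("not enough categories in pool")
    chosen = [labels[i] for i in rng.choice(len(labels), n_classes, replace=False)]
    train, test = [], []
    n_take = OBJECT_TRAIN_PER_CLASS + OBJECT_TEST_PER_CLASS
    for lab in chosen:
        ids = np.array(by_label[lab])
        picked = ids[rng.choice(len(ids), n_take, replace=False)]
        train += [(int(i), lab) for i in picked[:OBJECT_TRAIN_PER_CLASS]]
        test += [(int(i), lab) for i in picked[OBJECT_TRAIN_PER_CLASS:]]
    return Split(train=train, test=test)


def make_face_split(pool: list[LabelledImage], n_classes: int,
                    seed: int | np.random.Generator,
                    expressions_per_train_view: int = 3) -> Split:
    """Sample identities; train on views {0, +-45, +-90}, test on {+-22.5, +-67.5}.

    Every selected identity contributes all its expression images at each
    view (up to ``expressions_per_train_view`` per training view); the view
    sets never mix between train and test.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_classes < 2:
        raise ValueError("need at least two identities")
    by_ident: dict = {}
    for i, li in enumerate(pool):
        by_ident.setdefault(li.label, {}).setdefault(li.meta["view"], []).append(i)
    idents = sorted(by_ident, key=str)
    if n_classes > len(idents):
        raise ValueError("not enough identities in pool")
    for ident in idents:
        views = by_ident[ident]
        for v in TRAIN_VIEWS + TEST_VIEWS:
            if v not in views:
                raise ValueError(f"identity {ident!r} is missing view {v}")
            if v in TEST_VIEWS and len(views[v]) < 3:
                raise ValueError(
                    f"identity {ident!r} has < 3 expression images at test view {v}")
    chosen = [idents[i] for i in rng.choice(len(idents), n_classes, replace=False)]
    train, test = [], []
    for ident in chosen:
        for v in TRAIN_VIEWS:
            for i in by_ident[ident][v][:expressions_per_train_view]:
                train.append((i, ident))
        for v in TEST_VIEWS:
            for i in by_ident[ident][v]:
                test.append((i, ident))
    return Split(train=train, test=test)


def build_feature_learning_set(split: Split, mode: str, pools: DataPools,
                               task: str, seed: int | np.random.Generator,
                               n_learning_labels: int | None = None,
                               expressions_per_train_view: int = 3
                               ) -> tuple[str, list[int]]:
    """Image ids used for dictionary learning, per mode.

    Returns ``(pool_name, ids)`` where ``pool_name`` identifies which
    ``DataPools`` attribute the ids index into.  ``within`` returns the
    split's own training images; ``between`` samples fresh labels of the
    same domain, disjoint from the split's labels; ``natural`` returns the
    whole natural pool.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "within":
        return ("faces" if task == "face_id" else "objects",
                [i for i, _ in split.train])
    if mode == "natural":
        if not pools.natural:
            raise ValueError("natural mode requires a natural pool")
        return "natural", list(range(len(pools.natural)))
    # between: disjoint labels of the same domain
    pool_name = "faces" if task == "face_id" else "objects"
    pool = getattr(pools, pool_name)
    used = {lab for _, lab in split.train}
    spare = sorted({li.label for li in pool} - used, key=str)
    k = n_learning_labels or len(used)
    if len(spare) < 1:
        raise ValueError("no disjoint labels available for between mode")
    k = min(k, len(spare))
    chosen = set(np.array(spare, dtype=object)[rng.choice(len(spare), k, replace=False)])
    if task == "face_id":
        ids = [i for i, li in enumerate(pool)
               if li.label in chosen and li.meta["view"] in TRAIN_VIEWS]
    else:
        ids = [i for i, li in enumerate(pool) if li.label in chosen]
    return pool_name, ids


# ---------------------------------------------------------------------------
# running
# ---------------------------------------------------------------------------

class C1Cache:
    """Memoized C1 pyramids keyed by (pool name, image index)."""

    def __init__(self, pools: DataPools,
                 bank: list[frontend.GaborFilterSpec] | None = None,
                 bands: tuple[frontend.ScaleBand, ...] | None = None):
        self.pools = pools
        self.bank = bank if bank is not None else frontend.build_gabor_bank()
        if bands is None:
            scale_table = tuple(sorted({f.side for f in self.bank}))
            bands = frontend.default_bands(scale_table)
        self.bands = bands
        self._cache: dict = {}

    def get(self, pool_name: str, idx: int) -> frontend.C1Pyramid:
        key = (pool_name, idx)
        if key not in self._cache:
            img = getattr(self.pools, pool_name)[idx].image
            self._cache[key] = frontend.c1_pool(
                frontend.s1_transform(img, self.bank), self.bands)
        return self._cache[key]

    def get_many(self, pool_name: str, ids: list[int]) -> list[frontend.C1Pyramid]:
        return [self.get(pool_name, i) for i in ids]


def _fit_score(x_train, y_train, x_test, y_test) -> float:
    """Linear one-vs-rest SVM accuracy (%) with train-set standardization."""
    clf = make_pipeline(
        StandardScaler(),
        LinearSVC(C=1.0, multi_class="ovr", max_iter=10000))
    clf.fit(x_train, y_train)
    return 100.0 * float(clf.score(x_test, y_test))


def _build_dictionary(spec: ExperimentSpec, c1_learn, size: int,
                      seed: int) -> hmax_model.PrototypeDictionary:
    if spec.model == "hmax":
        budget = (spec.natural_n_per_size if spec.mode == "natural"
                  else spec.n_per_size)
        return hmax_model.sample_random_patches(
            c1_learn, sizes=(size,), n_per_size=budget, seed=seed)
    dictionary, _ = stable_model.learn_dictionary(
        c1_learn, spec.stable_config, sizes=(size,), seed=seed)
    return dictionary


def run_experiment(spec: ExperimentSpec, pools: DataPools,
                   cache: C1Cache | None = None) -> list[RunResult]:
    """Run the full multi-run experiment; one ``RunResult`` per patch size.

    Per run: draw a split, build the mode's feature-learning set, learn one
    dictionary per patch size, encode train and test images, fit a linear
    SVM and score test accuracy.  Everything is reproducible from
    ``spec.seed``.  With ``spec.combine_sizes`` an extra result keyed with
    size ``"all"`` is appended, computed on per-size C2 blocks concatenated
    into one feature vector.
    """
    if cache is None:
        cache = C1Cache(pools)
    master = np.random.default_rng(spec.seed)
    acc: dict = {s: [] for s in spec.sizes}
    if spec.combine_sizes:
        acc["all"] = []
    trace_censuses = []
    for run in range(spec.runs):
        rng = np.random.default_rng(master.integers(2**31 - 1))
        if spec.task == "face_id":
            split = make_face_split(pools.faces, spec.n_classes, rng,
                                    spec.expressions_per_train_view)
            pool_name = "faces"
        else:
            split = make_object_split(pools.objects, spec.n_classes, rng)
            pool_name = "objects"
        if len({lab for _, lab in split.train}) < 2:
            raise ValueError("degenerate single-class split")
        learn_pool, learn_ids = build_feature_learning_set(
            split, spec.mode, pools, spec.task, rng,
            expressions_per_train_view=spec.expressions_per_train_view)
        split.feature_learning_set = learn_ids
        logger.info("run %d split: %d train / %d test, %d feature-learning "
                    "images from %r", run + 1, len(split.train),
                    len(split.test), len(learn_ids), learn_pool)
        c1_learn = cache.get_many(learn_pool, learn_ids)
        c1_train = cache.get_many(pool_name, [i for i, _ in split.train])
        c1_test = cache.get_many(pool_name, [i for i, _ in split.test])
        y_train = [lab for _, lab in split.train]
        y_test = [lab for _, lab in split.test]
        if spec.shuffle_labels:
            y_train = [y_train[i] for i in rng.permutation(len(y_train))]
        per_size_feats = {}
        for size in spec.sizes:
            d = _build_dictionary(spec, c1_learn, size,
                                  int(rng.integers(2**31 - 1)))
            logger.info("run %d size %d: dictionary census %s", run + 1, size,
                        d.per_size_counts)
            x_train = hmax_model.encode_set(c1_train, d)
            x_test = hmax_model.encode_set(c1_test, d)
            per_size_feats[size] = (x_train, x_test)
            acc[size].append(_fit_score(x_train, y_train, x_test, y_test))
        if spec.combine_sizes:
            x_train = np.hstack([per_size_feats[s][0] for s in spec.sizes])
            x_test = np.hstack([per_size_feats[s][1] for s in spec.sizes])
            acc["all"].append(_fit_score(x_train, y_train, x_test, y_test))
        logger.info("run %d/%d done: %s", run + 1, spec.runs,
                    {s: round(a[-1], 1) for s, a in acc.items() if a})
    keys = list(spec.sizes) + (["all"] if spec.combine_sizes else [])
    return [RunResult(key=(spec.task, spec.mode, spec.model, s, spec.n_classes),
                      accuracies=acc[s]) for s in keys]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

SIGNIFICANCE_BANDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_band(p: float) -> str:
    for level, symbol in SIGNIFICANCE_BANDS:
        if p < level:
            return symbol
    return ""


@dataclass
class PValueMatrix:
    sizes: list
    matrix: np.ndarray            # symmetric, unit diagonal

    def annotate(self) -> list[list[str]]:
        return [[significance_band(p) for p in row] for row in self.matrix]


def rank_sum_p(a: list[float], b: list[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two per-run accuracy samples.

    Exact enumeration of the rank-sum distribution for samples smaller than
    8; tie-corrected normal approximation otherwise.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two runs per sample")
    method = "exact" if min(len(a), len(b)) < 8 else "asymptotic"
    if method == "exact" and (len(np.unique(np.concatenate([a, b])))
                              < len(a) + len(b)):
        # ties make the exact rank-sum distribution invalid; scipy falls
        # back to the tie-corrected approximation
        method = "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def compare_patch_sizes(results: list[RunResult]) -> PValueMatrix:
    """Pairwise rank-sum p-value matrix over the per-size accuracy samples."""
    if len(results) < 2:
        raise ValueError("need results for at least two sizes")
    n_runs = {len(r.accuracies) for r in results}
    if len(n_runs) != 1:
        raise ValueError("all sizes must have equal n_runs")
    if n_runs.pop() < 2:
        raise ValueError("need at least two runs")
    k = len(results)
    m = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            p = rank_sum_p(results[i].accuracies, results[j].accuracies)
            m[i, j] = m[j, i] = p
    return PValueMatrix(sizes=[r.size for r in results], matrix=m)


# ---------------------------------------------------------------------------
# result output
# ---------------------------------------------------------------------------

def results_to_frame(results: list[RunResult]):
    """Long-format DataFrame: one row per (run, size) with its accuracy."""
    import pandas as pd

    rows = []
    for r in results:
        task, mode, model, size, n_classes = r.key
        for run, a in enumerate(r.accuracies):
            rows.append(dict(task=task, mode=mode, model=model, size=size,
                             n_classes=n_classes, run=run, accuracy=a))
    return pd.DataFrame(rows)


def summarize(results: list[RunResult]) -> dict:
    return {str(r.size): {"mean": r.mean, "sd": r.sd,
                          "n_runs": len(r.accuracies)} for r in results}
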