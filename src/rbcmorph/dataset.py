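"""Labeling schemes, six-variant augmentation, and stratified k-fold plans."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic import CLASS_CODES, CLASS_NAMES

logger = logging.getLogger(__name__)

AUGMENT_TAGS = ("orig", "rot90", "rot180", "rot270", "hflip", "vflip")


@dataclass(frozen=True)
class LabelScheme:
    """Mapping from the 8 base morphology classes (plus an optional
    deoxygenation flag) onto an ordered list of output categories."""

    name: str
    classes: tuple[str, ...]
    merge_map: dict[str, int]  # base class -> index; absent = dropped
    deoxy_merge: str | None = None  # base classes remapped when deoxygenated

    def n_classes(self) -> int:
        return len(self.classes)

    def map_label(self, base: str, deoxy: bool = False) -> int | None:
        if base not in CLASS_NAMES:
            raise ValueError(f"unknown base class {base!r}")
        if deoxy and self.deoxy_merge is not None and base in ("elongated", "sickle"):
            return self.classes.index(self.deoxy_merge)
        return self.merge_map.get(base)


def _scheme_coarse5() -> LabelScheme:
    # Stomatocytes are not represented in the coarse labeling and drop out.
    classes = ("Dic+Ovl", "Ech", "El+Sk", "Grl", "Ret")
    merge = {
        "discocyte": 0,
        "oval": 0,
        "echinocyte": 1,
        "elongated": 2,
        "sickle": 2,
        "granular": 3,
        "reticulocyte": 4,
    }
    return LabelScheme("coarse5", classes, merge)


def _scheme_refined8() -> LabelScheme:
    classes = tuple(CLASS_CODES[c] for c in CLASS_NAMES)
    return LabelScheme("refined8", classes, {c: i for i, c in enumerate(CLASS_NAMES)})


def _scheme_oxydeoxy6() -> LabelScheme:
    base = _scheme_coarse5()
    classes = base.classes + ("El+Sk (DeOxy)",)
    return LabelScheme("oxydeoxy6", classes, dict(base.merge_map), "El+Sk (DeOxy)")


SCHEMES = {
    "coarse5": _scheme_coarse5(),
    "refined8": _scheme_refined8(),
    "oxydeoxy6": _scheme_oxydeoxy6(),
}


def get_scheme(name: str) -> LabelScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise ValueError(f"unknown scheme {name!r}; choose from {sorted(SCHEMES)}")


@dataclass
class LabeledDataset:
    """Stacked items with class indices and per-item provenance."""

    X: np.ndarray  # (n, H, W)
    y: np.ndarray  # (n,)
    source_ids: np.ndarray  # (n,) id of the unaugmented source patch
    aug_tags: list[str]
    scheme: LabelScheme

    def __len__(self) -> int:
        return self.X.shape[0]

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.scheme.n_classes())


@dataclass
class FoldPlan:
    """k disjoint validation index sets; training = complement per fold."""

    k: int
    val_indices: list[np.ndarray]
    n_items: int
    seed: int = 0
    fold_unit: str = "source"

    def train_indices(self, fold: int) -> np.ndarray:
        val = set(self.val_indices[fold].tolist())
        return np.array([i for i in range(self.n_items) if i not in val], np.int64)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "fold_unit": self.fold_unit,
            "val_indices": [v.tolist() for v in self.val_indices],
        }


def augment(patch: np.ndarray) -> list[np.ndarray]:
    """Original plus rotations 90/180/270 and horizontal/vertical
    reflection: exact pixel permutations, no interpolation."""
    patch = np.asarray(patch)
    if patch.shape[0] != patch.shape[1]:
        raise ValueError(f"augmentation requires a square patch, got {patch.shape}")
    return [
        patch.copy(),
        np.rot90(patch, 1).copy(),
        np.rot90(patch, 2).copy(),
        np.rot90(patch, 3).copy(),
        np.fliplr(patch).copy(),
        np.flipud(patch).copy(),
    ]


def assemble(
    patches,
    base_labels,
    scheme: LabelScheme | str,
    augment_data: bool = True,
    deoxy_flags=None,
    source_ids=None,
) -> LabeledDataset:
    """Map base labels through the scheme (dropping unmapped ones with a log
    line), optionally expanding each source patch into its 6 augmented
    variants."""
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    n = len(patches)
    if deoxy_flags is None:
        deoxy_flags = [False] * n
    if source_ids is None:
        source_ids = np.arange(n)
    xs, ys, sids, tags = [], [], [], []
    dropped = 0
    for patch, base, deoxy, sid in zip(patches, base_labels, deoxy_flags, source_ids):
        cls = scheme.map_label(base, deoxy=deoxy)
        if cls is None:
            dropped += 1
            continue
        variants = augment(patch) if augment_data else [np.asarray(patch)]
        vtags = AUGMENT_TAGS if augment_data else ("orig",)
        for var, tag in zip(variants, vtags):
            xs.append(var)
            ys.append(cls)
            sids.append(sid)
            tags.append(tag)
    if dropped:
        logger.info("assemble: dropped %d patches unmapped under %s", dropped, scheme.name)
    return LabeledDataset(
        X=np.stack(xs) if xs else np.zeros((0, 1, 1)),
        y=np.asarray(ys, np.int64),
        source_ids=np.asarray(sids, np.int64),
        aug_tags=tags,
        scheme=scheme,
    )


def kfold_split(
    ds: LabeledDataset, k: int = 5, seed: int = 0, fold_unit: str = "source"
) -> FoldPlan:
    """Stratified k-fold: per class, units are shuffled by seed and dealt
    round-robin into k validation subsets whose sizes differ by at most 1.

    With ``fold_unit='source'`` all augmented variants of one source patch
    travel together (leakage guard); ``'item'`` deals individual items.
    """
    if fold_unit not in ("source", "item"):
        raise ValueError("fold_unit must be 'source' or 'item'")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in range(ds.scheme.n_classes()):
        cls_idx = np.nonzero(ds.y == cls)[0]
        if cls_idx.size == 0:
            continue
        if fold_unit == "source":
            units = {}
            for i in cls_idx:
                units.setdefault(int(ds.source_ids[i]), []).append(int(i))
            unit_list = [units[key] for key in sorted(units)]
        else:
            unit_list = [[int(i)] for i in cls_idx]
        if len(unit_list) < k:
            raise ValueError(
                f"class {ds.scheme.classes[cls]!r} has only {len(unit_list)} "
                f"{fold_unit} units; need at least k={k}"
            )
        order = rng.permutation(len(unit_list))
        for pos, ui in enumerate(order):
            folds[pos % k].extend(unit_list[ui])
    val = [np.array(sorted(f), np.int64) for f in folds]
    return FoldPlan(k=k, val_indices=val, n_items=len(ds), seed=seed, fold_unit=fold_unit)
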