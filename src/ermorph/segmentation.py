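"""Three-class ER pixel classification (tubule / sheet / background).

A random-forest ensemble (100 trees, sqrt(n_features) tried per split) is
trained on sparsely labelled pixels of the feature stack, then applied to
whole images.  The trained model is saved and reused across images so that
segmentation is consistent and user-independent.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import DEFAULT_SCALES, FeatureStack, compute_features
from .image import (MASK_BACKGROUND, MASK_CLASS_NAMES, MASK_SHEET,
                    MASK_TUBULE, Image)

UNLABELLED = -1
# tie-break priority: tubule < sheet < background
CLASS_ORDER = (MASK_TUBULE, MASK_SHEET, MASK_BACKGROUND)


@dataclass
class ClassifierModel:
    forest: RandomForestClassifier
    classes: tuple[int, ...]
    seed: int
    feature_config_hash: str
    oob_accuracy: float

    def save(self, path) -> None:
        # canonicalize the object graph (dump -> load -> dump) so that a
        # freshly trained and a reloaded model serialize to identical bytes
        data = pickle.dumps(pickle.loads(pickle.dumps(self, protocol=4)),
                            protocol=4)
        with open(path, "wb") as fh:
            fh.write(data)

    @staticmethod
    def load(path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, ClassifierModel):
            raise ValueError("file does not contain a ClassifierModel")
        return model


@dataclass
class ClassMask:
    """Per-pixel ER label in {0 background, 1 tubule, 2 sheet}."""

    labels: np.ndarray
    pixel_size: float
    model_hash: str = ""

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.isin(lab, list(MASK_CLASS_NAMES)).all():
            raise ValueError("labels must be in {0, 1, 2}")
        self.labels = lab.astype(np.uint8)

    def area(self, cls: int, where: Optional[np.ndarray] = None) -> float:
        """Class area in um^2, optionally restricted to a boolean ROI."""
        sel = self.labels == cls
        if where is not None:
            sel &= where
        return float(sel.sum()) * self.pixel_size**2


def train_classifier(stack: FeatureStack, labels: np.ndarray,
                     seed: int = 0, n_trees: int = 100) -> ClassifierModel:
    """Fit the ensemble on labelled pixels (label -1 = unlabelled).

    Requires at least one labelled pixel in each of the three classes and
    reports out-of-bag accuracy.
    """
    stacks = stack if isinstance(stack, (list, tuple)) else [stack]
    labs = labels if isinstance(labels, (list, tuple)) else [labels]
    if len(stacks) != len(labs):
        raise ValueError("stacks and labels must pair up")
    if len({s.config_hash for s in stacks}) != 1:
        raise ValueError("all stacks must share one feature configuration")
    stack = stacks[0]
    Xs, ys = [], []
    for st, lab in zip(stacks, labs):
        lab = np.asarray(lab)
        if lab.shape != st.shape:
            raise ValueError("labels must match the feature stack shape")
        sel = lab.ravel() != UNLABELLED
        Xs.append(st.matrix()[sel])
        ys.append(lab.ravel()[sel])
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    missing = [MASK_CLASS_NAMES[c] for c in CLASS_ORDER if not np.any(y == c)]
    if missing:
        raise ValueError(f"no labelled pixels for class(es): {', '.join(missing)}")
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", oob_score=True,
        random_state=int(seed), n_jobs=1)
    forest.fit(X, y)
    return ClassifierModel(forest=forest,
                           classes=tuple(int(c) for c in forest.classes_),
                           seed=int(seed),
                           feature_config_hash=stack.config_hash,
                           oob_accuracy=float(forest.oob_score_))


def classify(model: ClassifierModel, img: Image,
             stack: Optional[FeatureStack] = None,
             scales=DEFAULT_SCALES) -> ClassMask:
    """Apply a trained model; ties resolved tubule < sheet < background."""
    if stack is None:
        if img.data.std() == 0:
            # structureless image: nothing but background by definition
            return ClassMask(labels=np.zeros(img.shape, dtype=np.uint8),
                             pixel_size=img.pixel_size,
                             model_hash=model.feature_config_hash)
        stack = compute_features(img, scales)
    if stack.config_hash != model.feature_config_hash:
        raise ValueError("feature configuration hash mismatch between "
                         "model and stack")
    proba = model.forest.predict_proba(stack.matrix())
    cols = [model.classes.index(c) for c in CLASS_ORDER]
    ordered = proba[:, cols]
    pick = np.argmax(ordered, axis=1)  # first max wins -> fixed tie order
    lab = np.array(CLASS_ORDER, dtype=np.uint8)[pick].reshape(stack.shape)
    return ClassMask(labels=lab, pixel_size=img.pixel_size,
                     model_hash=model.feature_config_hash)
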