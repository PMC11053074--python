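"""Stage 1: clear-vs-blurry image classification and the blur gate.

The classifier scores each frame with the probability that it is sharp
enough to analyse.  Its head follows the backbone's final stage: layer
normalization over channels, global average pooling over tokens, and a
single-logit affine map through a sigmoid.  "Clear" is the positive class;
an image passes the gate iff ``score >= threshold`` (ties pass).

A two-logit softmax head is also available (``head="softmax"``) for parity
with categorical cross-entropy training; the default sigmoid head trains
with binary cross-entropy, which is the same objective reparameterized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import BackboneConfig, PyramidFeatures, SwinBackbone
from .gating import GateDecision, GateOutcome
from .losses import binary_cross_entropy, cross_entropy
from .nn import Tensor

__all__ = ["BlurVerdict", "ClassifierHead", "BlurClassifier", "blur_gate",
           "train_classifier", "DEFAULT_BLUR_THRESHOLD"]

DEFAULT_BLUR_THRESHOLD = 0.5


@dataclass(frozen=True)
class BlurVerdict:
    """Classifier output for one image: P(clear), label, threshold used."""

    score: float
    threshold: float = DEFAULT_BLUR_THRESHOLD

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def label(self) -> str:
        return "clear" if self.score >= self.threshold else "blurry"


class ClassifierHead(nn.Module):
    """LayerNorm -> global token pooling -> affine -> sigmoid (or softmax)."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 head: str = "sigmoid"):
        if head not in ("sigmoid", "softmax"):
            raise ValueError(f"unknown head type '{head}'")
        self.head = head
        self.norm = nn.LayerNorm(channels)
        self.fc = nn.Linear(channels, 1 if head == "sigmoid" else 2, rng)

    def forward(self, features: PyramidFeatures) -> Tensor:
        final = features.s32
        if final is None:
            raise RuntimeError("pipeline error: final backbone stage missing")
        x = self.norm(final)
        B = x.shape[0]
        pooled = x.reshape(B, -1, x.shape[-1]).mean(axis=1)
        logits = self.fc(pooled)
        if self.head == "sigmoid":
            return logits.reshape(B).sigmoid()
        return logits.softmax(axis=-1)[:, 1]


class BlurClassifier(nn.Module):
    """Backbone plus classification head; scores are P(clear) in (0, 1)."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator,
                 head: str = "sigmoid"):
        self.config = config
        self.backbone = SwinBackbone(config, rng)
        self.head = ClassifierHead(config.stage_channels(3), rng, head)

    def forward(self, images) -> Tensor:
        return self.head(self.backbone(images))

    def predict(self, image: np.ndarray,
                threshold: float = DEFAULT_BLUR_THRESHOLD,
                tta: bool = True) -> BlurVerdict:
        """Score one uint8 or [0,1]-float image.

        With ``tta`` (default) the score is averaged over the eight
        flip/rotation variants of the frame — sharpness is
        orientation-invariant, and averaging the symmetric views reduces
        prediction variance.  Requires a square image; set ``tta=False``
        for single-view scoring.
        """
        x = _to_float(image)
        if tta and x.shape[0] == x.shape[1]:
            views = []
            for k in range(4):
                rot = np.rot90(x, k, axes=(0, 1))
                views.append(rot)
                views.append(rot[:, ::-1])
            batch = np.ascontiguousarray(np.stack(views))
            score = float(self.forward(batch).data.mean())
        else:
            score = float(self.forward(x[None]).data[0])
        return BlurVerdict(score=score, threshold=threshold)


def blur_gate(verdict: BlurVerdict, now: float = 0.0,
              wait_s: float = 0.0) -> GateDecision:
    """PASS for a clear verdict, otherwise FILTERED_BLUR with a re-shoot."""
    if verdict.label == "clear":
        return GateDecision(GateOutcome.PASS,
                            scores={"clear_probability": verdict.score},
                            timestamp=now)
    return GateDecision(GateOutcome.FILTERED_BLUR,
                        scores={"clear_probability": verdict.score},
                        timestamp=now, reshoot_at=now + wait_s)


def _random_dihedral(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random flip / 90-degree rotation per image (square images only)."""
    out = []
    for im in batch:
        k = int(rng.integers(4))
        im = np.rot90(im, k, axes=(0, 1))
        if rng.integers(2):
            im = im[:, ::-1]
        out.append(np.ascontiguousarray(im))
    return np.stack(out)


def _to_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype == np.uint8:
        return image.astype(np.float32) / 255.0
    return image.astype(np.float32)


def train_classifier(images: np.ndarray, labels: np.ndarray,
                     config: BackboneConfig, *, epochs: int = 150,
                     lr: float = 5e-5, batch_size: int = 4, seed: int = 0,
                     val_images: np.ndarray | None = None,
                     val_labels: np.ndarray | None = None,
                     head: str = "sigmoid", augment: bool = True,
                     lr_schedule: str = "constant",
                     log=None) -> tuple[BlurClassifier, dict]:
    """Train a blur classifier with Adam; returns the best-loss model.

    ``labels``: 1 for clear, 0 for blurry.  ``augment`` applies random
    flips and 90-degree rotations each step — sharpness labels are
    orientation-invariant, and the extra variety curbs memorization on
    small training sets.  The model state with the lowest (validation, else
    training) epoch loss is restored before returning.
    """
    rng = np.random.default_rng(seed)
    model = BlurClassifier(config, rng, head=head)
    opt = nn.Adam(model.parameters(), lr=lr)
    x = np.stack([_to_float(im) for im in images])
    y = np.asarray(labels, dtype=np.float32)
    history = {"loss": [], "val_loss": []}
    best = (np.inf, model.state_dict())
    n = len(x)
    for epoch in range(epochs):
        if lr_schedule == "cosine":
            opt.set_cosine_lr(epoch, epochs)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            batch = x[idx]
            if augment:
                batch = _random_dihedral(batch, rng)
            scores = model(batch)
            if head == "sigmoid":
                loss = binary_cross_entropy(Tensor(y[idx]), scores)
            else:
                onehot = np.stack([1 - y[idx], y[idx]], axis=1)
                probs = nn.stack([1.0 - scores, scores], axis=1)
                loss = cross_entropy(Tensor(onehot), probs)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        epoch_loss = float(np.mean(losses))
        history["loss"].append(epoch_loss)
        monitor = epoch_loss
        if val_images is not None:
            vx = np.stack([_to_float(im) for im in val_images])
            vscores = model(vx).data
            vloss = binary_cross_entropy(np.asarray(val_labels, float), vscores)
            history["val_loss"].append(float(vloss))
            monitor = float(vloss)
        if monitor < best[0]:
            best = (monitor, model.state_dict())
        if log is not None:
            log({"stage": 1, "epoch": epoch, "L_cls": epoch_loss})
    model.load_state_dict(best[1])
    history["best_loss"] = best[0]
    return model, history
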