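"""Assembly of the multi-branch attention models.

``build_mbeegcbam`` composes three parallel branches (EEGNet block followed
by CBAM attention), flattens and concatenates the three attended maps (952
features for a 1125-sample input under the default branch settings) and
classifies with a single shared dense softmax layer.

``build_fmbeegcbam`` is the fusion variant: the same branch layers are
tapped twice — once after the EEGNet blocks (concat-A) and once after the
CBAM blocks (concat-B) — and both flattened taps are fused by concatenation
(1904 features) before the shared dense softmax.  Because the branch layers
are shared by construction, the fusion variant differs from the base variant
only in the wider classifier: exactly ``n_classes * flattened_width`` extra
trainable parameters (3808 for four classes and 1125-sample input).

``build_eegcbam`` builds a single-branch ablation.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from .attention import CBAM, AttentionConfig
from .containers import TrialSet
from .eegnet import BranchConfig, EEGNetBlock, default_branch_configs
from . import nn

__all__ = ["Model", "build_mbeegcbam", "build_fmbeegcbam", "build_eegcbam",
           "count_trainable_parameters", "predict", "export_features",
           "save_checkpoint", "load_checkpoint"]


class Model:
    """A composed computation graph with a named parameter registry."""

    def __init__(self, variant: str, input_shape: tuple[int, int], n_classes: int,
                 branch_configs: tuple[BranchConfig, ...], seed: int, dtype=np.float32):
        if variant not in ("mb", "fmb", "single"):
            raise ValueError(f"unknown variant {variant!r}")
        if variant in ("mb", "fmb") and len(branch_configs) != 3:
            raise ValueError(f"exactly 3 branch configs required, got {len(branch_configs)}")
        if variant == "single" and len(branch_configs) != 1:
            raise ValueError("single-branch model takes exactly 1 branch config")
        self.variant = variant
        self.input_shape = tuple(input_shape)
        self.n_classes = int(n_classes)
        self.branch_configs = tuple(branch_configs)
        self.seed = int(seed)
        self.dtype = dtype

        n_electrodes, n_samples = self.input_shape
        rng = np.random.default_rng(seed)
        self.branches: list[tuple[EEGNetBlock, CBAM]] = []
        widths = []
        for i, cfg in enumerate(self.branch_configs):
            block = EEGNetBlock(cfg, n_electrodes, rng, dtype, name=f"branch{i}.eegnet")
            att = CBAM(cfg.n_output_channels, cfg.attention, rng, dtype,
                       name=f"branch{i}.cbam")
            shape = block.output_shape(self.input_shape)  # validates sample count
            widths.append(int(np.prod(shape)))
            self.branches.append((block, att))
        self.branch_widths = tuple(widths)
        self.flat_width = sum(widths)
        self.feature_width = 2 * self.flat_width if variant == "fmb" else self.flat_width
        self.classifier = nn.Dense(self.feature_width, n_classes, rng, dtype,
                                   name="classifier")
        self._shapes = None

    # -- parameter registry -------------------------------------------------
    def params(self) -> list[nn.Param]:
        out = []
        for block, att in self.branches:
            out.extend(block.params())
            out.extend(att.params())
        out.extend(self.classifier.params())
        return out

    def trainable_params(self) -> list[nn.Param]:
        return [p for p in self.params() if p.trainable]

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim == 3:  # (N, E, T) trials
            x = x[:, None]
        if x.ndim != 4 or x.shape[2:] != self.input_shape:
            raise ValueError(
                f"expected trials of shape {self.input_shape}, got input {x.shape}")
        return x.astype(self.dtype, copy=False)

    def forward_features(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """Flat pre-classifier feature matrix (N, feature_width)."""
        x = self._check_input(x)
        n = x.shape[0]
        raw_flats, att_flats, shapes = [], [], []
        for block, att in self.branches:
            h = block.forward(x, training, rng)
            shapes.append(h.shape)
            a = att.forward(h, training, rng)
            raw_flats.append(h.reshape(n, -1))
            att_flats.append(a.reshape(n, -1))
        self._shapes = shapes
        if self.variant == "fmb":
            feat = np.concatenate(raw_flats + att_flats, axis=1)
        else:
            feat = np.concatenate(att_flats, axis=1)
        return feat

    def forward_logits(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        return self.classifier.forward(self.forward_features(x, training, rng),
                                       training, rng)

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """Class probabilities (N, n_classes); rows sum to 1."""
        return nn.softmax(self.forward_logits(x, training, rng))

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        dfeat = self.classifier.backward(dlogits)
        segs = np.cumsum(self.branch_widths)[:-1]
        if self.variant == "fmb":
            draw = np.split(dfeat[:, :self.flat_width], segs, axis=1)
            datt = np.split(dfeat[:, self.flat_width:], segs, axis=1)
        else:
            draw = [None] * len(self.branches)
            datt = np.split(dfeat, segs, axis=1)
        for (block, att), shape, draw_i, datt_i in zip(self.branches, self._shapes,
                                                       draw, datt):
            dh = att.backward(datt_i.reshape(shape))
            if draw_i is not None:
                dh = dh + draw_i.reshape(shape)
            block.backward(dh)


def build_mbeegcbam(input_shape: tuple[int, int] = (22, 1125), n_classes: int = 4,
                    branch_configs=None, seed: int = 0, dtype=np.float32) -> Model:
    """Three-branch model: branch CBAM outputs concatenated into one softmax."""
    return Model("mb", input_shape, n_classes,
                 tuple(branch_configs or default_branch_configs()), seed, dtype)


def build_fmbeegcbam(input_shape: tuple[int, int] = (22, 1125), n_classes: int = 4,
                     branch_configs=None, seed: int = 0, dtype=np.float32) -> Model:
    """Fusion variant: pre- and post-attention taps concatenated before softmax."""
    return Model("fmb", input_shape, n_classes,
                 tuple(branch_configs or default_branch_configs()), seed, dtype)


def build_eegcbam(input_shape: tuple[int, int], n_classes: int,
                  branch_config: BranchConfig, seed: int = 0, dtype=np.float32) -> Model:
    """Single-branch ablation (one EEGNet block + CBAM + softmax)."""
    return Model("single", input_shape, n_classes, (branch_config,), seed, dtype)


def count_trainable_parameters(model) -> int:
    """Total element count of trainable tensors (batch-norm running
    statistics excluded).  Accepts a model or any iterable of parameters;
    an empty collection counts 0."""
    params = model.trainable_params() if hasattr(model, "trainable_params") else model
    return sum(p.size for p in params if getattr(p, "trainable", True))


def predict(model: Model, trials) -> tuple[np.ndarray, np.ndarray]:
    """Inference-mode labels and probability matrix.

    Accepts a TrialSet or a (N, E, T) array.  Labels are the argmax of each
    softmax row; ties resolve to the lowest class index.
    """
    x = trials.trials if isinstance(trials, TrialSet) else np.asarray(trials)
    probs = model.forward(x, training=False)
    return probs.argmax(axis=1), probs


def export_features(model: Model, trials) -> np.ndarray:
    """Flattened pre-classifier feature vectors (for external embedding
    tools such as t-SNE); (N, 952) for the base variant, (N, 1904) for the
    fusion variant under the default branch settings."""
    x = trials.trials if isinstance(trials, TrialSet) else np.asarray(trials)
    return model.forward_features(x, training=False)


# -- checkpointing ----------------------------------------------------------

def _sidecar(model: Model) -> dict:
    return {
        "variant": model.variant,
        "input_shape": list(model.input_shape),
        "n_classes": model.n_classes,
        "seed": model.seed,
        "branch_configs": [asdict(cfg) for cfg in model.branch_configs],
    }


def save_checkpoint(model: Model, path) -> None:
    """Keyed tensor archive (npz) plus a JSON sidecar describing the build."""
    path = str(path)
    arrays = {f"p{i:04d}": p.value for i, p in enumerate(model.params())}
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    side = path[:-4] if path.endswith(".npz") else path
    with open(side + ".json", "w") as f:
        json.dump(_sidecar(model), f, indent=2)


def load_checkpoint(path) -> Model:
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as f:
        meta = json.load(f)
    configs = tuple(
        BranchConfig(
            n_temporal_filters=c["n_temporal_filters"],
            temporal_kernel=c["temporal_kernel"],
            dropout_rate=c["dropout_rate"],
            attention=AttentionConfig(**c["attention"]),
            depth_multiplier=c["depth_multiplier"],
            pool1=c["pool1"], pool2=c["pool2"],
            separable_kernel=c["separable_kernel"],
        ) for c in meta["branch_configs"])
    model = Model(meta["variant"], tuple(meta["input_shape"]), meta["n_classes"],
                  configs, meta["seed"])
    with np.load(base + ".npz") as arc:
        for i, p in enumerate(model.params()):
            stored = arc[f"p{i:04d}"]
            if stored.shape != p.value.shape:
                raise ValueError(f"checkpoint tensor {i} shape mismatch")
            p.value = stored.astype(p.value.dtype)
            p.grad = np.zeros_like(p.value)
    return model
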