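"""Three-branch feature extraction.

Each branch is a small, fixed-seed, deterministic network echoing the
architectural idea of a well-known backbone family, behind one common
contract (image in, fixed-length finite vector out):

* branch 1 — stacked small-filter convolution/average-pool stages
  (VGG-style depth with 3x3 filters);
* branch 2 — an input summary vector passed through residual stages,
  each computing ``y = F(n; W) + n`` with an identity skip;
* branch 3 — dense connectivity: every stage consumes the concatenation of
  all previous stage outputs, finishing with global average pooling.

The weights of every branch are drawn once from constant seeds, so the
extractors are pure functions: the same image always yields bit-identical
vectors.  They are desk-scale stand-ins with the same input/output contract
as ImageNet-scale backbones — a user with pretrained VGG16/ResNet/DenseNet
features can plug them in through the same :class:`FeatureSet` interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .preprocess import GrayImage

__all__ = [
    "FeatureSet",
    "extract_branch1",
    "extract_branch2",
    "extract_branch3",
    "extract_all",
    "DEFAULT_DIM",
    "branch3_stage_dims",
]

DEFAULT_DIM = 64
_INPUT_SIDE = 32  # images are resampled to this square before extraction

_SEED_B1 = 1001
_SEED_B2 = 2002
_SEED_B3 = 3003


@dataclass(frozen=True)
class FeatureSet:
    """A per-image feature vector tagged with its branch of origin."""

    values: np.ndarray
    branch: str

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


def _as_float_image(img) -> np.ndarray:
    if isinstance(img, GrayImage):
        arr = img.pixels.astype(float) / img.max_level
    else:
        arr = np.asarray(img, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty single-channel image")
    return resize(arr, (_INPUT_SIDE, _INPUT_SIDE), anti_aliasing=True, mode="reflect")


def _summary_vector(arr: np.ndarray, dim: int) -> np.ndarray:
    """Fixed-length image summary: block means on a sqrt(dim) grid."""
    side = int(np.sqrt(dim))
    if side * side != dim:
        raise ValueError("output_dim must be a perfect square for the summary grid")
    block = _INPUT_SIDE // side
    return arr[: side * block, : side * block].reshape(side, block, side, block).mean(axis=(1, 3)).ravel()


def _quantile_vector(arr: np.ndarray, dim: int) -> np.ndarray:
    """Intensity-quantile profile: dim evenly spaced quantiles of the image.

    Position-invariant by construction; the upper quantiles carry the
    hot-spot signal of a thermogram.
    """
    return np.quantile(arr, np.linspace(0.0, 1.0, dim))


def _filter_bank(seed: int, n_filters: int, size: int = 3) -> np.ndarray:
    rng = np.random.default_rng(seed)
    bank = rng.standard_normal((n_filters, size, size))
    return bank / np.abs(bank).sum(axis=(1, 2), keepdims=True)


def extract_branch1(img, output_dim: int = DEFAULT_DIM) -> FeatureSet:
    """Multi-scale intensity statistics from stacked small-filter conv/pool stages.

    Two stages of 3x3 convolution + ReLU + 2x2 max pooling over a fixed
    seeded filter bank; the final maps are max-pooled into a coarse grid
    whose cells fill the feature vector.  Max pooling keeps the extremal
    local responses — on a thermogram, the hottest spots — approximately
    translation invariant; a non-negative DC-responsive bank makes the
    response monotone in overall image brightness.
    """
    arr = _as_float_image(img)
    n_filters = 4
    bank = np.abs(_filter_bank(_SEED_B1, n_filters))  # non-negative filters
    maps = [arr]
    for _stage in range(2):
        new_maps = []
        for m in maps[-n_filters:] if len(maps) > 1 else maps:
            for k in range(n_filters):
                resp = ndimage.convolve(m, bank[k], mode="reflect")
                resp = np.maximum(resp, 0.0)  # ReLU
                h, w = resp.shape
                resp = resp[: h - h % 2, : w - w % 2]
                resp = resp.reshape(h // 2, 2, w // 2, 2).max(axis=(1, 3))
                new_maps.append(resp)
        maps = new_maps
    per_map = max(output_dim // len(maps), 1)
    side = max(int(np.sqrt(per_map)), 1)
    feats = []
    for m in maps:
        h, w = m.shape
        bh, bw = max(h // side, 1), max(w // side, 1)
        pooled = m[: side * bh, : side * bw].reshape(side, bh, side, bw).max(axis=(1, 3))
        feats.append(pooled.ravel())
    vec = np.concatenate(feats)
    if vec.size < output_dim:
        vec = np.pad(vec, (0, output_dim - vec.size), mode="wrap")
    return FeatureSet(vec[:output_dim], "f1")


def extract_branch2(
    img,
    output_dim: int = DEFAULT_DIM,
    n_stages: int = 3,
    skip: bool = True,
    residual_fn=None,
) -> FeatureSet:
    """Residual-stage features: each stage maps ``n -> F(n; W) + n``.

    The input summary is the image's intensity-quantile profile (a
    position-invariant curve whose upper tail encodes hot spots); ``F`` is a
    fixed seeded linear map followed by tanh.  ``skip=False`` drops the
    identity term (ablation only), and ``residual_fn`` overrides ``F``
    entirely (e.g. a zero map turns every stage into the identity).
    """
    if n_stages < 2:
        raise ValueError("need at least two residual stages")
    arr = _as_float_image(img)
    n = _quantile_vector(arr, output_dim)
    rng = np.random.default_rng(_SEED_B2)
    for _stage in range(n_stages):
        w = rng.standard_normal((output_dim, output_dim)) / np.sqrt(output_dim)
        if residual_fn is not None:
            f = np.asarray(residual_fn(n), dtype=float)
        else:
            f = np.tanh(w @ n)
        n = f + n if skip else f
    return FeatureSet(n, "f2")


def branch3_stage_dims(output_dim: int = DEFAULT_DIM, n_stages: int = 3) -> list[tuple[int, int]]:
    """(input_dim, output_dim) of every dense stage; inputs are concatenations
    of all previous stage outputs."""
    dims = []
    widths = [output_dim]  # stage 0 consumes the image summary
    for _ in range(n_stages):
        in_dim = sum(widths)
        dims.append((in_dim, output_dim))
        widths.append(output_dim)
    return dims


def extract_branch3(
    img,
    output_dim: int = DEFAULT_DIM,
    n_stages: int = 3,
    activation: str = "tanh",
) -> FeatureSet:
    """Densely connected stages ending in global average pooling.

    Stage k consumes the concatenation of the image summary and every
    previous stage's output; the final feature is the element-wise average
    (GAP) over all stage outputs.  ``activation='identity'`` makes every
    stage linear, so the features respond linearly to a constant input.
    """
    arr = _as_float_image(img)
    x0 = _summary_vector(arr, output_dim)
    act = {"tanh": np.tanh, "identity": lambda z: z}[activation]
    rng = np.random.default_rng(_SEED_B3)
    outputs = [x0]
    for in_dim, out_dim in branch3_stage_dims(output_dim, n_stages):
        concat = np.concatenate(outputs)
        assert concat.size == in_dim
        w = rng.standard_normal((out_dim, in_dim)) / np.sqrt(in_dim)
        outputs.append(act(w @ concat))
    gap = np.mean(outputs[1:], axis=0)
    return FeatureSet(gap, "f3")


def extract_all(img, output_dim: int = DEFAULT_DIM) -> tuple[FeatureSet, FeatureSet, FeatureSet]:
    """Run all three branches on one image."""
    return (
        extract_branch1(img, output_dim),
        extract_branch2(img, output_dim),
        extract_branch3(img, output_dim),
    )
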