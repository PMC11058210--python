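"""Generative model contract and a desk-scale linear generator.

The reconstruction optimizer only needs three things from a generative
model: a deterministic ``evaluate`` mapping a latent matrix to an image, a
``gradient`` that backpropagates an image-sized sensitivity to the latent,
and the latent mean used by the prior term.  :class:`GeneratorContract`
captures this interface.

The reference production model is a style-based GAN whose per-resolution
style inputs form an ``n_res x 512`` latent matrix with
``n_res = 2 (log2(w) - 1)`` for output width ``w``.  Training such a network
is out of scope here; :class:`StyleGan2Adapter` is the documented slot for a
fully trained external network, and :class:`TrainingConfig` records the
training configuration of record verbatim so an adapter can refuse silently
altered settings.

:class:`LinearGenerator` is the trainable desk-scale model: a PCA basis of
the training depth maps.  The latent rows are folded (averaged) into a
single 512-vector whose leading ``rank`` entries are PCA coordinates — rows
can disagree during optimization, which keeps the colinearity loss
meaningful — and the output is ``clip(mean + B c, 0, 255)`` with an analytic
gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from .projection import DepthMap

__all__ = [
    "LATENT_WIDTH",
    "n_res",
    "mirror_augment",
    "split_dataset",
    "GeneratorContract",
    "LinearGenerator",
    "fit_linear_generator",
    "generate",
    "TrainingConfig",
    "StyleGan2Adapter",
]

LATENT_WIDTH = 512


def n_res(width: int) -> int:
    """Number of latent rows for a square power-of-two image width."""
    if width != int(width) or width < 4:
        raise ValueError("width must be an integer >= 4")
    width = int(width)
    if width & (width - 1):
        raise ValueError(f"width {width} is not a power of two")
    return 2 * (int(np.log2(width)) - 1)


def mirror_augment(dataset: Sequence[DepthMap]) -> list[DepthMap]:
    """Originals followed by their left-right mirrors (doubles the set)."""
    out = list(dataset)
    for dm in dataset:
        mirrored = dm.copy_with(dm.pixels[:, ::-1].copy())
        mirrored.provenance["mirrored"] = True
        out.append(mirrored)
    return out


def split_dataset(
    dataset: Sequence, n_test: int, seed: int = 0
) -> tuple[list, list]:
    """Deterministic disjoint train/test split by random permutation."""
    if not (0 <= n_test < len(dataset)):
        raise ValueError("n_test must satisfy 0 <= n_test < len(dataset)")
    order = np.random.default_rng(seed).permutation(len(dataset))
    test_idx = set(order[:n_test].tolist())
    train = [dataset[i] for i in range(len(dataset)) if i not in test_idx]
    test = [dataset[i] for i in sorted(test_idx)]
    return train, test


@runtime_checkable
class GeneratorContract(Protocol):
    """Interface the reconstruction optimizer relies on."""

    resolution: int
    n_res: int
    deterministic: bool

    @property
    def latent_mean(self) -> np.ndarray: ...

    def evaluate(self, w: np.ndarray) -> np.ndarray: ...

    def gradient(self, w: np.ndarray, upstream: np.ndarray) -> np.ndarray: ...


class LinearGenerator:
    """PCA-basis generator: image = clip(mean + B fold(w)[:rank], 0, 255).

    ``fold`` averages the latent rows into one 512-vector; entries beyond
    ``rank`` are inert.  Component columns are scaled by the singular values
    so a unit latent coordinate moves the image by about one standard
    deviation of the training data.
    """

    deterministic = True

    def __init__(
        self,
        mean_image: np.ndarray,
        components: np.ndarray,
        z_norm: float,
        plane_size: float,
    ):
        mean_image = np.asarray(mean_image, dtype=float)
        if mean_image.ndim != 2 or mean_image.shape[0] != mean_image.shape[1]:
            raise ValueError("mean image must be square")
        self.resolution = mean_image.shape[0]
        self.n_res = n_res(self.resolution)
        self.mean_image = mean_image
        self.components = np.asarray(components, dtype=float)
        if self.components.shape[0] != mean_image.size:
            raise ValueError("component rows must match the pixel count")
        self.rank = self.components.shape[1]
        if self.rank > LATENT_WIDTH:
            raise ValueError(f"rank must be <= {LATENT_WIDTH}")
        self.z_norm = float(z_norm)
        self.plane_size = float(plane_size)

    @property
    def latent_mean(self) -> np.ndarray:
        return np.zeros((self.n_res, LATENT_WIDTH))

    def _check_latent(self, w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        if w.shape != (self.n_res, LATENT_WIDTH):
            raise ValueError(
                f"latent must have shape ({self.n_res}, {LATENT_WIDTH}), "
                f"got {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("latent contains non-finite entries")
        return w

    def _code(self, w: np.ndarray) -> np.ndarray:
        return w.mean(axis=0)[: self.rank]

    def _raw(self, w: np.ndarray) -> np.ndarray:
        c = self._code(w)
        return self.mean_image + (self.components @ c).reshape(
            self.resolution, self.resolution
        )

    def evaluate(self, w: np.ndarray) -> np.ndarray:
        w = self._check_latent(w)
        return np.clip(self._raw(w), 0.0, 255.0)

    def gradient(self, w: np.ndarray, upstream: np.ndarray) -> np.ndarray:
        """Adjoint of evaluate: latent-shaped sensitivity for an image one.

        The clip is handled with a pass-through subgradient on the open
        interval (0, 255); saturated pixels transmit no sensitivity.
        """
        w = self._check_latent(w)
        upstream = np.asarray(upstream, dtype=float)
        if upstream.shape != (self.resolution, self.resolution):
            raise ValueError("upstream sensitivity must be image-shaped")
        raw = self._raw(w)
        inside = (raw > 0.0) & (raw < 255.0)
        g_img = (upstream * inside).ravel()
        g_code = self.components.T @ g_img
        g_w = np.zeros((self.n_res, LATENT_WIDTH))
        g_w[:, : self.rank] = g_code / self.n_res
        return g_w

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            Path(path),
            mean_image=self.mean_image,
            components=self.components,
            z_norm=self.z_norm,
            plane_size=self.plane_size,
        )

    @classmethod
    def load(cls, path: str | Path) -> "LinearGenerator":
        data = np.load(Path(path))
        return cls(
            mean_image=data["mean_image"],
            components=data["components"],
            z_norm=float(data["z_norm"]),
            plane_size=float(data["plane_size"]),
        )


def fit_linear_generator(
    train: Sequence[DepthMap], latent_rank: int
) -> LinearGenerator:
    """Fit the PCA basis of a set of canonical depth maps.

    Requires at least ``latent_rank + 1`` images; the basis holds the top
    ``latent_rank`` principal components scaled by ``s_i / sqrt(n)`` (data
    standard deviations along each component).
    """
    if latent_rank < 1:
        raise ValueError("latent_rank must be >= 1")
    if len(train) < latent_rank + 1:
        raise ValueError(
            f"need at least {latent_rank + 1} images for rank {latent_rank}"
        )
    res = train[0].resolution
    z_norm = train[0].z_norm
    plane_size = train[0].plane_size
    X = np.stack([dm.pixels.ravel() for dm in train]).astype(float)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    positive = int(np.count_nonzero(S > 1e-9 * S[0]))
    if latent_rank > positive:
        raise ValueError(
            f"rank {latent_rank} exceeds the data rank {positive}"
        )
    scale = S[:latent_rank] / np.sqrt(len(train))
    B = Vt[:latent_rank].T * scale
    return LinearGenerator(
        mean_image=mean.reshape(res, res),
        components=B,
        z_norm=z_norm,
        plane_size=plane_size,
    )


def generate(G: GeneratorContract, w: np.ndarray) -> np.ndarray:
    """Evaluate a conforming generator on a latent matrix."""
    return G.evaluate(w)


@dataclass(frozen=True)
class TrainingConfig:
    """Training configuration of record for the external style-based GAN.

    Values are recorded verbatim for provenance; an adapter refuses to run
    with silently altered settings.
    """

    adam_alpha: float = 0.002
    adam_beta1: float = 0.0
    adam_beta2: float = 0.99
    minibatch: int = 32
    augmentation: bool = False
    gamma_pl: float = 10.0
    beta_pl: float = 0.99
    images_shown: float = 7e5
    n_train: int = 89
    n_test: int = 3
    n_train_mirrored: int = 178


class StyleGan2Adapter:
    """Adapter slot for a fully trained external style-based generator.

    Wraps user-supplied ``evaluate``/``gradient`` callables (e.g. closing
    over a deep-learning runtime) and the empirical latent mean of the
    trained network.  No network is bundled; the adapter only enforces the
    contract and the recorded training configuration.
    """

    deterministic = True

    def __init__(
        self,
        resolution: int,
        evaluate: Callable[[np.ndarray], np.ndarray],
        gradient: Callable[[np.ndarray, np.ndarray], np.ndarray],
        latent_mean: np.ndarray,
        training_config: TrainingConfig | None = None,
        allow_config_override: bool = False,
    ):
        self.resolution = resolution
        self.n_res = n_res(resolution)
        cfg = training_config or TrainingConfig()
        if cfg != TrainingConfig() and not allow_config_override:
            raise ValueError(
                "training configuration differs from the configuration of "
                "record; pass allow_config_override=True to accept it"
            )
        self.training_config = cfg
        self._evaluate = evaluate
        self._gradient = gradient
        self._latent_mean = np.asarray(latent_mean, dtype=float)
        if self._latent_mean.shape != (self.n_res, LATENT_WIDTH):
            raise ValueError("latent mean has the wrong shape")

    @property
    def latent_mean(self) -> np.ndarray:
        return self._latent_mean

    def evaluate(self, w: np.ndarray) -> np.ndarray:
        return self._evaluate(np.asarray(w, dtype=float))

    def gradient(self, w: np.ndarray, upstream: np.ndarray) -> np.ndarray:
        return self._gradient(
            np.asarray(w, dtype=float), np.asarray(upstream, dtype=float)
        )
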