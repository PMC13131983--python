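"""SmoothGrad input attribution per view.

SmoothGrad averages the absolute input gradient of a scalar target over
noisy copies of the input: mean_n |d target / d (x + eps_n)| with
eps_n ~ N(0, (noise_scale * dynamic_range)^2).  The target here is a
risk-score functional of one task's probability vector (prognosis or
practice mode at a horizon bin), which is linear in the probabilities,
so its gradient seed is an indicator vector pushed back through the
softmax.  Channel-summed magnitudes are split back into the four view
planes (AP, PA, INF, SUP).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .errors import ConfigurationError, InputError
from .network import preprocess
from .synthmap.mesh import VIEWS


@dataclass(frozen=True)
class SmoothGradConfig:
    n_samples: int = 32
    noise_scale: float = 0.1  # fraction of the input dynamic range
    task: str = "PVI"
    mode: str = "prognosis"
    horizon_bin: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ConfigurationError("need at least one SmoothGrad sample")
        if self.noise_scale < 0:
            raise ConfigurationError("noise scale must be non-negative")
        if self.mode not in ("prognosis", "practice"):
            raise ConfigurationError(f"unknown decision mode {self.mode!r}")


def target_gradient_seed(n_outputs: int, mode: str, horizon_bin: int) -> np.ndarray:
    """d(risk score)/d(probability vector) for the chosen functional."""
    K = n_outputs - 2
    if not 1 <= horizon_bin <= K:
        raise InputError(f"horizon bin {horizon_bin} out of range 1..{K}")
    seed = np.zeros(n_outputs)
    seed[0] = 1.0
    if mode == "prognosis":
        seed[1 : horizon_bin + 1] = 1.0
    return seed


def smoothgrad(model, stack: np.ndarray, cfg: SmoothGradConfig) -> np.ndarray:
    """Per-view saliency maps, shape (4, S, S).

    ``model`` must expose ``input_gradients(x, task, d_probs)`` returning
    the gradient of ``d_probs . p_task`` with respect to the input batch;
    any object with that contract works (the trained network does).
    """
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim != 3 or stack.shape[0] % len(VIEWS) != 0:
        raise InputError("expected a (12, S, S) preprocessed stack")
    d_probs = target_gradient_seed(model.arch.n_outputs, cfg.mode, cfg.horizon_bin) \
        if hasattr(model, "arch") else model.gradient_seed(cfg.mode, cfg.horizon_bin)
    rng = np.random.default_rng(cfg.seed)
    dyn_range = float(stack.max() - stack.min())
    sigma = cfg.noise_scale * dyn_range
    acc = np.zeros_like(stack, dtype=np.float64)
    for _ in range(cfg.n_samples):
        noisy = stack if sigma == 0.0 else stack + rng.normal(0.0, sigma, stack.shape).astype(np.float32)
        grad = model.input_gradients(noisy[None], cfg.task, d_probs)[0]
        acc += np.abs(grad)
    acc /= cfg.n_samples
    n_ch = stack.shape[0] // len(VIEWS)
    side = stack.shape[1]
    return acc.reshape(len(VIEWS), n_ch, side, side).sum(axis=1)


def overlay_heat(image: np.ndarray, heat: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Blend a saliency heat map over a rendered RGB view."""
    h = heat - heat.min()
    peak = h.max()
    if peak > 0:
        h = h / peak
    heat_rgb = (colormaps["inferno"](h)[..., :3] * 255.0).astype(np.float64)
    blended = (1.0 - alpha) * image.astype(np.float64) + alpha * heat_rgb
    return np.clip(np.round(blended), 0, 255).astype(np.uint8)


def saliency_report(samples, model, cfg: SmoothGradConfig, out_dir) -> list:
    """Write one overlay PNG per view per map plus a JSON config echo.

    Returns the list of written paths (4 x number of maps, byte-identical
    across runs at a fixed seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for sample in samples:
        stack = preprocess(sample.images)
        heat = smoothgrad(model, stack, cfg)
        for vi, view in enumerate(VIEWS):
            path = out_dir / f"{sample.map_id}_{view}_saliency.png"
            Image.fromarray(overlay_heat(sample.images[vi], heat[vi])).save(path)
            written.append(path)
    (out_dir / "saliency_config.json").write_text(json.dumps(asdict(cfg), indent=2))
    return written
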