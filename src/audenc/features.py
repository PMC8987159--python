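"""From trained encoder to voxel-model design matrices.

For each TR-length audio window, the encoder's pooling outputs give one
feature map of shape (t_i, c_i) per layer. Temporal averaging reduces
each map to a c_i-vector; stacking the vectors of an excerpt's windows
in stimulus order gives an (n_windows, c_i) design (60 x c_i at the
default protocol). Finally each design column is convolved with the
canonical double-gamma hemodynamic response function (HRF) sampled on
the TR grid, because the BOLD signal is a delayed, dispersed response to
the underlying neural drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .stimulus import StimulusSpec, segment_excerpt


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma parameters (seconds, unitless ratio).

    The haemodynamic response is modeled as the difference of two gamma
    densities: a positive response peaking near ``response_delay`` and a
    later undershoot of 1/``undershoot_ratio`` relative amplitude.
    """

    response_delay: float = 6.0
    undershoot_delay: float = 16.0
    response_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    duration: float = 32.0


def hrf_kernel(tr: float, params: HRFParams = HRFParams()) -> np.ndarray:
    """Sample the double-gamma HRF at TR resolution, peak-normalized to 1.

    Sample times are 0, tr, 2*tr, ... strictly below ``params.duration``
    (22 taps at tr = 1.5 s with the default 32-s duration).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, params.duration, tr)
    h = gamma_dist.pdf(
        t, params.response_delay / params.response_dispersion,
        scale=params.response_dispersion,
    ) - gamma_dist.pdf(
        t, params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    ) / params.undershoot_ratio
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ValueError("degenerate HRF: kernel is identically zero")
    return h / np.max(h)


def hrf_convolve(design: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal column-wise convolution, truncated to the input row count.

    Row k of the output mixes rows <= k of the input only (zero initial
    conditions, no wrap-around): hemodynamics cannot precede the stimulus.
    """
    design = np.atleast_2d(np.asarray(design, dtype=float))
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size == 0:
        raise ValueError("empty HRF kernel")
    m = design.shape[0]
    if m < 1:
        raise ValueError("design must have at least one row")
    full = np.apply_along_axis(lambda col: np.convolve(col, kernel), 0, design)
    return full[:m]


def extract_layer_features(model, window: np.ndarray) -> list[np.ndarray]:
    """Feature map (t_i, c_i) of every encoder pooling layer for one window."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 1:
        raise ValueError("window must be 1-D")
    return [m[0] for m in model.encode(window[None, :])]


def temporal_average(feature_map: np.ndarray) -> np.ndarray:
    """Mean over time of each channel: (t_i, c_i) -> (c_i,)."""
    feature_map = np.asarray(feature_map, dtype=float)
    if feature_map.ndim != 2 or feature_map.shape[0] < 1:
        raise ValueError("feature map must be a non-empty (t, c) matrix")
    return feature_map.mean(axis=0)


def build_excerpt_design(
    model, waveform: np.ndarray, spec: StimulusSpec, layer: int
) -> np.ndarray:
    """Pre-HRF design of one excerpt for one layer: (n_windows, c_layer).

    Row k is the temporally averaged layer feature of window k, in
    stimulus order.
    """
    windows = segment_excerpt(waveform, spec)
    maps = model.encode(windows)[layer - 1]  # (n_windows, t_i, c_i)
    return maps.mean(axis=1)


def build_layer_designs(
    model,
    waveforms,
    spec: StimulusSpec,
    *,
    layers=None,
    hrf_params: HRFParams = HRFParams(),
    apply_hrf: bool = True,
) -> dict[int, list[np.ndarray]]:
    """HRF-convolved designs for every excerpt and requested layer.

    Returns {layer: [design of excerpt 0, design of excerpt 1, ...]}.
    A single encoder pass per excerpt serves all layers.
    """
    layers = list(range(1, model.n_layers_ + 1)) if layers is None else list(layers)
    kernel = hrf_kernel(spec.tr, hrf_params)
    out: dict[int, list[np.ndarray]] = {i: [] for i in layers}
    for w in waveforms:
        maps = model.encode(segment_excerpt(w, spec))
        for i in layers:
            d = maps[i - 1].mean(axis=1)
            out[i].append(hrf_convolve(d, kernel) if apply_hrf else d)
    return out
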