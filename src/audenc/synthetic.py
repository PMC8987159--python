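"""Seeded synthetic stimuli and simulated BOLD with known ground truth.

The real experiment played naturalistic excerpts from three semantic
categories (classical music, pop music, speech) to six listeners. That
corpus cannot be redistributed, so this module generates a stand-in with
the same layout and the property the analysis actually relies on: the
categories are spectrally distinct. Three generative families are used:

* ``harmonic``  — note sequences of stacked harmonics in a low band
  (classical-music stand-in);
* ``am_noise``  — amplitude-modulated band-passed noise in a high band
  with a periodic beat envelope (pop-music stand-in);
* ``chirp``     — formant-like frequency sweeps gated by a slow syllabic
  envelope with pauses (speech stand-in).

Simulated voxels invert the encoding model generatively: a responsive
voxel's time series is ``D @ w + noise`` where ``D`` is the HRF-convolved
design of its assigned network layer and ``w`` is a known sparse weight
vector; null voxels are pure Gaussian noise. This gives every downstream
stage a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .stimulus import StimulusSpec

CATEGORY_FAMILIES = ("harmonic", "am_noise", "chirp")


@dataclass
class SyntheticCorpus:
    """A generated stimulus corpus: waveforms plus integer category labels."""

    waveforms: list[np.ndarray]
    labels: np.ndarray
    spec: StimulusSpec
    seed: int

    def __len__(self) -> int:
        return len(self.waveforms)


def _note_track(rng, n, sr, f_lo, f_hi, note_dur, n_harmonics=6):
    """Concatenated harmonic-stack notes with Hann envelopes."""
    out = np.empty(n)
    pos = 0
    note_n = max(1, int(note_dur * sr))
    while pos < n:
        m = min(note_n, n - pos)
        t = np.arange(m) / sr
        f0 = np.exp(rng.uniform(np.log(f_lo), np.log(f_hi)))
        x = np.zeros(m)
        for h in range(1, n_harmonics + 1):
            if h * f0 < sr / 2:
                x += np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi)) / h
        x *= np.hanning(m) if m > 8 else 1.0
        out[pos : pos + m] = x
        pos += m
    return out


def _am_noise_track(rng, n, sr):
    """High-band noise with beat-rate amplitude modulation."""
    nyq = sr / 2
    lo, hi = 0.35 * nyq, 0.75 * nyq
    sos = signal.butter(4, [lo, hi], btype="band", fs=sr, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    t = np.arange(n) / sr
    beat = rng.uniform(1.5, 3.0)
    env = 0.55 + 0.45 * np.sin(2 * np.pi * beat * t + rng.uniform(0, 2 * np.pi))
    wob = 0.8 + 0.2 * np.sin(2 * np.pi * rng.uniform(5, 9) * t)
    return x * env * wob


def _chirp_track(rng, n, sr):
    """Syllable-gated frequency sweeps with silent gaps (speech-like)."""
    nyq = sr / 2
    out = np.zeros(n)
    pos = 0
    while pos < n:
        syl_n = int(rng.uniform(0.08, 0.25) * sr)
        gap_n = int(rng.uniform(0.02, 0.12) * sr)
        m = min(syl_n, n - pos)
        if m > 8:
            t = np.arange(m) / sr
            f0 = rng.uniform(0.02, 0.08) * nyq
            f1 = rng.uniform(0.05, 0.18) * nyq
            x = signal.chirp(t, f0=f0, t1=t[-1], f1=f1, method="logarithmic")
            # second "formant" an octave-ish above the sweep
            x = x + 0.5 * signal.chirp(
                t, f0=2.3 * f0, t1=t[-1], f1=2.3 * f1, method="logarithmic"
            )
            out[pos : pos + m] = x * np.hanning(m)
        pos += m + gap_n
    return out


_FAMILY_FUNCS = {
    "harmonic": lambda rng, n, sr: _note_track(
        rng, n, sr, f_lo=0.03 * sr / 2, f_hi=0.12 * sr / 2, note_dur=0.4
    ),
    "am_noise": _am_noise_track,
    "chirp": _chirp_track,
}


def generate_excerpt(category: int, spec: StimulusSpec, rng) -> np.ndarray:
    """One excerpt waveform for a category, peak-normalized to 0.9."""
    family = CATEGORY_FAMILIES[category % len(CATEGORY_FAMILIES)]
    x = _FAMILY_FUNCS[family](rng, spec.excerpt_samples, spec.sample_rate)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    return x


def generate_corpus(spec: StimulusSpec, seed: int) -> SyntheticCorpus:
    """Generate the full category-structured corpus, deterministically.

    Each (category, excerpt) pair gets an independent child generator
    spawned from ``seed``, so regenerating with the same seed is
    bit-identical and excerpts are statistically independent.
    """
    waveforms: list[np.ndarray] = []
    labels = []
    for cat in range(spec.n_categories):
        for k in range(spec.excerpts_per_category):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(cat, k))
            )
            waveforms.append(generate_excerpt(cat, spec, rng))
            labels.append(cat)
    return SyntheticCorpus(
        waveforms=waveforms, labels=np.asarray(labels), spec=spec, seed=seed
    )


@dataclass
class GroundTruthVoxels:
    """Known sparse encodings for simulated voxels.

    ``layers[v]`` is the 1-based network layer voxel ``v`` responds to,
    ``weights[v]`` its weight vector (exactly ``k`` nonzeros) over that
    layer's channels, ``noise_sd[v]`` the additive Gaussian noise SD.
    ``n_null`` further voxels carry pure noise of SD ``null_noise_sd``.
    Voxel ordering everywhere is: responsive voxels first (in record
    order), then null voxels.
    """

    layers: np.ndarray
    weights: list[np.ndarray]
    noise_sd: np.ndarray
    n_null: int
    null_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.noise_sd < 0) or self.null_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if len(self.weights) != len(self.layers) or len(self.noise_sd) != len(
            self.layers
        ):
            raise ValueError("per-voxel record lengths disagree")

    @property
    def n_responsive(self) -> int:
        return len(self.layers)

    @property
    def n_voxels(self) -> int:
        return self.n_responsive + self.n_null

    @property
    def layer_assignment(self) -> np.ndarray:
        """Length-V vector of assigned layers, 0 for null voxels."""
        return np.concatenate(
            [np.asarray(self.layers, dtype=int), np.zeros(self.n_null, dtype=int)]
        )


def sample_ground_truth(
    designs: Mapping[int, Sequence[np.ndarray]],
    n_per_layer: int,
    n_null: int,
    *,
    k: int = 5,
    snr: float = 5.0,
    seed: int = 0,
) -> GroundTruthVoxels:
    """Draw sparse ground-truth voxels calibrated to a target SNR.

    Each responsive voxel is assigned a layer and a weight vector with
    ``k`` nonzeros of magnitude Uniform[0.5, 1.5] and random sign. Its
    noise SD is set to (signal SD across all excerpt designs) / ``snr``,
    so the realized signal-to-noise ratio is ``snr`` by construction.
    """
    rng = np.random.default_rng(seed)
    layers, weights, noise_sds = [], [], []
    for layer in sorted(designs):
        mats = list(designs[layer])
        c = mats[0].shape[1]
        if k >= c:
            raise ValueError(f"k={k} must be < channel count {c} of layer {layer}")
        stacked = np.concatenate(mats, axis=0)
        for _ in range(n_per_layer):
            w = np.zeros(c)
            support = rng.choice(c, size=k, replace=False)
            w[support] = rng.uniform(0.5, 1.5, size=k) * rng.choice([-1.0, 1.0], size=k)
            sig_sd = np.std(stacked @ w)
            layers.append(layer)
            weights.append(w)
            noise_sds.append(sig_sd / snr if snr > 0 else 0.0)
    return GroundTruthVoxels(
        layers=np.asarray(layers, dtype=int),
        weights=weights,
        noise_sd=np.asarray(noise_sds),
        n_null=n_null,
    )


def generate_voxels(
    designs: Mapping[int, np.ndarray],
    truth: GroundTruthVoxels,
    seed: int,
) -> np.ndarray:
    """Simulate one (excerpt, subject) BOLD sample: an (m, V) matrix.

    ``designs`` maps layer index -> that excerpt's (m, c_layer) design.
    Responsive voxel v gets ``designs[layers[v]] @ weights[v]`` plus
    Gaussian noise of its recorded SD; null voxels are pure noise.
    """
    m = next(iter(designs.values())).shape[0]
    for layer, d in designs.items():
        if d.shape[0] != m:
            raise ValueError("design matrices disagree on row count")
    rng = np.random.default_rng(seed)
    cols = []
    for layer, w, sd in zip(truth.layers, truth.weights, truth.noise_sd):
        if layer not in designs:
            raise ValueError(f"no design provided for layer {layer}")
        d = designs[layer]
        if d.shape[1] != w.shape[0]:
            raise ValueError(
                f"layer {layer} design has {d.shape[1]} columns but the "
                f"weight vector has {w.shape[0]}"
            )
        cols.append(d @ w + rng.normal(0.0, sd, size=m))
    for _ in range(truth.n_null):
        cols.append(rng.normal(0.0, truth.null_noise_sd, size=m))
    return np.column_stack(cols) if cols else np.empty((m, 0))
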