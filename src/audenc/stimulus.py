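"""Stimulus timing: the TR-locked window grid shared by audio and BOLD.

Every stage of the pipeline slices audio into non-overlapping windows of
one repetition time (TR). A :class:`StimulusSpec` fixes the sampling rate,
the TR, and the corpus layout (categories x excerpts x duration), and all
segmentation arithmetic derives from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InvalidSpecError(ValueError):
    """Raised when a stimulus specification has inconsistent timing."""


@dataclass(frozen=True)
class StimulusSpec:
    """Timing and layout of the auditory stimulation protocol.

    Parameters
    ----------
    sample_rate : int
        Audio sampling rate in Hz.
    tr : float
        fMRI repetition time in seconds; also the length of one
        analysis window of audio.
    n_categories : int
        Number of semantic stimulus categories.
    excerpts_per_category : int
        Number of distinct excerpts per category.
    excerpt_duration : float
        Duration of one excerpt in seconds. Must be an integer number
        of TRs so each excerpt yields a whole number of windows.
    n_subjects : int
        Number of scanned participants.
    """

    sample_rate: int = 16_000
    tr: float = 1.5
    n_categories: int = 3
    excerpts_per_category: int = 7
    excerpt_duration: float = 90.0
    n_subjects: int = 6

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.tr <= 0:
            raise InvalidSpecError("sample_rate and tr must be positive")
        if not float(self.sample_rate * self.tr).is_integer():
            raise InvalidSpecError(
                f"sample_rate * tr = {self.sample_rate * self.tr} is not an "
                "integer number of samples per window"
            )
        ratio = self.excerpt_duration / self.tr
        if abs(ratio - round(ratio)) > 1e-9:
            raise InvalidSpecError(
                f"excerpt_duration / tr = {ratio} is not an integer number "
                "of windows per excerpt"
            )
        for name in ("n_categories", "excerpts_per_category", "n_subjects"):
            if getattr(self, name) < 1:
                raise InvalidSpecError(f"{name} must be >= 1")

    @property
    def window_length(self) -> int:
        """Samples per TR window (24,000 at defaults)."""
        return int(round(self.sample_rate * self.tr))

    @property
    def windows_per_excerpt(self) -> int:
        """TR windows per excerpt (60 at defaults)."""
        return int(round(self.excerpt_duration / self.tr))

    @property
    def excerpt_samples(self) -> int:
        """Audio samples per excerpt."""
        return int(round(self.sample_rate * self.excerpt_duration))

    @property
    def n_excerpts(self) -> int:
        return self.n_categories * self.excerpts_per_category

    @property
    def total_windows(self) -> int:
        """Stimulus windows in the whole corpus (1,260 at defaults)."""
        return self.n_excerpts * self.windows_per_excerpt

    @property
    def n_encoding_samples(self) -> int:
        """(excerpt, subject) pairs: one encoding sample each (126 at defaults)."""
        return self.n_excerpts * self.n_subjects


def segment_excerpt(waveform: np.ndarray, spec: StimulusSpec) -> np.ndarray:
    """Cut a waveform into consecutive non-overlapping TR windows.

    Returns an (n_windows, window_length) matrix; any trailing remainder
    shorter than one window is discarded.
    """
    waveform = np.asarray(waveform)
    if waveform.ndim != 1:
        raise ValueError("waveform must be one-dimensional")
    wl = spec.window_length
    n = waveform.shape[0] // wl
    if n < 1:
        raise ValueError(
            f"waveform of {waveform.shape[0]} samples is shorter than one "
            f"window ({wl} samples)"
        )
    return waveform[: n * wl].reshape(n, wl)


def segment_corpus(waveforms, spec: StimulusSpec) -> np.ndarray:
    """Segment a list of excerpt waveforms and stack all windows."""
    return np.concatenate([segment_excerpt(w, spec) for w in waveforms], axis=0)
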