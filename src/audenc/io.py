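"""File I/O: WAV stimuli, NIfTI BOLD volumes, manifests.

Corpora are stored as 16-bit PCM mono RIFF WAV plus a TSV manifest
(filename, category). BOLD matrices are stored as NIfTI-1 4-D volumes
with the TR recorded in the header; voxels are flattened in C order over
the three spatial axes (x slowest), which is documented here and kept
round-trip stable.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger("audenc")

_PCM16 = 32767


def write_audio(path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write a [-1, 1] float waveform as 16-bit PCM mono WAV."""
    x = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(str(path), int(sample_rate), (x * _PCM16).astype(np.int16))


def read_audio(path, target_rate: int | None = None) -> tuple[np.ndarray, int]:
    """Read a WAV file to a float waveform in [-1, 1].

    Stereo input is down-mixed to the channel mean. If ``target_rate``
    differs from the file's rate the signal is polyphase-resampled, with
    a logged warning. Returns (waveform, rate actually delivered).
    """
    rate, data = wavfile.read(str(path))
    if data.size == 0:
        raise ValueError(f"empty audio file: {path}")
    if np.issubdtype(data.dtype, np.integer):
        x = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        x = data.astype(float)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if target_rate is not None and rate != target_rate:
        logger.warning("resampling %s from %d Hz to %d Hz", path, rate, target_rate)
        frac = Fraction(target_rate, rate)
        x = resample_poly(x, frac.numerator, frac.denominator)
        rate = target_rate
    return np.clip(x, -1.0, 1.0), rate


def write_manifest(path, filenames, categories) -> None:
    pd.DataFrame({"filename": filenames, "category": categories}).to_csv(
        path, sep="\t", index=False
    )


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_corpus(corpus, out_dir) -> Path:
    """Write every excerpt as WAV plus a TSV label manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, (w, cat) in enumerate(zip(corpus.waveforms, corpus.labels)):
        name = f"excerpt_{i:03d}_cat{cat}.wav"
        write_audio(out_dir / name, w, corpus.spec.sample_rate)
        names.append(name)
    manifest = out_dir / "manifest.tsv"
    write_manifest(manifest, names, corpus.labels)
    return manifest


def load_corpus_audio(manifest_path, sample_rate) -> tuple[list[np.ndarray], np.ndarray]:
    """Read back a saved corpus; returns (waveforms, labels)."""
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    waveforms = [
        read_audio(base / row.filename, target_rate=sample_rate)[0]
        for row in manifest.itertuples()
    ]
    return waveforms, manifest["category"].to_numpy()


# ---------------------------------------------------------------------------
# BOLD volumes


def _grid_shape(n_voxels: int) -> tuple[int, int, int]:
    """A compact synthetic 3-D geometry holding >= n_voxels voxels."""
    side = max(1, math.ceil(n_voxels ** (1 / 3)))
    nx = side
    ny = side
    nz = math.ceil(n_voxels / (nx * ny))
    return nx, ny, nz


def write_bold(path, matrix: np.ndarray, tr: float, shape3d=None) -> None:
    """Write an (m, V) voxel-by-time matrix as a NIfTI-1 4-D volume.

    Voxels map to the 3-D grid in C order (x slowest); surplus grid
    positions are zero-filled. The TR lands in the header's pixdim[4].
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    m, v = matrix.shape
    nx, ny, nz = _grid_shape(v) if shape3d is None else shape3d
    vol = np.zeros((nx * ny * nz, m))
    vol[:v] = matrix.T
    data = vol.reshape(nx, ny, nz, m)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, float(tr)))
    nib.save(img, str(path))


def read_bold(
    path, expected_tr: float | None = None, n_voxels: int | None = None
) -> tuple[np.ndarray, float]:
    """Read a NIfTI 4-D volume back to an (m, V) matrix.

    Validates the header TR against ``expected_tr`` (tolerance 1e-6 s);
    ``n_voxels`` truncates the zero-padded grid back to the stored count.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {data.shape}")
    tr = float(img.header.get_zooms()[3])
    if expected_tr is not None and abs(tr - expected_tr) > 1e-6:
        raise ValueError(f"header TR {tr} s does not match configured {expected_tr} s")
    nx, ny, nz, m = data.shape
    mat = data.reshape(nx * ny * nz, m).T
    if n_voxels is not None:
        mat = mat[:, :n_voxels]
    return mat, tr


def write_mask(path, layer_assignment: np.ndarray, shape3d=None) -> None:
    """Integer mask volume: assigned layer per voxel, 0 for null voxels."""
    la = np.asarray(layer_assignment, dtype=np.int16)
    nx, ny, nz = _grid_shape(la.size) if shape3d is None else shape3d
    vol = np.zeros(nx * ny * nz, dtype=np.int16)
    vol[: la.size] = la
    nib.save(nib.Nifti1Image(vol.reshape(nx, ny, nz), affine=np.eye(4)), str(path))


def write_zmap_volumes(out_prefix, zmap, n_voxels=None, shape3d=None) -> list[Path]:
    """Write t/p/z/mask of a group map as separate 3-D NIfTI volumes."""
    out_prefix = Path(out_prefix)
    written = []
    for name, arr in (
        ("t", zmap.t),
        ("p", zmap.p),
        ("z", zmap.z),
        ("mask", zmap.mask.astype(np.int16)),
    ):
        arr = np.asarray(arr)
        v = arr.size if n_voxels is None else n_voxels
        nx, ny, nz = _grid_shape(v) if shape3d is None else shape3d
        vol = np.zeros(nx * ny * nz, dtype=np.float64)
        finite = np.nan_to_num(arr.astype(float), posinf=1e10, neginf=-1e10)
        vol[: arr.size] = finite
        path = out_prefix.parent / f"{out_prefix.name}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol.reshape(nx, ny, nz), affine=np.eye(4)), str(path))
        written.append(path)
    return written
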