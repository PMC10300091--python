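"""Sparse-representation fusion over an overcomplete DCT dictionary.

Sliding patches (mean-removed) are coded by orthogonal matching pursuit
against a fixed analytic overcomplete DCT dictionary. Per patch, the code
with larger L1 norm wins (activity-level selection); its reconstruction and
the matching source mean form the fused patch, and overlapping patches are
averaged back into the image. Ties average codes and means.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.linear_model import orthogonal_mp


def dct_dictionary(patch: int = 8, atoms: int = 256) -> np.ndarray:
    """Separable overcomplete DCT dictionary, ``patch**2 x atoms``, unit-norm
    columns. ``atoms`` must be a fourth power-compatible square (e.g. 256 for
    8x8 patches -> 16 one-dimensional frequencies per axis)."""
    n1 = int(round(np.sqrt(atoms)))
    if n1 * n1 != atoms:
        raise ValueError("atoms must be a perfect square")
    i = np.arange(patch)[:, None]
    k = np.arange(n1)[None, :]
    d1 = np.cos(np.pi * (i + 0.5) * k / n1)
    d1[:, 1:] -= d1[:, 1:].mean(axis=0)  # zero-mean AC atoms
    dictionary = np.kron(d1, d1)  # (patch^2, atoms)
    norms = np.linalg.norm(dictionary, axis=0)
    return dictionary / norms


def omp_code(
    dictionary: np.ndarray,
    signals: np.ndarray,
    max_atoms: int = 8,
    tol: float | None = None,
) -> np.ndarray:
    """Sparse codes (atoms x n_signals) by orthogonal matching pursuit."""
    norms = np.linalg.norm(dictionary, axis=0)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("dictionary atoms must have unit norm")
    code = orthogonal_mp(
        dictionary,
        signals,
        n_nonzero_coefs=None if tol is not None else max_atoms,
        tol=tol,
        precompute=True,
    )
    if code.ndim == 1:
        code = code[:, None]
    return code


def _extract_patches(img: np.ndarray, patch: int, stride: int) -> np.ndarray:
    windows = sliding_window_view(img, (patch, patch))[::stride, ::stride]
    return windows.reshape(-1, patch * patch).T  # (patch^2, n)


def fuse_sparse(
    a: np.ndarray,
    b: np.ndarray,
    patch: int = 8,
    stride: int = 2,
    atoms: int = 256,
    max_atoms: int = 8,
    tol: float | None = None,
    dictionary: np.ndarray | None = None,
) -> np.ndarray:
    if dictionary is None:
        dictionary = dct_dictionary(patch, atoms)
    if dictionary.shape[0] != patch * patch:
        raise ValueError("atom length must equal patch**2")
    h, w = a.shape
    # reflect-pad a full patch on every side so each output pixel is covered
    # by the full complement of overlapping patches
    ph = (-(h + patch)) % stride
    pw = (-(w + patch)) % stride
    pad_spec = ((patch, patch + ph), (patch, patch + pw))
    ap = np.pad(a, pad_spec, mode="symmetric")
    bp = np.pad(b, pad_spec, mode="symmetric")

    xa = _extract_patches(ap, patch, stride)
    xb = _extract_patches(bp, patch, stride)
    mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
    code_a = omp_code(dictionary, xa - mean_a, max_atoms, tol)
    code_b = omp_code(dictionary, xb - mean_b, max_atoms, tol)

    l1a = np.abs(code_a).sum(axis=0)
    l1b = np.abs(code_b).sum(axis=0)
    take_a = l1a > l1b
    take_b = l1b > l1a
    tie = ~(take_a | take_b)
    code_f = np.where(take_a, code_a, code_b)
    code_f[:, tie] = 0.5 * (code_a[:, tie] + code_b[:, tie])
    mean_f = np.where(take_a, mean_a, np.where(take_b, mean_b, 0.5 * (mean_a + mean_b)))

    recon = dictionary @ code_f + mean_f  # (patch^2, n)

    hh, ww = ap.shape
    n_r = (hh - patch) // stride + 1
    n_c = (ww - patch) // stride + 1
    out = np.zeros((hh, ww))
    counts = np.zeros((hh, ww))
    tiles = recon.T.reshape(n_r, n_c, patch, patch)
    ones = np.ones((patch, patch))
    for r in range(n_r):
        r0 = r * stride
        for c in range(n_c):
            c0 = c * stride
            out[r0 : r0 + patch, c0 : c0 + patch] += tiles[r, c]
            counts[r0 : r0 + patch, c0 : c0 + patch] += ones
    out /= counts
    return np.clip(out[patch : patch + h, patch : patch + w], 0.0, 1.0)


def learned_dictionary(
    training_image: np.ndarray,
    patch: int = 8,
    atoms: int = 256,
    seed: int | None = None,
    iters: int = 10,
) -> np.ndarray:
    """Dictionary learned from an image's own patches (K-SVD-style sparse
    coding via scikit-learn); a seed is required for determinism. The
    analytic DCT dictionary remains the default for reproducibility."""
    if seed is None:
        raise ValueError("dictionary learning requires an explicit seed")
    from sklearn.decomposition import MiniBatchDictionaryLearning

    x = _extract_patches(np.asarray(training_image, float), patch, patch).T
    x = x - x.mean(axis=1, keepdims=True)
    model = MiniBatchDictionaryLearning(
        n_components=atoms,
        transform_algorithm="omp",
        max_iter=iters,
        random_state=seed,
        dict_init=dct_dictionary(patch, atoms).T,
    )
    model.fit(x)
    d = model.components_.T
    norms = np.linalg.norm(d, axis=0)
    norms[norms == 0] = 1.0
    return d / norms
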