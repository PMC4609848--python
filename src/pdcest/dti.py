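"""Diffusion-tensor estimation: log-linear fit, FA and MD maps.

The single-shell tensor model is ``S(g) = S0 * exp(-b g^T D g)``.  Taking
logs gives a linear system in the six unique tensor components plus
``log(S0)``, solved per voxel by ordinary least squares.  Tensors are
reported in 1e-3 mm^2/s so healthy gray-matter MD is around 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DwiScheme", "TensorMaps", "design_matrix", "fit_tensor", "fa_md", "tensor_from_eigs"]

#: conversion from mm^2/s to the reported 1e-3 mm^2/s convention
_TENSOR_UNIT = 1.0e3

#: eigenvalue norm (1e-3 mm^2/s units) below which a tensor counts as zero;
#: tissue tensors have norms near 1, pure-roundoff fits near 1e-13
_ZERO_TENSOR_TOL = 1.0e-8


@dataclass(frozen=True)
class DwiScheme:
    """Acquisition scheme: b-values (s/mm^2) and unit gradient directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bvals", np.asarray(self.bvals, dtype=float))
        object.__setattr__(self, "bvecs", np.asarray(self.bvecs, dtype=float))
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must be (n, 3) matching bvals")
        if self.bvals.size < 7:
            raise ValueError("need at least 7 measurements (1 b=0 + 6 directions)")
        if not np.any(self.bvals == 0):
            raise ValueError("scheme must include a b=0 volume")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gradient directions must be unit norm for b > 0")

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.size)


@dataclass
class TensorMaps:
    """Fitted tensor field and derived scalar maps.

    ``tensor`` holds the six unique components (xx, yy, zz, xy, xz, yz) in
    1e-3 mm^2/s; ``fa`` is dimensionless in [0, 1]; ``md`` in 1e-3 mm^2/s.
    ``validity_mask`` is False where the fit was impossible; ``clamped`` marks
    voxels whose negative eigenvalues were clamped to zero.
    """

    tensor: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    validity_mask: np.ndarray
    clamped: np.ndarray


def design_matrix(scheme: DwiScheme) -> np.ndarray:
    """Rows ``[-b*gx^2, -b*gy^2, -b*gz^2, -2b*gxgy, -2b*gxgz, -2b*gygz, 1]``
    so that ``log S = X @ [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, log S0]``.
    """
    b, g = scheme.bvals, scheme.bvecs
    x = np.column_stack(
        [
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
            np.ones_like(b),
        ]
    )
    return x


def _tensor_matrix(six: np.ndarray) -> np.ndarray:
    """(…, 6) unique components -> (…, 3, 3) symmetric matrices."""
    xx, yy, zz, xy, xz, yz = np.moveaxis(six, -1, 0)
    m = np.empty(six.shape[:-1] + (3, 3))
    m[..., 0, 0], m[..., 1, 1], m[..., 2, 2] = xx, yy, zz
    m[..., 0, 1] = m[..., 1, 0] = xy
    m[..., 0, 2] = m[..., 2, 0] = xz
    m[..., 1, 2] = m[..., 2, 1] = yz
    return m


def fa_md(tensor_six: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """FA and MD from the six unique tensor components (any leading shape).

    ``MD = (l1+l2+l3)/3``; ``FA = sqrt(3/2) * ||l - MD|| / ||l||`` with the
    zero tensor assigned FA = 0.  Negative eigenvalues should be clamped
    upstream; FA is clipped into [0, 1] against roundoff.
    """
    eigs = np.linalg.eigvalsh(_tensor_matrix(np.asarray(tensor_six, dtype=float)))
    md = eigs.mean(axis=-1)
    num = np.sqrt(((eigs - md[..., None]) ** 2).sum(axis=-1))
    den = np.sqrt((eigs**2).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > _ZERO_TENSOR_TOL, fa, 0.0)
    return np.clip(fa, 0.0, 1.0), md


def fit_tensor(dwi: np.ndarray, scheme: DwiScheme, mask: np.ndarray | None = None) -> TensorMaps:
    """Ordinary-least-squares tensor fit per voxel.

    Parameters
    ----------
    dwi:
        Signal volumes, shape ``spatial + (n_volumes,)``.
    scheme:
        Matching :class:`DwiScheme`.
    mask:
        Optional boolean/integer mask restricting the fit.

    Voxels with any non-positive signal are invalidated.  Negative fitted
    eigenvalues are clamped to zero (voxel flagged in ``clamped``) before FA
    and MD are computed.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.shape[-1] != scheme.n_volumes:
        raise ValueError("dwi volume count does not match the scheme")
    x = design_matrix(scheme)
    if np.linalg.matrix_rank(x) < 7:
        raise ValueError("gradient scheme is rank-deficient (collinear directions)")

    shape = dwi.shape[:-1]
    usable = np.all(dwi > 0, axis=-1)
    if mask is not None:
        usable &= np.asarray(mask) != 0

    flat = dwi.reshape(-1, scheme.n_volumes)
    sel = usable.ravel()
    tensor = np.full((flat.shape[0], 6), np.nan)
    if sel.any():
        logs = np.log(flat[sel])
        coef, *_ = np.linalg.lstsq(x, logs.T, rcond=None)
        tensor[sel] = coef[:6].T * _TENSOR_UNIT

    eigs = np.full((flat.shape[0], 3), np.nan)
    clamped = np.zeros(flat.shape[0], dtype=bool)
    if sel.any():
        w, v = np.linalg.eigh(_tensor_matrix(tensor[sel]))
        neg = w < 0
        clamped[sel] = neg.any(axis=-1)
        w = np.clip(w, 0.0, None)
        eigs[sel] = w
        # rebuild clamped tensors so the stored field matches the metrics
        rebuilt = np.einsum("...ij,...j,...kj->...ik", v, w, v)
        tensor[sel, 0] = rebuilt[..., 0, 0]
        tensor[sel, 1] = rebuilt[..., 1, 1]
        tensor[sel, 2] = rebuilt[..., 2, 2]
        tensor[sel, 3] = rebuilt[..., 0, 1]
        tensor[sel, 4] = rebuilt[..., 0, 2]
        tensor[sel, 5] = rebuilt[..., 1, 2]

    md = eigs.mean(axis=-1)
    num = np.sqrt(((eigs - md[:, None]) ** 2).sum(axis=-1))
    den = np.sqrt((eigs**2).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > _ZERO_TENSOR_TOL, fa, np.where(np.isnan(md), np.nan, 0.0))
    fa = np.clip(fa, 0.0, 1.0)

    return TensorMaps(
        tensor=tensor.reshape(shape + (6,)),
        fa=fa.reshape(shape),
        md=md.reshape(shape),
        validity_mask=usable,
        clamped=clamped.reshape(shape),
    )


def tensor_from_eigs(eigenvalues, axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Axially oriented symmetric tensor (six unique components).

    ``eigenvalues`` are ``(l1, l2, l3)`` with ``l1`` along ``axis``; the two
    minor eigenvectors complete an orthonormal frame.  Used to build
    ground-truth tensors for the phantom.
    """
    l1, l2, l3 = eigenvalues
    e1 = np.asarray(axis, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    d = l1 * np.outer(e1, e1) + l2 * np.outer(e2, e2) + l3 * np.outer(e3, e3)
    return np.array([d[0, 0], d[1, 1], d[2, 2], d[0, 1], d[0, 2], d[1, 2]])
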