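"""Rigid translation, deformable registration stand-in, and DVF algebra.

The clinical workflow obtains dense deformation vector fields (DVFs)
from a multi-modal DIR algorithm whose internals are out of scope here;
a mono-modal multi-resolution demons-style registrar stands behind the
same interface, and externally produced DVFs are accepted anywhere a
registrar output is.

Convention (declared, and tested for self-consistency): a DVF ``u`` is a
per-voxel displacement in mm on the reference grid used for *pull-back*
warping, ``warp(vol, u)(x) = vol(x + u(x))``.  If ``u`` aligns a moving
image onto a fixed one (``warp(moving, u) ≈ fixed``) then the material
displacement of the underlying anatomy is ``invert_dvf(u)``; dose
computed on the current anatomy is mapped back to the reference frame by
warping with the inverse field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import Volume


@dataclass
class DVF:
    """Dense displacement field, mm, on a regular grid.

    ``disp`` has shape ``(3, nx, ny, nz)``; components are displacements
    along (LR, AP, CC).
    """

    disp: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 4 or self.disp.shape[0] != 3:
            raise ValueError("DVF needs shape (3, nx, ny, nz)")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("DVF must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.disp.shape[1:]

    @classmethod
    def zeros_like(cls, vol: Volume) -> "DVF":
        return cls(np.zeros((3, *vol.shape)), vol.spacing, vol.origin)

    @classmethod
    def constant(cls, vol: Volume, t_mm) -> "DVF":
        d = np.zeros((3, *vol.shape))
        for a in range(3):
            d[a] = t_mm[a]
        return cls(d, vol.spacing, vol.origin)

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.disp**2, axis=0))

    def max_voxel_displacement(self) -> float:
        """Largest displacement expressed in voxel units."""
        vox = self.disp / np.array(self.spacing)[:, None, None, None]
        return float(np.sqrt(np.sum(vox**2, axis=0)).max())

    def to_volume_stack(self) -> list[Volume]:
        return [Volume(self.disp[a], self.spacing, self.origin) for a in range(3)]

    def save_nifti(self, path) -> None:
        import nibabel as nib

        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        img = nib.Nifti1Image(
            np.moveaxis(self.disp, 0, -1).astype(np.float32), aff
        )
        nib.save(img, str(path))

    @classmethod
    def load_nifti(cls, path) -> "DVF":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.moveaxis(np.asarray(img.dataobj, dtype=np.float64), -1, 0)
        aff = img.affine
        spacing = tuple(float(np.linalg.norm(aff[:3, a])) for a in range(3))
        return cls(data, spacing, tuple(float(x) for x in aff[:3, 3]))


# ---------------------------------------------------------------------------
# rigid translation
# ---------------------------------------------------------------------------


def apply_translation(vol: Volume, t_mm, cval: float = 0.0) -> Volume:
    """Volume rigidly translated by ``t_mm``: out(x) = vol(x - t).

    Out-of-grid regions are filled with the background value ``cval``.
    """
    t = np.asarray(t_mm, dtype=float)
    shift_vox = t / np.array(vol.spacing)
    out = ndimage.shift(
        vol.values.astype(float), shift_vox, order=1, mode="constant", cval=cval
    )
    return vol.like(out)


# ---------------------------------------------------------------------------
# warping and DVF algebra
# ---------------------------------------------------------------------------


def _sample_displacement(dvf: DVF, idx_coords: np.ndarray) -> np.ndarray:
    """Sample each DVF component at fractional index coords (3, ...)."""
    out = np.empty((3, *idx_coords.shape[1:]))
    for a in range(3):
        out[a] = ndimage.map_coordinates(
            dvf.disp[a], idx_coords, order=1, mode="nearest"
        )
    return out


def warp(vol: Volume, dvf: DVF, order: int = 1) -> Volume:
    """Pull-back warp: out(x) = vol(x + u(x)).

    Edge values are extended outside the grid, so the warped volume's
    range stays within the input range.
    """
    if vol.shape != dvf.shape:
        raise ValueError(f"grid mismatch: {vol.shape} vs {dvf.shape}")
    idx = np.indices(vol.shape, dtype=float)
    coords = idx + dvf.disp / np.array(vol.spacing)[:, None, None, None]
    out = ndimage.map_coordinates(
        vol.values.astype(float), coords, order=order, mode="nearest"
    )
    return vol.like(out)


def warp_mask(mask: np.ndarray, dvf: DVF, spacing=None, origin=(0, 0, 0)) -> np.ndarray:
    """Warp a boolean mask: linear interpolation then re-threshold at 0.5."""
    spacing = spacing if spacing is not None else dvf.spacing
    vol = Volume(mask.astype(float), spacing, origin)
    return warp(vol, dvf).values >= 0.5


def compose(u: DVF, v: DVF) -> DVF:
    """Displacement field c with warp(vol, c) == warp(warp(vol, u), v).

    ``c(x) = v(x) + u(x + v(x))``.
    """
    if u.shape != v.shape:
        raise ValueError("grid mismatch in compose")
    idx = np.indices(u.shape, dtype=float)
    coords = idx + v.disp / np.array(u.spacing)[:, None, None, None]
    return DVF(v.disp + _sample_displacement(u, coords), u.spacing, u.origin)


def invert_dvf(
    u: DVF, max_iter: int = 60, tol_voxel: float = 0.01
) -> DVF:
    """Inverse displacement field by fixed-point iteration.

    Solves ``v(x) = -u(x + v(x))`` so that ``compose(u, v) ≈ 0``.  Raises
    if the update has not converged after ``max_iter`` iterations,
    reporting the residual in voxel units.
    """
    spacing = np.array(u.spacing)[:, None, None, None]
    idx = np.indices(u.shape, dtype=float)
    v = -u.disp.copy()
    for _ in range(max_iter):
        coords = idx + v / spacing
        v_new = -_sample_displacement(u, coords)
        step = np.abs(v_new - v) / spacing
        v = v_new
        if step.max() < tol_voxel:
            break
    else:
        resid = compose(u, DVF(v, u.spacing, u.origin))
        raise RuntimeError(
            "DVF inversion did not converge: residual "
            f"{resid.max_voxel_displacement():.3f} voxels after {max_iter} iterations"
        )
    return DVF(v, u.spacing, u.origin)


# ---------------------------------------------------------------------------
# demons-style deformable registration stand-in
# ---------------------------------------------------------------------------


def _zoom_to(arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    factors = [t / s for t, s in zip(shape, arr.shape)]
    return ndimage.zoom(arr, factors, order=1, grid_mode=True, mode="nearest")


def register(
    fixed: Volume,
    moving: Volume,
    levels: int = 3,
    iters_per_level: int = 40,
    smooth_sigma_mm: float = 6.0,
    step_scale: float = 1.0,
    return_residuals: bool = False,
):
    """Estimate a DVF ``u`` with ``warp(moving, u) ≈ fixed`` (demons-style).

    Mono-modal, deterministic, multi-resolution.  Each iteration applies
    the classic intensity-driven force
    ``du = -(m_w - f) grad(f) / (|grad f|^2 + (m_w - f)^2 / s^2)``
    followed by Gaussian smoothing of the field (diffusion-like
    regularization).  An update that increases the intensity MSE is
    retried at half step and the level stops when no improving step
    exists, so the recorded residual is non-increasing.

    Returns the DVF, optionally with the per-iteration MSE history as
    one list per resolution level (the MSE scale changes across levels).
    """
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must share a grid")
    spacing = np.array(fixed.spacing)
    full_shape = np.array(fixed.shape)

    u = None
    residuals: list[list[float]] = []
    for level in range(levels - 1, -1, -1):
        factor = 2**level
        shape_l = tuple(max(4, int(round(s / factor))) for s in full_shape)
        spacing_l = spacing * full_shape / np.array(shape_l)
        f_l = _zoom_to(ndimage.gaussian_filter(fixed.values.astype(float),
                                               sigma=max(factor / 2.0, 0.0)), shape_l)
        m_l = _zoom_to(ndimage.gaussian_filter(moving.values.astype(float),
                                               sigma=max(factor / 2.0, 0.0)), shape_l)
        vol_l = Volume(f_l, tuple(spacing_l), fixed.origin)
        if u is None:
            u = DVF.zeros_like(vol_l)
        else:
            u = DVF(
                np.stack([_zoom_to(u.disp[a], shape_l) for a in range(3)]),
                tuple(spacing_l),
                fixed.origin,
            )

        grad = np.stack(np.gradient(f_l, *spacing_l))
        g2 = np.sum(grad**2, axis=0)
        inten_scale = float(np.std(f_l)) or 1.0
        mvol = Volume(m_l, tuple(spacing_l), fixed.origin)

        mse = float(np.mean((warp(mvol, u).values - f_l) ** 2))
        sig_vox = smooth_sigma_mm / spacing_l
        level_hist = [mse]
        for _ in range(iters_per_level):
            diff = warp(mvol, u).values - f_l
            denom = g2 + (diff / inten_scale) ** 2 * g2.mean() + 1e-12
            force = -diff[None] * grad / denom[None]
            scale = step_scale
            improved = False
            for _try in range(4):
                cand = u.disp + scale * force
                for a in range(3):
                    cand[a] = ndimage.gaussian_filter(cand[a], sig_vox[a])
                cand_dvf = DVF(cand, u.spacing, u.origin)
                cand_mse = float(np.mean((warp(mvol, cand_dvf).values - f_l) ** 2))
                if cand_mse <= mse:
                    u, mse = cand_dvf, cand_mse
                    improved = True
                    break
                scale *= 0.5
            level_hist.append(mse)
            if not improved:
                break
        residuals.append(level_hist)

    # upsample final field to the full grid if the finest level was coarser
    if u.shape != tuple(full_shape):
        u = DVF(
            np.stack([_zoom_to(u.disp[a], tuple(full_shape)) for a in range(3)]),
            fixed.spacing,
            fixed.origin,
        )
    else:
        u = DVF(u.disp, fixed.spacing, fixed.origin)
    if return_residuals:
        return u, residuals
    return u
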