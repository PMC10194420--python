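"""Landmark-based similarity registration of section stacks into CT space.

The section stack (optical images and ion volumes share one grid) and
the microCT volume come from different specimens and instruments; the
link between them is a set of corresponding anatomical landmarks (eyes,
brain regions, mouthparts) picked by an expert in both frames.  A
similarity transform — rotation, uniform ("proportional") scale, and
translation — is estimated from the landmark pairs in closed form by the
SVD-based least-squares method (Umeyama), with a reflection guard.  The
transform fitted on the optical stack is then transferred unchanged to
every ion volume, which is resampled onto the CT grid by pull-back
interpolation.  Gap-filled planes are treated as missing data: under
trilinear interpolation their weights are renormalised away rather than
averaged in as zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from neuromap3d.volume import IonVolume, VolumeError


class RegistrationError(ValueError):
    pass


@dataclass(frozen=True)
class LandmarkSet:
    """Paired (moving, fixed) points in physical µm with text labels."""

    moving: np.ndarray       # n x 3
    fixed: np.ndarray        # n x 3
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.moving, dtype=float)
        f = np.asarray(self.fixed, dtype=float)
        object.__setattr__(self, "moving", m)
        object.__setattr__(self, "fixed", f)
        if m.shape != f.shape or m.ndim != 2 or m.shape[1] != 3:
            raise RegistrationError("landmarks must be matched n x 3 arrays")
        if len(m) < 3:
            raise RegistrationError("at least 3 landmark pairs required")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"lm{i}" for i in range(len(m)))
            )
        # collinearity check: rank of centred moving cloud must be >= 2
        c = m - m.mean(axis=0)
        if np.linalg.matrix_rank(c, tol=1e-9 * max(1.0, np.abs(c).max())) < 2:
            raise RegistrationError("moving landmarks are collinear")

    @classmethod
    def from_csv(cls, path: str) -> "LandmarkSet":
        """Read landmark CSV with columns label,mx,my,mz,fx,fy,fz (µm)."""
        df = pd.read_csv(path)
        need = ["label", "mx", "my", "mz", "fx", "fy", "fz"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise RegistrationError(f"landmark CSV missing columns {missing}")
        return cls(
            moving=df[["mx", "my", "mz"]].to_numpy(float),
            fixed=df[["fx", "fy", "fz"]].to_numpy(float),
            labels=tuple(df["label"].astype(str)),
        )

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {
                "label": self.labels,
                "mx": self.moving[:, 0], "my": self.moving[:, 1],
                "mz": self.moving[:, 2],
                "fx": self.fixed[:, 0], "fy": self.fixed[:, 1],
                "fz": self.fixed[:, 2],
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SimilarityTransform:
    """x_fixed = scale · R · x_moving + t  (physical µm, column points)."""

    rotation: np.ndarray       # 3 x 3, orthonormal, det +1
    scale: float
    translation: np.ndarray    # 3-vector

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise RegistrationError("rotation must be 3x3 orthonormal")
        if np.linalg.det(R) < 0:
            raise RegistrationError("rotation must have det +1 (no reflection)")
        if self.scale <= 0:
            raise RegistrationError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map n x 3 moving points into the fixed frame."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (self.scale * (self.rotation @ p.T)).T + self.translation

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        """Map n x 3 fixed points back into the moving frame."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return ((self.rotation.T @ (p - self.translation).T) / self.scale).T

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "scale": float(self.scale),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(
            rotation=np.asarray(d["rotation"], dtype=float),
            scale=float(d["scale"]),
            translation=np.asarray(d["translation"], dtype=float),
        )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "SimilarityTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), 1.0, np.zeros(3))


def estimate_similarity(
    landmarks: LandmarkSet,
) -> tuple[SimilarityTransform, float]:
    """Closed-form least-squares similarity fit (Umeyama, SVD-based).

    Minimises sum ||s·R·m_i + t − f_i||² over rotation R (det +1), scale
    s > 0 and translation t.  Returns the transform and the RMS residual
    in µm.  Unique for non-degenerate (non-collinear) configurations.
    """
    m = landmarks.moving
    f = landmarks.fixed
    n = len(m)
    mu_m = m.mean(axis=0)
    mu_f = f.mean(axis=0)
    mc = m - mu_m
    fc = f - mu_f
    cov = fc.T @ mc / n
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0   # reflection guard
    R = U @ S @ Vt
    var_m = (mc ** 2).sum() / n
    if var_m <= 0:
        raise RegistrationError("degenerate landmark configuration")
    s = float(np.trace(np.diag(D) @ S) / var_m)
    if s <= 0:
        raise RegistrationError("non-positive scale from degenerate landmarks")
    t = mu_f - s * (R @ mu_m)
    T = SimilarityTransform(R, s, t)
    residuals = T.apply(m) - f
    rms = float(np.sqrt((residuals ** 2).sum() / n))
    return T, rms


def apply_to_volume(
    v: IonVolume,
    T: SimilarityTransform,
    target_shape: tuple[int, int, int],
    target_voxel_size: float,
    target_origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    interp: str = "trilinear",
) -> IonVolume:
    """Resample a section-stack volume onto an isotropic CT grid.

    Pull-back resampling: every target voxel samples the moving volume
    at T⁻¹ of its physical center.  Gap-filled planes contribute nothing
    — their trilinear weights are renormalised over measured neighbors,
    and a voxel whose support is entirely missing is marked unmeasured in
    ``meta['voxel_mask']``.  ``interp`` is 'trilinear' (intensities) or
    'nearest' (labels).
    """
    if target_voxel_size <= 0:
        raise RegistrationError("target voxel size must be positive")
    nz, ny, nx = target_shape
    ox, oy, oz = target_origin
    zz, yy, xx = np.meshgrid(
        oz + np.arange(nz) * target_voxel_size,
        oy + np.arange(ny) * target_voxel_size,
        ox + np.arange(nx) * target_voxel_size,
        indexing="ij",
    )
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    mov = T.inverse_apply(pts)
    vx, vy, vz = v.origin
    fx = (mov[:, 0] - vx) / v.pixel_size
    fy = (mov[:, 1] - vy) / v.pixel_size
    fz = (mov[:, 2] - vz) / v.z_spacing
    depth, rows, cols = v.data.shape
    plane_ok = v.plane_mask

    if interp == "nearest":
        iz = np.round(fz).astype(int)
        iy = np.round(fy).astype(int)
        ix = np.round(fx).astype(int)
        inside = (
            (iz >= 0) & (iz < depth) & (iy >= 0) & (iy < rows)
            & (ix >= 0) & (ix < cols)
        )
        measured = inside.copy()
        measured[inside] = plane_ok[iz[inside]]
        vals = np.zeros(len(pts))
        vals[measured] = v.data[iz[measured], iy[measured], ix[measured]]
    elif interp == "trilinear":
        vals = np.zeros(len(pts))
        wsum = np.zeros(len(pts))
        z0 = np.floor(fz).astype(int)
        y0 = np.floor(fy).astype(int)
        x0 = np.floor(fx).astype(int)
        dz = fz - z0
        dy = fy - y0
        dx = fx - x0
        for cz in (0, 1):
            wz = np.where(cz == 0, 1 - dz, dz)
            z = z0 + cz
            for cy in (0, 1):
                wy = np.where(cy == 0, 1 - dy, dy)
                y = y0 + cy
                for cx in (0, 1):
                    wx = np.where(cx == 0, 1 - dx, dx)
                    x = x0 + cx
                    ok = (
                        (z >= 0) & (z < depth) & (y >= 0) & (y < rows)
                        & (x >= 0) & (x < cols)
                    )
                    ok_m = ok.copy()
                    ok_m[ok] = plane_ok[z[ok]]
                    w = wz * wy * wx * ok_m
                    idx = np.nonzero(w > 0)[0]
                    vals[idx] += w[idx] * v.data[z[idx], y[idx], x[idx]]
                    wsum[idx] += w[idx]
        measured = wsum > 1e-12
        vals[measured] /= wsum[measured]
        vals[~measured] = 0.0
    else:
        raise RegistrationError(f"unknown interpolation {interp!r}")

    if not measured.any():
        import warnings

        warnings.warn("apply_to_volume: empty overlap with the target grid")
    out = IonVolume(
        data=vals.reshape(target_shape),
        plane_mask=np.ones(nz, dtype=bool),
        pixel_size=target_voxel_size,
        z_spacing=target_voxel_size,
        origin=target_origin,
        mz_center=v.mz_center,
        meta={
            "voxel_mask": measured.reshape(target_shape),
            "transform": T.to_dict(),
            "interp": interp,
        },
    )
    return out


def transfer(
    T: SimilarityTransform,
    optical: IonVolume,
    ion_volumes: list[IonVolume],
    target_shape: tuple[int, int, int],
    target_voxel_size: float,
    target_origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    interp: str = "trilinear",
) -> list[IonVolume]:
    """Apply the optical-stack transform unchanged to every ion volume.

    Each ion volume must share the optical stack's grid (shape, pixel
    size, z spacing and origin); the resampled outputs carry the
    transform in their metadata as provenance.
    """
    for iv in ion_volumes:
        if iv.data.shape != optical.data.shape:
            raise RegistrationError("ion volume grid shape mismatch")
        if not np.isclose(iv.pixel_size, optical.pixel_size):
            raise RegistrationError("ion volume pixel_size mismatch")
        if not np.isclose(iv.z_spacing, optical.z_spacing):
            raise RegistrationError("ion volume z_spacing mismatch")
        if not np.allclose(iv.origin, optical.origin):
            raise RegistrationError("ion volume origin mismatch")
    return [
        apply_to_volume(
            iv, T, target_shape, target_voxel_size, target_origin, interp
        )
        for iv in ion_volumes
    ]
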