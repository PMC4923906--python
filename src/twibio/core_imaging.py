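"""Image-volume data model, diffusion tensor fitting and ROI statistics.

The diffusion tensor is estimated per voxel by log-linearised least squares
of the monoexponential signal model ln S = ln S0 − b gᵀDg, with S0 taken as
the geometric mean of the non-diffusion-weighted (b0) volumes. Scalar maps
(FA, AD, RD, TR) derive from the tensor eigenvalues; ROI volumetry and ROI
medians operate on any scalar map sharing the mask lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScalarVolume",
    "ROIMask",
    "DiffusionScheme",
    "TensorField",
    "fit_tensor",
    "tensor_metrics",
    "roi_volume",
    "roi_median",
]


class LatticeError(ValueError):
    """Volumes that should share a voxel lattice do not."""


class EmptyROIError(ValueError):
    """An ROI has no eligible voxels."""


@dataclass
class ScalarVolume:
    """A 3D scalar grid with a voxel-index → world-mm affine.

    Voxel centers sit at integer indices (NIfTI convention); indices are
    0-based. ``voxel_size`` is derived from the affine column norms.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-30:
            raise ValueError("affine is singular")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel cell in mm³."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm coordinates to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, voxels: np.ndarray) -> np.ndarray:
        vox = np.atleast_2d(np.asarray(voxels, dtype=float))
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_lattice(self, other: "ScalarVolume | ROIMask") -> bool:
        other_shape = other.labels.shape if isinstance(other, ROIMask) else other.data.shape
        return self.data.shape == other_shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


@dataclass
class ROIMask:
    """Integer label grid on the lattice of an associated volume.

    Label 0 is background. ``label_names`` maps label values to region
    names (e.g. ipsilateral cortex).
    """

    labels: np.ndarray
    affine: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("mask must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValueError("mask contains non-integer labels")
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise ValueError("mask labels must be >= 0")

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def present_labels(self) -> list[int]:
        lab = np.unique(self.labels)
        return [int(v) for v in lab if v != 0]


@dataclass
class DiffusionScheme:
    """Acquisition scheme: b-values (s/mm²) and unit gradient directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must be (n, 3) matching bvals")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dwi = self.bvals > 0
        if np.any(np.abs(norms[dwi] - 1.0) > 1e-3):
            raise ValueError("diffusion-weighted b-vectors must be unit length")
        if not np.any(~dwi):
            raise ValueError("scheme needs at least one b0 acquisition")
        if np.count_nonzero(dwi) < 6:
            raise ValueError("insufficient directions: need >= 6 diffusion-weighted volumes")

    def __len__(self) -> int:
        return int(self.bvals.size)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def design_matrix(self) -> np.ndarray:
        """Rows [gx², gy², gz², 2gxgy, 2gxgz, 2gygz]·b for the DWI rows."""
        g = self.bvecs
        b = self.bvals[:, None]
        return b * np.column_stack(
            [
                g[:, 0] ** 2,
                g[:, 1] ** 2,
                g[:, 2] ** 2,
                2 * g[:, 0] * g[:, 1],
                2 * g[:, 0] * g[:, 2],
                2 * g[:, 1] * g[:, 2],
            ]
        )


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor with sorted eigenvalues.

    ``tensor`` holds the 6 unique components (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
    in mm²/s; ``evals`` the eigenvalues sorted descending (λ1 ≥ λ2 ≥ λ3).
    ``n_flagged`` counts voxels zeroed because of non-positive signal.
    """

    tensor: np.ndarray
    evals: np.ndarray
    s0: np.ndarray
    affine: np.ndarray
    n_flagged: int = 0

    def tensor_matrix(self) -> np.ndarray:
        """Full (..., 3, 3) symmetric matrices."""
        d = self.tensor
        out = np.empty(d.shape[:-1] + (3, 3), dtype=d.dtype)
        out[..., 0, 0] = d[..., 0]
        out[..., 1, 1] = d[..., 1]
        out[..., 2, 2] = d[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = d[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = d[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = d[..., 5]
        return out


def fit_tensor(
    dwi: np.ndarray,
    scheme: DiffusionScheme,
    affine: np.ndarray | None = None,
    mask: ROIMask | None = None,
    weighted: bool = False,
) -> TensorField:
    """Fit the diffusion tensor per voxel by log-linear least squares.

    S0 is the geometric mean of the b0 volumes; the tensor solves the
    overdetermined system −b gᵀDg = ln(S/S0) over the diffusion-weighted
    rows (ordinary least squares by default; ``weighted=True`` applies the
    conventional S² weights). Voxels with any non-positive signal are
    flagged and zeroed rather than propagating NaNs.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4D (x, y, z, acquisition)")
    if dwi.shape[3] != len(scheme):
        raise ValueError(
            f"dwi has {dwi.shape[3]} volumes but scheme has {len(scheme)} entries"
        )
    if affine is None:
        affine = np.eye(4)

    shape = dwi.shape[:3]
    in_mask = np.ones(shape, dtype=bool) if mask is None else mask.labels > 0

    signals = dwi.reshape(-1, len(scheme))
    sel = in_mask.ravel()
    b0 = scheme.b0_mask
    dwi_rows = ~b0

    valid = sel & np.all(signals > 0, axis=1)
    n_flagged = int(np.count_nonzero(sel & ~valid))

    s0_flat = np.zeros(signals.shape[0])
    tensor_flat = np.zeros((signals.shape[0], 6))

    if np.any(valid):
        s = signals[valid]
        s0_v = np.exp(np.mean(np.log(s[:, b0]), axis=1))
        y = np.log(s[:, dwi_rows] / s0_v[:, None])  # (nvox, ndwi)
        design = scheme.design_matrix()[dwi_rows]  # (ndwi, 6)
        if weighted:
            # per-voxel WLS with weights S²: solve (XᵀWX) D = XᵀW y
            w = s[:, dwi_rows] ** 2
            lhs = np.einsum("ni,ij,ik->njk", w, design, design)
            rhs = np.einsum("ni,ij,ni->nj", w, design, y)
            d = -np.linalg.solve(lhs, rhs[..., None])[..., 0]
        else:
            d = -np.linalg.lstsq(design, y.T, rcond=None)[0].T
        s0_flat[valid] = s0_v
        tensor_flat[valid] = d

    tensor = tensor_flat.reshape(shape + (6,))
    s0 = s0_flat.reshape(shape)

    fieldv = TensorField(tensor=tensor, evals=np.zeros(shape + (3,)),
                         s0=s0, affine=np.asarray(affine, dtype=float),
                         n_flagged=n_flagged)
    evals = np.linalg.eigvalsh(fieldv.tensor_matrix())  # ascending
    fieldv.evals = evals[..., ::-1]
    return fieldv


def tensor_metrics(field: TensorField) -> dict[str, ScalarVolume]:
    """FA, AD, RD and TR scalar maps from tensor eigenvalues.

    AD = λ1, RD = (λ2+λ3)/2, TR = λ1+λ2+λ3,
    FA = sqrt(3/2)·sqrt(Σ(λi−λ̄)²) / sqrt(Σλi²), defined as 0 where all
    eigenvalues vanish. Negative eigenvalues from noisy fits are used as-is.
    """
    ev = field.evals
    ad = ev[..., 0]
    rd = (ev[..., 1] + ev[..., 2]) / 2.0
    tr = ev.sum(axis=-1)
    mean = tr / 3.0
    num = np.sqrt(((ev - mean[..., None]) ** 2).sum(axis=-1))
    den = np.sqrt((ev**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    aff = field.affine
    return {
        "FA": ScalarVolume(fa, aff),
        "AD": ScalarVolume(ad, aff),
        "RD": ScalarVolume(rd, aff),
        "TR": ScalarVolume(tr, aff),
    }


def roi_volume(mask: ROIMask, label: int) -> float:
    """Total volume (mm³) of a label: voxel count × voxel cell volume."""
    n = int(np.count_nonzero(mask.labels == label))
    if n == 0:
        raise EmptyROIError(f"label absent: {label}")
    return n * mask.voxel_volume


def roi_median(
    vol: ScalarVolume,
    mask: ROIMask,
    label: int,
    min_count_map: ScalarVolume | None = None,
    include_empty: bool = False,
) -> tuple[float, int]:
    """Median of a scalar map over an ROI; returns (median, n_voxels_used).

    With ``min_count_map`` supplied (a streamline-count volume), voxels
    with count < 1 are excluded unless ``include_empty`` is set — a
    track-weighted map is undefined where no streamlines pass.
    An even-count median is the mean of the two central values.
    """
    if not vol.same_lattice(mask):
        raise LatticeError("volume and mask are on different lattices")
    sel = mask.labels == label
    if not np.any(sel):
        raise EmptyROIError(f"label absent: {label}")
    if min_count_map is not None and not include_empty:
        if not vol.same_lattice(min_count_map):
            raise LatticeError("count map on a different lattice")
        sel = sel & (min_count_map.data >= 1)
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise EmptyROIError(f"empty ROI after filtering: label {label}")
    return float(np.median(vol.data[sel])), n
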