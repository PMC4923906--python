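"""Seeded synthetic phantoms with known ground truth.

Generators for every input the analysis stages consume:

* streamline bundles (straight / arc / helix) whose per-track length and
  curvature are analytically known;
* two-cohort tractography phantoms in which the "injured" group's
  ipsilateral bundles are truncated and straightened, with ROI label
  blocks on a common grid;
* diffusion-weighted signal volumes from known tensors under the study
  acquisition scheme (b = 1200 s/mm², 81 directions + 8 b0);
* serial-dilution fluorescence plates generated from a known 5PL response
  with noise and gross outliers.

All randomness flows from ``numpy.random.SeedSequence`` streams derived
from a master seed and stable per-(subject, stage) keys, so identical
seeds give bit-identical outputs and distinct subjects get independent
streams.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_imaging import DiffusionScheme, ROIMask, ScalarVolume
from .rppm import LOG10_2, FiveParamLogistic, fivepl_eval
from .tractometry import StreamlineSet

__all__ = [
    "BundleSpec",
    "CohortSpec",
    "PlateSpec",
    "Subject",
    "make_bundle",
    "make_cohort",
    "make_dwi",
    "make_plate",
    "make_scheme",
    "tensor_components",
    "derive_rng",
]


def derive_rng(master_seed: int, *keys) -> np.random.Generator:
    """Deterministic independent stream for (master seed, keys).

    String keys are mapped to integers with CRC32 (stable across runs and
    platforms) and folded into a SeedSequence with the master seed.
    """
    ints = [int(master_seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


# ---------------------------------------------------------------------------
# Streamline bundles
# ---------------------------------------------------------------------------


@dataclass
class BundleSpec:
    """A coherent streamline bundle around a parametric centerline.

    kind "straight" uses ``length``; "arc" uses ``radius`` and
    ``arc_angle`` (radians); "helix" uses ``radius``, ``pitch`` (the b in
    z = b·t) and ``t_span``. Copies of the centerline are rigidly offset
    within a disc of ``disc_radius`` perpendicular to the bundle axis
    (rigid translation preserves the analytic length and curvature), then
    Gaussian point jitter of ``jitter_sd`` mm is added.
    """

    kind: str
    length: float = 10.0
    radius: float = 5.0
    arc_angle: float = math.pi / 2
    pitch: float = 1.0
    t_span: float = 4.0 * math.pi
    t_step: float = 0.05
    n_streamlines: int = 50
    n_points: int = 30
    disc_radius: float = 0.5
    jitter_sd: float = 0.0
    jitter_corr_mm: float = 1.5
    center: tuple = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "arc", "helix"):
            raise ValueError(f"unknown bundle kind {self.kind!r}")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.length <= 0 or self.radius <= 0 or self.pitch <= 0:
            raise ValueError("geometry parameters must be positive")


def correlated_jitter(
    rng: np.random.Generator,
    n_points: int,
    sd: float,
    corr_points: float,
) -> np.ndarray:
    """Smooth Gaussian displacement field along a streamline.

    White Gaussian noise is convolved with a Gaussian kernel of width
    ``corr_points`` (in point-index units) and renormalised so every
    point's displacement is marginally N(0, sd²) per axis. Tracking noise
    is smooth at the step scale — independent per-point jitter would add
    spurious curvature of order sd/ℓ² (ℓ the segment length), swamping the
    geometric signal.
    """
    if sd == 0:
        return np.zeros((n_points, 3))
    if corr_points <= 0:
        return rng.normal(0.0, sd, size=(n_points, 3))
    half = max(int(math.ceil(4 * corr_points)), 1)
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / corr_points) ** 2)
    k /= math.sqrt(float((k**2).sum()))
    white = rng.normal(0.0, sd, size=(n_points + 2 * half, 3))
    out = np.empty((n_points, 3))
    for a in range(3):
        out[:, a] = np.convolve(white[:, a], k, mode="valid")
    return out


def _centerline(spec: BundleSpec) -> tuple[np.ndarray, float, float]:
    """Centerline points plus analytic (length, curvature)."""
    c = np.asarray(spec.center, dtype=float)
    if spec.kind == "straight":
        t = np.linspace(-spec.length / 2, spec.length / 2, spec.n_points)
        pts = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)]) + c
        return pts, spec.length, 0.0
    if spec.kind == "arc":
        r, theta = spec.radius, spec.arc_angle
        phi = np.linspace(-theta / 2, theta / 2, spec.n_points)
        # circle center sits at +r along y so the arc midpoint is at `center`
        pts = np.column_stack([r * np.sin(phi), r * (1 - np.cos(phi)), np.zeros_like(phi)]) + c
        return pts, r * theta, 1.0 / r
    # helix: x = a cos t, y = a sin t, z = b t
    a, b = spec.radius, spec.pitch
    n = max(spec.n_points, int(round(spec.t_span / spec.t_step)) + 1)
    t = np.linspace(0.0, spec.t_span, n)
    pts = np.column_stack([a * np.cos(t), a * np.sin(t), b * t]) + c
    length = math.hypot(a, b) * spec.t_span
    curvature = a / (a * a + b * b)
    return pts, length, curvature


def make_bundle(spec: BundleSpec) -> tuple[StreamlineSet, dict]:
    """Generate a bundle and its analytic ground truth.

    Returns (StreamlineSet, {"length": mm, "curvature": mm⁻¹}).
    """
    center, length, curvature = _centerline(spec)
    rng = derive_rng(spec.seed, "bundle", spec.kind)

    # offsets in the disc perpendicular to the bundle's principal axis
    if spec.kind == "straight":
        n1, n2 = np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])
    elif spec.kind == "arc":
        n1, n2 = np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])
    else:  # helix axis is z; offset in xy
        n1, n2 = np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])

    seg = float(np.mean(np.linalg.norm(np.diff(center, axis=0), axis=1)))
    corr_points = spec.jitter_corr_mm / seg if seg > 0 else 0.0
    streamlines = []
    for _ in range(spec.n_streamlines):
        rho = spec.disc_radius * math.sqrt(rng.uniform())
        ang = rng.uniform(0.0, 2.0 * math.pi)
        offset = rho * (math.cos(ang) * n1 + math.sin(ang) * n2)
        pts = center + offset
        if spec.jitter_sd > 0:
            pts = pts + correlated_jitter(rng, pts.shape[0], spec.jitter_sd, corr_points)
        streamlines.append(pts)
    return StreamlineSet(streamlines), {"length": length, "curvature": curvature}


# ---------------------------------------------------------------------------
# Cohort phantom
# ---------------------------------------------------------------------------

DEFAULT_ROI_LAYOUT = {
    "ipsilateral_cortex": 1,
    "contralateral_cortex": 2,
    "corpus_callosum": 3,
    "hippocampus": 4,
}

# regions the injury affects (the lesion is ipsilateral; the contralateral
# cortex bundle is identical across groups)
_AFFECTED = ("ipsilateral_cortex", "corpus_callosum", "hippocampus")


@dataclass
class CohortSpec:
    """Two-group tractography phantom.

    ``effect_truncation`` removes that fraction of bundle length in the
    injured group's affected bundles; ``effect_straightening`` multiplies
    their curvature (1 = no change). Per-subject biological variability is
    a Gaussian multiplicative factor of sd ``subject_sd`` on both length
    and curvature, plus point jitter of ``jitter_sd`` mm.
    """

    n_per_group: int = 10
    effect_truncation: float = 0.2
    effect_straightening: float = 1.0
    roi_layout: dict = field(default_factory=lambda: dict(DEFAULT_ROI_LAYOUT))
    seed: int = 0
    jitter_sd: float = 0.1
    jitter_corr_mm: float = 1.5
    subject_sd: float = 0.03
    n_streamlines: int = 30
    n_points: int = 30
    voxel_size: float = 0.5
    grid_shape: tuple = (40, 40, 8)
    bundle_length: float = 8.0
    bundle_curvature: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.effect_truncation < 1.0):
            raise ValueError("effect_truncation must be in [0, 1)")
        if not (0.0 < self.effect_straightening <= 1.0):
            raise ValueError("effect_straightening must be in (0, 1]")
        labels = list(self.roi_layout.values())
        if len(labels) != len(set(labels)) or any(l <= 0 for l in labels):
            raise ValueError("ROI labels must be distinct positive integers")


@dataclass
class Subject:
    subject_id: str
    group: str
    streamlines: StreamlineSet
    mask: ROIMask
    grid: ScalarVolume


def _roi_boxes(spec: CohortSpec) -> dict[str, tuple[slice, slice, slice]]:
    nx, ny, nz = spec.grid_shape
    hx, hy = nx // 2, ny // 2
    pad = 2
    boxes = {
        "ipsilateral_cortex": (slice(pad, hx - pad), slice(hy + pad, ny - pad)),
        "contralateral_cortex": (slice(pad, hx - pad), slice(pad, hy - pad)),
        "corpus_callosum": (slice(hx + pad, nx - pad), slice(hy + pad, ny - pad)),
        "hippocampus": (slice(hx + pad, nx - pad), slice(pad, hy - pad)),
    }
    zsl = slice(1, nz - 1)
    return {name: (bx, by, zsl) for name, (bx, by) in boxes.items()}


def cohort_grid(spec: CohortSpec) -> tuple[ScalarVolume, ROIMask]:
    """Common reference grid and ROI label mask for a cohort."""
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    grid = ScalarVolume(np.zeros(spec.grid_shape), affine)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    boxes = _roi_boxes(spec)
    for name, label in spec.roi_layout.items():
        if name not in boxes:
            raise ValueError(f"unknown ROI name {name!r}")
        bx, by, bz = boxes[name]
        if np.any(labels[bx, by, bz] != 0):
            raise ValueError("overlapping ROI labels")
        labels[bx, by, bz] = label
    names = {label: name for name, label in spec.roi_layout.items()}
    return grid, ROIMask(labels, affine, names)


def _box_center_mm(spec: CohortSpec, box) -> np.ndarray:
    centers = []
    for sl, n in zip(box, spec.grid_shape):
        lo = sl.start if sl.start is not None else 0
        hi = sl.stop if sl.stop is not None else n
        centers.append((lo + hi - 1) / 2.0)
    return np.asarray(centers) * spec.voxel_size


def make_cohort(spec: CohortSpec) -> list[Subject]:
    """Generate the two-group phantom: per-subject streamlines routed
    through the ROI blocks of a common grid.

    Sham subjects carry the nominal arc bundles in every ROI; injured
    subjects' affected (ipsilateral) bundles are shortened by
    ``effect_truncation`` and their curvature multiplied by
    ``effect_straightening``, while the contralateral bundle is drawn from
    the same distribution in both groups.
    """
    grid, mask = cohort_grid(spec)
    boxes = _roi_boxes(spec)
    subjects = []
    for group in ("sham", "injured"):
        for si in range(spec.n_per_group):
            subject_id = f"{group}_{si + 1:02d}"
            all_streams = []
            for name, label in sorted(spec.roi_layout.items()):
                # stream keyed by (subject index, ROI) only: matched sham /
                # injured subjects share draws, so unaffected bundles are
                # identical across groups and effects are pure transforms
                rng = derive_rng(spec.seed, "subject", si, name)
                affected = group == "injured" and name in _AFFECTED
                length = spec.bundle_length
                curv = spec.bundle_curvature
                if affected:
                    length *= 1.0 - spec.effect_truncation
                    curv *= spec.effect_straightening
                # per-subject biological variability, independent per ROI
                length *= 1.0 + spec.subject_sd * rng.standard_normal()
                curv *= 1.0 + spec.subject_sd * rng.standard_normal()
                curv = max(curv, 1e-6)
                radius = 1.0 / curv
                theta = length / radius
                bspec = BundleSpec(
                    kind="arc",
                    radius=radius,
                    arc_angle=theta,
                    n_streamlines=spec.n_streamlines,
                    n_points=spec.n_points,
                    disc_radius=0.4,
                    jitter_sd=0.0,
                    center=tuple(_box_center_mm(spec, boxes[name])),
                    seed=0,
                )
                center, _, _ = _centerline(bspec)
                seg = float(np.mean(np.linalg.norm(np.diff(center, axis=0), axis=1)))
                corr_points = spec.jitter_corr_mm / seg if seg > 0 else 0.0
                for _ in range(spec.n_streamlines):
                    rho = bspec.disc_radius * math.sqrt(rng.uniform())
                    ang = rng.uniform(0.0, 2.0 * math.pi)
                    offset = np.array(
                        [0.0, rho * math.cos(ang), rho * math.sin(ang)]
                    )
                    pts = center + offset
                    if spec.jitter_sd > 0:
                        pts = pts + correlated_jitter(
                            rng, pts.shape[0], spec.jitter_sd, corr_points
                        )
                    all_streams.append(pts)
            subjects.append(
                Subject(
                    subject_id=subject_id,
                    group=group,
                    streamlines=StreamlineSet(all_streams),
                    mask=mask,
                    grid=grid,
                )
            )
    return subjects


# ---------------------------------------------------------------------------
# Diffusion-weighted signals
# ---------------------------------------------------------------------------


def make_scheme(n_dirs: int = 81, n_b0: int = 8, bval: float = 1200.0) -> DiffusionScheme:
    """The study acquisition scheme: ``n_b0`` b0 volumes followed by
    ``n_dirs`` unit directions spread by a deterministic golden-spiral
    construction (non-collinear by construction)."""
    i = np.arange(n_dirs)
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n_dirs
    phi = 2.0 * math.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(bval))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return DiffusionScheme(bvals, bvecs)


def tensor_components(evals, principal_axis=(1.0, 0.0, 0.0)) -> np.ndarray:
    """6-component tensor [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] with eigenvalues
    ``evals`` and λ1 along ``principal_axis`` (the remaining eigenvectors
    complete an orthonormal frame)."""
    evals = np.asarray(evals, dtype=float)
    e1 = np.asarray(principal_axis, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    basis = np.column_stack([e1, e2, e3])
    d = basis @ np.diag(evals) @ basis.T
    return np.array([d[0, 0], d[1, 1], d[2, 2], d[0, 1], d[0, 2], d[1, 2]])


def make_dwi(
    tensor_layout: np.ndarray,
    scheme: DiffusionScheme,
    noise_sd: float = 0.0,
    seed: int = 0,
    s0: float = 1000.0,
) -> np.ndarray:
    """Synthesize DWI signals S = S0·exp(−b gᵀDg) (+ Gaussian noise).

    ``tensor_layout`` has shape (X, Y, Z, 6) in the [Dxx, Dyy, Dzz, Dxy,
    Dxz, Dyz] convention; ``noise_sd`` is in units of S0. A Rician option
    is deliberately not the default so recovery statistics stay analytic.
    """
    layout = np.asarray(tensor_layout, dtype=float)
    if layout.ndim != 4 or layout.shape[-1] != 6:
        raise ValueError("tensor_layout must have shape (X, Y, Z, 6)")
    design = np.column_stack(
        [
            scheme.bvecs[:, 0] ** 2,
            scheme.bvecs[:, 1] ** 2,
            scheme.bvecs[:, 2] ** 2,
            2 * scheme.bvecs[:, 0] * scheme.bvecs[:, 1],
            2 * scheme.bvecs[:, 0] * scheme.bvecs[:, 2],
            2 * scheme.bvecs[:, 1] * scheme.bvecs[:, 2],
        ]
    )  # (n, 6)
    exponent = -scheme.bvals[None, None, None, :] * np.einsum(
        "xyzc,nc->xyzn", layout, design
    )
    signal = s0 * np.exp(exponent)
    if noise_sd > 0:
        rng = derive_rng(seed, "dwi")
        signal = signal + rng.normal(0.0, noise_sd * s0, size=signal.shape)
    return signal


# ---------------------------------------------------------------------------
# Serial-dilution plates
# ---------------------------------------------------------------------------


@dataclass
class PlateSpec:
    """Serial-dilution fluorescence plate from a known 5PL response.

    Each sample s at dilution step k is printed at x = log10 abundance −
    k·log10 2; log10 net fluorescence is the 5PL response plus Gaussian
    noise of sd ``noise_sd`` (log10 units). A fraction ``outlier_fraction``
    of spots is displaced by ±``outlier_magnitude`` log10 units. The SNR
    column is net fluorescence over the scanner noise floor, so dim spots
    fail the SNR < 2 filter exactly when real spots would.
    """

    n_samples: int = 8
    n_dilution_steps: int = 16
    true_log10_abundance: np.ndarray | None = None
    shape: FiveParamLogistic = field(
        default_factory=lambda: FiveParamLogistic(A=4.7, D=2.2, B=1.0, G=1.5, x_mid=-2.0)
    )
    noise_sd: float = 0.02
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 1.0
    noise_floor: float = 5.0
    background: float = 50.0
    groups: list | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dilution_steps < 4:
            raise ValueError("need >= 4 dilution steps")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.outlier_fraction <= 0.2):
            raise ValueError("outlier_fraction must be in [0, 0.2]")
        if self.true_log10_abundance is None:
            self.true_log10_abundance = np.zeros(self.n_samples)
        self.true_log10_abundance = np.asarray(self.true_log10_abundance, dtype=float)
        if self.true_log10_abundance.size != self.n_samples:
            raise ValueError("true_log10_abundance must have n_samples entries")
        if self.groups is not None and len(self.groups) != self.n_samples:
            raise ValueError("groups must have n_samples entries")


def make_plate(spec: PlateSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a SpotTable plus ground truth.

    Returns (table, truth) where the table has columns sample_id, block,
    dilution_step, fg, bg, snr (and group when specified), and truth holds
    the generating 5PL shape, per-sample abundances and outlier row keys.
    """
    rng = derive_rng(spec.seed, "plate")
    rows = []
    for s in range(spec.n_samples):
        abundance = spec.true_log10_abundance[s]
        for k in range(spec.n_dilution_steps):
            x = abundance - k * LOG10_2
            y = fivepl_eval(spec.shape, x)
            if spec.noise_sd > 0:
                y += rng.normal(0.0, spec.noise_sd)
            rows.append(
                {
                    "sample_id": f"S{s + 1:02d}",
                    "block": s + 1,
                    "dilution_step": k,
                    "log10_net": y,
                }
            )
    df = pd.DataFrame(rows)

    n_out = int(round(spec.outlier_fraction * len(df)))
    outlier_rows = np.array([], dtype=int)
    if n_out > 0:
        outlier_rows = rng.choice(len(df), size=n_out, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        df.loc[outlier_rows, "log10_net"] += signs * spec.outlier_magnitude

    net = np.power(10.0, df["log10_net"].to_numpy())
    df["bg"] = spec.background
    df["fg"] = net + spec.background
    df["snr"] = net / spec.noise_floor
    if spec.groups is not None:
        df["group"] = [spec.groups[int(b) - 1] for b in df["block"]]
    df = df.drop(columns=["log10_net"])

    truth = {
        "shape": spec.shape,
        "true_log10_abundance": spec.true_log10_abundance.copy(),
        "outlier_rows": np.sort(outlier_rows),
    }
    return df, truth
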