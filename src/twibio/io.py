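"""File formats, configuration and pipeline orchestration.

Tractograms use the TCK format (textual header, Float32LE XYZ triplets,
NaN-triplet streamline delimiters, Inf-triplet terminator) through
nibabel's streamline layer; volumes and masks are NIfTI-1; diffusion
schemes are FSL-style whitespace b-value/b-vector text files; all tables
are CSV with headers. ``run_pipeline`` executes a configured sequence of
stages and writes a RunRecord capturing every parameter used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_imaging import ROIMask, ScalarVolume
from .tractometry import StreamlineSet

__all__ = [
    "read_tck",
    "write_tck",
    "read_volume",
    "write_volume",
    "read_mask",
    "read_scheme",
    "PipelineConfig",
    "RunRecord",
    "run_pipeline",
]


class TractogramError(RuntimeError):
    """A TCK file is malformed or uses an unsupported datatype."""


def read_tck(path) -> StreamlineSet:
    """Read a TCK tractogram (world-mm coordinates, Float32LE payload)."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            head = fh.read(2048).split(b"\n")
        for line in head:
            if line.startswith(b"datatype:"):
                dtype = line.split(b":", 1)[1].strip().decode()
                if dtype != "Float32LE":
                    raise TractogramError(f"unsupported TCK datatype: {dtype}")
        tck = nib.streamlines.load(str(path))
    except TractogramError:
        raise
    except Exception as exc:
        raise TractogramError(f"corrupt tractogram: {path} ({exc})") from exc
    streams = [np.asarray(s, dtype=np.float32) for s in tck.streamlines]
    return StreamlineSet([s.astype(float) for s in streams])


def write_tck(ts: StreamlineSet, path) -> None:
    """Write a TCK tractogram; coordinates are stored as float32, so a
    round trip is bit-exact on the float32 payload."""
    path = Path(path)
    streams = [np.asarray(s, dtype=np.float32) for s in ts.streamlines]
    tractogram = nib.streamlines.Tractogram(streams, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(nib.streamlines.TckFile(tractogram), str(path))


def read_volume(path) -> ScalarVolume:
    """Read a 3D NIfTI-1 volume."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return ScalarVolume(data, img.affine)


def read_dwi(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 4D NIfTI-1 DWI series; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got shape {data.shape}")
    return data, img.affine


def write_volume(vol: ScalarVolume | np.ndarray, path, affine=None) -> None:
    if isinstance(vol, ScalarVolume):
        data, aff = vol.data, vol.affine
    else:
        data, aff = np.asarray(vol), affine if affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), aff), str(path))


def read_mask(path, label_names: dict | None = None) -> ROIMask:
    """Read an ROI label mask; rejects non-integer voxel values."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: mask must be 3D")
    if not np.all(data == np.round(data)):
        raise ValueError(f"{path}: mask contains non-integer labels")
    return ROIMask(data.astype(np.int32), img.affine, label_names or {})


def write_mask(mask: ROIMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int32), mask.affine), str(path))


def read_scheme(bvals_path, bvecs_path):
    """Read FSL-style b-value and b-vector text files.

    bvals: whitespace-separated scalars; bvecs: 3×N or N×3 whitespace
    matrix.
    """
    from .core_imaging import DiffusionScheme

    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    return DiffusionScheme(bvals, bvecs)


def write_scheme(scheme, bvals_path, bvecs_path) -> None:
    np.savetxt(bvals_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, scheme.bvecs.T, fmt="%.9g")


# ---------------------------------------------------------------------------
# Configuration and orchestration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "pipeline",
    "seed",
    "out_dir",
    "q",
    "snr_min",
    "net_min",
    "statistic",
    "t_test_variant",
    "include_empty",
    "n_per_group",
    "effect_truncation",
    "effect_straightening",
    "jitter_sd",
    "n_samples",
    "n_dilution_steps",
    "noise_sd",
    "outlier_fraction",
    "abundance_offsets",
    "groups",
    "log_level",
}


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected up front.

    ``pipeline`` selects the stage sequence: "cohort" (simulate → maps →
    ROI stats → compare) or "rppm" (simulate plate → quantify → compare).
    Every defaulted parameter is echoed into the RunRecord for provenance.
    """

    pipeline: str = "cohort"
    seed: int = 0
    out_dir: str = "twibio_out"
    q: float = 0.01
    snr_min: float = 2.0
    net_min: float = 10.0
    statistic: str = "pathlength"
    t_test_variant: str = "student"
    include_empty: bool = False
    n_per_group: int = 10
    effect_truncation: float = 0.2
    effect_straightening: float = 1.0
    jitter_sd: float = 0.1
    n_samples: int = 8
    n_dilution_steps: int = 16
    noise_sd: float = 0.02
    outlier_fraction: float = 0.0
    abundance_offsets: list = field(default_factory=list)
    groups: list = field(default_factory=list)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.pipeline not in ("cohort", "rppm"):
            raise ValueError(f"unknown pipeline {cfg.pipeline!r}")
        return cfg


@dataclass
class RunRecord:
    """Provenance snapshot written alongside every pipeline run."""

    config: dict
    version: str
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def run_pipeline(config: PipelineConfig) -> RunRecord:
    """Execute the configured stage sequence and write all outputs.

    Stage failures propagate as RuntimeError prefixed with the stage name.
    Reruns with identical config (including seed) produce byte-identical
    numeric outputs.
    """
    from . import synthetic
    from .group_stats import compare_table
    from .rppm import run_rppm_pipeline
    from .tractometry import track_weighted_map, twi_roi_stats

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = RunRecord(config=asdict(config), version=__version__)

    if config.pipeline == "cohort":
        spec = synthetic.CohortSpec(
            n_per_group=config.n_per_group,
            effect_truncation=config.effect_truncation,
            effect_straightening=config.effect_straightening,
            jitter_sd=config.jitter_sd,
            seed=config.seed,
        )
        subjects = synthetic.make_cohort(spec)
        record.counts["subjects"] = len(subjects)
        rows = []
        for subj in subjects:
            twm = track_weighted_map(subj.streamlines, subj.grid, config.statistic)
            stats_df = twi_roi_stats(twm, subj.mask, include_empty=config.include_empty)
            stats_df.insert(0, "subject", subj.subject_id)
            stats_df.insert(1, "group", subj.group)
            rows.append(stats_df)
        roi_stats = pd.concat(rows, ignore_index=True)
        roi_path = out_dir / "roi_stats.csv"
        roi_stats.to_csv(roi_path, index=False, float_format="%.10g")
        record.outputs.append(str(roi_path))
        record.counts["streamlines_per_subject"] = len(subjects[0].streamlines)

        long = roi_stats.rename(columns={"roi": "measure", "median": "value"})
        comparisons = compare_table(long, variant=config.t_test_variant)
        cmp_path = out_dir / "comparisons.csv"
        comparisons.to_csv(cmp_path, index=False, float_format="%.10g")
        record.outputs.append(str(cmp_path))
    else:  # rppm
        offsets = list(config.abundance_offsets) or [0.0] * config.n_samples
        spec = synthetic.PlateSpec(
            n_samples=config.n_samples,
            n_dilution_steps=config.n_dilution_steps,
            true_log10_abundance=np.asarray(offsets, dtype=float),
            noise_sd=config.noise_sd,
            outlier_fraction=config.outlier_fraction,
            groups=list(config.groups) or None,
            seed=config.seed,
        )
        plate, _truth = synthetic.make_plate(spec)
        plate_path = out_dir / "plate.csv"
        plate.to_csv(plate_path, index=False, float_format="%.10g")
        record.outputs.append(str(plate_path))
        quants, summary, master = run_rppm_pipeline(plate, q=config.q)
        q_path = out_dir / "quants.csv"
        quants.to_csv(q_path, index=False, float_format="%.10g")
        record.outputs.append(str(q_path))
        record.counts["samples_quantified"] = len(quants)
        record.counts["spots_excluded_as_outliers"] = (
            0 if master.excluded_points is None else len(master.excluded_points)
        )
        if summary is not None:
            s_path = out_dir / "group_summary.csv"
            summary.to_csv(s_path, index=False, float_format="%.10g")
            record.outputs.append(str(s_path))

    record.save(out_dir / "run_record.json")
    return record
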