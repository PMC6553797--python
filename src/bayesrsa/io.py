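"""File I/O and result serialization.

Data enter as 4-D NIfTI volumes with a binary mask (voxel order =
flattened nonzero mask positions in C order, 0-based) or as plain
time-by-voxel TSV matrices.  Designs enter either as precomputed
time-by-condition TSV tables or as BIDS-style events tables
(onset / duration / trial_type) convolved with the canonical HRF.
Results leave as TSV matrices, NIfTI maps (when the input was NIfTI)
and a JSON metadata record carrying the config hash and seed so every
run is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .likelihood import DataMatrix, TaskDesign
from .simulate import build_design_matrix

logger = logging.getLogger("bayesrsa")

__all__ = [
    "RunManifest",
    "ResultBundle",
    "read_data",
    "read_design",
    "write_results",
    "config_hash",
]


@dataclass
class RunManifest:
    """Paths and scan parameters for one subject's runs."""

    data_paths: list[str]
    design_paths: list[str]
    TR: float
    mask_path: str | None = None
    subject_id: str = "sub-01"
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if len(self.data_paths) != len(self.design_paths):
            raise ValueError("one design per data run required")
        missing = [
            p
            for p in [*self.data_paths, *self.design_paths]
            + ([self.mask_path] if self.mask_path else [])
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


@dataclass
class ResultBundle:
    """Everything a fitting or similarity run produces, ready to serialize."""

    method: str
    seed: int
    config: dict = field(default_factory=dict)
    similarity: np.ndarray | None = None
    covariance: np.ndarray | None = None
    snr_map: np.ndarray | None = None
    scores: dict = field(default_factory=dict)
    decoded: np.ndarray | None = None
    extra_maps: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return config_hash(self.config)


def config_hash(config: dict) -> str:
    """Deterministic short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------


def _is_nifti(path) -> bool:
    s = str(path)
    return s.endswith(".nii") or s.endswith(".nii.gz")


def read_data(path, mask_path=None, run_index=None) -> DataMatrix:
    """Load a time-by-voxel data matrix.

    NIfTI input requires a 3-D binary mask; voxels are ordered by the
    flattened (C-order) nonzero mask positions.  TSV input is used
    as-is (header row optional, detected).  NaNs raise with locations.
    """
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.ndim != 4:
            raise ValueError(f"expected a 4-D NIfTI volume, got shape {vol.shape}")
        if mask_path is None:
            raise ValueError("NIfTI input requires a mask")
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        if mask.shape != vol.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume {vol.shape[:3]}"
            )
        Y = vol[mask].T  # (n_T, n_V), C-order flattened mask
    else:
        df = pd.read_csv(path, sep="\t", header=None)
        # header detection: a non-numeric first row
        if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
            df = pd.read_csv(path, sep="\t")
        Y = df.to_numpy(dtype=float)
    if np.isnan(Y).any():
        bad = np.argwhere(np.isnan(Y))
        raise ValueError(f"NaNs in data at (time, voxel) {bad[:10].tolist()}")
    n_T = Y.shape[0]
    if run_index is None:
        run_index = np.zeros(n_T, dtype=int)
    const = np.flatnonzero(np.ptp(Y, axis=0) == 0)
    if const.size:
        logger.warning("constant voxel(s) at indices %s", const[:20].tolist())
    return DataMatrix(Y=Y, run_index=np.asarray(run_index))


def read_design(path, TR: float, n_T: int, run_index=None) -> TaskDesign:
    """Load a task design.

    A BIDS-style events table (onset, duration, trial_type columns) is
    convolved with the double-gamma HRF; a time-by-condition TSV is
    passed through unchanged (its row count must equal ``n_T``).
    """
    df = pd.read_csv(path, sep="\t")
    if run_index is None:
        run_index = np.zeros(n_T, dtype=int)
    events_cols = {"onset", "duration", "trial_type"}
    if events_cols.issubset(df.columns):
        X = build_design_matrix(df, TR, n_T)
    else:
        if not all(pd.api.types.is_numeric_dtype(t) for t in df.dtypes):
            raise ValueError(
                f"unknown design columns {list(df.columns)}; expected either "
                "a numeric time-by-condition table or onset/duration/trial_type"
            )
        X = df.to_numpy(dtype=float)
        if X.shape[0] != n_T:
            raise ValueError(
                f"design has {X.shape[0]} rows, expected n_T={n_T}"
            )
    return TaskDesign(X=X, run_index=np.asarray(run_index), TR=TR)


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------


def _write_matrix(path: Path, M: np.ndarray) -> None:
    pd.DataFrame(M).to_csv(path, sep="\t", header=False, index=False,
                           float_format="%.10g")


def write_results(bundle: ResultBundle, outdir, mask_img=None) -> dict:
    """Serialize a result bundle; returns {name: path} of written files.

    Matrices go to TSV; voxel maps to NIfTI when ``mask_img`` (a loaded
    mask image) is given, else TSV; metadata and scalar scores to JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    meta = {
        "method": bundle.method,
        "version": __import__("bayesrsa").__version__,
        "seed": bundle.seed,
        "config_hash": bundle.config_hash,
        "config": {k: str(v) for k, v in bundle.config.items()},
        "scores": bundle.scores,
    }
    for name, mat in [
        ("similarity", bundle.similarity),
        ("covariance", bundle.covariance),
        ("decoded", bundle.decoded),
    ]:
        if mat is not None:
            p = outdir / f"{name}.tsv"
            _write_matrix(p, np.asarray(mat))
            written[name] = str(p)
    maps = dict(bundle.extra_maps)
    if bundle.snr_map is not None:
        maps["pseudo_snr"] = bundle.snr_map
    for name, vals in maps.items():
        vals = np.asarray(vals, dtype=float)
        if mask_img is not None:
            mask = np.asarray(mask_img.dataobj) > 0
            vol = np.zeros(mask.shape, dtype=float)
            vol[mask] = vals
            p = outdir / f"{name}.nii.gz"
            nib.save(nib.Nifti1Image(vol, mask_img.affine), str(p))
        else:
            p = outdir / f"{name}.tsv"
            _write_matrix(p, vals[:, None])
        written[name] = str(p)
    p = outdir / "results.json"
    with open(p, "w") as fh:
        json.dump(meta, fh, indent=2, default=float)
    written["metadata"] = str(p)
    logger.info("results written to %s (config %s, seed %d)", outdir,
                bundle.config_hash, bundle.seed)
    return written
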