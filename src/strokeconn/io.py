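"""File formats: matrix CSV round-trips, streamline JSON-lines, NIfTI
volumes, subject tables and YAML provenance sidecars.

CSV and JSON are the primary interchange formats so that desk-scale runs
stay diff-able; NIfTI appears only at the imaging boundary (phantom
volumes), streamlines as one-JSON-object-per-line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import Parcellation
from .synthetic import SubjectRecord
from .tracking import Streamline, TrackingVolume

logger = logging.getLogger(__name__)


def write_matrix(path, matrix: np.ndarray, roi_labels: Sequence[int]) -> None:
    """Write a symmetric matrix as CSV with ROI labels as header row/column."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if len(roi_labels) != m.shape[0]:
        raise ValueError("label count does not match matrix dimension")
    asym = np.abs(m - m.T).max() if m.size else 0.0
    if asym > 0:
        raise ValueError(f"matrix is asymmetric: max |a_ij - a_ji| = {asym:g}")
    if np.isnan(m).any():
        i, j = np.argwhere(np.isnan(m))[0]
        raise ValueError(f"NaN entry at ({roi_labels[i]}, {roi_labels[j]})")
    df = pd.DataFrame(m, index=list(roi_labels), columns=list(roi_labels))
    df.to_csv(path, index_label="roi")


def read_matrix(path, parcellation: Parcellation | None = None) -> tuple[np.ndarray, list[int]]:
    """Read a labeled matrix CSV; if a parcellation is given, align row/column
    order to the parcellation's label order."""
    df = pd.read_csv(path, index_col=0)
    labels = [int(l) for l in df.index]
    if [int(c) for c in df.columns] != labels:
        raise ValueError("row and column labels differ")
    m = df.to_numpy(dtype=float)
    if np.isnan(m).any():
        i, j = np.argwhere(np.isnan(m))[0]
        raise ValueError(f"NaN entry at ({labels[i]}, {labels[j]})")
    if parcellation is not None:
        want = parcellation.labels.tolist()
        if sorted(want) != sorted(labels):
            raise ValueError("file labels do not match parcellation labels")
        order = [labels.index(l) for l in want]
        m = m[np.ix_(order, order)]
        labels = want
    return m, labels


def write_streamlines(path, streamlines: Iterable[Streamline]) -> None:
    """One JSON object per line: points, length, mean_fa, endpoint labels."""
    with open(path, "w") as fh:
        for sl in streamlines:
            fh.write(json.dumps({
                "points": np.asarray(sl.points).tolist(),
                "length": sl.length,
                "mean_fa": sl.mean_fa,
                "endpoint_labels": list(sl.endpoint_labels) if sl.endpoint_labels else None,
                "excluded": sl.excluded,
                "exclusion_reason": sl.exclusion_reason,
            }) + "\n")


def read_streamlines(path) -> list[Streamline]:
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(Streamline(
                points=np.array(d["points"]),
                mean_fa=d["mean_fa"],
                endpoint_labels=tuple(d["endpoint_labels"]) if d["endpoint_labels"] else None,
                excluded=d["excluded"],
                exclusion_reason=d.get("exclusion_reason", ""),
            ))
    return out


def write_phantom_nifti(volume: TrackingVolume, prefix) -> dict[str, Path]:
    """Write direction (4D float), FA (3D float) and labels (3D int) NIfTIs."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    paths = {
        "directions": prefix.with_name(prefix.name + "_dirs.nii"),
        "fa": prefix.with_name(prefix.name + "_fa.nii"),
        "labels": prefix.with_name(prefix.name + "_labels.nii"),
    }
    nib.save(nib.Nifti1Image(volume.directions.astype(np.float32), aff), paths["directions"])
    nib.save(nib.Nifti1Image(volume.fa.astype(np.float32), aff), paths["fa"])
    nib.save(nib.Nifti1Image(volume.labels.astype(np.int32), aff), paths["labels"])
    return paths


def read_phantom_nifti(prefix) -> TrackingVolume:
    prefix = Path(prefix)
    dirs = nib.load(prefix.with_name(prefix.name + "_dirs.nii")).get_fdata()
    fa = nib.load(prefix.with_name(prefix.name + "_fa.nii")).get_fdata()
    labels = np.asarray(
        nib.load(prefix.with_name(prefix.name + "_labels.nii")).dataobj
    ).astype(int)
    return TrackingVolume(directions=dirs, fa=fa, labels=labels)


def subjects_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        d["lesion_locations"] = ";".join(r.lesion_locations)
        rows.append(d)
    return pd.DataFrame(rows)


def frame_to_subjects(df: pd.DataFrame) -> list[SubjectRecord]:
    recs = []
    for row in df.to_dict(orient="records"):
        locs = row.get("lesion_locations") or ""
        if isinstance(locs, float):
            locs = ""
        row["lesion_locations"] = tuple(l for l in str(locs).split(";") if l)
        for k, v in list(row.items()):
            if isinstance(v, float) and np.isnan(v):
                row[k] = None
        for k in ("arat", "fma_ue", "fma_se", "fma_wh"):
            if row.get(k) is not None:
                row[k] = int(row[k])
        recs.append(SubjectRecord(**row))
    return recs


def _config_to_plain(config) -> dict:
    if is_dataclass(config):
        return asdict(config)
    return dict(config)


def write_provenance(path, config, seed: int | None = None, extra: dict | None = None) -> None:
    """YAML sidecar with version, seed and a hash of the full configuration."""
    plain = _config_to_plain(config)
    blob = json.dumps(plain, sort_keys=True, default=str).encode()
    doc = {
        "strokeconn_version": __version__,
        "rng_seed": seed,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "config": plain,
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=False)
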