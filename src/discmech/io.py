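"""Plain-text and NIfTI input/output.

Formats: cohort tables as CSV (one row per sample x region), mechanical
curves as CSV with a JSON geometry/schedule sidecar, phantoms as
long-format voxel tables (CSV) or per-sequence NIfTI stacks, dendrograms
as Newick.  CSV files may carry ``#``-prefixed header comments (run
manifest hash); readers here skip them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import B0_INDEX, default_protocol
from .biomech import Geometry, MechCurve, RampSchedule

COHORT_COLUMNS = ["sample_id", "group", "region", "T1_ms", "T2_ms", "MTR",
                  "ADC", "FA", "E", "k_r", "H_A0", "k_0", "k_a"]


def write_csv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks columns: {missing}")
    return df


def write_cohort_csv(df: pd.DataFrame, path,
                     header_comment: str | None = None) -> None:
    write_csv(df[COHORT_COLUMNS], path, header_comment)


# ---------------------------------------------------------------------------
# mechanical curves
# ---------------------------------------------------------------------------

def write_mech_curve(curve: MechCurve, csv_path) -> None:
    """CSV (t_s, force_N, displacement_mm) plus a JSON sidecar with
    geometry, schedule and test kind."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t_s": curve.t, "force_N": curve.force,
                  "displacement_mm": curve.displacement}).to_csv(csv_path,
                                                                 index=False)
    meta = {
        "kind": curve.kind,
        "geometry": {"radius_mm": curve.geometry.radius_mm,
                     "thickness_mm": curve.geometry.thickness_mm},
        "schedule": {"n_ramps": curve.schedule.n_ramps,
                     "strain_increment": curve.schedule.strain_increment,
                     "ramp_duration": curve.schedule.ramp_duration,
                     "hold_duration": curve.schedule.hold_duration},
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_mech_curve(csv_path) -> MechCurve:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, comment="#")
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return MechCurve(df["t_s"].to_numpy(), df["force_N"].to_numpy(),
                     df["displacement_mm"].to_numpy(),
                     Geometry(**meta["geometry"]),
                     RampSchedule(**meta["schedule"]),
                     kind=meta.get("kind", "unconfined"))


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def phantom_to_voxel_table(phantom) -> pd.DataFrame:
    """Long-format voxel table: (voxel_id, roi, sequence, index_value, signal)."""
    rows = []
    labels = phantom.roi_labels
    proto = phantom.protocol
    coords = {"ir": np.array(proto.inversion_times),
              "echo": np.array(proto.echo_times_t2),
              "mt": np.array([0.0, 1.0]),
              "dwi": np.concatenate([[B0_INDEX],
                                     np.arange(proto.gradient_dirs.shape[0])])}
    for vid, vox in enumerate(np.ndindex(labels.shape)):
        roi = labels[vox]
        if roi == "background":
            continue
        for seq, xs in coords.items():
            for x, y in zip(xs, phantom.stacks[seq][vox]):
                rows.append({"voxel_id": vid, "roi": roi, "sequence": seq,
                             "index_value": x, "signal": y})
    return pd.DataFrame(rows)


def voxel_table_to_stacks(df: pd.DataFrame):
    """Rebuild per-voxel stacks (1-D grid) from a long voxel table.

    Returns an object usable by :func:`discmech.qmri.fit_voxelwise`
    (duck-typed phantom with ``stacks``, ``roi_labels``, ``protocol``)."""
    from .synthetic import PhantomImage
    proto = default_protocol()
    vids = np.sort(df["voxel_id"].unique())
    n = vids.size
    labels = np.empty(n, object)
    stacks = {seq: None for seq in ("ir", "echo", "mt", "dwi")}
    for k, vid in enumerate(vids):
        sub = df[df["voxel_id"] == vid]
        labels[k] = sub["roi"].iloc[0]
        for seq in stacks:
            block = sub[sub["sequence"] == seq].sort_index()
            y = block["signal"].to_numpy()
            if stacks[seq] is None:
                stacks[seq] = np.zeros((n, y.size))
            stacks[seq][k] = y
    return PhantomImage(roi_labels=labels, truths={}, stacks=stacks,
                        protocol=proto, noise_sigma=np.nan, seed=-1)


def phantom_to_nifti(phantom, out_dir) -> list[Path]:
    """One NIfTI per sequence (grid dims + sample dim) plus an ROI label
    volume (NP=1, AF=2, background=0)."""
    import nibabel as nib
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    affine = np.eye(4)
    for seq, arr in phantom.stacks.items():
        grid = arr.reshape(arr.shape[:-1] + (arr.shape[-1],))
        while grid.ndim < 4:
            grid = grid[None]
        img = nib.Nifti1Image(np.asarray(grid, np.float64), affine)
        p = out_dir / f"{seq}.nii"
        nib.save(img, p)
        written.append(p)
    code = {"background": 0, "NP": 1, "AF": 2}
    lab = np.vectorize(code.get)(phantom.roi_labels).astype(np.int16)
    while lab.ndim < 3:
        lab = lab[None]
    p = out_dir / "roi_labels.nii"
    nib.save(nib.Nifti1Image(lab, affine), p)
    written.append(p)
    return written


def write_newick(dendrogram, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(dendrogram.to_newick() + "\n")
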