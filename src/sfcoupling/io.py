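"""Cohort directory readers and writers.

Layout (``format="tsv"``, the default)::

    cohort/
      manifest.json            full generating config, seed, format
      phenotype.tsv            subject_id, score, age, sex, motion
      roi_volumes.tsv          subjects x ROIs voxel counts
      gmv.tsv                  subjects x ROIs gray-matter volumes
      subjects/<id>_sc.tsv     directed streamline counts (ints)
      subjects/<id>_ts.tsv     ROI time series (timepoints x ROIs)  [or]
      subjects/<id>_fc.tsv     precomputed Fisher-z FC matrix

``format="hdf5"`` replaces the per-subject TSVs with one ``matrices.h5``
holding datasets ``sc/<id>`` and ``ts/<id>`` (or ``fc/<id>``); the tabular
files stay plain text either way.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .synthetic import SubjectRecord, SyntheticConfig

__all__ = ["write_cohort", "read_cohort", "roi_labels_for"]


def roi_labels_for(n: int) -> list[str]:
    return [f"ROI{i:03d}" for i in range(n)]


def write_cohort(
    records: Sequence[SubjectRecord],
    path: str | Path,
    config: SyntheticConfig | None = None,
    fmt: str = "tsv",
) -> Path:
    """Write a cohort directory; returns its path."""
    if fmt not in ("tsv", "hdf5"):
        raise DataError(f"unknown cohort format {fmt!r}")
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    n = records[0].sc_counts.shape[0]
    labels = roi_labels_for(n)
    ids = [r.subject_id for r in records]

    pheno = pd.DataFrame(
        {
            "subject_id": ids,
            "score": [r.score for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "motion": [r.motion for r in records],
        }
    )
    pheno.to_csv(root / "phenotype.tsv", sep="\t", index=False, float_format="%.10g")

    for fname, attr in (("roi_volumes.tsv", "roi_volumes"), ("gmv.tsv", "gmv")):
        tab = pd.DataFrame(
            np.vstack([getattr(r, attr) for r in records]), index=ids, columns=labels
        )
        tab.index.name = "subject_id"
        tab.to_csv(root / fname, sep="\t", float_format="%.10g")

    mode = "timeseries" if records[0].timeseries is not None else "fc"
    if fmt == "tsv":
        sub = root / "subjects"
        sub.mkdir(exist_ok=True)
        for r in records:
            np.savetxt(sub / f"{r.subject_id}_sc.tsv", r.sc_counts, fmt="%d", delimiter="\t")
            if r.timeseries is not None:
                np.savetxt(
                    sub / f"{r.subject_id}_ts.tsv", r.timeseries, fmt="%.10g", delimiter="\t"
                )
            else:
                np.savetxt(sub / f"{r.subject_id}_fc.tsv", r.fc, fmt="%.10g", delimiter="\t")
    else:
        import h5py

        with h5py.File(root / "matrices.h5", "w") as h5:
            for r in records:
                h5.create_dataset(f"sc/{r.subject_id}", data=r.sc_counts)
                if r.timeseries is not None:
                    h5.create_dataset(f"ts/{r.subject_id}", data=r.timeseries)
                else:
                    h5.create_dataset(f"fc/{r.subject_id}", data=r.fc)

    manifest = {
        "format": fmt,
        "mode": mode,
        "n_subjects": len(records),
        "n_rois": n,
        "subject_ids": ids,
        "roi_labels": labels,
        "samples_per_voxel": records[0].samples_per_voxel,
        "config": config.to_dict() if config is not None else None,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return root


def read_cohort(path: str | Path) -> tuple[list[SubjectRecord], dict]:
    """Load a cohort directory written by :func:`write_cohort`."""
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise DataError(f"no manifest.json in {root}")
    manifest = json.loads(mpath.read_text())
    pheno = pd.read_csv(root / "phenotype.tsv", sep="\t")
    vols = pd.read_csv(root / "roi_volumes.tsv", sep="\t", index_col=0)
    gmv = pd.read_csv(root / "gmv.tsv", sep="\t", index_col=0)
    ids = manifest["subject_ids"]
    missing = [s for s in ids if s not in set(pheno["subject_id"])]
    if missing:
        raise DataError(f"phenotype.tsv missing subjects: {missing}")
    pheno = pheno.set_index("subject_id").loc[ids]
    fmt = manifest.get("format", "tsv")
    mode = manifest.get("mode", "timeseries")
    spv = int(manifest.get("samples_per_voxel", 5000))

    h5 = None
    if fmt == "hdf5":
        import h5py

        h5 = h5py.File(root / "matrices.h5", "r")
    records = []
    try:
        for sid in ids:
            if fmt == "tsv":
                sc = np.loadtxt(root / "subjects" / f"{sid}_sc.tsv", delimiter="\t")
                if mode == "timeseries":
                    ts, fc = np.loadtxt(
                        root / "subjects" / f"{sid}_ts.tsv", delimiter="\t"
                    ), None
                else:
                    ts, fc = None, np.loadtxt(
                        root / "subjects" / f"{sid}_fc.tsv", delimiter="\t"
                    )
            else:
                sc = h5[f"sc/{sid}"][()]
                ts = h5[f"ts/{sid}"][()] if mode == "timeseries" else None
                fc = h5[f"fc/{sid}"][()] if mode != "timeseries" else None
            row = pheno.loc[sid]
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    sc_counts=sc.astype(np.int64),
                    roi_volumes=vols.loc[sid].to_numpy(dtype=float),
                    gmv=gmv.loc[sid].to_numpy(dtype=float),
                    score=float(row["score"]),
                    age=float(row["age"]),
                    sex=int(row["sex"]),
                    motion=float(row["motion"]),
                    timeseries=ts,
                    fc=fc,
                    samples_per_voxel=spv,
                )
            )
    finally:
        if h5 is not None:
            h5.close()
    return records, manifest
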