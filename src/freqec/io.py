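"""Plain-text cohort serialization.

A cohort on disk is: one delimited time-course file per subject (tab-separated,
header row of component ids, one column per component), ``metadata.csv``,
``labels.csv`` mapping components to networks, and ``ground_truth.json`` with
the generating edges, bands and seed when the cohort is synthetic.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CohortSpec, CouplingEdge, TimeCourseSet

__all__ = ["write_cohort", "load_cohort", "validate_inputs"]


def _component_ids(n: int) -> list[str]:
    return [f"C{i:02d}" for i in range(n)]


def write_cohort(
    out_dir: str | Path,
    metadata: pd.DataFrame,
    tcs: TimeCourseSet,
    labels: dict[int, str],
    ground_truth: list[CouplingEdge] | None = None,
    spec: CohortSpec | None = None,
) -> Path:
    out = Path(out_dir)
    (out / "timecourses").mkdir(parents=True, exist_ok=True)
    comp_ids = _component_ids(tcs.data.shape[1])
    for i, sid in enumerate(tcs.subject_ids):
        df = pd.DataFrame(tcs.data[i].T, columns=comp_ids)
        df.to_csv(out / "timecourses" / f"{sid}_timecourses.tsv", sep="\t", index=False)
    metadata.to_csv(out / "metadata.csv", index=False)
    pd.DataFrame(
        {"component_id": comp_ids, "network": [labels[i] for i in range(len(comp_ids))]}
    ).to_csv(out / "labels.csv", index=False)
    gt: dict = {"sampling_interval": tcs.sampling_interval}
    if spec is not None:
        gt["seed"] = spec.seed
        gt["bands"] = [list(b) for b in spec.bands]
        gt["noise_sd"] = spec.noise_sd
    if ground_truth is not None:
        gt["edges"] = [asdict(e) for e in ground_truth]
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1)
    return out


def load_cohort(in_dir: str | Path) -> tuple[pd.DataFrame, TimeCourseSet, dict[int, str]]:
    src = Path(in_dir)
    metadata = pd.read_csv(src / "metadata.csv")
    lab = pd.read_csv(src / "labels.csv")
    labels = {i: net for i, net in enumerate(lab["network"])}
    with open(src / "ground_truth.json") as fh:
        gt = json.load(fh)
    arrays = []
    for sid in metadata["subject_id"]:
        df = pd.read_csv(src / "timecourses" / f"{sid}_timecourses.tsv", sep="\t")
        arrays.append(df.to_numpy(float).T)
    tcs = TimeCourseSet(
        data=np.stack(arrays),
        sampling_interval=float(gt.get("sampling_interval", 2.0)),
        subject_ids=metadata["subject_id"].tolist(),
    )
    return metadata, tcs, labels


def validate_inputs(in_dir: str | Path) -> list[str]:
    """Report-only validation of a cohort directory; returns violations."""
    src = Path(in_dir)
    violations: list[str] = []
    meta_path = src / "metadata.csv"
    if not meta_path.exists():
        return [f"missing metadata file: {meta_path}"]
    metadata = pd.read_csv(meta_path)
    for col in ("subject_id", "group"):
        if col not in metadata.columns:
            violations.append(f"metadata missing column '{col}'")
    if "group" in metadata.columns:
        counts = metadata["group"].value_counts()
        for grp in ("patient", "control"):
            if counts.get(grp, 0) < 2:
                violations.append(f"group '{grp}' has fewer than 2 subjects")
    lab_path = src / "labels.csv"
    n_components = None
    if not lab_path.exists():
        violations.append(f"missing label map: {lab_path}")
    else:
        lab = pd.read_csv(lab_path)
        n_components = len(lab)
        unknown = set(lab["network"]) - {"DMN", "SN", "CEN"}
        if unknown:
            violations.append(f"unknown network labels: {sorted(unknown)}")
    shapes = set()
    for sid in metadata.get("subject_id", []):
        f = src / "timecourses" / f"{sid}_timecourses.tsv"
        if not f.exists():
            violations.append(f"missing time-course file for subject {sid}: {f.name}")
            continue
        df = pd.read_csv(f, sep="\t")
        arr = df.to_numpy(float)
        if not np.all(np.isfinite(arr)):
            violations.append(f"non-finite values in {f.name}")
        shapes.add(arr.shape)
        if n_components is not None and arr.shape[1] != n_components:
            violations.append(
                f"component count mismatch in {f.name}: {arr.shape[1]} vs {n_components} labels"
            )
    if len(shapes) > 1:
        violations.append(f"inconsistent time-course shapes across subjects: {sorted(shapes)}")
    return violations
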