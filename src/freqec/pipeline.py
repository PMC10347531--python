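"""End-to-end orchestration: synthesize/ingest -> prep -> decompose -> band EC
-> group statistics -> classification.

The pipeline is driven by a `PipelineConfig` (loadable from YAML), writes every
stage's outputs plus a manifest under the output directory, derives all stage
seeds deterministically from one global seed, and caches per-subject
decompositions keyed by a content hash so reruns with an identical
configuration reproduce identical result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import CVConfig, combine_band_features, ec_feature_table, nested_cv
from .connectivity import conditional_gc, ec_long_frame, fit_var, select_order, subject_significance
from .decompose import FOIBand, FOIBandSet, build_hwf_table, ceemdan, derive_fois, extract_band_signal
from .groupstats import run_group_analysis
from .io import load_cohort, validate_inputs, write_cohort
from .preprocess import postprocess
from .synthetic import CohortSpec, CouplingEdge, TimeCourseSet, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("synthesize", "prep", "decompose", "connectivity", "groupstats", "classify")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "STAGES"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stage seed = low 31 bits of sha256("<global_seed>:<stage>")."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    out_dir: str = "freqec_out"
    seed: int = 0
    # either a synthesis block or an input cohort directory
    input_dir: str | None = None
    synthesis: dict = field(default_factory=dict)
    # decomposition
    ensemble_size: int = 100
    ceemdan_noise_sd: float = 0.2
    max_imfs: int = 5
    foi_ci_level: float = 0.95
    fixed_bands: list | None = None  # [[name, low, high], ...] skips CEEMDAN/FOI stage
    band_mode: str = "imf"  # 'imf' or 'filter'
    # postprocessing
    detrend_order: int = 3
    despike_z: float = 4.0
    lowpass_cutoff: float = 0.15
    # VAR / GC
    p_max: int = 5
    edge_alpha: float = 0.05
    # group inference
    n_perm: int = 10000
    q: float = 0.05
    # classification
    cv: dict = field(default_factory=dict)
    classify_bands: list | None = None  # bands to classify on; None = all + combined
    run_classification: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _spec_from_config(config: PipelineConfig) -> CohortSpec:
    syn = dict(config.synthesis)
    edges = [CouplingEdge(**e) for e in syn.pop("coupling_edges", [])]
    if "network_labels" in syn:
        syn["network_labels"] = {int(k): v for k, v in syn["network_labels"].items()}
    if "bands" in syn:
        syn["bands"] = tuple(tuple(b) for b in syn["bands"])
    if "symptom_edge" in syn and syn["symptom_edge"] is not None:
        syn["symptom_edge"] = tuple(syn["symptom_edge"])
    syn.setdefault("seed", stage_seed(config.seed, "synthesize"))
    return CohortSpec(coupling_edges=tuple(edges), **syn)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in order; returns the manifest dict.

    Partial results are preserved on stage failure and the manifest marks the
    failure point. Decompositions are cached under ``out_dir/cache`` keyed by
    a content hash of the subject data and decomposition settings.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in stages:
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, out, state)
            manifest["stages"][stage] = {
                "status": "completed",
                "seconds": round(time.perf_counter() - t0, 3),
            }
        except Exception as exc:  # preserve partial results, mark failure
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            logger.exception("stage %s failed", stage)
            break
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=_json_default)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _ensure_cohort(config: PipelineConfig, out: Path, state: dict) -> None:
    if "tcs" in state:
        return
    src = out / "cohort" if config.input_dir is None else Path(config.input_dir)
    state["metadata"], state["tcs"], state["labels"] = load_cohort(src)


def _stage_synthesize(config: PipelineConfig, out: Path, state: dict) -> None:
    if config.input_dir is not None:
        violations = validate_inputs(config.input_dir)
        report = out / "validation_report.json"
        with open(report, "w") as fh:
            json.dump({"violations": violations}, fh, indent=1)
        if violations:
            raise ValueError(f"input validation failed; see {report}")
        state["metadata"], state["tcs"], state["labels"] = load_cohort(config.input_dir)
        return
    spec = _spec_from_config(config)
    metadata, tcs, truth = generate_cohort(spec)
    write_cohort(out / "cohort", metadata, tcs, spec.network_labels, truth, spec)
    state.update(metadata=metadata, tcs=tcs, labels=spec.network_labels, spec=spec)


def _stage_prep(config: PipelineConfig, out: Path, state: dict) -> None:
    _ensure_cohort(config, out, state)
    tcs: TimeCourseSet = state["tcs"]
    clean = np.empty_like(tcs.data)
    logs = {}
    for s, sid in enumerate(tcs.subject_ids):
        spikes = 0
        for c in range(tcs.data.shape[1]):
            clean[s, c], log = postprocess(
                tcs.data[s, c],
                tcs.sampling_interval,
                detrend_order=config.detrend_order,
                despike_z=config.despike_z,
                lowpass_cutoff=None,  # band stages apply their own limits
            )
            spikes += log["n_spikes_replaced"]
        logs[sid] = {"n_spikes_replaced": spikes}
    state["clean"] = TimeCourseSet(clean, tcs.sampling_interval, tcs.subject_ids)
    with open(out / "prep_log.json", "w") as fh:
        json.dump(logs, fh, indent=1)


def _decomp_key(config: PipelineConfig, data: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(data.tobytes())
    h.update(
        f"{config.ensemble_size}:{config.ceemdan_noise_sd}:{config.max_imfs}".encode()
    )
    return h.hexdigest()[:24]


def _stage_decompose(config: PipelineConfig, out: Path, state: dict) -> None:
    if config.fixed_bands is not None:
        bands = [FOIBand(low=float(b[1]), high=float(b[2]), name=str(b[0])) for b in config.fixed_bands]
        state["bandset"] = FOIBandSet(bands=[b for b in bands if b.name != "FOI-N"])
        state["imfsets"] = None
        state["bandset"].to_frame().to_csv(out / "foi_bands.csv", index=False)
        return
    _ensure_cohort(config, out, state)
    clean: TimeCourseSet = state.get("clean") or state["tcs"]
    cache_dir = out / "cache"
    cache_dir.mkdir(exist_ok=True)
    seed = stage_seed(config.seed, "decompose")
    imfsets = {}
    for s, sid in enumerate(clean.subject_ids):
        for c in range(clean.data.shape[1]):
            sig = clean.data[s, c]
            key = _decomp_key(config, sig)
            cache_file = cache_dir / f"{key}.npz"
            if cache_file.exists():
                z = np.load(cache_file)
                from .decompose import IMFSet

                imfset = IMFSet(
                    imfs=[z[f"imf{i}"] for i in range(int(z["n_imfs"]))],
                    residue=z["residue"],
                    source_length=len(sig),
                )
            else:
                imfset = ceemdan(
                    sig,
                    ensemble_size=config.ensemble_size,
                    noise_sd=config.ceemdan_noise_sd,
                    max_imfs=config.max_imfs,
                    seed=seed,
                )
                np.savez(
                    cache_file,
                    n_imfs=len(imfset.imfs),
                    residue=imfset.residue,
                    **{f"imf{i}": imf for i, imf in enumerate(imfset.imfs)},
                )
            imfsets[(sid, f"C{c:02d}")] = imfset
    hwf = build_hwf_table(imfsets, clean.sampling_interval)
    hwf.to_csv(out / "hwf_table.csv", index=False)
    bandset = derive_fois(hwf, ci_level=config.foi_ci_level, max_order=config.max_imfs)
    bandset.to_frame().to_csv(out / "foi_bands.csv", index=False)
    state["imfsets"] = imfsets
    state["bandset"] = bandset


def _stage_connectivity(config: PipelineConfig, out: Path, state: dict) -> None:
    _ensure_cohort(config, out, state)
    clean: TimeCourseSet = state.get("clean") or state["tcs"]
    bandset: FOIBandSet = state["bandset"]
    imfsets = state.get("imfsets")
    dt = clean.sampling_interval
    n_subj, n, _ = clean.data.shape
    ec_by_band: dict[str, np.ndarray] = {}
    all_ecs = []
    for band in bandset.all_bands():
        stack = np.empty((n_subj, n, n))
        for s, sid in enumerate(clean.subject_ids):
            sigs = np.empty_like(clean.data[s])
            for c in range(n):
                raw = clean.data[s, c]
                if band.name == "FOI-N" and config.lowpass_cutoff:
                    from .preprocess import lowpass

                    raw = lowpass(raw, config.lowpass_cutoff, dt)
                imfset = imfsets.get((sid, f"C{c:02d}")) if imfsets else None
                sigs[c] = extract_band_signal(raw, imfset, band, dt, mode=config.band_mode)
            sd = sigs.std(axis=1)
            if np.any(sd < 1e-12):  # a band can be empty for some components
                sigs[sd < 1e-12] += 1e-6 * np.random.default_rng(0).standard_normal(sigs.shape[1])
            p = select_order(sigs, config.p_max)
            ec = conditional_gc(sigs, p, band_id=band.name, subject_id=sid)
            model = fit_var((sigs - sigs.mean(1, keepdims=True)) / sigs.std(1, keepdims=True), p)
            ec = subject_significance(ec, model, alpha=config.edge_alpha)
            stack[s] = np.nan_to_num(ec.values)
            all_ecs.append(ec)
        ec_by_band[band.name] = stack
    state["ec_by_band"] = ec_by_band
    ec_long_frame(all_ecs).to_csv(out / "ec_long.csv", index=False)


def _stage_groupstats(config: PipelineConfig, out: Path, state: dict) -> None:
    result = run_group_analysis(
        state["ec_by_band"],
        state["metadata"],
        state["labels"],
        q=config.q,
        n_perm=config.n_perm,
        seed=stage_seed(config.seed, "groupstats"),
    )
    tidy = pd.concat([result.edges, result.blocks], ignore_index=True)
    tidy.to_csv(out / "group_results.csv", index=False)
    result.correlations.to_csv(out / "symptom_correlations.csv", index=False)
    with open(out / "group_summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=1, default=_json_default)
    state["group_result"] = result


def _stage_classify(config: PipelineConfig, out: Path, state: dict) -> None:
    if not config.run_classification:
        return
    metadata = state["metadata"]
    labels01 = (metadata["group"] == "patient").astype(int).to_numpy()
    sids = metadata["subject_id"].tolist()
    ec_by_band = state["ec_by_band"]
    band_names = config.classify_bands or list(ec_by_band)
    tables = {
        b: ec_feature_table(ec_by_band[b], b, labels01, sids) for b in band_names
    }
    cv_config = CVConfig(**config.cv) if config.cv else CVConfig()
    seed = stage_seed(config.seed, "classify")
    results = {}
    for b, table in tables.items():
        results[b] = nested_cv(table, cv_config, seed=seed)
    if len(tables) > 1:
        combined = combine_band_features(list(tables.values()))
        results["combined"] = nested_cv(combined, cv_config, seed=seed)
    summary = {b: r.metrics() for b, r in results.items()}
    with open(out / "classification_metrics.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=_json_default)
    rows = []
    for b, r in results.items():
        fpr, tpr = r.roc_points
        rows.append(pd.DataFrame({"band": b, "fpr": fpr, "tpr": tpr}))
    pd.concat(rows, ignore_index=True).to_csv(out / "roc_points.csv", index=False)
    top = pd.concat(
        [r.top_features(10).assign(condition=b) for b, r in results.items()],
        ignore_index=True,
    )
    top.to_csv(out / "top_features.csv", index=False)
    state["cv_results"] = results


_STAGE_FUNCS = {
    "synthesize": _stage_synthesize,
    "prep": _stage_prep,
    "decompose": _stage_decompose,
    "connectivity": _stage_connectivity,
    "groupstats": _stage_groupstats,
    "classify": _stage_classify,
}
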