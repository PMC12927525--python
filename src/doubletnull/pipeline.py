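"""End-to-end pipeline: QC -> normalize -> HVG -> doublet null -> markers.

``PipelineConfig`` collects every stage's parameters (loadable from YAML,
unknown keys rejected); :func:`run_pipeline` executes the stages in order,
writes each stage's artifact into the output directory, and returns the
combined report.  A single master seed deterministically derives the
per-stage seeds, so a config re-run reproduces the report byte for byte
(timestamps aside).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import os
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from .features import select_hvg
from .io import read_10x, read_labels
from .markers import DEConfig, NegativeBinomialMarkers
from .nulltest import HybridDoubletTest
from .preprocess import QCThresholds, normalize_log10k, qc_filter

__all__ = ["PipelineConfig", "run_pipeline", "stage_seeds"]


def _pkg_version() -> str:
    try:
        return version("doubletnull")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class PipelineConfig:
    matrix_dir: str
    parent_a: str
    parent_b: str
    query: str
    labels_file: str | None = None
    output_dir: str = "doubletnull_out"
    qc: QCThresholds = field(default_factory=QCThresholds)
    n_hvg: int = 2000
    n_pairs: int = 5000
    n_negative: int = 5000
    de: DEConfig = field(default_factory=DEConfig)
    seed: int = 0
    mito_prefix: str = "mt-"

    def validate(self) -> None:
        self.qc.validate()
        self.de.validate()
        if self.n_hvg < 1 or self.n_pairs < 1 or self.n_negative < 1:
            raise ValueError("n_hvg, n_pairs and n_negative must be positive")
        if len({self.parent_a, self.parent_b, self.query}) != 3:
            raise ValueError("parent_a, parent_b and query must be three distinct clusters")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in (("qc", QCThresholds), ("de", DEConfig)):
            if key in raw and isinstance(raw[key], dict):
                sub_known = {f.name for f in dataclasses.fields(sub)}
                sub_unknown = set(raw[key]) - sub_known
                if sub_unknown:
                    raise ValueError(f"unknown config keys under {key!r}: {sorted(sub_unknown)}")
                raw[key] = sub(**raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def stage_seeds(master: int) -> dict[str, int]:
    """Derive independent per-stage seeds from one master seed."""
    ss = np.random.SeedSequence(master)
    children = ss.spawn(2)
    names = ("doublet_sim", "reserved")
    return {n: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig, counts: ad.AnnData | None = None) -> dict:
    """Run every stage and write all artifacts under ``config.output_dir``.

    ``counts`` may be passed directly (tests, notebooks); otherwise the 10x
    triplet in ``config.matrix_dir`` is read.  Returns the pipeline report
    (also written as ``pipeline_report.json``).
    """
    config.validate()
    t_start = datetime.datetime.now().isoformat(timespec="seconds")
    if counts is None:
        counts, labels = read_10x(config.matrix_dir, mito_prefix=config.mito_prefix)
        if config.labels_file is not None:
            labels = read_labels(config.labels_file).reindex(counts.obs_names)
            counts.obs["cluster"] = labels.to_numpy()
    if "cluster" not in counts.obs:
        raise ValueError("no cluster labels: provide clusters.tsv or labels_file")
    labels = counts.obs["cluster"].astype(str)
    for lab in (config.parent_a, config.parent_b, config.query):
        if lab not in set(labels):
            raise ValueError(f"cluster {lab!r} not present in the label table")

    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    seeds = stage_seeds(config.seed)

    filtered, qc_report = qc_filter(counts, config.qc)
    qc_report.to_csv(os.path.join(out, "qc_report.tsv"), sep="\t", index=False)
    labels = filtered.obs["cluster"].astype(str)
    for lab in (config.parent_a, config.parent_b, config.query):
        if lab not in set(labels):
            raise ValueError(f"cluster {lab!r} has no cells left after QC")

    norm = normalize_log10k(filtered)
    hvg = select_hvg(filtered, n_hvg=config.n_hvg)
    hvg.to_frame().to_csv(os.path.join(out, "hvg.tsv"), sep="\t", index=False)

    model = HybridDoubletTest(
        norm,
        config.parent_a,
        config.parent_b,
        config.query,
        labels=labels,
        hvg=hvg,
        n_pairs=config.n_pairs,
        n_negative=config.n_negative,
    )
    res = model.fit(seed=seeds["doublet_sim"])
    res.distance_report.to_csv(os.path.join(out, "distance_report.tsv"), sep="\t")
    with open(os.path.join(out, "verdict.json"), "w") as fh:
        json.dump(res.verdict_.to_dict(), fh, indent=1)

    de_model = NegativeBinomialMarkers(filtered, labels, config.de)
    de_results = {}
    for lab in (config.query, config.parent_a, config.parent_b):
        r = de_model.fit(lab)
        r.table.to_csv(os.path.join(out, f"de_{lab}.tsv"), sep="\t")
        de_results[lab] = r
    sharing = de_model.sharing(config.query, config.parent_a, config.parent_b)
    with open(os.path.join(out, "marker_sharing.json"), "w") as fh:
        json.dump(sharing.to_dict(), fh, indent=1)

    report = {
        "software": {"package": "doubletnull", "version": _pkg_version()},
        "config": config.to_dict(),
        "timestamps": {"start": t_start, "end": datetime.datetime.now().isoformat(timespec="seconds")},
        "stage_seeds": seeds,
        "qc": {
            "n_cells_in": int(len(qc_report)),
            "n_cells_kept": int(qc_report["kept"].sum()),
            "n_removed_low_features": int(qc_report["reason"].str.contains("low_features").sum()),
            "n_removed_high_features": int(qc_report["reason"].str.contains("high_features").sum()),
            "n_removed_high_mito": int(qc_report["reason"].str.contains("high_mito").sum()),
        },
        "hvg": {"n_requested": config.n_hvg, "n_selected": len(hvg.genes)},
        "distance_report": res.distance_report.to_dict(orient="index"),
        "verdict": res.verdict_.to_dict(),
        "marker_sharing": sharing.to_dict(),
        "n_markers": {lab: int(len(r.markers)) for lab, r in de_results.items()},
    }
    with open(os.path.join(out, "pipeline_report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
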