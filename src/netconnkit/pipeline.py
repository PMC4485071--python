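"""Configuration-driven pipeline: preprocess -> connectivity -> graphs -> metrics.

A YAML config lists subjects (time-series text files), the preprocessing
steps to apply in order, the member/threshold/network-type choices and the
outputs to produce. Per-subject work can run on several processes; results
are reduced in subject order so parallel output is byte-identical to a
serial run. Every run writes a sidecar metadata file recording the config
hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .connectivity import ConnectivityMatrix, fisher_group_mean, pearson_matrix
from .exceptions import NetconnkitError
from .graphs import ThresholdSpec, graph_series, select_members
from .metrics import GLOBAL_METRIC_NAMES, auc, global_metrics
from .preprocess import (
    BoldTimeSeries,
    ConfoundSet,
    detrend,
    ideal_bandpass,
    regress_confounds,
    remove_volumes,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(NetconnkitError):
    """A pipeline step failed; the message names the step and subject."""


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    subjects: tuple[tuple[str, str], ...]  # (subject id, time-series path)
    dt: float
    out_dir: str
    seed: int = 0
    preprocess_steps: tuple[tuple[str, dict], ...] = ()
    member: str = "positive"
    threshold: ThresholdSpec = field(
        default_factory=lambda: ThresholdSpec.default_grid("sparsity")
    )
    network_types: tuple[str, ...] = ("binary",)
    n_jobs: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        base = base_dir or Path(".")
        subjects = tuple(
            (str(s["id"]), str(base / s["timeseries"]))
            for s in raw.get("subjects", [])
        )
        for sid, tspath in subjects:
            if not Path(tspath).exists():
                raise PipelineError(f"subject {sid}: missing time series {tspath}")
        steps = []
        for step in raw.get("preprocess", []):
            if isinstance(step, str):
                steps.append((step, {}))
            else:
                ((name, params),) = step.items()
                steps.append((name, dict(params or {})))
        thr = raw.get("threshold", {})
        if "values" in thr:
            spec = ThresholdSpec(thr.get("method", "sparsity"), tuple(thr["values"]))
        elif thr:
            grid = np.round(
                np.arange(thr["start"], thr["stop"] + 1e-9, thr["step"]), 10
            )
            spec = ThresholdSpec(thr.get("method", "sparsity"), tuple(grid))
        else:
            spec = ThresholdSpec.default_grid("sparsity")
        ntype = raw.get("network_type", "binary")
        types = ("binary", "weighted") if ntype == "both" else (ntype,)
        return cls(
            subjects=subjects,
            dt=float(raw.get("dt", 2.0)),
            out_dir=str(base / raw.get("out_dir", "netconnkit_out")),
            seed=int(raw.get("seed", 0)),
            preprocess_steps=tuple(steps),
            member=raw.get("member", "positive"),
            threshold=spec,
            network_types=types,
            n_jobs=int(raw.get("n_jobs", 1)),
        )

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "subjects": self.subjects,
                "dt": self.dt,
                "seed": self.seed,
                "preprocess": self.preprocess_steps,
                "member": self.member,
                "threshold": [self.threshold.method, self.threshold.values],
                "network_types": self.network_types,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_STEP_FUNCS = {
    "remove_volumes": remove_volumes,
    "detrend": detrend,
    "bandpass": ideal_bandpass,
}


def _apply_steps(
    ts: BoldTimeSeries, steps: tuple[tuple[str, dict], ...], subject: str
) -> BoldTimeSeries:
    for name, params in steps:
        try:
            if name in _STEP_FUNCS:
                ts = _STEP_FUNCS[name](ts, **params)
            elif name == "regress":
                conf_path = params.get("confounds")
                conf = (
                    ConfoundSet(np.loadtxt(conf_path, ndmin=2))
                    if conf_path
                    else ConfoundSet(np.empty((ts.n_timepoints, 0)))
                )
                ts = regress_confounds(ts, conf)
            else:
                raise ValueError(f"unknown preprocessing step {name!r}")
        except Exception as exc:
            raise PipelineError(f"step {name!r} failed for subject {subject}: {exc}") from exc
    return ts


def _process_subject(args: tuple[str, str, float, tuple]) -> tuple[str, np.ndarray]:
    sid, path, dt, steps = args
    ts = nio.read_timeseries(path, dt)
    ts = _apply_steps(ts, steps, sid)
    try:
        return sid, pearson_matrix(ts).r
    except Exception as exc:
        raise PipelineError(f"connectivity failed for subject {sid}: {exc}") from exc


def run_pipeline(cfg: PipelineConfig) -> int:
    """Execute the configured pipeline; returns 0 on success.

    Artifacts under ``cfg.out_dir``: per-subject connectivity matrices, the
    Fisher-averaged group matrix, per-network-type global-metric tables
    (rows = thresholds, columns = metrics) with an AUC row, and a
    ``run_metadata.json`` sidecar with the config hash and seed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tasks = [(sid, path, cfg.dt, cfg.preprocess_steps) for sid, path in cfg.subjects]
    if cfg.n_jobs > 1 and len(tasks) > 1:
        with ProcessPoolExecutor(max_workers=cfg.n_jobs) as pool:
            results = list(pool.map(_process_subject, tasks))
    else:
        results = [_process_subject(t) for t in tasks]

    subject_mats = []
    for sid, r in results:  # map() preserves submission order: deterministic
        mat = ConnectivityMatrix(r)
        nio.write_matrix(mat, out / f"{sid}_connectivity.txt")
        subject_mats.append(mat)

    if subject_mats:
        group = fisher_group_mean(subject_mats)
        nio.write_matrix(group, out / "group_connectivity.txt")
        selected = select_members(group, cfg.member)
        for kind in cfg.network_types:
            graphs = graph_series(selected, cfg.threshold, kind)
            rows = []
            for thr, g in zip(cfg.threshold.values, graphs):
                if g.n_edges == 0:
                    rows.append([thr] + [np.nan] * len(GLOBAL_METRIC_NAMES))
                    continue
                gm = global_metrics(g).as_dict()
                rows.append([thr] + [gm[name] for name in GLOBAL_METRIC_NAMES])
            table = pd.DataFrame(rows, columns=["threshold", *GLOBAL_METRIC_NAMES])
            auc_row: dict[str, float] = {"threshold": np.nan}
            x = table["threshold"].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for name in GLOBAL_METRIC_NAMES:
                    y = table[name].to_numpy()
                    auc_row[name] = auc(x, y) if np.isfinite(y).sum() >= 2 else np.nan
            table = pd.concat([table, pd.DataFrame([auc_row])], ignore_index=True)
            table.insert(0, "row", [f"thr_{t:g}" for t in cfg.threshold.values] + ["auc"])
            table.to_csv(out / f"global_metrics_{kind}.tsv", sep="\t", index=False)

    meta = {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "n_subjects": len(cfg.subjects),
        "member": cfg.member,
        "threshold_method": cfg.threshold.method,
        "network_types": list(cfg.network_types),
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return 0
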