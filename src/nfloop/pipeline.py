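"""End-to-end orchestration of the synthetic neurofeedback experiment.

One config drives simulate -> feedback -> metrics -> connectivity -> glm;
every stage writes its artifacts plus a JSON provenance sidecar (config
hash, seeds, package version), and the whole pipeline is a pure function of
(config, master seed): re-running reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import DenoiseConfig, denoise, seed_map
from .design import AcquisitionSpec, make_training_design
from .glm import first_level, second_level
from .metrics import learning_slope, run_table, session_delta, upregulation_test
from .realtime import FeedbackConfig, run_feedback_session, write_trace
from .simulate import FEEDBACK_ROIS, SubjectParams, simulate_network_run, write_dataset
from .stats import compare_groups

logger = logging.getLogger(__name__)

DEFAULT_GROUP_GAINS = {"AG": 0.28, "CG1": 0.20, "CG2sham": 0.0}


def stable_seed(*parts) -> int:
    """Deterministic sub-seed below 2^31 from arbitrary hashable parts."""
    digest = hashlib.sha256(":".join(map(str, parts)).encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class ExperimentConfig:
    """Validated experiment description (see ``from_dict`` for the schema)."""

    acquisition: AcquisitionSpec
    roster: dict  # subject id -> group label
    group_params: dict  # group label -> SubjectParams kwargs overrides
    sessions: int = 2
    runs_per_session: int = 4
    drops: list = field(default_factory=list)  # (subject, session, run) triples
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "feedback": True, "metrics": True,
        "connectivity": True, "glm": False,
    })
    network_labels: tuple = ()
    network_correlation: np.ndarray | None = None
    connectivity_seeds: tuple = ("left_FG", "right_FG")
    glm_grid: tuple = (10, 10, 6)
    glm_active_box: tuple = ((3, 3, 2), (6, 6, 4))  # lo, hi corners
    glm_amplitude_pct: float = 2.0
    master_seed: int = 0
    out_dir: Path = Path("nfloop_out")

    def __post_init__(self) -> None:
        if len(set(self.roster)) != len(self.roster):
            raise ValueError("subject ids must be unique")
        for sub, grp in self.roster.items():
            if grp not in self.group_params:
                raise ValueError(f"subject {sub}: no parameters for group {grp!r}")
        overlap = set(self.network_labels) & set(FEEDBACK_ROIS)
        if overlap:
            raise ValueError(f"network_labels must not repeat feedback ROIs: {overlap}")
        if self.network_correlation is not None:
            n = len(self.network_labels)
            if np.asarray(self.network_correlation).shape != (n, n):
                raise ValueError("network_correlation shape must match network_labels")
            for s in self.connectivity_seeds:
                if s not in self.network_labels:
                    raise ValueError(f"connectivity seed {s!r} not a network label")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        acq = AcquisitionSpec(**d.get("acquisition", {}))
        roster, group_params = {}, {}
        for grp, spec in d["groups"].items():
            group_params[grp] = dict(spec.get("params", {}))
            group_params[grp].setdefault(
                "regulation_gain",
                {"roi1_left": DEFAULT_GROUP_GAINS.get(grp, 0.0),
                 "roi1_right": DEFAULT_GROUP_GAINS.get(grp, 0.0),
                 "roi2": 0.0},
            )
            subjects = spec.get("subjects") or [
                f"sub-{grp}{i + 1:02d}" for i in range(int(spec.get("n", 0)))
            ]
            if not subjects:
                raise ValueError(f"group {grp!r}: give 'subjects' or a positive 'n'")
            for sub in subjects:
                if sub in roster:
                    raise ValueError(f"duplicate subject id {sub!r}")
                roster[sub] = grp
        net = d.get("network", {})
        corr = np.asarray(net["correlation"], float) if "correlation" in net else None
        kwargs = dict(
            acquisition=acq, roster=roster, group_params=group_params,
            sessions=int(d.get("sessions", 2)),
            runs_per_session=int(d.get("runs_per_session", 4)),
            drops=[tuple(t) for t in d.get("drops", [])],
            network_labels=tuple(net.get("labels", ())),
            network_correlation=corr,
            master_seed=int(d.get("master_seed", 0)),
            out_dir=Path(d.get("out_dir", "nfloop_out")),
        )
        if "stages" in d:
            kwargs["stages"] = {**cls.__dataclass_fields__["stages"].default_factory(),
                                **d["stages"]}
        if "connectivity_seeds" in d:
            kwargs["connectivity_seeds"] = tuple(d["connectivity_seeds"])
        for key in ("glm_grid", "glm_active_box", "glm_amplitude_pct"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def subject_params(self, subject: str) -> SubjectParams:
        grp = self.roster[subject]
        kwargs = dict(self.group_params[grp])
        labels = tuple(FEEDBACK_ROIS) + tuple(
            l for l in self.network_labels if l not in FEEDBACK_ROIS
        )
        corr = np.eye(len(labels))
        if self.network_correlation is not None:
            offset = len(labels) - len(self.network_labels)
            corr[offset:, offset:] = self.network_correlation
        return SubjectParams(
            group=grp, network_labels=labels, network_correlation=corr,
            seed=stable_seed(self.master_seed, subject), **kwargs,
        )


def _provenance(cfg: ExperimentConfig, stage: str, extra: dict | None = None) -> dict:
    return {
        "stage": stage, "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed, "nfloop_version": __version__,
        **(extra or {}),
    }


def _write_sidecar(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=str))


def run_pipeline(cfg: ExperimentConfig) -> dict:
    """Execute the enabled stages in order and return the report bundle.

    Returns a dict with the per-stage in-memory products (dataset, traces,
    run table, test results, connectivity maps, GLM map) plus the rendered
    markdown report; artifacts and provenance sidecars land under
    ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict = {"config": cfg}
    design = make_training_design(cfg.acquisition)
    t0 = time.time()

    if cfg.stages.get("simulate", True):
        dataset = {}
        for sub in cfg.roster:
            params = cfg.subject_params(sub)
            runs = []
            for ses in range(1, cfg.sessions + 1):
                for run in range(1, cfg.runs_per_session + 1):
                    if (sub, ses, run) in cfg.drops:
                        logger.warning("dropping %s ses-%d run-%d per config", sub, ses, run)
                        continue
                    series = simulate_network_run(
                        design, params,
                        seed=stable_seed(cfg.master_seed, sub, ses, run),
                        subject=sub, session=ses, run=run,
                    )
                    runs.append({"session": ses, "run": run, "series": series})
            dataset[sub] = {"params": params, "acquisition": cfg.acquisition, "runs": runs}
        write_dataset(dataset, out / "dataset")
        _write_sidecar(out / "dataset" / "provenance.json", _provenance(cfg, "simulate"))
        outputs["dataset"] = dataset

    if cfg.stages.get("feedback", True):
        dataset = outputs["dataset"]
        traces = {}
        trace_dir = out / "feedback"
        trace_dir.mkdir(exist_ok=True)
        for sub, entry in dataset.items():
            mode = "sham" if cfg.roster[sub] == "CG2sham" else "contingent"
            for rec in entry["runs"]:
                feedback_rois = {r: rec["series"][r] for r in FEEDBACK_ROIS}
                trace = run_feedback_session(
                    feedback_rois, design, mode=mode, config=FeedbackConfig(),
                    seed=stable_seed(cfg.master_seed, "sham", sub,
                                     rec["session"], rec["run"]),
                )
                traces[(sub, rec["session"], rec["run"])] = trace
                write_trace(trace, trace_dir / f"{sub}_ses-{rec['session']}"
                                               f"_run-{rec['run']}_trace.tsv")
        _write_sidecar(trace_dir / "provenance.json",
                       _provenance(cfg, "feedback", {"n_traces": len(traces)}))
        outputs["traces"] = traces

    if cfg.stages.get("metrics", True):
        table = run_table(outputs["dataset"])
        table.to_csv(out / "run_table.tsv", sep="\t", index=False, float_format="%.17g")
        tests = {}
        for grp, g in table.groupby("group"):
            for side in ("r_left", "r_right"):
                per_subject = g.groupby("subject")[side].mean()
                tests[(grp, side, "vs_zero")] = upregulation_test(per_subject.to_numpy())
                run_means = g.groupby("run")[side].mean()
                if len(run_means) >= 3:
                    tests[(grp, side, "learning_slope")] = learning_slope(
                        run_means.to_numpy())
        for side in ("r_left", "r_right", "sd_left", "sd_right"):
            by_group = {grp: g[side].to_numpy() for grp, g in table.groupby("group")}
            if len(by_group) >= 2:
                tests[("all", side, "group_compare")] = compare_groups(by_group)
        deltas = session_delta(table)
        if not deltas.empty:
            deltas.to_csv(out / "session_deltas.tsv", sep="\t", index=False,
                          float_format="%.17g")
        _write_sidecar(out / "metrics_provenance.json", _provenance(cfg, "metrics"))
        outputs["run_table"] = table
        outputs["tests"] = tests
        outputs["session_deltas"] = deltas

    if cfg.stages.get("connectivity", True) and cfg.network_labels:
        maps = {}
        tr = cfg.acquisition.tr
        rows = []
        for sub, entry in outputs["dataset"].items():
            cleaned_runs = []
            for rec in entry["runs"]:
                labels = [l for l in rec["series"] if l in cfg.network_labels]
                mat = np.column_stack([rec["series"][l].values for l in labels])
                clean = denoise(mat, tr, config=DenoiseConfig())
                cleaned_runs.append({l: clean[:, j] for j, l in enumerate(labels)})
            for seed_label in cfg.connectivity_seeds:
                m = seed_map(cleaned_runs, seed_label, design)
                maps[(sub, seed_label)] = m
                for _, r in m.table.iterrows():
                    rows.append({"subject": sub, "group": cfg.roster[sub],
                                 "seed": seed_label, **r.to_dict()})
        conn_table = pd.DataFrame(rows)
        conn_table.to_csv(out / "connectivity.tsv", sep="\t", index=False,
                          float_format="%.17g")
        _write_sidecar(out / "connectivity_provenance.json",
                       _provenance(cfg, "connectivity"))
        outputs["connectivity"] = maps
        outputs["connectivity_table"] = conn_table

    if cfg.stages.get("glm", False):
        grid = tuple(cfg.glm_grid)
        lo, hi = cfg.glm_active_box
        subject_maps = []
        rng_labels = sorted(cfg.roster)
        from .simulate import simulate_localizer_volume  # same volume machinery

        acq_small = AcquisitionSpec(
            tr=cfg.acquisition.tr, n_dummy=cfg.acquisition.n_dummy,
            n_scans_total=cfg.acquisition.n_scans_total, grid_shape=grid,
            voxel_size=cfg.acquisition.voxel_size,
        )
        active = [(i, j, k)
                  for i in range(lo[0], hi[0])
                  for j in range(lo[1], hi[1])
                  for k in range(lo[2], hi[2])]
        for s_i, sub in enumerate(rng_labels):
            vol, _ = simulate_localizer_volume(
                design, acq_small, active,
                seed=stable_seed(cfg.master_seed, "glm", sub),
                amplitude_pct=cfg.glm_amplitude_pct, condition="regulate",
            )
            subject_maps.append(first_level(vol, design))
        group_map = second_level(subject_maps)
        _write_sidecar(out / "glm_provenance.json",
                       _provenance(cfg, "glm", group_map.provenance))
        outputs["glm"] = group_map

    outputs["report"] = make_report(outputs)
    (out / "report.md").write_text(outputs["report"])
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return outputs


def _fmt_test(t) -> str:
    return (f"{t.name}: stat={t.statistic:.3g}, p={t.p:.4g}, n={t.n}, "
            f"method={t.method or 'n/a'}")


def make_report(outputs: dict) -> str:
    """Human-readable markdown summary of whatever stages actually ran."""
    cfg: ExperimentConfig = outputs["config"]
    lines = [
        "# Neurofeedback pipeline report",
        f"config hash: `{cfg.config_hash()}`  |  master seed: {cfg.master_seed}",
        "",
    ]
    if "run_table" in outputs:
        table = outputs["run_table"]
        lines.append("## Up-regulation (r_FFA, percent)")
        summary = table.groupby("group")[["r_left", "r_right"]].agg(["mean", "std"])
        lines.append(summary.round(4).to_string())
        lines.append("")
        for key, t in outputs.get("tests", {}).items():
            lines.append(f"- {'/'.join(map(str, key))}: {_fmt_test(t)}")
        lines.append("")
    else:
        lines.append("## Up-regulation: stage skipped\n")
    if "connectivity_table" in outputs:
        ct = outputs["connectivity_table"]
        lines.append("## Connectivity")
        counts = ct[ct["selected"]].groupby(["group", "seed"]).size()
        lines.append("selected edges per group/seed:")
        lines.append(counts.to_string() if len(counts) else "(none selected)")
        lines.append("")
    else:
        lines.append("## Connectivity: stage skipped\n")
    if "glm" in outputs:
        g = outputs["glm"]
        lines.append("## Group GLM (Regulation > Rest)")
        lines.append(f"surviving clusters (voxel p<{g.provenance['voxel_p']}, "
                     f"K={g.provenance['k']}):")
        lines.append(g.cluster_table.to_string(index=False)
                     if g.cluster_table is not None and len(g.cluster_table)
                     else "(none)")
        lines.append("")
    else:
        lines.append("## Group GLM: stage skipped\n")
    return "\n".join(lines)
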