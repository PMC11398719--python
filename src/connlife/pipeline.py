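"""End-to-end study orchestration: simulate/load -> QC -> metrics ->
PLS -> rolling correlations -> regressions -> consolidated report.

Every stochastic stage draws its seed from the run seed through a
``numpy.random.SeedSequence`` spawn tree, and the config (plus its hash)
is embedded in every output, so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import metrics as cmetrics
from . import pls as cpls
from . import stats as cstats
from . import synthetic as csynth

log = logging.getLogger("connlife")

STAGES = ("qc", "metrics", "pls", "rolling", "regress")

PLS_MODES = ("edges", "nodal", "local")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``fixture_dir`` selects on-disk data; when it is None a synthetic
    study is generated from ``synthetic_spec`` (defaulting to the
    package's standard study conditions).  Resampling counts default to
    the full profile (1000); ``reduced=True`` drops them to 100.
    """

    fixture_dir: str | None = None
    synthetic_spec: dict | None = None
    stages: tuple[str, ...] = STAGES
    pls_modes: tuple[str, ...] = PLS_MODES
    pls_groups: tuple[str, ...] = ("all", "YA", "OA")
    n_perm: int = 1000
    n_boot: int = 1000
    n_splits: int = 1000
    n_null_perm: int = 10
    n_null_graphs: int = 10
    consistency_fraction: float = 0.5
    density_sd: float = 3.0
    bsr_threshold: float = 2.0
    age_split: float = 50.0
    rolling_width: float = 10.0
    rolling_step: int = 1
    seed: int = 0
    out_dir: str = "connlife_out"
    reduced: bool = False

    def __post_init__(self):
        for name in ("n_perm", "n_boot", "n_splits", "n_null_perm",
                     "n_null_graphs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("consistency_fraction", "density_sd", "bsr_threshold",
                     "age_split", "rolling_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reduced:
            self.n_perm = min(self.n_perm, 100)
            self.n_boot = min(self.n_boot, 100)
            self.n_splits = min(self.n_splits, 100)
            self.n_null_perm = min(self.n_null_perm, 5)
            self.n_null_graphs = min(self.n_null_graphs, 5)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["pls_modes"] = list(self.pls_modes)
        d["pls_groups"] = list(self.pls_groups)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True,
                          default=_json_default).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_json_default))


def validate_inputs(fixture_dir) -> list[str]:
    """Structural diagnostics for an on-disk fixture; empty when clean."""
    d = Path(fixture_dir)
    diags: list[str] = []
    try:
        cohort = cio.load_cohort(d / "subjects.csv")
    except Exception as e:  # noqa: BLE001 - reported, never corrected
        return [f"subjects.csv: {e}"]
    try:
        regions = pd.read_csv(d / "regions.csv")
        if not {"label", "hemisphere", "subcortical"} <= set(regions.columns):
            diags.append("regions.csv: missing metadata columns")
    except Exception as e:  # noqa: BLE001
        diags.append(f"regions.csv: {e}")
        regions = None
    for sid in cohort.ids:
        for kind in ("sc", "dist"):
            p = d / kind / f"{sid}.csv"
            if not p.exists():
                diags.append(f"{kind}/{sid}.csv: missing matrix for subject")
                continue
            m = np.loadtxt(p, delimiter=",")
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                diags.append(f"{kind}/{sid}.csv: matrix not square")
                continue
            if regions is not None and m.shape[0] != len(regions):
                diags.append(f"{kind}/{sid}.csv: size does not match regions.csv")
            if not np.allclose(m, m.T, atol=1e-10):
                diags.append(f"{kind}/{sid}.csv: matrix not symmetric")
            if np.any(m < 0):
                diags.append(f"{kind}/{sid}.csv: negative entries")
            if kind == "sc" and np.any(m > 1):
                diags.append(f"sc/{sid}.csv: streamline probability above 1")
    for kind in ("sc", "dist"):
        kd = d / kind
        if kd.is_dir():
            known = {f"{sid}.csv" for sid in cohort.ids}
            for p in sorted(kd.glob("*.csv")):
                if p.name not in known:
                    diags.append(f"{kind}/{p.name}: matrix without behavior row")
    return diags


def _pls_block(cset, cohort, metrics_df, mode, group, cfg: RunConfig,
               seed: int) -> dict:
    ids = cohort.group_ids(group)
    sub_cohort = cohort.subset(ids)
    if mode == "edges":
        inp = cpls.edge_pls_input(cset.subset(ids), sub_cohort)
    else:
        prefix = "ne_" if mode == "nodal" else "le_"
        inp = cpls.metric_pls_input(metrics_df, sub_cohort, prefix)
    ana = cpls.pls_analysis(inp, n_perm=cfg.n_perm, n_boot=cfg.n_boot,
                            n_splits=cfg.n_splits, seed=seed,
                            n_null_perm=cfg.n_null_perm)
    block = {
        "mode": mode,
        "group": group,
        "n_subjects": inp.n,
        "n_variables": inp.X.shape[1],
        "singular_values": ana.model.S,
        "permutation_p": ana.permutation.p,
        "z_sval": ana.split.z_sval,
        "z_svec": ana.split.z_svec,
        "z_sval_threshold": ana.split.sval_threshold,
        "z_svec_threshold": ana.split.svec_threshold,
        "reproducible": ana.split.reproducible.tolist(),
        "lv_behavior_corr": ana.model.lv_behavior_corr,
        "lv_behavior_corr_ci": ana.bootstrap.corr_ci,
        "behaviors": ana.model.y_labels,
    }
    patterns = {}
    for sign in ("positive", "negative"):
        pat = cpls.reliable_pattern(
            ana.model, ana.bootstrap, lv=0, bsr_threshold=cfg.bsr_threshold,
            region_metadata=cset.regions,
            edge_index=inp.edge_index if mode == "edges" else None,
            sign=sign,
        )
        entry = {"n_selected": len(pat.variables),
                 "labels": pat.variables["label"].tolist()}
        if mode == "edges":
            entry.update(hubs=pat.hubs, pct_intra_left=pat.pct_intra_left,
                         pct_intra_right=pat.pct_intra_right,
                         pct_inter=pat.pct_inter)
        patterns[sign] = entry
    block["lv1_patterns"] = patterns
    return block


def _pattern_regions(block: dict, sign: str, metrics_prefix: str) -> list[str]:
    """Region labels behind a reliable metric-mode pattern."""
    return [l.removeprefix(metrics_prefix) for l in
            block["lv1_patterns"][sign]["labels"]]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the report manifest (also written to ``report.json`` in the
    output directory together with per-stage artifacts).
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(s) for name, s in
                   zip(("metrics", "pls", "rolling"),
                       ss.generate_state(3, dtype=np.uint32) >> np.uint32(1))}
    provenance = {"config": config.to_dict(), "config_hash": config.config_hash,
                  "seed": config.seed}

    if config.fixture_dir is not None:
        cset, cohort = cio.load_connectome_set(config.fixture_dir)
        log.info("loaded fixture %s (%d subjects)", config.fixture_dir,
                 cohort.n)
    else:
        spec = (csynth.SyntheticSpec.from_dict(config.synthetic_spec)
                if config.synthetic_spec is not None
                else csynth.default_study_spec(seed=config.seed))
        cohort = csynth.generate_behavior(spec)
        cset, _ = csynth.generate_connectomes(spec, cohort)
        provenance["synthetic_spec"] = spec.to_dict()
        log.info("generated synthetic cohort (%d subjects, %d regions)",
                 cohort.n, cset.n_regions)

    report: dict = {"provenance": provenance, "stages": {}}
    artifacts: dict[str, object] = {}

    def require(stage: str, needed: str):
        if needed not in artifacts:
            raise RuntimeError(
                f"stage '{stage}' requires stage '{needed}' which did not run"
            )

    if "qc" in config.stages:
        t = time.time()
        cset, cohort, qc = cio.apply_qc(
            cset, cohort, sd_threshold=config.density_sd,
            min_fraction=config.consistency_fraction,
        )
        qc.to_json(out / "qc_report.json")
        for line in qc.log_lines():
            log.info("%s", line)
        artifacts["qc"] = qc
        report["stages"]["qc"] = {
            "retained": len(qc.retained_ids),
            "excluded": [{"id": i, "reason": r} for i, r in qc.excluded],
            "retained_edge_count": qc.retained_edge_count,
            "seconds": round(time.time() - t, 3),
        }

    if "metrics" in config.stages:
        require("metrics", "qc")
        t = time.time()
        metrics_df = cmetrics.compute_metrics(
            cset, n_null=config.n_null_graphs, seed=stage_seeds["metrics"])
        metrics_df.to_csv(out / "metrics.csv", index=False)
        artifacts["metrics"] = metrics_df
        report["stages"]["metrics"] = {
            "n_subjects": len(metrics_df),
            "edge_length": metrics_df.attrs.get("edge_length"),
            "seconds": round(time.time() - t, 3),
        }
        log.info("metrics stage done in %.1fs", time.time() - t)

    if "pls" in config.stages:
        require("pls", "qc")
        if set(config.pls_modes) & {"nodal", "local"}:
            require("pls", "metrics")
        t = time.time()
        metrics_df = artifacts.get("metrics")
        blocks = []
        pls_ss = np.random.SeedSequence([config.seed, 17])
        seeds = pls_ss.generate_state(
            len(config.pls_modes) * len(config.pls_groups))
        k = 0
        for mode in config.pls_modes:
            for group in config.pls_groups:
                blocks.append(_pls_block(cset, cohort, metrics_df, mode,
                                         group, config, int(seeds[k])))
                k += 1
        artifacts["pls"] = blocks
        report["stages"]["pls"] = {
            "blocks": blocks,
            "seconds": round(time.time() - t, 3),
        }
        log.info("pls stage done in %.1fs (%d blocks)", time.time() - t,
                 len(blocks))

    if "rolling" in config.stages:
        require("rolling", "metrics")
        require("rolling", "pls")
        t = time.time()
        metrics_df = artifacts["metrics"]
        blocks = {f"{b['mode']}:{b['group']}": b for b in artifacts["pls"]}
        curves = {}
        # mirror the study design: nodal efficiency regions positively
        # related to cognition in OA; local efficiency regions positive in YA
        for mode, prefix, group, sign in (("nodal", "ne_", "OA", "positive"),
                                          ("local", "le_", "YA", "positive")):
            key = f"{mode}:{group}"
            if key not in blocks:
                continue
            regions = _pattern_regions(blocks[key], sign, prefix)
            cols = ([f"{prefix}{r}" for r in regions] if regions
                    else [c for c in metrics_df.columns
                          if c.startswith(prefix)])
            m = metrics_df.set_index("id").loc[cohort.ids]
            mean_metric = m[cols].mean(axis=1).to_numpy()
            curve = cstats.rolling_correlation(
                cohort.table["age"].to_numpy(), mean_metric,
                cohort.table["fluid_intelligence"].to_numpy(float),
                width=config.rolling_width, step=config.rolling_step,
                n_boot=config.n_boot, seed=stage_seeds["rolling"],
            )
            curve.to_csv(out / f"rolling_{mode}.csv", index=False)
            curves[mode] = {
                "regions": regions or "all",
                "n_windows": len(curve),
                "peak_window_start": (
                    float(curve.loc[curve["r"].idxmax(), "age_start"])
                    if curve["r"].notna().any() else None),
            }
        artifacts["rolling"] = curves
        report["stages"]["rolling"] = {
            "curves": curves, "seconds": round(time.time() - t, 3)}

    if "regress" in config.stages:
        require("regress", "metrics")
        t = time.time()
        metrics_df = artifacts["metrics"]
        region_labels = None
        if "pls" in artifacts:
            blocks = {f"{b['mode']}:{b['group']}": b for b in artifacts["pls"]}
            if "local:OA" in blocks:
                regs = _pattern_regions(blocks["local:OA"], "negative", "le_")
                region_labels = regs or None
        tables = {}
        comparisons = []
        fits: dict[tuple[int, str], cstats.RegressionFit] = {}
        for model_id in (1, 2, 3):
            for group in ("YA", "OA"):
                fit = cstats.fit_local_efficiency_models(
                    metrics_df, cohort, model_id, group,
                    region_labels=region_labels)
                fits[(model_id, group)] = fit
                fit.table.to_csv(
                    out / f"regression_model{model_id}_{group}.csv",
                    index=False)
                tables[f"model{model_id}_{group}"] = {
                    "r_squared": fit.r_squared,
                    "n": fit.n,
                    "terms": fit.table.to_dict(orient="records"),
                }
        for model_id in (1, 2, 3):
            for term in ("Age", "Small-worldness"):
                cmp = cstats.compare_group_estimates(
                    fits[(model_id, "YA")], fits[(model_id, "OA")], term)
                cmp["model"] = model_id
                comparisons.append(cmp)
        report["stages"]["regress"] = {
            "dependent_regions": region_labels or "all",
            "tables": tables,
            "group_comparisons": comparisons,
            "seconds": round(time.time() - t, 3),
        }

    report["total_seconds"] = round(time.time() - t0, 3)
    # drop wall-clock timings from the serialized report so identical
    # configs produce byte-identical report files
    serializable = json.loads(json.dumps(report, default=_json_default))
    for st in serializable["stages"].values():
        st.pop("seconds", None)
    serializable.pop("total_seconds", None)
    _write_json(out / "report.json", serializable)
    return report
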