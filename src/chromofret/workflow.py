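"""End-to-end orchestration of the multimodal analysis workflow.

A single YAML/dict configuration drives simulation (or loading) of the
two data modalities, burst MFD analysis, subensemble lifetime fitting,
FCS, dynamic PDA, TIRF trace analysis and an optional structural screen,
writing every stage's outputs as TSV/JSON into a write-once output tree
with full seed provenance.  One global seed fans out to per-stage seeds
through a stable hash, so any stage can be reproduced in isolation;
identical config + seed gives byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burst as bm
from . import fcs as fcsm
from . import lifetime as lt
from . import pda as pdam
from . import synthetic as syn
from . import tirf as tirfm
from .kinetics import (
    ALEXA568_647,
    DomainError,
    KineticModel,
    model_from_config,
    two_state_model,
)

__all__ = ["WorkflowConfig", "run_workflow", "validate_report", "stage_seed"]

DEFAULT_STAGES = ("simulate", "bursts", "subensemble", "fcs", "pda", "tirf")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class WorkflowConfig:
    seed: int = 0
    outdir: str = "chromofret_run"
    stages: tuple = DEFAULT_STAGES
    model: dict | None = None  # kinetics config block; default two-state
    confocal: dict = field(default_factory=dict)
    tirf: dict = field(default_factory=dict)
    pda: dict = field(default_factory=dict)
    subensemble: dict = field(default_factory=dict)
    fcs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    def build_model(self) -> KineticModel:
        if self.model is not None:
            return model_from_config(self.model)
        from .kinetics import FRETSpecies

        hi = FRETSpecies("compact", ALEXA568_647, efficiency=0.8)
        lo = FRETSpecies("open", ALEXA568_647, efficiency=0.1)
        return two_state_model(hi, lo, relaxation_time=3.7e-3, population0=0.5)


def _df_to_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_workflow(config: WorkflowConfig) -> dict:
    """Execute the enabled stages in dependency order; return the report.

    The report maps each stage to its parameter echoes, key numbers and
    output files (with checksums).  A stage failure aborts the run with a
    partial report saved to ``<outdir>/report.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "status": "running"}
    model = config.build_model()
    calib = syn.CalibrationConfig(**config.confocal.get("calibration", {}))
    pair = model.species[0].pair
    state: dict = {}

    def finish_stage(name, info, files=()):
        info = dict(info)
        info["seed"] = stage_seed(config.seed, name)
        info["files"] = {str(f.name): _checksum(f) for f in files}
        report["stages"][name] = info

    try:
        if "simulate" in config.stages:
            seed = stage_seed(config.seed, "simulate")
            ccfg = syn.ConfocalSimConfig(
                burst_count=int(config.confocal.get("burst_count", 500)),
                mean_burst_duration=float(config.confocal.get("mean_burst_duration", 1.5e-3)),
                molecule_brightness=float(config.confocal.get("molecule_brightness", 8e4)),
                pie=bool(config.confocal.get("pie", False)),
                calibration=calib,
                seed=seed,
            )
            stream, truth = syn.simulate_bursts(model, ccfg)
            f_stream = out / "photons.tsv"
            stream.to_tsv(f_stream)
            f_truth = out / "photons_truth.tsv"
            _df_to_tsv(truth.table(), f_truth)
            # donor-only reference stream for the subensemble stage
            from .kinetics import FRETSpecies

            d0 = KineticModel(
                [FRETSpecies("donor_only", pair, efficiency=1e-6)], np.zeros((1, 1))
            )
            ref_stream, _ = syn.simulate_bursts(
                d0, syn.ConfocalSimConfig(
                    burst_count=int(config.confocal.get("burst_count", 500)),
                    calibration=calib, seed=seed + 1,
                )
            )
            tcfg = syn.TIRFSimConfig(
                n_traces=int(config.tirf.get("n_traces", 40)),
                trace_length=int(config.tirf.get("trace_length", 900)),
                bleach_rate_donor=float(config.tirf.get("bleach_rate_donor", 1 / 30)),
                bleach_rate_acceptor=float(config.tirf.get("bleach_rate_acceptor", 1 / 25)),
                seed=seed + 2,
            )
            slow = config.tirf.get("model")
            tirf_model = model_from_config(slow) if slow else _default_slow_model(pair)
            traces, t_truth = syn.simulate_tirf_traces(tirf_model, tcfg)
            f_traces = out / "tirf_traces.tsv"
            tirfm.traces_to_tsv(traces, f_traces)
            state.update(stream=stream, ref_stream=ref_stream, traces=traces, tcfg=tcfg)
            finish_stage("simulate", {"n_photons": len(stream), "n_traces": len(traces)},
                         [f_stream, f_truth, f_traces])

        if "bursts" in config.stages:
            stream = state["stream"]
            bursts = bm.analyze_bursts(stream, calib, pair)
            f_bursts = out / "bursts.tsv"
            _df_to_tsv(bm.bursts_to_table(bursts), f_bursts)
            hist = bm.mfd_histogram2d(bursts)
            f_hist = out / "mfd_hist.tsv"
            grid = pd.DataFrame(hist["grid"])
            _df_to_tsv(grid, f_hist)
            state["bursts"] = bursts
            es = np.array([b.efficiency for b in bursts])
            finish_stage("bursts", {"n_bursts": len(bursts), "mean_e": float(es.mean()) if len(es) else None},
                         [f_bursts, f_hist])

        if "subensemble" in config.stages:
            bursts = state["bursts"]
            stream = state["stream"]
            sel = bm.select_subensemble(bursts, config.subensemble.get("e_min", 0.065))
            micro = np.concatenate(
                [
                    stream.micro_time[b.index_start : b.index_stop][
                        stream.channel[b.index_start : b.index_stop] == syn.CHANNEL_DONOR
                    ]
                    for b in sel
                ]
            ) if sel else np.empty(0)
            ref = state["ref_stream"]
            ref_micro = ref.micro_time[ref.channel == syn.CHANNEL_DONOR]
            t_max = float(min(stream.period_ns, 30.0))
            eps = lt.fret_induced_decay(
                lt.decay_histogram(micro, t_max_ns=t_max),
                lt.decay_histogram(ref_micro, t_max_ns=t_max),
            )
            n_sp = int(config.subensemble.get("n_species", 2))
            fit = lt.fit_species_decay(eps, n_sp, pair, seed=stage_seed(config.seed, "subensemble"))
            f_eps = out / "epsilon.tsv"
            _df_to_tsv(lt.epsilon_to_table(eps), f_eps)
            finish_stage(
                "subensemble",
                {
                    "n_bursts_selected": len(sel),
                    "distances": [float(x) for x in fit.distances],
                    "fractions": [float(x) for x in fit.fractions],
                    "redchi": fit.redchi,
                },
                [f_eps],
            )

        if "fcs" in config.stages:
            stream = state["stream"]
            curves = fcsm.correlate_channels(
                stream,
                base_bin=float(config.fcs.get("base_bin", 2e-6)),
                max_lag=float(config.fcs.get("max_lag", 0.02)),
            )
            files = []
            for name, c in curves.items():
                f = out / f"fcs_{name}.tsv"
                _df_to_tsv(c.to_table(), f)
                files.append(f)
            fit = fcsm.fcs_global_fit(list(curves.values()), n_kinetic=1, fit_diffusion=True)
            finish_stage(
                "fcs",
                {
                    "kinetic_times": [float(x) for x in fit["kinetic_times"]],
                    "cross_amplitude": float(fit["models"][2].kinetic_amplitudes[0]),
                    "redchi": fit["redchi"],
                },
                files,
            )

        if "pda" in config.stages:
            stream = state["stream"]
            bursts = state["bursts"]
            dts = [float(x) for x in config.pda.get("window_durations", (1e-3, 2e-3, 3e-3))]
            datasets = [pdam.slice_time_windows(bursts, stream, dt) for dt in dts]
            tmpl = pdam.PDAModel(model, calibration=calib, seed=stage_seed(config.seed, "pda"))
            fit = pdam.fit_kinetic_model(
                datasets, tmpl, pdam.FitSpec(n_starts=int(config.pda.get("n_starts", 4))),
                seed=stage_seed(config.seed, "pda"),
            )
            f_par = out / "pda_fit.tsv"
            _df_to_tsv(pd.DataFrame([fit.params]), f_par)
            rts = {k: [float(x) for x in v] for k, v in fit.relaxation_times().items()}
            finish_stage(
                "pda",
                {"params": fit.params, "relaxation_times": rts, "redchi": float(fit.redchi),
                 "n_windows": fit.n_windows},
                [f_par],
            )

        if "tirf" in config.stages:
            traces = state["traces"]
            crit = tirfm.SelectionCriteria(
                background_donor=float(config.tirf.get("background_donor", 50.0)),
                background_acceptor=float(config.tirf.get("background_acceptor", 50.0)),
                require_donor_bleach_within=float(config.tirf.get("donor_bleach_within", 120.0)),
            )
            accepted, rejected = tirfm.select_traces(traces, crit)
            rows = [{"trace_id": t.trace_id, "accepted": True, "reason": ""} for t in accepted]
            rows += [{"trace_id": t.trace_id, "accepted": False, "reason": r} for t, r in rejected]
            f_sel = out / "tirf_selection.tsv"
            _df_to_tsv(pd.DataFrame(rows).sort_values("trace_id"), f_sel)
            info = {"n_accepted": len(accepted), "n_rejected": len(rejected)}
            files = [f_sel]
            if len(accepted) >= 10:
                es = []
                for t in accepted:
                    e, m = tirfm.efficiency_trace(
                        t, beta=0.0, background_donor=crit.background_donor,
                        background_acceptor=crit.background_acceptor,
                    )
                    es.append(e[m])
                pooled = np.concatenate(es)
                if len(pooled) >= 500:
                    pf = tirfm.fit_population_gaussians(pooled, 2)
                    f_pop = out / "tirf_populations.tsv"
                    _df_to_tsv(
                        pd.DataFrame({"mean": pf.means, "sigma": pf.sigmas, "weight": pf.weights}),
                        f_pop,
                    )
                    files.append(f_pop)
                    info["population_means"] = [float(x) for x in pf.means]
                cc = tirfm.trace_cross_correlation(accepted, max_lag=3.0)
                f_cc = out / "tirf_cc.tsv"
                _df_to_tsv(pd.DataFrame({"lag_s": cc.lags, "cc": cc.pooled, "sem": cc.sem}), f_cc)
                files.append(f_cc)
                info["cc_time"] = float(cc.fit_times[0])
                info["cc_amplitude"] = float(cc.fit_amplitudes[0])
            finish_stage("tirf", info, files)

        report["status"] = "ok"
    except Exception as exc:  # halt with partial, machine-readable report
        report["status"] = "failed"
        report["error"] = {"stage": "unknown", "message": str(exc), "type": type(exc).__name__}
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        raise
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _default_slow_model(pair) -> KineticModel:
    from .kinetics import FRETSpecies

    lo = FRETSpecies("open", pair, efficiency=0.1)
    hi = FRETSpecies("compact", pair, efficiency=0.5)
    return two_state_model(lo, hi, relaxation_time=0.3, population0=0.5)


def validate_report(report: dict, expectations) -> list[dict]:
    """Compare report values against tolerance-tagged expectations.

    ``expectations`` is a list of ``{"key": "stages/pda/redchi", "max":
    2.0}``-style records (``min``/``max``/``value`` + ``tol``); the key is
    a slash path into the report.  Returns one record per expectation
    with a pass flag; malformed expectations raise.
    """
    if isinstance(expectations, (str, Path)):
        with open(expectations) as fh:
            expectations = yaml.safe_load(fh) or []
    results = []
    for exp in expectations:
        if "key" not in exp:
            raise DomainError("expectation missing 'key'")
        node = report
        try:
            for part in str(exp["key"]).split("/"):
                node = node[int(part)] if isinstance(node, list) else node[part]
        except (KeyError, IndexError, TypeError):
            results.append({**exp, "passed": False, "actual": None, "reason": "missing key"})
            continue
        ok, reason = True, ""
        if "min" in exp and not (node >= exp["min"]):
            ok, reason = False, f"{node} < min {exp['min']}"
        if "max" in exp and not (node <= exp["max"]):
            ok, reason = False, f"{node} > max {exp['max']}"
        if "value" in exp:
            tol = exp.get("tol", 0.0)
            if not (abs(node - exp["value"]) <= tol):
                ok, reason = False, f"|{node} - {exp['value']}| > {tol}"
        results.append({**exp, "passed": ok, "actual": node, "reason": reason})
    return results
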