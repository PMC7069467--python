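"""Configuration-driven orchestration of the full analysis.

Stages: cohort -> simulate/preprocess -> ERP statistics -> connectivity
(Kalman MVAAR + ADTF) -> difference networks & graph properties ->
CRS-R association.  Every stage writes TSV/JSON outputs plus a marker
file carrying the effective-config hash, so a rerun with an unchanged
config resumes downstream of completed stages.  Identical config + seed
give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adtf import average_trials, trial_networks, TimeVaryingNetwork
from .cohort import CohortTable, parse_cohort_table, summarize_group, write_cohort_table
from .erp import DEFAULT_COMPONENTS, average_erp, mass_univariate_ttest, measure_component
from .errors import PipelineError
from .mvaar import KalmanConfig, fit_kalman_mvaar_trials
from .netstats import pearson_association, snapshot_series, subject_properties
from .preprocessing import EpochSet, baseline_correct, reject_amplitude
from .simulate import (SimulationScenario, SyntheticCohort, generate_cohort,
                       simulate_subject_epochs, subject_static_network)

logger = logging.getLogger(__name__)

STAGES = ("cohort", "epochs", "erp", "connectivity", "network", "associate",
          "manifest")


@dataclass
class PipelineConfig:
    out_dir: str = "dynconn_run"
    seed: int = 0
    # scenario
    montage: str = "desk10"               # "desk10" | "full27"
    n_per_cell: int = 8
    n_standard: int = 86
    n_deviant: int = 60
    rho_traumatic: float = 0.5
    rho_nontraumatic: float = 0.0
    # preprocessing (applied to the simulated epoch sets)
    baseline_ms: tuple = (-200.0, 0.0)
    reject_k: float = 3.0
    # kalman
    order: int = 5
    uc: float = 1e-3
    # adtf
    freq_lo: float = 1.0
    freq_hi: float = 30.0
    freq_step: float = 1.0
    band: tuple = (1.0, 30.0)
    store_every: int = 25
    # network stats
    snapshots: tuple = (100.0, 200.0, 300.0, 600.0, 1000.0)
    alpha: float = 0.05
    directed_handling: str = "symmetrize"
    property_window: tuple = (0.0, 1000.0)
    # erp stats
    q: float = 0.05

    def scenario(self) -> SimulationScenario:
        if self.montage == "desk10":
            scn = SimulationScenario.desk_scale()
        elif self.montage == "full27":
            scn = SimulationScenario()
        else:
            raise PipelineError("config", "bad_montage",
                                f"unknown montage {self.montage!r}")
        return dataclasses.replace(scn, n_standard=self.n_standard,
                                   n_deviant=self.n_deviant,
                                   n_subjects_per_group=self.n_per_cell)

    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_lo, self.freq_hi + 1e-9, self.freq_step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise PipelineError("config", "unknown_keys",
                                f"unknown config keys: {sorted(bad)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


@dataclass
class ResultBundle:
    out_dir: Path
    cohort: SyntheticCohort
    networks: dict               # subject_id -> TimeVaryingNetwork
    difference_networks: list
    properties: pd.DataFrame
    associations: pd.DataFrame
    manifest: dict


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    marker = out / f"{stage}.done.json"
    if marker.exists():
        try:
            return json.loads(marker.read_text()).get("config_hash") == cfg_hash
        except json.JSONDecodeError:
            return False
    return False


def _mark_done(out: Path, stage: str, cfg_hash: str, **extra) -> None:
    _write_json(out / f"{stage}.done.json", {"config_hash": cfg_hash, **extra})


def _subject_seed(base_seed: int, patient_id: str) -> int:
    h = hashlib.sha256(f"{base_seed}:{patient_id}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def component_present(res, channel: str, window_ms: tuple,
                      min_samples: int = 5) -> bool:
    """Is a component's FDR significance present at one electrode?

    Requires at least ``min_samples`` significant samples inside the
    component window: isolated single-sample discoveries (which BH-FDR
    permits by design) do not constitute a component.
    """
    ci = list(res.channel_labels).index(channel)
    sel = (res.times_ms >= window_ms[0] - 1e-9) & (res.times_ms <= window_ms[1] + 1e-9)
    return int(res.fdr_mask[ci, sel].sum()) >= min_samples


def run_replicate(seed: int, n_subjects: int = 8,
                  scn: Optional[SimulationScenario] = None,
                  kalman_cfg: Optional[KalmanConfig] = None,
                  snapshots=(100.0, 200.0, 300.0, 600.0, 1000.0),
                  alpha: float = 0.05, store_every: int = 25,
                  n_bootstrap: int = 500) -> dict:
    """One end-to-end replicate of the qualitative headline study.

    Simulates MCS-like vs UWS-like subjects, runs the deviant-vs-standard
    ERP contrast, the per-trial Kalman/ADTF networks and group edge tests,
    plus the cohort-level CRS-R association, and reports the planted-edge
    retention pattern, P3a/N1 specificity and the association estimates.
    """
    scn = scn if scn is not None else SimulationScenario.desk_scale()
    kalman_cfg = kalman_cfg if kalman_cfg is not None else KalmanConfig()
    rng = np.random.default_rng(seed)
    src, snk = scn.coupling_edges[0].source, scn.coupling_edges[0].sink

    group_nets, group_erp = {}, {}
    for diag in ("MCS", "UWS"):
        nets, dev_erps, std_erps = [], [], []
        for s_i in range(n_subjects):
            sub_seed = int(rng.integers(2 ** 31))
            ep, _ = simulate_subject_epochs(scn, (diag, "traumatic"), sub_seed)
            ep = baseline_correct(ep)
            dev_erps.append(average_erp(ep, "deviant"))
            std_erps.append(average_erp(ep, "standard"))
            models = fit_kalman_mvaar_trials(
                ep.select_condition("deviant"), kalman_cfg, rate=ep.rate,
                store_every=store_every, channel_labels=ep.channel_labels)
            nets.append(average_trials(trial_networks(
                models, window_start_ms=ep.window_ms[0])))
        group_nets[diag] = nets
        group_erp[diag] = mass_univariate_ttest(dev_erps, std_erps, paired=True)

    diffs = snapshot_series(group_nets["MCS"], group_nets["UWS"],
                            times_ms=snapshots, alpha=alpha)
    edge_at = {}
    for d, t in zip(diffs, snapshots):
        hit = [e for e in d.edges if e.source == src and e.sink == snk]
        edge_at[t] = hit[0].direction if hit else None

    from .erp import N1, P3A
    p3a = {d: component_present(group_erp[d], "Fz", P3A.window_ms)
           for d in ("MCS", "UWS")}
    n1 = {d: component_present(group_erp[d], "Fz", N1.window_ms)
          for d in ("MCS", "UWS")}

    # cohort-level association (fast stationary network model)
    syn = generate_cohort(n_subjects, seed=int(rng.integers(2 ** 31)))
    meas_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
    assoc = {}
    for grp in ("traumatic", "nontraumatic"):
        subj = [r for r in syn.table if r.traumatic_group == grp]
        props = [subject_properties(
            subject_static_network(scn, "MCS",
                                   syn.strength_scale[r.patient_id],
                                   rng=meas_rng),
            window_ms=(-1e9, 1e9)) for r in subj]
        scores = np.asarray([r.crs_r_total for r in subj], dtype=float)
        res = {a.property: a.r for a in pearson_association(props, scores)}
        x = np.asarray([q.Ge for q in props])
        boot = []
        for _ in range(n_bootstrap):
            idx = meas_rng.integers(0, len(x), len(x))
            if np.ptp(x[idx]) > 0 and np.ptp(scores[idx]) > 0:
                boot.append(np.corrcoef(x[idx], scores[idx])[0, 1])
        lo, hi = np.percentile(boot, [2.5, 97.5])
        assoc[grp] = {"r": res, "r_Ge": res["Ge"], "ci_Ge": (float(lo), float(hi))}

    return {
        "edge_at": edge_at,
        "edge_ok": (edge_at[100.0] is None
                    and all(edge_at[t] == "A>B" for t in (300.0, 600.0, 1000.0))),
        "p3a_present": p3a,
        "p3a_ok": p3a["MCS"] and not p3a["UWS"],
        "n1_present": n1,
        "association": assoc,
        "assoc_cover_ok": assoc["traumatic"]["ci_Ge"][0] <= 0.5
                          <= assoc["traumatic"]["ci_Ge"][1],
        "assoc_null_ok": abs(assoc["nontraumatic"]["r_Ge"]) < 0.4,
    }


def run_pipeline(cfg: PipelineConfig, resume: bool = True) -> ResultBundle:
    """Execute every stage; returns the collected results.

    EEG is simulated for the traumatic MCS and traumatic UWS cells (the
    primary diagnosis contrast); the CRS-R association stage uses the
    fast stationary network model for all four cells.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    _write_json(out / "effective_config.json", cfg.to_dict())
    scn = cfg.scenario()
    counters = {"trials_rejected": 0}

    def fail(stage, code, msg):
        raise PipelineError(stage, code, msg)

    # -- stage: cohort -----------------------------------------------------
    cohort_path = out / "cohort.tsv"
    syn = generate_cohort(cfg.n_per_cell, cfg.rho_traumatic,
                          cfg.rho_nontraumatic, seed=cfg.seed)
    if not (resume and _stage_done(out, "cohort", h)):
        write_cohort_table(syn.table, cohort_path)
        summary = {}
        for diag in ("MCS", "UWS"):
            s = summarize_group(syn.table, diagnosis=diag)
            summary[diag] = {"n": s.n, "mean_age": s.mean_age,
                             "n_male": s.n_male, "n_traumatic": s.n_traumatic}
        _write_json(out / "cohort_summary.json", summary)
        _mark_done(out, "cohort", h)

    # -- stage: epochs (simulate + preprocess) ------------------------------
    eeg_subjects = [r for r in syn.table
                    if r.traumatic_group == "traumatic"]
    ep_dir = out / "epochs"
    ep_dir.mkdir(exist_ok=True)
    epochs = {}
    if resume and _stage_done(out, "epochs", h):
        for r in eeg_subjects:
            z = np.load(ep_dir / f"{r.patient_id}.npz", allow_pickle=True)
            epochs[r.patient_id] = EpochSet(
                data=z["data"], window_ms=tuple(z["window_ms"]), rate=float(z["rate"]),
                condition=z["condition"], channel_labels=tuple(z["channel_labels"]),
                baseline_window_ms=tuple(cfg.baseline_ms))
    else:
        for r in eeg_subjects:
            ep, _truth = simulate_subject_epochs(
                scn, (r.diagnosis, r.traumatic_group),
                subject_seed=_subject_seed(cfg.seed, r.patient_id),
                strength_scale=syn.strength_scale[r.patient_id])
            ep = baseline_correct(ep, cfg.baseline_ms)
            ep, log = reject_amplitude(ep, k=cfg.reject_k)
            counters["trials_rejected"] += int((~log["kept"]).sum())
            epochs[r.patient_id] = ep
            np.savez_compressed(ep_dir / f"{r.patient_id}.npz", data=ep.data,
                                window_ms=np.array(ep.window_ms), rate=ep.rate,
                                condition=np.array(ep.condition, dtype=str),
                                channel_labels=np.array(ep.channel_labels, dtype=str))
        _mark_done(out, "epochs", h, n_subjects=len(epochs),
                   trials_rejected=counters["trials_rejected"])

    # -- stage: erp ---------------------------------------------------------
    if not (resume and _stage_done(out, "erp", h)):
        comp_rows, contrast_frames = [], []
        for diag in ("MCS", "UWS"):
            subj = [r for r in eeg_subjects if r.diagnosis == diag]
            dev = [average_erp(epochs[r.patient_id], "deviant") for r in subj]
            std = [average_erp(epochs[r.patient_id], "standard") for r in subj]
            montage = set(scn.channel_labels)
            components = []
            for comp in DEFAULT_COMPONENTS:
                present = tuple(e for e in comp.electrodes if e in montage)
                if present:
                    components.append(dataclasses.replace(comp, electrodes=present))
            for r, d_erp, s_erp in zip(subj, dev, std):
                for comp in components:
                    for cond, erp_w in (("deviant", d_erp), ("standard", s_erp)):
                        comp_rows.append({
                            "patient_id": r.patient_id, "diagnosis": diag,
                            "condition": cond, "component": comp.name,
                            "mean_amplitude_uv": measure_component(erp_w, comp)})
            res = mass_univariate_ttest(dev, std, paired=True, q=cfg.q)
            rows = []
            for ci, ch in enumerate(res.channel_labels):
                for ti, tm in enumerate(res.times_ms):
                    rows.append((diag, ch, tm, res.t_values[ci, ti],
                                 res.p_values[ci, ti], bool(res.fdr_mask[ci, ti])))
            contrast_frames.append(pd.DataFrame(
                rows, columns=["group", "channel", "time_ms", "t", "p",
                               "significant"]))
        pd.DataFrame(comp_rows).to_csv(out / "erp_components.tsv", sep="\t",
                                       index=False, float_format="%.10g")
        pd.concat(contrast_frames).to_csv(out / "erp_mass_univariate.tsv",
                                          sep="\t", index=False,
                                          float_format="%.10g")
        _mark_done(out, "erp", h)

    # -- stage: connectivity -----------------------------------------------
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    networks = {}
    kalman_cfg = KalmanConfig(order=cfg.order, uc=cfg.uc)
    if resume and _stage_done(out, "connectivity", h):
        for r in eeg_subjects:
            z = np.load(net_dir / f"{r.patient_id}.npz", allow_pickle=True)
            networks[r.patient_id] = TimeVaryingNetwork(
                w=z["w"], times_ms=z["times_ms"], band_hz=tuple(z["band_hz"]),
                channel_labels=tuple(z["channel_labels"]),
                n_trials_averaged=int(z["n_trials"]))
    else:
        for r in eeg_subjects:
            ep = epochs[r.patient_id]
            trials = ep.select_condition("deviant")
            models = fit_kalman_mvaar_trials(
                trials, kalman_cfg, rate=ep.rate, store_every=cfg.store_every,
                channel_labels=ep.channel_labels)
            nets = trial_networks(models, freqs_hz=cfg.freqs(),
                                  band_hz=cfg.band,
                                  window_start_ms=ep.window_ms[0])
            net = average_trials(nets)
            networks[r.patient_id] = net
            np.savez_compressed(net_dir / f"{r.patient_id}.npz", w=net.w,
                                times_ms=net.times_ms,
                                band_hz=np.array(net.band_hz),
                                channel_labels=np.array(net.channel_labels, dtype=str),
                                n_trials=net.n_trials_averaged)
        _mark_done(out, "connectivity", h)

    # -- stage: network (difference networks + properties) ------------------
    mcs_nets = [networks[r.patient_id] for r in eeg_subjects if r.diagnosis == "MCS"]
    uws_nets = [networks[r.patient_id] for r in eeg_subjects if r.diagnosis == "UWS"]
    diffs = snapshot_series(mcs_nets, uws_nets, times_ms=cfg.snapshots,
                            alpha=cfg.alpha)
    prop_rows = []
    for r in eeg_subjects:
        q = subject_properties(networks[r.patient_id], cfg.property_window,
                               cfg.directed_handling, subject_id=r.patient_id)
        prop_rows.append({"patient_id": r.patient_id, "diagnosis": r.diagnosis,
                          "traumatic_group": r.traumatic_group, **q.as_dict()})
    properties = pd.DataFrame(prop_rows)
    if not (resume and _stage_done(out, "network", h)):
        records = [rec for d in diffs for rec in d.to_records()]
        pd.DataFrame(records, columns=["time_ms", "source", "sink", "t", "p",
                                       "direction"]).to_csv(
            out / "difference_networks.tsv", sep="\t", index=False,
            float_format="%.10g")
        properties.to_csv(out / "network_properties.tsv", sep="\t",
                          index=False, float_format="%.10g")
        _mark_done(out, "network", h,
                   edges_per_snapshot=[len(d.edges) for d in diffs])

    # -- stage: associate ----------------------------------------------------
    rng = np.random.default_rng(_subject_seed(cfg.seed, "associate"))
    assoc_rows = []
    for grp in ("traumatic", "nontraumatic"):
        subj = [r for r in syn.table if r.traumatic_group == grp]
        # networks at a nominal (MCS-level) coupling scaled by each
        # subject's latent multiplier: the only planted score-network link
        # is the per-aetiology latent correlation
        props = [subject_properties(
            subject_static_network(scn, "MCS",
                                   syn.strength_scale[r.patient_id], rng=rng),
            window_ms=(-1e9, 1e9), subject_id=r.patient_id)
            for r in subj]
        scores = [r.crs_r_total for r in subj]
        for a in pearson_association(props, scores):
            assoc_rows.append({"group": grp, "property": a.property,
                               "r": a.r, "p": a.p, "n": a.n})
    associations = pd.DataFrame(assoc_rows)
    if not (resume and _stage_done(out, "associate", h)):
        associations.to_csv(out / "associations.tsv", sep="\t", index=False,
                            float_format="%.10g")
        _mark_done(out, "associate", h)

    # -- stage: manifest -----------------------------------------------------
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config_hash": h,
        "stages_completed": list(STAGES),
        "counters": counters,
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    _write_json(out / "manifest.json", manifest)
    _mark_done(out, "manifest", h)
    return ResultBundle(out_dir=out, cohort=syn, networks=networks,
                        difference_networks=diffs, properties=properties,
                        associations=associations, manifest=manifest)
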