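"""Synthetic study generator: oddball stimulus blocks, ERP-bearing
time-varying VAR epochs for simulated patient groups, and cohort tables
with planted score-network associations.

The generator emulates the structure of an auditory emotional-oddball EEG
study in disorders of consciousness:

* stimulus blocks of 110 sounds (86 standards, 12 happy and 12 sad
  deviants) with no two deviants adjacent;
* trials sampled from a stable VAR background whose planted frontal ->
  parietal coupling switches on in a 300-1000 ms post-stimulus window
  during deviant (emotional) trials, with a larger coupling strength for
  MCS-like than for UWS-like subjects;
* additive ERP templates (Gaussian bumps with fixed scalp weight
  vectors): N1 in all groups with an emotion-enhanced deviant amplitude,
  P3a only in MCS-like subjects, and no LPP in either patient group;
* a cohort table whose latent network-strength scalar correlates with the
  CRS-R total in the "traumatic" cell (rho = 0.5 by default) and not in
  the "nontraumatic" cell (rho = 0).

All randomness flows from explicit seeds through named substreams, so
fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .adtf import DEFAULT_BAND_HZ, DEFAULT_FREQS_HZ, TimeVaryingNetwork, integrate_band, transfer_function
from .cohort import CRS_SUBSCALE_MAX, CohortTable, PatientRecord
from .errors import ParameterError
from .mvaar import TVMVARModel, stability_check
from .preprocessing import DEFAULT_NETWORK_MONTAGE, EpochSet, Recording, n_window_samples

# ---------------------------------------------------------------------------
# stimulus paradigm


@dataclass(frozen=True)
class StimulusBlock:
    sequence: tuple              # labels in {"standard", "happy", "sad"}
    block_index: int = 0

    @property
    def counts(self) -> tuple:
        seq = self.sequence
        return (sum(s == "standard" for s in seq),
                sum(s == "happy" for s in seq),
                sum(s == "sad" for s in seq))


def generate_block(n_standard: int = 86, n_happy: int = 12, n_sad: int = 12,
                   seed: Optional[int] = None, block_index: int = 0,
                   rng: Optional[np.random.Generator] = None) -> StimulusBlock:
    """Randomly ordered oddball block with no two deviants adjacent.

    Deviants are dropped into distinct gaps between standards, which is
    the weakest ordering constraint ensuring the same rare sound never
    occurs twice in a row; infeasible when deviants > standards + 1.
    """
    if min(n_standard, n_happy, n_sad) < 0:
        raise ParameterError("stimulus counts must be >= 0")
    n_dev = n_happy + n_sad
    if n_dev > n_standard + 1:
        raise ParameterError("cannot avoid adjacent deviants: too few standards")
    rng = rng if rng is not None else np.random.default_rng(seed)
    gaps = rng.choice(n_standard + 1, size=n_dev, replace=False)
    labels = np.array(["happy"] * n_happy + ["sad"] * n_sad, dtype=object)
    rng.shuffle(labels)
    by_gap = dict(zip(gaps, labels))
    seq = []
    for g in range(n_standard + 1):
        if g in by_gap:
            seq.append(str(by_gap[g]))
        if g < n_standard:
            seq.append("standard")
    return StimulusBlock(sequence=tuple(seq), block_index=block_index)


# ---------------------------------------------------------------------------
# scenario


@dataclass(frozen=True)
class ErpTemplate:
    """Gaussian voltage bump with a fixed scalp weight vector.

    Amplitudes (uV, signed) are resolved per condition; ``diagnoses``
    restricts a component to the listed diagnosis-like groups (None = all).
    """

    name: str
    latency_ms: float
    sigma_ms: float
    weights: Dict[str, float]
    amp_standard: float
    amp_deviant: float
    diagnoses: Optional[tuple] = None

    def amplitude(self, condition: str, diagnosis: str) -> float:
        if self.diagnoses is not None and diagnosis not in self.diagnoses:
            return 0.0
        return self.amp_deviant if condition == "deviant" else self.amp_standard

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((times_ms - self.latency_ms) / self.sigma_ms) ** 2)

    def spatial(self, channel_labels: Sequence[str]) -> np.ndarray:
        return np.array([self.weights.get(l, 0.0) for l in channel_labels])


def default_templates() -> tuple:
    """N1 for everyone (emotion-enhanced), P3a only MCS-like, no LPP."""
    return (
        ErpTemplate("N1", 150.0, 25.0,
                    {"Fz": 1.0, "F3": 0.7, "F4": 0.7, "Cz": 0.6},
                    amp_standard=-3.0, amp_deviant=-6.0),
        ErpTemplate("P3a", 300.0, 45.0,
                    {"Fz": 1.0, "Cz": 0.8, "F3": 0.6, "F4": 0.6},
                    amp_standard=0.0, amp_deviant=5.0, diagnoses=("MCS",)),
        ErpTemplate("LPP", 650.0, 180.0,
                    {"Pz": 1.0, "CP1": 0.8, "CP2": 0.8, "Cz": 0.6,
                     "P3": 0.7, "P4": 0.7},
                    amp_standard=0.0, amp_deviant=0.0),
    )


@dataclass(frozen=True)
class CouplingEdge:
    source: str
    sink: str
    strength_by_diagnosis: Dict[str, float]
    on_window_ms: Tuple[float, float] = (300.0, 1000.0)


@dataclass(frozen=True)
class SimulationScenario:
    channel_labels: tuple = DEFAULT_NETWORK_MONTAGE
    rate: float = 500.0
    window_ms: tuple = (-200.0, 1000.0)
    base_ar: tuple = (0.5, -0.2)     # diagonal AR background, one entry per lag
    coupling_edges: tuple = (
        CouplingEdge("Fz", "Pz", {"MCS": 0.4, "UWS": 0.1}),
    )
    ring_coupling: float = 0.15      # weak always-on background ring (lag 1)
    noise_std: float = 4.0           # innovation SD, uV
    erp_templates: tuple = field(default_factory=default_templates)
    n_standard: int = 86
    n_deviant: int = 60              # artefact-free deviant trials per subject
    n_subjects_per_group: int = 8
    burnin_samples: int = 200

    @property
    def order(self) -> int:
        return max(len(self.base_ar), 1)

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def lag_matrices(self, diagnosis: Optional[str] = None,
                     strength_scale: float = 1.0,
                     coupling_on: bool = True) -> np.ndarray:
        """Stacked lag matrices (p, n, n) with couplings on or off.

        The always-on background is a diagonal AR plus a weak directed
        ring (each channel driven by its montage neighbour), both shared
        by all groups; the subject's strength multiplier scales every
        cross-channel coupling (ring and planted edges alike).
        """
        n, p = self.n_channels, self.order
        A = np.zeros((p, n, n))
        for k, a in enumerate(self.base_ar):
            A[k] += a * np.eye(n)
        if self.ring_coupling and n > 1:
            for i in range(n):
                A[0, i, (i - 1) % n] += self.ring_coupling * strength_scale
        if coupling_on and diagnosis is not None:
            for e in self.coupling_edges:
                s = e.strength_by_diagnosis.get(diagnosis, 0.0) * strength_scale
                A[0, self.channel_index(e.sink), self.channel_index(e.source)] += s
        return A

    def validate_stability(self, strength_scale: float = 1.0) -> None:
        for diag in ("MCS", "UWS"):
            if not stability_check(self.lag_matrices(diag, strength_scale)):
                raise ParameterError(
                    f"scenario unstable with couplings on ({diag}, "
                    f"scale={strength_scale})")

    @classmethod
    def desk_scale(cls, **overrides) -> "SimulationScenario":
        """Reduced 10-electrode montage for fast desk-scale replication
        studies; everything else keeps the full-scenario defaults."""
        montage = ("Fz", "F3", "F4", "Cz", "C3", "C4", "Pz", "P3", "P4", "O1")
        return cls(channel_labels=montage, **overrides)


# ---------------------------------------------------------------------------
# epoch simulation


def simulate_subject_epochs(scn: SimulationScenario,
                            group: Tuple[str, str] = ("MCS", "traumatic"),
                            subject_seed: int = 0,
                            strength_scale: float = 1.0,
                            n_standard: Optional[int] = None,
                            n_deviant: Optional[int] = None):
    """Simulate one subject's epoch set plus the planted ground truth.

    Each trial is an innovation-driven sample path of the scenario VAR;
    during deviant trials the coupling edges switch on inside their
    post-stimulus windows.  Condition- and group-gated ERP templates are
    added on top.  Returns ``(EpochSet, ground_truth)`` where the ground
    truth records the coupling schedule and template table for recovery
    tests.
    """
    diagnosis, _aetiology = group
    scn.validate_stability(strength_scale)
    rng = np.random.default_rng(subject_seed)
    n_std = scn.n_standard if n_standard is None else n_standard
    n_dev = scn.n_deviant if n_deviant is None else n_deviant
    n, p = scn.n_channels, scn.order
    n_samp = n_window_samples(scn.window_ms, scn.rate)
    steps = scn.burnin_samples + n_samp

    condition = np.array(["standard"] * n_std + ["deviant"] * n_dev, dtype=object)
    rng.shuffle(condition)
    dev_mask = condition == "deviant"
    T = len(condition)

    times_ms = scn.window_ms[0] + 1000.0 * np.arange(n_samp) / scn.rate
    base = np.asarray(scn.base_ar)
    couplings = []
    for e in scn.coupling_edges:
        s = e.strength_by_diagnosis.get(diagnosis, 0.0) * strength_scale
        lo, hi = e.on_window_ms
        on = (times_ms >= lo - 1e-9) & (times_ms < hi - 1e-9)
        couplings.append((scn.channel_index(e.source), scn.channel_index(e.sink),
                          s, on))

    ring = scn.ring_coupling * strength_scale
    y = np.zeros((T, n, steps))
    noise = rng.standard_normal((T, n, steps)) * scn.noise_std
    for t in range(steps):
        acc = noise[:, :, t].copy()
        for k in range(1, p + 1):
            if t - k >= 0:
                acc += base[k - 1] * y[:, :, t - k]
        if ring and t >= 1 and n > 1:
            acc += ring * np.roll(y[:, :, t - 1], 1, axis=1)
        ep_idx = t - scn.burnin_samples
        if ep_idx >= 0 and t >= 1:
            for src, sink, s, on in couplings:
                if s != 0.0 and on[ep_idx]:
                    acc[dev_mask, sink] += s * y[dev_mask, src, t - 1]
        y[:, :, t] = acc

    data = y[:, :, scn.burnin_samples:]

    # additive ERP templates
    for tpl in scn.erp_templates:
        wave = tpl.waveform(times_ms)
        spat = tpl.spatial(scn.channel_labels)
        bump = spat[:, None] * wave[None, :]
        for cond in ("standard", "deviant"):
            amp = tpl.amplitude(cond, diagnosis)
            if amp != 0.0:
                data[condition == cond] += amp * bump

    ep = EpochSet(data=data, window_ms=scn.window_ms, rate=scn.rate,
                  condition=condition, channel_labels=scn.channel_labels,
                  baseline_window_ms=None)
    truth = {
        "diagnosis": diagnosis,
        "strength_scale": strength_scale,
        "couplings": [
            {"source": e.source, "sink": e.sink,
             "strength": e.strength_by_diagnosis.get(diagnosis, 0.0) * strength_scale,
             "on_window_ms": e.on_window_ms}
            for e in scn.coupling_edges],
        "templates": [
            {"name": tpl.name, "latency_ms": tpl.latency_ms,
             "sigma_ms": tpl.sigma_ms,
             "amp_standard": tpl.amplitude("standard", diagnosis),
             "amp_deviant": tpl.amplitude("deviant", diagnosis)}
            for tpl in scn.erp_templates],
    }
    return ep, truth


def render_recording(scn: SimulationScenario,
                     group: Tuple[str, str] = ("MCS", "traumatic"),
                     subject_seed: int = 0,
                     n_standard: int = 10, n_deviant: int = 5,
                     soa_ms: float = 2200.0,
                     strength_scale: float = 1.0) -> Recording:
    """Continuous recording (plus TP9/TP10 reference channels) with event
    markers, for exercising the full preprocessing chain.

    Trials are simulated as epochs and placed at a fixed stimulus-onset
    asynchrony on a background of reference-channel noise.
    """
    ep, _ = simulate_subject_epochs(scn, group, subject_seed,
                                    strength_scale=strength_scale,
                                    n_standard=n_standard, n_deviant=n_deviant)
    rng = np.random.default_rng((subject_seed, 1))
    soa = int(round(soa_ms * scn.rate / 1000.0))
    pre = n_window_samples((scn.window_ms[0], 0.0), scn.rate)
    n_trials, n_ch, n_samp = ep.data.shape
    total = soa * (n_trials + 1) + n_samp
    labels = scn.channel_labels + ("TP9", "TP10")
    data = rng.standard_normal((len(labels), total)) * scn.noise_std * 0.25
    events = []
    for i in range(n_trials):
        onset = soa * (i + 1)
        a = onset - pre
        data[:n_ch, a:a + n_samp] += ep.data[i]
        events.append((onset, str(ep.condition[i])))
    return Recording(data=data, rate=scn.rate, channel_labels=labels,
                     events=events)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class SyntheticCohort:
    table: CohortTable
    latent_strength: Dict[str, float]      # z-scored latent per patient
    strength_scale: Dict[str, float]       # positive multiplier for couplings
    rho_traumatic: float
    rho_nontraumatic: float


def _decompose_total(total: int) -> tuple:
    """Fixed greedy split of a CRS-R total into schema-valid sub-scores."""
    left = total
    subs = []
    for cap in CRS_SUBSCALE_MAX:
        take = min(cap, left)
        subs.append(take)
        left -= take
    return tuple(subs)


#: Aetiology-group CRS-R total location/spread (the reference cohort's
#: pooled totals are ~7 +- 3); diagnosis follows the behavioural score.
_TOTAL_MEAN = 7.0
_TOTAL_SD = 3.0
_STRENGTH_SD = 0.3


def generate_cohort(n_per_cell: int = 8, rho_traumatic: float = 0.5,
                    rho_nontraumatic: float = 0.0,
                    seed: int = 0) -> SyntheticCohort:
    """Cohort with a planted latent-strength / CRS-R correlation.

    For each aetiology group (2*n_per_cell subjects), latent network
    strength and the CRS-R total are drawn from a bivariate Gaussian with
    the configured per-aetiology correlation.  Diagnosis is assigned by
    ranking totals within the group (the higher-scoring half is MCS), as
    the diagnosis is itself a reading of the behavioural scale.  Totals
    are clipped to [0, 23] and decomposed into schema-valid sub-scores,
    so generated totals always equal their sub-score sums.  The latent
    strength maps to a positive multiplier applied to a subject's
    coupling strengths.
    """
    if n_per_cell < 3:
        raise ParameterError("n_per_cell must be >= 3")
    for rho in (rho_traumatic, rho_nontraumatic):
        if abs(rho) >= 1:
            raise ParameterError("|rho| must be < 1")
    rng = np.random.default_rng(seed)
    records, latent, scale = [], {}, {}
    pid = 0
    aet_cycle = {"traumatic": ("trauma",),
                 "nontraumatic": ("hemorrhage", "anoxia")}
    for grp, rho in (("traumatic", rho_traumatic),
                     ("nontraumatic", rho_nontraumatic)):
        m = 2 * n_per_cell
        cov = np.array([[1.0, rho], [rho, 1.0]])
        zs = rng.multivariate_normal([0.0, 0.0], cov, size=m)
        order = np.argsort(-zs[:, 1])          # high scores first -> MCS half
        for rank, i in enumerate(order):
            pid += 1
            z_strength, z_score = zs[i]
            diagnosis = "MCS" if rank < n_per_cell else "UWS"
            total = int(np.clip(round(_TOTAL_MEAN + _TOTAL_SD * z_score), 0, 23))
            subs = _decompose_total(total)
            patient_id = f"S{pid:02d}"
            rec = PatientRecord(
                patient_id=patient_id,
                diagnosis=diagnosis,
                sex="M" if rng.random() < 0.6 else "F",
                age=int(rng.integers(26, 76)),
                aetiology=aet_cycle[grp][rank % len(aet_cycle[grp])],
                lesion_text="synthetic",
                months_since_injury=float(np.round(rng.uniform(0.5, 11.0), 1)),
                crs_r_sub=subs,
                crs_r_total=sum(subs),
            )
            records.append(rec)
            latent[patient_id] = float(z_strength)
            scale[patient_id] = float(max(0.25, 1.0 + _STRENGTH_SD * z_strength))
    return SyntheticCohort(table=CohortTable(records), latent_strength=latent,
                           strength_scale=scale, rho_traumatic=rho_traumatic,
                           rho_nontraumatic=rho_nontraumatic)


def subject_static_network(scn: SimulationScenario, diagnosis: str,
                           strength_scale: float = 1.0,
                           edge_noise_sd: float = 0.005,
                           rng: Optional[np.random.Generator] = None,
                           freqs_hz=DEFAULT_FREQS_HZ,
                           band_hz=DEFAULT_BAND_HZ) -> TimeVaryingNetwork:
    """Noisy band-integrated network of the subject's stationary VAR.

    The coupling-on lag matrices (scaled by the subject's strength
    multiplier) are pushed through the transfer function and band
    integration, and each edge receives additive estimation noise.  This
    is the fast network model used for cohort-level association studies,
    bypassing the per-trial EEG simulation.
    """
    rng = rng if rng is not None else np.random.default_rng()
    A = scn.lag_matrices(diagnosis, strength_scale)[None]    # single time point
    model = TVMVARModel(order=scn.order, coeffs=A, times=np.array([0]),
                        residual_cov=np.eye(scn.n_channels), uc=0.0,
                        rate=scn.rate, channel_labels=scn.channel_labels)
    w = integrate_band(transfer_function(model, freqs_hz), band_hz)
    w = np.clip(w + rng.normal(0.0, edge_noise_sd, size=w.shape), 0.0, None)
    return TimeVaryingNetwork(w=w, times_ms=np.array([0.0]),
                              band_hz=tuple(band_hz),
                              channel_labels=scn.channel_labels,
                              n_trials_averaged=1)
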