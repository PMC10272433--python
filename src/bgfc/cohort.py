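"""Calibrated synthetic cohort: BOLD-like ROI signals + behaviour tables.

The generator is a generative twin of the study's analysis assumptions,
not a biophysical simulator. Per task state, ROI samples follow a
stationary factor model whose implied correlation matrix hits the
calibrated basal-ganglia coupling targets:

* two cortical modes carry the baseline cortico-cortical correlation and
  the seed-to-cortex (global FC) coupling, with the caudate loading mostly
  on one mode and the putamen/pallidum on the other so that weak
  caudate-putamen coupling can coexist with strong seed-cortex coupling;
* three correlated structure factors carry homotopic coupling and the
  named-pair (local FC) targets;
* independent band-limited residuals complete each region's unit variance.

All latent series are band-limited to the analysis passband before the
state-dependent mixing is applied, so the cleaning filter is close to an
identity on the signal and the within-task sample correlations
concentrate tightly around their targets. Confound signals (WM, CSF, six
motion parameters), broadband white noise and a linear drift are then
added; the standard cleaning pipeline removes them.

Because Pearson correlations of finite filtered segments are slightly
biased and noisy, the generator *self-calibrates*: pilot subjects are run
through the actual cleaning/segmentation/connectivity pipeline to
estimate the small post-pipeline bias and the measurement-noise SD of
every calibrated FC statistic. Targets are offset by the estimated bias,
and the printed between-subject SD is decomposed into subject-level
target jitter plus measurement noise. Behavioural variables are drawn
conditionally on each subject's *realised* post-pipeline FC statistics,
so the FC-behaviour correlation targets are hit without attenuation
corrections.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import signal as scisig

from .atlas import BG_REGIONS, load_aal116
from .behaviour import SubjectBehaviour
from .cleaning import CleaningConfig, NuisanceRegressor, BandpassFilter
from .connectivity import BG_PAIRS, BG_SEEDS, correlation_matrix, fisher_z, local_bg_fc, global_bg_fc
from .containers import ConfoundSet, RoiTimeSeriesSet
from .schedule import ParadigmSchedule, default_schedule, n_volumes_for, segment_by_task

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "PipelineCalibration",
    "calibrate_pipeline",
    "generate_cohort",
    "behaviour_table",
    "plant_rt_outliers",
    "render_nifti_fixture",
    "load_default_calibration",
]

GROUPS = ("HC", "MS")
CONDITIONS = ("handgrip_only", "mental_imagery_first")
PAIRS = tuple(BG_PAIRS)
TASK_LIST = ("T1", "T2", "T3")
#: order of the behaviour-linked FC statistics (alertness tasks x pairs)
Q_STATS = tuple((task, pair) for task in ("T2", "T3") for pair in PAIRS)

_Z_FEASIBLE = 3.8          # |z| + 3*sd beyond this implies |r| >= 0.999
_JITTER_TRUNC = 3.0        # subject jitter truncated at +/- 3 SD
_TRUNC_VAR = 0.97334       # variance of a standard normal truncated at +/- 3
_SIGMA_Z_FLOOR = 0.02


def load_default_calibration() -> dict:
    text = (resources.files("bgfc.data") / "calibration.yaml").read_text()
    return yaml.safe_load(text)


def _deep_update(base: dict, upd: dict) -> dict:
    out = dict(base)
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Complete specification of a synthetic cohort.

    ``coupling``, ``fc_behaviour``, ``behaviour``, ``cohort``, ``noise``
    and ``calibration_pilot`` follow the structure of the packaged
    calibration file (see ``bgfc/data/calibration.yaml``).
    """

    n_hc: int
    n_ms: int
    tr_seconds: float
    schedule: ParadigmSchedule
    coupling: dict
    fc_behaviour: dict
    behaviour: dict
    cohort: dict
    noise: dict
    calibration_pilot: dict
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    seed: int = 42

    @classmethod
    def default(
        cls,
        n_hc: int | None = None,
        n_ms: int | None = None,
        seed: int = 42,
        rt_outliers: dict | None = None,
        overrides: dict | None = None,
        tr_seconds: float = 0.906,
        schedule: ParadigmSchedule | None = None,
    ) -> "CohortSpec":
        cal = load_default_calibration()
        if overrides:
            cal = _deep_update(cal, overrides)
        cohort = dict(cal["cohort"])
        sizes_changed = False
        if n_hc is not None and n_hc != cohort["n_hc"]:
            cohort["n_hc"] = n_hc
            sizes_changed = True
        if n_ms is not None and n_ms != cohort["n_ms"]:
            cohort["n_ms"] = n_ms
            sizes_changed = True
        if rt_outliers is not None:
            cohort["rt_outliers"] = rt_outliers
        elif sizes_changed and "cohort" not in (overrides or {}):
            # the shipped planting counts belong to the default 40+40 fixture
            cohort["rt_outliers"] = {"HC": 0, "MS": 0}
        return cls(
            n_hc=int(cohort["n_hc"]),
            n_ms=int(cohort["n_ms"]),
            tr_seconds=tr_seconds,
            schedule=schedule or default_schedule(tr_seconds),
            coupling=cal["coupling"],
            fc_behaviour=cal["fc_behaviour"],
            behaviour=cal["behaviour"],
            cohort=cohort,
            noise=cal["noise"],
            calibration_pilot=cal["calibration_pilot"],
            seed=seed,
        )

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_ms < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        for group in GROUPS:
            for task, pairs in self.coupling["local"][group].items():
                for pair, entry in pairs.items():
                    z, sd = float(entry["z"]), float(entry["sd"])
                    if not np.isfinite(z):
                        raise ValueError(f"non-finite coupling target ({group},{task},{pair})")
                    if sd < 0:
                        raise ValueError(f"negative coupling SD ({group},{task},{pair})")
                    if abs(z) + 3 * sd > _Z_FEASIBLE:
                        raise ValueError(
                            f"coupling target ({group},{task},{pair}) z={z}+-{sd} implies "
                            f"|r| >= 1 within the jitter range; rejected"
                        )

    def n_of(self, group: str) -> int:
        return self.n_hc if group == "HC" else self.n_ms

    def condition_counts(self, group: str) -> tuple[int, int]:
        n = self.n_of(group)
        split = self.cohort.get("condition_split", {}).get(group)
        if split and sum(split) == n:
            return int(split[0]), int(split[1])
        return (n + 1) // 2, n // 2

    def local_z(self, group: str, task: str, pair: str) -> tuple[float, float]:
        e = self.coupling["local"][group][task][pair]
        return float(e["z"]), float(e["sd"])

    def global_z(self, group: str, task: str, structure: str) -> float:
        return float(self.coupling["global"][group][task][structure])

    def content_key(self) -> str:
        payload = {
            "n_hc": self.n_hc,
            "n_ms": self.n_ms,
            "tr": self.tr_seconds,
            "schedule": self.schedule.to_frame().to_dict("records"),
            "coupling": self.coupling,
            "fc_behaviour": self.fc_behaviour,
            "behaviour": self.behaviour,
            "cohort": self.cohort,
            "noise": self.noise,
            "pilot": self.calibration_pilot,
            "cleaning": (
                self.cleaning.band_low_hz,
                self.cleaning.band_high_hz,
                self.cleaning.filter_order,
                self.cleaning.detrend,
            ),
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    group: str
    condition: str
    behaviour: SubjectBehaviour
    roi_timeseries: RoiTimeSeriesSet | None = None
    confounds: ConfoundSet | None = None


# ---------------------------------------------------------------------------
# signal model
# ---------------------------------------------------------------------------

_NAMES = load_aal116().names
_BG_IDX = {name: _NAMES.index(name) for name in BG_REGIONS}
_STRUCT_IDX = {
    "ca": [_BG_IDX["Caudate_L"], _BG_IDX["Caudate_R"]],
    "pu": [_BG_IDX["Putamen_L"], _BG_IDX["Putamen_R"]],
    "pa": [_BG_IDX["Pallidum_L"], _BG_IDX["Pallidum_R"]],
}
_STRUCT_OF = {"Caudate": "ca", "Putamen": "pu", "Pallidum": "pa"}
_PAIR_STRUCTS = {"Caudate-Putamen": ("ca", "pu"), "Caudate-Pallidum": ("ca", "pa"),
                 "Putamen-Pallidum": ("pu", "pa")}
_N_REGIONS = 116
_CORTEX = np.array([i for i in range(_N_REGIONS) if i not in _BG_IDX.values()])
_C_SPLIT = 0.15  # minor-mode loading shared by all three structures


def _factor_loadings(r_cc: float, r_gc: dict, r_h: float, r_pairs: dict) -> tuple[np.ndarray, np.ndarray]:
    """Loadings (116 x 5 iid factors) + residual SDs realising the targets.

    Factors: two cortical modes (A carrying mostly caudate coupling, B
    mostly putamen/pallidum), then the Cholesky-mixed structure factors.
    """
    bb = np.sqrt(max(r_cc, 1e-12) / 2.0)
    S = {s: r_gc[s] / bb for s in ("ca", "pu", "pa")}
    cvec = {
        "ca": np.array([S["ca"] - _C_SPLIT, _C_SPLIT]),
        "pu": np.array([_C_SPLIT, S["pu"] - _C_SPLIT]),
        "pa": np.array([_C_SPLIT, S["pa"] - _C_SPLIT]),
    }
    u = {}
    for s in ("ca", "pu", "pa"):
        u[s] = np.sqrt(max(r_h - float(cvec[s] @ cvec[s]), 1e-4))
    rho = {}
    for pair, (s1, s2) in _PAIR_STRUCTS.items():
        induced = float(cvec[s1] @ cvec[s2])
        rho[pair] = float(np.clip((r_pairs[pair] - induced) / (u[s1] * u[s2]), -0.95, 0.95))
    Rh = np.array([
        [1.0, rho["Caudate-Putamen"], rho["Caudate-Pallidum"]],
        [rho["Caudate-Putamen"], 1.0, rho["Putamen-Pallidum"]],
        [rho["Caudate-Pallidum"], rho["Putamen-Pallidum"], 1.0],
    ])
    ev, V = np.linalg.eigh(Rh)
    if ev[0] < 1e-8:
        ev = np.clip(ev, 1e-8, None)
        Rh = V @ np.diag(ev) @ V.T
        d = np.sqrt(np.diag(Rh))
        Rh = Rh / np.outer(d, d)
    Lh = np.linalg.cholesky(Rh)
    Lam = np.zeros((_N_REGIONS, 5))
    Lam[_CORTEX, 0] = bb
    Lam[_CORTEX, 1] = bb
    for si, s in enumerate(("ca", "pu", "pa")):
        for i in _STRUCT_IDX[s]:
            Lam[i, :2] = cvec[s]
            Lam[i, 2:] = u[s] * Lh[si]
    w = np.sqrt(np.clip(1.0 - np.einsum("ij,ij->i", Lam, Lam), 1e-4, None))
    return Lam, w


def _state_models(spec: CohortSpec, group: str, z_local: dict, z_global: dict):
    """Loadings per state from Fisher-z targets.

    ``z_local[(task, pair)]`` and ``z_global[(task, structure)]`` hold the
    (possibly bias-adjusted, jittered) targets on the z scale.
    """
    r_cc = float(spec.coupling["cortex_cortex_r"])
    r_h = float(spec.coupling["homotopic_r"])
    models = {}
    for task in TASK_LIST:
        r_gc = {_STRUCT_OF[s]: float(np.tanh(z_global[(task, s)])) for s in _STRUCT_OF}
        r_pairs = {p: float(np.tanh(z_local[(task, p)])) for p in PAIRS}
        models[task] = _factor_loadings(r_cc, r_gc, r_h, r_pairs)
    rest_local = spec.coupling.get("rest_local_z", {})
    r_pairs = {p: float(np.tanh(float(rest_local.get(p, 0.2)))) for p in PAIRS}
    r_gc = {_STRUCT_OF[s]: float(np.tanh(z_global[("T2", s)])) for s in _STRUCT_OF}
    models["rest"] = _factor_loadings(r_cc, r_gc, r_h, r_pairs)
    return models


_LAYOUT_CACHE: dict = {}


def _scan_layout(spec: CohortSpec) -> "_ScanLayout":
    key = (
        spec.tr_seconds,
        tuple(spec.schedule.entries),
        spec.cleaning.band_low_hz,
        spec.cleaning.band_high_hz,
        spec.cleaning.filter_order,
    )
    if key not in _LAYOUT_CACHE:
        _LAYOUT_CACHE[key] = _ScanLayout(spec)
    return _LAYOUT_CACHE[key]


class _ScanLayout:
    """Volume-level state labels and filter constants for one spec."""

    def __init__(self, spec: CohortSpec):
        self.tr = spec.tr_seconds
        self.n_vol = n_volumes_for(spec.schedule, self.tr)
        state = np.array(["rest"] * self.n_vol, dtype=object)
        for e in spec.schedule.entries:
            start = int(np.floor(e.onset_s / self.tr + 1e-9))
            stop = int(np.floor((e.onset_s + e.duration_s) / self.tr + 1e-9))
            state[start:stop] = e.task
        self.state_masks = {s: state == s for s in ("rest",) + TASK_LIST}
        nyq = 0.5 / self.tr
        cfg = spec.cleaning
        self.ba = scisig.butter(
            cfg.filter_order, [cfg.band_low_hz / nyq, cfg.band_high_hz / nyq], btype="band"
        )
        # unit-variance scale for band-limited innovations
        probe = scisig.filtfilt(*self.ba, np.random.default_rng(0).standard_normal(1 << 17))
        self.band_scale = 1.0 / probe.std()

    def bandlimited(self, rng: np.random.Generator, shape) -> np.ndarray:
        x = rng.standard_normal(shape)
        return scisig.filtfilt(*self.ba, x, axis=0) * self.band_scale


def _generate_signal(
    rng: np.random.Generator,
    layout: _ScanLayout,
    models: dict,
    noise: dict,
) -> tuple[np.ndarray, ConfoundSet]:
    T = layout.n_vol
    # one stacked filtering pass: 5 factors + 116 residuals + wm + csf
    band = layout.bandlimited(rng, (T, 5 + _N_REGIONS + 2))
    f = band[:, :5]
    eps = band[:, 5:5 + _N_REGIONS]
    y = np.empty((T, _N_REGIONS))
    for st, mask in layout.state_masks.items():
        if not mask.any():
            continue
        Lam, w = models[st]
        y[mask] = f[mask] @ Lam.T + eps[mask] * w
    wm = band[:, -2:-1]
    csf = band[:, -1:]
    motion = np.cumsum(rng.standard_normal((T, 6)) * float(noise["motion_step_sd"]), axis=0)
    conf = np.column_stack([wm, csf, motion])
    mix = rng.standard_normal((8, _N_REGIONS)) * float(noise["confound_mix_sd"])
    y = y + conf @ mix
    y += rng.standard_normal((T, _N_REGIONS)) * float(noise["white_noise_sd"])
    y += np.outer(np.linspace(-1.0, 1.0, T), rng.standard_normal(_N_REGIONS) * float(noise["drift_sd"]))
    return y, ConfoundSet(conf[:, 0], conf[:, 1], motion)


def _fc_stats(spec: CohortSpec, data: np.ndarray, confounds: ConfoundSet,
              tasks: tuple[str, ...] | None = None) -> dict:
    """Run the standard cleaning/segmentation/connectivity pipeline and
    return every calibrated FC statistic of one subject."""
    reg = NuisanceRegressor().fit(data, confounds=confounds)
    resid = reg.transform(data)
    filt = BandpassFilter(
        spec.tr_seconds,
        spec.cleaning.band_low_hz,
        spec.cleaning.band_high_hz,
        spec.cleaning.filter_order,
        spec.cleaning.detrend,
    ).fit()
    cleaned = filt.transform(resid)
    out = {}
    for task in (tasks or spec.schedule.tasks):
        seg = segment_by_task(cleaned, spec.schedule, task, spec.tr_seconds)
        z = fisher_z(correlation_matrix(seg, _NAMES))
        for pair in PAIRS:
            out[("local", task, pair)] = local_bg_fc(z, pair)
        for seed_name in BG_SEEDS:
            out[("global", task, seed_name)] = global_bg_fc(z, seed_name)
    return out


# ---------------------------------------------------------------------------
# pipeline self-calibration
# ---------------------------------------------------------------------------

def _u_correlation(spec: CohortSpec) -> np.ndarray:
    """Correlation of the six pair-jitter latents (Q_STATS order)."""
    free = spec.behaviour["free_corr"]
    within = float(free["fc_within_task"])
    across = float(free["fc_across_task"])
    R = np.full((6, 6), across)
    for t0 in (0, 3):
        R[t0:t0 + 3, t0:t0 + 3] = within
    np.fill_diagonal(R, 1.0)
    return R


@dataclass(frozen=True)
class PipelineCalibration:
    """Pilot-estimated correction constants, per group.

    ``z_adj[group][(kind, task, name)]`` are bias-adjusted Fisher-z
    targets; ``sigma_z[group][(task, pair)]`` the subject-level jitter SD
    after removing measurement noise from the printed between-subject SD;
    ``q_mu/q_sd/R_q`` the realised moments of the behaviour-linked FC
    statistics (Q_STATS order).
    """

    z_adj: dict
    sigma_z: dict
    sigma_m: dict
    q_mu: dict
    q_sd: dict
    R_q: dict


_CAL_CACHE: dict[str, PipelineCalibration] = {}


def _base_targets(spec: CohortSpec, group: str) -> dict:
    t = {}
    for task in TASK_LIST:
        for pair in PAIRS:
            t[("local", task, pair)] = spec.local_z(group, task, pair)[0]
        for s in _STRUCT_OF:
            t[("global", task, s)] = spec.global_z(group, task, s)
    return t


def _targets_to_models(spec: CohortSpec, group: str, targets: dict, jitter: dict | None = None):
    z_local = {}
    z_global = {}
    for task in TASK_LIST:
        for pair in PAIRS:
            z = targets[("local", task, pair)]
            if jitter:
                z = z + jitter.get((task, pair), 0.0)
            z_local[(task, pair)] = z
        for s in _STRUCT_OF:
            z_global[(task, s)] = targets[("global", task, s)]
    return _state_models(spec, group, z_local, z_global)


def _run_pilot(
    spec: CohortSpec,
    layout: _ScanLayout,
    group: str,
    targets: dict,
    m: int,
    ss: np.random.SeedSequence,
    sigma_z: dict | None,
    R_u: np.ndarray | None,
) -> pd.DataFrame:
    rows = []
    children = ss.spawn(m)
    Lu = np.linalg.cholesky(R_u) if R_u is not None else None
    models_nojitter = None if sigma_z else _targets_to_models(spec, group, targets)
    for child in children:
        rng = np.random.default_rng(child)
        if sigma_z:
            u = np.clip(Lu @ rng.standard_normal(6), -_JITTER_TRUNC, _JITTER_TRUNC)
            jitter = {
                (task, pair): sigma_z[(task, pair)] * u[k]
                for k, (task, pair) in enumerate(Q_STATS)
            }
            models = _targets_to_models(spec, group, targets, jitter)
        else:
            models = models_nojitter
        y, conf = _generate_signal(rng, layout, models, spec.noise)
        rows.append(_fc_stats(spec, y, conf))
    return pd.DataFrame(rows)


def calibrate_pipeline(spec: CohortSpec, groups: tuple[str, ...] = GROUPS) -> PipelineCalibration:
    """Estimate bias/measurement-noise corrections by pilot simulation.

    Deterministic given ``spec`` (the pilot stream is seeded from
    ``spec.seed``), and cached per spec content so replicate cohorts share
    one calibration.
    """
    key = spec.content_key() + "/" + ",".join(sorted(groups))
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    layout = _scan_layout(spec)
    slope = float(spec.calibration_pilot.get("damped_slope", 0.85))
    m1 = int(spec.calibration_pilot.get("n_round1", 192))
    m2 = int(spec.calibration_pilot.get("n_round2", 256))
    R_u = _u_correlation(spec)
    z_adj: dict = {}
    sigma_z: dict = {}
    sigma_m: dict = {}
    q_mu: dict = {}
    q_sd: dict = {}
    R_q: dict = {}
    for gi, group in enumerate(groups):
        base = _base_targets(spec, group)
        ss1 = np.random.SeedSequence([int(spec.seed) % (1 << 31), 101, gi])
        stats1 = _run_pilot(spec, layout, group, base, m1, ss1, None, None)
        adj = {k: base[k] - (stats1[k].mean() - base[k]) / slope for k in base}
        sm = {k: float(stats1[k].std(ddof=1)) for k in base}
        sz = {}
        for task, pair in Q_STATS:
            cal_sd = spec.local_z(group, task, pair)[1]
            sz[(task, pair)] = float(
                np.sqrt(max(cal_sd**2 - sm[("local", task, pair)] ** 2, _SIGMA_Z_FLOOR**2))
            )
        ss2 = np.random.SeedSequence([int(spec.seed) % (1 << 31), 202, gi])
        stats2 = _run_pilot(spec, layout, group, adj, m2, ss2, sz, R_u)
        final = {k: adj[k] - (stats2[k].mean() - base[k]) / slope for k in base}
        qcols = [("local", task, pair) for task, pair in Q_STATS]
        qf = stats2[qcols]
        shift = np.array([final[c] - adj[c] for c in qcols])
        z_adj[group] = final
        sigma_z[group] = sz
        sigma_m[group] = sm
        q_mu[group] = qf.mean().to_numpy() + shift
        # decompose the covariance of the q statistics into measurement
        # covariance (estimated from both pilot rounds; round 2 after
        # subtracting the jitter part, which is known analytically from
        # sigma_z and the jitter correlation R_u) plus that jitter part.
        # This pools all pilots for the noisy component while keeping the
        # designed component exact.
        D = np.diag([sz[qs] for qs in Q_STATS])
        jitter_cov = _TRUNC_VAR * (D @ R_u @ D)
        C1 = np.cov(stats1[qcols].to_numpy(), rowvar=False)
        C2 = np.cov(qf.to_numpy(), rowvar=False) - jitter_cov
        Cm = (m1 * C1 + m2 * C2) / (m1 + m2)
        Ctot = Cm + jitter_cov
        ev, V = np.linalg.eigh((Ctot + Ctot.T) / 2.0)
        Ctot = V @ np.diag(np.clip(ev, 1e-8, None)) @ V.T
        sd_tot = np.sqrt(np.diag(Ctot))
        q_sd[group] = sd_tot
        R_q[group] = Ctot / np.outer(sd_tot, sd_tot)
    cal = PipelineCalibration(z_adj, sigma_z, sigma_m, q_mu, q_sd, R_q)
    _CAL_CACHE[key] = cal
    return cal


# ---------------------------------------------------------------------------
# behavioural design
# ---------------------------------------------------------------------------

_BVARS = ("fss", "rt_t2", "rt_t3", "force_t2", "force_t3")


def _force_block_means(spec: CohortSpec, group: str, condition: str, task: str) -> np.ndarray:
    if task == "T1":
        # self-paced control task: use the mean of the two alertness tasks
        a = _force_block_means(spec, group, condition, "T2")
        b = _force_block_means(spec, group, condition, "T3")
        return (a + b) / 2.0
    m1, m4 = spec.behaviour["force_block_means_high"][group][condition][task]
    return np.linspace(float(m1), float(m4), 4)


def _rt_block_means(spec: CohortSpec, group: str, condition: str, task: str) -> np.ndarray:
    return np.asarray(spec.behaviour["rt_block_means_ms"][group][condition][task], dtype=float)


def _grand_moments(spec: CohortSpec, group: str, var: str) -> tuple[float, float]:
    """Population mean and variance of a measured grand behaviour variable."""
    beh = spec.behaviour
    counts = spec.condition_counts(group)
    wts = np.array(counts, dtype=float) / sum(counts)
    task = "T2" if var.endswith("t2") else "T3"
    if var.startswith("rt"):
        mm = [float(_rt_block_means(spec, group, c, task).mean()) for c in CONDITIONS]
        sigma = float(beh["rt_subject_sd_ms"])
        block_noise = float(beh["rt_block_noise_sd_ms"])
    else:
        mm = [float(_force_block_means(spec, group, c, task).mean()) for c in CONDITIONS]
        sigma = float(beh["force_subject_sd"])
        block_noise = float(beh["force_block_noise_sd"])
    mu = float(wts @ np.asarray(mm))
    var_cond = float(wts @ (np.asarray(mm) - mu) ** 2)
    return mu, sigma**2 + block_noise**2 / 4.0 + var_cond


def _solve_within_lambda(spec: CohortSpec, var: str) -> float:
    """Within-group FSS-behaviour latent correlation matching the pooled
    target given the between-group mean gaps (closed form)."""
    key = {"rt_t2": "fss_rt_t2", "rt_t3": "fss_rt_t3",
           "force_t2": "fss_force_t2", "force_t3": "fss_force_t3"}[var]
    rho = float(spec.behaviour["pooled_corr"][key])
    n = {g: spec.n_of(g) for g in GROUPS}
    w = {g: n[g] / (n["HC"] + n["MS"]) for g in GROUPS}
    fss = spec.behaviour["fss"]
    mu_f = {g: float(fss[g]["mean"]) for g in GROUPS}
    sd_f = {g: float(fss[g]["sd"]) for g in GROUPS}
    sigma_v = float(
        spec.behaviour["rt_subject_sd_ms"] if var.startswith("rt") else spec.behaviour["force_subject_sd"]
    )
    mu_v, var_v = {}, {}
    for g in GROUPS:
        mu_v[g], var_v[g] = _grand_moments(spec, g, var)
    fbar = sum(w[g] * mu_f[g] for g in GROUPS)
    vbar = sum(w[g] * mu_v[g] for g in GROUPS)
    B = sum(w[g] * (mu_f[g] - fbar) * (mu_v[g] - vbar) for g in GROUPS)
    var_f_tot = sum(w[g] * (sd_f[g] ** 2 + (mu_f[g] - fbar) ** 2) for g in GROUPS)
    var_v_tot = sum(w[g] * (var_v[g] + (mu_v[g] - vbar) ** 2) for g in GROUPS)
    denom = sigma_v * sum(w[g] * sd_f[g] for g in GROUPS)
    lam = (rho * np.sqrt(var_f_tot * var_v_tot) - B) / denom
    if abs(lam) > 0.95:
        warnings.warn(
            f"pooled target {key}={rho} requires within-group correlation {lam:.2f}; capped"
        )
        lam = float(np.clip(lam, -0.95, 0.95))
    return float(lam)


def _behaviour_latent_corr(spec: CohortSpec) -> np.ndarray:
    """5x5 latent correlation of (fss, rt_t2, rt_t3, force_t2, force_t3)."""
    free = spec.behaviour["free_corr"]
    C = np.eye(5)
    lam = {v: _solve_within_lambda(spec, v) for v in _BVARS[1:]}
    order = {v: i for i, v in enumerate(_BVARS)}
    def put(a, b, v):
        C[order[a], order[b]] = C[order[b], order[a]] = v
    put("fss", "rt_t2", lam["rt_t2"])
    put("fss", "rt_t3", lam["rt_t3"])
    put("fss", "force_t2", lam["force_t2"])
    put("fss", "force_t3", lam["force_t3"])
    put("rt_t2", "rt_t3", float(free["rt_t2_rt_t3"]))
    put("force_t2", "force_t3", float(free["force_t2_force_t3"]))
    for a in ("rt_t2", "rt_t3"):
        for bvar in ("force_t2", "force_t3"):
            put(a, bvar, float(free["rt_force"]))
    return C


def _gamma_matrix(spec: CohortSpec, group: str) -> np.ndarray:
    """5x6 latent cross-correlation between behaviour latents and the
    standardised FC statistics, inflated for the measurement/condition
    variance on the behaviour side so the *measured* correlations hit the
    calibration targets."""
    G = np.zeros((5, 6))
    for col, (task, pair) in enumerate(Q_STATS):
        targets = spec.fc_behaviour[group][task][pair]  # (fss, rt2, rt3, f2, f3)
        for row, var in enumerate(_BVARS):
            target = float(targets[row])
            if var == "fss":
                infl = 1.0
            else:
                sigma = float(
                    spec.behaviour["rt_subject_sd_ms"] if var.startswith("rt")
                    else spec.behaviour["force_subject_sd"]
                )
                _, var_tot = _grand_moments(spec, group, var)
                infl = np.sqrt(var_tot) / sigma
            G[row, col] = float(np.clip(target * infl, -0.95, 0.95))
    return G


@dataclass(frozen=True)
class _BehaviourSampler:
    """Per-group conditional sampler of the behaviour latents given q."""

    M: np.ndarray       # 5x6 regression of latents on standardised q
    L: np.ndarray       # 5x5 residual Cholesky factor
    C_b: np.ndarray

    @classmethod
    def build(cls, spec: CohortSpec, group: str, R_q: np.ndarray | None) -> "_BehaviourSampler":
        C_b = _behaviour_latent_corr(spec)
        if R_q is None:
            M = np.zeros((5, 6))
            resid = C_b
        else:
            G = _gamma_matrix(spec, group)
            Rinv = np.linalg.pinv(R_q)
            M = G @ Rinv
            resid = C_b - G @ Rinv @ G.T
        ev, V = np.linalg.eigh((resid + resid.T) / 2.0)
        if ev[0] < 1e-8:
            ev = np.clip(ev, 1e-8, None)
        L = V @ np.diag(np.sqrt(ev))
        return cls(M, L, C_b)

    def draw(self, rng: np.random.Generator, q_std: np.ndarray | None) -> np.ndarray:
        nu = rng.standard_normal(5)
        if q_std is None:
            if self.M.any():
                raise ValueError("sampler was built conditionally; q is required")
            return self.L @ nu
        return self.M @ q_std + self.L @ nu


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _subject_behaviour(
    spec: CohortSpec,
    rng: np.random.Generator,
    group: str,
    condition: str,
    subject_id: str,
    eta: np.ndarray,
) -> SubjectBehaviour:
    beh = spec.behaviour
    fss_cfg = beh["fss"][group]
    fss = float(np.clip(fss_cfg["mean"] + fss_cfg["sd"] * eta[0], 9.0, 63.0))
    hads_cfg = beh["hads"]
    hads = np.clip(hads_cfg["mean"] + hads_cfg["sd"] * rng.standard_normal(2), 0.0, 21.0)
    rt_sd = float(beh["rt_subject_sd_ms"])
    rt_noise = float(beh["rt_block_noise_sd_ms"])
    f_sd = float(beh["force_subject_sd"])
    f_noise = float(beh["force_block_noise_sd"])
    fractions = beh["force_level_fractions"]
    rt_ms = {}
    force = {}
    eta_rt = {"T2": eta[1], "T3": eta[2]}
    eta_f = {"T2": eta[3], "T3": eta[4], "T1": (eta[3] + eta[4]) / 2.0}
    for task in ("T2", "T3"):
        means = _rt_block_means(spec, group, condition, task)
        for blk in range(1, 5):
            val = means[blk - 1] + rt_sd * eta_rt[task] + rt_noise * rng.standard_normal()
            rt_ms[(task, blk)] = float(max(val, 80.0))
    for task in TASK_LIST:
        means = _force_block_means(spec, group, condition, task)
        for blk in range(1, 5):
            high = means[blk - 1] + f_sd * eta_f[task] + f_noise * rng.standard_normal()
            high = float(max(high, 0.5))
            force[(task, blk, "high")] = high
            force[(task, blk, "low")] = float(fractions["low"]) * high
            force[(task, blk, "medium")] = float(fractions["medium"]) * high
    return SubjectBehaviour(
        subject_id=subject_id,
        group=group,
        condition=condition,
        rt_ms=rt_ms,
        force=force,
        fss_total=fss,
        hads_anxiety=float(hads[0]),
        hads_depression=float(hads[1]),
    )


def generate_cohort(
    spec: CohortSpec,
    seed: int | None = None,
    include_imaging: bool = True,
    calibration: PipelineCalibration | None = None,
    groups: tuple[str, ...] = GROUPS,
) -> list[SyntheticSubject]:
    """Generate the full synthetic cohort (deterministic given seed).

    With ``include_imaging`` the ROI time series are generated, passed
    through the standard cleaning pipeline internally, and the behavioural
    variables are drawn conditionally on the realised FC statistics. In
    behaviour-only mode (``include_imaging=False``) the behavioural
    correlation structure is realised directly; no imaging data or pilot
    calibration is needed.

    RT outliers configured in ``spec.cohort['rt_outliers']`` are planted
    via :func:`plant_rt_outliers` semantics as part of generation.
    """
    seed = int(spec.seed if seed is None else seed) % (1 << 31)
    groups_present = tuple(g for g in GROUPS if spec.n_of(g) > 0 and g in groups)
    if include_imaging:
        calibration = calibration or calibrate_pipeline(spec, groups_present)
        layout = _scan_layout(spec)
    R_u = _u_correlation(spec)
    Lu = np.linalg.cholesky(R_u)
    subjects: list[SyntheticSubject] = []
    for gi, group in enumerate(groups_present):
        n = spec.n_of(group)
        counts = spec.condition_counts(group)
        conditions = [CONDITIONS[0]] * counts[0] + [CONDITIONS[1]] * counts[1]
        sampler = _BehaviourSampler.build(
            spec, group, calibration.R_q[group] if include_imaging else None
        )
        if include_imaging:
            final = calibration.z_adj[group]
            sz = calibration.sigma_z[group]
            q_mu = calibration.q_mu[group]
            q_sd = calibration.q_sd[group]
        for i in range(n):
            sid = f"{group}{i + 1:03d}"
            rng = np.random.default_rng(np.random.SeedSequence([seed, 7000 + gi, i]))
            ts = conf = None
            q_std = None
            if include_imaging:
                u = np.clip(Lu @ rng.standard_normal(6), -_JITTER_TRUNC, _JITTER_TRUNC)
                jitter = {
                    (task, pair): sz[(task, pair)] * u[k]
                    for k, (task, pair) in enumerate(Q_STATS)
                }
                models = _targets_to_models(spec, group, final, jitter)
                y, conf = _generate_signal(rng, layout, models, spec.noise)
                stats = _fc_stats(spec, y, conf, tasks=("T2", "T3"))
                q_raw = np.array([stats[("local", t, p)] for t, p in Q_STATS])
                q_std = (q_raw - q_mu) / q_sd
                ts = RoiTimeSeriesSet(y, spec.tr_seconds, _NAMES)
            eta = sampler.draw(rng, q_std)
            beh = _subject_behaviour(spec, rng, group, conditions[i], sid, eta)
            subjects.append(SyntheticSubject(sid, group, conditions[i], beh, ts, conf))
    outliers = spec.cohort.get("rt_outliers") or {}
    if any(int(outliers.get(g, 0)) > 0 for g in GROUPS):
        split = spec.cohort.get("outlier_condition_split")
        if split and any(
            sum(split.get(g, [0])) != int(outliers.get(g, 0)) for g in GROUPS if g in split
        ):
            split = None  # counts were overridden; fall back to unconstrained picks
        table = behaviour_table(subjects)
        planted = plant_rt_outliers(
            table,
            {g: int(outliers.get(g, 0)) for g in GROUPS},
            seed=seed,
            condition_split=split,
        )
        subjects = _apply_table_rts(subjects, planted)
    return subjects


def behaviour_table(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    """Tidy cohort behaviour table (one row per subject x task x block)."""
    rows = []
    for s in subjects:
        b = s.behaviour
        for task in TASK_LIST:
            for blk in range(1, 5):
                rt = b.rt_ms.get((task, blk), np.nan)
                rows.append({
                    "subject": s.subject_id,
                    "group": s.group,
                    "condition": s.condition,
                    "task": task,
                    "block": blk,
                    "mean_rt_ms": rt,
                    "mean_peak_force": b.force[(task, blk, "high")],
                    "force_low": b.force[(task, blk, "low")],
                    "force_medium": b.force[(task, blk, "medium")],
                    "fss": b.fss_total,
                    "hads_anx": b.hads_anxiety,
                    "hads_dep": b.hads_depression,
                })
    return pd.DataFrame(rows)


def _apply_table_rts(subjects: list[SyntheticSubject], table: pd.DataFrame) -> list[SyntheticSubject]:
    out = []
    for s in subjects:
        sel = table[(table["subject"] == s.subject_id) & table["task"].isin(("T2", "T3"))]
        rt_ms = dict(s.behaviour.rt_ms)
        for row in sel.itertuples():
            rt_ms[(row.task, int(row.block))] = float(row.mean_rt_ms)
        beh = replace(s.behaviour, rt_ms=rt_ms)
        out.append(replace(s, behaviour=beh))
    return out


def plant_rt_outliers(
    table: pd.DataFrame,
    n_outliers_per_group: dict | int,
    seed: int = 0,
    k_sd: float = 2.0,
    condition_split: dict | None = None,
) -> pd.DataFrame:
    """Plant exactly-n RT outliers per group, above and below the mean.

    Chosen subjects get their grand-mean RT shifted beyond ``k_sd`` group
    SDs such that, with the group statistics recomputed *after* planting,
    the +/-k SD filter flags exactly the planted subjects. Raises if no
    placement magnitude achieves that (tiny or pathological groups).
    """
    from .behaviour import subject_grand_rt

    if isinstance(n_outliers_per_group, int):
        n_outliers_per_group = {g: n_outliers_per_group for g in GROUPS}
    table = table.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (1 << 31), 515]))
    groups = table.drop_duplicates("subject").set_index("subject")[["group", "condition"]]
    for group in GROUPS:
        n_out = int(n_outliers_per_group.get(group, 0))
        if n_out == 0:
            continue
        members = groups[groups["group"] == group]
        if n_out >= len(members):
            raise ValueError(f"cannot plant {n_out} outliers in a group of {len(members)}")
        if condition_split and group in condition_split:
            if sum(condition_split[group]) != n_out:
                raise ValueError(
                    f"outlier condition split {condition_split[group]} does not sum "
                    f"to the requested {n_out} outliers for group {group}"
                )
            picks = []
            for cond, k in zip(CONDITIONS, condition_split[group]):
                pool = members[members["condition"] == cond].index.to_numpy()
                if int(k) > len(pool):
                    raise ValueError(f"not enough {cond} subjects in {group} to plant {k}")
                picks.extend(rng.choice(pool, size=int(k), replace=False))
        else:
            picks = list(rng.choice(members.index.to_numpy(), size=n_out, replace=False))
        grand = subject_grand_rt(table)
        ids = [s for s in members.index if s in grand.index]
        clean_ids = [s for s in ids if s not in picks]
        mean0 = float(grand.loc[clean_ids].mean())
        sd0 = float(grand.loc[clean_ids].std(ddof=1))
        if sd0 == 0:
            raise ValueError(f"degenerate RT distribution in group {group}")
        signs = [1 if j % 2 == 0 else -1 for j in range(len(picks))]
        for c in np.arange(3.5, 8.01, 0.5):
            trial = table.copy()
            for subj, sign in zip(picks, signs):
                target = mean0 + sign * c * sd0
                if target < 100.0:
                    target = mean0 + c * sd0  # keep RT physical; plant above instead
                offset = target - float(grand.loc[subj])
                mask = (trial["subject"] == subj) & trial["task"].isin(("T2", "T3"))
                trial.loc[mask, "mean_rt_ms"] = trial.loc[mask, "mean_rt_ms"] + offset
            g1 = subject_grand_rt(trial).loc[ids]
            m1, s1 = float(g1.mean()), float(g1.std(ddof=1))
            flagged = set(g1.index[np.abs((g1 - m1) / s1) > k_sd])
            if flagged == set(picks):
                table = trial
                break
        else:
            raise ValueError(f"could not plant {n_out} detectable outliers in group {group}")
    return table


# ---------------------------------------------------------------------------
# NIfTI fixture rendering
# ---------------------------------------------------------------------------

def render_nifti_fixture(
    subject: SyntheticSubject,
    shape: tuple[int, int, int] = (6, 5, 4),
    voxel_noise_sd: float = 0.0,
    layout: dict | None = None,
    seed: int = 0,
):
    """Render a subject as a tiny 4-D NIfTI plus label image and masks.

    Every atlas label receives at least one voxel (by default the first
    116 voxels in C order); voxel series equal the ROI series plus
    optional voxel noise, so extraction round-trips exactly at zero
    noise. Two spare voxels carry the WM and CSF confound series and are
    marked in the returned tissue masks.

    ``layout`` may map label values to lists of voxel index triples; it
    must cover all 116 labels (missing labels are reported by name).
    """
    import nibabel as nib

    if subject.roi_timeseries is None:
        raise ValueError("subject has no imaging data")
    table = load_aal116()
    n_vox = int(np.prod(shape))
    if layout is None:
        if n_vox < 118:
            raise ValueError(f"grid {shape} too small for 116 labels + 2 mask voxels")
        layout = {value: [j] for j, value in enumerate(table.labels)}
        flat_extra = {"wm": 116, "csf": 117}
    else:
        missing = [name for value, name in zip(table.labels, table.names) if value not in layout]
        if missing:
            raise ValueError(f"layout misses labels for regions: {missing[:8]}")
        used = {v for voxels in layout.values() for v in np.ravel_multi_index(
            np.asarray(voxels).T, shape)} if layout else set()
        free = [v for v in range(n_vox) if v not in used]
        if len(free) < 2:
            raise ValueError("no free voxels left for WM/CSF mask")
        flat_extra = {"wm": free[0], "csf": free[1]}
        layout = {
            value: list(np.ravel_multi_index(np.asarray(voxels).T, shape))
            for value, voxels in layout.items()
        }
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (1 << 31), 99]))
    ts = subject.roi_timeseries
    T = ts.n_volumes
    label_flat = np.zeros(n_vox, dtype=np.int32)
    data_flat = np.zeros((n_vox, T), dtype=np.float64)
    for j, value in enumerate(table.labels):
        for v in layout[value]:
            label_flat[v] = value
            series = ts.data[:, j]
            if voxel_noise_sd > 0:
                series = series + rng.standard_normal(T) * voxel_noise_sd
            data_flat[v] = series
    masks = {}
    for tissue, v in flat_extra.items():
        conf = getattr(subject.confounds, tissue) if subject.confounds is not None else np.zeros(T)
        data_flat[v] = conf
        m = np.zeros(n_vox, dtype=np.uint8)
        m[v] = 1
        masks[tissue] = m.reshape(shape)
    affine = np.eye(4)
    img4d = nib.Nifti1Image(data_flat.reshape(shape + (T,)), affine)
    label_img = nib.Nifti1Image(label_flat.reshape(shape), affine)
    mask_imgs = {k: nib.Nifti1Image(v, affine) for k, v in masks.items()}
    return img4d, label_img, mask_imgs
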