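"""Synthetic multi-center, multi-lesion radiomics cohorts.

Emulates the statistical structure of a two-center Hodgkin-lymphoma-like
imaging study: lesions nested in patients nested in centers, scanners nested
in centers, collinear radiomic feature blocks, additive + multiplicative
location/scale batch effects with optional interaction and nonlinear
distortion terms, patient-level cloud heterogeneity, and right-censored
survival driven by that heterogeneity.

The generative model
--------------------
Patient p in center c gets a latent disease profile u_p ~ N(0, I_q) and a
heterogeneity scale h_p ~ LogNormal; lesion l of p has latent
z_l = u_p + h_p * xi_l. A fixed block-structured loading matrix W maps the
q latent factors to d features (six column blocks emulating the six radiomic
feature families: histogram, shape, GLCM, GLRLM, GLZLM, NGLDM), plus i.i.d.
Gaussian measurement noise:

    clean:       Y_lf  = (W z_l)_f + sigma_eps * eps_lf
    confounded:  Y'_lf = (W z_l)_f + gamma_c[f] + gamma_s[f]
                        + delta_c[f] * delta_s[f] * sigma_eps * eps_lf
                        + kappa * shift_cs[f]
                        + rho * m_c[f] * tanh((W z_l)_f)

i.e. a location/scale batch model in which the multiplicative effects act on
the residual term, extended by a center-x-scanner interaction shift (kappa)
and a center-specific signal-dependent tanh warp (rho) — the nonlinear noise
component that location/scale corrections cannot represent.

Survival: per-patient log-hazard eta_p = beta_h * (h_p - E[h]) + beta_m * u_p1,
Weibull event times under proportional hazards, uniform censoring calibrated
to a target censoring fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_data import LesionTable, SurvivalTable

N_FEATURE_BLOCKS = 6  # the six radiomic feature families


@dataclass
class SimulationConfig:
    """Cohort-generator settings; defaults mirror the two-center study shape
    (128 + 78 patients, ~10.5 lesions/patient, 2 + 3 scanners, 45 features).
    """

    n_patients_per_center: tuple[int, ...] = (128, 78)
    n_scanners_per_center: tuple[int, ...] = (2, 3)
    lesion_mean: float = 10.5          # Poisson mean lesions per patient
    lesion_min: int = 3                # floor so point clouds are non-degenerate
    latent_dim: int = 5
    feature_dim: int = 45
    loading_seed: int = 202311         # fixed loading matrix, separate from the cohort seed
    secondary_loading_scale: float = 0.2
    patient_latent_sd: float = 1.0
    heterogeneity_log_mean: float = float(np.log(0.6))
    heterogeneity_log_sd: float = 0.6  # per-patient dispersion law (lognormal)
    noise_sd: float = 0.5
    # batch-effect magnitudes
    center_effect_sd: float = 1.0      # additive gamma_c ~ N(0, sd^2) per feature
    scanner_effect_sd: float = 0.7     # additive gamma_s ~ N(0, sd^2) per feature
    center_scale_log_sd: float = 0.5   # delta_c lognormal(0, sd) per feature
    scanner_scale_log_sd: float = 0.5  # delta_s lognormal(0, sd) per feature
    interaction_strength: float = 0.3  # kappa
    nonlinear_strength: float = 0.3    # rho
    # survival generation
    survival_baseline_scale: float = 24.0  # Weibull scale (months)
    survival_shape: float = 1.5
    beta_heterogeneity: float = 2.5
    beta_centroid: float = 0.5
    censoring_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_patients_per_center) != len(self.n_scanners_per_center):
            raise ValueError(
                "n_patients_per_center and n_scanners_per_center must align "
                f"(got {self.n_patients_per_center} vs {self.n_scanners_per_center})"
            )
        if self.survival_baseline_scale <= 0:
            raise ValueError("survival baseline scale must be positive")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must be in [0, 1)")
        if min(self.n_patients_per_center) < 1 or min(self.n_scanners_per_center) < 1:
            raise ValueError("need >= 1 patient and >= 1 scanner per center")

    @property
    def n_centers(self) -> int:
        return len(self.n_patients_per_center)

    @property
    def n_scanners(self) -> int:
        return int(sum(self.n_scanners_per_center))

    def scanner_map(self) -> dict[str, list[str]]:
        """Center label -> list of scanner labels hosted there (partition)."""
        out, idx = {}, 1
        for c, k in enumerate(self.n_scanners_per_center, start=1):
            out[f"C{c}"] = [f"S{idx + j}" for j in range(k)]
            idx += k
        return out


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must rediscover."""

    lesion_latents: dict[str, list[float]]        # lesion_id -> z_l
    patient_heterogeneity: dict[str, float]       # patient_id -> h_p
    patient_centroid_score: dict[str, float]      # patient_id -> u_p[0]
    patient_log_hazard: dict[str, float]          # patient_id -> eta_p
    additive_center: dict[str, list[float]]       # center -> gamma_c (d,)
    additive_scanner: dict[str, list[float]]      # scanner -> gamma_s (d,)
    scale_center: dict[str, list[float]]          # center -> delta_c (d,)
    scale_scanner: dict[str, list[float]]         # scanner -> delta_s (d,)
    interaction_shift: dict[str, list[float]] = field(default_factory=dict)
    nonlinear_gain: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _loading_matrix(cfg: SimulationConfig) -> np.ndarray:
    """q x d block-structured loading: six column blocks, each dominated by one
    latent factor (cycled), plus a small dense component to avoid exact rank
    deficiency. Collinearity within a block mirrors a radiomic feature family.
    """
    rng = np.random.default_rng(cfg.loading_seed)
    q, d = cfg.latent_dim, cfg.feature_dim
    w = cfg.secondary_loading_scale * rng.standard_normal((q, d))
    bounds = np.linspace(0, d, N_FEATURE_BLOCKS + 1).astype(int)
    for b in range(N_FEATURE_BLOCKS):
        lo, hi = bounds[b], bounds[b + 1]
        w[b % q, lo:hi] += rng.standard_normal(hi - lo)
    return w


def generate_cohort(
    config: SimulationConfig,
) -> tuple[LesionTable, LesionTable, SurvivalTable, GroundTruth]:
    """Simulate a cohort; returns (clean table, confounded table, survival, truth).

    Deterministic given ``config.seed`` (and ``config.loading_seed`` for the
    feature loading matrix).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    w = _loading_matrix(cfg)
    d, q = cfg.feature_dim, cfg.latent_dim
    scanner_map = cfg.scanner_map()
    centers = list(scanner_map)

    # batch-effect parameters
    gamma_c = {c: cfg.center_effect_sd * rng.standard_normal(d) for c in centers}
    gamma_s = {
        s: cfg.scanner_effect_sd * rng.standard_normal(d)
        for c in centers
        for s in scanner_map[c]
    }
    delta_c = {c: np.exp(cfg.center_scale_log_sd * rng.standard_normal(d)) for c in centers}
    delta_s = {
        s: np.exp(cfg.scanner_scale_log_sd * rng.standard_normal(d))
        for c in centers
        for s in scanner_map[c]
    }
    shift_cs = {
        f"{c}|{s}": rng.standard_normal(d) for c in centers for s in scanner_map[c]
    }
    gain_c = {c: rng.standard_normal(d) for c in centers}

    rows_clean, rows_conf, meta = [], [], []
    truth = GroundTruth(
        lesion_latents={},
        patient_heterogeneity={},
        patient_centroid_score={},
        patient_log_hazard={},
        additive_center={c: gamma_c[c].tolist() for c in centers},
        additive_scanner={s: gamma_s[s].tolist() for s in gamma_s},
        scale_center={c: delta_c[c].tolist() for c in centers},
        scale_scanner={s: delta_s[s].tolist() for s in delta_s},
        interaction_shift={k: v.tolist() for k, v in shift_cs.items()},
        nonlinear_gain={c: gain_c[c].tolist() for c in centers},
    )

    pid = 0
    for ci, c in enumerate(centers):
        for _ in range(cfg.n_patients_per_center[ci]):
            pid += 1
            patient = f"P{pid:04d}"
            scanner = scanner_map[c][rng.integers(len(scanner_map[c]))]
            u = cfg.patient_latent_sd * rng.standard_normal(q)
            h = float(
                np.exp(cfg.heterogeneity_log_mean + cfg.heterogeneity_log_sd * rng.standard_normal())
            )
            k_lesions = max(int(rng.poisson(cfg.lesion_mean)), cfg.lesion_min)
            truth.patient_heterogeneity[patient] = h
            truth.patient_centroid_score[patient] = float(u[0])
            for li in range(1, k_lesions + 1):
                lesion = f"{patient}_L{li:02d}"
                z = u + h * rng.standard_normal(q)
                signal = z @ w
                eps = rng.standard_normal(d)
                clean = signal + cfg.noise_sd * eps
                conf = (
                    signal
                    + gamma_c[c]
                    + gamma_s[scanner]
                    + delta_c[c] * delta_s[scanner] * cfg.noise_sd * eps
                    + cfg.interaction_strength * shift_cs[f"{c}|{scanner}"]
                    + cfg.nonlinear_strength * gain_c[c] * np.tanh(signal)
                )
                truth.lesion_latents[lesion] = z.tolist()
                rows_clean.append(clean)
                rows_conf.append(conf)
                meta.append((lesion, patient, c, scanner))

    cols = [f"f{i}" for i in range(1, d + 1)]
    meta_df = pd.DataFrame(meta, columns=["lesion_id", "patient_id", "center", "scanner"])
    clean_df = pd.concat([meta_df, pd.DataFrame(rows_clean, columns=cols)], axis=1)
    conf_df = pd.concat([meta_df, pd.DataFrame(rows_conf, columns=cols)], axis=1)

    clean_tab, conf_tab = LesionTable(clean_df), LesionTable(conf_df)
    survival = generate_survival(truth, cfg)
    return clean_tab, conf_tab, survival, truth


def generate_survival(ground_truth: GroundTruth, config: SimulationConfig) -> SurvivalTable:
    """Weibull proportional-hazards event times from the true per-patient
    log-hazard, with uniform censoring calibrated to the target fraction.
    """
    cfg = config
    if cfg.survival_baseline_scale <= 0:
        raise ValueError("survival baseline scale must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7**5]))
    patients = sorted(ground_truth.patient_heterogeneity)
    h = np.array([ground_truth.patient_heterogeneity[p] for p in patients])
    m = np.array([ground_truth.patient_centroid_score[p] for p in patients])
    eta = cfg.beta_heterogeneity * (h - h.mean()) + cfg.beta_centroid * m
    for p, e in zip(patients, eta):
        ground_truth.patient_log_hazard[p] = float(e)
    u = rng.uniform(size=len(patients))
    times = cfg.survival_baseline_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / cfg.survival_shape)

    if cfg.censoring_fraction > 0:
        cu = rng.uniform(size=len(patients))
        # pick the uniform-censoring upper bound that hits the target fraction
        lo, hi = 1e-6, float(times.max()) * 10
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            frac_cens = np.mean(cu * mid < times)
            if frac_cens > cfg.censoring_fraction:
                lo = mid
            else:
                hi = mid
        cens_time = cu * 0.5 * (lo + hi)
        event = (times <= cens_time).astype(int)
        obs = np.minimum(times, cens_time)
    else:
        event = np.ones(len(patients), int)
        obs = times
    obs = np.maximum(obs, 1e-9)
    return SurvivalTable(
        pd.DataFrame({"patient_id": patients, "time": obs, "event": event})
    )
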