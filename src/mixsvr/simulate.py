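"""Synthetic telemonitoring-like datasets.

Emulates the structure of the UCI Parkinson's Telemonitoring cohort so that
every stage of the pipeline can be exercised without any download: ~42
patients followed for ~6 months, voice recorded in roughly weekly sessions
(several recordings per session, ~140 per patient), clinician UPDRS assessed
only at three anchor visits (baseline, ~3 months, ~6 months) and linearly
interpolated to the recording times, strongly collinear jitter and shimmer
feature blocks, HNR anti-correlated with NHR, and a smooth nonlinear
relationship from voice features, age and sex to total UPDRS.

The generative model, per patient: a latent severity score drives patient-
level shifts of the voice profile; recording-level features are built from
block factors (one per jitter block, shimmer block and noise pair) plus
idiosyncratic noise, mapped through moment-matched lognormal or Gaussian
marginals.  Anchor UPDRS values start from the deterministic ground-truth
function of the patient's profile and drift upward with noisy non-negative-
in-expectation increments; per-recording targets are linear interpolations
between anchors plus measurement noise.  Motor UPDRS is an affine transform
of total plus noise, carried only for schema fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data import COLUMNS, JITTER_BLOCK, SHIMMER_BLOCK, VOICE_FEATURES

__all__ = ["SynthConfig", "EffectSpec", "generate", "ground_truth", "write_csv"]

# target marginal (mean, sd) per voice feature, mirroring the published
# summary of the UCI telemonitoring cohort; the generator matches these two
# moments (lognormal for strictly positive skewed measures, Gaussian else)
FEATURE_MARGINALS: dict = {
    "Jitter(%)": (0.0066, 0.0056),
    "Jitter(Abs)": (4.4e-05, 3.6e-05),
    "Jitter:RAP": (0.0030, 0.0031),
    "Jitter:PPQ5": (0.0034, 0.0032),
    "Jitter:DDP": (0.0089, 0.0092),
    "Shimmer": (0.034, 0.026),
    "Shimmer(dB)": (0.31, 0.23),
    "Shimmer:APQ3": (0.017, 0.013),
    "Shimmer:APQ5": (0.020, 0.017),
    "Shimmer:APQ11": (0.028, 0.020),
    "Shimmer:DDA": (0.052, 0.040),
    "NHR": (0.032, 0.060),
    "HNR": (21.68, 4.29),
    "RPDE": (0.54, 0.10),
    "DFA": (0.65, 0.07),
    "PPE": (0.22, 0.09),
}

_LOGNORMAL = set(JITTER_BLOCK) | set(SHIMMER_BLOCK) | {"NHR"}

# factor loadings (severity, patient-idiosyncratic); the remaining variance
# sqrt(1 - s^2 - p^2) is session/recording noise.  Voice measures are
# strongly patient-determined in repeated-recording studies (high ICC):
# partly disease severity, partly anatomy and habit, hence the two
# patient-level components.
_LOADINGS = {"jitter": (0.5, 0.7), "shimmer": (0.5, 0.7),
             "noise": (0.55, 0.65), "PPE": (0.7, 0.55),
             "RPDE": (0.5, 0.65), "DFA": (0.5, 0.65)}

UPDRS_RANGE = (7.0, 55.0)


@dataclass(frozen=True)
class EffectSpec:
    """Coefficients of the ground-truth UPDRS function (UPDRS points).

    The nonlinear block acts on z-scored PPE, HNR and DFA (cohort moments):
    saturating (tanh, with ``steepness`` controlling how quickly the effect
    plateaus) main effects for PPE and inverted HNR, a linear DFA term, and a
    PPE x HNR interaction.  Zeroing the four nonlinear coefficients leaves a
    function exactly affine in (age, sex).
    """

    baseline: float = 25.0
    age_slope: float = 0.35        # points per year, positive
    male_offset: float = 4.0       # men score higher on average
    ppe_scale: float = 8.0
    hnr_scale: float = 6.0
    dfa_scale: float = 2.0
    interaction_scale: float = 5.0
    steepness: float = 1.5         # saturation rate of the tanh effects

    def without_nonlinearity(self) -> "EffectSpec":
        return replace(self, ppe_scale=0.0, hnr_scale=0.0, dfa_scale=0.0,
                       interaction_scale=0.0)


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic cohort."""

    n_patients: int = 42
    mean_recordings_per_patient: float = 140.0
    trial_days: float = 180.0
    anchor_days: tuple = (0.0, 90.0, 180.0)
    age_range: tuple = (36.0, 85.0)
    male_fraction: float = 28.0 / 42.0
    block_correlation: float = 0.9       # within jitter / shimmer blocks
    hnr_noise_correlation: float = -0.6  # corr(HNR, NHR)
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    noise_sd: float = 2.0                # UPDRS measurement noise, points
    progression_rate_mean: float = 0.5   # severity-SD drift per trial
    progression_rate_sd: float = 0.3     # across patients
    anchor_progression_mean: float = 0.0  # extra drift per anchor interval
    anchor_progression_sd: float = 1.5   # visit-level assessment noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not (0.0 < self.block_correlation < 1.0):
            raise ValueError("block_correlation must lie in (0, 1)")
        if not (-1.0 < self.hnr_noise_correlation < 1.0):
            raise ValueError("hnr_noise_correlation must lie in (-1, 1)")
        if list(self.anchor_days) != sorted(self.anchor_days) or self.anchor_days[0] != 0:
            raise ValueError("anchor_days must be sorted and start at 0")


def _zscore(name: str, value) -> np.ndarray:
    m, s = FEATURE_MARGINALS[name]
    return (np.asarray(value, dtype=float) - m) / s


def ground_truth(config: SynthConfig, age, sex, voice: Mapping) -> np.ndarray:
    """Noiseless total UPDRS for given demographics and voice profile.

    ``sex`` uses the telemonitoring coding (0 = male, 1 = female); ``voice``
    is any mapping with at least PPE, HNR and DFA in raw units.  The value is
    clipped to the cohort's total-UPDRS range [7, 55].
    """
    e = config.effect_spec
    age = np.asarray(age, dtype=float)
    male = (np.asarray(sex) == 0).astype(float)
    z_ppe = _zscore("PPE", voice["PPE"])
    z_hnr = _zscore("HNR", voice["HNR"])
    z_dfa = _zscore("DFA", voice["DFA"])
    k = e.steepness
    u = (e.baseline
         + e.age_slope * (age - 65.0)
         + e.male_offset * male
         + e.ppe_scale * np.tanh(k * z_ppe)
         + e.hnr_scale * np.tanh(-k * z_hnr)
         + e.dfa_scale * z_dfa
         + e.interaction_scale * np.tanh(k * z_ppe) * np.tanh(-k * z_hnr))
    return np.clip(u, *UPDRS_RANGE)


def _raw_from_z(name: str, z: np.ndarray) -> np.ndarray:
    """Map standard-normal draws to the feature's marginal (moment-matched)."""
    m, s = FEATURE_MARGINALS[name]
    if name in _LOGNORMAL:
        sigma2 = np.log1p((s / m) ** 2)
        sigma = np.sqrt(sigma2)
        mu = np.log(m) - sigma2 / 2.0
        return np.exp(mu + sigma * z)
    out = m + s * z
    if name in ("RPDE", "DFA"):
        return np.clip(out, 0.01, 0.99)
    return np.maximum(out, 1e-4)  # voice measures are nonnegative


#: per-recording measurement noise on each feature's z-scale; same-session
#: recordings of a sustained phonation are near-replicates
MEASUREMENT_SD = 0.15


def _block_loading(name: str, rho: float) -> float:
    """Latent loading on the block factor compensating lognormal attenuation.

    For a lognormal marginal with shape sigma, a latent correlation rho_z
    realizes as (e^{rho_z si sj} - 1)/sqrt((e^{si^2}-1)(e^{sj^2}-1)) on the
    observed scale; choosing loading a = sqrt(ln(1 + rho (e^{s^2}-1)))/s per
    feature makes realized pairwise correlations ~= rho.  Gaussian marginals
    reduce to the usual sqrt(rho).
    """
    m, s = FEATURE_MARGINALS[name]
    if name not in _LOGNORMAL:
        return float(np.sqrt(rho))
    sig2 = np.log1p((s / m) ** 2)
    a = np.sqrt(np.log1p(rho * np.expm1(sig2))) / np.sqrt(sig2)
    return float(min(a, 0.995))


def generate(config: SynthConfig | None = None) -> pd.DataFrame:
    """Generate a telemonitoring-schema dataset (reader-compatible)."""
    if config is None:
        config = SynthConfig()
    rng = np.random.default_rng(config.seed)
    rho = config.block_correlation
    anchors = np.asarray(config.anchor_days, dtype=float)

    # session layout: weekly visits across the trial, several recordings each
    n_sessions = max(1, int(round(config.trial_days / 7.0)) + 1)
    per_session = max(config.mean_recordings_per_patient / n_sessions, 0.2)

    frames = []
    for pid in range(1, config.n_patients + 1):
        age = float(rng.uniform(*config.age_range))
        sex = 0 if rng.random() < config.male_fraction else 1
        # latent severity drifts over the trial: the disease progresses, and
        # the progression shows in the voice as well as in the UPDRS anchors
        severity = float(rng.standard_normal())
        rate = float(rng.normal(config.progression_rate_mean,
                                config.progression_rate_sd))

        def sev_at(day):
            # centered at mid-trial so cohort-level marginal moments stay at
            # their targets while severity still drifts within the trial
            return severity + rate * (np.asarray(day, dtype=float)
                                      / config.trial_days - 0.5)

        # session times: roughly weekly, jittered; first may dip pre-baseline
        session_days = 7.0 * np.arange(n_sessions) + rng.uniform(-2.5, 2.5,
                                                                 n_sessions)
        counts = np.maximum(rng.poisson(per_session, n_sessions), 0)
        if counts.sum() == 0:
            counts[rng.integers(n_sessions)] = 1
        times = np.repeat(session_days, counts)
        n = times.size
        sev_rec = np.repeat(sev_at(session_days), counts)

        # per-patient idiosyncratic factor offsets (anatomy/habit)
        idio = {key: float(rng.standard_normal()) for key in _LOADINGS}

        def session_noise() -> np.ndarray:
            return np.repeat(rng.standard_normal(n_sessions), counts)

        def factor(key: str) -> np.ndarray:
            """Block/feature factor: severity + patient offset + session state."""
            s, pw = _LOADINGS[key]
            w_rest = np.sqrt(max(0.0, 1.0 - s ** 2 - pw ** 2))
            return s * sev_rec + pw * idio[key] + w_rest * session_noise()

        def measured(z_sess: np.ndarray) -> np.ndarray:
            """Session-level signal plus small per-recording measurement noise.

            Same-session recordings are near-replicates, as in the real
            cohort; the slight variance inflation is normalized away so the
            target marginal moments still hold.
            """
            z = z_sess + MEASUREMENT_SD * rng.standard_normal(n)
            return z / np.sqrt(1.0 + MEASUREMENT_SD ** 2)

        f_jit = factor("jitter")
        f_shi = factor("shimmer")
        f_noi = factor("noise")

        voice: dict = {}
        for name in JITTER_BLOCK:
            a = _block_loading(name, rho)
            voice[name] = _raw_from_z(name, measured(
                a * f_jit + np.sqrt(1 - a * a) * session_noise()))
        for name in SHIMMER_BLOCK:
            a = _block_loading(name, rho)
            voice[name] = _raw_from_z(name, measured(
                a * f_shi + np.sqrt(1 - a * a) * session_noise()))
        # NHR rides the noise factor; HNR is anti-correlated with it.  NHR's
        # lognormal marginal attenuates Pearson correlation relative to the
        # latent scale by sigma/sqrt(e^{sigma^2}-1); compensate so the
        # configured target holds for the observed values.
        m_nhr, s_nhr = FEATURE_MARGINALS["NHR"]
        sig2 = np.log1p((s_nhr / m_nhr) ** 2)
        atten = np.sqrt(sig2) / np.sqrt(np.expm1(sig2))
        c = min(abs(config.hnr_noise_correlation) / atten, 0.98)
        a_nhr = np.sqrt(c)
        z_nhr = a_nhr * f_noi + np.sqrt(1 - c) * session_noise()
        z_hnr = -a_nhr * f_noi + np.sqrt(1 - c) * session_noise()
        if config.hnr_noise_correlation > 0:
            z_hnr = -z_hnr
        voice["NHR"] = _raw_from_z("NHR", measured(z_nhr))
        voice["HNR"] = _raw_from_z("HNR", measured(z_hnr))
        for name in ("RPDE", "DFA", "PPE"):
            s, pw = _LOADINGS[name]
            w_rest = np.sqrt(max(0.0, 1.0 - s ** 2 - pw ** 2))
            z = s * sev_rec + pw * idio[name] + w_rest * session_noise()
            voice[name] = _raw_from_z(name, measured(z))

        # anchor UPDRS: ground truth at the patient's expected voice profile
        # at each clinic visit (expected z-score of each driver feature,
        # idiosyncratic offsets included), plus a noisy drift between visits
        hnr_sign = 1.0 if config.hnr_noise_correlation > 0 else -1.0
        sev_anchor = sev_at(anchors)

        def expected_z(key: str, sev: np.ndarray) -> np.ndarray:
            s, pw = _LOADINGS[key]
            return s * sev + pw * idio[key]

        profile_z = {"PPE": expected_z("PPE", sev_anchor),
                     "DFA": expected_z("DFA", sev_anchor),
                     "HNR": hnr_sign * a_nhr * expected_z("noise", sev_anchor)}
        profile = {nm: _raw_from_z(nm, z) for nm, z in profile_z.items()}
        base = ground_truth(config, age, sex, profile)
        increments = rng.normal(config.anchor_progression_mean,
                                config.anchor_progression_sd,
                                anchors.size - 1)
        anchor_vals = np.clip(base + np.concatenate([[0.0],
                                                     np.cumsum(increments)]),
                              *UPDRS_RANGE)

        noiseless = np.interp(times, anchors, anchor_vals)
        total = np.clip(noiseless + rng.normal(0.0, config.noise_sd, n),
                        *UPDRS_RANGE)
        motor = 0.7 * total + 0.8 + rng.normal(0.0, 1.0, n)

        frame = pd.DataFrame({"subject#": pid, "age": age, "sex": sex,
                              "test_time": times, "motor_UPDRS": motor,
                              "total_UPDRS": total})
        for name in VOICE_FEATURES:
            frame[name] = voice[name]
        frames.append(frame)

    out = pd.concat(frames, ignore_index=True)[list(COLUMNS)]
    out["subject#"] = out["subject#"].astype(int)
    return out


def write_csv(dataset: pd.DataFrame, path) -> None:
    """Write a dataset in the canonical telemonitoring CSV schema."""
    missing = [c for c in COLUMNS if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset is missing columns: {missing}")
    dataset[list(COLUMNS)].to_csv(path, index=False)
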