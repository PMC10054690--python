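"""Synthetic multi-reader study generator.

The real annotation data of observer studies are usually private, so this
module generates studies with the statistical structure the analysis
assumes, from a binormal equal-variance latent model with a shared case
random effect:

    x_{ris} = d_r * D_i + eta_i + s_r * eps_{ris}

where D_i is the slice truth (Bernoulli prevalence, grouped into patients),
eta_i ~ N(0, sigma_c^2) is a case difficulty shared by all readers (it
induces inter-reader correlation beyond what the truth explains), d_r is
reader r's discrimination, and eps is unit-normal reader noise scaled by a
per-reader reliability s_r (>= 1; inexperienced readers are noisier, which
lowers their mutual agreement much more than their individual AUC).  For
repeat readings the noise mixes a persistent and a session-specific part,

    eps_{ris} = (eps0_{ri} + tau * zeta_{ris}) / sqrt(1 + tau^2),

so the marginal stays N(0,1) for any tau and the two sessions coincide
exactly at tau = 0.  The latent signal is cut into an ordinal score 0-5 by
five cutpoints; any score >= 1 emits one box annotation at a seeded random
location (box geometry is cosmetic — the analysis is slice-level).

The continuous-score AUC of this model is available in closed form,
Phi(d / sqrt(2 (s^2 + sigma_c^2))), which makes parameter-recovery tests
self-validating.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

import pandas as pd

from .study_data import (
    AnnotationRecord,
    ObserverProfile,
    ReferenceStandard,
    assign_groups,
)

__all__ = [
    "ObserverSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_study",
    "theoretical_auc",
    "discrimination_for_auc",
    "default_cutpoints",
    "adhesion_study_fixture",
    "OBSERVER_EXPERIENCE_TABLE",
]

#: image geometry used for cosmetic box placement (pixels)
IMAGE_WIDTH, IMAGE_HEIGHT, BOX_SIZE = 256, 192, 40

#: defaults reproducing the design of the study this generator emulates
DEFAULT_N_PATIENTS = 10
DEFAULT_SLICES_PER_PATIENT = (5, 7)
DEFAULT_SLICE_PREVALENCE = 19.0 / 61.0
DEFAULT_CASE_EFFECT_SD = 1.0
DEFAULT_INTRA_SESSION_NOISE = 0.8


@dataclass(frozen=True)
class ObserverSpec:
    """Generating parameters for one simulated observer.

    ``discrimination`` is the standardized latent mean shift d between
    positive and negative slices; ``noise_sd`` scales the reader's
    idiosyncratic noise (1 = a reliable reader; larger values model erratic
    reading, which lowers agreement with other readers more than it lowers
    AUC); ``cutpoints`` (5 ordered reals) bin the latent signal into scores
    0-5 (None = quantile default adapted to this reader's marginal);
    ``second_session`` marks observers who re-read the full slice set.
    """

    observer_id: str
    years_experience: int
    cine_cases: int
    adhesion_cases: int
    clinical_threshold_pct: int
    discrimination: float
    noise_sd: float = 1.0
    is_consensus: bool = False
    second_session: bool = False
    cutpoints: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.discrimination < 0:
            raise ValueError("discrimination must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.cutpoints is not None:
            cp = tuple(float(c) for c in self.cutpoints)
            if len(cp) != 5 or any(a >= b for a, b in zip(cp, cp[1:])):
                raise ValueError("cutpoints must be 5 strictly increasing reals")

    @property
    def profile(self) -> ObserverProfile:
        return ObserverProfile(
            observer_id=self.observer_id,
            years_experience=self.years_experience,
            cine_cases=self.cine_cases,
            adhesion_cases=self.adhesion_cases,
            clinical_threshold_pct=self.clinical_threshold_pct,
            is_consensus=self.is_consensus,
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Latent-model parameters for a synthetic multi-reader study.

    ``slice_layout``/``positive_layout`` optionally fix the exact number of
    slices and positive slices per patient (otherwise slice counts are
    uniform in ``slices_per_patient`` and truth is Bernoulli
    ``slice_prevalence``).
    """

    observer_specs: tuple[ObserverSpec, ...]
    n_patients: int = DEFAULT_N_PATIENTS
    slices_per_patient: tuple[int, int] = DEFAULT_SLICES_PER_PATIENT
    slice_prevalence: float = DEFAULT_SLICE_PREVALENCE
    case_effect_sd: float = DEFAULT_CASE_EFFECT_SD
    intra_session_noise: float = DEFAULT_INTRA_SESSION_NOISE
    seed: int = 0
    slice_layout: tuple[int, ...] | None = None
    positive_layout: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.observer_specs:
            raise ValueError("need at least one observer spec")
        if not 0.0 < self.slice_prevalence < 1.0:
            raise ValueError(
                f"slice_prevalence must be in (0, 1), got {self.slice_prevalence}"
            )
        if self.case_effect_sd < 0 or self.intra_session_noise < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        lo, hi = self.slices_per_patient
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid slices_per_patient range {self.slices_per_patient}")
        if self.slice_layout is not None:
            if len(self.slice_layout) != self.n_patients or min(self.slice_layout) < 1:
                raise ValueError("slice_layout must give >=1 slice per patient")
        if self.positive_layout is not None:
            if self.slice_layout is None:
                raise ValueError("positive_layout requires slice_layout")
            if len(self.positive_layout) != self.n_patients:
                raise ValueError("positive_layout must cover every patient")
            if any(
                p < 0 or p > s for p, s in zip(self.positive_layout, self.slice_layout)
            ):
                raise ValueError("positive_layout exceeds slice_layout")


@dataclass(frozen=True)
class SimulatedStudy:
    """A generated study: annotations (all sessions), profiles, truth."""

    annotations: tuple[AnnotationRecord, ...]
    profiles: tuple[ObserverProfile, ...]
    reference: ReferenceStandard
    config: SimulationConfig

    @property
    def slices(self) -> list[str]:
        return list(self.reference.slice_labels.index)

    @property
    def observers(self) -> list[str]:
        return [p.observer_id for p in self.profiles]

    @property
    def dual_session_observers(self) -> list[str]:
        return [s.observer_id for s in self.config.observer_specs if s.second_session]


def theoretical_auc(d: float, sigma_c: float = 0.0, noise_sd: float = 1.0) -> float:
    """Continuous-score AUC of the latent model.

    Both classes share variance noise_sd^2 + sigma_c^2 (reader noise plus
    case effect) and differ by mean shift d, so the probability that a
    positive slice outscores a negative one is
    Phi(d / sqrt(2 (noise_sd^2 + sigma_c^2))); with a unit-reliability
    reader this is the familiar Phi(d / sqrt(2 (1 + sigma_c^2))).
    """
    if d < 0 or sigma_c < 0:
        raise ValueError("d and sigma_c must be >= 0")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    return float(norm.cdf(d / np.sqrt(2.0 * (noise_sd**2 + sigma_c**2))))


def discrimination_for_auc(
    auc: float, sigma_c: float = 0.0, noise_sd: float = 1.0
) -> float:
    """Invert :func:`theoretical_auc`: the d giving a target continuous AUC."""
    if not 0.5 <= auc < 1.0:
        raise ValueError(f"target AUC must be in [0.5, 1), got {auc}")
    return float(norm.ppf(auc) * np.sqrt(2.0 * (noise_sd**2 + sigma_c**2)))


def default_cutpoints(
    d: float = 1.0,
    sigma_c: float = DEFAULT_CASE_EFFECT_SD,
    prevalence: float = DEFAULT_SLICE_PREVALENCE,
    noise_sd: float = 1.0,
) -> tuple[float, ...]:
    """Cutpoints making the six score levels roughly equiprobable.

    The marginal latent distribution is a two-component normal mixture
    (negatives at 0, positives at d, common sd sqrt(noise_sd^2 + sigma_c^2));
    the cutpoints are its 1/6 .. 5/6 quantiles, found by root-finding on the
    mixture CDF.
    """
    sd = float(np.sqrt(noise_sd**2 + sigma_c**2))

    def cdf(x: float) -> float:
        return (1.0 - prevalence) * norm.cdf(x, 0.0, sd) + prevalence * norm.cdf(
            x, d, sd
        )

    lo, hi = -10.0 * sd, 10.0 * sd + d
    return tuple(
        float(brentq(lambda x, q=q: cdf(x) - q, lo, hi, xtol=1e-12))
        for q in (1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6)
    )


def _draw_truth(config: SimulationConfig, rng: np.random.Generator):
    """Slice ids, patient ids and slice truth for the study design."""
    if config.slice_layout is not None:
        counts = list(config.slice_layout)
    else:
        lo, hi = config.slices_per_patient
        counts = rng.integers(lo, hi + 1, size=config.n_patients).tolist()
    slice_ids: list[str] = []
    patient_of: list[str] = []
    truth: list[bool] = []
    for p_idx, n_slices in enumerate(counts, start=1):
        patient_id = f"p{p_idx:02d}"
        if config.positive_layout is not None:
            n_pos = config.positive_layout[p_idx - 1]
            pos_slots = set(rng.choice(n_slices, size=n_pos, replace=False).tolist())
            labels = [s in pos_slots for s in range(n_slices)]
        else:
            labels = (rng.random(n_slices) < config.slice_prevalence).tolist()
        for s_idx in range(1, n_slices + 1):
            slice_ids.append(f"{patient_id}_s{s_idx}")
            patient_of.append(patient_id)
            truth.append(labels[s_idx - 1])
    return slice_ids, patient_of, np.array(truth, dtype=bool)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full synthetic study from the latent model.

    Deterministic given ``config.seed``: the same configuration always
    produces byte-identical annotation tables.
    """
    rng = np.random.default_rng(config.seed)
    slice_ids, patient_of, truth = _draw_truth(config, rng)
    n = len(slice_ids)
    eta = rng.normal(0.0, config.case_effect_sd, size=n)
    tau = config.intra_session_noise
    records: list[AnnotationRecord] = []
    for spec in config.observer_specs:
        if spec.cutpoints is not None:
            cuts = np.array(spec.cutpoints)
        else:
            cuts = np.array(
                default_cutpoints(
                    sigma_c=config.case_effect_sd,
                    prevalence=config.slice_prevalence,
                    noise_sd=spec.noise_sd,
                )
            )
        eps0 = rng.normal(size=n)
        sessions = (1, 2) if spec.second_session else (1,)
        for session in sessions:
            zeta = rng.normal(size=n)
            eps = (eps0 + tau * zeta) / np.sqrt(1.0 + tau**2)
            x = spec.discrimination * truth + eta + spec.noise_sd * eps
            scores = np.searchsorted(cuts, x)
            for i in np.flatnonzero(scores >= 1):
                x0 = float(rng.integers(0, IMAGE_WIDTH - BOX_SIZE))
                y0 = float(rng.integers(0, IMAGE_HEIGHT - BOX_SIZE))
                records.append(
                    AnnotationRecord(
                        observer_id=spec.observer_id,
                        patient_id=patient_of[i],
                        slice_id=slice_ids[i],
                        box=(x0, y0, x0 + BOX_SIZE, y0 + BOX_SIZE),
                        confidence=int(scores[i]),
                        session=session,
                    )
                )
    reference = ReferenceStandard(
        slice_labels=pd.Series(truth, index=slice_ids, dtype=bool),
        slice_to_patient=pd.Series(patient_of, index=slice_ids),
    )
    return SimulatedStudy(
        annotations=tuple(records),
        profiles=tuple(s.profile for s in config.observer_specs),
        reference=reference,
        config=config,
    )


# ---------------------------------------------------------------------------
# Study-like fixture
# ---------------------------------------------------------------------------

#: (observer id, years, cine cases, adhesion cases, threshold %, consensus)
#: — the experience table of the emulated study: 15 readers, 3 consensus
OBSERVER_EXPERIENCE_TABLE: tuple[tuple[str, int, int, int, int, bool], ...] = (
    ("obs01", 4, 30, 30, 40, True),
    ("obs02", 30, 100, 100, 80, True),
    ("obs03", 0, 0, 0, 60, True),
    ("obs04", 6, 30, 30, 40, False),
    ("obs05", 15, 100, 0, 20, False),
    ("obs06", 5, 150, 0, 40, False),
    ("obs07", 7, 50, 50, 80, False),
    ("obs08", 6, 30, 30, 40, False),
    ("obs09", 17, 0, 0, 0, False),
    ("obs10", 2, 15, 15, 40, False),
    ("obs11", 2, 0, 0, 0, False),
    ("obs12", 2, 0, 0, 60, False),
    ("obs13", 3, 0, 0, 60, False),
    ("obs14", 3, 50, 0, 40, False),
    ("obs15", 4, 20, 20, 60, False),
)

#: readers who completed a second session in the emulated study
_SECOND_SESSION = frozenset({"obs02", "obs03", "obs04", "obs07", "obs15"})

# Experience -> latent parameter map.  Readers with high general or high
# cine experience are "experienced": reliable (noise_sd 1) with a
# continuous-score AUC target of 0.70; readers low in both are erratic
# (noise_sd 3), which depresses inter-reader agreement sharply while their
# AUC target only drops to 0.66; adhesion-specific experience adds a small
# +0.02 AUC bump.  These targets sit at the group AUC levels typical of
# adhesion cine-MRI reader panels (about 0.66 low / 0.72 high), and the
# reliability contrast reproduces the strong agreement gap between the
# experience groups that accuracy differences alone cannot produce.
_AUC_EXPERIENCED, _AUC_NOVICE, _AUC_ADHESION_BONUS = 0.70, 0.66, 0.02
_NOISE_SD_NOVICE = 3.0


def _experience_parameters(
    profile: ObserverProfile, sigma_c: float
) -> tuple[float, float]:
    """(discrimination, noise_sd) implied by an observer's experience."""
    g = assign_groups(replace(profile, is_consensus=False))
    experienced = g.year == "high" or g.cine == "high"
    noise_sd = 1.0 if experienced else _NOISE_SD_NOVICE
    target = (_AUC_EXPERIENCED if experienced else _AUC_NOVICE) + (
        _AUC_ADHESION_BONUS * (g.adhesion == "high")
    )
    return discrimination_for_auc(target, sigma_c, noise_sd), noise_sd


def adhesion_study_fixture(seed: int = 0) -> SimulatedStudy:
    """A synthetic study mirroring the emulated design exactly in structure.

    10 patients (7 positive, 3 negative), 61 sagittal slices of which 19 are
    positive, 15 observers with the study's experience table and clinical
    thresholds (3 consensus readers), discrimination increasing with
    experience, and 5 observers reading a second session.
    """
    specs = []
    for obs_id, years, cine, adhesion, thr, consensus in OBSERVER_EXPERIENCE_TABLE:
        profile = ObserverProfile(
            observer_id=obs_id,
            years_experience=years,
            cine_cases=cine,
            adhesion_cases=adhesion,
            clinical_threshold_pct=thr,
            is_consensus=consensus,
        )
        d, noise_sd = _experience_parameters(profile, DEFAULT_CASE_EFFECT_SD)
        specs.append(
            ObserverSpec(
                observer_id=obs_id,
                years_experience=years,
                cine_cases=cine,
                adhesion_cases=adhesion,
                clinical_threshold_pct=thr,
                discrimination=d,
                noise_sd=noise_sd,
                is_consensus=consensus,
                second_session=obs_id in _SECOND_SESSION,
            )
        )
    config = SimulationConfig(
        observer_specs=tuple(specs),
        n_patients=10,
        slice_layout=(6, 6, 6, 6, 6, 6, 6, 6, 6, 7),  # 61 slices
        positive_layout=(4, 3, 3, 3, 2, 2, 2, 0, 0, 0),  # 19 positive, 3 neg patients
        slice_prevalence=19.0 / 61.0,
        seed=seed,
    )
    return simulate_study(config)
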