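"""Synthetic cytometry cohorts with known ground truth.

The event-level model is deliberately simple: each leukocyte population is a
multivariate Gaussian with diagonal covariance on the analysis scale (asinh
for fluorescence, linear for scatter), with population weights drawn
multinomially. Doublets have roughly twice the FSC-A of singlets at similar
FSC-H. Every GFAP-negative event — in every population — draws its GFAP (and
PLP1) intensity from the same background distribution as the lymphocytes, so
the lymphocyte-background positivity rule is well-posed by construction;
marker-positive events receive an additive intensity shift.

At cohort level, each sample's true GFAP+ fraction among non-classical
monocytes is drawn from a per-diagnosis-group distribution (lognormal or
beta); the intermediate-monocyte rate is a fixed ratio of it. Overall
survival for glioblastoma (and metastasis) follows a two-arm Weibull whose
hazard ratio applies when the true non-classical GFAP+ fraction exceeds the
prognostic threshold, with independent uniform censoring on [0, H] where H is
solved so the expected censoring fraction matches the requested rate. Stroke
patients get a rise-and-decay GFAP+CD16+ time course whose peak scales with
infarct volume.

Group-level defaults are configuration choices that reproduce the qualitative
structure of the assay (healthy < glioma/metastasis; ~18% of glioblastoma
patients above the 20% prognostic threshold; arm medians 8.8 vs 11.8 months),
not claims about any particular dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .io import EventTable, write_event_table

__all__ = [
    "CHANNELS",
    "PopulationSpec",
    "SampleSpec",
    "GroupSpec",
    "SurvivalSpec",
    "AISProfile",
    "CohortSpec",
    "SpecError",
    "default_populations",
    "default_sample_spec",
    "default_cohort_spec",
    "simulate_sample",
    "simulate_cohort",
    "simulate_ais_timecourse",
    "ais_profile_value",
]

CHANNELS = ("FSC-A", "FSC-H", "SSC-A", "CD45", "HLA-DR", "CD300e", "CD14",
            "CD16", "GFAP", "PLP1")

POPULATION_NAMES = ("debris", "doublet", "lymphocyte", "classical_mono",
                    "intermediate_mono", "nonclassical_mono", "dendritic",
                    "other_leukocyte")


class SpecError(ValueError):
    """Invalid simulation specification."""


@dataclass(frozen=True)
class PopulationSpec:
    """One population's location/spread per channel plus marker-positive rates."""

    name: str
    weight: float
    mean: dict[str, float]
    sd: dict[str, float]
    gfap_pos_fraction: float = 0.0
    plp1_pos_fraction: float = 0.0


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    n_events: int
    populations: tuple[PopulationSpec, ...]
    marker_shift: float = 2.0
    background_mean: float = 0.8
    background_sd: float = 0.25
    seed: int = 0


# Population templates on the analysis scale (scatter linear, fluorescence
# asinh units). Means are separated by >=4 SD on every channel a gate uses.
_SCATTER_SD = {"FSC-A": 35.0, "FSC-H": 32.0, "SSC-A": 35.0}
_FLUOR_SD = 0.25

_TEMPLATES: dict[str, dict[str, float]] = {
    "debris":            {"FSC-A": 80, "FSC-H": 75, "SSC-A": 60, "CD45": 0.8,
                          "HLA-DR": 0.8, "CD300e": 0.8, "CD14": 0.8, "CD16": 0.8},
    "doublet":           {"FSC-A": 950, "FSC-H": 470, "SSC-A": 350, "CD45": 5.2,
                          "HLA-DR": 2.0, "CD300e": 2.0, "CD14": 3.0, "CD16": 1.5},
    "lymphocyte":        {"FSC-A": 450, "FSC-H": 445, "SSC-A": 150, "CD45": 6.0,
                          "HLA-DR": 1.2, "CD300e": 1.0, "CD14": 0.9, "CD16": 1.0},
    "classical_mono":    {"FSC-A": 550, "FSC-H": 530, "SSC-A": 330, "CD45": 4.8,
                          "HLA-DR": 4.6, "CD300e": 4.6, "CD14": 5.5, "CD16": 1.2},
    "intermediate_mono": {"FSC-A": 550, "FSC-H": 530, "SSC-A": 330, "CD45": 4.8,
                          "HLA-DR": 5.0, "CD300e": 4.6, "CD14": 5.2, "CD16": 4.3},
    "nonclassical_mono": {"FSC-A": 530, "FSC-H": 510, "SSC-A": 300, "CD45": 5.0,
                          "HLA-DR": 4.8, "CD300e": 4.6, "CD14": 1.4, "CD16": 4.5},
    "dendritic":         {"FSC-A": 520, "FSC-H": 500, "SSC-A": 260, "CD45": 5.0,
                          "HLA-DR": 5.2, "CD300e": 1.2, "CD14": 1.2, "CD16": 1.4},
    "other_leukocyte":   {"FSC-A": 600, "FSC-H": 575, "SSC-A": 700, "CD45": 4.2,
                          "HLA-DR": 1.0, "CD300e": 1.0, "CD14": 1.8, "CD16": 4.8},
}
_TEMPLATE_SD_OVERRIDES = {"doublet": {"FSC-A": 60.0, "FSC-H": 40.0, "SSC-A": 50.0},
                          "other_leukocyte": {"SSC-A": 60.0, "FSC-A": 40.0}}

#: Whole-blood event weights after erythrocyte lysis: ~24% monocytes of which
#: ~82% classical, lymphocytes 30%, granulocytes/other 37%, debris+doublets 8%.
DEFAULT_WEIGHTS = {
    "debris": 0.05, "doublet": 0.03, "lymphocyte": 0.30,
    "classical_mono": 0.197, "intermediate_mono": 0.037,
    "nonclassical_mono": 0.0065, "dendritic": 0.0095, "other_leukocyte": 0.37,
}


def default_populations(
    gfap_nonclassical: float = 0.0,
    gfap_intermediate: float = 0.0,
    plp1_nonclassical: float = 0.0,
    plp1_intermediate: float = 0.0,
    weights: dict[str, float] | None = None,
) -> tuple[PopulationSpec, ...]:
    """Default population mixture with the given true marker-positive rates."""
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    pops = []
    for name, wt in w.items():
        mean = dict(_TEMPLATES[name])
        sd = {ch: _SCATTER_SD.get(ch, _FLUOR_SD) for ch in mean}
        sd.update(_TEMPLATE_SD_OVERRIDES.get(name, {}))
        gfap = {"nonclassical_mono": gfap_nonclassical,
                "intermediate_mono": gfap_intermediate}.get(name, 0.0)
        plp1 = {"nonclassical_mono": plp1_nonclassical,
                "intermediate_mono": plp1_intermediate}.get(name, 0.0)
        pops.append(PopulationSpec(name, wt, mean, sd, gfap, plp1))
    return tuple(pops)


def default_sample_spec(
    sample_id: str = "sample",
    n_events: int = 30_000,
    seed: int = 0,
    **marker_rates,
) -> SampleSpec:
    return SampleSpec(sample_id, n_events, default_populations(**marker_rates),
                      seed=seed)


def simulate_sample(spec: SampleSpec) -> EventTable:
    """Draw one event-level sample with per-event truth labels."""
    weights = np.array([p.weight for p in spec.populations], dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise SpecError("population weights must be >= 0 and sum to 1 within 1e-9")
    if spec.n_events < 1:
        raise SpecError("n_events must be >= 1")
    if spec.marker_shift <= 0:
        raise SpecError("marker_shift must be > 0")

    rng = np.random.default_rng(spec.seed)
    counts = rng.multinomial(spec.n_events, weights)

    blocks, labels, gfap_truth, plp1_truth = [], [], [], []
    for pop, n_i in zip(spec.populations, counts):
        block = np.empty((n_i, len(CHANNELS)))
        for j, ch in enumerate(CHANNELS):
            if ch in ("GFAP", "PLP1"):
                block[:, j] = rng.normal(spec.background_mean, spec.background_sd, n_i)
            else:
                block[:, j] = rng.normal(pop.mean[ch], pop.sd[ch], n_i)
        g_pos = rng.random(n_i) < pop.gfap_pos_fraction
        p_pos = rng.random(n_i) < pop.plp1_pos_fraction
        block[g_pos, CHANNELS.index("GFAP")] += spec.marker_shift
        block[p_pos, CHANNELS.index("PLP1")] += spec.marker_shift
        blocks.append(block)
        labels.append(np.full(n_i, pop.name, dtype=object))
        gfap_truth.append(g_pos)
        plp1_truth.append(p_pos)

    return EventTable(
        sample_id=spec.sample_id,
        channels=list(CHANNELS),
        values=np.vstack(blocks),
        truth_labels=np.concatenate(labels),
        truth_gfap=np.concatenate(gfap_truth),
        truth_plp1=np.concatenate(plp1_truth),
    )


# ---------------------------------------------------------------------------
# Cohort-level specification


@dataclass(frozen=True)
class GroupSpec:
    """Per-diagnosis-group sample count and distributions.

    ``gfap_nc_dist``: true GFAP+ fraction (in %) among non-classical
    monocytes; ``("lognormal", median_pct, sigma)`` or ``("beta", a, b)``
    (beta values are fractions, reported in %).
    """

    n_samples: int
    gfap_nc_dist: tuple = ("lognormal", 2.0, 0.8)
    wbc_median: float = 7000.0
    wbc_sigma: float = 0.25
    mean_tumour_size_cm: float = float("nan")
    median_age: float = 60.0
    has_survival: bool = False


@dataclass(frozen=True)
class SurvivalSpec:
    """Two-arm Weibull overall-survival model dichotomized at the threshold."""

    shape: float = 2.3
    median_low_months: float = 11.8
    hazard_ratio: float = 1.96
    censoring_rate: float = 0.30
    threshold_pct: float = 20.0

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise SpecError("hazard ratio must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise SpecError("censoring rate must be in [0, 1)")

    @property
    def scale_low(self) -> float:
        return self.median_low_months / math.log(2) ** (1 / self.shape)

    @property
    def scale_high(self) -> float:
        return self.scale_low * self.hazard_ratio ** (-1 / self.shape)

    @property
    def median_high_months(self) -> float:
        return self.scale_high * math.log(2) ** (1 / self.shape)


@dataclass(frozen=True)
class AISProfile:
    """Rise-and-decay GFAP+CD16+ time course for one stroke patient."""

    patient_id: str
    infarct_volume: float  # cm^3
    peak_pct: float
    peak_time_h: float = 4.0
    half_life_h: float = 10.0
    baseline_pct: float = 0.05


def ais_profile_value(profile: AISProfile, hours: np.ndarray) -> np.ndarray:
    """Noiseless time-course value: linear rise to the peak, exponential decay."""
    t = np.asarray(hours, dtype=float)
    rise = profile.peak_pct * t / profile.peak_time_h
    decay = profile.peak_pct * 2.0 ** (-(t - profile.peak_time_h) / profile.half_life_h)
    return profile.baseline_pct + np.where(t < profile.peak_time_h, rise, decay)


@dataclass(frozen=True)
class CohortSpec:
    groups: dict[str, GroupSpec]
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    ais_profiles: tuple[AISProfile, ...] = ()
    sampling_times_h: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 24.0, 48.0, 72.0, 96.0)
    ais_noise_sd_pct: float = 0.05
    gfap_int_ratio: float = 0.05  # intermediate rate as a ratio of non-classical
    plp1_ratio: float = 0.15     # PLP1+ rate as a ratio of the GFAP+ rate
    n_events: int = 30_000
    marker_shift: float = 2.0
    multi_sample_fraction: float = 0.12


#: Table-2-like stroke profiles: three large infarcts (>=100 cm^3) with high
#: early peaks, two borderline patients with a single marginal excursion, and
#: four small/no infarcts that stay below the cutoff.
DEFAULT_AIS_PROFILES = (
    AISProfile("AIS001", 16.7, 0.75, 2.0, 1.5),
    AISProfile("AIS002", 25.2, 0.25),
    AISProfile("AIS004", 0.1, 0.10),
    AISProfile("AIS005", 191.2, 2.0),
    AISProfile("AIS007", 0.0, 0.10),
    AISProfile("AIS008", 96.1, 0.75, 2.0, 1.5),
    AISProfile("AIS010", 33.2, 0.25),
    AISProfile("AIS013", 219.1, 2.2),
    AISProfile("AIS014", 120.0, 1.5),
)


def default_cohort_spec(n_events: int = 30_000, scale: float = 1.0) -> CohortSpec:
    """Default glioma-suspect cohort mirroring a realistic case mix.

    ``scale`` shrinks every group proportionally (minimum one sample per
    group) for fast smoke runs; the default is the full case mix.
    """
    groups = {
        "WHO-I": GroupSpec(2, ("lognormal", 4.0, 1.0), mean_tumour_size_cm=3.6,
                           median_age=50),
        "diffuse-astrocytoma": GroupSpec(28, ("lognormal", 6.0, 1.0),
                                         mean_tumour_size_cm=2.8, median_age=51),
        "oligodendroglioma": GroupSpec(32, ("lognormal", 7.0, 1.0),
                                       mean_tumour_size_cm=3.5, median_age=55),
        "GBM": GroupSpec(145, ("lognormal", 8.5, 1.0), mean_tumour_size_cm=3.5,
                         median_age=63, has_survival=True),
        "metastasis": GroupSpec(21, ("lognormal", 9.0, 1.0), mean_tumour_size_cm=2.7,
                                median_age=61, has_survival=True),
        "healthy": GroupSpec(38, ("lognormal", 2.0, 0.8), median_age=52),
    }
    if scale != 1.0:
        groups = {name: replace(g, n_samples=max(int(round(g.n_samples * scale)), 1))
                  for name, g in groups.items()}
    return CohortSpec(groups=groups, ais_profiles=DEFAULT_AIS_PROFILES,
                      n_events=n_events)


def _draw_fraction(dist: tuple, rng: np.random.Generator) -> float:
    """Draw a true GFAP+ non-classical fraction, in percent."""
    family = dist[0]
    if family == "lognormal":
        median_pct, sigma = dist[1], dist[2]
        return float(min(np.exp(rng.normal(np.log(median_pct), sigma)), 90.0))
    if family == "beta":
        return float(100.0 * rng.beta(dist[1], dist[2]))
    raise SpecError(f"unknown fraction distribution family {family!r}")


def _censoring_horizon(surv: SurvivalSpec, p_high: float) -> float:
    """Solve for H with C ~ U(0, H) s.t. E[censoring fraction] = censoring_rate."""
    k = surv.shape

    def surv_mix(t: float) -> float:
        s_lo = math.exp(-((t / surv.scale_low) ** k))
        s_hi = math.exp(-((t / surv.scale_high) ** k))
        return (1 - p_high) * s_lo + p_high * s_hi

    def censor_frac(h: float) -> float:
        e_min = integrate.quad(surv_mix, 0, h, limit=200)[0]
        return e_min / h

    return float(optimize.brentq(lambda h: censor_frac(h) - surv.censoring_rate,
                                 1e-3, 1e5, xtol=1e-6))


def _p_high_arm(dist: tuple, threshold_pct: float) -> float:
    if dist[0] == "lognormal":
        from scipy.stats import norm
        z = (math.log(threshold_pct) - math.log(dist[1])) / dist[2]
        return float(1 - norm.cdf(z))
    if dist[0] == "beta":
        from scipy.stats import beta as beta_dist
        return float(beta_dist.sf(threshold_pct / 100.0, dist[1], dist[2]))
    raise SpecError(f"unknown fraction distribution family {dist[0]!r}")


def simulate_cohort(
    spec: CohortSpec,
    seed: int = 0,
    out_dir: str | Path | None = None,
    event_level: bool = True,
    format: str = "csv",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, EventTable]]:
    """Generate a whole cohort: metadata, truth table, optional event files.

    Returns ``(cohort, truth, events)``. The cohort table holds the clinical
    metadata columns; the truth table the generator's per-sample true marker
    fractions and survival arm. Whole-cohort generation is a pure function of
    ``(spec, seed)``.
    """
    if not spec.groups:
        raise SpecError("cohort spec needs at least one diagnosis group")
    rng = np.random.default_rng(seed)

    horizon: float | None = None
    surv_groups = [g for g in spec.groups.values() if g.has_survival]
    if surv_groups and spec.survival.censoring_rate > 0:
        p_high = _p_high_arm(surv_groups[0].gfap_nc_dist, spec.survival.threshold_pct)
        horizon = _censoring_horizon(spec.survival, p_high)

    cohort_rows, truth_rows = [], []
    events: dict[str, EventTable] = {}
    sample_counter = 0
    for group_name, g in spec.groups.items():
        remaining = g.n_samples
        patient_counter = 0
        while remaining > 0:
            patient_counter += 1
            patient_id = f"{group_name}-P{patient_counter:03d}"
            n_for_patient = 2 if (remaining >= 2
                                  and rng.random() < spec.multi_sample_fraction) else 1
            r_nc_pct = _draw_fraction(g.gfap_nc_dist, rng)

            os_months = os_event = None
            high_arm = r_nc_pct > spec.survival.threshold_pct
            if g.has_survival:
                scale = (spec.survival.scale_high if high_arm
                         else spec.survival.scale_low)
                t = float(scale * rng.weibull(spec.survival.shape))
                if horizon is None:
                    os_months, os_event = t, True
                else:
                    c = float(rng.uniform(0, horizon))
                    os_months, os_event = min(t, c), t <= c

            for _ in range(n_for_patient):
                remaining -= 1
                sample_counter += 1
                sample_id = f"S{sample_counter:04d}"
                # a repeat sample re-measures the same biology with mild drift
                r_nc = min(r_nc_pct * float(np.exp(rng.normal(0, 0.1))), 90.0) / 100
                r_int = r_nc * spec.gfap_int_ratio
                wbc = float(np.exp(rng.normal(np.log(g.wbc_median), g.wbc_sigma)))
                diam = (np.nan, np.nan, np.nan)
                if np.isfinite(g.mean_tumour_size_cm):
                    base = g.mean_tumour_size_cm * (r_nc * 100 / g.gfap_nc_dist[1]) ** 0.2
                    diam = tuple(np.maximum(
                        rng.normal(base, 0.6, size=3), 0.5).round(1))
                w_int = DEFAULT_WEIGHTS["intermediate_mono"]
                w_nc = DEFAULT_WEIGHTS["nonclassical_mono"]
                true_cd16_pct = 100 * (w_int * r_int + w_nc * r_nc) / (w_int + w_nc)

                cohort_rows.append({
                    "sample_id": sample_id,
                    "patient_id": patient_id,
                    "diagnosis_group": group_name,
                    "age": float(np.clip(rng.normal(g.median_age, 10), 18, 95)),
                    "sex": "M" if rng.random() < 0.62 else "F",
                    "kps": int(rng.choice([60, 70, 80, 90, 100],
                                          p=[0.05, 0.1, 0.2, 0.45, 0.2])),
                    "dexamethasone_use": bool(rng.random() < 0.5
                                              and group_name != "healthy"),
                    "tumour_diameter_1": diam[0],
                    "tumour_diameter_2": diam[1],
                    "tumour_diameter_3": diam[2],
                    "wbc_count": round(wbc, 1),
                    "os_months": (round(os_months, 3)
                                  if os_months is not None else np.nan),
                    "os_event": os_event if os_event is not None else pd.NA,
                    "sampling_timing": "pre-operative",
                })
                truth_rows.append({
                    "sample_id": sample_id,
                    "patient_id": patient_id,
                    "diagnosis_group": group_name,
                    "true_gfap_nc_pct": r_nc * 100,
                    "true_gfap_int_pct": r_int * 100,
                    "true_gfap_cd16_pct": true_cd16_pct,
                    "high_arm": high_arm if g.has_survival else pd.NA,
                })
                if event_level:
                    sub_seed = int(rng.integers(0, 2**31 - 1))
                    sspec = SampleSpec(
                        sample_id, spec.n_events,
                        default_populations(
                            gfap_nonclassical=r_nc,
                            gfap_intermediate=r_int,
                            plp1_nonclassical=min(r_nc * spec.plp1_ratio, 1.0),
                            plp1_intermediate=min(r_int * spec.plp1_ratio, 1.0)),
                        marker_shift=spec.marker_shift, seed=sub_seed)
                    events[sample_id] = simulate_sample(sspec)

    cohort = pd.DataFrame(cohort_rows)
    truth = pd.DataFrame(truth_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out / "cohort_metadata.csv", index=False)
        truth.to_csv(out / "cohort_truth.csv", index=False)
        for sid, table in events.items():
            write_event_table(table, out / f"{sid}.{format}", format=format)
    return cohort, truth, events


def simulate_ais_timecourse(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Per-patient GFAP+CD16+ monocyte time series after stroke onset.

    Columns: patient_id, hours_since_onset, pct_gfap_cd16 (noisy, >= 0),
    true_pct (noiseless curve), infarct_volume.
    """
    times = np.asarray(spec.sampling_times_h, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise SpecError("sampling times must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for profile in spec.ais_profiles:
        truth = ais_profile_value(profile, times)
        noisy = np.maximum(truth + rng.normal(0, spec.ais_noise_sd_pct, times.size), 0)
        for t, y, y0 in zip(times, noisy, truth):
            rows.append({"patient_id": profile.patient_id,
                         "hours_since_onset": t,
                         "pct_gfap_cd16": float(y),
                         "true_pct": float(y0),
                         "infarct_volume": profile.infarct_volume})
    return pd.DataFrame(rows)
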