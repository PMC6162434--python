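"""Multi-subject synthetic cohorts with known ground truth.

A cohort is drawn from per-group normal distributions (truncated at zero)
of the per-tumor metrics the pipeline measures — normalized conversion
(nLac), ¹³C lactate and pyruvate ADCs, H&E cellularity and % MCT4 staining
— and the corresponding raw data (dynamic HP series, diffusion stacks,
histology images) are synthesized so that running the analysis pipeline on
the noiseless data recovers the drawn values.

The default cohort emulates three orthotopic human renal-cell-carcinoma
lines with distinct glycolytic phenotypes: A-498 (n = 8; high LDHA-driven
conversion, high MCT4 lactate export, low cellularity), UOK262 (n = 7; an
FH-deficient hereditary papillary line) and 786-O (n = 8).  Group SDs are
reconstructed from reported SEMs as SD = SEM·√n.

The tumor ¹H ADC is not an independent draw: it is derived linearly from
the subject's cellularity (water diffusion is restricted by cell density),
anchored at 1.35×10⁻³ mm²/s for 16% cellularity with a −0.0357×10⁻³ slope
per cellularity point plus Gaussian scatter, which reproduces an inverse
cellularity–ADC correlation near r ≈ −0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from hpcmri.dynamics import DynamicSeries, conversion_metrics, flip_angle_correct
from hpcmri.phantoms import (
    DabPhantom,
    HEPhantom,
    HistoPhantomSpec,
    generate_dab_phantom,
    generate_he_phantom,
)
from hpcmri.simulate import (
    B_VALUES_C13,
    B_VALUES_H1,
    AcquisitionSchedule,
    DiffusionPhantomSpec,
    ExchangeParams,
    make_vfa_schedule,
    simulate_diffusion_signal,
)

# 1H-ADC-from-cellularity model (mm²/s per cellularity point)
H1_ADC_AT_16PCT = 1.35e-3
H1_ADC_SLOPE = -0.0357e-3
H1_ADC_SCATTER_SD = 0.14e-3
H1_ADC_FLOOR = 0.4e-3

METRICS = ("nlac", "lactate_adc", "pyruvate_adc", "cellularity_pct", "mct4_pct")


@dataclass(frozen=True)
class GroupSpec:
    """One tumor group: label, size, and (mean, SD) per ground-truth metric."""

    label: str
    n: int
    metrics: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        missing = set(METRICS) - set(self.metrics)
        if missing:
            raise ValueError(f"group {self.label!r} missing metrics: {sorted(missing)}")
        for name, (mean, sd) in self.metrics.items():
            if sd < 0:
                raise ValueError(f"{self.label}/{name}: SD must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """A set of groups plus the RNG seed that makes the cohort reproducible."""

    groups: tuple[GroupSpec, ...]
    seed: int | None = None


@dataclass
class SubjectData:
    """Ground truth and synthesized raw data for one tumor."""

    subject_id: str
    group: str
    truth: dict[str, float]
    dynamics: DynamicSeries | None = None
    h1_stack: np.ndarray | None = None
    h1_b_values: tuple[float, ...] = B_VALUES_H1
    lac_stack: np.ndarray | None = None
    pyr_stack: np.ndarray | None = None
    c13_b_values: tuple[float, ...] = B_VALUES_C13
    dwi_mask: np.ndarray | None = None
    he: HEPhantom | None = None
    dab: DabPhantom | None = None


@dataclass
class CohortResult:
    """Ground-truth table plus per-subject synthetic datasets."""

    truth: pd.DataFrame
    subjects: list[SubjectData] = field(default_factory=list)


def default_cohort_spec(seed: int | None = None) -> CohortSpec:
    """Cohort emulating the three orthotopic RCC lines (SD = SEM·√n)."""

    def g(label, n, nlac_sem, lac_sem, pyr_sem, cell_sem, mct4_sem,
          nlac, lac, pyr, cell, mct4):
        rt = np.sqrt(n)
        return GroupSpec(
            label=label,
            n=n,
            metrics={
                "nlac": (nlac, nlac_sem * rt),
                "lactate_adc": (lac, lac_sem * rt),
                "pyruvate_adc": (pyr, pyr_sem * rt),
                "cellularity_pct": (cell, cell_sem * rt),
                "mct4_pct": (mct4, mct4_sem * rt),
            },
        )

    return CohortSpec(
        groups=(
            g("A-498", 8, 0.25e-3, 0.018e-3, 0.115e-3, 0.5, 0.63,
              2.70e-3, 0.495e-3, 1.120e-3, 16.0, 9.87),
            g("UOK262", 7, 0.23e-3, 0.024e-3, 0.058e-3, 1.0, 0.68,
              1.90e-3, 0.443e-3, 0.977e-3, 23.0, 5.87),
            g("786-O", 8, 0.15e-3, 0.027e-3, 0.037e-3, 0.8, 0.47,
              2.05e-3, 0.421e-3, 0.916e-3, 23.0, 4.4),
        ),
        seed=seed,
    )


def conversion_ratio_for_kpl(
    kpl: float,
    schedule: AcquisitionSchedule | None = None,
    params: ExchangeParams | None = None,
) -> float:
    """Lac_AUC/Pyr_max produced by the acquisition model at a given kPL.

    Deterministic (noiseless simulation → flip-angle correction → metrics);
    monotonically increasing in kPL over the physiological range.
    """
    from hpcmri.simulate import simulate_hp_dynamics

    schedule = schedule or make_vfa_schedule()
    base = params or ExchangeParams()
    p = ExchangeParams(
        kpl=kpl, r1p=base.r1p, r1l=base.r1l,
        input_start=base.input_start, input_duration=base.input_duration,
        input_amplitude=base.input_amplitude, p0=base.p0, l0=base.l0,
    )
    series = simulate_hp_dynamics(p, schedule)
    corrected = flip_angle_correct(series)
    return conversion_metrics(corrected).ratio


def solve_kpl_for_ratio(
    ratio_target: float,
    schedule: AcquisitionSchedule | None = None,
    params: ExchangeParams | None = None,
    kpl_max: float = 0.5,
) -> float:
    """Invert the monotone ratio(kPL) map of the acquisition model."""
    if ratio_target < 0:
        raise ValueError("ratio_target must be >= 0")
    if ratio_target == 0:
        return 0.0
    f = lambda k: conversion_ratio_for_kpl(k, schedule, params) - ratio_target
    hi = kpl_max
    if f(hi) < 0:
        raise ValueError(f"ratio {ratio_target} not reachable with kPL <= {kpl_max}")
    return float(brentq(f, 0.0, hi, xtol=1e-7))


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated at zero (metrics are physically non-negative)."""
    if sd == 0:
        return np.full(size, mean, dtype=float)
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                         random_state=rng)


def generate_cohort(
    spec: CohortSpec,
    schedule: AcquisitionSchedule | None = None,
    exchange_defaults: ExchangeParams | None = None,
    image_shape: tuple[int, int] = (512, 512),
    dwi_grid: tuple[int, int] = (8, 8),
    include_dynamics: bool = True,
    include_diffusion: bool = True,
    include_histology: bool = True,
) -> CohortResult:
    """Draw ground-truth metrics per subject and synthesize their raw data.

    Noiseless synthesis: re-running the analysis pipeline on the returned
    raw data recovers the drawn ground truth (to solver/segmentation
    accuracy), which is the basis of the parameter-recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    schedule = schedule or make_vfa_schedule()
    rows = []
    subjects: list[SubjectData] = []
    for group in spec.groups:
        draws = {
            m: _draw_truncated(rng, *group.metrics[m], size=group.n) for m in METRICS
        }
        for i in range(group.n):
            sid = f"{group.label}-{i + 1:02d}"
            cell = float(draws["cellularity_pct"][i])
            h1_adc = (
                H1_ADC_AT_16PCT
                + H1_ADC_SLOPE * (cell - 16.0)
                + rng.normal(0.0, H1_ADC_SCATTER_SD)
            )
            h1_adc = max(h1_adc, H1_ADC_FLOOR)
            truth = {m: float(draws[m][i]) for m in METRICS}
            truth["h1_adc"] = h1_adc
            truth["ratio"] = truth["nlac"] / h1_adc
            subject = SubjectData(subject_id=sid, group=group.label, truth=truth)

            if include_dynamics:
                kpl = solve_kpl_for_ratio(truth["ratio"], schedule, exchange_defaults)
                truth["kpl"] = kpl
                base = exchange_defaults or ExchangeParams()
                params = ExchangeParams(
                    kpl=kpl, r1p=base.r1p, r1l=base.r1l,
                    input_start=base.input_start,
                    input_duration=base.input_duration,
                    input_amplitude=base.input_amplitude,
                )
                from hpcmri.simulate import simulate_hp_dynamics

                subject.dynamics = simulate_hp_dynamics(params, schedule)
            if include_diffusion:
                subject.h1_stack = simulate_diffusion_signal(
                    DiffusionPhantomSpec(
                        adc_true=h1_adc, b_values=B_VALUES_H1, grid_shape=dwi_grid
                    )
                )
                subject.lac_stack = simulate_diffusion_signal(
                    DiffusionPhantomSpec(
                        adc_true=truth["lactate_adc"],
                        b_values=B_VALUES_C13,
                        grid_shape=dwi_grid,
                    )
                )
                subject.pyr_stack = simulate_diffusion_signal(
                    DiffusionPhantomSpec(
                        adc_true=truth["pyruvate_adc"],
                        b_values=B_VALUES_C13,
                        grid_shape=dwi_grid,
                    )
                )
                subject.dwi_mask = np.ones(dwi_grid, dtype=bool)
            if include_histology:
                he_seed, dab_seed = rng.integers(0, 2**31 - 1, size=2)
                subject.he = generate_he_phantom(
                    HistoPhantomSpec(
                        image_shape=image_shape,
                        target_nuclei_fraction=truth["cellularity_pct"] / 100.0,
                        seed=int(he_seed),
                    )
                )
                subject.dab = generate_dab_phantom(
                    HistoPhantomSpec(
                        image_shape=image_shape,
                        target_stain_fraction=truth["mct4_pct"] / 100.0,
                        seed=int(dab_seed),
                    )
                )
            rows.append({"subject_id": sid, "group": group.label, **truth})
            subjects.append(subject)
    return CohortResult(truth=pd.DataFrame(rows), subjects=subjects)
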