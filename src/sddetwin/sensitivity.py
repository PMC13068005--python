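"""Robustness analyses for the delay–event association.

Three perturbations probe whether the association between the time-to-peak
delay feature and the event label survives departures from the calibrated,
fully deterministic event definition:

1. **Prevalence variation** — the event threshold is recalibrated at
   alternative prevalences (15%, 20%, 30%) and the association reassessed.
2. **Outcome noise** — independent Gaussian noise, with SD a fraction of
   the cohort SD of max Y, is added to max Y *at the event-definition
   stage only* (trajectories untouched) and events are relabeled from the
   noisy values.
3. **Parameter heterogeneity** — selected parameters (by default the delay
   and gain terms linking CRP and albumin to the output: tau7, tau8,
   beta1, beta2) vary across subjects, drawn from normal distributions
   centered on the nominal values with a given coefficient of variation;
   non-positive draws are rejected and redrawn, and perturbed delays are
   snapped to the nearest positive grid multiple.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import stats as st
from .cohort import (
    CohortResult,
    TrajectoryMetrics,
    build_cohort,
    calibrate_threshold,
    label_events,
)
from .inflammation_models import (
    CASCADE_DELAY_FIELDS,
    CascadeParameters,
    default_parameters,
)

__all__ = [
    "OutcomeNoiseConfig",
    "HeterogeneitySpec",
    "AssociationSummary",
    "relabel_at_prevalence",
    "add_outcome_noise",
    "draw_heterogeneous_parameters",
    "run_sensitivity_suite",
    "DEFAULT_PERTURBED_PARAMETERS",
]

DEFAULT_PERTURBED_PARAMETERS = ("tau7", "tau8", "beta1", "beta2")


@dataclass(frozen=True)
class OutcomeNoiseConfig:
    """Noise at the event-definition stage: SD = sd_fraction x SD(max Y)."""

    sd_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sd_fraction <= 1.0:
            raise ValueError(
                f"sd_fraction must lie in [0, 1], got {self.sd_fraction}"
            )


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Interindividual variability of selected cascade parameters."""

    cv: float = 0.10
    perturbed_parameters: tuple = DEFAULT_PERTURBED_PARAMETERS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")
        object.__setattr__(
            self, "perturbed_parameters", tuple(self.perturbed_parameters)
        )
        valid = {f for f in CascadeParameters.__dataclass_fields__}
        for name in self.perturbed_parameters:
            if name not in valid:
                raise ValueError(f"unknown cascade parameter {name!r}")


@dataclass(frozen=True)
class AssociationSummary:
    """Delay–event association under one labeling of the cohort."""

    n_events: int
    mean_tpk_event: float
    mean_tpk_nonevent: float
    p_value: float
    auc: float
    separated: bool
    overlap_fraction: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "mean_tpk_event": self.mean_tpk_event,
            "mean_tpk_nonevent": self.mean_tpk_nonevent,
            "p_value": self.p_value,
            "auc": self.auc,
            "separated": self.separated,
            "overlap_fraction": self.overlap_fraction,
            "degenerate": self.degenerate,
        }


def summarize_association(metrics: Sequence[TrajectoryMetrics]) -> AssociationSummary:
    """Group means, rank-sum p, AUC and separation flag for a labeled cohort."""
    tpk = np.array([m.time_to_peak_y for m in metrics])
    ev = np.array([m.event_cv for m in metrics])
    n_events = int(ev.sum())
    if n_events == 0 or n_events == ev.size:
        return AssociationSummary(
            n_events=n_events,
            mean_tpk_event=float(tpk[ev == 1].mean()) if n_events else float("nan"),
            mean_tpk_nonevent=float(tpk[ev == 0].mean()) if n_events < ev.size
            else float("nan"),
            p_value=float("nan"), auc=float("nan"),
            separated=False, overlap_fraction=float("nan"), degenerate=True,
        )
    comp = st.mann_whitney_u(tpk[ev == 1], tpk[ev == 0])
    sep = st.detect_complete_separation(tpk, ev)
    return AssociationSummary(
        n_events=n_events,
        mean_tpk_event=float(tpk[ev == 1].mean()),
        mean_tpk_nonevent=float(tpk[ev == 0].mean()),
        p_value=comp.p_value,
        auc=st.roc_auc(tpk, ev),
        separated=sep.separated,
        overlap_fraction=sep.overlap_fraction,
    )


def relabel_at_prevalence(
    metrics: Sequence[TrajectoryMetrics], prevalence: float
):
    """Recalibrate the threshold at a new prevalence and reassess association.

    Returns ``(threshold, relabeled metrics, AssociationSummary)``; a
    degenerate labeling (all or no events) is flagged in the summary rather
    than raising.
    """
    if len(metrics) == 0:
        raise ValueError("metrics must be nonempty")
    max_y = [m.max_y for m in metrics]
    threshold = calibrate_threshold(max_y, prevalence)
    relabeled = label_events(metrics, threshold)
    return threshold, relabeled, summarize_association(relabeled)


def add_outcome_noise(
    metrics: Sequence[TrajectoryMetrics],
    config: OutcomeNoiseConfig,
    prevalence: float = 0.20,
) -> list:
    """Relabel events from noisy observed peaks max_y + eps.

    eps is Gaussian, independent per subject, with SD equal to
    ``sd_fraction`` times the sample SD of max Y. The returned metrics keep
    the original max_y (trajectories and stored peaks are untouched); only
    event_cv reflects the noisy observation, relabeled by a threshold
    recalibrated on the noisy values at the given prevalence.
    """
    if len(metrics) < 2:
        raise ValueError("outcome noise needs >= 2 subjects (SD undefined)")
    max_y = np.array([m.max_y for m in metrics])
    sd = float(np.std(max_y, ddof=1))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    noisy = max_y + rng.normal(0.0, config.sd_fraction * sd, size=max_y.size)
    threshold = calibrate_threshold(noisy, prevalence)
    return [
        replace(m, event_cv=int(v > threshold))
        for m, v in zip(metrics, noisy)
    ]


def draw_heterogeneous_parameters(
    nominal: CascadeParameters,
    spec: HeterogeneitySpec,
    n_subjects: int,
) -> list:
    """Per-subject parameter sets with Normal(nominal, (cv*nominal)^2) draws.

    Non-positive draws are rejected and redrawn (preserving the truncated
    normal shape rather than clamping); perturbed delays are snapped to the
    nearest positive multiple of the grid step. Unlisted parameters stay at
    their nominal values. Returns a list of ``CascadeParameters``; the
    number of rejected draws is recorded on the function attribute
    ``last_rejections``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    dt = nominal.grid.dt
    delay_fields = set(CASCADE_DELAY_FIELDS)
    rejections = 0
    out = []
    for _ in range(n_subjects):
        updates = {}
        for name in spec.perturbed_parameters:
            mu = getattr(nominal, name)
            if spec.cv == 0 or mu == 0:
                continue
            draw = rng.normal(mu, spec.cv * mu)
            while draw <= 0:
                rejections += 1
                draw = rng.normal(mu, spec.cv * mu)
            if name in delay_fields:
                draw = max(1, round(draw / dt)) * dt
            updates[name] = float(draw)
        out.append(nominal.with_updates(**updates) if updates else nominal)
    draw_heterogeneous_parameters.last_rejections = rejections
    return out


def _perturbed_cohort(
    params: CascadeParameters,
    n_subjects: int,
    master_seed: int,
    het: HeterogeneitySpec,
    noise: OutcomeNoiseConfig,
    prevalence: float = 0.20,
) -> CohortResult:
    """Cohort under heterogeneity + outcome noise, relabeled at ``prevalence``."""
    plist = draw_heterogeneous_parameters(params, het, n_subjects)
    cohort = build_cohort(params, n_subjects, prevalence, master_seed,
                          param_list=plist)
    noisy_metrics = add_outcome_noise(cohort.metrics, noise, prevalence)
    return replace(cohort, metrics=tuple(noisy_metrics))


def run_sensitivity_suite(
    preset: str = "reference",
    master_seed: int = 0,
    n_subjects: int = 100,
    prevalences: Sequence[float] = (0.15, 0.20, 0.30),
    noise: OutcomeNoiseConfig | None = None,
    heterogeneity: HeterogeneitySpec | None = None,
) -> dict:
    """Run all three robustness analyses on a common base cohort.

    Returns a JSON-serializable report with one block per analysis plus the
    unperturbed base association; fully reproducible from
    (preset, master_seed).
    """
    params = default_parameters(preset)
    base = build_cohort(params, n_subjects, 0.20, master_seed,
                        preset_name=preset)
    base_summary = summarize_association(base.metrics)

    prevalence_block = {}
    for prev in prevalences:
        thr, _, summary = relabel_at_prevalence(base.metrics, prev)
        prevalence_block[f"{prev:.2f}"] = {
            "threshold": thr, **summary.to_dict(),
        }

    noise = noise or OutcomeNoiseConfig(seed=master_seed + 1)
    noisy_metrics = add_outcome_noise(base.metrics, noise)
    noise_block = {
        "sd_fraction": noise.sd_fraction,
        **summarize_association(noisy_metrics).to_dict(),
    }

    heterogeneity = heterogeneity or HeterogeneitySpec(seed=master_seed + 2)
    het_cohort = _perturbed_cohort(
        params, n_subjects, master_seed + 3, heterogeneity,
        OutcomeNoiseConfig(sd_fraction=noise.sd_fraction, seed=master_seed + 4),
    )
    het_block = {
        "cv": heterogeneity.cv,
        "perturbed_parameters": list(heterogeneity.perturbed_parameters),
        "rejected_draws": draw_heterogeneous_parameters.last_rejections,
        **summarize_association(het_cohort.metrics).to_dict(),
    }

    return {
        "preset": preset,
        "preset_hash": params.content_hash(),
        "master_seed": master_seed,
        "n_subjects": n_subjects,
        "base": base_summary.to_dict(),
        "analyses": {
            "prevalence_variation": prevalence_block,
            "outcome_noise": noise_block,
            "parameter_heterogeneity": het_block,
        },
    }
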