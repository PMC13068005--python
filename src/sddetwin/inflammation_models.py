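"""Concrete SDDE systems for delayed inflammatory biomarker cascades.

Two models are defined:

* a two-variable stimulus → biomarker → output system,

      dB = [a1 S(t-tau1) - a2 B(t-tau2)] dt + s1 B(t-tau2) dW1
      dY = [b1 B(t-tau3) - b2 Y(t-tau3)] dt + s2 Y(t-tau3) dW2

* the four-variable cascade used for virtual cohorts, in which a stressor
  S(t) triggers a fast neutrophil response B1, which induces the
  intermediate acute-phase reactant CRP (B2), which suppresses the slow
  negative regulator albumin (B3); a latent cardio-inflammatory output Y
  integrates the pro-inflammatory (CRP, positive) and regulatory (albumin,
  negative) arms:

      dB1 = [a1 S(t-tau1) - a2 B1(t-tau2)] dt + s1 B1(t-tau2) dW1
      dB2 = [g1 B1(t-tau3) - g2 B2(t-tau4)] dt + s2 B2(t-tau4) dW2
      dB3 = [th1 - th2 B2(t-tau5) - th3 B3(t-tau6)] dt + s3 B3(t-tau6) dW3
      dY  = [b1 B2(t-tau7) - b2 B3(t-tau8) - b3 Y(t-tau9)] dt + s4 Y(t-tau9) dW4

Each interaction carries its own lag tau_i; the lags respect the
fast / intermediate / slow ordering of the innate immune cascade
(neutrophil activation within the shortest lags, CRP induction at
intermediate lags, albumin regulation at the longest). All noise is
multiplicative in a *delayed* state — fluctuations manifest with a memory
of where the system was, not where it is. Time is in abstract units.

Parameter values ship as version-pinned presets (YAML files under
``presets/``); :func:`default_parameters` loads them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, asdict, replace
from importlib import resources

import numpy as np
import yaml

from .sdde_core import GridError, InvalidLagError, SDDESystem, TimeGrid, delay_to_steps

__all__ = [
    "StressorSpec",
    "TwoVarParameters",
    "CascadeParameters",
    "stressor_value",
    "build_two_var_system",
    "build_cascade_system",
    "default_parameters",
    "available_presets",
    "CASCADE_RATE_FIELDS",
    "CASCADE_SIGMA_FIELDS",
    "CASCADE_DELAY_FIELDS",
]


@dataclass(frozen=True)
class StressorSpec:
    """External input stressor S(t): a rectangular pulse by default.

    ``amplitude`` for ``onset <= t < onset + duration``, zero elsewhere.
    """

    amplitude: float = 1.0
    onset: float = 5.0
    duration: float = 10.0
    shape: str = "rectangular"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"stressor amplitude must be >= 0, got {self.amplitude}")
        if self.duration < 0:
            raise ValueError(f"stressor duration must be >= 0, got {self.duration}")
        if self.shape != "rectangular":
            raise ValueError(f"unknown stressor shape {self.shape!r}")


def stressor_value(spec: StressorSpec, t):
    """Evaluate S(t) (scalar or array t): amplitude inside the pulse, else 0."""
    t = np.asarray(t, dtype=float)
    inside = (t >= spec.onset) & (t < spec.onset + spec.duration)
    out = np.where(inside, spec.amplitude, 0.0)
    return float(out) if out.ndim == 0 else out


def _check_nonneg(obj, names) -> None:
    for name in names:
        v = getattr(obj, name)
        if v < 0:
            raise ValueError(f"parameter {name} must be >= 0, got {v}")


@dataclass(frozen=True)
class TwoVarParameters:
    """Rates, noise intensities, lags and baselines of the two-variable model."""

    alpha1: float = 1.0   # stimulus amplification of B
    alpha2: float = 0.5   # biomarker clearance
    beta1: float = 0.5    # output sensitivity to B
    beta2: float = 0.2    # output decay
    sigma1: float = 0.0
    sigma2: float = 0.0
    tau1: float = 1.0
    tau2: float = 1.0
    tau3: float = 2.0
    baseline_b: float = 0.0
    baseline_y: float = 0.0

    def __post_init__(self) -> None:
        _check_nonneg(self, ["alpha1", "alpha2", "beta1", "beta2",
                             "sigma1", "sigma2", "tau1", "tau2", "tau3"])


CASCADE_RATE_FIELDS = (
    "alpha1", "alpha2", "gamma1", "gamma2",
    "theta1", "theta2", "theta3", "beta1", "beta2", "beta3",
)
CASCADE_SIGMA_FIELDS = ("sigma1", "sigma2", "sigma3", "sigma4")
CASCADE_DELAY_FIELDS = (
    "tau1", "tau2", "tau3", "tau4", "tau5", "tau6", "tau7", "tau8", "tau9",
)


@dataclass(frozen=True)
class CascadeParameters:
    """Every constant of the four-variable cascade plus stressor and grid.

    Rates: alpha1/alpha2 (stress→neutrophil gain, neutrophil clearance),
    gamma1/gamma2 (neutrophil→CRP gain, CRP clearance), theta1/theta2/theta3
    (albumin baseline production, CRP→albumin suppression, albumin
    relaxation), beta1/beta2/beta3 (CRP→Y gain, albumin→Y suppression,
    Y decay). sigma1..4 are multiplicative noise intensities; tau1..tau9 the
    interaction lags; baselines give the constant pre-history.
    """

    alpha1: float
    alpha2: float
    gamma1: float
    gamma2: float
    theta1: float
    theta2: float
    theta3: float
    beta1: float
    beta2: float
    beta3: float
    sigma1: float
    sigma2: float
    sigma3: float
    sigma4: float
    tau1: float
    tau2: float
    tau3: float
    tau4: float
    tau5: float
    tau6: float
    tau7: float
    tau8: float
    tau9: float
    baseline_b1: float = 0.0
    baseline_b2: float = 0.0
    baseline_b3: float = 0.0
    baseline_y: float = 0.0
    stressor: StressorSpec = field(default_factory=StressorSpec)
    grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self) -> None:
        _check_nonneg(self, CASCADE_RATE_FIELDS + CASCADE_SIGMA_FIELDS
                      + CASCADE_DELAY_FIELDS)
        # fast (neutrophil) <= intermediate (CRP) <= slow (albumin) lags
        if not (max(self.tau1, self.tau2) <= min(self.tau3, self.tau4)
                and max(self.tau3, self.tau4) <= min(self.tau5, self.tau6)):
            raise ValueError(
                "cascade delay ordering violated: need tau1,tau2 <= tau3,tau4 "
                "<= tau5,tau6"
            )
        for name in CASCADE_DELAY_FIELDS:
            tau = getattr(self, name)
            if tau != 0.0 and tau < self.grid.dt:
                raise GridError(f"{name}={tau} not representable on dt={self.grid.dt}")

    @property
    def delays(self) -> tuple:
        return tuple(getattr(self, name) for name in CASCADE_DELAY_FIELDS)

    @property
    def baselines(self) -> np.ndarray:
        """Constant pre-history vector (B1, B2, B3, Y)."""
        return np.array([self.baseline_b1, self.baseline_b2,
                         self.baseline_b3, self.baseline_y])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stressor"] = asdict(self.stressor)
        d["grid"] = {"t0": self.grid.t0, "t_end": self.grid.t_end, "dt": self.grid.dt}
        return d

    def content_hash(self) -> str:
        """Stable short hash of the full parameter set, for output metadata."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def with_updates(self, **kwargs) -> "CascadeParameters":
        return replace(self, **kwargs)


def build_two_var_system(
    p: TwoVarParameters,
    stressor: StressorSpec,
    literal_clearance_on_stimulus: bool = False,
) -> SDDESystem:
    """Two-variable SDDE: stimulus-driven biomarker B and delayed output Y.

    The clearance term acts on the biomarker, -alpha2*B(t-tau2). Setting
    ``literal_clearance_on_stimulus`` replaces it with -alpha2*S(t-tau2)
    (a fidelity-audit variant in which the second drift term reads the
    stimulus rather than the biomarker).
    """
    delays = (p.tau1, p.tau2, p.tau3)

    def drift(t, x, delayed):
        s_lag = stressor_value(stressor, t - p.tau1)
        if literal_clearance_on_stimulus:
            clear = p.alpha2 * stressor_value(stressor, t - p.tau2)
        else:
            clear = p.alpha2 * delayed[1][0]
        return np.array([
            p.alpha1 * s_lag - clear,
            p.beta1 * delayed[2][0] - p.beta2 * delayed[2][1],
        ])

    def diffusion(t, delayed):
        return np.array([p.sigma1 * delayed[1][0], p.sigma2 * delayed[2][1]])

    return SDDESystem(state_dim=2, delays=delays, drift=drift, diffusion=diffusion)


def build_cascade_system(p: CascadeParameters) -> SDDESystem:
    """Four-variable cascade SDDE (states ordered B1, B2, B3, Y)."""
    s = p.stressor
    for name in CASCADE_DELAY_FIELDS:
        tau = getattr(p, name)
        if tau != 0.0 and tau < p.grid.dt:
            raise GridError(f"{name}={tau} smaller than dt={p.grid.dt}")

    def drift(t, x, delayed):
        # delayed[i] is the state at t - tau_{i+1}
        s_lag = stressor_value(s, t - p.tau1)
        b1_t2 = delayed[1][0]
        b1_t3 = delayed[2][0]
        b2_t4 = delayed[3][1]
        b2_t5 = delayed[4][1]
        b3_t6 = delayed[5][2]
        b2_t7 = delayed[6][1]
        b3_t8 = delayed[7][2]
        y_t9 = delayed[8][3]
        return np.array([
            p.alpha1 * s_lag - p.alpha2 * b1_t2,
            p.gamma1 * b1_t3 - p.gamma2 * b2_t4,
            p.theta1 - p.theta2 * b2_t5 - p.theta3 * b3_t6,
            p.beta1 * b2_t7 - p.beta2 * b3_t8 - p.beta3 * y_t9,
        ])

    def diffusion(t, delayed):
        return np.array([
            p.sigma1 * delayed[1][0],
            p.sigma2 * delayed[3][1],
            p.sigma3 * delayed[5][2],
            p.sigma4 * delayed[8][3],
        ])

    return SDDESystem(state_dim=4, delays=p.delays, drift=drift, diffusion=diffusion)


def _preset_dir():
    return resources.files("sddetwin") / "presets"


def available_presets() -> list:
    """Names of the shipped parameter presets."""
    return sorted(
        path.name[:-5] for path in _preset_dir().iterdir() if path.name.endswith(".yaml")
    )


def default_parameters(preset_name: str = "reference") -> CascadeParameters:
    """Load a version-pinned cascade parameter preset by name.

    The shipped default, ``"reference"``, was calibrated once (see
    ``scripts/calibrate_preset.py``) to give a stable system without input,
    nontrivial transients under the delayed pulse, and heterogeneous
    trajectories across seeds under identical input.
    """
    path = _preset_dir() / f"{preset_name}.yaml"
    if not path.is_file():
        raise KeyError(
            f"unknown preset {preset_name!r}; available: {available_presets()}"
        )
    raw = yaml.safe_load(path.read_text())
    stressor = StressorSpec(**raw.pop("stressor"))
    grid = TimeGrid(**raw.pop("grid"))
    raw.pop("name", None)
    return CascadeParameters(stressor=stressor, grid=grid, **raw)
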