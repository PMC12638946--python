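"""Simulation of threshold-guided treatment and the artifacts it induces.

The causal model: a single biomarker ``x`` carries monotone *intrinsic*
(untreated) risk ``p0(x)``; treatment changes risk to ``p1(x)`` according to
one of four benefit shapes (flattens risk to a constant level, limits risk at
a cap, shifts the biomarker down, or subtracts a constant log-odds benefit);
clinicians treat with probability ``pi(x)`` that either steps at a protocol
threshold (strict adherence) or ramps smoothly through it (loose guidance).
The *observed* population risk is the mixture

    p(x) = pi(x) * p1(x) + (1 - pi(x)) * p0(x).

Strict adherence imprints a jump discontinuity on ``p`` at the protocol
threshold; loose adherence bends ``p`` into a concave peak — the two artifact
classes the detection pipeline searches for.  The eight-scenario suite (four
benefit shapes x two adherence modes) plus patient-level cohort sampling make
the whole pipeline testable end-to-end without clinical data.

Excess risk quantifies the cost of a misaligned protocol: the density-weighted
integral of population risk under the protocol policy minus risk under strict
adherence at the optimal threshold ``x*`` (where untreated risk crosses above
treated risk).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .data import DatasetSchema, FeatureSpec, PatientTable

BENEFIT_KINDS = ("flattens_risk", "limits_risk", "reduces_biomarker", "constant_benefit")
POLICY_KINDS = ("strict", "loose")

#: absolute-risk jump below which a curve counts as continuous on the grid
JUMP_TOL = 0.02

_DOMAIN = (0.0, 10.0)
_GRID_STEP = 0.05


class ScenarioError(ValueError):
    pass


class MultipleCrossingsError(ScenarioError):
    """p0 - p1 changes sign more than once; refine the scenario."""


# ---------------------------------------------------------------------------
# risk curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticRisk:
    """Monotone intrinsic risk ``p0(x) = expit(a + b x)`` with ``b > 0``."""

    a: float = -4.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if not (self.b > 0):
            raise ScenarioError("untreated intrinsic risk must increase: require b > 0")

    def __call__(self, x):
        return expit(self.a + self.b * np.asarray(x, dtype=float))


def make_untreated_risk(a: float = -4.0, b: float = 1.0) -> LogisticRisk:
    """Smoothly increasing untreated risk curve (logistic in the biomarker)."""
    return LogisticRisk(a=a, b=b)


@dataclass(frozen=True)
class UShapedRisk:
    """Convex intrinsic risk with a healthy range: ``expit(a + c (x - x0)^2)``.

    Not a treatment artifact — used to check that genuine healthy-range
    valleys are classified convex and never flagged.
    """

    a: float = -4.0
    c: float = 0.25
    center: float = 5.0

    def __post_init__(self) -> None:
        if not (self.c > 0):
            raise ScenarioError("U-shaped risk needs positive curvature c")

    def __call__(self, x):
        d = np.asarray(x, dtype=float) - self.center
        return expit(self.a + self.c * d * d)


@dataclass(frozen=True)
class BenefitCurve:
    """Treatment benefit: how treated risk ``p1`` derives from ``p0``.

    kinds: ``flattens_risk`` (p1 = level), ``limits_risk`` (p1 = min(p0, cap)),
    ``reduces_biomarker`` (p1(x) = p0(x - shift)), ``constant_benefit``
    (p1 = expit(logit(p0) - offset)).
    """

    kind: str
    level: float = 0.15     # flattens_risk
    cap: float = 0.3        # limits_risk
    shift: float = 2.0      # reduces_biomarker
    offset: float = 1.5     # constant_benefit

    def __post_init__(self) -> None:
        if self.kind not in BENEFIT_KINDS:
            raise ScenarioError(f"benefit kind must be one of {BENEFIT_KINDS}, got {self.kind!r}")
        if self.kind == "flattens_risk" and not (0 < self.level < 1):
            raise ScenarioError("flattens_risk level must be in (0, 1)")
        if self.kind == "limits_risk" and not (0 < self.cap < 1):
            raise ScenarioError("limits_risk cap must be in (0, 1)")
        if self.kind == "reduces_biomarker" and not (self.shift > 0):
            raise ScenarioError("reduces_biomarker shift must be positive")
        if self.kind == "constant_benefit" and not (self.offset > 0):
            raise ScenarioError("constant_benefit offset must be positive")


def make_treated_risk(benefit: BenefitCurve, p0: Callable) -> Callable:
    """Treated-risk curve ``p1`` for a benefit shape applied to ``p0``."""
    if benefit.kind == "flattens_risk":
        return lambda x: np.full_like(np.asarray(x, dtype=float), benefit.level)
    if benefit.kind == "limits_risk":
        return lambda x: np.minimum(np.asarray(p0(x), dtype=float), benefit.cap)
    if benefit.kind == "reduces_biomarker":
        return lambda x: np.asarray(p0(np.asarray(x, dtype=float) - benefit.shift), dtype=float)
    return lambda x: expit(logit(np.asarray(p0(x), dtype=float)) - benefit.offset)


@dataclass(frozen=True)
class AdherencePolicy:
    """Treatment probability ``pi(x)``: a step (strict) or logistic ramp (loose)
    at the protocol threshold ``tau``."""

    kind: str
    threshold: float
    width: float = 0.5  # loose only; biomarker units

    def __post_init__(self) -> None:
        if self.kind not in POLICY_KINDS:
            raise ScenarioError(f"policy kind must be one of {POLICY_KINDS}, got {self.kind!r}")
        if self.kind == "loose" and not (self.width > 0):
            raise ScenarioError("loose policy needs width > 0")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "strict":
            return (x >= self.threshold).astype(float)
        return expit((x - self.threshold) / self.width)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def default_grid() -> np.ndarray:
    lo, hi = _DOMAIN
    return np.round(np.arange(lo, hi + _GRID_STEP / 2, _GRID_STEP), 10)


def default_density():
    """Truncated normal biomarker density on the domain (mean 5, sd 2)."""
    lo, hi = _DOMAIN
    mu, sd = 5.0, 2.0
    return truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)


@dataclass
class SimulationScenario:
    """Untreated/treated risk curves + adherence policy on a biomarker grid."""

    name: str
    p0: Callable
    p1: Callable
    policy: Optional[AdherencePolicy]
    grid: np.ndarray = field(default_factory=default_grid)
    density: object = field(default_factory=default_density)
    benefit: Optional[BenefitCurve] = None

    def adherence(self, x) -> np.ndarray:
        if self.policy is None:
            return np.zeros_like(np.asarray(x, dtype=float))
        return self.policy(x)

    def population_risk(self, x) -> np.ndarray:
        """``p(x) = pi(x) p1(x) + (1 - pi(x)) p0(x)``."""
        x = np.asarray(x, dtype=float)
        pi = self.adherence(x)
        return pi * np.asarray(self.p1(x), float) + (1 - pi) * np.asarray(self.p0(x), float)

    def curve_table(self) -> pd.DataFrame:
        """Grid columns mirroring the simulation panels: intrinsic curves,
        adherence, and the composed observed risk."""
        g = self.grid
        return pd.DataFrame({
            "x": g,
            "untreated_risk": np.asarray(self.p0(g), float),
            "treated_risk": np.asarray(self.p1(g), float),
            "adherence": self.adherence(g),
            "population_risk": self.population_risk(g),
        })


def compose_population_risk(scenario: SimulationScenario) -> np.ndarray:
    """Observed population risk on the scenario grid."""
    return scenario.population_risk(scenario.grid)


@dataclass(frozen=True)
class OptimalThreshold:
    x: float
    crossing: bool  # False when p0 vs p1 never changes order on the grid
    note: str = ""


def optimal_threshold(scenario: SimulationScenario) -> OptimalThreshold:
    """Smallest grid point where untreated risk rises above treated risk.

    If treatment is beneficial everywhere the lower domain bound is returned
    flagged "treat everyone"; if never beneficial, the upper bound flagged
    "never treat".  More than one order change raises
    :class:`MultipleCrossingsError`.
    """
    g = scenario.grid
    d = np.asarray(scenario.p0(g), float) - np.asarray(scenario.p1(g), float)
    above = d > 1e-12
    flips = int(np.sum(np.diff(above.astype(int)) != 0))
    if flips > 1:
        raise MultipleCrossingsError(
            f"{scenario.name}: p0 - p1 changes sign {flips} times; refine the scenario")
    if above.all():
        return OptimalThreshold(float(g[0]), False, "treat everyone")
    if not above.any():
        return OptimalThreshold(float(g[-1]), False, "never treat")
    if not above[-1]:
        raise MultipleCrossingsError(
            f"{scenario.name}: treated risk exceeds untreated at high biomarker values")
    return OptimalThreshold(float(g[np.argmax(above)]), True)


def population_risk_peak(scenario: SimulationScenario) -> float:
    """Grid location of the maximum of the observed population risk."""
    p = compose_population_risk(scenario)
    return float(scenario.grid[int(np.argmax(p))])


def excess_risk(scenario: SimulationScenario,
                policy: Optional[AdherencePolicy] = None,
                density=None) -> float:
    """Density-weighted excess of policy risk over optimal-threshold risk.

    ``integral [p_policy(x) - p_optimal(x)] density(x) dx`` where
    ``p_optimal`` applies strict adherence at the optimal threshold ``x*``.
    Nonnegative up to quadrature error.
    """
    policy = policy or scenario.policy
    if policy is None:
        raise ScenarioError("excess_risk needs a policy")
    density = density if density is not None else scenario.density
    g = scenario.grid
    # midpoint rule per grid cell: exact for policy steps that sit on grid
    # points (a trapezoid would smear the jump across its cell)
    mid = (g[:-1] + g[1:]) / 2.0
    dx = np.diff(g)
    w = np.asarray(density.pdf(mid), dtype=float)
    w = w / np.sum(w * dx)
    p0 = np.asarray(scenario.p0(mid), float)
    p1 = np.asarray(scenario.p1(mid), float)
    pi = policy(mid)
    p_policy = pi * p1 + (1 - pi) * p0
    xstar = optimal_threshold(scenario).x
    p_opt = np.where(mid >= xstar, p1, p0)
    return float(np.sum((p_policy - p_opt) * w * dx))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Patient-level realization of a scenario.

    The treatment flag is generated but *excluded* from exported features by
    default: treatment acts as an unobserved confounder, which is the premise
    of the whole exercise.
    """

    biomarker: np.ndarray
    nuisance: np.ndarray          # (n, k) independent standard normals
    treated: np.ndarray           # bool
    outcome: np.ndarray           # {0,1}
    seed: int
    scenario_name: str

    @property
    def n(self) -> int:
        return int(self.biomarker.size)

    def schema(self, include_treatment: bool = False) -> DatasetSchema:
        feats = [FeatureSpec("biomarker", "continuous")]
        feats += [FeatureSpec(f"nuisance_{i}", "continuous")
                  for i in range(self.nuisance.shape[1])]
        if include_treatment:
            feats.append(FeatureSpec("treated", "boolean"))
        return DatasetSchema(outcome_name="outcome", features=tuple(feats))

    def to_dataframe(self, include_treatment: bool = False) -> pd.DataFrame:
        data = {"outcome": self.outcome.astype(int), "biomarker": self.biomarker}
        for i in range(self.nuisance.shape[1]):
            data[f"nuisance_{i}"] = self.nuisance[:, i]
        if include_treatment:
            data["treated"] = self.treated.astype(int)
        return pd.DataFrame(data)

    def to_table(self, include_treatment: bool = False) -> PatientTable:
        return PatientTable.from_dataframe(
            self.to_dataframe(include_treatment), self.schema(include_treatment))

    def to_csv(self, path, include_treatment: bool = False) -> None:
        self.to_dataframe(include_treatment).to_csv(path, index=False)


def sample_cohort(scenario: SimulationScenario, n: int, n_nuisance: int = 3,
                  seed: int = 0) -> SyntheticCohort:
    """Draw a patient cohort from the scenario's generative model.

    ``x ~ density``, ``treated ~ Bernoulli(pi(x))``,
    ``outcome ~ Bernoulli(p1(x))`` if treated else ``Bernoulli(p0(x))``;
    nuisance features are independent standard normals.  Reproducible from
    *seed*.
    """
    if n < 1:
        raise ScenarioError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = np.asarray(scenario.density.rvs(size=n, random_state=rng), dtype=float)
    treated = rng.random(n) < scenario.adherence(x)
    p = np.where(treated, np.asarray(scenario.p1(x), float),
                 np.asarray(scenario.p0(x), float))
    outcome = (rng.random(n) < p).astype(np.int8)
    nuis = rng.standard_normal((n, n_nuisance))
    return SyntheticCohort(biomarker=x, nuisance=nuis, treated=treated,
                           outcome=outcome, seed=seed,
                           scenario_name=scenario.name)


# ---------------------------------------------------------------------------
# the eight-scenario suite
# ---------------------------------------------------------------------------

def make_scenario(benefit_kind: str, policy_kind: str, *,
                  threshold: float = 4.0, loose_width: float = 0.5,
                  p0: Optional[Callable] = None,
                  benefit: Optional[BenefitCurve] = None) -> SimulationScenario:
    """One of the eight canonical scenarios: a benefit shape x adherence mode.

    The default protocol threshold (4.0) is a "round number" deliberately
    above the optimal threshold of the default benefit parameters, so strict
    scenarios carry a visible jump and loose ones a concave peak.
    """
    p0 = p0 or make_untreated_risk()
    benefit = benefit or BenefitCurve(kind=benefit_kind)
    if benefit.kind != benefit_kind:
        raise ScenarioError("benefit.kind does not match benefit_kind")
    policy = AdherencePolicy(kind=policy_kind, threshold=threshold, width=loose_width)
    return SimulationScenario(
        name=f"{benefit_kind}-{policy_kind}", p0=p0,
        p1=make_treated_risk(benefit, p0), policy=policy, benefit=benefit)


def convex_intrinsic_scenario(**kwargs) -> SimulationScenario:
    """Untreated U-shaped ("healthy range") risk with no treatment at all —
    the negative control for concave-artifact detection."""
    p0 = UShapedRisk(**kwargs)
    return SimulationScenario(name="convex-intrinsic", p0=p0, p1=p0, policy=None)


@dataclass
class ScenarioBundle:
    scenario: SimulationScenario
    cohort: SyntheticCohort
    expected_artifact: str  # "discontinuity" | "non_monotonicity"

    def manifest(self) -> dict:
        scn = self.scenario
        return {
            "scenario": scn.name,
            "benefit_kind": scn.benefit.kind if scn.benefit else None,
            "policy": None if scn.policy is None else {
                "kind": scn.policy.kind, "threshold": scn.policy.threshold,
                "width": scn.policy.width},
            "expected_artifact": self.expected_artifact,
            "n": self.cohort.n, "seed": self.cohort.seed,
            "optimal_threshold": optimal_threshold(scn).x,
            "population_risk_peak": population_risk_peak(scn),
        }

    def write(self, directory) -> None:
        import os
        os.makedirs(directory, exist_ok=True)
        self.scenario.curve_table().to_csv(os.path.join(directory, "curves.csv"),
                                           index=False)
        self.cohort.to_csv(os.path.join(directory, "cohort.csv"))
        with open(os.path.join(directory, "manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(self.manifest(), fh, indent=2)


def run_scenario_suite(seed: int = 0, n: int = 20_000, n_nuisance: int = 3,
                       threshold: float = 4.0, loose_width: float = 0.5,
                       out_dir=None) -> list[ScenarioBundle]:
    """All eight scenarios (4 benefit shapes x strict/loose), each with a
    sampled cohort; optionally written to per-scenario directories.

    Strict bundles are expected to show a discontinuity at the protocol
    threshold; loose bundles a concave non-monotonicity near the population
    risk peak.
    """
    bundles = []
    for k, benefit_kind in enumerate(BENEFIT_KINDS):
        for p, policy_kind in enumerate(POLICY_KINDS):
            scn = make_scenario(benefit_kind, policy_kind,
                                threshold=threshold, loose_width=loose_width)
            cohort = sample_cohort(scn, n=n, n_nuisance=n_nuisance,
                                   seed=seed + 17 * (2 * k + p))
            bundles.append(ScenarioBundle(
                scenario=scn, cohort=cohort,
                expected_artifact=("discontinuity" if policy_kind == "strict"
                                   else "non_monotonicity")))
    if out_dir is not None:
        import os
        for b in bundles:
            b.write(os.path.join(out_dir, b.scenario.name))
    return bundles
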