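"""Automatic detection of threshold-induced artifacts in fitted risk curves.

Two classes of statistical "surprises" in a piecewise-constant component
function betray threshold-guided treatment rather than biology:

* **Discontinuities** — a jump in the log-odds contribution at a threshold.
  Tested by a likelihood-ratio-style statistic ``T_d``: the Bernoulli
  log-likelihood of the observed outcomes under the fitted (discontinuous)
  component minus the log-likelihood under a locally-linearized version of
  the same component, all other components held fixed.  ``T_d > 0`` means the
  jump explains the data better than a smooth ramp through the same window.

* **Concave non-monotonicities** — a peak where risk *falls* as the biomarker
  worsens.  Found by changepoint detection on the signs of the non-zero
  per-threshold slopes of the component.  Convex valleys (U shapes) are
  classified but never flagged: they are usually genuine healthy ranges.

Bootstrap bags provide the significance currency: an artifact is flagged only
when it recurs in at least ``support_level`` of the bagged models.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .data import PatientTable
from .gam import AdditiveRiskResults, ComponentFunction

_PCLIP = 1e-12


@dataclass(frozen=True)
class DetectionConfig:
    """Tolerances and evidence thresholds for the artifact scan.

    ``support_level``: fraction of bags that must agree before flagging.
    ``slope_zero_tol``: |slope| below this (log-odds per unit) counts as zero.
    ``min_run``: a sign regime must persist this many non-zero slopes on each
    side of a flip to count as a changepoint.
    ``min_window_count``: linearization windows with fewer training samples
    are marked low-confidence (sparse-data caveat).
    """

    support_level: float = 0.95
    slope_zero_tol: float = 1e-8
    min_run: int = 2
    min_window_count: int = 20

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# local linearization and the discontinuity statistic
# ---------------------------------------------------------------------------

@dataclass
class LinearizedComponent:
    """A component with the window around one threshold replaced by a line.

    For threshold index ``j`` the window is ``[t_{j-1}, t_{j+1})``; inside it
    the contribution is the linear interpolation between the component's
    values at the window ends (``f(t_{j-1})`` and ``f(t_{j+1})``), outside it
    the base component is unchanged.
    """

    base: ComponentFunction
    j: int
    window_lo: float
    window_hi: float
    value_lo: float
    value_hi: float

    @property
    def feature(self) -> str:
        return self.base.feature

    def evaluate(self, x) -> np.ndarray:
        xf = np.asarray(x, dtype=float).ravel()
        out = np.asarray(self.base.evaluate(xf), dtype=float).copy()
        inside = (xf >= self.window_lo) & (xf < self.window_hi)
        if inside.any():
            frac = (xf[inside] - self.window_lo) / (self.window_hi - self.window_lo)
            out[inside] = self.value_lo + frac * (self.value_hi - self.value_lo)
        return out


def interior_threshold_indices(component: ComponentFunction) -> range:
    """Threshold indices testable for a discontinuity: both neighbour
    thresholds must exist, so the outermost thresholds are excluded."""
    K = component.thresholds.size
    return range(1, max(K - 1, 1))


def linearize_component(component: ComponentFunction, j: int) -> LinearizedComponent:
    """Locally-linear version of *component* around threshold index *j*.

    Requires ``1 <= j <= K-2`` for ``K`` thresholds (the window needs
    ``t_{j-1}`` and ``t_{j+1}``); outer thresholds raise ``IndexError``.
    """
    K = component.thresholds.size
    if not (1 <= j <= K - 2):
        raise IndexError(
            f"threshold index {j} is not interior for {component.feature!r} "
            f"(valid: 1..{K - 2}); outer thresholds have no linearization window")
    t = component.thresholds
    lo, hi = float(t[j - 1]), float(t[j + 1])
    # f(t_{j-1}) is the bin right of t_{j-1} (half-open convention): bin j;
    # f(t_{j+1}) is bin j+2.
    return LinearizedComponent(
        base=component, j=j, window_lo=lo, window_hi=hi,
        value_lo=float(component.values[j]), value_hi=float(component.values[j + 2]),
    )


def _bernoulli_ll(y: np.ndarray, p: np.ndarray) -> float:
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("predicted probabilities clipped away from {0,1} for the "
                      "log-likelihood", stacklevel=3)
    p = np.clip(p, _PCLIP, 1 - _PCLIP)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def log_likelihood(results: AdditiveRiskResults, table: PatientTable,
                   component_override=None) -> float:
    """Bernoulli log-likelihood of *table*'s outcomes under the model.

    ``component_override`` optionally replaces one component: anything with
    ``.feature`` and ``.evaluate(x)`` (e.g. a :class:`LinearizedComponent`).
    """
    if table.schema.feature_names != results.schema.feature_names:
        raise ValueError("model and table schemas do not match")
    total = np.full(table.n, results.intercept, dtype=float)
    for comp in results.components:
        use = comp
        if component_override is not None and component_override.feature == comp.feature:
            use = component_override
        total += use.evaluate(table.features[comp.feature])
    return _bernoulli_ll(table.outcome.astype(float), expit(total))


def discontinuity_statistic(results: AdditiveRiskResults, table: PatientTable,
                            feature: str, j: int, *,
                            method: str = "likelihood") -> float:
    """Discontinuity statistic ``T_d`` at threshold *j* of *feature*.

    Default (``method="likelihood"``): exact Bernoulli log-likelihood of the
    fitted component minus that of its locally-linearized version, all other
    components fixed.  ``method="signed_sum"`` is a documented alternative
    reduction (outcomes coded +/-1, component log-odds values summed
    directly); it is not the default because its scale mixes conventions.
    """
    comp = results.component(feature)
    lin = linearize_component(comp, j)
    if method == "likelihood":
        return log_likelihood(results, table) - log_likelihood(results, table, lin)
    if method == "signed_sum":
        x = np.asarray(table.features[feature], dtype=float)
        sgn = np.where(table.outcome == 1, 1.0, -1.0)
        return float(np.sum(sgn * (comp.evaluate(x) - lin.evaluate(x))))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# slopes, sign changepoints, curvature
# ---------------------------------------------------------------------------

@dataclass
class SlopeSequence:
    """Slopes of a component across its thresholds.

    ``slopes[j]`` is the value change across threshold ``j`` divided by the
    span between the neighbouring bin-representative points:
    ``(y_{j+1} - y_j) / (rep_{j+1} - rep_j)``.  ``signs`` thresholds them at
    ``slope_zero_tol``; only the signs feed the changepoint detector, so the
    (positive) span normalization is immaterial downstream.
    """

    feature: str
    slopes: np.ndarray
    signs: np.ndarray
    positions: np.ndarray  # threshold position of each slope

    def __len__(self) -> int:
        return int(self.slopes.size)


def compute_slopes(component: ComponentFunction,
                   slope_zero_tol: float = 1e-8) -> SlopeSequence:
    """Per-threshold slopes of the component (one per bin-to-bin step)."""
    m = component.n_bins
    if m < 3:
        raise ValueError(f"{component.feature!r}: need >= 3 bins for slopes, have {m}")
    reps = component.representatives()
    y = component.values
    slopes = (y[1:] - y[:-1]) / (reps[1:] - reps[:-1])
    signs = np.where(np.abs(slopes) <= slope_zero_tol, 0, np.sign(slopes)).astype(int)
    return SlopeSequence(feature=component.feature, slopes=slopes, signs=signs,
                         positions=component.thresholds.copy())


@dataclass(frozen=True)
class SignChangepoint:
    """A persistent flip in the sign regime of the slope sequence.

    ``left``/``right`` index the slope sequence: the last position of the old
    regime and the first of the new one (equal spacing not assumed; zeros may
    sit in between).  ``center`` is their midpoint in slope-index units.
    """

    left: int
    right: int
    sign_before: int
    sign_after: int

    @property
    def center(self) -> float:
        return (self.left + self.right) / 2.0


def detect_sign_changepoints(signs, min_run: int = 2) -> list[SignChangepoint]:
    """Changepoints of the persistent sign regime of non-zero slopes.

    Zeros are removed before detection.  A flip is reported only when both
    the old and the new sign persist for at least ``min_run`` consecutive
    non-zero slopes (noise guard).  Run-length regime detection — equivalent
    to binary segmentation with a 0/1 sign-agreement cost — suffices for
    these short ternary sequences.
    """
    if isinstance(signs, SlopeSequence):
        signs = signs.signs
    s = np.asarray(signs, dtype=int)
    nz = np.flatnonzero(s != 0)
    if nz.size == 0:
        return []
    vals = s[nz]
    # run-length encode
    boundaries = np.flatnonzero(np.diff(vals) != 0)
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries, [vals.size - 1]))
    out = []
    for b in range(len(starts) - 1):
        left_len = ends[b] - starts[b] + 1
        right_len = ends[b + 1] - starts[b + 1] + 1
        if left_len >= min_run and right_len >= min_run:
            out.append(SignChangepoint(
                left=int(nz[ends[b]]), right=int(nz[starts[b + 1]]),
                sign_before=int(vals[starts[b]]), sign_after=int(vals[starts[b + 1]]),
            ))
    return out


def classify_curvature(component: ComponentFunction,
                       changepoint: SignChangepoint) -> str:
    """``concave`` for a rising-then-falling peak, ``convex`` for a valley."""
    if changepoint.sign_before > 0 and changepoint.sign_after < 0:
        return "concave"
    if changepoint.sign_before < 0 and changepoint.sign_after > 0:
        return "convex"
    raise ValueError("changepoint does not flip sign")


# ---------------------------------------------------------------------------
# report types
# ---------------------------------------------------------------------------

@dataclass
class DiscontinuityResult:
    feature: str
    threshold_index: int
    threshold: float
    statistic: float                 # T_d on the reported (bag-mean) model
    statistic_median: float          # median T_d across bags
    bag_support: float               # fraction of bags with T_d > 0
    flagged: bool
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError("T_d must be finite")
        if not (0.0 <= self.bag_support <= 1.0 or np.isnan(self.bag_support)):
            raise ValueError("bag_support must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {"feature": self.feature, "threshold_index": self.threshold_index,
                "threshold": self.threshold, "statistic": self.statistic,
                "statistic_median": self.statistic_median,
                "bag_support": self.bag_support, "flagged": self.flagged,
                "low_confidence": self.low_confidence, "kind": "discontinuity"}


@dataclass
class NonMonotonicityResult:
    feature: str
    threshold: float                  # x position of the regime flip
    center_index: float               # threshold-index units (may be fractional)
    curvature: str                    # "concave" | "convex"
    bag_support: float
    flagged: bool

    def __post_init__(self) -> None:
        if self.flagged and self.curvature != "concave":
            raise ValueError("only concave non-monotonicities may be flagged")

    def to_dict(self) -> dict:
        return {"feature": self.feature, "threshold": self.threshold,
                "center_index": self.center_index, "curvature": self.curvature,
                "bag_support": self.bag_support, "flagged": self.flagged,
                "kind": "non_monotonicity"}


@dataclass
class ArtifactReport:
    """Ranked artifact findings, serializable to JSON.

    Discontinuities rank by (bag_support, |median T_d|) descending;
    non-monotonicities by (bag_support, curvature=concave first).
    """

    discontinuities: list[DiscontinuityResult] = field(default_factory=list)
    non_monotonicities: list[NonMonotonicityResult] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    mode: str = "likelihood"  # "likelihood" | "shape_only"

    def ranked_discontinuities(self) -> list[DiscontinuityResult]:
        return sorted(self.discontinuities,
                      key=lambda d: (np.nan_to_num(d.bag_support),
                                     abs(d.statistic_median)), reverse=True)

    def ranked_non_monotonicities(self) -> list[NonMonotonicityResult]:
        return sorted(self.non_monotonicities,
                      key=lambda r: (np.nan_to_num(r.bag_support),
                                     r.curvature == "concave"), reverse=True)

    def flagged(self):
        return ([d for d in self.ranked_discontinuities() if d.flagged],
                [r for r in self.ranked_non_monotonicities() if r.flagged])

    def top_artifact(self):
        """Highest-supported flagged finding across both classes (or the
        highest-ranked unflagged one when nothing is flagged)."""
        discs, monos = self.flagged()
        pool = discs + monos
        if not pool:
            pool = self.ranked_discontinuities() + self.ranked_non_monotonicities()
        if not pool:
            return None
        return max(pool, key=lambda a: (np.nan_to_num(a.bag_support),
                                        abs(getattr(a, "statistic_median", 0.0))))

    def to_dict(self) -> dict:
        return {
            "format": "riskaudit-report", "version": "1", "mode": self.mode,
            "likelihood_statistics": ("unavailable" if self.mode == "shape_only"
                                      else "bernoulli_log_likelihood"),
            "provenance": self.provenance,
            "discontinuities": [d.to_dict() for d in self.ranked_discontinuities()],
            "non_monotonicities": [r.to_dict() for r in self.ranked_non_monotonicities()],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = ["Artifact scan report", "=" * 60]
        discs, monos = (self.ranked_discontinuities(), self.ranked_non_monotonicities())
        lines.append(f"discontinuity candidates: {len(discs)} "
                     f"({sum(d.flagged for d in discs)} flagged)")
        for d in discs[:10]:
            mark = "*" if d.flagged else " "
            lc = " [low-confidence]" if d.low_confidence else ""
            lines.append(f" {mark} {d.feature:<18.18s} t={d.threshold:>10.4g} "
                         f"T_d(med)={d.statistic_median:>9.3f} "
                         f"support={d.bag_support:.2f}{lc}")
        lines.append(f"non-monotonicity candidates: {len(monos)} "
                     f"({sum(r.flagged for r in monos)} flagged)")
        for r in monos[:10]:
            mark = "*" if r.flagged else " "
            lines.append(f" {mark} {r.feature:<18.18s} x={r.threshold:>10.4g} "
                         f"{r.curvature:<8s} support={r.bag_support:.2f}")
        lines.append("=" * 60)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def _window_ll_diff(y, x, base_logit, contrib, lin: LinearizedComponent) -> float:
    """T_d computed on the window samples only (identical elsewhere)."""
    inside = (x >= lin.window_lo) & (x < lin.window_hi)
    if not inside.any():
        return 0.0
    xw = x[inside]
    frac = (xw - lin.window_lo) / (lin.window_hi - lin.window_lo)
    f_lin = lin.value_lo + frac * (lin.value_hi - lin.value_lo)
    lo_old = base_logit[inside]
    lo_new = lo_old + (f_lin - contrib[inside])
    yw = y[inside]
    p_old = np.clip(expit(lo_old), _PCLIP, 1 - _PCLIP)
    p_new = np.clip(expit(lo_new), _PCLIP, 1 - _PCLIP)
    ll_old = np.sum(yw * np.log(p_old) + (1 - yw) * np.log1p(-p_old))
    ll_new = np.sum(yw * np.log(p_new) + (1 - yw) * np.log1p(-p_new))
    return float(ll_old - ll_new)


def _changepoints_of(values: np.ndarray, comp: ComponentFunction,
                     config: DetectionConfig) -> list[tuple[float, str]]:
    """(center, curvature) pairs for a value vector on *comp*'s grid."""
    if comp.n_bins < 3:
        return []
    tmp = ComponentFunction(
        feature=comp.feature, kind=comp.kind, thresholds=comp.thresholds,
        values=values, bin_counts=comp.bin_counts, support=comp.support,
        categories=comp.categories)
    seq = compute_slopes(tmp, config.slope_zero_tol)
    cps = detect_sign_changepoints(seq.signs, config.min_run)
    return [(cp.center, classify_curvature(tmp, cp)) for cp in cps]


def _center_to_x(comp: ComponentFunction, center: float) -> float:
    """Map a slope-sequence center (threshold-index units) to x."""
    return float(np.interp(center, np.arange(comp.thresholds.size), comp.thresholds))


def _model_hash(results: AdditiveRiskResults) -> str:
    payload = json.dumps({
        "intercept": results.intercept,
        "values": [c.values.tolist() for c in results.components],
        "thresholds": [c.thresholds.tolist() for c in results.components],
    }).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def scan_artifacts(results: AdditiveRiskResults, table: PatientTable,
                   config: Optional[DetectionConfig] = None) -> ArtifactReport:
    """Scan every continuous component for discontinuities and concave
    non-monotonicities, with bootstrap-bag support.

    For every interior threshold, ``T_d`` is computed on the reported model
    and within each bag (each bag's own component linearized inside its own
    model); a discontinuity is flagged when at least ``support_level`` of
    bags have ``T_d > 0`` and the bag median is positive.  A concave
    changepoint is flagged when one appears within a one-bin window in at
    least ``support_level`` of bags.  Without bags the scan falls back to
    point estimates with ``flagged=False`` (no support evidence).
    """
    config = config or DetectionConfig()
    bags = results.bag_models
    if not bags:
        warnings.warn("model has no bootstrap bags: artifacts cannot be flagged, "
                      "reporting point estimates only", stacklevel=2)
    y = table.outcome.astype(float)

    # per-sample caches -----------------------------------------------------
    xcols, idx_cache = {}, {}
    for comp in results.components:
        if comp.kind == "continuous":
            x = np.asarray(table.features[comp.feature], dtype=float)
            xcols[comp.feature] = x
            idx_cache[comp.feature] = comp.bin_index(x)

    def model_logit(icpt, comps):
        out = np.full(table.n, icpt, dtype=float)
        for c in comps:
            if c.kind == "continuous":
                idx = idx_cache[c.feature]
                vals = np.append(c.values, c.missing_bin_value
                                 if c.missing_bin_value is not None else 0.0)
                out += vals[np.minimum(idx, c.n_bins)]
            else:
                out += c.evaluate(table.features[c.feature])
        return out

    point_logit = model_logit(results.intercept, results.components)
    bag_logits = [model_logit(b.intercept, b.components) for b in (bags or [])]

    report = ArtifactReport(provenance={
        "model_hash": _model_hash(results), "n_obs": int(table.n),
        "n_bags": results.n_bags, "detection_config": config.to_dict(),
    })

    for fi, comp in enumerate(results.components):
        if comp.kind != "continuous" or comp.n_bins < 3:
            continue
        x = xcols[comp.feature]
        contrib_pt = comp.evaluate(x)

        # --- discontinuities ---
        if comp.testable:
            for j in interior_threshold_indices(comp):
                lin = linearize_component(comp, j)
                t_pt = _window_ll_diff(y, x, point_logit, contrib_pt, lin)
                if bags:
                    t_bags = np.empty(len(bags))
                    for b, bag in enumerate(bags):
                        bcomp = bag.components[fi]
                        blin = linearize_component(bcomp, j)
                        t_bags[b] = _window_ll_diff(
                            y, x, bag_logits[b], bcomp.values[
                                np.minimum(idx_cache[comp.feature], bcomp.n_bins - 1)],
                            blin)
                    support = float(np.mean(t_bags > 0))
                    med = float(np.median(t_bags))
                    flagged = support >= config.support_level and med > 0
                else:
                    support, med, flagged = float("nan"), t_pt, False
                window_count = int(comp.bin_counts[j] + comp.bin_counts[j + 1])
                report.discontinuities.append(DiscontinuityResult(
                    feature=comp.feature, threshold_index=j,
                    threshold=float(comp.thresholds[j]), statistic=t_pt,
                    statistic_median=med, bag_support=support, flagged=flagged,
                    low_confidence=window_count < config.min_window_count))

        # --- non-monotonicities ---
        point_cps = _changepoints_of(comp.values, comp, config)
        bag_cps = [ _changepoints_of(bag.components[fi].values, comp, config)
                    for bag in (bags or []) ]
        candidates: dict[tuple[float, str], float] = {}
        pool = list(point_cps) + [cp for lst in bag_cps for cp in lst]
        for center, curv in pool:
            key = (round(center * 2) / 2, curv)
            candidates.setdefault(key, center)
        entries = []
        for (ckey, curv), center in candidates.items():
            if bags:
                hits = sum(any(abs(c - center) <= 1.0 and cv == curv for c, cv in lst)
                           for lst in bag_cps)
                support = hits / len(bags)
                flagged = curv == "concave" and support >= config.support_level
            else:
                support, flagged = float("nan"), False
            entries.append(NonMonotonicityResult(
                feature=comp.feature, threshold=_center_to_x(comp, center),
                center_index=center, curvature=curv,
                bag_support=support, flagged=flagged))
        # suppress overlapping candidates of the same curvature, keep strongest
        entries.sort(key=lambda e: np.nan_to_num(e.bag_support), reverse=True)
        kept: list[NonMonotonicityResult] = []
        for e in entries:
            if any(k.curvature == e.curvature and
                   abs(k.center_index - e.center_index) <= 1.0 for k in kept):
                continue
            kept.append(e)
        report.non_monotonicities.extend(kept)

    return report


def scan_curve_shapes(components: Sequence[ComponentFunction],
                      config: Optional[DetectionConfig] = None) -> ArtifactReport:
    """Shape-only audit of exported curves (no patient table, no likelihoods).

    Reports non-monotonicity candidates from the point curves; likelihood
    statistics are marked unavailable and nothing is flagged (no bag
    evidence).
    """
    config = config or DetectionConfig()
    report = ArtifactReport(mode="shape_only", provenance={
        "detection_config": config.to_dict(), "n_components": len(components)})
    for comp in components:
        if comp.kind != "continuous" or comp.n_bins < 3:
            continue
        for center, curv in _changepoints_of(comp.values, comp, config):
            report.non_monotonicities.append(NonMonotonicityResult(
                feature=comp.feature, threshold=_center_to_x(comp, center),
                center_index=center, curvature=curv,
                bag_support=float("nan"), flagged=False))
    return report
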