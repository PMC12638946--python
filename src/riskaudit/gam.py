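"""Bagged piecewise-constant additive logistic risk models.

The estimator fits a main-effects generalized additive model on the log-odds
scale by cyclic ("round-robin") gradient boosting of single-feature,
single-split tree learners: each boosting round visits every feature in a
fixed order, fits one depth-1 piecewise-constant regressor on that feature's
pre-computed bin grid to the current gradient of the Bernoulli log-loss, and
accumulates the shrunken leaf values into that feature's component function.
Because the learners are trees, component functions are free to place sharp
jumps at any bin edge — which is exactly what makes threshold-induced
artifacts of clinical practice visible in the fitted curves.

Bootstrap aggregation (bagging) across resamples of the training data gives
per-bin confidence bands; all bags share one bin grid computed on the full
data, so bag curves are directly comparable bin by bin.

Usage follows the Model/Results convention::

    model = AdditiveRiskModel.from_dataframe(df, outcome="died")
    res = model.fit(n_bags=16, seed=0)
    res.summary()
    res.predict_prob(df)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .data import DatasetSchema, PatientTable, ValidationError

_EPS = 1e-12


class FitError(ValueError):
    """Raised when the data cannot support a fit (e.g. one outcome class)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters of the boosted-GAM fit.

    Parameters
    ----------
    n_rounds : int
        Maximum boosting rounds (each round visits every feature once).
    learning_rate : float
        Shrinkage applied to every leaf value; log-odds per step.
    max_bins : int
        Upper bound on quantile bins per continuous feature.
    n_bags : int
        Bootstrap bags. ``0`` disables bagging (point fit, no bands);
        confidence bands require at least 2.
    bag_fraction : float
        Size of each bootstrap resample as a fraction of n (with replacement).
    seed : int
        Seed for all randomness (bag resampling, validation splits).
    early_stop_patience : int
        Stop a fit after this many rounds without validation improvement;
        ``0`` disables early stopping.
    validation_fraction : float
        Held-out fraction used for early stopping.
    ci_level : float
        Two-sided level of the empirical bag quantile bands.
    split_alpha : float
        Noise gate: a feature's component stays at zero until the first visit
        in which its best split improves the second-order gain over the
        no-split update by more than the chi-square(1) critical value at
        level ``split_alpha / n_candidate_splits`` (a Bonferroni bound on the
        best of the feature's candidate splits under the null).  Once
        activated, the feature is boosted without further gating, so real
        effects converge unbiased while null features stay exactly flat.
        ``0`` disables the gate.
    """

    n_rounds: int = 500
    learning_rate: float = 0.1
    max_bins: int = 64
    n_bags: int = 100
    bag_fraction: float = 1.0
    seed: int = 0
    early_stop_patience: int = 50
    validation_fraction: float = 0.15
    ci_level: float = 0.95
    split_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_rounds < 0 or self.max_bins < 1 or self.n_bags < 0:
            raise ValidationError("n_rounds, max_bins, n_bags must be non-negative")
        if not (self.learning_rate > 0):
            raise ValidationError("learning_rate must be positive")
        if not (0 < self.bag_fraction <= 1):
            raise ValidationError("bag_fraction must be in (0, 1]")
        if not (0 <= self.validation_fraction < 1):
            raise ValidationError("validation_fraction must be in [0, 1)")
        if not (0 < self.ci_level < 1):
            raise ValidationError("ci_level must be in (0, 1)")
        if not (0 <= self.split_alpha <= 1):
            raise ValidationError("split_alpha must be in [0, 1]")
        if self.n_bags == 1:
            raise ValidationError("n_bags must be 0 (no bagging) or >= 2")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d) -> "FitConfig":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def discretize_feature(values: Sequence[float], max_bins: int) -> np.ndarray:
    """Quantile bin edges for a continuous feature.

    Returns the interior cut points (length ``m - 1`` for ``m`` bins): the
    empirical quantiles of the finite values at equally spaced probabilities,
    deduplicated, then greedily merged so that every bin contains at least one
    training sample.  When the feature has at most ``max_bins`` distinct
    values, edges are the midpoints between consecutive distinct values.  A
    constant feature yields zero edges (a single bin).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.empty(0)
    uniq = np.unique(v)
    if uniq.size < 2:
        return np.empty(0)
    if uniq.size <= max_bins:
        edges = (uniq[:-1] + uniq[1:]) / 2.0
    else:
        probs = np.linspace(0.0, 1.0, max_bins + 1)[1:-1]
        edges = np.unique(np.quantile(v, probs))
    # merge any empty bin into its left neighbour
    while edges.size:
        counts = np.bincount(np.searchsorted(edges, v, side="right"),
                             minlength=edges.size + 1)
        empty = np.flatnonzero(counts == 0)
        if empty.size == 0:
            break
        i = int(empty[0])
        edges = np.delete(edges, max(i - 1, 0))
    return edges


# ---------------------------------------------------------------------------
# component functions
# ---------------------------------------------------------------------------

@dataclass
class ComponentFunction:
    """One feature's piecewise-constant log-odds contribution.

    ``thresholds`` (strictly increasing, length ``m - 1``) split the axis into
    ``m`` half-open bins ``[t_{j-1}, t_j)``; the first bin is unbounded below
    and the last unbounded above (and closed).  ``support`` records the finite
    observed data range, used for bin-representative positions.  An optional
    dedicated missing bin absorbs NaN inputs.
    """

    feature: str
    kind: str
    thresholds: np.ndarray
    values: np.ndarray
    bin_counts: np.ndarray
    support: tuple[float, float]
    ci_lower: Optional[np.ndarray] = None
    ci_upper: Optional[np.ndarray] = None
    missing_bin_value: Optional[float] = None
    missing_count: int = 0
    categories: Optional[list] = None

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.bin_counts = np.asarray(self.bin_counts, dtype=np.int64)
        if self.thresholds.size and not np.all(np.diff(self.thresholds) > 0):
            raise ValidationError(f"{self.feature}: thresholds must be strictly increasing")
        if self.values.size != self.thresholds.size + 1:
            raise ValidationError(f"{self.feature}: need len(values) == len(thresholds) + 1")
        if self.bin_counts.size != self.values.size:
            raise ValidationError(f"{self.feature}: bin_counts length mismatch")

    # -- geometry ----------------------------------------------------------

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    @property
    def testable(self) -> bool:
        """Whether interior thresholds exist for discontinuity testing."""
        return self.kind == "continuous" and self.n_bins >= 4

    def bin_edges(self) -> np.ndarray:
        """Edges including unbounded outer sentinels, length ``m + 1``."""
        return np.concatenate(([-np.inf], self.thresholds, [np.inf]))

    def representatives(self) -> np.ndarray:
        """Per-bin representative positions: midpoints, with the outer bins
        anchored at the observed data range."""
        lo, hi = self.support
        edges = np.concatenate(([lo], self.thresholds, [hi]))
        return (edges[:-1] + edges[1:]) / 2.0

    # -- evaluation --------------------------------------------------------

    def bin_index(self, x) -> np.ndarray:
        """Bin index for each value; missing maps to ``n_bins`` (the missing
        bin slot), categories map through ``categories`` for nominal kind."""
        if self.kind == "nominal":
            lut = {c: i for i, c in enumerate(self.categories or [])}
            xi = np.asarray(x, dtype=object).ravel()
            return np.array([lut.get(v, self.n_bins) for v in xi], dtype=np.int64)
        xf = np.asarray(x, dtype=float).ravel()
        idx = np.searchsorted(self.thresholds, xf, side="right")
        idx[np.isnan(xf)] = self.n_bins
        return idx

    def evaluate(self, x) -> np.ndarray:
        """Log-odds contribution at *x* (vectorized).

        Values exactly on a threshold land in the right-hand bin (half-open
        convention); NaN maps to the missing bin if present, else contributes
        0 with a warning.
        """
        idx = self.bin_index(x)
        out = np.empty(idx.shape, dtype=float)
        miss = idx >= self.n_bins
        out[~miss] = self.values[idx[~miss]]
        if miss.any():
            if self.missing_bin_value is not None:
                out[miss] = self.missing_bin_value
            else:
                warnings.warn(
                    f"{self.feature}: missing/unseen values with no missing bin; "
                    "contributing 0", stacklevel=2)
                out[miss] = 0.0
        return out

    def centered(self) -> "ComponentFunction":
        """Shift so the training-count-weighted mean value is zero; returns
        the shift applied (to be absorbed by the intercept) via attribute."""
        w = self.bin_counts.astype(float)
        vals = self.values.copy()
        tot = w.sum() + self.missing_count
        mean = (w @ vals + self.missing_count * (self.missing_bin_value or 0.0)) / max(tot, 1.0)
        new = replace(
            self,
            thresholds=self.thresholds.copy(),
            values=vals - mean,
            bin_counts=self.bin_counts.copy(),
            ci_lower=None if self.ci_lower is None else self.ci_lower - mean,
            ci_upper=None if self.ci_upper is None else self.ci_upper - mean,
            missing_bin_value=None if self.missing_bin_value is None
            else self.missing_bin_value - mean,
        )
        new.center_shift = mean  # type: ignore[attr-defined]
        return new


def evaluate_component(component: ComponentFunction, x) -> np.ndarray:
    """Functional alias for :meth:`ComponentFunction.evaluate`."""
    return component.evaluate(x)


# ---------------------------------------------------------------------------
# the boosting engine
# ---------------------------------------------------------------------------

def _fit_additive(bin_idx: list[np.ndarray], n_split_bins: list[int],
                  n_total_bins: list[int], y: np.ndarray,
                  fit_idx: np.ndarray, val_idx: Optional[np.ndarray],
                  config: FitConfig) -> tuple[float, list[np.ndarray], int]:
    """Round-robin boost on pre-binned features.

    ``bin_idx[f]`` holds each sample's bin index for feature ``f`` (missing
    slot included); splits are searched over the first ``n_split_bins[f]``
    ordered bins, the missing slot (if any) forms its own leaf each visit.
    Returns (intercept, per-feature value arrays, rounds used).
    """
    lr = config.learning_rate
    if config.split_alpha > 0:
        from scipy.stats import chi2
        gain_floor = [float(chi2.isf(min(config.split_alpha / max(nb - 1, 1), 1.0), 1))
                      if nb >= 2 else 0.0 for nb in n_split_bins]
    else:
        gain_floor = [0.0] * len(n_split_bins)
    active = [config.split_alpha <= 0] * len(n_split_bins)
    y_fit = y[fit_idx].astype(float)
    base = float(np.clip(y_fit.mean(), 1e-9, 1 - 1e-9))
    intercept = float(np.log(base / (1 - base)))
    F = len(bin_idx)
    values = [np.zeros(nb) for nb in n_total_bins]
    idx_fit = [b[fit_idx] for b in bin_idx]
    logit_fit = np.full(fit_idx.size, intercept)
    if val_idx is not None and val_idx.size:
        idx_val = [b[val_idx] for b in bin_idx]
        y_val = y[val_idx].astype(float)
        logit_val = np.full(val_idx.size, intercept)
    else:
        val_idx = None

    best_loss = np.inf
    best_values = None
    best_round = 0
    since_improve = 0
    rounds_used = 0

    for rnd in range(config.n_rounds):
        for f in range(F):
            nb, ntot = n_split_bins[f], n_total_bins[f]
            if ntot == 0:
                continue
            p = expit(logit_fit)
            g = y_fit - p
            h = p * (1.0 - p)
            ib = idx_fit[f]
            sg = np.bincount(ib, weights=g, minlength=ntot)
            sh = np.bincount(ib, weights=h, minlength=ntot)
            d = np.zeros(ntot)
            if nb >= 2:
                cg = np.cumsum(sg[:nb])
                ch = np.cumsum(sh[:nb])
                gl, hl = cg[:-1], ch[:-1]
                gr, hr = cg[-1] - gl, ch[-1] - hl
                gain = gl * gl / np.maximum(hl, _EPS) + gr * gr / np.maximum(hr, _EPS)
                k = int(np.argmax(gain))  # first max -> smaller bin index on ties
                # noise gate: until first activation, skip the feature while
                # its best split's gain sits within the null chi-square range
                if not active[f]:
                    if gain[k] - (cg[-1] ** 2) / max(ch[-1], _EPS) < gain_floor[f]:
                        continue
                    active[f] = True
                d[: k + 1] = lr * gl[k] / max(hl[k], _EPS)
                d[k + 1: nb] = lr * gr[k] / max(hr[k], _EPS)
            elif nb == 1:
                d[0] = lr * sg[0] / max(sh[0], _EPS)
            if ntot > nb and sh[nb] > 0:  # missing-bin leaf
                d[nb] = lr * sg[nb] / max(sh[nb], _EPS)
            values[f] += d
            logit_fit += d[ib]
            if val_idx is not None:
                logit_val += d[idx_val[f]]
        rounds_used = rnd + 1
        if val_idx is not None and config.early_stop_patience > 0:
            pv = np.clip(expit(logit_val), _EPS, 1 - _EPS)
            loss = -float(np.mean(y_val * np.log(pv) + (1 - y_val) * np.log1p(-pv)))
            if loss < best_loss - 1e-9:
                best_loss = loss
                best_values = [v.copy() for v in values]
                best_round = rounds_used
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= config.early_stop_patience:
                    break
    if best_values is not None:
        values = best_values
        rounds_used = best_round
    return intercept, values, rounds_used


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class AdditiveRiskModel:
    """Additive logistic risk model (estimator).

    Parameters
    ----------
    table : PatientTable
        Validated patient-level data.

    Construct from a dataframe with :meth:`from_dataframe`; call :meth:`fit`
    to obtain an :class:`AdditiveRiskResults`.
    """

    def __init__(self, table: PatientTable):
        self.table = table
        if len(np.unique(table.outcome)) < 2:
            raise FitError("outcome has a single class; cannot fit a risk model")

    @classmethod
    def from_dataframe(cls, df, outcome: str,
                       schema: Optional[DatasetSchema] = None) -> "AdditiveRiskModel":
        schema = schema or DatasetSchema.infer(df, outcome)
        return cls(PatientTable.from_dataframe(df, schema))

    # -- internal: shared bin grid ----------------------------------------

    def _prepare_bins(self, max_bins: int):
        """Bin every feature once on the full data; all bags share the grid."""
        tab = self.table
        prepared = []
        for spec in tab.schema.features:
            col = tab.features[spec.name]
            if spec.kind == "nominal":
                cats = sorted({v for v in col.tolist()})
                lut = {c: i for i, c in enumerate(cats)}
                idx = np.array([lut[v] for v in col.tolist()], dtype=np.int64)
                prepared.append(dict(
                    spec=spec, thresholds=np.arange(len(cats) - 1) + 0.5,
                    categories=cats, idx=idx, n_bins=len(cats),
                    has_missing=False, support=(0.0, float(max(len(cats) - 1, 1))),
                ))
                continue
            x = col.astype(float)
            finite = x[np.isfinite(x)]
            if finite.size == 0:
                raise FitError(f"feature {spec.name!r} has no finite values")
            edges = discretize_feature(x, max_bins if spec.kind == "continuous" else 2)
            n_bins = edges.size + 1
            idx = np.searchsorted(edges, x, side="right").astype(np.int64)
            has_missing = bool(np.isnan(x).any())
            idx[np.isnan(x)] = n_bins
            prepared.append(dict(
                spec=spec, thresholds=edges, categories=None, idx=idx,
                n_bins=n_bins, has_missing=has_missing,
                support=(float(finite.min()), float(finite.max())),
            ))
        return prepared

    # -- fitting -----------------------------------------------------------

    def fit(self, config: Optional[FitConfig] = None, **overrides) -> "AdditiveRiskResults":
        """Fit the model; keyword overrides update :class:`FitConfig` fields.

        With ``n_bags >= 2`` the reported components are bag means on the
        shared bin grid with empirical quantile confidence bands; with
        ``n_bags = 0`` a single point fit on the full data is returned.
        """
        if config is None:
            config = FitConfig(**overrides)
        elif overrides:
            config = replace(config, **overrides)
        tab = self.table
        n = tab.n
        if n < 10 and config.n_bags >= 2:
            warnings.warn("fewer than 10 samples: bootstrap bands will be unreliable",
                          stacklevel=2)
        prepared = self._prepare_bins(config.max_bins)
        y = tab.outcome.astype(float)
        bin_idx = [p["idx"] for p in prepared]
        n_split = [p["n_bins"] for p in prepared]
        n_tot = [p["n_bins"] + (1 if p["has_missing"] else 0) for p in prepared]

        ss = np.random.SeedSequence(config.seed)
        vf = config.validation_fraction if config.early_stop_patience > 0 else 0.0

        def one_fit(sample_idx, rng):
            if vf > 0 and sample_idx.size >= 20:
                perm = rng.permutation(sample_idx)
                n_val = max(1, int(round(vf * perm.size)))
                return _fit_additive(bin_idx, n_split, n_tot, y,
                                     perm[n_val:], perm[:n_val], config)
            return _fit_additive(bin_idx, n_split, n_tot, y, sample_idx, None, config)

        all_idx = np.arange(n)
        if config.n_bags >= 2:
            children = ss.spawn(config.n_bags)
            bag_values, bag_intercepts, rounds_used = [], [], []
            m_boot = max(1, int(round(config.bag_fraction * n)))
            for child in children:
                rng = np.random.default_rng(child)
                boot = rng.integers(0, n, size=m_boot)
                icpt, vals, r = one_fit(boot, rng)
                bag_intercepts.append(icpt)
                bag_values.append(vals)
                rounds_used.append(r)
            point_values = [np.mean([bv[f] for bv in bag_values], axis=0)
                            for f in range(len(prepared))]
            intercept = float(np.mean(bag_intercepts))
            alpha = 1.0 - config.ci_level
            ci_lo = [np.quantile([bv[f] for bv in bag_values], alpha / 2, axis=0)
                     for f in range(len(prepared))]
            ci_hi = [np.quantile([bv[f] for bv in bag_values], 1 - alpha / 2, axis=0)
                     for f in range(len(prepared))]
        else:
            rng = np.random.default_rng(ss)
            intercept, point_values, r = one_fit(all_idx, rng)
            bag_values, bag_intercepts, rounds_used = None, None, [r]
            ci_lo = ci_hi = [None] * len(prepared)

        def build_component(p, vals, lo, hi):
            nb = p["n_bins"]
            counts = np.bincount(np.minimum(p["idx"], nb), minlength=nb + 1)
            comp = ComponentFunction(
                feature=p["spec"].name, kind=p["spec"].kind,
                thresholds=p["thresholds"], values=vals[:nb],
                bin_counts=counts[:nb], support=p["support"],
                ci_lower=None if lo is None else lo[:nb],
                ci_upper=None if hi is None else hi[:nb],
                missing_bin_value=float(vals[nb]) if p["has_missing"] else None,
                missing_count=int(counts[nb]) if p["has_missing"] else 0,
                categories=p["categories"],
            )
            return comp

        components = []
        total_shift = 0.0
        for f, p in enumerate(prepared):
            comp = build_component(p, point_values[f], ci_lo[f], ci_hi[f])
            comp = comp.centered()
            total_shift += comp.center_shift  # type: ignore[attr-defined]
            components.append(comp)
        intercept += total_shift

        # center each bag the same way so bag curves remain comparable
        centered_bags = None
        if bag_values is not None:
            centered_bags = []
            for b, bv in enumerate(bag_values):
                comps_b, shift_b = [], 0.0
                for f, p in enumerate(prepared):
                    cb = build_component(p, bv[f], None, None).centered()
                    shift_b += cb.center_shift  # type: ignore[attr-defined]
                    comps_b.append(cb)
                centered_bags.append(
                    BagModel(intercept=bag_intercepts[b] + shift_b, components=comps_b))

        return AdditiveRiskResults(
            schema=tab.schema, intercept=intercept, components=components,
            fit_config=config, bag_models=centered_bags,
            n_obs=n, rounds_used=rounds_used,
        )

    def fit_bagged(self, config: Optional[FitConfig] = None, **overrides) -> "AdditiveRiskResults":
        """:meth:`fit` with bagging enforced (``n_bags >= 2``)."""
        if config is None:
            config = FitConfig(**overrides)
        elif overrides:
            config = replace(config, **overrides)
        if config.n_bags < 2:
            raise ValidationError("fit_bagged requires n_bags >= 2")
        return self.fit(config)


@dataclass
class BagModel:
    """One bootstrap bag: intercept + per-feature components on the shared grid."""

    intercept: float
    components: list[ComponentFunction]


@dataclass
class AdditiveRiskResults:
    """Fitted additive risk model: intercept + one component per feature.

    The log-odds of the outcome for a row x is
    ``intercept + sum_r f_r(x_r)``; components are centered so each has
    training-weighted mean zero and the intercept carries the base rate.
    """

    schema: DatasetSchema
    intercept: float
    components: list[ComponentFunction]
    fit_config: FitConfig
    bag_models: Optional[list[BagModel]] = None
    n_obs: int = 0
    rounds_used: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.intercept):
            raise ValidationError("intercept must be finite")
        names = [c.feature for c in self.components]
        if names != self.schema.feature_names:
            raise ValidationError("components must match schema features in order")

    # -- access ------------------------------------------------------------

    def component(self, feature: str) -> ComponentFunction:
        for c in self.components:
            if c.feature == feature:
                return c
        raise KeyError(feature)

    @property
    def n_bags(self) -> int:
        return 0 if self.bag_models is None else len(self.bag_models)

    # -- prediction --------------------------------------------------------

    def _columns(self, data) -> dict[str, np.ndarray]:
        if isinstance(data, PatientTable):
            return data.features
        if isinstance(data, dict):
            return {k: np.atleast_1d(np.asarray(v)) for k, v in data.items()}
        return {name: data[name].to_numpy() for name in self.schema.feature_names}

    def predict_logit(self, data, *, _components=None, _intercept=None) -> np.ndarray:
        """Log-odds ``intercept + sum_r f_r(x_r)`` for each row."""
        cols = self._columns(data)
        comps = self.components if _components is None else _components
        icpt = self.intercept if _intercept is None else _intercept
        out = None
        for comp in comps:
            contrib = comp.evaluate(cols[comp.feature])
            out = contrib if out is None else out + contrib
        if out is None:
            n = len(next(iter(cols.values()))) if cols else 1
            out = np.zeros(n)
        return out + icpt

    def predict_prob(self, data) -> np.ndarray:
        """Outcome probability; strictly inside (0, 1)."""
        return expit(self.predict_logit(data))

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = []
        lines.append("Additive logistic risk model (piecewise-constant components)")
        lines.append("=" * 64)
        lines.append(f"observations: {self.n_obs:>8d}    features: {len(self.components)}")
        lines.append(f"intercept (log-odds): {self.intercept:+.4f}   "
                     f"base risk: {float(expit(self.intercept)):.4f}")
        bags = self.n_bags
        rounds = (f"{int(np.mean(self.rounds_used))} (mean)" if len(self.rounds_used) > 1
                  else str(self.rounds_used[0] if self.rounds_used else 0))
        lines.append(f"bags: {bags}    boosting rounds used: {rounds}")
        lines.append("-" * 64)
        lines.append(f"{'feature':<20s} {'kind':<11s} {'bins':>5s} "
                     f"{'min f':>9s} {'max f':>9s} {'range':>8s}")
        for c in self.components:
            lines.append(
                f"{c.feature:<20.20s} {c.kind:<11s} {c.n_bins:>5d} "
                f"{c.values.min():>9.3f} {c.values.max():>9.3f} "
                f"{c.values.max() - c.values.min():>8.3f}")
        lines.append("=" * 64)
        return "\n".join(lines)

    # -- persistence (implemented in riskaudit.io) -------------------------

    def save(self, path) -> None:
        from .io import serialize_model
        serialize_model(self, path)

    @classmethod
    def load(cls, path) -> "AdditiveRiskResults":
        from .io import deserialize_model
        return deserialize_model(path)

    def export_curves(self, path) -> None:
        from .io import export_component_curves
        export_component_curves(self, path)

    # -- plotting (optional) ----------------------------------------------

    def plot_components(self, features=None, axes=None):
        """Step plots of the fitted component curves with confidence bands.

        Requires matplotlib; returns the axes array.
        """
        import matplotlib.pyplot as plt

        comps = [self.component(f) for f in features] if features else [
            c for c in self.components if c.kind == "continuous"]
        if axes is None:
            _, axes = plt.subplots(1, len(comps), figsize=(4 * len(comps), 3),
                                   squeeze=False)
            axes = axes[0]
        for ax, c in zip(axes, comps):
            lo, hi = c.support
            grid = np.linspace(lo, hi, 400)
            ax.step(grid, c.evaluate(grid), where="post")
            if c.ci_lower is not None:
                idx = np.minimum(c.bin_index(grid), c.n_bins - 1)
                ax.fill_between(grid, c.ci_lower[idx], c.ci_upper[idx],
                                alpha=0.25, step="post")
            ax.set_xlabel(c.feature)
            ax.set_ylabel("log-odds contribution")
        return axes


# convenience wrappers mirroring a functional surface ------------------------

def fit_gam(table: PatientTable, config: Optional[FitConfig] = None,
            **overrides) -> AdditiveRiskResults:
    """Point fit (no bagging unless the config asks for it)."""
    if config is None:
        overrides.setdefault("n_bags", 0)
        config = FitConfig(**overrides)
    return AdditiveRiskModel(table).fit(config)


def fit_bagged_gam(table: PatientTable, config: Optional[FitConfig] = None,
                   **overrides) -> AdditiveRiskResults:
    if config is None:
        config = FitConfig(**overrides)
    return AdditiveRiskModel(table).fit_bagged(config)


def predict_logit(results: AdditiveRiskResults, data) -> np.ndarray:
    return results.predict_logit(data)


def predict_prob(results: AdditiveRiskResults, data) -> np.ndarray:
    return results.predict_prob(data)
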