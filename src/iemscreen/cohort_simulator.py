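"""Synthetic screening-cohort generator.

The screened population itself is not distributed, so this module emulates it
from the only population facts available: the cut-off reference intervals
(healthy specimens), the per-disorder observed case ranges at both screening
tiers (affected specimens), the published disease-spectrum counts
(prevalences) and the published funnel (positive rate, recall loss).

Model
-----
* **Healthy marginals** are independent log-normals per primary marker:
  location at the interval's log-midpoint, scale solved in closed form so the
  untruncated tail mass outside [lower, upper] equals a per-marker shape
  parameter (``healthy_marker_alpha``, split equally between the two tails).
  Markers whose printed lower bound is 0 get an effective lower bound of
  upper/100 for locating the distribution, and the whole tail mass sits above
  the upper bound.
* **Panel-level calibration**: analyte ratios share numerators and
  denominators, so per-marker tail probabilities do not compose into a panel
  positive rate.  Instead the *panel-level* false-positive probability
  ``alpha`` is exact by construction: with probability 1 − alpha a healthy
  panel is rejection-sampled until every marker — ratios included — lies in
  range; with probability alpha one randomly chosen primary marker is drawn
  from outside its interval.  The default alpha is solved so the expected
  primary positive rate matches the published 2.2%.
* **Affected panels** draw each signature marker uniformly from its printed
  (min, max) range at the relevant tier; other markers come from the healthy
  model.  Ratio signatures are honoured by back-solving the ratio's
  denominator primary whenever the drawn primaries alone do not satisfy the
  printed range (deterministic adjustment order: pattern order, sole/last
  denominator member adjusted).
* **Recall**: primary positives are lost to follow-up with ``loss_rate``
  (default 1 − 2,275/2,464).  Recall panels apply multiplicative log-normal
  re-measurement noise (``noise_cv``); persistent affected specimens redraw
  their signature from the re-examination ranges, persistent healthy false
  positives redraw their forced marker from the tail, and non-persistent
  specimens redraw as fully in-range healthy panels.

Randomness is reproducible: one root seed, one child stream per specimen
(spawn-keyed by specimen index), so cohorts are byte-stable under reordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from .disorder_rules import DisorderPattern, patterns_by_id
from .panel_model import (
    AnalytePanel,
    CutoffTable,
    IemscreenError,
    MarkerDefinition,
    _load_structured,
    primary_markers,
    ratio_markers,
)
from .screening_pipeline import apply_recall, confirm, run_primary_screen, summarize

#: effective dynamic range (upper/lower) assumed for markers printed with a 0 lower bound
ZERO_LOWER_SPAN = 100.0
#: cap on rejection-sampling attempts for a fully in-range healthy panel
MAX_REJECTION_TRIES = 1000


class ConfigurationError(IemscreenError):
    pass


def load_published_counts() -> dict:
    """The published cohort counts (funnel + disease spectra + carrier study)."""
    return _load_structured(None, "cohort_counts.json")


def default_prevalence(cohort: str = "newborn") -> dict[str, float]:
    """Per-disorder prevalence from the published spectrum counts."""
    counts = load_published_counts()[cohort]
    n = counts["n_screened"]
    return {
        row["disorder"]: row["cases"] / n
        for row in counts["spectrum"]
        if row["disorder"] is not None
    }


def solve_alpha(target_positive_rate: float, prevalence: Mapping[str, float]) -> float:
    """Healthy panel-level false-positive probability hitting a target overall rate.

    Affected specimens are always primary positive, so the expected rate is
    P + (1 − P)·alpha with P = total prevalence.
    """
    p = sum(prevalence.values())
    if not 0 <= p < target_positive_rate <= 1:
        raise ConfigurationError(
            f"target positive rate {target_positive_rate} must exceed total prevalence {p}"
        )
    return (target_positive_rate - p) / (1.0 - p)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults are the published newborn-screening conditions: prevalences from
    the 30-case spectrum over 111,986 newborns, loss rate 1 − 2,275/2,464
    (≈7.7%), and ``alpha`` solved so the expected primary positive rate is
    2.2% under the ``any_abnormal_marker`` trigger.  Both persistence
    probabilities default to 1: in the published funnel the recalled
    specimens persist as the PPV denominator and confirmation does the
    discrimination.
    """

    n_newborns: int = 10_000
    n_high_risk: int = 0
    seed: int = 0
    prevalence: Mapping[str, float] = field(default_factory=default_prevalence)
    prevalence_high_risk: Mapping[str, float] = field(
        default_factory=lambda: default_prevalence("high_risk")
    )
    target_primary_positive_rate: float = 0.022
    alpha: float | None = None  # None → solved from the target rate
    loss_rate: float = 1.0 - 2275 / 2464
    fp_persistence: float = 1.0
    tp_persistence: float = 1.0
    noise_cv: float = 0.10
    healthy_marker_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_newborns < 0 or self.n_high_risk < 0:
            raise ConfigurationError("cohort sizes must be non-negative")
        for name in ("loss_rate", "fp_persistence", "tp_persistence", "healthy_marker_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be non-negative")
        for prev in (self.prevalence, self.prevalence_high_risk):
            if any(p < 0 for p in prev.values()) or sum(prev.values()) >= 1:
                raise ConfigurationError("prevalences must be non-negative and sum below 1")

    def alpha_for(self, cohort: str) -> float:
        if self.alpha is not None:
            return self.alpha
        prev = self.prevalence if cohort == "newborn" else self.prevalence_high_risk
        return solve_alpha(self.target_primary_positive_rate, prev)


@dataclass
class HealthyMarkerModel:
    """Independent log-normal marginals for the healthy population.

    ``mu``/``sigma`` are the log-scale location and scale per primary marker;
    ``alpha`` is the per-marker probability mass outside [lower, upper]
    (split equally between the tails when the lower bound is positive).
    """

    markers: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    _index: dict[str, int] = field(default_factory=dict, repr=False)
    _cdf_lo: np.ndarray | None = field(default=None, repr=False)
    _cdf_hi: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._index = {m: i for i, m in enumerate(self.markers)}
        with np.errstate(divide="ignore", invalid="ignore"):
            log_lo = np.where(self.lower > 0, np.log(np.maximum(self.lower, 1e-300)), -np.inf)
            a = np.where(self.sigma > 0, (log_lo - self.mu) / np.where(self.sigma > 0, self.sigma, 1.0), -np.inf)
            b = np.where(self.sigma > 0, (np.log(self.upper) - self.mu) / np.where(self.sigma > 0, self.sigma, 1.0), np.inf)
        self._cdf_lo = ndtr(a)
        self._cdf_hi = ndtr(b)

    def index(self, marker: str) -> int:
        return self._index[marker]

    def tail_mass(self, marker: str) -> float:
        """Closed-form P(value outside [lower, upper]) for one marker."""
        j = self._index[marker]
        return float(self._cdf_lo[j] + (1.0 - self._cdf_hi[j]))

    def sample(self, marker: str, n: int, rng: np.random.Generator) -> np.ndarray:
        """Unconstrained draws from one marker's log-normal marginal."""
        j = self._index[marker]
        return np.exp(self.mu[j] + self.sigma[j] * rng.standard_normal(n))

    def sample_in_range(self, rng: np.random.Generator) -> np.ndarray:
        """One panel's primaries, each truncated to its reference interval."""
        u = self._cdf_lo + rng.random(len(self.markers)) * (self._cdf_hi - self._cdf_lo)
        x = np.exp(self.mu + self.sigma * ndtri(np.clip(u, 1e-15, 1 - 1e-15)))
        return np.where(self.sigma > 0, x, np.exp(self.mu))

    def sample_tail(self, j: int, side: str, rng: np.random.Generator) -> float:
        """One draw from outside the interval of marker ``j`` on ``side``."""
        if self.sigma[j] == 0:
            # degenerate model: displace just beyond the bound
            return float(self.lower[j] * 0.99 if side == "low" else self.upper[j] * 1.01)
        if side == "low":
            u = rng.random() * self._cdf_lo[j]
        else:
            u = self._cdf_hi[j] + rng.random() * (1.0 - self._cdf_hi[j])
        return float(np.exp(self.mu[j] + self.sigma[j] * ndtri(np.clip(u, 1e-15, 1 - 1e-15))))


def fit_healthy_model(cutoffs: CutoffTable, alpha: float) -> HealthyMarkerModel:
    """Solve the healthy log-normal marginals from the reference intervals.

    For a marker with bounds 0 < L < U: location μ = (ln L + ln U)/2 and
    scale σ = (ln U − μ) / Φ⁻¹(1 − α/2), which puts exactly α/2 of the mass
    below L and α/2 above U.  For L = 0 the mass below the bound is zero, so
    σ is solved one-sided (P(X > U) = α) with the location anchored two
    decades below U.  α = 0 degenerates to a point mass at the log-midpoint
    (clamped σ = 0).
    """
    if not 0.0 <= alpha < 1.0:
        raise ConfigurationError(f"alpha must lie in [0, 1), got {alpha}")
    markers = primary_markers(cutoffs.schema())
    mu = np.empty(len(markers))
    sigma = np.empty(len(markers))
    lower = np.empty(len(markers))
    upper = np.empty(len(markers))
    for j, m in enumerate(markers):
        lo, hi = cutoffs[m]
        lower[j], upper[j] = lo, hi
        if lo > 0:
            mu[j] = 0.5 * (math.log(lo) + math.log(hi))
            sigma[j] = 0.0 if alpha == 0 else (math.log(hi) - mu[j]) / ndtri(1 - alpha / 2)
        else:
            eff_lo = hi / ZERO_LOWER_SPAN
            mu[j] = 0.5 * (math.log(eff_lo) + math.log(hi))
            sigma[j] = 0.0 if alpha == 0 else (math.log(hi) - mu[j]) / ndtri(1 - alpha)
    return HealthyMarkerModel(
        markers=markers, mu=mu, sigma=sigma, lower=lower, upper=upper, alpha=alpha
    )


@dataclass
class _RatioSpec:
    """Precompiled ratio marker: index arrays plus cut-off bounds."""

    id: str
    num_idx: np.ndarray
    den_idx: np.ndarray
    lower: float
    upper: float
    adjust_idx: int  # denominator member adjusted when back-solving


class _PanelSampler:
    """Compiled sampling machinery shared by all specimens of a run."""

    def __init__(
        self,
        cutoffs: CutoffTable,
        patterns: Sequence[DisorderPattern],
        model: HealthyMarkerModel,
    ):
        self.cutoffs = cutoffs
        self.model = model
        self.schema = cutoffs.schema()
        self.patterns = patterns_by_id(patterns)
        self.ratios: list[_RatioSpec] = []
        for r in ratio_markers(self.schema):
            lo, hi = cutoffs[r.id]
            self.ratios.append(
                _RatioSpec(
                    id=r.id,
                    num_idx=np.array([model.index(m) for m in r.numerator]),
                    den_idx=np.array([model.index(m) for m in r.denominator]),
                    lower=lo,
                    upper=hi,
                    adjust_idx=model.index(r.denominator[-1]),
                )
            )
        self.ratio_by_id = {r.id: r for r in self.ratios}

    # -- healthy panels ---------------------------------------------------

    def _ratios_in_range(self, x: np.ndarray) -> bool:
        for r in self.ratios:
            den = x[r.den_idx].sum()
            if den == 0:
                return False
            v = x[r.num_idx].sum() / den
            if v < r.lower or v > r.upper:
                return False
        return True

    def healthy_negative(self, rng: np.random.Generator) -> np.ndarray:
        """A fully in-range panel (all primaries and ratios within cut-offs)."""
        for _ in range(MAX_REJECTION_TRIES):
            x = self.model.sample_in_range(rng)
            if self._ratios_in_range(x):
                return x
        raise IemscreenError(
            "could not draw an in-range healthy panel; the healthy model is "
            "inconsistent with the ratio cut-offs"
        )

    def healthy_positive(self, rng: np.random.Generator) -> tuple[np.ndarray, int, str]:
        """An in-range panel with one forced out-of-range primary marker."""
        x = self.healthy_negative(rng)
        j = int(rng.integers(len(self.model.markers)))
        if self.model.lower[j] > 0:
            side = "low" if rng.random() < 0.5 else "high"
        else:
            side = "high"
        x = x.copy()
        x[j] = self.model.sample_tail(j, side, rng)
        return x, j, side

    # -- affected panels --------------------------------------------------

    def affected(
        self, disorder: str, rng: np.random.Generator, tier: str = "primary"
    ) -> np.ndarray:
        """Panel for an affected specimen at the given screening tier."""
        pattern = self.patterns.get(disorder)
        if pattern is None:
            raise ConfigurationError(f"no pattern for disorder {disorder!r}")
        observed = pattern.observed_primary if tier == "primary" else pattern.observed_recall
        if not observed:
            raise ConfigurationError(f"disorder {disorder!r} has no observed {tier} ranges")
        x = self.model.sample_in_range(rng)
        return self._impose_signature(x, pattern, observed, rng)

    def _impose_signature(
        self,
        x: np.ndarray,
        pattern: DisorderPattern,
        observed: Mapping[str, tuple[float, float, float]],
        rng: np.random.Generator,
    ) -> np.ndarray:
        def draw(marker: str) -> float:
            _, lo, hi = observed[marker]
            return float(lo if lo == hi else rng.uniform(lo, hi))

        # primaries first, then ratios, each in pattern order (deterministic)
        for marker, _direction in pattern.required:
            if marker not in self.ratio_by_id:
                x[self.model.index(marker)] = draw(marker)
        for marker, _direction in pattern.required:
            r = self.ratio_by_id.get(marker)
            if r is None:
                continue
            num = x[r.num_idx].sum()
            den = x[r.den_idx].sum()
            _, obs_lo, obs_hi = observed[marker]
            if den > 0 and obs_lo <= num / den <= obs_hi:
                continue
            target = draw(marker)
            other_den = den - x[r.adjust_idx]
            new_val = num / target - other_den
            x[r.adjust_idx] = max(new_val, 1e-9)
        return x

    def impose_median_signature(self, disorder: str) -> np.ndarray:
        """Deterministic panel: signature at observed medians, rest at the
        reference midpoints (geometric, matching the healthy location)."""
        pattern = self.patterns[disorder]
        x = np.exp(self.model.mu.copy())
        observed = {m: (v[0], v[0], v[0]) for m, v in pattern.observed_primary.items()}
        rng = np.random.default_rng(0)  # unused: all ranges are degenerate
        return self._impose_signature(x, pattern, observed, rng)

    # -- panel assembly ---------------------------------------------------

    def to_panel(
        self,
        x: np.ndarray,
        specimen_id: str,
        tier: str,
        cohort: str,
        truth_label: str | None,
    ) -> AnalytePanel:
        values = {m: float(v) for m, v in zip(self.model.markers, x)}
        return AnalytePanel(
            specimen_id=specimen_id,
            values=values,
            tier=tier,
            cohort=cohort,
            truth_label=truth_label,
        )


def sample_affected_panel(
    disorder: str,
    patterns: Sequence[DisorderPattern],
    model: HealthyMarkerModel,
    rng: np.random.Generator,
    *,
    cutoffs: CutoffTable | None = None,
    specimen_id: str = "sim",
    cohort: str = "newborn",
    tier: str = "primary",
) -> AnalytePanel:
    """Draw one affected specimen's panel (module-level convenience)."""
    cutoffs = CutoffTable.load() if cutoffs is None else cutoffs
    sampler = _PanelSampler(cutoffs, patterns, model)
    x = sampler.affected(disorder, rng, tier=tier)
    return sampler.to_panel(x, specimen_id, "primary", cohort, disorder)


@dataclass
class SimulatedCohort:
    """Everything the screening funnel needs, plus the ground truth."""

    config: SimulationConfig
    primary_panels: list[AnalytePanel]
    recall_panels: list[AnalytePanel]
    lost_ids: set[str]
    truth: dict[str, str]  # specimen_id → disorder, affected specimens only


def simulate_cohort(
    config: SimulationConfig,
    cutoffs: CutoffTable | None = None,
    patterns: Sequence[DisorderPattern] | None = None,
) -> SimulatedCohort:
    """Generate a full two-tier cohort under the configured study conditions."""
    from .disorder_rules import load_patterns

    cutoffs = CutoffTable.load() if cutoffs is None else cutoffs
    patterns = load_patterns() if patterns is None else patterns
    known = {p.disorder_id for p in patterns}
    for prev in (config.prevalence, config.prevalence_high_risk):
        unknown = set(prev) - known
        if unknown:
            raise ConfigurationError(f"prevalence references unknown disorders: {sorted(unknown)}")

    model = fit_healthy_model(cutoffs, config.healthy_marker_alpha)
    sampler = _PanelSampler(cutoffs, patterns, model)
    noise_sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))

    primary_panels: list[AnalytePanel] = []
    recall_panels: list[AnalytePanel] = []
    lost_ids: set[str] = set()
    truth: dict[str, str] = {}

    plans = [
        ("newborn", "NB", config.n_newborns, config.prevalence,
         config.alpha_for("newborn") if config.n_newborns else 0.0),
        ("high_risk", "HR", config.n_high_risk, config.prevalence_high_risk,
         config.alpha_for("high_risk") if config.n_high_risk else 0.0),
    ]
    index = 0
    for cohort, prefix, n, prevalence, alpha in plans:
        disorders = list(prevalence)
        cum = np.cumsum([prevalence[d] for d in disorders])
        for _ in range(n):
            sid = f"{prefix}{index:06d}"
            rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))
            rng_recall = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(index, 1))
            )
            index += 1

            u = rng.random()
            disorder = None
            if cum.size and u < cum[-1]:
                disorder = disorders[int(np.searchsorted(cum, u, side="right"))]

            if disorder is not None:
                x = sampler.affected(disorder, rng, tier="primary")
                truth[sid] = disorder
                positive = True
                forced = None
            elif rng.random() < alpha:
                x, j, side = sampler.healthy_positive(rng)
                positive = True
                forced = (j, side)
            else:
                x = sampler.healthy_negative(rng)
                positive = False
                forced = None
            primary_panels.append(sampler.to_panel(x, sid, "primary", cohort, disorder))

            if not positive:
                continue
            if rng.random() < config.loss_rate:
                lost_ids.add(sid)
                continue

            # recall re-measurement: multiplicative log-normal noise, mean 1
            noise = np.exp(
                rng_recall.standard_normal(len(x)) * noise_sigma - 0.5 * noise_sigma**2
            )
            xr = x * noise
            if disorder is not None:
                if rng_recall.random() < config.tp_persistence:
                    pattern = sampler.patterns[disorder]
                    xr = sampler._impose_signature(
                        xr, pattern, pattern.observed_recall, rng_recall
                    )
                else:
                    xr = sampler.healthy_negative(rng_recall)
            else:
                if rng_recall.random() < config.fp_persistence:
                    j, side = forced  # type: ignore[misc]
                    xr[j] = model.sample_tail(j, side, rng_recall)
                else:
                    xr = sampler.healthy_negative(rng_recall)
            recall_panels.append(sampler.to_panel(xr, sid, "recall", cohort, disorder))

    return SimulatedCohort(
        config=config,
        primary_panels=primary_panels,
        recall_panels=recall_panels,
        lost_ids=lost_ids,
        truth=truth,
    )


def screen_cohort(
    cohort: SimulatedCohort,
    cutoffs: CutoffTable | None = None,
    patterns: Sequence[DisorderPattern] | None = None,
    trigger_policy: str = "any_abnormal_marker",
):
    """Push a simulated cohort through the full funnel with truth-oracle
    confirmation; returns (records, summary)."""
    from .disorder_rules import load_patterns

    cutoffs = CutoffTable.load() if cutoffs is None else cutoffs
    patterns = load_patterns() if patterns is None else patterns
    records = run_primary_screen(cohort.primary_panels, cutoffs, patterns, trigger_policy)
    records = apply_recall(
        records, cohort.recall_panels, cohort.lost_ids, cutoffs, patterns, trigger_policy
    )
    diagnoses = {
        r.specimen_id: cohort.truth[r.specimen_id]
        for r in records
        if r.recall_positive and r.specimen_id in cohort.truth
    }
    records = confirm(records, diagnoses)
    return records, summarize(records, patterns)
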