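"""Monte Carlo quantitative bias analysis (QBA).

Corrects a crude self-reported effectiveness proportion for two bias
sources, at the summary (count) level:

1. **Outcome misclassification.**  With self-report sensitivity ``Se``
   (P(report complete | truly complete)) and specificity ``Sp``
   (P(report not-complete/unsure | truly not complete)), the observed
   proportion relates to the true one by
   ``p_obs = Se*p + (1-Sp)*(1-p)``, inverted as

       p = (p_obs - (1 - Sp)) / (Se + Sp - 1).

   A corrected value outside [0, 1] marks the (Se, Sp) draw as
   incompatible with the observed data.

2. **Selection from differential loss to follow-up.**  Participants with
   a truly complete abortion may be more likely to attend the final
   follow-up than those without.  Given attendance probabilities per true
   outcome, the followed counts are weighted by inverse probability of
   attendance.

Each Monte Carlo iteration draws (Se, Sp, attendance probabilities) from
their prior distributions, applies the misclassification correction, the
selection weighting, and finally a binomial random-error draw.  The
adjusted estimate is the median of kept iterations with an equal-tailed
2.5th–97.5th percentile simulation interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

# ---------------------------------------------------------------------------
# Prior distribution specs


@dataclass(frozen=True)
class Dist:
    """A prior over a probability-scale bias parameter.

    families: ``point(value)``, ``uniform(low, high)``,
    ``beta(alpha, beta)``, ``trapezoidal(low, mode_low, mode_high, high)``.
    Support must lie within (0, 1].
    """

    family: str
    params: tuple

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "point":
            return np.full(size, self.params[0])
        if self.family == "uniform":
            a, b = self.params
            return rng.uniform(a, b, size)
        if self.family == "beta":
            a, b = self.params
            return rng.beta(a, b, size)
        if self.family == "trapezoidal":
            return _sample_trapezoid(rng, size, *self.params)
        raise ValueError(f"unknown distribution family {self.family!r}")

    def support(self) -> tuple:
        if self.family == "point":
            return (self.params[0], self.params[0])
        if self.family in ("uniform", "trapezoidal"):
            return (self.params[0], self.params[-1])
        return (0.0, 1.0)  # beta; validated as open at 0 by density

    def validate(self, name: str) -> None:
        if self.family not in ("point", "uniform", "beta", "trapezoidal"):
            raise ValueError(f"{name}: unknown family {self.family!r}")
        np_ = {"point": 1, "uniform": 2, "beta": 2, "trapezoidal": 4}[self.family]
        if len(self.params) != np_:
            raise ValueError(f"{name}: {self.family} takes {np_} parameter(s)")
        if self.family == "beta":
            if min(self.params) <= 0:
                raise ValueError(f"{name}: beta parameters must be > 0")
            return
        lo, hi = self.support()
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"{name}: support must lie within (0, 1]")
        if self.family == "trapezoidal":
            a, b, c, d = self.params
            if not a <= b <= c <= d:
                raise ValueError(f"{name}: trapezoidal needs low<=mode_low<=mode_high<=high")


def point(v: float) -> Dist:
    return Dist("point", (v,))


def uniform(a: float, b: float) -> Dist:
    return Dist("uniform", (a, b))


def beta(a: float, b: float) -> Dist:
    return Dist("beta", (a, b))


def trapezoidal(low: float, mode_low: float, mode_high: float, high: float) -> Dist:
    return Dist("trapezoidal", (low, mode_low, mode_high, high))


def _sample_trapezoid(rng, size, a, b, c, d):
    """Inverse-CDF sampling of a trapezoidal density on [a, d] with flat
    top on [b, c]."""
    if a == d:
        return np.full(size, a)
    u = rng.uniform(0.0, 1.0, size)
    h = 2.0 / (d + c - b - a)  # height of the flat top
    area_rise = 0.5 * (b - a) * h
    area_top = (c - b) * h
    out = np.empty(size)
    m1 = u < area_rise
    m2 = (~m1) & (u < area_rise + area_top)
    m3 = ~(m1 | m2)
    if np.any(m1):
        out[m1] = a + np.sqrt(2.0 * u[m1] * (b - a) / h)
    if np.any(m2):
        out[m2] = b + (u[m2] - area_rise) / h
    if np.any(m3):
        rem = 1.0 - u[m3]
        out[m3] = d - np.sqrt(2.0 * rem * (d - c) / h)
    return out


# ---------------------------------------------------------------------------
# Parameters and results


@dataclass(frozen=True)
class BiasParameters:
    """Priors for the bias model plus Monte Carlo controls.

    ``impossible_draw_policy``: "discard" drops iterations whose drawn
    (Se, Sp) are incompatible with the observed proportion (corrected
    value outside [0, 1]); "truncate" clips them to the boundary.
    """

    se_dist: Dist = field(default_factory=lambda: point(1.0))
    sp_dist: Dist = field(default_factory=lambda: point(1.0))
    attend_given_complete: Dist = field(default_factory=lambda: point(1.0))
    attend_given_incomplete: Dist = field(default_factory=lambda: point(1.0))
    n_iter: int = 50_000
    seed: int = 0
    impossible_draw_policy: str = "discard"
    point_statistic: str = "median"  # or "mean"

    def validate(self) -> None:
        for name in ("se_dist", "sp_dist", "attend_given_complete",
                     "attend_given_incomplete"):
            getattr(self, name).validate(name)
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.impossible_draw_policy not in ("discard", "truncate"):
            raise ValueError("impossible_draw_policy must be discard or truncate")
        if self.point_statistic not in ("median", "mean"):
            raise ValueError("point_statistic must be median or mean")


@dataclass(frozen=True)
class QbaResult:
    """Bias-adjusted estimate with its percentile simulation interval."""

    point_estimate: float
    sim_low: float
    sim_high: float
    n_kept: int
    n_discarded: int
    n_iter: int
    seed: int
    trace: Optional[np.ndarray] = None

    def __str__(self) -> str:
        return (f"bias-adjusted estimate {100 * self.point_estimate:.1f}% "
                f"(95% simulation interval, {100 * self.sim_low:.1f}%-"
                f"{100 * self.sim_high:.1f}%); kept {self.n_kept}/{self.n_iter} draws")


# ---------------------------------------------------------------------------
# Correction primitives (closed forms; also used per-iteration)


def misclassification_correct(observed_pos: float, n: float, se: float, sp: float) -> float:
    """Back-correct an observed proportion for imperfect self-report.

    Returns ``(p_obs - (1 - sp)) / (se + sp - 1)`` with
    ``p_obs = observed_pos / n``.  The result may fall outside [0, 1]; that
    signals an (se, sp) pair incompatible with the observed data, and the
    caller decides whether to discard or truncate.  Requires
    ``se + sp > 1`` (an informative classifier).
    """
    if not 0 <= observed_pos <= n:
        raise ValueError("require 0 <= observed_pos <= n")
    if se + sp <= 1:
        raise ValueError("require se + sp > 1 (informative self-report)")
    p_obs = observed_pos / n
    return (p_obs - (1.0 - sp)) / (se + sp - 1.0)


def selection_adjust(n_complete: float, n_incomplete: float,
                     attend_given_complete: float,
                     attend_given_incomplete: float) -> float:
    """Inverse-probability-of-attendance weighted proportion complete.

    Counts among followed participants are up-weighted by 1/attendance
    probability of their (corrected) outcome class.  Equal probabilities
    cancel and return the crude followed proportion.
    """
    if not (0 < attend_given_complete <= 1 and 0 < attend_given_incomplete <= 1):
        raise ValueError("attendance probabilities must lie in (0, 1]")
    if n_complete < 0 or n_incomplete < 0 or n_complete + n_incomplete == 0:
        raise ValueError("need nonnegative counts with a positive total")
    wc = n_complete / attend_given_complete
    wi = n_incomplete / attend_given_incomplete
    return wc / (wc + wi)


# ---------------------------------------------------------------------------
# The Monte Carlo engine


def run_qba(observed_pos: int, n_followed: int, n_total: int,
            params: BiasParameters, keep_trace: bool = False) -> QbaResult:
    """Run the Monte Carlo bias analysis on summary counts.

    ``observed_pos`` of ``n_followed`` followed participants reported a
    complete abortion without procedural intervention; ``n_total`` is the
    full cohort size used for the binomial random-error draw.

    Per iteration: draw (Se, Sp, attendance | complete, attendance |
    incomplete); misclassification-correct the observed proportion;
    inverse-probability-weight for differential attendance; draw the final
    count from Binomial(n_total, adjusted p).  Iterations whose corrected
    proportion leaves [0, 1] follow ``params.impossible_draw_policy``.
    Reproducible for a fixed ``params.seed``.
    """
    params.validate()
    if not 0 <= observed_pos <= n_followed <= n_total:
        raise ValueError("require 0 <= observed_pos <= n_followed <= n_total")

    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    m = params.n_iter
    se = params.se_dist.sample(rng, m)
    sp = params.sp_dist.sample(rng, m)
    ac = params.attend_given_complete.sample(rng, m)
    ai = params.attend_given_incomplete.sample(rng, m)

    informative = se + sp > 1.0
    p_obs = observed_pos / n_followed
    with np.errstate(divide="ignore", invalid="ignore"):
        p_corr = (p_obs - (1.0 - sp)) / (se + sp - 1.0)
    valid = informative & (p_corr >= 0.0) & (p_corr <= 1.0)

    if params.impossible_draw_policy == "truncate":
        p_corr = np.clip(p_corr, 0.0, 1.0)
        keep = informative
    else:
        keep = valid
    n_discarded = int(m - keep.sum())
    if not np.any(keep):
        raise RuntimeError(
            "all draws discarded: the (se, sp) prior region is incompatible "
            f"with the observed proportion {p_obs:.4f}"
        )

    p_corr = p_corr[keep]
    ac, ai = ac[keep], ai[keep]
    # corrected counts among followed, then IP-of-attendance weighting
    nc = p_corr * n_followed
    ni = (1.0 - p_corr) * n_followed
    wc = nc / ac
    wi = ni / ai
    p_sel = wc / (wc + wi)
    # conventional final step: propagate random (sampling) error
    k = rng.binomial(n_total, p_sel)
    p_final = k / n_total

    stat = np.median if params.point_statistic == "median" else np.mean
    lo, hi = np.percentile(p_final, [2.5, 97.5])
    return QbaResult(
        point_estimate=float(stat(p_final)),
        sim_low=float(lo), sim_high=float(hi),
        n_kept=int(keep.sum()), n_discarded=n_discarded,
        n_iter=m, seed=params.seed,
        trace=p_final if keep_trace else None,
    )


def default_bias_parameters(seed: int = 0, n_iter: int = 50_000) -> BiasParameters:
    """Illustrative priors for the two bias sources.

    Self-report of abortion completion validates well against
    ultrasonography, so sensitivity is concentrated just below 1 — note
    that any Se draw below the observed proportion is logically
    incompatible with the data (the corrected proportion exceeds 1 even
    if everyone is truly complete), so with crude proportions near 0.99
    a sensitivity prior must sit essentially at 1 to be admissible.
    Specificity (correctly reporting a continuing/incomplete abortion)
    gets a wide prior; attendance at the final follow-up is near-complete
    for truly complete abortions and allowed to be substantially lower
    otherwise.  These are configuration defaults, not estimates from any
    particular validation study; analyses should supply priors matched to
    their own setting.
    """
    return BiasParameters(
        se_dist=trapezoidal(0.99, 0.995, 1.0, 1.0),
        sp_dist=uniform(0.75, 1.0),
        attend_given_complete=uniform(0.90, 1.0),
        attend_given_incomplete=uniform(0.50, 0.90),
        n_iter=n_iter,
        seed=seed,
    )


def with_seed(params: BiasParameters, seed: int) -> BiasParameters:
    """Copy of ``params`` with a different seed."""
    return replace(params, seed=seed)
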