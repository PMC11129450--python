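"""Statistical layer: Wald odds ratios, IRLS logistic regression,
Mann–Whitney U, and two-proportion post-hoc power.

All methods are the crude (unadjusted) forms appropriate to 2×K outcome
tables: the odds ratio of an event outcome versus a reference outcome for a
group versus a reference group is the cross-product ratio ad/bc with the
Woolf (Wald) interval exp(ln OR ± z·√(1/a+1/b+1/c+1/d)).  The logistic fit
is plain Newton/IRLS on a dummy-coded design and, on a saturated 2×2,
agrees with the closed-form OR to floating-point accuracy.  Power for the
difference of two independent proportions uses Cohen's arcsine effect size
h = 2·asin√p₂ − 2·asin√p₁ with the two-sided normal test, the convention of
the G*Power "two independent proportions" z-family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "EffectEstimate",
    "ZeroCellError",
    "SeparationError",
    "ConvergenceError",
    "odds_ratio_wald",
    "LogisticResult",
    "logistic_fit",
    "MannWhitneyResult",
    "mann_whitney_u",
    "cohens_h",
    "PowerInput",
    "power_two_proportions",
]


class ZeroCellError(ValueError):
    """A 2×2 subtable has an empty cell; the Wald OR is undefined."""


class SeparationError(ValueError):
    """The logistic likelihood is unbounded (perfect separation)."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


@dataclass
class ContingencyTable:
    """Outcome counts per metabolizer group with designated references.

    ``counts`` is a DataFrame indexed by group with one column per outcome;
    ``reference_group`` (default the first index entry, conventionally NM)
    and ``reference_outcome`` (default "maintained") anchor the odds ratios.
    """

    counts: pd.DataFrame
    reference_group: str | None = None
    reference_outcome: str | None = None

    def __post_init__(self):
        self.counts = self.counts.astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("contingency counts must be non-negative")
        if self.reference_group is None:
            self.reference_group = self.counts.index[0]
        if self.reference_outcome is None:
            self.reference_outcome = (
                "maintained" if "maintained" in self.counts.columns
                else self.counts.columns[0]
            )
        if self.reference_group not in self.counts.index:
            raise ValueError(f"reference group {self.reference_group!r} absent")
        if self.reference_outcome not in self.counts.columns:
            raise ValueError(f"reference outcome {self.reference_outcome!r} absent")

    @classmethod
    def from_labels(
        cls,
        groups,
        outcomes,
        reference_group: str | None = None,
        reference_outcome: str | None = None,
    ) -> "ContingencyTable":
        """Cross-tabulate parallel group / outcome label sequences."""
        counts = pd.crosstab(pd.Series(groups, name="group"),
                             pd.Series(outcomes, name="outcome"))
        return cls(counts, reference_group, reference_outcome)

    def cell(self, group, outcome) -> int:
        return int(self.counts.loc[group, outcome])


@dataclass(frozen=True)
class EffectEstimate:
    """Odds ratio with a Wald interval symmetric on the log scale."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    log_se: float
    alpha: float
    p_value: float

    def __post_init__(self):
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")


def _wald_from_cells(a: int, b: int, c: int, d: int, alpha: float,
                     haldane: bool) -> EffectEstimate:
    cells = [a, b, c, d]
    if min(cells) == 0:
        if not haldane:
            raise ZeroCellError(
                f"zero cell in 2x2 table {cells}; pass haldane=True to "
                "apply the 0.5 correction"
            )
        a, b, c, d = (x + 0.5 for x in cells)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    p = 2 * sps.norm.sf(abs(log_or) / se)
    return EffectEstimate(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        log_se=se,
        alpha=alpha,
        p_value=float(p),
    )


def odds_ratio_wald(
    table: ContingencyTable,
    group: str,
    outcome: str | None = None,
    alpha: float = 0.05,
    haldane: bool = False,
) -> EffectEstimate:
    """Cross-product OR of ``group`` vs the reference group for an outcome.

    The 2×2 subtable is (group, reference group) × (event outcome,
    reference outcome); the event outcome defaults to the single non-
    reference column and must be named when the table has several.  Zero
    cells raise :class:`ZeroCellError` unless ``haldane`` adds 0.5 to every
    cell.
    """
    if outcome is None:
        events = [c for c in table.counts.columns if c != table.reference_outcome]
        if len(events) != 1:
            raise ValueError("several event outcomes; name one explicitly")
        outcome = events[0]
    if group == table.reference_group:
        raise ValueError("group must differ from the reference group")
    a = table.cell(group, outcome)
    b = table.cell(group, table.reference_outcome)
    c = table.cell(table.reference_group, outcome)
    d = table.cell(table.reference_group, table.reference_outcome)
    return _wald_from_cells(a, b, c, d, alpha, haldane)


@dataclass
class LogisticResult:
    """Maximum-likelihood logistic coefficients with Wald inference."""

    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    n_iter: int
    converged: bool
    names: list[str] = field(default_factory=list)

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05, exponentiate: bool = True) -> np.ndarray:
        z = sps.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        ci = np.column_stack([lo, hi])
        return np.exp(ci) if exponentiate else ci

    def summary_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        z = self.params / self.bse
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "odds_ratio": np.exp(self.params),
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p_value": 2 * sps.norm.sf(np.abs(z)),
            },
            index=self.names or [f"x{i}" for i in range(len(self.params))],
        )


def logistic_fit(
    y,
    X,
    add_intercept: bool = True,
    names: list[str] | None = None,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    param_tol: float = 1e-10,
) -> LogisticResult:
    """Binary logistic regression by Newton iterations (IRLS).

    Converges when the largest absolute score falls below ``score_tol`` or
    the largest coefficient change below ``param_tol``.  Degenerate
    outcomes (all 0 or all 1) and perfect separation raise
    :class:`SeparationError`; rank-deficient designs raise ``ValueError``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        if names is not None:
            names = ["intercept"] + list(names)
    if len(y) != len(X):
        raise ValueError("outcome and design lengths differ")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise SeparationError("degenerate outcome: all observations identical")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        if np.abs(eta).max() > 30.0:
            raise SeparationError(
                "fitted log-odds diverged; data are perfectly separated"
            )
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        beta = beta + step
        if np.abs(score).max() < score_tol or np.abs(step).max() < param_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    return LogisticResult(
        params=beta,
        bse=np.sqrt(np.diag(cov)),
        cov=cov,
        n_iter=it,
        converged=converged,
        names=list(names) if names is not None else [],
    )


def expand_2x2(a: int, b: int, c: int, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Individual-level (y, x) data for a 2×2 table.

    ``a``/``b`` are event / reference-outcome counts in the exposed group
    (x = 1), ``c``/``d`` the same in the reference group (x = 0).
    """
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    return y, x


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    z: float
    p_value: float
    method: str


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    # midrank-based U for the first sample
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney_u(
    x,
    y,
    method: str = "asymptotic",
    continuity: bool = False,
    alternative: str = "two-sided",
) -> MannWhitneyResult:
    """Mann–Whitney U with tie-corrected normal approximation.

    U is computed from midrank sums; the z statistic uses the tie-corrected
    variance without continuity correction unless requested.  With
    ``method="exact"`` (ties allowed; requires n1+n2 ≤ 12) the two-sided p
    is the exact probability, under random allocation of the pooled values,
    of a U at least as far from its null mean as observed.  When every
    pooled value is tied the variance is zero and p is reported as 1.
    """
    if alternative != "two-sided":
        raise NotImplementedError("only the two-sided test is provided")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    mean_u = n1 * n2 / 2.0

    if method == "exact":
        if n1 + n2 > 12:
            raise ValueError("exact enumeration limited to n1+n2 <= 12")
        pooled = np.concatenate([x, y])
        obs_dev = abs(u - mean_u)
        hits = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mean_u) >= obs_dev - 1e-12:
                hits += 1
        return MannWhitneyResult(u=u, z=float("nan"), p_value=hits / total,
                                 method="exact")

    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")

    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return MannWhitneyResult(u=u, z=0.0, p_value=1.0, method="asymptotic")
    num = u - mean_u
    if continuity:
        num = num - 0.5 * np.sign(num)
    z = num / math.sqrt(var_u)
    p = 2 * sps.norm.sf(abs(z))
    return MannWhitneyResult(u=u, z=float(z), p_value=float(min(p, 1.0)),
                             method="asymptotic")


@dataclass(frozen=True)
class PowerInput:
    """Inputs to the two-proportion arcsine power calculation."""

    p1: float
    p2: float
    n1: int
    n2: int
    alpha: float = 0.05

    def __post_init__(self):
        for p in (self.p1, self.p2):
            if not 0.0 < p < 1.0:
                raise ValueError("proportions must be strictly inside (0, 1)")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def cohens_h(p1: float, p2: float) -> float:
    """Arcsine-transformed difference of proportions, h = 2asin√p2 − 2asin√p1."""
    return 2 * math.asin(math.sqrt(p2)) - 2 * math.asin(math.sqrt(p1))


def power_two_proportions(inp: PowerInput) -> float:
    """Post-hoc power of the two-sided two-proportion z-test via Cohen's h."""
    h = cohens_h(inp.p1, inp.p2)
    z = abs(h) / math.sqrt(1.0 / inp.n1 + 1.0 / inp.n2)
    z_crit = sps.norm.ppf(1 - inp.alpha / 2)
    return float(sps.norm.cdf(z - z_crit) + sps.norm.cdf(-z - z_crit))
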