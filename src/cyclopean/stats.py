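"""Session statistics: repeated-measures ANOVA, Bayes factors, power.

Implements the analysis pipeline applied to the simulated experiments:

* baseline normalization (each post-deprivation value minus the same
  subject's pre-deprivation value);
* one-way and fully crossed two-way within-subject ANOVA from the classical
  sums-of-squares decomposition, with Mauchly's sphericity test gating a
  Greenhouse-Geisser degrees-of-freedom correction (per effect in the
  two-way design);
* a BIC approximation to the Bayes factor BF01 in favor of the null
  ("no condition effect") model, with the conventional interpretation bands
  (anecdotal < 3, substantial 3-10, strong 10-30, very strong 30-100,
  decisive > 100);
* exact noncentral-t power for a one-sample (paired-difference) t-test and
  the minimum sample size achieving a target power.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

__all__ = [
    "RepeatedMeasuresTable", "AnovaResult", "Bf01Result", "PowerSpec",
    "normalize_to_baseline", "rm_anova_one_way", "rm_anova_two_way",
    "bf01_bic", "bf01_band", "power_one_sample_t", "min_sample_size_t",
    "RepeatedMeasuresAnova", "RMAnovaResults",
]

_REL_TOL = 1e-12


class RepeatedMeasuresTable:
    """Subjects x conditions matrix of a within-subject measure.

    ``data`` is a wide DataFrame indexed by subject.  For two-factor designs
    the columns are a 2-level MultiIndex (factor A level, factor B level)
    forming a full cross.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError("need at least 2 subjects and 2 conditions")
        if data.isna().any().any():
            raise ValueError("repeated-measures table has missing cells")
        self.data = data.astype(float)

    @classmethod
    def from_long(cls, df: pd.DataFrame, subject: str, within, value: str
                  ) -> "RepeatedMeasuresTable":
        within = [within] if isinstance(within, str) else list(within)
        wide = df.pivot(index=subject, columns=within, values=value)
        return cls(wide)

    @property
    def subjects(self):
        return self.data.index

    @property
    def conditions(self):
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def two_way(self) -> bool:
        return isinstance(self.data.columns, pd.MultiIndex)


def normalize_to_baseline(
    table: RepeatedMeasuresTable, baseline, drop_baseline: bool = False
) -> RepeatedMeasuresTable:
    """Subtract each subject's baseline condition from every cell."""
    if baseline not in table.data.columns:
        raise ValueError(f"baseline condition {baseline!r} not present")
    out = table.data.sub(table.data[baseline], axis=0)
    if drop_baseline:
        out = out.drop(columns=baseline)
    return RepeatedMeasuresTable(out)


@dataclass(frozen=True)
class AnovaResult:
    """One within-subject F test, possibly sphericity-corrected."""

    effect: str
    F: float
    df1: float
    df2: float
    p: float
    epsilon: float
    mauchly_w: float
    mauchly_p: float
    corrected: bool
    ss_effect: float
    ss_error: float
    degenerate: bool = False

    @property
    def ms_effect(self) -> float:
        return self.ss_effect / self.df1 if self.df1 else np.nan

    def summary(self) -> str:
        tag = " (GG-corrected)" if self.corrected else ""
        return (f"{self.effect}: F({self.df1:.4g}, {self.df2:.4g}) = {self.F:.4g}, "
                f"p = {self.p:.4g}, eps = {self.epsilon:.4g}{tag}")


def _gg_epsilon_and_mauchly(Y: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    """Greenhouse-Geisser epsilon and Mauchly test from orthonormal contrasts.

    ``C`` has d orthonormal rows spanning the effect's contrast space over
    the k response columns of ``Y`` (n subjects x k).
    """
    n = Y.shape[0]
    d = C.shape[0]
    if d == 1:
        return 1.0, 1.0, 1.0  # a single contrast is trivially spherical
    S = np.cov(Y, rowvar=False, ddof=1)
    M = C @ S @ C.T
    tr = np.trace(M)
    eps = tr**2 / (d * np.trace(M @ M)) if tr > 0 else 1.0
    eps = float(min(1.0, max(eps, 1.0 / d)))

    det = np.linalg.det(M)
    if det <= 0 or tr <= 0 or n - 1 <= d:
        # singular contrast covariance: sphericity untestable; report W=0, p=0
        return eps, 0.0, 0.0
    W = float(det / (tr / d) ** d)
    c = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * (n - 1.0))
    chi2 = -(n - 1.0) * c * np.log(W)
    df = d * (d + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df))
    return eps, W, p


def _f_test(ss_eff, df_eff, ss_err, df_err, eps, corrected, effect,
            mauchly_w, mauchly_p) -> AnovaResult:
    if ss_err <= _REL_TOL * max(ss_eff, 1.0):
        F = 0.0 if ss_eff <= _REL_TOL else np.inf
        return AnovaResult(effect, F, df_eff, df_err, np.nan, eps,
                           mauchly_w, mauchly_p, False, ss_eff, ss_err,
                           degenerate=True)
    F = (ss_eff / df_eff) / (ss_err / df_err)
    scale = eps if corrected else 1.0
    df1, df2 = df_eff * scale, df_err * scale
    p = float(sps.f.sf(F, df1, df2))
    return AnovaResult(effect, float(F), float(df1), float(df2), p, eps,
                       mauchly_w, mauchly_p, corrected, float(ss_eff), float(ss_err))


def _gate(correction: str, mauchly_p: float, d: int) -> bool:
    if d == 1:
        return False
    if correction == "always":
        return True
    if correction == "never":
        return False
    if correction == "auto":
        return mauchly_p < 0.05
    raise ValueError("correction must be 'auto', 'always' or 'never'")


def rm_anova_one_way(
    table: RepeatedMeasuresTable, correction: str = "auto", effect: str = "condition"
) -> AnovaResult:
    """Classical one-way within-subject ANOVA with GG-corrected df.

    Mauchly's test at alpha = 0.05 gates the Greenhouse-Geisser correction
    under ``correction="auto"``; epsilon is exactly 1 for two conditions.
    """
    if table.two_way:
        raise ValueError("table has two factors; use rm_anova_two_way")
    Y = table.values
    n, k = Y.shape
    grand = Y.mean()
    ss_cond = n * np.sum((Y.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((Y.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((Y - grand) ** 2)
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)

    C = helmert(k, full=False)
    eps, w, p_sph = _gg_epsilon_and_mauchly(Y, C)
    if k == 2:
        eps = 1.0
    corrected = _gate(correction, p_sph, k - 1)
    return _f_test(ss_cond, k - 1, ss_err, (n - 1) * (k - 1), eps, corrected,
                   effect, w, p_sph)


def rm_anova_two_way(
    table: RepeatedMeasuresTable, correction: str = "auto"
) -> dict[str, AnovaResult]:
    """Fully crossed two-way within-subject ANOVA.

    Returns one result per effect (factor A, factor B, interaction), each
    tested against its own subject-interaction error term with a per-effect
    Greenhouse-Geisser epsilon.  A single-level factor reduces exactly to the
    one-way analysis of the other factor.
    """
    if not table.two_way:
        raise ValueError("two-way analysis needs MultiIndex (A, B) columns")
    cols = table.data.columns
    a_levels = list(dict.fromkeys(cols.get_level_values(0)))
    b_levels = list(dict.fromkeys(cols.get_level_values(1)))
    a, b = len(a_levels), len(b_levels)
    expected = [(x, y) for x in a_levels for y in b_levels]
    if sorted(map(tuple, cols)) != sorted(expected) or len(cols) != a * b:
        raise ValueError("two-way design must be balanced and fully crossed")
    ordered = table.data[expected]  # row-major (A, B) order to match kron below
    n = ordered.shape[0]
    Y = ordered.to_numpy().reshape(n, a, b)

    name_a = cols.names[0] or "A"
    name_b = cols.names[1] or "B"

    # degenerate factor: collapse to the one-way analysis of the other factor
    if a == 1 or b == 1:
        flat = pd.DataFrame(Y.reshape(n, a * b),
                            index=ordered.index,
                            columns=b_levels if a == 1 else a_levels)
        name = name_b if a == 1 else name_a
        return {name: rm_anova_one_way(RepeatedMeasuresTable(flat),
                                       correction, effect=name)}

    grand = Y.mean()
    mean_a = Y.mean(axis=(0, 2))
    mean_b = Y.mean(axis=(0, 1))
    mean_s = Y.mean(axis=(1, 2))
    cell_ab = Y.mean(axis=0)
    mean_sa = Y.mean(axis=2)
    mean_sb = Y.mean(axis=1)

    ss_a = n * b * np.sum((mean_a - grand) ** 2)
    ss_b = n * a * np.sum((mean_b - grand) ** 2)
    ss_s = a * b * np.sum((mean_s - grand) ** 2)
    ss_ab = n * np.sum((cell_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((mean_sa - mean_s[:, None] - mean_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((mean_sb - mean_s[:, None] - mean_b[None, :] + grand) ** 2)
    ss_tot = np.sum((Y - grand) ** 2)
    ss_sab = max(ss_tot - ss_a - ss_b - ss_s - ss_ab - ss_sa - ss_sb, 0.0)

    Y2 = Y.reshape(n, a * b)
    Ha, Hb = helmert(a, full=False), helmert(b, full=False)
    ua = np.full((1, a), 1.0 / np.sqrt(a))
    ub = np.full((1, b), 1.0 / np.sqrt(b))
    contrasts = {
        name_a: (np.kron(Ha, ub), ss_a, a - 1, ss_sa, (n - 1) * (a - 1)),
        name_b: (np.kron(ua, Hb), ss_b, b - 1, ss_sb, (n - 1) * (b - 1)),
        f"{name_a} x {name_b}": (np.kron(Ha, Hb), ss_ab, (a - 1) * (b - 1),
                                 ss_sab, (n - 1) * (a - 1) * (b - 1)),
    }
    out: dict[str, AnovaResult] = {}
    for effect, (C, ss_eff, df_eff, ss_err, df_err) in contrasts.items():
        eps, w, p_sph = _gg_epsilon_and_mauchly(Y2, C)
        corrected = _gate(correction, p_sph, C.shape[0])
        out[effect] = _f_test(ss_eff, df_eff, ss_err, df_err, eps, corrected,
                              effect, w, p_sph)
    return out


def bf01_band(bf01: float) -> str:
    """Conventional evidence band for a Bayes factor in favor of the null."""
    if bf01 < 3:
        return "anecdotal"
    if bf01 < 10:
        return "substantial"
    if bf01 < 30:
        return "strong"
    if bf01 < 100:
        return "very strong"
    return "decisive"


@dataclass(frozen=True)
class Bf01Result:
    bf01: float
    bic_null: float
    bic_alt: float
    band: str = field(default="")

    def __post_init__(self) -> None:
        if not self.band:
            object.__setattr__(self, "band", bf01_band(self.bf01))


def _ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def bf01_bic(
    table: RepeatedMeasuresTable,
    null_terms: tuple[str, ...] = ("subject",),
    alt_terms: tuple[str, ...] = ("subject", "condition"),
) -> Bf01Result:
    """BIC approximation to the Bayes factor for the null over the alternative.

    Both models are fixed-effects OLS fits to the long-format table (terms
    from {"subject", "condition"}, always including an intercept); the
    alternative must nest the null.  BF01 = exp((BIC_alt - BIC_null) / 2), so
    BF01 > 1 favors the model *without* the condition effect.
    """
    allowed = {"subject", "condition"}
    if not set(null_terms) <= set(alt_terms):
        raise ValueError("the null model must be nested in the alternative")
    if not set(alt_terms) <= allowed:
        raise ValueError(f"model terms must come from {sorted(allowed)}")

    wide = table.data.rename_axis(index="_subject")
    long = wide.stack(list(range(wide.columns.nlevels)),
                      future_stack=True).rename("y").reset_index()
    subj_col = "_subject"
    cond_cols = [c for c in long.columns if c not in ("y", subj_col)]
    long["_cond"] = long[cond_cols].astype(str).agg("|".join, axis=1)
    y = long["y"].to_numpy()
    N = len(y)

    def design(terms) -> np.ndarray:
        parts = [np.ones((N, 1))]
        if "subject" in terms:
            parts.append(pd.get_dummies(long[subj_col], drop_first=True).to_numpy(float))
        if "condition" in terms:
            parts.append(pd.get_dummies(long["_cond"], drop_first=True).to_numpy(float))
        return np.hstack(parts)

    def bic(terms) -> float:
        rss, rank = _ols_rss(y, design(terms))
        return N * np.log(rss / N) + (rank + 1) * np.log(N)  # +1 for sigma^2

    bic_null, bic_alt = bic(null_terms), bic(alt_terms)
    bf01 = float(np.exp((bic_alt - bic_null) / 2.0))
    return Bf01Result(bf01=bf01, bic_null=float(bic_null), bic_alt=float(bic_alt))


@dataclass(frozen=True)
class PowerSpec:
    """A paired-difference effect in its native units and the test settings."""

    effect_mean: float
    effect_sd: float
    alpha: float = 0.05
    target_power: float = 0.80
    tail: str = "one"

    def __post_init__(self) -> None:
        if self.effect_sd <= 0:
            raise ValueError("effect_sd must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must lie in (0, 1)")
        if self.tail not in ("one", "two"):
            raise ValueError("tail must be 'one' or 'two'")


def power_one_sample_t(spec: PowerSpec, n: int) -> float:
    """Exact noncentral-t power of a one-sample t test at sample size n."""
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    nc = (spec.effect_mean / spec.effect_sd) * np.sqrt(n)
    if spec.tail == "one":
        t_crit = sps.t.ppf(1.0 - spec.alpha, df)
        return float(sps.nct.sf(t_crit, df, nc))
    t_crit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(sps.nct.sf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc))


def min_sample_size_t(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest n whose exact noncentral-t power reaches the target."""
    if spec.effect_mean == 0:
        raise ValueError("a null effect can never reach the target power")
    for n in range(2, n_max + 1):
        if power_one_sample_t(spec, n) >= spec.target_power:
            return n
    raise ValueError(f"target power not reached by n = {n_max}")


class RepeatedMeasuresAnova:
    """Model object bundling a table with its within-subject analysis.

    `fit()` runs the one- or two-way decomposition (chosen by the table's
    column structure) and returns an :class:`RMAnovaResults` with the F
    tests, the BIC Bayes factor for the condition effect (one-way designs)
    and a `summary()` table.
    """

    def __init__(self, table: RepeatedMeasuresTable | pd.DataFrame,
                 baseline=None, drop_baseline: bool = False):
        if isinstance(table, pd.DataFrame):
            table = RepeatedMeasuresTable(table)
        if baseline is not None:
            table = normalize_to_baseline(table, baseline, drop_baseline)
        self.table = table

    @classmethod
    def from_long(cls, df: pd.DataFrame, subject: str, within, value: str,
                  **kwargs) -> "RepeatedMeasuresAnova":
        return cls(RepeatedMeasuresTable.from_long(df, subject, within, value),
                   **kwargs)

    def fit(self, correction: str = "auto") -> "RMAnovaResults":
        if self.table.two_way:
            effects = rm_anova_two_way(self.table, correction)
            bf = None
        else:
            effects = {"condition": rm_anova_one_way(self.table, correction)}
            bf = bf01_bic(self.table)
        return RMAnovaResults(self.table, effects, bf)


@dataclass
class RMAnovaResults:
    table: RepeatedMeasuresTable
    effects: dict[str, AnovaResult]
    bf01: Bf01Result | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect": r.effect, "F": r.F, "df1": r.df1, "df2": r.df2, "p": r.p,
             "epsilon": r.epsilon, "mauchly_p": r.mauchly_p,
             "GG_corrected": r.corrected}
            for r in self.effects.values()
        ]
        return pd.DataFrame(rows).set_index("effect")

    def summary(self) -> str:
        buf = io.StringIO()
        n, k = self.table.values.shape
        buf.write(f"Repeated-measures ANOVA  ({n} subjects x {k} conditions)\n")
        for r in self.effects.values():
            buf.write("  " + r.summary() + "\n")
        if self.bf01 is not None:
            buf.write(f"  BF01 (BIC approximation) = {self.bf01.bf01:.4g} "
                      f"[{self.bf01.band} evidence for the null]\n")
        return buf.getvalue()
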