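"""Effect-size statistics for semiquantitative gel-shift and reporter assays.

Raw inputs are replicate band densities (EMSA, arbitrary film units) or
reporter protein levels (ELISA, ratio scale).  Densitometry is standardized
per film -- each signal becomes (x - film mean)/film SD, then the film's
wildtype-control value is subtracted so the control sits at exactly 0.
Ratio-scale measurements are divided by a cotransfection covariate and
rescaled so the control mean is exactly 1.

Inference follows a shared-variance design: a balanced one-way ANOVA pools
the within-group mean square (MSerror), which is the common denominator for

* per-variant bias-corrected standardized differences (Hedges g),
      g = (m_j - m_c)/sqrt(MSerror) * J(n),
      J(n) = Gamma(df/2) / (Gamma((df-1)/2) * sqrt(df/2)),  df = 2n - 2;
* the assay-level root-mean-square standardized effect,
      Psi = J(n) * sqrt( sum_j (m_j - GM)^2 / ((k-1) * MSerror) );
* Dunnett's multiple t of every variant against the control, using the
  two-sided equicoordinate critical value of the equicorrelated
  (rho = 1/2) multivariate t, computed by numerical integration over the
  shared control variate.

Residual normality is gated by the Anderson-Darling test; ratio-scale data
failing the gate are Box-Cox transformed (maximum likelihood on a lambda
grid) before ANOVA/Dunnett, with reported means back-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats
from statsmodels.stats.diagnostic import normal_ad

__all__ = [
    "AssayTable",
    "StandardizedTable",
    "AnovaResult",
    "EffectSizeSet",
    "bias_correction",
    "standardize_by_film",
    "normalize_ratio",
    "gate_and_transform",
    "anova_oneway",
    "hedges_g",
    "hedges_g_se",
    "sqrt_mserror_from_g",
    "rmsse_psi",
    "dunnett_critical",
    "dunnett_test",
    "analyze_assay",
]


class DegenerateFilmError(ValueError):
    """A film has zero signal standard deviation."""


class DesignError(ValueError):
    """The replicate layout violates the assumed design."""


class UndefinedEffectError(ValueError):
    """Effect sizes are undefined (MSerror = 0 or no error df)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class AssayTable:
    """Raw replicate measurements grouped by film and variant.

    ``data`` columns: film_id, variant, replicate, signal and (for ratio
    assays) optionally covariate.  ``kind`` is "subtractive" (densitometry,
    film-standardized) or "ratio" (reporter levels, strictly positive).
    """

    assay_id: str
    kind: str
    data: pd.DataFrame
    control: str

    def __post_init__(self) -> None:
        if self.kind not in ("subtractive", "ratio"):
            raise ValueError(f"unknown assay kind {self.kind!r}")
        required = {"film_id", "variant", "replicate", "signal"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        sig = self.data["signal"].to_numpy(float)
        if not np.all(np.isfinite(sig)):
            raise ValueError("non-finite signal values")
        if self.kind == "ratio" and np.any(sig <= 0):
            raise ValueError("ratio-kind signals must be strictly positive")
        for film, grp in self.data.groupby("film_id"):
            if self.control not in set(grp["variant"]):
                raise DesignError(
                    f"control {self.control!r} missing from film {film!r}"
                )
            if self.kind == "subtractive":
                if len(grp) < 2 or grp["signal"].std(ddof=1) == 0:
                    raise DegenerateFilmError(
                        f"film {film!r} has zero signal SD"
                    )

    @classmethod
    def from_tsv(cls, path, assay_id: str, kind: str, control: str) -> "AssayTable":
        df = pd.read_csv(path, sep="\t")
        return cls(assay_id=assay_id, kind=kind, data=df, control=control)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class StandardizedTable:
    """Per-record adjusted (dimensionless) values anchored on the control.

    For subtractive assays the control's adjusted mean is exactly 0; for
    ratio assays exactly 1.  ``transform_lambda`` records a Box-Cox
    transformation applied downstream (None = identity).
    """

    assay_id: str
    kind: str
    data: pd.DataFrame  # film_id, variant, replicate, adjusted
    control: str
    transform_lambda: float | None = None

    @property
    def control_mean(self) -> float:
        return 0.0 if self.kind == "subtractive" else 1.0

    def variant_means(self) -> pd.Series:
        """Group means on the analysis scale, variants in first-seen order."""
        return self.data.groupby("variant", sort=False)["adjusted"].mean()

    def variant_se(self) -> pd.Series:
        g = self.data.groupby("variant", sort=False)["adjusted"]
        return g.std(ddof=1) / np.sqrt(g.count())

    def report_means(self) -> pd.Series:
        """Back-transformed group means for reporting."""
        means = self.variant_means()
        if self.transform_lambda is None:
            return means
        lam = self.transform_lambda
        return pd.Series(special.inv_boxcox(means.to_numpy(), lam), index=means.index)


@dataclass
class AnovaResult:
    """Balanced one-way decomposition; MSerror is shared downstream."""

    k: int
    n: int
    df_error: int
    ms_error: float
    grand_mean: float
    F: float
    p: float


@dataclass
class EffectSizeSet:
    """Per-variant Hedges g, assay-level Psi, and Dunnett flags."""

    g: pd.Series
    correction: float
    se: pd.Series
    psi: float
    dunnett_flags: pd.Series
    critical_value: float
    alpha: float


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def standardize_by_film(table: AssayTable) -> StandardizedTable:
    """Standardize densitometry within each film and anchor on the control.

    Within a film each signal becomes (x - film mean)/film SD; the control's
    standardized value for that film (averaged if replicated) is then
    subtracted from all of the film's values, so the control mean is 0 and
    additive/multiplicative film effects cancel exactly.
    """
    if table.kind != "subtractive":
        raise ValueError("standardize_by_film requires a subtractive-kind assay")
    out = []
    for film, grp in table.data.groupby("film_id", sort=False):
        x = grp["signal"].to_numpy(float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise DegenerateFilmError(f"film {film!r} has zero signal SD")
        z = (x - x.mean()) / sd
        ctrl = z[(grp["variant"] == table.control).to_numpy()]
        if ctrl.size == 0:
            raise DesignError(f"control missing from film {film!r}")
        g2 = grp.copy()
        g2["adjusted"] = z - ctrl.mean()
        out.append(g2)
    data = pd.concat(out, ignore_index=True)[
        ["film_id", "variant", "replicate", "adjusted"]
    ]
    return StandardizedTable(table.assay_id, "subtractive", data, table.control)


def normalize_ratio(
    table: AssayTable, covariate: Sequence[float] | None = None
) -> StandardizedTable:
    """Adjust ratio-scale signals for a covariate and rescale to control = 1.

    Each signal is divided by its (positive) covariate -- e.g. a
    cotransfected beta-gal level -- then all values are divided by the
    control variant's adjusted mean.
    """
    if table.kind != "ratio":
        raise ValueError("normalize_ratio requires a ratio-kind assay")
    if covariate is None:
        if "covariate" in table.data.columns:
            cov = table.data["covariate"].to_numpy(float)
        else:
            cov = np.ones(len(table.data))
    else:
        cov = np.asarray(covariate, float)
    sig = table.data["signal"].to_numpy(float)
    if np.any(cov <= 0) or np.any(sig <= 0):
        raise ValueError("signals and covariates must be strictly positive")
    adj = sig / cov
    ctrl_mean = adj[(table.data["variant"] == table.control).to_numpy()].mean()
    data = table.data[["film_id", "variant", "replicate"]].copy()
    data["adjusted"] = adj / ctrl_mean
    return StandardizedTable(table.assay_id, "ratio", data, table.control)


def gate_and_transform(std: StandardizedTable, alpha: float = 0.05,
                       grid: tuple[float, float, float] = (-3.0, 3.0, 0.01)
                       ) -> StandardizedTable:
    """Anderson-Darling gate on ANOVA residuals, Box-Cox if it fails.

    Residuals are the adjusted values minus their group means.  If the AD
    p-value is below ``alpha`` and all values are strictly positive, a
    Box-Cox transform with lambda chosen by maximum likelihood on a grid is
    applied; the returned table carries the transformed values and records
    ``transform_lambda``.  Otherwise the table is returned unchanged.
    """
    vals = std.data["adjusted"].to_numpy(float)
    resid = vals - std.data.groupby("variant")["adjusted"].transform("mean").to_numpy()
    _, p = normal_ad(resid)
    if p >= alpha:
        return replace(std, transform_lambda=None)
    if np.any(vals <= 0):
        raise ValueError(
            "Box-Cox transformation requested on nonpositive values"
        )
    lo, hi, step = grid
    lams = np.arange(lo, hi + step / 2, step)
    llf = np.array([stats.boxcox_llf(l, vals) for l in lams])
    lam = float(lams[np.argmax(llf)])
    data = std.data.copy()
    data["adjusted"] = stats.boxcox(vals, lmbda=lam)
    return StandardizedTable(std.assay_id, std.kind, data, std.control,
                             transform_lambda=lam)


# ---------------------------------------------------------------------------
# ANOVA and effect sizes
# ---------------------------------------------------------------------------


def anova_oneway(std: StandardizedTable) -> AnovaResult:
    """Balanced one-way ANOVA of adjusted values by variant."""
    groups = std.data.groupby("variant", sort=False)["adjusted"]
    sizes = groups.count()
    k = len(sizes)
    if k < 2:
        raise DesignError("ANOVA requires at least 2 groups")
    if sizes.nunique() != 1:
        raise DesignError("unbalanced design: unequal replicates per group")
    n = int(sizes.iloc[0])
    if n < 2:
        raise DesignError("no error degrees of freedom (n = 1)")
    vals = std.data["adjusted"].to_numpy(float)
    gm = vals.mean()
    means = groups.mean()
    ss_between = n * float(((means - gm) ** 2).sum())
    ss_within = float(
        ((vals - groups.transform("mean").to_numpy()) ** 2).sum()
    )
    df_b, df_e = k - 1, k * (n - 1)
    ms_error = ss_within / df_e
    if ms_error == 0:
        F, p = float("nan"), float("nan")
    else:
        F = (ss_between / df_b) / ms_error
        p = float(stats.f.sf(F, df_b, df_e))
    return AnovaResult(k=k, n=n, df_error=df_e, ms_error=ms_error,
                       grand_mean=gm, F=F, p=p)


def bias_correction(n: int) -> float:
    """Small-sample bias factor J(n) for a two-group comparison, df = 2n-2."""
    if n < 2:
        raise ValueError("n must be >= 2")
    df = 2 * n - 2
    return float(np.exp(special.gammaln(df / 2) - special.gammaln((df - 1) / 2))
                 / np.sqrt(df / 2))


def hedges_g(m_j: float, m_c: float, ms_error: float, n: int) -> float:
    """Bias-corrected standardized difference of a variant vs. the control."""
    if ms_error <= 0:
        raise UndefinedEffectError("MSerror must be > 0")
    return (m_j - m_c) / np.sqrt(ms_error) * bias_correction(n)


def hedges_g_se(g: float, n: int, df_error: int) -> float:
    """Delta-method approximate standard error of g."""
    return float(np.sqrt(2.0 / n + g * g / (2.0 * df_error)))


def sqrt_mserror_from_g(m_j: float, m_c: float, g: float, n: int) -> float:
    """Recover sqrt(MSerror) from one group's (mean, g) pair.

    Fixture helper for reproducing published effect-size tables when raw
    replicates are unavailable; not a pipeline stage.
    """
    if g == 0:
        raise ValueError("cannot recover scale from g = 0")
    return abs((m_j - m_c) * bias_correction(n) / g)


def rmsse_psi(means: Sequence[float], ms_error: float, k: int, n: int) -> float:
    """Bias-adjusted root-mean-square standardized effect of an assay.

    Psi expresses the spread of the k group means around the grand mean in
    units of sqrt(MSerror), scaled by the same J(n) small-sample factor as
    g, so the two are on comparable scales.  Psi = 0 iff all means coincide.
    """
    means = np.asarray(means, float)
    if len(means) != k:
        raise ValueError("means length must equal k")
    if k < 2:
        raise DesignError("Psi requires k >= 2 groups")
    if ms_error <= 0:
        raise UndefinedEffectError("MSerror must be > 0")
    gm = means.mean()
    return float(bias_correction(n)
                 * np.sqrt(((means - gm) ** 2).sum() / ((k - 1) * ms_error)))


# ---------------------------------------------------------------------------
# Dunnett's multiple t vs. a control
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _gauss_legendre(npts: int, lo: float, hi: float):
    x, w = np.polynomial.legendre.leggauss(npts)
    return 0.5 * (hi - lo) * x + 0.5 * (hi + lo), 0.5 * (hi - lo) * w


def _dunnett_prob(c: float, r: int, df: int, two_sided: bool) -> float:
    """P(max_i |T_i| <= c) for r equicorrelated (rho=1/2) t variates.

    Balanced design: T_i = (Z_i - Z_0)/(S*sqrt(2)) with iid N(0,1) Z and
    S^2 ~ chi2_df/df, so the joint probability factorizes given the control
    variate Z_0 and the scale S, leaving a 2-D quadrature.
    """
    z, wz = _gauss_legendre(257, -9.0, 9.0)
    hi_u = float(np.sqrt(stats.chi2.ppf(1 - 1e-12, df) / df))
    lo_u = float(np.sqrt(stats.chi2.ppf(1e-12, df) / df))
    u, wu = _gauss_legendre(257, lo_u, hi_u)
    # log density of U = S/sigma: nu*U^2 ~ chi2_nu
    nu = df
    logf = (np.log(2) + (nu / 2) * np.log(nu / 2) - special.gammaln(nu / 2)
            + (nu - 1) * np.log(u) - nu * u * u / 2)
    fu = np.exp(logf)
    phi = np.exp(-z * z / 2) / np.sqrt(2 * np.pi)
    # grid: rows u, cols z
    shift = np.sqrt(2.0) * c * u[:, None]
    if two_sided:
        core = stats.norm.cdf(z[None, :] + shift) - stats.norm.cdf(z[None, :] - shift)
    else:
        core = stats.norm.cdf(z[None, :] + shift)
    inner = (core ** r) @ (phi * wz)
    return float(inner @ (fu * wu))


@lru_cache(maxsize=None)
def dunnett_critical(k: int, df: int, alpha: float = 0.05,
                     two_sided: bool = True, tol: float = 1e-4) -> float:
    """Equicoordinate Dunnett critical value for k-1 comparisons vs. control.

    Solves P(max |T_i| <= c) = 1 - alpha by root finding on the joint
    equicorrelated multivariate-t probability (absolute tolerance ``tol``).
    For k = 2 this collapses to the ordinary Student t quantile.
    """
    if k < 2:
        raise DesignError("Dunnett test requires k >= 2 groups")
    if df < 1:
        raise DesignError("no error degrees of freedom")
    r = k - 1
    target = 1.0 - alpha
    f = lambda c: _dunnett_prob(c, r, df, two_sided) - target
    return float(optimize.brentq(f, 0.5, 15.0, xtol=tol))


def dunnett_test(
    means: Mapping[str, float] | pd.Series,
    control: str,
    ms_error: float,
    n: int,
    alpha: float = 0.05,
    two_sided: bool = True,
) -> tuple[pd.Series, float]:
    """Flag variants whose mean differs from the control's by Dunnett's t.

    Returns (boolean flags per non-control variant, critical value).  The
    statistic is |m_j - m_c| / sqrt(2*MSerror/n); the control is never
    flagged.
    """
    means = pd.Series(means, dtype=float)
    if control not in means.index:
        raise DesignError(f"control {control!r} not among group means")
    if ms_error <= 0:
        raise UndefinedEffectError("MSerror must be > 0")
    k = len(means)
    df = k * (n - 1)
    crit = dunnett_critical(k, df, alpha, two_sided)
    se = np.sqrt(2.0 * ms_error / n)
    t = (means - means[control]) / se
    if two_sided:
        flags = t.abs() > crit
    else:
        flags = t > crit
    flags[control] = False
    return flags, crit


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def analyze_assay(
    table: AssayTable,
    alpha: float = 0.05,
    boxcox: str = "auto",
    covariate: Sequence[float] | None = None,
) -> dict:
    """Full effect-size analysis of one assay table.

    Normalizes (per-film standardization or covariate/ratio adjustment),
    optionally gates and Box-Cox-transforms ratio data (``boxcox`` in
    {"auto", "off"}), then computes ANOVA, Hedges g per variant, Psi, and
    Dunnett flags.  Returns a JSON-serializable report.
    """
    if table.kind == "subtractive":
        std = standardize_by_film(table)
    else:
        std = normalize_ratio(table, covariate)
        if boxcox == "auto":
            std = gate_and_transform(std, alpha=alpha)
    an = anova_oneway(std)
    means = std.variant_means()
    m_c = float(means[table.control])
    if an.ms_error <= 0:
        raise UndefinedEffectError("MSerror = 0: effects undefined")
    g = means.apply(lambda m: hedges_g(m, m_c, an.ms_error, an.n))
    se = g.apply(lambda v: hedges_g_se(v, an.n, an.df_error))
    psi = rmsse_psi(means.to_numpy(), an.ms_error, an.k, an.n)
    flags, crit = dunnett_test(means, table.control, an.ms_error, an.n, alpha)
    report_means = std.report_means()
    variants = list(means.index)
    return {
        "assay_id": table.assay_id,
        "kind": table.kind,
        "control": table.control,
        "alpha": alpha,
        "transform_lambda": std.transform_lambda,
        "k": an.k,
        "n": an.n,
        "df_error": an.df_error,
        "ms_error": an.ms_error,
        "grand_mean": an.grand_mean,
        "F": an.F,
        "p": an.p,
        "psi": psi,
        "dunnett_critical": crit,
        "variants": [
            {
                "variant": v,
                "adjusted_mean": float(report_means[v]),
                "se": float(std.variant_se()[v]),
                "g": float(g[v]),
                "g_se": float(se[v]),
                "dunnett_flag": bool(flags[v]),
            }
            for v in variants
        ],
    }


def report_to_frame(report: dict) -> pd.DataFrame:
    """Tabular (TSV-ready) view of an ``analyze_assay`` report."""
    df = pd.DataFrame(report["variants"])
    df.insert(0, "assay_id", report["assay_id"])
    return df
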