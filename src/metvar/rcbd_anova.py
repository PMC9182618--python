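"""Per-location randomized-complete-block ANOVA for one trait.

The two-way additive model y_ij = mu + t_i + r_j + e_ij (genotype i in
replicate/block j) is decomposed with the definitional sums of squares:

    SS_genotype  = r * sum_i (mean_i. - grand)^2
    SS_replicate = g * sum_j (mean_.j - grand)^2
    SS_error     = SS_total - SS_genotype - SS_replicate

The genotype F statistic MSG/MSE and its upper-tail p-value feed the
significance stars; MSG and MSE are the raw material of every genetic
parameter downstream. LSD gives the classical mean-separation yardstick and
CV% the experimental precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import TrialDataset

__all__ = ["AnovaTable", "SignificanceMark", "significance_mark",
           "anova_rcbd", "lsd", "cv_percent"]


@dataclass(frozen=True)
class SignificanceMark:
    """Star convention: ``**`` for p <= 0.01, ``*`` for p <= 0.05, else ``ns``."""

    p: float
    mark: str

    @property
    def significant(self) -> bool:
        return self.mark != "ns"


def significance_mark(p: float) -> SignificanceMark:
    if not np.isfinite(p):
        return SignificanceMark(p=float(p), mark="ns")
    if p <= 0.01:
        mark = "**"
    elif p <= 0.05:
        mark = "*"
    else:
        mark = "ns"
    return SignificanceMark(p=float(p), mark=mark)


@dataclass
class AnovaTable:
    """df/SS/MS/F/p decomposition of one trait at one location.

    ``rows`` is a DataFrame indexed by source (replicate, genotype, error,
    total) with columns df, SS, MS, F, p; F and p are NaN except for the
    genotype row (replicates are a fixed blocking factor and are not
    tested), and undefined when MSE is zero.
    """

    trait: str
    location: str
    rows: pd.DataFrame
    n_replicates: int
    n_genotypes: int
    trait_mean: float

    @property
    def msg(self) -> float:
        return float(self.rows.loc["genotype", "MS"])

    @property
    def mse(self) -> float:
        return float(self.rows.loc["error", "MS"])

    @property
    def df_error(self) -> int:
        return int(self.rows.loc["error", "df"])

    @property
    def f_genotype(self) -> float:
        return float(self.rows.loc["genotype", "F"])

    @property
    def p_genotype(self) -> float:
        return float(self.rows.loc["genotype", "p"])

    @property
    def genotype_mark(self) -> SignificanceMark:
        return significance_mark(self.p_genotype)


def _balanced_matrix(df: pd.DataFrame, trait: str, location: str) -> np.ndarray:
    """Genotype x replicate value matrix; errors on imbalance or missing data."""
    piv = df.pivot_table(index="genotype", columns="replicate", values=trait,
                         aggfunc="count", sort=False)
    counts = piv.fillna(0).to_numpy()
    if counts.size == 0 or not (counts == 1).all():
        raise ValueError(
            f"location {location!r} is not a complete balanced RCBD for "
            f"trait {trait!r} (each genotype must appear once per replicate)"
        )
    vals = df.pivot_table(index="genotype", columns="replicate", values=trait,
                          aggfunc="first", sort=False).to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError(
            f"missing values for trait {trait!r} at {location!r}; the "
            "variance-component formulas assume complete data"
        )
    return vals


def anova_rcbd(ds: TrialDataset, trait: str, location: str) -> AnovaTable:
    """Two-way RCBD ANOVA of one trait at one location.

    Raises on unbalanced or incomplete data and on single-replicate layouts
    (zero error degrees of freedom).
    """
    ds.require_trait(trait)
    sub = ds.subset_location(location)
    y = _balanced_matrix(sub, trait, location)
    g, r = y.shape
    if r < 2:
        raise ValueError("at least 2 replicates required (df_error would be 0)")

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_gen = float(r * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_rep = float(g * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_err = ss_total - ss_gen - ss_rep
    if ss_err < 0:
        if ss_err < -1e-8 * max(ss_total, 1.0):
            warnings.warn(
                f"negative error SS ({ss_err:.3g}) clamped to 0", RuntimeWarning
            )
        ss_err = 0.0

    df_gen, df_rep = g - 1, r - 1
    df_err = df_gen * df_rep
    msg, msr, mse = ss_gen / df_gen, ss_rep / df_rep, ss_err / df_err
    if mse > 0:
        f = msg / mse
        p = float(stats.f.sf(f, df_gen, df_err))
    else:
        f, p = np.nan, np.nan

    rows = pd.DataFrame(
        {
            "df": [df_rep, df_gen, df_err, g * r - 1],
            "SS": [ss_rep, ss_gen, ss_err, ss_total],
            "MS": [msr, msg, mse, np.nan],
            "F": [np.nan, f, np.nan, np.nan],
            "p": [np.nan, p, np.nan, np.nan],
        },
        index=pd.Index(["replicate", "genotype", "error", "total"], name="source"),
    )
    return AnovaTable(trait=trait, location=location, rows=rows,
                      n_replicates=r, n_genotypes=g, trait_mean=float(grand))


def lsd(at: AnovaTable, alpha: float = 0.05) -> float:
    """Least significant difference between two genotype means.

    LSD = t(1 - alpha/2, df_error) * sqrt(2 * MSE / r).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if at.df_error < 1:
        raise ValueError("error degrees of freedom must be >= 1")
    t_crit = stats.t.ppf(1 - alpha / 2, at.df_error)
    return float(t_crit * np.sqrt(2.0 * at.mse / at.n_replicates))


def cv_percent(at: AnovaTable, trait_mean: float | None = None) -> float:
    """Experimental coefficient of variation, 100 * sqrt(MSE) / mean."""
    mean = at.trait_mean if trait_mean is None else float(trait_mean)
    if not mean > 0:
        raise ValueError("trait mean must be positive for CV%")
    return float(100.0 * np.sqrt(at.mse) / mean)
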