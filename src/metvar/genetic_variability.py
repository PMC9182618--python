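"""Genetic parameters derived from RCBD mean squares.

For each (location, trait) the RCBD expected mean squares give the classical
moment estimators

    sigma2_g = (MSG - MSE) / r        (clamped at 0 when MSG < MSE)
    sigma2_e = MSE
    sigma2_p = sigma2_g + sigma2_e

from which follow the genotypic / phenotypic / environmental coefficients of
variation (100 * sd / mean), broad-sense heritability h2 = sigma2_g /
sigma2_p, and the expected genetic advance under truncation selection
GA = K * h2 * sigma_p with selection intensity K (2.06 when the best 5% of
genotypes are kept), plus GA as a percent of the trait mean (GAM).

Within a single location the genotype and genotype-by-location effects are
confounded, so the per-location sigma2_g estimates Var(g) + Var(gl). The
combined multi-location ANOVA separates the two;
:func:`variance_components_combined` provides those estimators for
parameter-recovery work.

The conventional descriptive bands (low / medium or moderate / high) for
GCV, PCV, h2 and GAM are provided as configurable classification schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rcbd_anova import AnovaTable, SignificanceMark, anova_rcbd, cv_percent, lsd
from .trial_data import TrialDataset

__all__ = [
    "VarianceComponents",
    "GeneticSummary",
    "variance_components",
    "variance_components_combined",
    "coefficients_of_variation",
    "heritability_broad",
    "genetic_advance",
    "classify_bands",
    "variability_report",
    "SELECTION_INTENSITY_5PCT",
]

#: Standardized selection differential when the top 5% of a normal
#: distribution is selected.
SELECTION_INTENSITY_5PCT = 2.06


@dataclass(frozen=True)
class VarianceComponents:
    """Moment estimates of the genotypic / environmental / phenotypic variances."""

    sigma2_g: float
    sigma2_e: float
    sigma2_p: float
    r: int
    truncated: bool = False


def variance_components(at: AnovaTable) -> VarianceComponents:
    """sigma2_g = max(0, (MSG - MSE)/r); sigma2_e = MSE; sigma2_p = sum.

    A negative raw estimate (MSG < MSE) is truncated at zero, flagged in
    ``truncated``; heritability and the genetic CV are then zero as well.
    """
    if at.n_replicates < 2:
        raise ValueError("variance components require r >= 2")
    raw = (at.msg - at.mse) / at.n_replicates
    s2g = max(0.0, raw)
    return VarianceComponents(
        sigma2_g=s2g,
        sigma2_e=at.mse,
        sigma2_p=s2g + at.mse,
        r=at.n_replicates,
        truncated=raw < 0,
    )


def variance_components_combined(gxl_table) -> pd.Series:
    """Variance components from the combined genotype x location ANOVA.

    With g genotypes, l locations and r replicates, the expected mean
    squares give the unbiased moment estimators

        sigma2_e  = MS_residual
        sigma2_gl = (MS_GxL - MS_residual) / r
        sigma2_g  = (MS_genotype - MS_GxL) / (r * l)

    each clamped at zero. Returns a Series with keys ``sigma2_g``,
    ``sigma2_gl``, ``sigma2_e`` and ``h2`` (= sigma2_g / (sigma2_g +
    sigma2_e), the genotype-level broad-sense heritability free of the
    interaction confounding a single location suffers).
    """
    rows = gxl_table.rows
    r = gxl_table.n_replicates
    n_loc = gxl_table.n_locations
    mse = float(rows.loc["residual", "MS"])
    ms_gl = float(rows.loc["genotype_x_location", "MS"])
    ms_g = float(rows.loc["genotype", "MS"])
    s2e = mse
    s2gl = max(0.0, (ms_gl - mse) / r)
    s2g = max(0.0, (ms_g - ms_gl) / (r * n_loc))
    h2 = s2g / (s2g + s2e) if (s2g + s2e) > 0 else 0.0
    return pd.Series({"sigma2_g": s2g, "sigma2_gl": s2gl, "sigma2_e": s2e, "h2": h2})


def coefficients_of_variation(
    vc: VarianceComponents, mean: float
) -> tuple[float, float, float]:
    """(GCV, PCV, ECV), each 100 * sqrt(variance) / mean. Requires mean > 0."""
    if not mean > 0:
        raise ValueError("trait mean must be positive")
    gcv = 100.0 * np.sqrt(vc.sigma2_g) / mean
    pcv = 100.0 * np.sqrt(vc.sigma2_p) / mean
    ecv = 100.0 * np.sqrt(vc.sigma2_e) / mean
    return float(gcv), float(pcv), float(ecv)


def heritability_broad(vc: VarianceComponents) -> float:
    """Broad-sense heritability sigma2_g / sigma2_p (0 when sigma2_p = 0)."""
    if vc.sigma2_p <= 0:
        return 0.0
    return float(vc.sigma2_g / vc.sigma2_p)


def genetic_advance(
    vc: VarianceComponents,
    mean: float,
    k: float = SELECTION_INTENSITY_5PCT,
    mode: str = "standard",
    h2_override: float | None = None,
) -> tuple[float, float]:
    """Expected genetic advance (GA) and GA as percent of the mean (GAM).

    ``mode="standard"`` is the textbook GA = K * h2 * sigma_p (phenotypic
    standard deviation). ``mode="variance"`` computes K * h2 * sigma2_p —
    a variant on the variance rather than the SD scale that some published
    trial reports use; ``h2_override`` substitutes a rounded external
    heritability in that product. GAM = 100 * GA / mean in either mode.
    """
    if not mean > 0:
        raise ValueError("trait mean must be positive for GAM")
    h2 = heritability_broad(vc) if h2_override is None else float(h2_override)
    if mode == "standard":
        ga = k * h2 * np.sqrt(vc.sigma2_p)
    elif mode == "variance":
        ga = k * h2 * vc.sigma2_p
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'standard' or 'variance'")
    return float(ga), float(100.0 * ga / mean)


# Band schemes. Convention: a value exactly on a boundary belongs to the
# upper band named by the quoted wording ("10-20% is medium" => [10, 20]
# medium, > 20 high), so intervals are closed on the left.
_BAND_SCHEMES = {
    # GCV / PCV: < 10 low, 10-20 medium, > 20 high.
    "cv": ((10.0, 20.0), ("low", "medium", "high")),
    # heritability, results-style bands (percent): < 40 low, 40-80 medium, > 80 high
    "h2_results": ((40.0, 80.0), ("low", "medium", "high")),
    # heritability, methods-style bands: 0-30 low, 30-60 moderate, > 60 high
    "h2_methods": ((30.0, 60.0), ("low", "moderate", "high")),
    # GAM: < 10 low, 10-20 medium, > 20 high
    "gam": ((10.0, 20.0), ("low", "medium", "high")),
}


def _band(value: float, scheme: str) -> str:
    (lo, hi), names = _BAND_SCHEMES[scheme]
    if value < lo:
        return names[0]
    if value <= hi:
        return names[1]
    return names[2]


def classify_bands(
    gcv: float, h2_percent: float, gam: float, h2_scheme: str = "results"
) -> tuple[str, str, str]:
    """Descriptive (GCV band, h2 band, GAM band) labels.

    ``h2_scheme`` selects the heritability cutpoints: ``"results"``
    (40/80) or ``"methods"`` (30/60); ``h2_percent`` is on the 0-100 scale.
    """
    if h2_scheme not in ("results", "methods"):
        raise ValueError("h2_scheme must be 'results' or 'methods'")
    return (
        _band(gcv, "cv"),
        _band(h2_percent, f"h2_{h2_scheme}"),
        _band(gam, "gam"),
    )


@dataclass
class GeneticSummary:
    """One report row: all genetic parameters of a trait at a location."""

    trait: str
    location: str
    mean: float
    lsd_5pct: float
    cv_pct: float
    sigma2_g: float
    sigma2_p: float
    sigma2_e: float
    gcv: float
    pcv: float
    ecv: float
    h2: float
    ga: float
    gam: float
    bands: tuple[str, str, str]
    significance: SignificanceMark

    def to_dict(self) -> dict:
        d = {
            "trait": self.trait, "location": self.location, "mean": self.mean,
            "LSD": self.lsd_5pct, "CV%": self.cv_pct,
            "sigma2_g": self.sigma2_g, "sigma2_p": self.sigma2_p,
            "sigma2_e": self.sigma2_e, "GCV": self.gcv, "PCV": self.pcv,
            "ECV": self.ecv, "h2": self.h2, "GA": self.ga, "GAM": self.gam,
            "gcv_band": self.bands[0], "h2_band": self.bands[1],
            "gam_band": self.bands[2], "sig": self.significance.mark,
        }
        return d


def summarize_trait(
    ds: TrialDataset,
    trait: str,
    location: str,
    ga_mode: str = "standard",
    h2_scheme: str = "results",
) -> GeneticSummary:
    """Full genetic-parameter row for one (trait, location)."""
    at = anova_rcbd(ds, trait, location)
    vc = variance_components(at)
    gcv, pcv, ecv = coefficients_of_variation(vc, at.trait_mean)
    h2 = heritability_broad(vc)
    ga, gam = genetic_advance(vc, at.trait_mean, mode=ga_mode)
    return GeneticSummary(
        trait=trait, location=location, mean=at.trait_mean,
        lsd_5pct=lsd(at, 0.05), cv_pct=cv_percent(at),
        sigma2_g=vc.sigma2_g, sigma2_p=vc.sigma2_p, sigma2_e=vc.sigma2_e,
        gcv=gcv, pcv=pcv, ecv=ecv, h2=h2, ga=ga, gam=gam,
        bands=classify_bands(gcv, 100.0 * h2, gam, h2_scheme=h2_scheme),
        significance=at.genotype_mark,
    )


def variability_report(
    ds: TrialDataset,
    traits: list[str] | None = None,
    locations: list[str] | None = None,
    ga_mode: str = "standard",
    h2_scheme: str = "results",
) -> pd.DataFrame:
    """Genetic-parameter table over all (location, trait) pairs.

    One row per pair with mean, LSD (5%), CV%, variance components, GCV /
    PCV / ECV, h2, GA, GAM, descriptive bands, and the genotype-effect
    significance star.
    """
    traits = traits or ds.trait_names
    locations = locations or ds.locations
    rows = [
        summarize_trait(ds, t, loc, ga_mode=ga_mode, h2_scheme=h2_scheme).to_dict()
        for loc in locations
        for t in traits
    ]
    return pd.DataFrame(rows)
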