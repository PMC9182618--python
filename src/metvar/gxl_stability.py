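"""Combined genotype x location ANOVA and adaptation indices.

The combined model over locations, y_ijk = mu + g_i + l_j + (gl)_ij + e_ijk,
partitions the total sum of squares into Location, Genotype, Genotype x
Location and Residual strata (replicates within locations are pooled into
the residual). The percent-of-total-SS column reported for each of the
three structural strata uses their own sum as the denominator — the three
percentages sum to 100 by construction, making the relative weight of G,
L and G x L immediately readable.

Simple adaptation indices follow from the two-way table of genotype x
location means:

    Pi (phenotypic index) = genotype mean over locations - grand mean
    Li (locational index) = location mean over genotypes - grand mean

Both are zero-sum. Top performers are flagged per location and overall by
their means; locations are ranked by Li.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import TrialDataset, genotype_location_means

__all__ = [
    "GxLAnovaTable",
    "StabilityReport",
    "combined_anova",
    "pct_total_ss",
    "phenotypic_index",
    "locational_index",
    "stability_report",
    "top_performers",
]


@dataclass
class GxLAnovaTable:
    """Combined ANOVA rows (location, genotype, genotype_x_location, residual,
    total) with df / SS / MS / F / p, plus the %-of-structural-SS column."""

    trait: str
    rows: pd.DataFrame
    n_genotypes: int
    n_locations: int
    n_replicates: int


def combined_anova(
    ds: TrialDataset, trait: str, rep_within_location: bool = False
) -> GxLAnovaTable:
    """Genotype x location ANOVA of one trait over all locations.

    Requires a multi-location balanced dataset (same genotypes and number
    of replicates everywhere). Genotype and interaction mean squares are
    tested against the residual. By default replicates within locations
    are pooled into the residual; ``rep_within_location=True`` adds a
    separate replicate-within-location stratum, which keeps the F tests
    exact when replicate (block) effects are present. The
    ``pct_total_SS`` column covers the three structural rows and sums
    to 100.
    """
    ds.require_trait(trait)
    if len(ds.locations) < 2:
        raise ValueError("combined ANOVA needs at least two locations")

    # genotype x location x replicate array; errors on imbalance
    counts = ds.data.pivot_table(index="genotype", columns="location",
                                 values=trait, aggfunc="count", sort=False)
    arr_counts = counts.fillna(0).to_numpy()
    r_set = np.unique(arr_counts)
    if len(r_set) != 1 or r_set[0] < 1:
        raise ValueError("dataset is not multi-location balanced for this trait")
    r = int(r_set[0])
    if np.isnan(ds.data[trait].to_numpy(dtype=float)).any():
        raise ValueError(f"missing values for trait {trait!r}")

    g, l = len(ds.genotypes), len(ds.locations)
    cell = genotype_location_means(ds, trait).to_numpy(dtype=float)  # g x l
    grand = float(ds.data[trait].mean())
    gmeans = cell.mean(axis=1)
    lmeans = cell.mean(axis=0)

    ss_total = float(((ds.data[trait].to_numpy(dtype=float) - grand) ** 2).sum())
    ss_loc = float(g * r * ((lmeans - grand) ** 2).sum())
    ss_gen = float(l * r * ((gmeans - grand) ** 2).sum())
    ss_gl = float(
        r * ((cell - gmeans[:, None] - lmeans[None, :] + grand) ** 2).sum()
    )
    ss_res = max(0.0, ss_total - ss_loc - ss_gen - ss_gl)

    df_loc, df_gen = l - 1, g - 1
    df_gl = df_loc * df_gen
    df_res = g * l * (r - 1)
    ss_rep, df_rep = 0.0, 0
    if rep_within_location:
        # block stratum: per-location replicate means about the location mean
        rep_means = ds.data.pivot_table(index="location", columns="replicate",
                                        values=trait, aggfunc="mean", sort=False)
        rep_means = rep_means.reindex(ds.locations)
        dev = rep_means.to_numpy(dtype=float) - lmeans[:, None]
        ss_rep = float(g * (dev ** 2).sum())
        df_rep = l * (r - 1)
        ss_res = max(0.0, ss_res - ss_rep)
        df_res -= df_rep
    if df_res < 1:
        raise ValueError("single replicate: no residual degrees of freedom")
    ms = np.array([ss_loc / df_loc, ss_gen / df_gen, ss_gl / df_gl, ss_res / df_res])
    mse = ms[3]

    def ftest(msx, dfx):
        if mse <= 0:
            return np.nan, np.nan
        f = msx / mse
        return f, float(stats.f.sf(f, dfx, df_res))

    f_loc, p_loc = ftest(ms[0], df_loc)
    f_gen, p_gen = ftest(ms[1], df_gen)
    f_gl, p_gl = ftest(ms[2], df_gl)

    structural = ss_loc + ss_gen + ss_gl
    pct = [100.0 * s / structural if structural > 0 else np.nan
           for s in (ss_loc, ss_gen, ss_gl)]

    index = ["location", "genotype", "genotype_x_location", "residual", "total"]
    data = {
        "df": [df_loc, df_gen, df_gl, df_res, g * l * r - 1],
        "SS": [ss_loc, ss_gen, ss_gl, ss_res, ss_total],
        "MS": [*ms, np.nan],
        "F": [f_loc, f_gen, f_gl, np.nan, np.nan],
        "p": [p_loc, p_gen, p_gl, np.nan, np.nan],
        "pct_total_SS": [*pct, np.nan, np.nan],
    }
    if rep_within_location:
        index.insert(3, "replicate_within_location")
        for key, val in [("df", df_rep), ("SS", ss_rep),
                         ("MS", ss_rep / df_rep if df_rep else np.nan),
                         ("F", np.nan), ("p", np.nan),
                         ("pct_total_SS", np.nan)]:
            data[key].insert(3, val)
    rows = pd.DataFrame(data, index=pd.Index(index, name="source"))
    return GxLAnovaTable(trait=trait, rows=rows, n_genotypes=g,
                         n_locations=l, n_replicates=r)


def pct_total_ss(ss_location: float, ss_genotype: float, ss_gxl: float) -> tuple[float, float, float]:
    """Percent of structural SS for the three non-residual strata.

    The denominator is the sum of the three structural sums of squares, so
    the result sums to 100. Useful to reproduce the percentage column of a
    published combined-ANOVA table directly from its printed SS.
    """
    total = ss_location + ss_genotype + ss_gxl
    if total <= 0:
        raise ValueError("structural SS must be positive")
    return tuple(100.0 * s / total for s in (ss_location, ss_genotype, ss_gxl))


def _means_table(source, trait: str | None) -> pd.DataFrame:
    if isinstance(source, TrialDataset):
        if trait is None:
            raise ValueError("trait required when passing a TrialDataset")
        return genotype_location_means(source, trait)
    tab = pd.DataFrame(source).astype(float)
    return tab


def phenotypic_index(source, trait: str | None = None) -> pd.Series:
    """Pi per genotype: across-location genotype mean minus grand mean.

    ``source`` is a TrialDataset (with ``trait``) or a genotype x location
    means table. The grand mean is the mean of the genotype means, so Pi
    sums to zero exactly.
    """
    tab = _means_table(source, trait)
    gmeans = tab.mean(axis=1)
    return gmeans - gmeans.mean()


def locational_index(source, trait: str | None = None) -> pd.Series:
    """Li per location: location mean over genotypes minus grand mean."""
    tab = _means_table(source, trait)
    lmeans = tab.mean(axis=0)
    return lmeans - tab.to_numpy().mean()


@dataclass
class StabilityReport:
    """Genotype x location means with Pi / Li indices and top-k flags."""

    table: pd.DataFrame            # genotype rows: location means, mean, Pi, top flags
    location_summary: pd.DataFrame  # location rows: mean, Li, rank
    grand_mean: float
    k: int


def top_performers(means: pd.Series, k: int = 5) -> list:
    """Labels of the k largest entries; ties broken by original order."""
    if k > len(means):
        raise ValueError("k exceeds the number of entries")
    order = np.argsort(-means.to_numpy(), kind="stable")
    return [means.index[i] for i in order[:k]]


def stability_report(source, trait: str | None = None, k: int = 5) -> StabilityReport:
    """Adaptation summary from a genotype x location means table.

    Per genotype: the location means, across-location mean, Pi, and top-k
    membership per location and overall. Per location: mean, Li, and rank
    by Li (1 = best). ``source`` as in :func:`phenotypic_index`.
    """
    tab = _means_table(source, trait)
    overall = tab.mean(axis=1)
    pi = overall - overall.mean()
    li = locational_index(tab)
    grand = float(overall.mean())

    out = tab.copy()
    out["mean"] = overall
    out["Pi"] = pi
    top_overall = set(top_performers(overall, k))
    out["top_overall"] = [g in top_overall for g in out.index]
    for loc in tab.columns:
        top_loc = set(top_performers(tab[loc], k))
        out[f"top_{loc}"] = [g in top_loc for g in out.index]

    loc_sum = pd.DataFrame({"mean": tab.mean(axis=0), "Li": li})
    loc_sum["rank"] = loc_sum["Li"].rank(ascending=False, method="first").astype(int)
    return StabilityReport(table=out, location_summary=loc_sum,
                           grand_mean=grand, k=k)
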