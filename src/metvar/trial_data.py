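"""Data model and delimited-text I/O for plot-level multi-location RCBD trials.

A multi-environment trial (MET) evaluates a common set of genotypes at several
locations, each laid out as a randomized complete block design (RCBD): every
genotype appears exactly once in every replicate (block) within a location.
The :class:`TrialDataset` holds one row per plot with the location, replicate
and genotype labels plus one numeric column per measured trait; everything
downstream (ANOVA, variance components, correlations, diversity, stability)
consumes this container.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "TrialDataset",
    "DesignSummary",
    "SchemaError",
    "DesignError",
    "STANDARD_MAIZE_TRAITS",
    "read_trial_table",
    "write_trial_table",
    "validate_design",
    "genotype_means",
]

#: Mandatory design columns, in canonical order.
DESIGN_COLUMNS = ("location", "replicate", "genotype")


class SchemaError(ValueError):
    """Input table does not have the required columns or types."""


class DesignError(ValueError):
    """Plot layout violates the RCBD structure (duplicates, missing cells)."""


@dataclass(frozen=True)
class TraitSpec:
    """Description of one measured trait.

    Parameters
    ----------
    name : str
        Short column identifier, e.g. ``"GY"``.
    label : str
        Human-readable name, e.g. ``"grain yield"``.
    units : str
        Measurement units, e.g. ``"t/ha"``.
    nonnegative : bool
        Whether negative values are physically impossible for this trait.
    """

    name: str
    label: str = ""
    units: str = ""
    nonnegative: bool = False


#: The eight standard maize yield / yield-component traits: flowering dates
#: (days to anthesis and silking and their interval), architecture (plant and
#: ear height) and yield components (kernels per ear, thousand-kernel weight,
#: grain yield).
STANDARD_MAIZE_TRAITS: tuple[TraitSpec, ...] = (
    TraitSpec("AD", "days to anthesis", "days", nonnegative=True),
    TraitSpec("SD", "days to silking", "days", nonnegative=True),
    TraitSpec("ASI", "anthesis-silking interval", "days"),
    TraitSpec("PH", "plant height", "cm", nonnegative=True),
    TraitSpec("EH", "ear height", "cm", nonnegative=True),
    TraitSpec("KPE", "kernels per ear", "count", nonnegative=True),
    TraitSpec("TKW", "thousand-kernel weight", "g", nonnegative=True),
    TraitSpec("GY", "grain yield", "t/ha", nonnegative=True),
)


@dataclass(frozen=True)
class DesignSummary:
    """Counts and balance diagnosis for a trial layout."""

    n_genotypes: int
    n_replicates: int
    n_locations: int
    n_plots: int
    balanced: bool
    missing_cells: tuple[tuple[str, str, str], ...] = ()

    def to_dict(self) -> dict:
        return {
            "n_genotypes": self.n_genotypes,
            "n_replicates": self.n_replicates,
            "n_locations": self.n_locations,
            "n_plots": self.n_plots,
            "balanced": self.balanced,
            "missing_cells": [list(c) for c in self.missing_cells],
        }


@dataclass
class TrialDataset:
    """Plot-level observations of a multi-location RCBD trial.

    Attributes
    ----------
    data : pandas.DataFrame
        One row per plot; columns ``location``, ``replicate``, ``genotype``
        (strings) plus one float column per trait. Row order is preserved
        from the source.
    traits : tuple of TraitSpec
        Trait metadata, in column order.
    provenance : str
        Free-text note on where the data came from.
    """

    data: pd.DataFrame
    traits: tuple[TraitSpec, ...] = ()
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        if not self.traits:
            inferred = [c for c in self.data.columns if c not in DESIGN_COLUMNS]
            self.traits = tuple(TraitSpec(name) for name in inferred)
        names = [t.name for t in self.traits]
        if len(names) != len(set(names)):
            raise SchemaError("trait names must be unique")
        if not names:
            raise SchemaError("at least one trait column is required")
        absent = [n for n in names if n not in self.data.columns]
        if absent:
            raise SchemaError(f"trait column(s) not in table: {', '.join(absent)}")

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def locations(self) -> list[str]:
        """Location labels in order of first appearance."""
        return list(dict.fromkeys(self.data["location"]))

    @property
    def genotypes(self) -> list[str]:
        """Genotype labels in order of first appearance."""
        return list(dict.fromkeys(self.data["genotype"]))

    @property
    def replicates(self) -> list[str]:
        return list(dict.fromkeys(self.data["replicate"]))

    def subset_location(self, location: str) -> pd.DataFrame:
        sub = self.data[self.data["location"] == location]
        if sub.empty:
            raise KeyError(f"unknown location: {location!r}")
        return sub

    def require_trait(self, trait: str) -> None:
        if trait not in self.trait_names:
            raise KeyError(f"unknown trait: {trait!r}")

    def with_data(self, data: pd.DataFrame) -> "TrialDataset":
        return replace(self, data=data)


def _coerce_trait_columns(df: pd.DataFrame, trait_cols: list[str], path: str) -> pd.DataFrame:
    df = df.copy()
    for col in trait_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in trait column "
                f"{col!r} at data row {row + 1}"
            )
        df[col] = coerced.astype(float)
    return df


def read_trial_table(
    path,
    sep: str | None = None,
    traits: tuple[TraitSpec, ...] = (),
) -> TrialDataset:
    """Read a delimited plot-level trial table.

    The header must name ``location``, ``replicate`` and ``genotype`` plus at
    least one trait column. The delimiter is auto-detected (comma or tab)
    unless ``sep`` is given. Decimal separator is always the point.

    Raises
    ------
    SchemaError
        Missing mandatory column or a non-numeric trait cell.
    DesignError
        A (location, genotype, replicate) plot key occurs more than once.
    """
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        dtype=str,
        skipinitialspace=True,
    )
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    for col in DESIGN_COLUMNS:
        df[col] = df[col].astype(str).str.strip()
    trait_cols = [t.name for t in traits] if traits else [
        c for c in df.columns if c not in DESIGN_COLUMNS
    ]
    df = _coerce_trait_columns(df, trait_cols, str(path))
    dup = df.duplicated(subset=list(DESIGN_COLUMNS), keep=False)
    if dup.any():
        keys = (
            df.loc[dup, list(DESIGN_COLUMNS)]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise DesignError(f"{path}: duplicated plot key(s): {sorted(keys)}")
    ds = TrialDataset(df[list(DESIGN_COLUMNS) + trait_cols], traits=traits,
                      provenance=str(path))
    return ds


def write_trial_table(ds: TrialDataset, path, sep: str = ",") -> None:
    """Write the dataset back to delimited text, preserving full precision."""
    cols = list(DESIGN_COLUMNS) + ds.trait_names
    ds.data[cols].to_csv(path, sep=sep, index=False)


def to_csv_string(ds: TrialDataset) -> str:
    buf = io.StringIO()
    write_trial_table(ds, buf)
    return buf.getvalue()


def validate_design(ds: TrialDataset) -> DesignSummary:
    """Diagnose balance of the RCBD layout without mutating the dataset.

    A balanced MET has every (genotype, replicate) cell present exactly once
    in every location, with identical genotype and replicate label sets across
    locations. Trait values are not inspected (missing values are a separate
    policy, handled by the analysis operations).
    """
    df = ds.data
    genotypes = ds.genotypes
    replicates = ds.replicates
    locations = ds.locations
    n_plots = len(df)
    expected = len(genotypes) * len(replicates) * len(locations)

    present = set(zip(df["location"], df["genotype"], df["replicate"]))
    missing = [
        (loc, g, r)
        for loc in locations
        for g in genotypes
        for r in replicates
        if (loc, g, r) not in present
    ]
    balanced = not missing and n_plots == expected and len(present) == n_plots
    return DesignSummary(
        n_genotypes=len(genotypes),
        n_replicates=len(replicates),
        n_locations=len(locations),
        n_plots=n_plots,
        balanced=bool(balanced),
        missing_cells=tuple(missing),
    )


def genotype_means(
    ds: TrialDataset, trait: str, location: str | None = None
) -> pd.Series:
    """Arithmetic genotype means for one trait.

    With ``location`` given, means are over the replicates at that location;
    otherwise over all plots across locations (requires a multi-location
    balanced dataset for the across-location mean to be design-unbiased).
    Ordering follows first appearance of each genotype.
    """
    ds.require_trait(trait)
    df = ds.subset_location(location) if location is not None else ds.data
    if df.empty:
        raise ValueError("no observations in scope")
    means = df.groupby("genotype", sort=False)[trait].mean()
    return means.reindex([g for g in ds.genotypes if g in means.index])


def location_means(ds: TrialDataset, trait: str) -> pd.Series:
    """Per-location means of one trait, in location appearance order."""
    ds.require_trait(trait)
    means = ds.data.groupby("location", sort=False)[trait].mean()
    return means.reindex(ds.locations)


def grand_mean(ds: TrialDataset, trait: str) -> float:
    ds.require_trait(trait)
    return float(ds.data[trait].mean())


def genotype_location_means(ds: TrialDataset, trait: str) -> pd.DataFrame:
    """Genotype x location table of cell means (rows: genotypes in order)."""
    ds.require_trait(trait)
    tab = ds.data.pivot_table(
        index="genotype", columns="location", values=trait, aggfunc="mean",
        sort=False,
    )
    return tab.reindex(index=ds.genotypes, columns=ds.locations)
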