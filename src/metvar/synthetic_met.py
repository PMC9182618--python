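"""Simulation of balanced multi-trait RCBD multi-environment trials.

The generator realises the additive two-way model with replication

    y_ijkt = mu_t + g_it + l_jt + (gl)_ijt + r_jkt + e_ijkt

for genotype i, location j, replicate k and trait t, where genotype effects
g_i are multivariate normal with a configurable genetic covariance matrix,
location effects are fixed per-location offsets, genotype-by-location
interaction and replicate-within-location effects are independent normals
with per-trait variances, and plot residuals are multivariate normal with a
residual covariance matrix. All draws derive from one seed in a fixed order
(genotype, interaction, replicate, residual) so a (config, seed) pair
reproduces the dataset bit for bit.

Ground truth (the realised effects and the generating variances) is returned
alongside the dataset so estimator bias and RMSE can be measured directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trial_data import TraitSpec, TrialDataset

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_met", "recovery_report"]


class ConfigError(ValueError):
    """Simulation configuration is invalid."""


def _as_cov(mat, k: int, name: str) -> np.ndarray:
    a = np.atleast_2d(np.asarray(mat, dtype=float))
    if a.shape != (k, k):
        raise ConfigError(f"{name} must be {k}x{k}, got {a.shape}")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ConfigError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(a)
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise ConfigError(f"{name} must be positive semi-definite")
    return a


def _psd_chol(a: np.ndarray) -> np.ndarray:
    # Cholesky with a PSD-safe fallback through the eigendecomposition.
    try:
        return np.linalg.cholesky(a)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(a)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


@dataclass
class SimulationConfig:
    """Generating parameters for one balanced MET.

    Defaults mirror a three-station maize hybrid trial: 45 genotypes x
    3 locations x 3 replicates with the eight standard traits absent —
    the default instance carries a single generic trait; pass ``traits``
    and matching matrices for multivariate runs.

    Parameters
    ----------
    n_genotypes, n_replicates : int
        Design size; both must be >= 1 (>= 2 replicates for any ANOVA).
    locations : tuple of str
        Location labels; their number sets the third design dimension.
    traits : tuple of TraitSpec
        Traits simulated; dimensions of ``mu``, ``sigma_g``, ``sigma_e``,
        ``sigma_gl`` and ``sigma_rep`` must match.
    mu : array, shape (t,)
        Per-trait grand means.
    sigma_g, sigma_e : array, shape (t, t)
        Genetic and plot-residual covariance matrices (symmetric PSD).
    sigma_gl, sigma_rep : array, shape (t,)
        Per-trait genotype-by-location and replicate-within-location
        variances (elementwise >= 0).
    location_offsets : array, shape (locations, t), optional
        Fixed per-location trait offsets (default all zero). Fixed offsets,
        rather than random draws, keep locational indices exactly
        recoverable.
    seed : int
        Master seed for all randomness.
    """

    n_genotypes: int = 45
    locations: tuple[str, ...] = ("Barishal", "Ishwardi", "Jashore")
    n_replicates: int = 3
    traits: tuple[TraitSpec, ...] = (TraitSpec("Y", "simulated trait"),)
    mu: tuple[float, ...] | np.ndarray = (10.0,)
    sigma_g: object = ((4.0,),)
    sigma_e: object = ((2.0,),)
    sigma_gl: tuple[float, ...] | np.ndarray = (1.0,)
    sigma_rep: tuple[float, ...] | np.ndarray = (0.0,)
    location_offsets: object = None
    seed: int = 0

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    def validated(self) -> dict:
        t = self.n_traits
        if t == 0:
            raise ConfigError("at least one trait required")
        if self.n_genotypes < 1 or self.n_replicates < 1 or self.n_locations < 1:
            raise ConfigError("design dimensions must be >= 1")
        mu = np.asarray(self.mu, dtype=float).reshape(-1)
        if mu.size != t:
            raise ConfigError(f"mu must have {t} entries")
        sg = _as_cov(self.sigma_g, t, "sigma_g")
        se = _as_cov(self.sigma_e, t, "sigma_e")
        sgl = np.asarray(self.sigma_gl, dtype=float).reshape(-1)
        srep = np.asarray(self.sigma_rep, dtype=float).reshape(-1)
        if sgl.size != t or srep.size != t:
            raise ConfigError("sigma_gl and sigma_rep must be per-trait vectors")
        if (sgl < 0).any() or (srep < 0).any():
            raise ConfigError("sigma_gl and sigma_rep must be >= 0")
        if self.location_offsets is None:
            offs = np.zeros((self.n_locations, t))
        else:
            offs = np.asarray(self.location_offsets, dtype=float)
            if offs.shape != (self.n_locations, t):
                raise ConfigError(
                    f"location_offsets must be {(self.n_locations, t)}"
                )
        return {"mu": mu, "sigma_g": sg, "sigma_e": se, "sigma_gl": sgl,
                "sigma_rep": srep, "offsets": offs}


@dataclass
class SimulationTruth:
    """Realised effects and generating parameters of one simulated MET."""

    config: SimulationConfig
    genotype_effects: pd.DataFrame          # genotype x trait
    location_offsets: pd.DataFrame          # location x trait
    interaction_effects: pd.DataFrame       # (genotype, location) x trait
    replicate_effects: pd.DataFrame         # (location, replicate) x trait
    sigma2_g: pd.Series                     # per-trait generating variances
    sigma2_e: pd.Series
    sigma2_gl: pd.Series
    genetic_correlation: pd.DataFrame       # from sigma_g
    h2: pd.Series                           # sigma2_g / (sigma2_g + sigma2_e)


def simulate_met(cfg: SimulationConfig) -> tuple[TrialDataset, SimulationTruth]:
    """Draw one balanced MET dataset plus its ground truth.

    Plot values follow the additive model in the module docstring; the draw
    order (genotype, interaction, replicate, residual) is fixed, so edits to
    later stages of the config do not perturb earlier effect draws of the
    same seed. Standard-normal draws are scaled through Cholesky factors, so
    scaling ``mu`` and all standard deviations by a constant scales every
    plot value by that constant for a matched seed.
    """
    p = cfg.validated()
    g, l, r, t = cfg.n_genotypes, cfg.n_locations, cfg.n_replicates, cfg.n_traits
    trait_names = [ts.name for ts in cfg.traits]
    geno_labels = [f"G{i + 1}" for i in range(g)]
    rep_labels = [f"R{k + 1}" for k in range(r)]

    rng = np.random.default_rng(cfg.seed)
    geno = rng.standard_normal((g, t)) @ _psd_chol(p["sigma_g"]).T
    inter = rng.standard_normal((g, l, t)) * np.sqrt(p["sigma_gl"])
    rep = rng.standard_normal((l, r, t)) * np.sqrt(p["sigma_rep"])
    resid = rng.standard_normal((g, l, r, t)) @ _psd_chol(p["sigma_e"]).T

    values = (
        p["mu"][None, None, None, :]
        + geno[:, None, None, :]
        + p["offsets"][None, :, None, :]
        + inter[:, :, None, :]
        + rep[None, :, :, :]
        + resid
    )

    rows = []
    for j, loc in enumerate(cfg.locations):
        for k, rl in enumerate(rep_labels):
            for i, gl_ in enumerate(geno_labels):
                rows.append((loc, rl, gl_, *values[i, j, k, :]))
    df = pd.DataFrame(rows, columns=["location", "replicate", "genotype", *trait_names])
    ds = TrialDataset(df, traits=cfg.traits, provenance=f"simulate_met(seed={cfg.seed})")

    sd_g = np.sqrt(np.diag(p["sigma_g"]))
    with np.errstate(invalid="ignore", divide="ignore"):
        gcor = p["sigma_g"] / np.outer(sd_g, sd_g)
    sigma2_g = pd.Series(np.diag(p["sigma_g"]), index=trait_names)
    sigma2_e = pd.Series(np.diag(p["sigma_e"]), index=trait_names)
    truth = SimulationTruth(
        config=cfg,
        genotype_effects=pd.DataFrame(geno, index=geno_labels, columns=trait_names),
        location_offsets=pd.DataFrame(p["offsets"], index=list(cfg.locations),
                                      columns=trait_names),
        interaction_effects=pd.DataFrame(
            inter.reshape(g * l, t),
            index=pd.MultiIndex.from_product([geno_labels, list(cfg.locations)],
                                             names=["genotype", "location"]),
            columns=trait_names,
        ),
        replicate_effects=pd.DataFrame(
            rep.reshape(l * r, t),
            index=pd.MultiIndex.from_product([list(cfg.locations), rep_labels],
                                             names=["location", "replicate"]),
            columns=trait_names,
        ),
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        sigma2_gl=pd.Series(p["sigma_gl"], index=trait_names),
        genetic_correlation=pd.DataFrame(gcor, index=trait_names, columns=trait_names),
        h2=sigma2_g / (sigma2_g + sigma2_e),
    )
    return ds, truth


def recovery_report(truth: SimulationTruth, estimates: pd.DataFrame) -> pd.DataFrame:
    """Bias and RMSE of variance-parameter estimates against ground truth.

    Parameters
    ----------
    truth : SimulationTruth
        Generating truth (any replicate's truth carries the same parameters
        when only the seed varies).
    estimates : pandas.DataFrame
        Tidy table with columns ``trait``, ``parameter`` (one of
        ``sigma2_g``, ``sigma2_e``, ``sigma2_gl``, ``h2``) and ``estimate``;
        one row per replicate per parameter.

    Returns
    -------
    pandas.DataFrame
        One row per (trait, parameter) with truth, mean estimate, bias,
        relative bias and RMSE over replicates.
    """
    required = {"trait", "parameter", "estimate"}
    if not required.issubset(estimates.columns):
        raise ValueError(f"estimates needs columns {sorted(required)}")
    truth_lookup = {
        "sigma2_g": truth.sigma2_g, "sigma2_e": truth.sigma2_e,
        "sigma2_gl": truth.sigma2_gl, "h2": truth.h2,
    }
    out = []
    for (trait, param), grp in estimates.groupby(["trait", "parameter"], sort=False):
        if param not in truth_lookup:
            raise ValueError(f"unknown parameter {param!r}")
        if trait not in truth_lookup[param].index:
            raise ValueError(f"trait {trait!r} not present in the simulation truth")
        tv = float(truth_lookup[param][trait])
        est = grp["estimate"].to_numpy(dtype=float)
        bias = float(est.mean() - tv)
        out.append({
            "trait": trait,
            "parameter": param,
            "truth": tv,
            "mean_estimate": float(est.mean()),
            "bias": bias,
            "relative_bias": bias / tv if tv != 0 else np.nan,
            "rmse": float(np.sqrt(np.mean((est - tv) ** 2))),
            "n_replicates": len(est),
        })
    return pd.DataFrame(out)
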