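"""Shared fixtures and independent oracles for the test suite.

The ANOVA oracles recompute sums of squares by explicit effect-mean
subtraction over plots — a deliberately different code path from the
library's scaled-marginal-mean formulas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metvar.trial_data import TraitSpec, TrialDataset


def make_dataset(values: np.ndarray, location: str = "L1",
                 trait: str = "Y") -> TrialDataset:
    """Single-location dataset from a genotype x replicate value matrix."""
    g, r = values.shape
    rows = [
        (location, f"R{j + 1}", f"G{i + 1}", float(values[i, j]))
        for i in range(g)
        for j in range(r)
    ]
    df = pd.DataFrame(rows, columns=["location", "replicate", "genotype", trait])
    return TrialDataset(df, traits=(TraitSpec(trait),))


def make_multilocation_dataset(values: np.ndarray, trait: str = "Y") -> TrialDataset:
    """Dataset from a genotype x location x replicate array."""
    g, l, r = values.shape
    rows = [
        (f"L{j + 1}", f"R{k + 1}", f"G{i + 1}", float(values[i, j, k]))
        for j in range(l)
        for k in range(r)
        for i in range(g)
    ]
    df = pd.DataFrame(rows, columns=["location", "replicate", "genotype", trait])
    return TrialDataset(df, traits=(TraitSpec(trait),))


def rcbd_oracle(y: np.ndarray) -> dict:
    """Two-way RCBD sums of squares by plot-wise effect-mean subtraction."""
    grand = y.mean()
    gi = np.broadcast_to(y.mean(axis=1, keepdims=True), y.shape)
    rj = np.broadcast_to(y.mean(axis=0, keepdims=True), y.shape)
    resid = y - gi - rj + grand
    return {
        "SS_gen": float(((gi - grand) ** 2).sum()),
        "SS_rep": float(((rj - grand) ** 2).sum()),
        "SS_err": float((resid ** 2).sum()),
        "SS_total": float(((y - grand) ** 2).sum()),
    }


def combined_oracle(y: np.ndarray) -> dict:
    """Combined G x L sums of squares by plot-wise effect-mean subtraction.

    ``y`` has shape (genotype, location, replicate).
    """
    grand = y.mean()
    cell = y.mean(axis=2)
    gm = y.mean(axis=(1, 2))
    lm = y.mean(axis=(0, 2))
    r = y.shape[2]
    ss_loc = float(sum((lm[j] - grand) ** 2 for j in range(y.shape[1]))
                   * y.shape[0] * r)
    ss_gen = float(sum((gm[i] - grand) ** 2 for i in range(y.shape[0]))
                   * y.shape[1] * r)
    ss_gl = float(
        r * ((cell - gm[:, None] - lm[None, :] + grand) ** 2).sum()
    )
    ss_res = float(((y - cell[:, :, None]) ** 2).sum())
    return {"SS_loc": ss_loc, "SS_gen": ss_gen, "SS_gl": ss_gl,
            "SS_res": ss_res,
            "SS_total": float(((y - grand) ** 2).sum())}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
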