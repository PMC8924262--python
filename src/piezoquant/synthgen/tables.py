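"""Per-cell responder and neurite tables.

Generates the tabular inputs of the statistics stage: for each experimental
group, a Bernoulli responder flag per recorded cell (feeding 2x2 exact
tests) and a neurite record per imaged cell — neurite-bearing flag, number
of neurites (1 + Poisson for bearing cells) and longest neurite length
(log-normal, µm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..exceptions import InvalidParameterError


@dataclass(frozen=True)
class GroupSpec:
    """Generative spec of one cell group.

    lognorm_mu / lognorm_sigma are the parameters of log(longest neurite µm);
    poisson_lam is the mean number of additional neurites beyond the first on
    neurite-bearing cells.
    """

    name: str
    n_cells: int
    responder_p: float = 0.2
    neurite_bearing_p: float = 0.5
    lognorm_mu: float = 2.5
    lognorm_sigma: float = 0.6
    poisson_lam: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")
        for p in (self.responder_p, self.neurite_bearing_p):
            if not (0.0 <= p <= 1.0) or not math.isfinite(p):
                raise InvalidParameterError(f"probability {p} outside [0, 1]")
        if self.poisson_lam < 0:
            raise InvalidParameterError("poisson_lam must be >= 0")


def simulate_cell_tables(
    groups: list[GroupSpec], seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-cell tables for a set of groups.

    Returns
    -------
    responder_counts : DataFrame
        One row per group: ``group, n_cells, n_responders``.
    neurite_table : DataFrame
        One row per cell: ``group, cell_id, responder, neurite_bearing,
        n_neurites, longest_neurite``.  ``neurite_bearing`` is equivalent to
        ``n_neurites >= 1``; non-bearing cells have longest_neurite = 0.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    counts = []
    for spec in groups:
        responders = rng.random(spec.n_cells) < spec.responder_p
        bearing = rng.random(spec.n_cells) < spec.neurite_bearing_p
        n_neurites = np.where(
            bearing, 1 + rng.poisson(spec.poisson_lam, size=spec.n_cells), 0
        )
        longest = np.where(
            bearing,
            rng.lognormal(spec.lognorm_mu, spec.lognorm_sigma, size=spec.n_cells),
            0.0,
        )
        counts.append(
            {
                "group": spec.name,
                "n_cells": spec.n_cells,
                "n_responders": int(responders.sum()),
            }
        )
        rows.append(
            pd.DataFrame(
                {
                    "group": spec.name,
                    "cell_id": np.arange(spec.n_cells),
                    "responder": responders,
                    "neurite_bearing": bearing,
                    "n_neurites": n_neurites,
                    "longest_neurite": longest,
                }
            )
        )
    return pd.DataFrame(counts), pd.concat(rows, ignore_index=True)
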