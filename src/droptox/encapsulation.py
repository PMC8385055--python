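"""Two-species Poisson co-encapsulation statistics.

When a cell suspension is emulsified into picoliter droplets, the number of
cells per droplet is Poisson distributed with mean

    lambda = concentration x dilution_factor x droplet_volume

(the dilution factor accounts for the fraction of the droplet volume
contributed by that cell stream; with two aqueous inlets at equal flow each
stream fills half the droplet).  Effector (e.g. NK) and target (e.g. K562)
cells are loaded from independent inlets, so their per-droplet counts are
independent Poissons and the joint occupancy pmf factorises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EncapsulationParams",
    "OccupancyClass",
    "lambda_from_concentration",
    "occupancy_pmf",
    "simulate_encapsulation",
    "compare_observed_predicted",
]

#: picoliters per milliliter
_PL_PER_ML = 1e9


def lambda_from_concentration(
    conc: float, droplet_volume_pl: float, dilution_factor: float = 0.5
) -> float:
    """Expected cells per droplet for one cell stream.

    Parameters
    ----------
    conc : float
        Cell concentration in the loaded suspension, cells per mL.
    droplet_volume_pl : float
        Droplet volume in picoliters.
    dilution_factor : float
        Fraction of the droplet volume contributed by this stream, in (0, 1].

    Returns
    -------
    float
        Poisson mean ``conc * dilution_factor * droplet_volume`` (unit
        consistent: 1 mL = 1e9 pL).
    """
    if conc <= 0:
        raise ValueError(f"concentration must be positive, got {conc}")
    if droplet_volume_pl <= 0:
        raise ValueError(f"droplet volume must be positive, got {droplet_volume_pl}")
    if not 0 < dilution_factor <= 1:
        raise ValueError(f"dilution_factor must be in (0, 1], got {dilution_factor}")
    return conc / _PL_PER_ML * dilution_factor * droplet_volume_pl


@dataclass(frozen=True)
class EncapsulationParams:
    """Loading parameters of a two-inlet droplet experiment.

    Defaults are the platform's standard conditions: 7e6 effector cells/mL
    and 10e6 target cells/mL co-flowed at equal rates (dilution 0.5) into
    ~70 pL droplets.
    """

    conc_effector: float = 7e6
    conc_target: float = 10e6
    droplet_volume_pl: float = 70.0
    dilution_factor: float = 0.5
    lambda_effector: float = field(init=False)
    lambda_target: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "lambda_effector",
            lambda_from_concentration(
                self.conc_effector, self.droplet_volume_pl, self.dilution_factor
            ),
        )
        object.__setattr__(
            self,
            "lambda_target",
            lambda_from_concentration(
                self.conc_target, self.droplet_volume_pl, self.dilution_factor
            ),
        )


@dataclass(frozen=True, order=True)
class OccupancyClass:
    """A droplet's (k_effector, k_target) cell-count pair, e.g. E:T 1:1."""

    k_effector: int
    k_target: int

    def __post_init__(self) -> None:
        if self.k_effector < 0 or self.k_target < 0:
            raise ValueError(f"occupancy counts must be non-negative, got {self}")

    @property
    def label(self) -> str:
        return f"E:T {self.k_effector}:{self.k_target}"


def occupancy_pmf(params: EncapsulationParams, k: OccupancyClass | tuple[int, int]) -> float:
    """Probability a droplet holds exactly ``k_effector`` effectors and
    ``k_target`` targets, assuming independent Poisson loading per species."""
    if not isinstance(k, OccupancyClass):
        k = OccupancyClass(*k)
    return float(
        stats.poisson.pmf(k.k_effector, params.lambda_effector)
        * stats.poisson.pmf(k.k_target, params.lambda_target)
    )


def simulate_encapsulation(
    params: EncapsulationParams, n_droplets: int, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Monte-Carlo twin of :func:`occupancy_pmf`.

    Draws independent per-droplet Poisson counts for each species and
    tabulates occupancy classes.

    Returns
    -------
    pandas.DataFrame
        Columns ``k_effector, k_target, observed_n, observed_frac`` with one
        row per occupancy class seen, sorted by class.
    """
    if n_droplets < 1:
        raise ValueError(f"n_droplets must be >= 1, got {n_droplets}")
    rng = np.random.default_rng(seed)
    k_e = rng.poisson(params.lambda_effector, n_droplets)
    k_t = rng.poisson(params.lambda_target, n_droplets)
    table = (
        pd.DataFrame({"k_effector": k_e, "k_target": k_t})
        .value_counts()
        .rename("observed_n")
        .reset_index()
        .sort_values(["k_effector", "k_target"], ignore_index=True)
    )
    table["observed_frac"] = table["observed_n"] / n_droplets
    return table


def compare_observed_predicted(
    observed: pd.DataFrame, params: EncapsulationParams
) -> pd.DataFrame:
    """Per-class comparison of an observed occupancy table with the Poisson
    prediction.

    Parameters
    ----------
    observed : pandas.DataFrame
        Columns ``k_effector, k_target, observed_n`` (as produced by
        :func:`simulate_encapsulation` or a droplet census).
    params : EncapsulationParams

    Returns
    -------
    pandas.DataFrame
        Columns ``k_effector, k_target, observed_n, observed_frac,
        predicted_frac, abs_dev, rel_dev``.  The function reports deviations
        as they are; observed loading commonly falls below the naive Poisson
        prediction (cell sedimentation, clumping).
    """
    if len(observed) == 0:
        raise ValueError("observed occupancy table is empty")
    if (observed["observed_n"] < 0).any():
        raise ValueError("observed counts must be non-negative")
    total = float(observed["observed_n"].sum())
    if total <= 0:
        raise ValueError("observed total count must be positive")
    out = observed[["k_effector", "k_target", "observed_n"]].copy()
    out["observed_frac"] = out["observed_n"] / total
    out["predicted_frac"] = [
        occupancy_pmf(params, (int(r.k_effector), int(r.k_target)))
        for r in out.itertuples()
    ]
    out["abs_dev"] = (out["observed_frac"] - out["predicted_frac"]).abs()
    out["rel_dev"] = out["abs_dev"] / out["predicted_frac"]
    return out
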