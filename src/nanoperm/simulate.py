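"""Synthetic Franz-cell experiments and parameter-recovery studies.

The generator emulates the measurement chain the analysis assumes: for
each filter stack the forward model (geometry -> retention law ->
effective diffusivity -> quasi-steady flux balance) produces the true
acceptor concentration, and replicate measurements perturb it with
multiplicative Gaussian noise — conductometric concentration readings
scale roughly with signal, so a relative error model is the default; an
additive noise floor is available as an option.  Derived quantities
(D_ef, a) are then recovered from the noisy concentration through the
same inversion chain the analysis applies to real measurements.

Randomness is reproducible and extendable: one root seed, with an
independent substream per (stack, replicate) derived via spawn keys, so
adding stacks or replicates never replays or shifts existing draws.

The default design mirrors the membrane experiments: twelve single- and
multi-layer filter configurations, four replicate concentration readings
each (two chambers x two runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .adsorption import RetentionObservation, fit_model_constant
from .datasets import (
    franz_cell_conditions,
    load_retention_table,
    nano_silver,
    stack_from_label,
    water,
)
from .geometry import FilterStack, stack_properties
from .physics import (
    CellConditions,
    MediumSpec,
    ParticleSpec,
    diffusion_coefficient,
    effective_diffusivity_from_concentration,
)
from .pipeline import membrane_prediction

__all__ = [
    "SyntheticExperimentConfig",
    "default_membrane_config",
    "simulate_measurements",
    "parameter_recovery_study",
    "RecoverySummary",
]


@dataclass(frozen=True)
class SyntheticExperimentConfig:
    """Design of a synthetic diffusion-cell campaign.

    ``noise_rel_sd`` is the relative standard deviation of the
    multiplicative Gaussian noise on the acceptor concentration;
    ``noise_abs_sd`` (g/m^3) adds an optional additive noise floor.
    """

    true_k: float
    stacks: tuple[FilterStack, ...]
    particle: ParticleSpec
    medium: MediumSpec
    conditions: CellConditions
    noise_rel_sd: float = 0.05
    noise_abs_sd: float = 0.0
    replicates: int = 4
    seed: int = 0

    def __init__(
        self,
        true_k: float,
        stacks: Sequence[FilterStack],
        particle: ParticleSpec,
        medium: MediumSpec,
        conditions: CellConditions,
        noise_rel_sd: float = 0.05,
        noise_abs_sd: float = 0.0,
        replicates: int = 4,
        seed: int = 0,
    ):
        if true_k < 0:
            raise ValueError(f"true_k must be non-negative, got {true_k!r}")
        if noise_rel_sd < 0 or noise_abs_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {replicates!r}")
        if len(stacks) == 0:
            raise ValueError("need at least one stack")
        object.__setattr__(self, "true_k", true_k)
        object.__setattr__(self, "stacks", tuple(stacks))
        object.__setattr__(self, "particle", particle)
        object.__setattr__(self, "medium", medium)
        object.__setattr__(self, "conditions", conditions)
        object.__setattr__(self, "noise_rel_sd", noise_rel_sd)
        object.__setattr__(self, "noise_abs_sd", noise_abs_sd)
        object.__setattr__(self, "replicates", replicates)
        object.__setattr__(self, "seed", seed)


def default_membrane_config(
    true_k: float = 0.3884,
    noise_rel_sd: float = 0.05,
    replicates: int = 4,
    seed: int = 0,
) -> SyntheticExperimentConfig:
    """The default campaign: the twelve measured filter configurations,
    silver nanoparticles in water, standard cell conditions."""
    labels = load_retention_table()["config"].unique()
    return SyntheticExperimentConfig(
        true_k=true_k,
        stacks=[stack_from_label(label) for label in labels],
        particle=nano_silver(),
        medium=water(),
        conditions=franz_cell_conditions(),
        noise_rel_sd=noise_rel_sd,
        replicates=replicates,
        seed=seed,
    )


def _replicate_rng(seed: int, stack_index: int, replicate: int) -> np.random.Generator:
    """Independent, extendable substream for one (stack, replicate) cell."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stack_index, replicate))
    return np.random.default_rng(ss)


def simulate_measurements(config: SyntheticExperimentConfig) -> pd.DataFrame:
    """Simulate noisy acceptor-concentration readings and their derived
    transport quantities.

    Returns one row per (stack, replicate) with columns: stack,
    replicate, Y, L_m, c_p_true, c_p_observed, D_ef, a, truncated.
    Negative concentration draws are truncated to zero and flagged;
    observations at or above the donor concentration (possible only
    under extreme noise) yield NaN derived values and are flagged too.
    """
    cond = config.conditions
    D = diffusion_coefficient(config.particle, config.medium)
    rows = []
    for i, stack in enumerate(config.stacks):
        L, Y = stack_properties(stack)
        truth = membrane_prediction(
            stack, config.particle, config.medium, cond, config.true_k
        )
        for j in range(config.replicates):
            rng = _replicate_rng(config.seed, i, j)
            eps = rng.normal(0.0, config.noise_rel_sd) if config.noise_rel_sd else 0.0
            eta = rng.normal(0.0, config.noise_abs_sd) if config.noise_abs_sd else 0.0
            c_obs = truth.c_p * (1.0 + eps) + eta
            truncated = False
            if c_obs < 0:
                c_obs = 0.0
                truncated = True
            if c_obs >= cond.c0:
                D_ef = np.nan
                a = np.nan
                truncated = True
            else:
                D_ef = effective_diffusivity_from_concentration(c_obs, cond, L)
                a = D_ef / D
            rows.append(
                {
                    "stack": stack.label,
                    "replicate": j,
                    "Y": Y,
                    "L_m": L,
                    "c_p_true": truth.c_p,
                    "c_p_observed": c_obs,
                    "D_ef": D_ef,
                    "a": a,
                    "truncated": truncated,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RecoverySummary:
    """Outcome of a parameter-recovery study over replicated datasets."""

    k_true: float
    k_median: float
    bias: float
    sd: float
    n_datasets: int
    estimates: tuple[float, ...] = field(repr=False, default=())

    def to_dict(self) -> dict:
        return {
            "k_true": self.k_true,
            "k_median": self.k_median,
            "bias": self.bias,
            "sd": self.sd,
            "n_datasets": self.n_datasets,
        }


def _fit_dataset(measurements: pd.DataFrame) -> float:
    """Pooled fit of k from one simulated measurement table."""
    valid = measurements.dropna(subset=["a"])
    valid = valid[valid["a"] > 0]
    obs = [
        RetentionObservation(Y=row.Y, a=row.a)
        for row in valid.itertuples(index=False)
    ]
    return fit_model_constant(obs).k


def parameter_recovery_study(
    config: SyntheticExperimentConfig, n_datasets: int = 100
) -> RecoverySummary:
    """Repeatedly simulate the campaign and refit k; summarize the spread.

    The constant k is identifiable only from variation in Y, so the
    design must contain at least two stacks with distinct surface
    parameters.  Each dataset gets its own derived seed from the root
    seed, so the study is reproducible and datasets are independent.
    """
    Ys = {round(stack_properties(s)[1], 12) for s in config.stacks}
    if len(Ys) < 2:
        raise ValueError(
            "k is not identifiable from a single surface parameter: "
            "provide stacks with at least two distinct Y values"
        )
    if n_datasets < 1:
        raise ValueError(f"n_datasets must be >= 1, got {n_datasets!r}")
    seeds = np.random.SeedSequence(config.seed).generate_state(n_datasets)
    estimates = []
    for dataset_seed in seeds:
        cfg = replace(config, seed=int(dataset_seed & 0x7FFFFFFF))
        estimates.append(_fit_dataset(simulate_measurements(cfg)))
    estimates_arr = np.asarray(estimates)
    k_median = float(np.median(estimates_arr))
    return RecoverySummary(
        k_true=config.true_k,
        k_median=k_median,
        bias=k_median - config.true_k,
        sd=float(np.std(estimates_arr, ddof=1)) if n_datasets > 1 else 0.0,
        n_datasets=n_datasets,
        estimates=tuple(float(e) for e in estimates),
    )
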