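"""Canonical benchmark runs with the study settings used throughout the docs.

These helpers pin the dataset sizes and estimator settings used by the test
suite and the reproduction script, so the same conditions are exercised
everywhere.  Sample sizes are scaled to single-CPU desk runs: parity over
five binary variables has 16 support states and MDS(7, 3) has 343, so a few
tens of thousands of samples already estimate every empirical frequency to
well under a percent and larger M changes nothing but run time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import gen_mds, gen_parity
from .made import MADEConfig, made_nll
from .model import NIDConfig, probe_mlp, train

__all__ = [
    "PARITY_M",
    "MDS_M",
    "parity_nid_config",
    "mds_nid_config",
    "parity_made_config",
    "run_parity_nid",
    "run_parity_made",
    "run_mds_probe",
]

PARITY_M = 20_000
MDS_M = 20_000


def parity_nid_config(n: int = 5, seed: int = 0) -> NIDConfig:
    """Five incremental layers with mean pooling, the default parity setup."""
    return NIDConfig(
        n_vars=n, supports=(2,) * n, n_layers=5, pooling="mean", seed=seed, epochs=120
    )


def mds_nid_config(n: int = 7, k: int = 3, seed: int = 0) -> NIDConfig:
    """Wider network for the categorical (q = 7) code benchmark."""
    return NIDConfig(
        n_vars=n,
        supports=(n,) * n,
        n_layers=5,
        embed_dim=12,
        stat_dim=48,
        hidden_dim=96,
        batch_size=2048,
        seed=seed,
        epochs=60,
        patience=15,
    )


def parity_made_config(n: int = 5, seed: int = 0) -> MADEConfig:
    return MADEConfig(n_vars=n, supports=(2,) * n, seed=seed)


@dataclass
class ParityNIDRun:
    final_nll: float  # final-layer summed validation NLL, nats
    probe_nll: float  # frozen-model + MLP probe summed validation NLL, nats
    deltas: np.ndarray  # layer-difference estimates of the local differences
    n_samples: int


def run_parity_nid(seed: int, n: int = 5, M: int = PARITY_M) -> ParityNIDRun:
    """Train NID on n-parity and probe the frozen model (one seed)."""
    samples = gen_parity(n, M, seed=seed)
    model, report = train(samples, parity_nid_config(n, seed=seed))
    pr = probe_mlp(model, samples, seed=seed)
    return ParityNIDRun(
        final_nll=report.final_sum,
        probe_nll=pr.summed_nll,
        deltas=report.estimated_local_differences(),
        n_samples=M,
    )


def run_parity_made(seed: int, n: int = 5, M: int = PARITY_M) -> float:
    """Last-variable validation NLL of single-ordering MADE on n-parity."""
    samples = gen_parity(n, M, seed=seed)
    _, result = made_nll(parity_made_config(n, seed=seed), samples)
    return result.last_variable_nll


def run_mds_probe(seed: int, n: int = 7, k: int = 3, M: int = MDS_M) -> float:
    """Frozen NID + MLP probe summed validation NLL on the MDS(n, k) code."""
    samples = gen_mds(n, k, M, seed=seed)
    model, _ = train(samples, mds_nid_config(n, k, seed=seed))
    # wider, longer probe with a gentler step size: the categorical heads
    # have 7 classes per variable and need more capacity than the parity probe
    return probe_mlp(
        model, samples, hidden_dim=64, epochs=80, lr=5e-3, seed=seed
    ).summed_nll
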