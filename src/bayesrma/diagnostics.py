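"""Chain diagnostics: spike detection, split-chain PSRF, run-length checks.

Variance chains sampled under improper or near-improper inverse-gamma
priors can show extreme excursions ("spikes") that inflate posterior
summaries.  A spike here is a draw exceeding ``threshold_multiplier``
times the chain median -- a scale-free proxy for the visual trace-plot
judgment.  The split-chain potential scale reduction factor compares the
two halves of one retained chain, matching a single-chain, fixed-iteration
workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes_fit import (
    PriorSpec,
    SamplerConfig,
    gibbs_sample,
    summarize_posterior,
)
from .exceptions import InputError
from .growth_model import ContrastBasis, LongitudinalDataset


@dataclass(frozen=True)
class SpikeReport:
    """Spikes found in a single-parameter chain."""

    parameter: str
    n_spikes: int
    spike_iterations: tuple[int, ...]
    max_draw: float
    median_draw: float
    threshold_used: float


def spike_report(
    chain: np.ndarray,
    threshold_multiplier: float = 50.0,
    parameter: str = "",
) -> SpikeReport:
    """Count draws exceeding ``threshold_multiplier`` times the chain median."""
    chain = np.asarray(chain, dtype=float)
    if chain.size == 0:
        raise InputError("spike report requires a non-empty chain")
    if not threshold_multiplier > 1.0:
        raise InputError("threshold_multiplier must exceed 1")
    median = float(np.median(chain))
    threshold = threshold_multiplier * median
    idx = np.flatnonzero(chain > threshold)
    return SpikeReport(
        parameter=parameter,
        n_spikes=int(idx.size),
        spike_iterations=tuple(int(i) for i in idx),
        max_draw=float(np.max(chain)),
        median_draw=median,
        threshold_used=float(threshold),
    )


def split_psrf(chain: np.ndarray) -> float:
    """Potential scale reduction factor on the two halves of one chain.

    sqrt(((L-1)/L * W + B/L) / W) with W the mean within-half variance and
    B the between-half variance; values near 1 indicate the halves agree.
    """
    chain = np.asarray(chain, dtype=float)
    if chain.size < 4:
        raise InputError("split PSRF requires a chain of length >= 4")
    half = chain.size // 2
    h1, h2 = chain[:half], chain[half : 2 * half]
    w = 0.5 * (np.var(h1, ddof=1) + np.var(h2, ddof=1))
    if w == 0.0:
        raise InputError("degenerate chain: zero within-half variance")
    b = half * np.var([np.mean(h1), np.mean(h2)], ddof=1)
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def iteration_stability(
    data: LongitudinalDataset,
    basis: ContrastBasis | None = None,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    multipliers: tuple[int, ...] = (5, 10),
    parameter: str = "beta",
) -> dict[int, float]:
    """Percent change of a point estimate when the run length is multiplied.

    Refits the same data with ``multiplier * n_iterations`` iterations and
    reports ``100 * (longer - base) / base`` for the requested parameter; a
    routine convergence check for a fixed-iteration design.
    """
    if config is None:
        config = SamplerConfig()
    base = summarize_posterior(
        gibbs_sample(data, basis, priors, config)
    ).point[parameter]
    if base == 0.0:
        raise InputError("base point estimate is zero; percent change undefined")
    changes: dict[int, float] = {}
    for mult in multipliers:
        if mult < 2:
            raise InputError("multipliers must be >= 2")
        longer_cfg = config.with_iterations(mult * config.n_iterations)
        longer = summarize_posterior(
            gibbs_sample(data, basis, priors, longer_cfg)
        ).point[parameter]
        changes[int(mult)] = 100.0 * (longer - base) / base
    return changes


def plot_traces(draws: dict[str, np.ndarray], path: str) -> None:
    """Trace plot, one panel per parameter, written as an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(draws)
    fig, axes = plt.subplots(len(names), 1, figsize=(7, 1.6 * len(names)),
                             sharex=True, squeeze=False)
    for ax, name in zip(axes[:, 0], names):
        ax.plot(np.asarray(draws[name]), lw=0.4)
        ax.set_ylabel(name, fontsize=8)
    axes[-1, 0].set_xlabel("retained iteration")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
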