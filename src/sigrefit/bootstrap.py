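"""Bootstrap resampling of catalogues and exposure-stability summaries.

A catalogue of n mutations is resampled by drawing n mutations with
replacement from its own channel distribution — a multinomial draw of size n
with probabilities m/n, which is exactly the nonparametric bootstrap at the
channel level. Refitting each resample and summarizing the spread of the
estimated exposures gives a per-signature stability interval around the
point estimate.

Quartiles use linear interpolation between order statistics (numpy's default
"linear" rule); quartile conventions differ between tools, so the choice is
stated here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue_io import (
    LOW_COUNT_THRESHOLD,
    LowCountWarning,
    MutationalCatalogue,
    SignatureMatrix,
)
from .exposure_fit import ExposureEstimate, estimate_exposure

__all__ = ["BootstrapSummary", "bootstrap_catalogues", "summarize_exposures"]

#: default number of bootstrap resamples
DEFAULT_R = 1000


@dataclass
class BootstrapSummary:
    """Spread of exposure estimates over bootstrap resamples of one sample.

    ``table`` has one row per signature with columns: original (the point
    estimate from the unresampled catalogue), min, q1, median, q3, max over
    the R resampled estimates — all proportions in [0, 1].
    """

    sample_id: str
    R: int
    seed: int
    constraint_mode: str
    table: pd.DataFrame
    original: ExposureEstimate
    resampled_proportions: np.ndarray  # shape (R, N), kept for plotting

    def __post_init__(self) -> None:
        t = self.table
        expected = ["original", "min", "q1", "median", "q3", "max"]
        if list(t.columns) != expected:
            raise ValueError(f"summary table must have columns {expected}")
        quant = t[["min", "q1", "median", "q3", "max"]].to_numpy()
        if np.any(np.diff(quant, axis=1) < -1e-12):
            raise ValueError("bootstrap quantiles out of order")
        if (t.to_numpy() < -1e-12).any() or (t.to_numpy() > 1 + 1e-12).any():
            raise ValueError("bootstrap summary values must be proportions in [0, 1]")


def bootstrap_catalogues(
    m: MutationalCatalogue, R: int = DEFAULT_R, seed: int = 0
) -> list[MutationalCatalogue]:
    """Draw R bootstrap resamples of a counts catalogue.

    Each resample redraws the n observed mutations with replacement from the
    96 channels with probabilities m/n, so every resample total equals n.
    Deterministic given ``seed``.
    """
    if m.scale != "counts":
        raise ValueError("bootstrap resampling needs a counts-scale catalogue")
    n = m.total
    if n <= 0:
        raise ValueError(f"catalogue {m.sample_id!r} has zero total; cannot resample")
    if R < 1:
        raise ValueError("R must be >= 1")
    if n < LOW_COUNT_THRESHOLD:
        warnings.warn(
            f"catalogue {m.sample_id!r} has only {n:.0f} mutations "
            f"(< {LOW_COUNT_THRESHOLD}); bootstrap intervals will be wide",
            LowCountWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(int(round(n)), m.values / n, size=R)
    return [
        MutationalCatalogue(
            f"{m.sample_id}:boot{r}",
            draws[r].astype(float),
            "counts",
            {"bootstrap_of": m.sample_id, "replicate": r, "seed": seed},
        )
        for r in range(R)
    ]


def summarize_exposures(
    m: MutationalCatalogue,
    P: SignatureMatrix,
    R: int = DEFAULT_R,
    seed: int = 0,
    constraint_mode: str = "simplex",
) -> BootstrapSummary:
    """Fit a catalogue and R bootstrap resamples; summarize the spread.

    One seed governs the whole summary. Returns the per-signature original
    estimate together with min / Q1 / median / Q3 / max of the resampled
    exposure proportions.
    """
    original = estimate_exposure(m, P, constraint_mode)
    resamples = bootstrap_catalogues(m, R, seed)
    with warnings.catch_warnings():
        # the low-count condition was already reported for the original draw
        warnings.simplefilter("ignore", LowCountWarning)
        fits = estimate_exposure(resamples, P, constraint_mode)
    props = np.vstack([f.proportions for f in fits])
    q1, med, q3 = np.percentile(props, [25, 50, 75], axis=0)
    table = pd.DataFrame(
        {
            "original": original.proportions,
            "min": props.min(axis=0),
            "q1": q1,
            "median": med,
            "q3": q3,
            "max": props.max(axis=0),
        },
        index=list(P.names),
    )
    return BootstrapSummary(
        sample_id=m.sample_id,
        R=R,
        seed=seed,
        constraint_mode=constraint_mode,
        table=table,
        original=original,
        resampled_proportions=props,
    )


def plot_summary(summary: BootstrapSummary, path=None, ax=None):
    """Box-style plot of the bootstrap exposure distributions.

    One box per signature from the resampled proportions; a star marks the
    point estimate of the original catalogue. Presentation only — every
    number shown is in ``summary.table``.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.3 * len(summary.table)), 4))
    names = list(summary.table.index)
    ax.boxplot(
        summary.resampled_proportions,
        tick_labels=names,
        whis=(0, 100),
        showfliers=False,
    )
    ax.plot(
        np.arange(1, len(names) + 1),
        summary.table["original"].to_numpy(),
        linestyle="none",
        marker="*",
        markersize=10,
        color="tab:red",
        label="original catalogue",
    )
    ax.set_ylabel("estimated exposure (proportion)")
    ax.set_title(f"{summary.sample_id} (R={summary.R})")
    ax.tick_params(axis="x", rotation=90)
    ax.legend()
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
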