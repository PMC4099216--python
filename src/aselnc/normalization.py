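"""Two-channel intensity normalization for allele fractions.

Raw Infinium-style fluorescence has an intensity-dependent dye bias: the ratio
of the two channel gains drifts with total signal, so raw allele fractions
x/(x+y) at heterozygous SNPs drift away from 0.5 as a function of intensity.
The correction fits, per channel, a quadratic (in log10 of the summed
two-channel signal) through the medians of equal-count intensity bins, and
divides each channel by its predicted typical intensity before recomputing the
fraction:

    f_adj = (x / p_x(t)) / (x / p_x(t) + y / p_y(t)),   t = x + y.

When the two channels are unbiased the two fitted curves coincide and the
adjustment is an exact no-op; when one channel carries a smooth multiplicative
gain g(t), the ratio p_x/p_y recovers g and the adjusted heterozygous fraction
returns to 0.5 at every intensity level.

Fitting is pooled over all samples of one template (gDNA or cDNA), one model
per channel.  In the pipeline the fit uses data points whose gDNA genotype is
heterozygous, so each channel's bin median estimates gain x total/2 without
being skewed by the population genotype mix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SingularFitError(ValueError):
    """All signals identical (or otherwise degenerate): quadratic fit undefined."""


@dataclass
class NormalizationModel:
    """Quadratic model of a channel's median log-intensity vs log10(binning signal).

    coeffs are (a, b, c) of  log10 p(t) = a*log10(t)^2 + b*log10(t) + c;
    fitting on the log scale keeps the identity component of the median curve
    exactly linear, so the three coefficients track the gain drift rather than
    the exponential trend.  Predictions are floored at ``floor`` (the 1st
    percentile of the raw signals) so division by the prediction cannot blow
    up.
    """

    channel: str
    bin_edges: np.ndarray  # boundaries of the binning signal, len n_bins+1
    bin_medians: np.ndarray  # per-bin median of the channel signal
    coeffs: tuple[float, float, float]
    floor: float
    log10_range: tuple[float, float] = (-np.inf, np.inf)

    def predict(self, t) -> np.ndarray:
        """Predicted typical channel intensity at binning-signal value t."""
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lt = np.log10(np.where(t > 0, t, np.nan))
        lt = np.clip(lt, *self.log10_range)
        a, b, c = self.coeffs
        p = 10.0 ** (a * lt * lt + b * lt + c)
        return np.maximum(p, self.floor)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.bin_medians)
        df = pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "bin_median": self.bin_medians,
            }
        )
        df.insert(0, "channel", self.channel)
        a, b, c = self.coeffs
        df["coef_a"], df["coef_b"], df["coef_c"] = a, b, c
        df["floor"] = self.floor
        df["log10_lo"], df["log10_hi"] = self.log10_range
        return df


def fit_normalization(
    signals,
    n_bins: int = 100,
    bin_by=None,
    channel: str = "x",
) -> NormalizationModel:
    """Fit the binned-median quadratic for one channel.

    Parameters
    ----------
    signals
        Channel intensities pooled over all SNPs and samples.
    n_bins
        Number of equal-count bins on log10 of the binning signal (>= 3).
    bin_by
        Signal used for binning and as the quadratic's abscissa.  Defaults to
        the channel's own signals; the pipeline passes the summed two-channel
        signal so that the two channels share a common intensity axis.
    """
    signals = np.asarray(signals, dtype=float)
    bin_by = signals if bin_by is None else np.asarray(bin_by, dtype=float)
    if bin_by.shape != signals.shape:
        raise ValueError("bin_by must have the same shape as signals")
    if n_bins < 3:
        raise ValueError(f"n_bins must be >= 3, got {n_bins}")

    ok = np.isfinite(signals) & np.isfinite(bin_by) & (bin_by > 0) & (signals >= 0)
    n_dropped = int(signals.size - ok.sum())
    if n_dropped:
        logger.info("fit_normalization[%s]: excluded %d nonpositive/missing signals",
                    channel, n_dropped)
    sig, bby = signals[ok], bin_by[ok]
    if sig.size < n_bins:
        raise ValueError(f"need >= n_bins={n_bins} usable signals, got {sig.size}")
    if np.ptp(bby) == 0:
        raise SingularFitError("all binning signals are equal; fit is singular")

    order = np.argsort(bby, kind="stable")
    chunks = np.array_split(order, n_bins)
    bin_abscissa = np.array([np.median(bby[idx]) for idx in chunks])
    bin_medians = np.array([np.median(sig[idx]) for idx in chunks])
    edges = np.empty(n_bins + 1)
    edges[0] = bby[order[0]]
    edges[-1] = bby[order[-1]]
    for i in range(1, n_bins):
        edges[i] = 0.5 * (bby[chunks[i - 1][-1]] + bby[chunks[i][0]])

    lx = np.log10(bin_abscissa)
    if np.ptp(lx) == 0:
        raise SingularFitError("bin medians all equal; fit is singular")
    if np.any(bin_medians <= 0):
        # medians at zero (e.g. a channel silent in a stratum) cannot be
        # log-fitted; lift them to the smallest positive median
        positive = bin_medians[bin_medians > 0]
        if positive.size == 0:
            raise SingularFitError("all bin medians are zero")
        bin_medians = np.maximum(bin_medians, positive.min())
    a, b, c = np.polyfit(lx, np.log10(bin_medians), deg=2)

    model = NormalizationModel(
        channel=channel,
        bin_edges=edges,
        bin_medians=bin_medians,
        coeffs=(float(a), float(b), float(c)),
        floor=float(np.percentile(sig[sig > 0], 1)) if (sig > 0).any() else 1e-9,
        log10_range=(float(lx.min()), float(lx.max())),
    )
    return model


def adjust_fraction(x_raw, y_raw, model_x: NormalizationModel, model_y: NormalizationModel):
    """Adjusted allele-A fraction in [0, 1]; NaN where both channels are zero.

    Both models are evaluated at the data point's summed signal, so swapping
    the channels (and models) maps f to 1-f exactly.
    """
    x = np.asarray(x_raw, dtype=float)
    y = np.asarray(y_raw, dtype=float)
    t = x + y
    px = model_x.predict(t)
    py = model_y.predict(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        xs = x / px
        ys = y / py
        f = xs / (xs + ys)
    f = np.where(t > 0, f, np.nan)
    f = np.clip(f, 0.0, 1.0)
    if np.isscalar(x_raw) and np.isscalar(y_raw):
        return float(f)
    return f


def raw_fraction(x_raw, y_raw):
    """Unadjusted allele-A fraction, kept for diagnostics; NaN where sum is 0."""
    x = np.asarray(x_raw, dtype=float)
    y = np.asarray(y_raw, dtype=float)
    t = x + y
    with np.errstate(divide="ignore", invalid="ignore"):
        f = x / t
    return np.where(t > 0, f, np.nan)


def save_model(model: NormalizationModel, path: str | Path) -> None:
    model.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_model(path: str | Path) -> NormalizationModel:
    df = pd.read_csv(path, sep="\t")
    edges = np.concatenate([df["bin_lo"].to_numpy(), [df["bin_hi"].iloc[-1]]])
    return NormalizationModel(
        channel=str(df["channel"].iloc[0]),
        bin_edges=edges,
        bin_medians=df["bin_median"].to_numpy(),
        coeffs=(float(df["coef_a"].iloc[0]), float(df["coef_b"].iloc[0]),
                float(df["coef_c"].iloc[0])),
        floor=float(df["floor"].iloc[0]),
        log10_range=(float(df["log10_lo"].iloc[0]), float(df["log10_hi"].iloc[0])),
    )
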