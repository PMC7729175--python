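"""Average-ERP computation and pointwise KDE-based significance masking.

To verify that the interface elicits evoked potentials, the average waveform
of each channel (4-40 Hz band, 200 ms pre-stimulus through 800 ms
post-stimulus, baseline-corrected) is tested pointwise against the
distribution of its own pre-stimulus interval: a Gaussian kernel density is
estimated on the baseline samples and a post-stimulus amplitude is flagged
significant (two-tailed, level alpha) when it falls outside the KDE's
(alpha/2, 1 - alpha/2) quantile band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .session import Recording, epoch_samples
from . import preprocessing as pp

__all__ = [
    "ErpWindowSpec",
    "ErpResult",
    "baseline_band",
    "erp_significance",
    "extract_erp_epochs",
]


@dataclass(frozen=True)
class ErpWindowSpec:
    """ERP analysis window: 200 ms pre-stimulus, 800 ms post, 4-40 Hz band."""

    pre_ms: float = 200.0
    post_ms: float = 800.0
    band: pp.BandSpec = field(default_factory=lambda: pp.BandSpec(4.0, 40.0))
    sampling_rate: float = 256.0

    @property
    def n_pre(self) -> int:
        return int(np.floor(self.pre_ms / 1000.0 * self.sampling_rate))

    @property
    def n_post(self) -> int:
        return int(np.floor(self.post_ms / 1000.0 * self.sampling_rate))

    def times_ms(self) -> np.ndarray:
        """Time axis in ms relative to stimulus onset (pre + post samples)."""
        idx = np.arange(-self.n_pre, self.n_post)
        return idx / self.sampling_rate * 1000.0


@dataclass
class ErpResult:
    """Average waveforms, baseline quantile bands, and significance masks.

    Masks cover the post-stimulus samples only; +1 marks significantly
    positive amplitudes, -1 significantly negative, 0 not significant.
    """

    spec: ErpWindowSpec
    channel_names: tuple[str, ...]
    mean: dict[str, np.ndarray]               # class -> n_channels x (pre+post)
    band_limits: dict[str, np.ndarray]        # class -> n_channels x 2
    mask: dict[str, np.ndarray]               # class -> n_channels x n_post, int
    degenerate: dict[str, np.ndarray]         # class -> bool per channel
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: channel, time_ms, per-class mean, band, flag."""
        times = self.spec.times_ms()
        n_pre = self.spec.n_pre
        rows = []
        for ci, ch in enumerate(self.channel_names):
            for ti, t in enumerate(times):
                row = {"channel": ch, "time_ms": t}
                for cls in self.mean:
                    row[f"mean_{cls}"] = self.mean[cls][ci, ti]
                    row[f"lower_{cls}"] = self.band_limits[cls][ci, 0]
                    row[f"upper_{cls}"] = self.band_limits[cls][ci, 1]
                    row[f"sig_{cls}"] = (int(self.mask[cls][ci, ti - n_pre])
                                         if ti >= n_pre else 0)
                rows.append(row)
        return pd.DataFrame(rows)


def _normal_reference_bandwidth(samples: np.ndarray, multiplier: float) -> float:
    n = samples.size
    sd = samples.std(ddof=1)
    return multiplier * 1.06 * sd * n ** (-1 / 5)


def baseline_band(baseline_samples: np.ndarray, alpha: float = 0.05,
                  bandwidth_multiplier: float = 1.0) -> tuple[float, float]:
    """(alpha/2, 1 - alpha/2) quantiles of a Gaussian KDE of the baseline.

    The kernel bandwidth follows the normal-reference rule
    (1.06 * sd * n^{-1/5}), optionally scaled.  Constant input yields the
    degenerate band (c, c).
    """
    x = np.asarray(baseline_samples, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 baseline samples")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if np.ptp(x) == 0.0:
        return float(x[0]), float(x[0])
    h = _normal_reference_bandwidth(x, bandwidth_multiplier)
    # KDE CDF is the average of the kernel CDFs; invert it on a fine grid.
    lo = x.min() - 5 * h
    hi = x.max() + 5 * h
    grid = np.linspace(lo, hi, 4096)
    cdf = stats.norm.cdf((grid[:, None] - x[None, :]) / h).mean(axis=1)
    lower = float(np.interp(alpha / 2, cdf, grid))
    upper = float(np.interp(1 - alpha / 2, cdf, grid))
    return lower, upper


def extract_erp_epochs(recording: Recording, spec: ErpWindowSpec,
                       thresholds: pp.ArtifactThresholds = pp.ArtifactThresholds(),
                       filter_order: int = pp.DEFAULT_FILTER_ORDER
                       ) -> dict[str, np.ndarray]:
    """Artifact-free pre+post epochs by class from a calibration recording.

    Returns ``{"target": array(k, n_channels, n_pre + n_post), "non-target":
    ...}`` in the analysis band.  Artifact screening uses the standard
    post-stimulus validation on the three system bands.
    """
    bands = pp.filter_bands(recording, order=filter_order)
    analysis = pp.filter_recording(recording, spec.band, order=filter_order)
    n_pre, n_post = spec.n_pre, spec.n_post
    out: dict[str, list[np.ndarray]] = {"target": [], "non-target": []}
    for ev in recording.events:
        if ev.cued_target is None:
            continue
        start = ev.onset_sample - n_pre
        stop = ev.onset_sample + n_post
        if start < 0 or stop > recording.n_samples:
            continue
        epoch = pp.extract_epoch(bands, ev)
        if not pp.assess_quality(epoch, thresholds).is_valid:
            continue
        cls = "target" if ev.is_target else "non-target"
        out[cls].append(analysis.signals[:, start:stop].copy())
    return {cls: np.stack(eps) if eps else np.empty((0, recording.signals.shape[0],
                                                     n_pre + n_post))
            for cls, eps in out.items()}


def erp_significance(epochs_by_class: dict[str, np.ndarray],
                     spec: ErpWindowSpec = ErpWindowSpec(),
                     alpha: float = 0.05,
                     bandwidth_multiplier: float = 1.0,
                     channel_names: tuple[str, ...] | None = None) -> ErpResult:
    """Pointwise two-tailed significance of the average ERP per channel.

    Per channel and class the epochs are averaged, the whole averaged window
    is baseline-corrected by its pre-stimulus mean, and the baseline
    distribution is the averaged waveform's own 51 pre-stimulus samples
    (smoothed by the KDE).  A post-stimulus point is flagged +1/-1 when the
    averaged amplitude exceeds the upper / falls below the lower band limit.
    """
    n_pre, n_post = spec.n_pre, spec.n_post
    n_win = n_pre + n_post
    mean, band_limits, mask, degenerate = {}, {}, {}, {}
    n_channels = None
    for cls, eps in epochs_by_class.items():
        eps = np.asarray(eps, dtype=float)
        if eps.ndim != 3 or eps.shape[2] != n_win:
            raise ValueError(
                f"class {cls!r}: expected (k, n_channels, {n_win}) epochs "
                f"including {n_pre} pre-stimulus samples, got {eps.shape}")
        if eps.shape[0] == 0:
            raise ValueError(f"class {cls!r}: no epochs")
        n_channels = eps.shape[1]
        avg = eps.mean(axis=0)
        avg = avg - avg[:, :n_pre].mean(axis=1, keepdims=True)
        limits = np.empty((n_channels, 2))
        m = np.zeros((n_channels, n_post), dtype=int)
        degen = np.zeros(n_channels, dtype=bool)
        for c in range(n_channels):
            lower, upper = baseline_band(avg[c, :n_pre], alpha,
                                         bandwidth_multiplier)
            degen[c] = lower == upper
            limits[c] = (lower, upper)
            post = avg[c, n_pre:]
            m[c] = np.where(post > upper, 1, np.where(post < lower, -1, 0))
        mean[cls] = avg
        band_limits[cls] = limits
        mask[cls] = m
        degenerate[cls] = degen
    names = channel_names or tuple(f"ch{i}" for i in range(n_channels))
    return ErpResult(spec=spec, channel_names=names, mean=mean,
                     band_limits=band_limits, mask=mask, degenerate=degenerate,
                     alpha=alpha)
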