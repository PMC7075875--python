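"""Image-quality metrics: PSNR, SSIM, and artifact power.

All three compare a test image x against a reference r:

* PSNR = 20 log10(max(r) / sqrt(MSE)), with MSE the pixel-mean squared
  difference.  Note the peak is taken from the reference image itself, not
  from a fixed data-range constant, so PSNR of a [0,1] image against a
  reference whose maximum is 1 coincides with the usual convention.
* SSIM combines local (Gaussian-windowed) means, variances and covariance;
  the constants c1 = (k1 L)^2, c2 = (k2 L)^2 stabilise flat regions.
* Artifact power AP = sum(|r| - |x|)^2 / sum |r|^2 measures residual
  artifact energy normalised by the reference energy; 0 means artifact-free
  and x's sign/phase is irrelevant (only magnitudes enter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["psnr", "ssim", "artifact_power", "evaluate_set", "MetricsReport"]


def _check_pair(reference, test):
    r = np.asarray(reference, dtype=np.float64)
    x = np.asarray(test, dtype=np.float64)
    if r.shape != x.shape:
        raise ValueError(f"shape mismatch: reference {r.shape} vs test {x.shape}")
    return r, x


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    r, x = _check_pair(reference, test)
    if not np.any(r):
        raise ValueError("reference image is all-zero; PSNR undefined")
    mse = np.mean((r - x) ** 2)
    if mse == 0.0:
        return float("inf")
    return float(20.0 * np.log10(r.max() / np.sqrt(mse)))


def _gaussian_kernel(window_size: int, sigma: float) -> np.ndarray:
    half = window_size // 2
    g = np.exp(-np.arange(-half, half + 1) ** 2 / (2.0 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(reference: np.ndarray, test: np.ndarray, window_size: int = 11,
         k1: float = 0.01, k2: float = 0.03, data_range: float = 1.0,
         sigma: float = 1.5, gaussian: bool = True) -> float:
    """Mean structural similarity over sliding local windows.

    Windowed statistics are weighted by a normalised Gaussian (sigma=1.5 by
    default) or a uniform window, evaluated at all fully interior positions,
    and combined per window as

        ((2 mu_r mu_x + c1)(2 cov + c2)) /
        ((mu_r^2 + mu_x^2 + c1)(var_r + var_x + c2)).
    """
    r, x = _check_pair(reference, test)
    if window_size % 2 == 0 or window_size > min(r.shape):
        raise ValueError(f"window_size must be odd and <= image size, "
                         f"got {window_size} for shape {r.shape}")
    if gaussian:
        kernel = _gaussian_kernel(window_size, sigma)
    else:
        kernel = np.full((window_size, window_size),
                         1.0 / window_size ** 2)

    from numpy.lib.stride_tricks import sliding_window_view

    win_r = sliding_window_view(r, (window_size, window_size))
    win_x = sliding_window_view(x, (window_size, window_size))
    mu_r = np.tensordot(win_r, kernel, axes=([2, 3], [0, 1]))
    mu_x = np.tensordot(win_x, kernel, axes=([2, 3], [0, 1]))
    m_rr = np.tensordot(win_r * win_r, kernel, axes=([2, 3], [0, 1]))
    m_xx = np.tensordot(win_x * win_x, kernel, axes=([2, 3], [0, 1]))
    m_rx = np.tensordot(win_r * win_x, kernel, axes=([2, 3], [0, 1]))
    var_r = m_rr - mu_r ** 2
    var_x = m_xx - mu_x ** 2
    cov = m_rx - mu_r * mu_x

    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    num = (2.0 * mu_r * mu_x + c1) * (2.0 * cov + c2)
    den = (mu_r ** 2 + mu_x ** 2 + c1) * (var_r + var_x + c2)
    return float(np.mean(num / den))


def artifact_power(reference: np.ndarray, test: np.ndarray) -> float:
    """Residual artifact energy relative to the reference energy."""
    r, x = _check_pair(reference, test)
    denom = np.sum(np.abs(r) ** 2)
    if denom == 0.0:
        raise ValueError("reference image is all-zero; AP undefined")
    return float(np.sum((np.abs(r) - np.abs(x)) ** 2) / denom)


@dataclass
class MetricsReport:
    """Per-image metrics plus mean and sample standard deviation."""

    psnr_values: list = field(default_factory=list)
    ssim_values: list = field(default_factory=list)
    ap_values: list = field(default_factory=list)

    @staticmethod
    def _summary(values):
        a = np.asarray(values, dtype=np.float64)
        if np.isinf(a).any():  # identical-image PSNR sentinel
            return float(a.mean()), 0.0 if np.all(a == a[0]) else float("nan")
        mean = float(a.mean())
        sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
        return mean, sd

    @property
    def psnr_mean_sd(self):
        return self._summary(self.psnr_values)

    @property
    def ssim_mean_sd(self):
        return self._summary(self.ssim_values)

    @property
    def ap_mean_sd(self):
        return self._summary(self.ap_values)

    def to_dict(self) -> dict:
        pm, ps = self.psnr_mean_sd
        sm, ss = self.ssim_mean_sd
        am, asd = self.ap_mean_sd
        return {
            "psnr": self.psnr_values, "ssim": self.ssim_values,
            "artifact_power": self.ap_values,
            "psnr_mean": pm, "psnr_sd": ps,
            "ssim_mean": sm, "ssim_sd": ss,
            "ap_mean": am, "ap_sd": asd,
            "n_images": len(self.psnr_values),
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "psnr": self.psnr_values,
            "ssim": self.ssim_values,
            "artifact_power": self.ap_values,
        })


def evaluate_set(references, tests, **ssim_kwargs) -> MetricsReport:
    """Score a list of test images against paired references."""
    references = list(references)
    tests = list(tests)
    if len(references) != len(tests):
        raise ValueError(
            f"length mismatch: {len(references)} references vs {len(tests)} tests")
    report = MetricsReport()
    for r, x in zip(references, tests):
        report.psnr_values.append(psnr(r, x))
        report.ssim_values.append(ssim(r, x, **ssim_kwargs))
        report.ap_values.append(artifact_power(r, x))
    return report
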