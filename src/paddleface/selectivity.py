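"""Facial-selectivity prediction from d(Re)/d(Si) descriptor series.

A frame where d(Re) < d(Si) has its Re face more crowded by the carboxylate
ligands, steering alkene attack to the Si face. The primary statistic is the
paired, per-frame probability ``p_re_blocked`` = fraction of frames with
d(Re) < d(Si) (ties count one half); the predicted favored approach face is
Si when that probability exceeds the decision threshold, Re when it falls
below one minus the threshold, and "none" in between. Kernel density
estimates of the two distance distributions serve as shape/rigidity
diagnostics: a single sharp peak at short distance means a rigid, blocked
face (high enantiocontrol expected); multiple peaks flag conformational
flexibility and hence weak facial discrimination.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import AnalysisError

__all__ = [
    "KDEResult",
    "SelectivityReport",
    "kde",
    "facial_bias",
    "compare_to_experiment",
    "plot_kdes",
    "DECISION_THRESHOLD",
    "PEAK_HEIGHT_RATIO",
]

#: Default decision threshold on p_re_blocked for calling a face.
DECISION_THRESHOLD = 0.8

#: Secondary KDE peaks count only above this fraction of the main peak.
PEAK_HEIGHT_RATIO = 0.2

_BANDWIDTH_FLOOR = 0.01  # Å, for degenerate (zero-variance) samples


@dataclass(frozen=True)
class KDEResult:
    """Gaussian KDE of a distance sample on a regular grid.

    ``peaks`` lists (location Å, density height) for local maxima above the
    height-ratio threshold, sorted by height descending; the trapezoid
    integral of ``density`` over ``grid`` is 1 within 1%.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_samples: int
    peaks: tuple[tuple[float, float], ...]

    @property
    def mode(self) -> float:
        return self.peaks[0][0] if self.peaks else float(self.grid[np.argmax(self.density)])

    def to_dict(self) -> dict:
        return {
            "grid": [float(x) for x in self.grid],
            "density": [float(x) for x in self.density],
            "bandwidth": self.bandwidth,
            "n_samples": self.n_samples,
            "peaks": [[loc, h] for loc, h in self.peaks],
        }


def _silverman_bandwidth(samples: np.ndarray) -> float:
    n = len(samples)
    sd = float(np.std(samples, ddof=1))
    q75, q25 = np.percentile(samples, [75, 25])
    iqr = float(q75 - q25)
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * scale * n ** (-1 / 5)


def kde(
    samples,
    bandwidth: str | float = "silverman",
    grid_points: int = 512,
    peak_height_ratio: float = PEAK_HEIGHT_RATIO,
) -> KDEResult:
    """Gaussian kernel density estimate of a positive distance sample.

    ``bandwidth`` is either the Silverman rule
    h = 0.9·min(sd, IQR/1.34)·n^(−1/5) or a fixed width in Å. The grid spans
    [min − 3h, max + 3h] with at least 512 points. Zero-variance samples get
    a delta-like estimate at the 0.01 Å bandwidth floor, with a warning.
    """
    x = np.asarray(list(samples), dtype=float)
    if len(x) < 10:
        raise AnalysisError(f"kde needs at least 10 samples, got {len(x)}")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise AnalysisError("kde samples must be finite and positive")

    if isinstance(bandwidth, str):
        if bandwidth != "silverman":
            raise ValueError(f"unknown bandwidth mode {bandwidth!r}")
        h = _silverman_bandwidth(x)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("fixed bandwidth must be positive")
    if h < _BANDWIDTH_FLOOR:
        if isinstance(bandwidth, str):
            warnings.warn(
                "near-zero sample variance: bandwidth floored at "
                f"{_BANDWIDTH_FLOOR} Å (delta-like density)",
                stacklevel=2,
            )
        h = max(h, _BANDWIDTH_FLOOR)

    grid_points = max(int(grid_points), 512)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_points)
    z = (grid[:, None] - x[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (len(x) * h * math.sqrt(2 * math.pi))

    idx, _ = find_peaks(density)
    if len(idx) == 0:  # monotone edge case: fall back to global maximum
        idx = np.array([int(np.argmax(density))])
    heights = density[idx]
    keep = heights >= peak_height_ratio * heights.max()
    peaks = sorted(
        ((float(grid[i]), float(density[i])) for i in idx[keep]),
        key=lambda p: -p[1],
    )
    return KDEResult(
        grid=grid,
        density=density,
        bandwidth=h,
        n_samples=len(x),
        peaks=tuple(peaks),
    )


@dataclass(frozen=True)
class SelectivityReport:
    """Facial-selectivity prediction for one descriptor series."""

    p_re_blocked: float
    predicted_face: str  # "Si" | "Re" | "none"  (favored approach face)
    mode_re: float
    mode_si: float
    kde_re: KDEResult
    kde_si: KDEResult
    multimodal_re: bool
    multimodal_si: bool
    n_frames_used: int
    n_frames_missing: int
    decision_threshold: float
    bandwidth: str | float = "silverman"

    def to_dict(self, include_kde: bool = True) -> dict:
        doc = {
            "p_re_blocked": self.p_re_blocked,
            "predicted_face": self.predicted_face,
            "mode_re": self.mode_re,
            "mode_si": self.mode_si,
            "multimodal_re": self.multimodal_re,
            "multimodal_si": self.multimodal_si,
            "n_frames_used": self.n_frames_used,
            "n_frames_missing": self.n_frames_missing,
            "decision_threshold": self.decision_threshold,
            "bandwidth": self.bandwidth,
        }
        if include_kde:
            doc["kde_re"] = self.kde_re.to_dict()
            doc["kde_si"] = self.kde_si.to_dict()
        return doc


def _series_table(series) -> pd.DataFrame:
    return series.table if hasattr(series, "table") else pd.DataFrame(series)


def facial_bias(
    series,
    decision_threshold: float = DECISION_THRESHOLD,
    bandwidth: str | float = "silverman",
) -> SelectivityReport:
    """Predict the favored prochiral approach face from a descriptor series.

    ``series`` is a :class:`~paddleface.descriptors.DescriptorSeries` or any
    table with ``d_re``/``d_si`` columns. Only frames with both distances
    present are paired; at least 10 are required.
    """
    if not 0.5 < decision_threshold <= 1.0:
        raise ValueError("decision_threshold must be in (0.5, 1]")
    tab = _series_table(series)
    d_re = pd.to_numeric(tab["d_re"], errors="coerce").to_numpy(float)
    d_si = pd.to_numeric(tab["d_si"], errors="coerce").to_numpy(float)
    paired = np.isfinite(d_re) & np.isfinite(d_si)
    n_used = int(paired.sum())
    n_missing = len(tab) - n_used
    if n_used < 10:
        raise AnalysisError(
            f"insufficient paired frames: {n_used} with both d_re and d_si"
        )
    re_v, si_v = d_re[paired], d_si[paired]
    p_re_blocked = float(
        ((re_v < si_v).sum() + 0.5 * (re_v == si_v).sum()) / n_used
    )

    if p_re_blocked > decision_threshold:
        face = "Si"  # Re blocked → approach from Si
    elif p_re_blocked < 1.0 - decision_threshold:
        face = "Re"
    else:
        face = "none"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance warning already semantic here
        kde_re = kde(re_v, bandwidth=bandwidth)
        kde_si = kde(si_v, bandwidth=bandwidth)
    return SelectivityReport(
        p_re_blocked=p_re_blocked,
        predicted_face=face,
        mode_re=kde_re.mode,
        mode_si=kde_si.mode,
        kde_re=kde_re,
        kde_si=kde_si,
        multimodal_re=len(kde_re.peaks) >= 2,
        multimodal_si=len(kde_si.peaks) >= 2,
        n_frames_used=n_used,
        n_frames_missing=n_missing,
        decision_threshold=decision_threshold,
        bandwidth=bandwidth,
    )


def compare_to_experiment(
    report: SelectivityReport,
    experimental_ee_percent: float,
    ee_sign_convention: str = "positive_means_si",
) -> dict:
    """Check the predicted face against a signed experimental ee.

    Convention: positive ee means Si-face addition of the alkene is favored,
    negative means Re-face addition. Returns ``agrees`` as True/False, or
    ``"indeterminate"`` when no face was called (or ee is exactly zero).
    """
    if ee_sign_convention != "positive_means_si":
        raise ValueError(f"unknown sign convention {ee_sign_convention!r}")
    ee = float(experimental_ee_percent)
    if abs(ee) > 100:
        raise ValueError(f"|ee| must be ≤ 100, got {ee}")
    if report.predicted_face == "none" or ee == 0:
        agrees: bool | str = "indeterminate"
        detail = "no face called; cannot be checked against ee sign"
    else:
        experimental_face = "Si" if ee > 0 else "Re"
        agrees = report.predicted_face == experimental_face
        detail = (
            f"predicted approach face {report.predicted_face} "
            f"(p_re_blocked={report.p_re_blocked:.3f}) vs experimental "
            f"{experimental_face}-face addition (ee={ee:+.1f}%)"
        )
    return {
        "agrees": agrees,
        "detail": detail,
        "experimental_ee_percent": ee,
        "predicted_face": report.predicted_face,
    }


def plot_kdes(report: SelectivityReport, path) -> None:
    """Write a static plot of the d(Re)/d(Si) density estimates."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.0, 3.2))
    ax.plot(report.kde_re.grid, report.kde_re.density, label="d(Re)", color="#c0392b")
    ax.plot(report.kde_si.grid, report.kde_si.density, label="d(Si)", color="#2980b9")
    ax.set_xlabel("ligand–carbene centroid distance (Å)")
    ax.set_ylabel("probability density")
    ax.set_title(
        f"predicted approach face: {report.predicted_face} "
        f"(p_re_blocked={report.p_re_blocked:.2f})"
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
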