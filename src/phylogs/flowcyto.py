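"""Genome-size estimation from 1-D flow-cytometry fluorescence histograms.

A propidium-iodide histogram from a co-chopped sample + internal-standard
preparation shows two G1 peaks: one for the sample's nuclei and one for the
standard's.  Because fluorescence is proportional to DNA amount, the sample's
2C value follows from the ratio of peak positions:

    2C_sample = (sample G1 peak mean / standard G1 peak mean) * 2C_standard

with the standard's 2C known from the literature (e.g. *Triticum aestivum*
'Chinese Spring', 2C = 30.9 pg).  The monoploid genome size is
``1Cx = 2C / ploidy``.

Peak means are located by smoothing the histogram, finding the local maximum
in each search window, and refining the position by an intensity-weighted
centroid over +/- 2 FWHM around the mode.  Peak CV is estimated as
``(FWHM / 2.355) / mean * 100`` (the Gaussian FWHM-to-sigma conversion).
A Gaussian least-squares refinement is available behind a flag as a
cross-check.  Quality-control flags follow common FCM practice: minimum
number of individuals, minimum nuclei per run, maximum peak CV, and maximum
disagreement between replicate runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FlowHistogramError",
    "PeakNotFoundError",
    "PeaksUnresolvedError",
    "FlowHistogram",
    "PeakEstimate",
    "GenomeSizeEstimate",
    "detect_g1_peaks",
    "estimate_2c",
    "monoploid_gs",
    "qc_genome_size",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # approx 2.355


class FlowHistogramError(ValueError):
    """Raised for structurally invalid histograms."""


class PeakNotFoundError(RuntimeError):
    """No local maximum above the noise floor in a search window."""


class PeaksUnresolvedError(RuntimeError):
    """The refined sample and standard peak regions overlap."""


@dataclass
class FlowHistogram:
    """Binned 1-D fluorescence intensities.

    ``channels`` must be strictly increasing integers; ``counts`` are
    non-negative with a positive total.
    """

    channels: np.ndarray
    counts: np.ndarray
    sample_label: str = ""
    standard_label: str = ""

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.channels.ndim != 1 or self.channels.shape != self.counts.shape:
            raise FlowHistogramError("channels and counts must be matching 1-D arrays")
        if np.any(np.diff(self.channels) <= 0):
            raise FlowHistogramError("channels must be strictly increasing")
        if np.any(self.counts < 0):
            raise FlowHistogramError("negative counts")
        if self.counts.sum() <= 0:
            raise FlowHistogramError("empty histogram")

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "FlowHistogram":
        """Read a ``channel,count`` CSV (header required)."""
        df = pd.read_csv(path)
        if not {"channel", "count"} <= set(df.columns):
            raise FlowHistogramError(f"{path}: expected 'channel,count' header")
        return cls(df["channel"].to_numpy(), df["count"].to_numpy(), **meta)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"channel": self.channels, "count": self.counts.astype(int)}
        ).to_csv(path, index=False)


@dataclass
class PeakEstimate:
    """A located G1 peak: refined mean channel, CV (%), and events attributed."""

    mean_channel: float
    cv_percent: float
    nuclei: int
    window: tuple[int, int] | None = None


@dataclass
class GenomeSizeEstimate:
    """Species-level 2C/1Cx estimate with replicate structure and QC flags."""

    species: str
    two_c_pg: float
    one_cx_pg: float
    replicates: list[list[float]]
    n_individuals: int
    qc_flags: list[str] = field(default_factory=list)


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    width = max(1, int(width))
    kernel = np.ones(width) / width
    return np.convolve(y, kernel, mode="same")


def _refine_peak(
    channels: np.ndarray,
    counts: np.ndarray,
    smooth: np.ndarray,
    lo: int,
    hi: int,
    noise_floor: float,
    gaussian_fit: bool,
) -> PeakEstimate:
    """Locate and refine one peak within channel window [lo, hi]."""
    mask = (channels >= lo) & (channels <= hi)
    if not mask.any():
        raise PeakNotFoundError(f"window [{lo}, {hi}] outside histogram range")
    idx = np.flatnonzero(mask)
    seg = smooth[idx]
    # local maximum above the noise floor
    k_rel = int(np.argmax(seg))
    k = idx[k_rel]
    peak_height = smooth[k]
    if peak_height <= noise_floor:
        raise PeakNotFoundError(
            f"no peak above noise floor {noise_floor:.3g} in window [{lo}, {hi}]"
        )
    # FWHM on the smoothed curve, walking out from the mode
    half = peak_height / 2.0
    left = k
    while left > 0 and smooth[left] > half:
        left -= 1
    right = k
    while right < len(smooth) - 1 and smooth[right] > half:
        right += 1
    fwhm = max(float(channels[right] - channels[left]), 1.0)

    # centroid over +/- 2 FWHM around the mode, on the raw counts
    span = 2.0 * fwhm
    c_lo = channels[k] - span
    c_hi = channels[k] + span
    cmask = (channels >= c_lo) & (channels <= c_hi)
    w = counts[cmask]
    ch = channels[cmask]
    if w.sum() <= 0:
        raise PeakNotFoundError("empty centroid region")
    mean = float(np.sum(ch * w) / np.sum(w))

    if gaussian_fit:
        def gauss(x, a, mu, sig):
            return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)

        sigma0 = fwhm / FWHM_TO_SIGMA
        try:
            popt, _ = curve_fit(
                gauss, ch, w, p0=[counts[k], mean, sigma0], maxfev=2000
            )
            mean = float(popt[1])
            fwhm = abs(float(popt[2])) * FWHM_TO_SIGMA
        except RuntimeError:  # fall back to the centroid estimate
            pass

    cv = 100.0 * (fwhm / FWHM_TO_SIGMA) / mean if mean > 0 else np.inf
    return PeakEstimate(
        mean_channel=mean,
        cv_percent=float(cv),
        nuclei=int(round(w.sum())),
        window=(int(c_lo), int(c_hi)),
    )


def detect_g1_peaks(
    hist: FlowHistogram,
    expected_regions: tuple[tuple[int, int], tuple[int, int]] | None = None,
    smooth_width: int = 5,
    noise_factor: float = 3.0,
    sample_is_higher: bool = True,
    gaussian_fit: bool = False,
) -> tuple[PeakEstimate, PeakEstimate]:
    """Locate the sample and internal-standard G1 peaks.

    ``expected_regions`` gives the (sample, standard) channel windows; in auto
    mode (``None``) the two highest smoothed local maxima are used, and the
    higher-channel peak is taken as the sample when ``sample_is_higher``
    (large-genome samples fluoresce above a smaller-genome standard).

    The noise floor is ``noise_factor`` times the median smoothed count.
    Raises :class:`PeakNotFoundError` if a window holds no peak above the
    floor and :class:`PeaksUnresolvedError` if the refined regions overlap.
    """
    smooth = _moving_average(hist.counts, smooth_width)
    noise_floor = noise_factor * float(np.median(smooth))

    if expected_regions is None:
        windows = _auto_windows(hist.channels, smooth, noise_floor, sample_is_higher)
    else:
        windows = expected_regions
    (s_lo, s_hi), (r_lo, r_hi) = windows

    sample = _refine_peak(
        hist.channels, hist.counts, smooth, s_lo, s_hi, noise_floor, gaussian_fit
    )
    standard = _refine_peak(
        hist.channels, hist.counts, smooth, r_lo, r_hi, noise_floor, gaussian_fit
    )
    a, b = sorted([sample.window, standard.window])
    if a[1] >= b[0]:
        raise PeaksUnresolvedError(
            f"refined peak regions overlap: {sample.window} vs {standard.window}"
        )
    return sample, standard


def _auto_windows(
    channels: np.ndarray,
    smooth: np.ndarray,
    noise_floor: float,
    sample_is_higher: bool,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Pick (sample, standard) windows around the two highest local maxima."""
    interior = np.arange(1, len(smooth) - 1)
    is_max = (smooth[interior] >= smooth[interior - 1]) & (
        smooth[interior] >= smooth[interior + 1]
    )
    peaks = interior[is_max & (smooth[interior] > noise_floor)]
    if len(peaks) == 0:
        raise PeakNotFoundError("no local maximum above the noise floor")
    # merge plateau runs, keep the two tallest well-separated modes
    order = peaks[np.argsort(smooth[peaks])[::-1]]
    chosen: list[int] = []
    min_sep = max(5, (channels[-1] - channels[0]) // 20)
    for k in order:
        if all(abs(channels[k] - channels[c]) > min_sep for c in chosen):
            chosen.append(k)
        if len(chosen) == 2:
            break
    if len(chosen) < 2:
        raise PeakNotFoundError("fewer than two resolvable peaks in auto mode")
    chosen.sort(key=lambda k: channels[k])
    lo_peak, hi_peak = chosen
    half = max(3, abs(channels[hi_peak] - channels[lo_peak]) // 2 - 1)
    w_lo = (int(channels[lo_peak] - half), int(channels[lo_peak] + half))
    w_hi = (int(channels[hi_peak] - half), int(channels[hi_peak] + half))
    return (w_hi, w_lo) if sample_is_higher else (w_lo, w_hi)


def estimate_2c(
    sample_peak_mean: float, standard_peak_mean: float, standard_2c_pg: float
) -> float:
    """2C genome size by the internal-standard ratio equation.

    ``2C = (sample G1 peak mean / standard G1 peak mean) * standard 2C``.
    Equal peak means return the standard's 2C exactly (calibration identity),
    and the result is invariant to a common rescaling of both peak means.
    """
    for name, v in (
        ("sample_peak_mean", sample_peak_mean),
        ("standard_peak_mean", standard_peak_mean),
        ("standard_2c_pg", standard_2c_pg),
    ):
        if not (v > 0 and np.isfinite(v)):
            raise ValueError(f"{name} must be positive and finite, got {v}")
    return sample_peak_mean / standard_peak_mean * standard_2c_pg


def monoploid_gs(two_c_pg: float, ploidy: int) -> float:
    """Monoploid genome size 1Cx = 2C / ploidy (DNA per basic chromosome set)."""
    if not (two_c_pg > 0 and np.isfinite(two_c_pg)):
        raise ValueError(f"two_c_pg must be positive, got {two_c_pg}")
    if int(ploidy) != ploidy or ploidy < 2:
        raise ValueError(f"ploidy must be an integer >= 2, got {ploidy}")
    return two_c_pg / ploidy


def qc_genome_size(
    species: str,
    per_individual: Sequence[Sequence[float]],
    nuclei_counts: Sequence[int] | None = None,
    peak_cvs: Sequence[float] | None = None,
    ploidy: int = 2,
    min_individuals: int = 5,
    min_nuclei: int = 5000,
    max_peak_cv: float = 5.0,
    max_replicate_rel_diff: float = 0.02,
) -> GenomeSizeEstimate:
    """Aggregate per-individual replicate 2C values into a species estimate.

    ``per_individual`` holds one list of replicate 2C values per individual.
    The species 2C is the unweighted mean of individual means.  QC raises
    flags (never failures) for: fewer than ``min_individuals`` individuals
    (FEW_INDIVIDUALS), any run below ``min_nuclei`` nuclei (LOW_NUCLEI), any
    peak CV above ``max_peak_cv`` percent (HIGH_CV), and any replicate pair
    differing by more than ``max_replicate_rel_diff`` relative
    (REPLICATE_DISAGREEMENT).
    """
    if not per_individual:
        raise ValueError("at least one individual required")
    flags: list[str] = []
    indiv_means = []
    for reps in per_individual:
        reps = list(reps)
        if not reps:
            raise ValueError("individual with no replicate values")
        indiv_means.append(float(np.mean(reps)))
        if len(reps) >= 2:
            rel = (max(reps) - min(reps)) / float(np.mean(reps))
            if rel > max_replicate_rel_diff:
                _add_flag(flags, "REPLICATE_DISAGREEMENT")
    if len(per_individual) < min_individuals:
        _add_flag(flags, "FEW_INDIVIDUALS")
    if nuclei_counts is not None and any(n < min_nuclei for n in nuclei_counts):
        _add_flag(flags, "LOW_NUCLEI")
    if peak_cvs is not None and any(cv > max_peak_cv for cv in peak_cvs):
        _add_flag(flags, "HIGH_CV")

    two_c = float(np.mean(indiv_means))
    return GenomeSizeEstimate(
        species=species,
        two_c_pg=two_c,
        one_cx_pg=monoploid_gs(two_c, ploidy),
        replicates=[list(map(float, reps)) for reps in per_individual],
        n_individuals=len(per_individual),
        qc_flags=flags,
    )


def _add_flag(flags: list[str], code: str) -> None:
    if code not in flags:
        flags.append(code)
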