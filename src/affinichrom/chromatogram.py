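"""Chromatogram container, text I/O, baseline estimation and peak detection.

A chromatogram is a detector trace sampled on a strictly increasing time
grid (minutes). Files are plain delimited text with two numeric columns
(time, signal), comma or tab, with an optional single header line — the
universal denominator of instrument exports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ChromatogramParseError, PeakNotFoundError, ValidationError

__all__ = [
    "Chromatogram",
    "PeakSummary",
    "read_chromatogram",
    "write_chromatogram",
    "estimate_baseline",
    "detect_apex",
    "peak_centroid",
]

#: minimum trace length for peak detection to be attempted
MIN_SAMPLES_FOR_DETECTION = 50

#: fraction of samples pooled from each end for baseline statistics
BASELINE_WINDOW_FRACTION = 0.05


@dataclass(frozen=True)
class Chromatogram:
    """A sampled detector trace with acquisition metadata.

    ``time`` is in minutes and strictly increasing; ``signal`` is the
    detector response in arbitrary absorbance units. ``meta`` may carry
    analyte label, concentration (mol/L), injection volume (L), flow
    rate (mL/min) and detection wavelength (nm).
    """

    time: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or s.ndim != 1 or t.shape != s.shape:
            raise ValidationError("time and signal must be 1-D and equal length")
        if t.size < 2:
            raise ValidationError("chromatogram needs at least two samples")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("time grid must be strictly increasing")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(s)):
            raise ValidationError("time and signal must be finite everywhere")

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class PeakSummary:
    """Apex-based summary of a single detected peak.

    ``asymmetry`` is the ratio of right to left half-width at 10% of the
    apex height; a tailing peak has asymmetry > 1.
    """

    apex_time: float
    apex_height: float
    baseline_level: float
    area: float
    asymmetry: float

    def __post_init__(self):
        if self.apex_height <= 0:
            raise ValidationError("apex height must be positive")
        if self.asymmetry <= 0:
            raise ValidationError("asymmetry must be positive")


def _sniff_delimiter(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace fallback


def read_chromatogram(
    path: str | Path,
    *,
    delimiter: str | None = None,
    time_unit: str = "minutes",
    meta: dict | None = None,
) -> Chromatogram:
    """Read a two-column delimited text chromatogram.

    Comma or tab is auto-detected from the first data line unless
    ``delimiter`` is given; a single non-numeric header line is skipped.
    ``time_unit`` may be ``"minutes"`` (default) or ``"seconds"`` —
    seconds are converted to minutes on read.

    Raises
    ------
    ChromatogramParseError
        Non-numeric row (with its 1-based line number) or empty file.
    ValidationError
        Non-monotone time grid.
    """
    path = Path(path)
    if time_unit not in ("minutes", "seconds"):
        raise ValidationError(f"unknown time unit {time_unit!r}")
    lines = path.read_text().splitlines()
    times: list[float] = []
    signals: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        text = raw.strip()
        if not text:
            continue
        sep = delimiter or _sniff_delimiter(text)
        parts = [p for p in text.split(sep) if p.strip()]
        if len(parts) < 2:
            raise ChromatogramParseError(
                f"expected two columns, got {len(parts)}", line=lineno
            )
        try:
            t, s = float(parts[0]), float(parts[1])
        except ValueError:
            if lineno == 1 and not times:
                continue  # single header line
            raise ChromatogramParseError(
                f"non-numeric row {text!r}", line=lineno
            ) from None
        times.append(t)
        signals.append(s)
    if not times:
        raise ChromatogramParseError("no numeric data rows found")
    t_arr = np.asarray(times, dtype=float)
    if time_unit == "seconds":
        t_arr = t_arr / 60.0
    return Chromatogram(time=t_arr, signal=np.asarray(signals), meta=dict(meta or {}))


def write_chromatogram(chrom: Chromatogram, path: str | Path, *, header: bool = True) -> None:
    """Write a chromatogram as comma-delimited text at full float precision."""
    path = Path(path)
    rows = []
    if header:
        rows.append("time_min,signal")
    rows.extend(f"{float(t)!r},{float(s)!r}" for t, s in zip(chrom.time, chrom.signal))
    path.write_text("\n".join(rows) + "\n")


def _baseline_windows(chrom: Chromatogram) -> np.ndarray:
    n = len(chrom)
    k = max(1, int(math.floor(BASELINE_WINDOW_FRACTION * n)))
    return np.concatenate([chrom.signal[:k], chrom.signal[-k:]])


def estimate_baseline(chrom: Chromatogram) -> float:
    """Baseline level: pooled median of the first and last 5% of samples.

    Robust and deterministic; adequate for isocratic traces where the
    peak sits inside the middle of the acquisition window.
    """
    return float(np.median(_baseline_windows(chrom)))


def _half_width_crossings(
    time: np.ndarray, corrected: np.ndarray, apex_idx: int, level: float
) -> tuple[float, float]:
    """Left and right half-widths at ``level`` via linear interpolation."""
    t_apex = time[apex_idx]
    # walk left
    i = apex_idx
    while i > 0 and corrected[i] > level:
        i -= 1
    if corrected[i] > level:  # never crossed: clamp to trace edge
        t_left = time[0]
    else:
        f = (level - corrected[i]) / (corrected[i + 1] - corrected[i])
        t_left = time[i] + f * (time[i + 1] - time[i])
    # walk right
    j = apex_idx
    last = len(time) - 1
    while j < last and corrected[j] > level:
        j += 1
    if corrected[j] > level:
        t_right = time[last]
    else:
        f = (level - corrected[j - 1]) / (corrected[j] - corrected[j - 1])
        t_right = time[j - 1] + f * (time[j] - time[j - 1])
    return t_apex - t_left, t_right - t_apex


def detect_apex(chrom: Chromatogram, *, snr_threshold: float = 5.0) -> PeakSummary:
    """Locate the main peak by its apex on the baseline-corrected trace.

    The apex is the global maximum of the baseline-subtracted signal
    (earliest sample on an exact tie). The peak must exceed
    ``snr_threshold`` times the standard deviation of the pooled
    baseline windows, else :class:`PeakNotFoundError` is raised. Area is
    trapezoidal above baseline between the first and last samples
    exceeding 1% of the apex height; asymmetry is the right/left
    half-width ratio at 10% height.
    """
    if len(chrom) < MIN_SAMPLES_FOR_DETECTION:
        raise ValidationError(
            f"need at least {MIN_SAMPLES_FOR_DETECTION} samples for peak "
            f"detection, got {len(chrom)}"
        )
    baseline = estimate_baseline(chrom)
    noise_sd = float(np.std(_baseline_windows(chrom)))
    corrected = chrom.signal - baseline
    apex_idx = int(np.argmax(corrected))  # argmax returns the first maximum
    height = float(corrected[apex_idx])
    if height <= snr_threshold * noise_sd or height <= 0:
        raise PeakNotFoundError(
            f"no peak detected: max {height:.3g} above baseline does not "
            f"exceed {snr_threshold} x baseline SD {noise_sd:.3g}"
        )

    above = np.flatnonzero(corrected > 0.01 * height)
    lo, hi = int(above[0]), int(above[-1])
    area = float(np.trapezoid(corrected[lo : hi + 1], chrom.time[lo : hi + 1]))

    left, right = _half_width_crossings(chrom.time, corrected, apex_idx, 0.10 * height)
    left = max(left, float(np.min(np.diff(chrom.time))) * 1e-6)  # guard degenerate
    asymmetry = right / left

    return PeakSummary(
        apex_time=float(chrom.time[apex_idx]),
        apex_height=height,
        baseline_level=baseline,
        area=area,
        asymmetry=asymmetry,
    )


def peak_centroid(chrom: Chromatogram, *, snr_threshold: float = 5.0) -> float:
    """Intensity-weighted centroid time of the main peak, minutes.

    Alternative retention measure to the apex: for a tailing peak the
    centroid falls later than the apex. Uses the same detection gate and
    1%-of-height integration bounds as :func:`detect_apex`.
    """
    detect_apex(chrom, snr_threshold=snr_threshold)  # gate on detectability
    baseline = estimate_baseline(chrom)
    corrected = chrom.signal - baseline
    height = float(np.max(corrected))
    above = np.flatnonzero(corrected > 0.01 * height)
    lo, hi = int(above[0]), int(above[-1])
    w = corrected[lo : hi + 1]
    t = chrom.time[lo : hi + 1]
    return float(np.trapezoid(w * t, t) / np.trapezoid(w, t))
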