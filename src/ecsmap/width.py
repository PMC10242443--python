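"""ECS width measurement from line profiles over bilevel images.

Equally spaced parallel 1-pixel-wide lines (rows or columns) are drawn across
a binarized super-resolution image in which foreground is extracellular space
(ECS).  Along each profile, every maximal run of consecutive foreground
pixels bounded by background on both sides is one peak; its width is the run
length times the pixel pitch (nm).  Runs touching either profile end are
discarded because their true extent is unknown.  Widths from all lines are
pooled into one sample per image/axis, and samples are compared with the
two-sided Mann-Whitney U test.

The default line counts mirror the imaging protocol (3 lines for
s. pyramidale, 6 split across dendritic and axonal axes for s. radiatum);
the "axis" field is a direction label (profiles along the dendritic axis
measure widths across it, and vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import BinarizedImage
from .stats import TestReport, compare_groups, summarize

__all__ = [
    "LineProfileSet",
    "WidthSample",
    "sample_line_profiles",
    "measure_peak_widths",
    "compare_width_samples",
]


@dataclass
class LineProfileSet:
    axis: str  # semantic label, e.g. "dendritic" or "axonal"
    orientation: str  # "horizontal" (rows) or "vertical" (columns)
    offsets: np.ndarray  # row/column indices of the lines
    profiles: np.ndarray  # (n_lines, length) bilevel samples
    pitch_nm: float


@dataclass
class WidthSample:
    widths_nm: np.ndarray
    region: str = ""
    condition: str = ""
    axis: str = ""

    def __post_init__(self) -> None:
        self.widths_nm = np.asarray(self.widths_nm, dtype=float)
        if self.widths_nm.size and not np.all(self.widths_nm > 0):
            raise ValueError("widths must be positive")

    @property
    def n(self) -> int:
        return int(self.widths_nm.size)


def sample_line_profiles(
    img: BinarizedImage,
    axis: str = "dendritic",
    n_lines: int = 3,
    margin: int = 10,
    orientation: str = "horizontal",
) -> LineProfileSet:
    """Extract ``n_lines`` equally spaced parallel axis-aligned profiles.

    Lines are rows (orientation="horizontal") or columns ("vertical") at
    integer offsets equally spaced between ``margin`` and ``size - margin``.
    """
    if orientation not in ("horizontal", "vertical"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    size = img.shape[0] if orientation == "horizontal" else img.shape[1]
    hi = size - margin if margin > 0 else size - 1
    if margin < 0 or hi < margin or n_lines > (hi - margin + 1):
        raise ValueError(
            f"cannot place {n_lines} lines with margin {margin} in {size} pixels"
        )
    offsets = np.unique(np.round(np.linspace(margin, hi, n_lines)).astype(int))
    if offsets.size != n_lines:
        raise ValueError("line offsets collide; reduce n_lines or margin")
    if orientation == "horizontal":
        profiles = img.data[offsets, :]
    else:
        profiles = img.data[:, offsets].T
    return LineProfileSet(
        axis=axis,
        orientation=orientation,
        offsets=offsets,
        profiles=profiles,
        pitch_nm=img.pitch_nm,
    )


def _bounded_runs(profile: np.ndarray) -> np.ndarray:
    """Lengths of foreground runs bounded by background on both sides."""
    padded = np.concatenate([[0], profile.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    lengths = ends - starts
    interior = (starts > 0) & (ends < profile.size)
    return lengths[interior]


def measure_peak_widths(
    profiles: LineProfileSet, region: str = "", condition: str = ""
) -> WidthSample:
    """Pool bounded foreground run widths (nm) from all lines of a set."""
    widths = []
    for row in profiles.profiles:
        widths.extend(_bounded_runs(np.asarray(row, dtype=bool)) * profiles.pitch_nm)
    return WidthSample(
        np.asarray(widths, dtype=float),
        region=region,
        condition=condition,
        axis=profiles.axis,
    )


def compare_width_samples(a: WidthSample, b: WidthSample) -> TestReport:
    """Two-sided Mann-Whitney U on two pooled width samples, with
    mean +/- SEM and median summaries per sample."""
    if a.n < 2 or b.n < 2:
        raise ValueError("both width samples need at least 2 values")
    label_a = a.region or a.condition or "a"
    label_b = b.region or b.condition or "b"
    if label_a == label_b:
        label_a, label_b = f"{label_a}:a", f"{label_b}:b"
    report = compare_groups(
        {label_a: a.widths_nm, label_b: b.widths_nm}, design="two_group"
    )
    report.summary = {label_a: summarize(a.widths_nm), label_b: summarize(b.widths_nm)}
    return report
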