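"""Gap-segment second-derivative pretreatment (Norris method).

Each spectrum is smoothed with a centered ``segment``-point moving average,
then the second gap-difference d2(i) = s(i-g) - 2 s(i) + s(i+g) is taken.
Constant and linear baselines are annihilated exactly; a quadratic
c*wavelength^2 on a uniform grid of step h maps to the constant 2c(gh)^2.
Edge points without a full stencil are dropped and the retained indices
are reported alongside the transformed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PretreatmentSpec", "norris_second_derivative"]


@dataclass(frozen=True)
class PretreatmentSpec:
    kind: str = "norris_d2"  # none | norris_d2
    segment: int = 5  # smoothing window, points (odd)
    gap: int = 5  # difference gap, points

    def __post_init__(self) -> None:
        if self.kind not in ("none", "norris_d2"):
            raise ValueError(f"unknown pretreatment {self.kind!r}")
        if self.segment < 1 or self.gap < 1:
            raise ValueError("segment and gap must be >= 1")
        if self.segment % 2 == 0:
            raise ValueError("segment must be odd")

    def edge_width(self) -> int:
        """Points dropped at each end of the grid."""
        return self.gap + (self.segment - 1) // 2


def norris_second_derivative(
    spectrum: np.ndarray, spec: PretreatmentSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Transform one spectrum (1-D) or a sample matrix (2-D, rows = samples).

    Returns ``(d2, retained)`` where ``retained`` holds the indices of the
    original grid the output refers to.
    """
    if spec.kind == "none":
        x = np.asarray(spectrum, dtype=float)
        return x.copy(), np.arange(x.shape[-1])
    x = np.atleast_2d(np.asarray(spectrum, dtype=float))
    n_pts = x.shape[1]
    g, s = spec.gap, spec.segment
    if n_pts <= 2 * (g + s):
        raise ValueError(
            f"spectrum of {n_pts} points too short for segment={s}, gap={g}"
        )
    kernel = np.full(s, 1.0 / s)
    half = (s - 1) // 2
    # centered moving average, valid on [half, n_pts - 1 - half]
    smooth = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="valid"), 1, x
    )
    m = smooth.shape[1]
    d2 = smooth[:, : m - 2 * g] - 2.0 * smooth[:, g : m - g] + smooth[:, 2 * g :]
    retained = np.arange(half + g, n_pts - half - g)
    if np.asarray(spectrum).ndim == 1:
        return d2[0], retained
    return d2, retained
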