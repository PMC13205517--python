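"""Canonical 68-point face template and facial region definitions.

Landmark numbering follows the iBUG 68-point annotation scheme used by
face-api.js / OpenFace (1-based in all user-facing APIs):

* jawline  1-17
* brows    18-27
* nose     28-36 (nose tip = #34)
* right eye 37-42 (image left)
* left eye  43-48 (image right)
* mouth    49-68 (outer 49-60, inner 61-68)

The template is a fixed, synthetic canonical layout in pixel coordinates
(image convention, y increasing downwards) centred at (250, 250) with an
inter-ocular distance of exactly 63 px.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 1-based landmark index of the nose tip.
NOSE_TIP = 34

#: 1-based index ranges (inclusive) for each facial region.
REGION_RANGES: dict[str, tuple[int, int]] = {
    "jawline": (1, 17),
    "brows": (18, 27),
    "nose": (28, 36),
    "right_eye": (37, 42),
    "left_eye": (43, 48),
    "mouth": (49, 68),
}


def region_indices(name: str) -> np.ndarray:
    """0-based landmark indices of a named facial region."""
    lo, hi = REGION_RANGES[name]
    return np.arange(lo - 1, hi)


@dataclass(frozen=True)
class FaceTemplate:
    """Canonical face geometry used by the simulators and topography export."""

    points: np.ndarray  # (68, 2) pixel coordinates
    regions: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: region_indices(k) for k in REGION_RANGES}
    )

    def __post_init__(self) -> None:
        if self.points.shape != (68, 2):
            raise ValueError("face template must have exactly 68 (x, y) points")

    def region_points(self, name: str) -> np.ndarray:
        return self.points[self.regions[name]]


def _ellipse(cx: float, cy: float, a: float, b: float, angles: np.ndarray) -> np.ndarray:
    return np.column_stack([cx + a * np.cos(angles), cy + b * np.sin(angles)])


def _build_points() -> np.ndarray:
    pts = np.zeros((68, 2))
    # Jawline: lower half of an ellipse, left ear to right ear through the chin.
    th = np.linspace(np.pi, 2 * np.pi, 17)
    pts[0:17] = np.column_stack([-90.0 * np.cos(th - np.pi), 25.0 + 75.0 * np.sin(th - np.pi)])
    # Brows: shallow arcs above each eye.
    bx = np.linspace(-55.0, -12.0, 5)
    pts[17:22] = np.column_stack([bx, -48.0 - 6.0 * np.sin(np.linspace(0, np.pi, 5))])
    pts[22:27] = np.column_stack([-bx[::-1], -48.0 - 6.0 * np.sin(np.linspace(0, np.pi, 5))])
    # Nose bridge (28-31) and nostril row (32-36); #34 is the central tip.
    pts[27:31] = np.column_stack([np.zeros(4), np.linspace(-30.0, 2.0, 4)])
    pts[31:36] = np.column_stack([np.linspace(-12.0, 12.0, 5), np.full(5, 12.0)])
    # Eyes: 6-point ellipses; centroids at x = ±31.5 so the IOD is exactly 63.
    eye_angles = np.array([np.pi, 2 * np.pi / 3, np.pi / 3, 0.0, -np.pi / 3, -2 * np.pi / 3])
    pts[36:42] = _ellipse(-31.5, -30.0, 12.0, 5.0, eye_angles)
    pts[42:48] = _ellipse(31.5, -30.0, 12.0, 5.0, eye_angles)
    # Mouth: outer (12) and inner (8) lips.
    pts[48:60] = _ellipse(0.0, 45.0, 25.0, 12.0, np.linspace(np.pi, 3 * np.pi, 12, endpoint=False))
    pts[60:68] = _ellipse(0.0, 45.0, 15.0, 6.0, np.linspace(np.pi, 3 * np.pi, 8, endpoint=False))
    return pts + 250.0


_POINTS = _build_points()
_POINTS.setflags(write=False)


def face_template() -> FaceTemplate:
    """Return the canonical 68-landmark face template (stable across calls)."""
    return FaceTemplate(points=_POINTS)
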