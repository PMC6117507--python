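"""Line-scan acquisition geometry: ground pixel size and square-pixel frame rate.

A push-broom camera images one cross-track line per frame; the
along-track dimension is built from platform motion. For square pixels
the frame period must match the time the platform takes to advance one
ground pixel, so the frame rate is the platform speed divided by the
cross-track ground pixel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ScanConfig", "swath_width", "ground_pixel_size", "frame_rate"]


@dataclass(frozen=True)
class ScanConfig:
    """Geometry of a line-scan acquisition.

    fov: full field of view of the lens, degrees (< 180);
    distance: lens-to-target distance, m; cross_track_pixels: pixels per
    scan line; speed: platform speed, m/s.
    """

    fov: float
    distance: float
    cross_track_pixels: int
    speed: float

    def __post_init__(self) -> None:
        if not (0.0 < self.fov < 180.0):
            raise ValueError("fov must be in (0, 180) degrees")
        if self.distance <= 0 or self.speed <= 0 or self.cross_track_pixels <= 0:
            raise ValueError("distance, speed and pixel count must be positive")


def swath_width(cfg: ScanConfig) -> float:
    """Ground width covered by one scan line: 2 d tan(fov/2), meters."""
    return 2.0 * cfg.distance * math.tan(math.radians(cfg.fov) / 2.0)


def ground_pixel_size(cfg: ScanConfig) -> float:
    """Cross-track ground size of one pixel, meters."""
    return swath_width(cfg) / cfg.cross_track_pixels


def frame_rate(cfg: ScanConfig) -> tuple[float, int]:
    """Frame rate giving square ground pixels (aspect ratio 1:1).

    Returns ``(exact, rounded)`` frames per second; at the exact rate
    the along-track pixel length equals the cross-track pixel size, and
    the rounded integer is the value to program into the camera.
    """
    exact = cfg.speed / ground_pixel_size(cfg)
    return exact, int(round(exact))
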