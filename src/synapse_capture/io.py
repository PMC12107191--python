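"""Image-stack container and TIFF/CSV I/O helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = ["MovieStack"]


@dataclass
class MovieStack:
    """A single-channel time-lapse stack.

    ``pixels`` has shape (frames, rows, cols); ``pixel_size`` is um/px,
    ``frame_interval`` seconds per frame and ``channel`` a free-text label
    (e.g. ``"bound"`` for membrane-bound Atto550 antigen, ``"internalized"``
    for unquenched Atto647N).
    """

    pixels: np.ndarray
    pixel_size: float
    frame_interval: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (frames, rows, cols)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def frame_time(self, frame: int) -> float:
        """Acquisition time of a frame, s from the start of the movie."""
        return frame * self.frame_interval

    def write_tiff(self, path) -> None:
        tifffile.imwrite(
            path,
            np.asarray(self.pixels, np.float32),
            metadata={
                "axes": "TYX",
                "pixel_size_um": self.pixel_size,
                "frame_interval_s": self.frame_interval,
                "channel": self.channel,
            },
        )

    @classmethod
    def read_tiff(
        cls, path, pixel_size: float, frame_interval: float, channel: str = ""
    ) -> "MovieStack":
        return cls(
            pixels=tifffile.imread(path),
            pixel_size=pixel_size,
            frame_interval=frame_interval,
            channel=channel,
        )
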