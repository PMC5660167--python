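"""Single-channel 8-bit raster container and TIFF I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ChannelImage:
    """One 8-bit grayscale raster for one fluorescence channel.

    Parameters
    ----------
    data
        2-D uint8 array, row-major, 0-based pixel coordinates.
    channel
        Channel name; by convention one of ``"DAPI"``, ``"S830"``,
        ``"LAMININ"``.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    """

    data: np.ndarray
    channel: str
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"channel image must be 2-D, got shape {self.data.shape}")
        if self.data.dtype != np.uint8:
            if self.data.min() < 0 or self.data.max() > 255:
                raise ValueError("image intensities outside [0, 255] cannot be 8-bit")
            self.data = self.data.astype(np.uint8)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def write_tiff(self, path: str | Path) -> None:
        """Write as a single-page 8-bit grayscale TIFF."""
        tifffile.imwrite(
            str(path),
            self.data,
            photometric="minisblack",
            resolution=(1.0 / self.pixel_size_um, 1.0 / self.pixel_size_um),
            resolutionunit="NONE",
        )

    @classmethod
    def read_tiff(
        cls, path: str | Path, channel: str, pixel_size_um: float = 1.0
    ) -> "ChannelImage":
        data = tifffile.imread(str(path))
        if data.ndim == 3 and data.shape[0] == 1:
            data = data[0]
        return cls(data=data, channel=channel, pixel_size_um=pixel_size_um)
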