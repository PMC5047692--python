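"""Multi-channel image stacks with physical voxel sizes.

The :class:`ImageStack` is the common currency of every imaging operation in
the pipeline: a ``(C, Z, Y, X)`` array of fluorescence intensities plus the
in-plane pixel size and the axial z-step, both in micrometres.  All
micrometre/pixel conversions go through :func:`um_to_px` / :func:`px_to_um`
so that no operation hard-codes a pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError


def um_to_px(value_um: float, pixel_size_um: float) -> float:
    """Convert a physical length to (fractional) pixels."""
    if pixel_size_um <= 0:
        raise ParameterError("pixel_size_um must be strictly positive")
    return value_um / pixel_size_um


def px_to_um(value_px: float, pixel_size_um: float) -> float:
    """Convert a pixel length to micrometres."""
    if pixel_size_um <= 0:
        raise ParameterError("pixel_size_um must be strictly positive")
    return value_px * pixel_size_um


@dataclass
class ImageStack:
    """Multi-channel 3D voxel grid with physical voxel sizes.

    Parameters
    ----------
    voxels
        Array of shape ``(n_channels, n_z, n_y, n_x)``.
    channel_names
        One name per channel (e.g. ``["HRP", "SYT", "GS2"]``).
    pixel_size_um
        In-plane (x = y) pixel size in µm.
    z_step_um
        Axial step between optical sections in µm.
    """

    voxels: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    pixel_size_um: float = 0.1
    z_step_um: float = 0.2

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ParameterError(
                f"voxels must be 4D (C, Z, Y, X); got shape {self.voxels.shape}"
            )
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ParameterError(
                "channel_names length must equal the number of channels "
                f"({len(self.channel_names)} names, {self.voxels.shape[0]} channels)"
            )
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be strictly positive")
        if self.z_step_um <= 0:
            raise ParameterError("z_step_um must be strictly positive")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"unknown channel {channel!r}; available: {self.channel_names}"
            ) from None

    def channel(self, channel: str) -> np.ndarray:
        """Return the ``(Z, Y, X)`` sub-stack of one named channel."""
        return self.voxels[self.channel_index(channel)]


def max_project(stack: ImageStack, channel: str) -> tuple[np.ndarray, float]:
    """Maximum projection of one channel along z.

    Returns the per-pixel maximum over the z axis — the 2D representation the
    fragmentation and puncta scorers operate on — together with the in-plane
    pixel size in µm.
    """
    sub = stack.channel(channel)
    return sub.max(axis=0), stack.pixel_size_um
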