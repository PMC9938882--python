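"""Multi-channel image container and TIFF I/O.

Coordinate convention (shared by the whole package): pixel centers sit at
integer coordinates, the origin is the top-left pixel center, ``x`` runs
rightward along columns and ``y`` downward along rows.  Arrays are indexed
``data[channel, y, x]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

ROLES = ("cis", "tgn", "poi")


class ChannelRoleError(KeyError):
    """A required channel role (cis / tgn / poi) is missing or unknown."""


@dataclass
class MultiChannelImage:
    """A 2D fluorescence image with named channels and physical pixel size.

    Parameters
    ----------
    data : ndarray, shape (n_channels, height, width)
        Per-channel intensities (photons or arbitrary units).
    channels : tuple of str
        Channel names, e.g. ``("GM130", "TGN38", "AP1")``.
    pixel_size_nm : float
        Physical size of one pixel in nanometres; required for any
        distance reported in nm.
    roles : dict
        Mapping from role (``"cis"``, ``"tgn"``, ``"poi"``) to channel name.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    pixel_size_nm: float
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (C, H, W), got shape {self.data.shape}")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} planes"
            )
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")
        for role, name in self.roles.items():
            if role not in ROLES:
                raise ChannelRoleError(f"unknown role {role!r}; expected one of {ROLES}")
            if name not in self.channels:
                raise ChannelRoleError(f"role {role!r} maps to unknown channel {name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise ChannelRoleError(f"no channel named {name!r}; have {self.channels}")

    def channel_for_role(self, role: str) -> np.ndarray:
        if role not in self.roles:
            raise ChannelRoleError(
                f"image has no channel assigned to role {role!r}; roles={self.roles}"
            )
        return self.channel(self.roles[role])

    def require_roles(self) -> None:
        missing = [r for r in ROLES if r not in self.roles]
        if missing:
            raise ChannelRoleError(f"missing channel role(s): {missing}")

    # ------------------------------------------------------------------ I/O

    def to_tiff(self, path: str | Path) -> None:
        """Write one page per channel; names, roles and pixel size go into
        the image description as JSON."""
        meta = {
            "channels": list(self.channels),
            "pixel_size_nm": self.pixel_size_nm,
            "roles": self.roles,
        }
        tifffile.imwrite(
            str(path),
            np.asarray(self.data, dtype=np.float32),
            description=json.dumps(meta),
            photometric="minisblack",
        )

    @classmethod
    def from_tiff(cls, path: str | Path) -> "MultiChannelImage":
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        if data.ndim == 2:
            data = data[None]
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            raise ValueError(
                f"{path}: TIFF lacks the JSON metadata (channels, pixel_size_nm) "
                "this package writes; cannot convert distances to nm"
            )
        return cls(
            data=data,
            channels=tuple(meta["channels"]),
            pixel_size_nm=float(meta["pixel_size_nm"]),
            roles=dict(meta.get("roles", {})),
        )
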