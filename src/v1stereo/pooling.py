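"""Robust-averaging combination of per-channel disparity maps.

Each pixel is pooled independently across the channel maps: the mean of the
remaining channel values is computed, the value farthest from that mean is
removed, and the process repeats until half the values (``ceil(n/2)``
survivors) remain; the pooled estimate is the survivors' mean.  This trims
channels whose coarse-to-fine chain locked onto a false match while keeping
the consensus of the majority.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .search import ChannelDisparityMap


@dataclass(frozen=True)
class DisparityMap:
    """Final per-pixel disparity estimate with a validity mask."""

    disparity: np.ndarray = field(repr=False)
    valid_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.disparity.shape != self.valid_mask.shape:
            raise ValueError("disparity and valid_mask shapes differ")
        if not np.isfinite(self.disparity[self.valid_mask]).all():
            raise ValueError("disparity is non-finite inside the valid region")

    @property
    def shape(self) -> tuple[int, int]:
        return self.disparity.shape


def _as_arrays(maps: Sequence[ChannelDisparityMap | np.ndarray]) -> np.ndarray:
    arrays = [m.disparity if isinstance(m, ChannelDisparityMap) else np.asarray(m, dtype=float)
              for m in maps]
    if len(arrays) < 2:
        raise ValueError("pooling needs at least 2 maps")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all maps must share the same dimensions")
    return np.stack(arrays)


def robust_average(maps: Sequence[ChannelDisparityMap | np.ndarray],
                   method: str = "iterative") -> DisparityMap:
    """Pool channel disparity maps into the final map.

    ``method="iterative"`` (default) is the iterative farthest-from-mean
    removal described above; ties in the farthest distance remove the value
    from the lowest-indexed channel (deterministic).  ``method="median"`` is
    an optional per-pixel median baseline.

    The output at each pixel lies within [min, max] of that pixel's
    surviving values, hence within the range of the inputs.
    """
    values = _as_arrays(maps)  # (n, H, W)
    n = values.shape[0]
    if method == "median":
        pooled = np.median(values, axis=0)
    elif method == "iterative":
        keep = (n + 1) // 2  # ceil(n/2) survivors
        flat = values.reshape(n, -1)
        alive = np.ones_like(flat, dtype=bool)
        cols = np.arange(flat.shape[1])
        for _ in range(n - keep):
            count = alive.sum(axis=0)
            mean = np.where(alive, flat, 0.0).sum(axis=0) / count
            dist = np.where(alive, np.abs(flat - mean[None]), -1.0)
            worst = dist.argmax(axis=0)  # first (lowest channel) at ties
            alive[worst, cols] = False
        pooled = (np.where(alive, flat, 0.0).sum(axis=0)
                  / alive.sum(axis=0)).reshape(values.shape[1:])
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    return DisparityMap(disparity=pooled,
                        valid_mask=np.ones(values.shape[1:], dtype=bool))
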