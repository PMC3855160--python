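"""End-to-end disparity estimation: preprocess, filter, search, pool."""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .energy import StereoPair, preprocess
from .filterbank import build_frequency_grid
from .pooling import DisparityMap, robust_average
from .search import ChannelDisparityMap, run_coarse_to_fine


def estimate_disparity(left: np.ndarray, right: np.ndarray,
                       config: RunConfig | None = None
                       ) -> tuple[DisparityMap, list[ChannelDisparityMap]]:
    """Estimate the disparity map of a rectified stereo pair.

    Both images are mean-subtracted, filtered with the configured bank, the
    coarse-to-fine extremum search produces one map per (orientation,
    scale) channel, and robust averaging pools them into the final map.
    Returns ``(final_map, channel_maps)``.
    """
    config = config or RunConfig()
    pair = StereoPair(left=preprocess(left), right=preprocess(right))
    h, w = pair.shape
    grid = build_frequency_grid(w, h)
    maps = run_coarse_to_fine(pair, config.make_bank(), grid,
                              config.hypotheses(), rf_window=config.rf_window,
                              smooth_px=config.energy_smoothing_px)
    final = robust_average(maps, method=config.pooling_method)
    return final, maps
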