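"""Disparity-map quality metrics and batch Monte-Carlo evaluation.

Two metrics, both computed over valid pixels only (a border of ``border``
pixels on every side is excluded, since circular filtering contaminates the
image rim):

* ``B`` — bad-pixel percentage: the share of pixels whose absolute
  disparity error strictly exceeds a threshold (0.25 px for synthetic
  stereograms, 1 px for real-world pairs);
* ``R`` — root-mean-squared disparity error in pixels.

``batch_evaluate`` runs the full generation -> estimation -> scoring loop
over many seeded stereograms and reports the replicate means.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .pooling import DisparityMap

#: Default synthetic-stimulus border: the largest default filter wavelength
#: (3 * 1.6**3 = 12.288 px) rounded up.
DEFAULT_BORDER_PX = 13
DEFAULT_THRESHOLD_PX = 0.25

#: Real-world parameterization (external stereo pairs).
REAL_WORLD_BORDER_PX = 18
REAL_WORLD_THRESHOLD_PX = 1.0


@dataclass(frozen=True)
class EvalResult:
    """Metrics of one disparity map (or means over replicates)."""

    bad_percent: float
    rmse: float
    threshold: float
    border: int
    n_valid: int

    def to_dict(self) -> dict:
        return asdict(self)


def _valid_and_error(est, truth, border: int) -> np.ndarray:
    est_arr = est.disparity if isinstance(est, DisparityMap) else np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est_arr.shape != truth.shape:
        raise ValueError(f"estimate shape {est_arr.shape} != truth shape {truth.shape}")
    if border < 0:
        raise ValueError("border must be nonnegative")
    h, w = est_arr.shape
    mask = np.zeros((h, w), dtype=bool)
    if h - 2 * border > 0 and w - 2 * border > 0:
        mask[border:h - border, border:w - border] = True
    if isinstance(est, DisparityMap):
        mask &= est.valid_mask
    if not mask.any():
        raise ValueError(f"border {border} px leaves no valid pixels in {h}x{w}")
    err = np.abs(est_arr - truth)
    return err[mask]


def bad_pixel_rate(est, truth, threshold: float = DEFAULT_THRESHOLD_PX,
                   border: int = DEFAULT_BORDER_PX) -> float:
    """Percentage of valid pixels whose |error| strictly exceeds threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    err = _valid_and_error(est, truth, border)
    return 100.0 * float(np.count_nonzero(err > threshold)) / err.size


def rmse(est, truth, border: int = DEFAULT_BORDER_PX) -> float:
    """Root-mean-squared disparity error (pixels) over valid pixels."""
    err = _valid_and_error(est, truth, border)
    return float(np.sqrt(np.mean(err ** 2)))


def evaluate_map(est, truth, threshold: float = DEFAULT_THRESHOLD_PX,
                 border: int = DEFAULT_BORDER_PX) -> EvalResult:
    err = _valid_and_error(est, truth, border)
    return EvalResult(
        bad_percent=100.0 * float(np.count_nonzero(err > threshold)) / err.size,
        rmse=float(np.sqrt(np.mean(err ** 2))),
        threshold=threshold, border=border, n_valid=int(err.size))


def batch_evaluate(kind: str, n_reps: int, seed: int, config=None
                   ) -> tuple[EvalResult, pd.DataFrame]:
    """Mean metrics of the full pipeline over ``n_reps`` seeded stereograms.

    Stereogram ``i`` uses seed ``seed + i``; the run configuration (filter
    family, bank parameters, hypothesis step, border, threshold) comes from
    ``config`` (a :class:`~v1stereo.config.RunConfig`), defaulting to the
    family's standard parameters with the kind-appropriate step.  Returns
    the replicate-mean :class:`EvalResult` plus a per-replicate table with
    columns (kind, seed, family, B, R).
    """
    from .config import RunConfig
    from .pipeline import estimate_disparity

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = (config or RunConfig()).for_kind(kind)
    records = []
    for i in range(n_reps):
        sg_seed = seed + i
        from .stereogram import make_stereogram
        sg = make_stereogram(kind, sg_seed, density=config.dot_density)
        final, _ = estimate_disparity(sg.left, sg.right, config)
        res = evaluate_map(final, sg.truth, threshold=config.bad_pixel_threshold,
                           border=config.border_px)
        records.append({"kind": kind, "seed": sg_seed, "family": config.family,
                        "B": res.bad_percent, "R": res.rmse})
    table = pd.DataFrame.from_records(records)
    n_valid = res.n_valid  # identical across replicates of one kind
    mean = EvalResult(bad_percent=float(table["B"].mean()),
                      rmse=float(table["R"].mean()),
                      threshold=config.bad_pixel_threshold,
                      border=config.border_px, n_valid=n_valid)
    return mean, table
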