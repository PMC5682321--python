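"""ROI time-series containers and windowing.

The resting-state analysis operates on multivoxel BOLD matrices grouped
under named regions of interest (ROIs).  Before any causality estimation
the raw series are trimmed — a fixed number of leading scan volumes is
discarded to avoid start-up transients and the last ``keep_last`` volumes
are retained — and partitioned into contiguous, non-overlapping, equal
windows described by a :class:`WindowingScheme`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, LengthError

__all__ = ["ROITimeSeries", "WindowingScheme", "prepare_series"]


@dataclass
class ROITimeSeries:
    """Voxel-by-time BOLD matrix for one named ROI.

    Parameters
    ----------
    roi_name
        Label of the region (e.g. ``"L-Thalamus"``).
    voxel_ids
        0-based integer voxel coordinates, one triple per row of ``data``.
    data
        Array of shape ``(n_voxels, n_timepoints)`` in arbitrary BOLD-like
        units.
    tr_seconds
        Repetition time of the acquisition, in seconds.
    """

    roi_name: str
    voxel_ids: list[tuple[int, int, int]]
    data: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"ROI {self.roi_name!r}: data must be 2-D (voxels x time)")
        if len(self.voxel_ids) != self.data.shape[0]:
            raise ValueError(
                f"ROI {self.roi_name!r}: {len(self.voxel_ids)} voxel ids for "
                f"{self.data.shape[0]} rows"
            )
        if self.data.shape[1] < 20:
            raise LengthError(
                f"ROI {self.roi_name!r}: need >= 20 timepoints, got {self.data.shape[1]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"ROI {self.roi_name!r}: non-finite values in data")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowingScheme:
    """Contiguous, non-overlapping, equal-length analysis windows.

    ``start_indices`` are 0-based offsets into the *trimmed* series (after
    ``discard_leading`` volumes were dropped and the last ``keep_last``
    retained).
    """

    window_length: int
    n_windows: int
    start_indices: tuple[int, ...] = field(default=())
    discard_leading: int = 0

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.n_windows < 1:
            raise ConfigurationError("window_length and n_windows must be positive")
        if self.discard_leading < 0:
            raise ConfigurationError("discard_leading must be non-negative")
        if not self.start_indices:
            object.__setattr__(
                self,
                "start_indices",
                tuple(i * self.window_length for i in range(self.n_windows)),
            )
        starts = self.start_indices
        if len(starts) != self.n_windows:
            raise ConfigurationError("start_indices length must equal n_windows")
        for a, b in zip(starts, starts[1:]):
            if b - a != self.window_length:
                raise ConfigurationError("windows must be contiguous and equal length")

    @property
    def total_length(self) -> int:
        return self.window_length * self.n_windows

    def slices(self) -> list[slice]:
        return [slice(s, s + self.window_length) for s in self.start_indices]


def prepare_series(
    raw: np.ndarray,
    discard_leading: int,
    keep_last: int,
    n_windows: int,
) -> tuple[np.ndarray, WindowingScheme]:
    """Trim a raw series and build its windowing scheme.

    The leading ``discard_leading`` timepoints are removed (start-up
    transients) and the last ``keep_last`` of the remainder retained, then
    divided into ``n_windows`` contiguous equal windows.  With the default
    resting-state protocol (210 volumes at TR = 2 s) this yields 208
    retained points in four windows of 52.

    Parameters
    ----------
    raw
        1-D series or 2-D (channels x time) matrix.
    discard_leading, keep_last, n_windows
        Trimming and partition parameters; ``keep_last`` must be divisible
        by ``n_windows``.

    Returns
    -------
    (trimmed, scheme)
        ``trimmed`` has exactly ``keep_last`` columns.
    """
    raw = np.asarray(raw, dtype=float)
    squeeze = raw.ndim == 1
    mat = raw[None, :] if squeeze else raw
    if mat.ndim != 2:
        raise ValueError("raw must be 1-D or 2-D")
    n_total = mat.shape[1]
    if n_windows < 1:
        raise ConfigurationError("n_windows must be positive")
    if keep_last % n_windows != 0:
        raise ConfigurationError(
            f"keep_last={keep_last} is not divisible by n_windows={n_windows}"
        )
    if n_total < discard_leading + keep_last:
        raise LengthError(
            f"series has {n_total} timepoints; need >= {discard_leading + keep_last}"
        )
    after_discard = mat[:, discard_leading:]
    trimmed = after_discard[:, after_discard.shape[1] - keep_last:]
    scheme = WindowingScheme(
        window_length=keep_last // n_windows,
        n_windows=n_windows,
        discard_leading=discard_leading,
    )
    return (trimmed[0] if squeeze else trimmed), scheme
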