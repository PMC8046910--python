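"""Canonical haemodynamic response function and event regressors.

The double-gamma shape uses the standard constants (response peak 6 s,
undershoot peak 16 s, dispersions 1 s, peak:undershoot ratio 6) and is
normalised to unit peak so that an event of amplitude ``a`` contributes a
BOLD excursion of ``a`` at its peak.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma


def canonical_hrf(dt_s: float, duration_s: float = 32.0,
                  peak_delay_s: float = 6.0, undershoot_delay_s: float = 16.0,
                  peak_disp_s: float = 1.0, undershoot_disp_s: float = 1.0,
                  ratio: float = 6.0) -> np.ndarray:
    """Sample the canonical double-gamma HRF on a grid of step ``dt_s``.

    Returns the response at times 0, dt, 2*dt, ..., normalised to peak 1.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    h = (gamma.pdf(t, peak_delay_s / peak_disp_s, scale=peak_disp_s)
         - gamma.pdf(t, undershoot_delay_s / undershoot_disp_s,
                     scale=undershoot_disp_s) / ratio)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate HRF parameters")
    return h / peak


def event_regressor(frame_times_s: np.ndarray, onsets_s: np.ndarray,
                    durations_s: np.ndarray, oversampling: int = 16,
                    tr_s: float | None = None) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at the given frame times.

    Boxcars are built on a fine grid (``tr_s / oversampling``), convolved
    with the canonical HRF, and linearly interpolated at ``frame_times_s``.
    """
    frame_times_s = np.asarray(frame_times_s, dtype=float)
    onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    durations_s = np.broadcast_to(np.asarray(durations_s, dtype=float),
                                  onsets_s.shape)
    if tr_s is None:
        tr_s = float(np.median(np.diff(frame_times_s))) if frame_times_s.size > 1 else 2.0
    dt = tr_s / oversampling
    t_end = max(frame_times_s.max(), (onsets_s + durations_s).max()) + 40.0
    fine_t = np.arange(0.0, t_end, dt)
    boxcar = np.zeros_like(fine_t)
    for on, dur in zip(onsets_s, durations_s):
        boxcar[(fine_t >= on) & (fine_t < on + dur)] = 1.0
    h = canonical_hrf(dt)
    conv = np.convolve(boxcar, h)[: fine_t.size] * dt
    return np.interp(frame_times_s, fine_t, conv)
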