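"""Canonical double-gamma hemodynamic response function and task regressors.

The canonical HRF is the difference of two gamma densities: a response
peaking ~6 s after stimulus onset and an undershoot peaking ~16 s, with a
peak/undershoot amplitude ratio of 6. Condition regressors are built by
placing unit-height boxcars for each event on a fine time grid (0.1 s),
convolving with the HRF, and sampling at the acquisition times (multiples
of TR).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import gamma as _gamma

log = logging.getLogger(__name__)

# canonical double-gamma parameterization (the convention shared
# by the major neuroimaging packages):
# shape 6 response, shape 16 undershoot, unit scale, ratio 6
_PEAK_SHAPE = 6.0
_UNDER_SHAPE = 16.0
_RATIO = 6.0
_DT = 0.1          # s, fine grid used for convolution
_HRF_LEN_S = 32.0  # s, support kept for the kernel


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Evaluate the canonical HRF at times ``t`` (seconds), peak-normalized."""
    t = np.asarray(t, dtype=float)
    h = _gamma.pdf(t, _PEAK_SHAPE) - _gamma.pdf(t, _UNDER_SHAPE) / _RATIO
    h = np.where(t < 0, 0.0, h)
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def condition_regressors(design) -> np.ndarray:
    """HRF-convolved regressors for every condition of a design.

    Returns an (n_timepoints, n_conditions) array sampled at multiples of
    TR, columns ordered as ``design.conditions``. Overlapping events within
    one condition add up (logged, not an error).
    """
    n_t = design.n_timepoints
    run_len = n_t * design.tr
    n_fine = int(np.ceil(run_len / _DT)) + 1
    fine_t = np.arange(n_fine) * _DT
    kernel = double_gamma_hrf(np.arange(0.0, _HRF_LEN_S, _DT))

    cols = []
    for cond in design.conditions:
        box = np.zeros(n_fine)
        for onset, duration in design.events.get(cond, []):
            i0 = int(round(onset / _DT))
            i1 = int(round((onset + duration) / _DT))
            i1 = max(i1, i0 + 1)  # instantaneous events still get one bin
            box[i0:min(i1, n_fine)] += 1.0
        if (box > 1).any():
            log.info("condition %r has overlapping events; boxcars summed", cond)
        conv = np.convolve(box, kernel)[:n_fine] * _DT
        peak = np.abs(conv).max()
        if peak > 0:
            conv = conv / peak  # peak-normalized: betas are response amplitudes
        sample_idx = np.round(np.arange(n_t) * design.tr / _DT).astype(int)
        cols.append(conv[np.minimum(sample_idx, n_fine - 1)])
    return np.column_stack(cols) if cols else np.zeros((n_t, 0))
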