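"""Numba inner loops for echo synthesis and delay-and-sum beamforming.

These kernels are the hot paths of the simulate -> reconstruct pipeline;
everything else in the package is plain NumPy/SciPy.  Slow, obviously
correct NumPy references for both kernels live in the test suite and act
as oracles.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def born_deposit(rf, tt, dd, refl, pulse, fs, t0, eps_mm):
    """Accumulate single-scattering echoes into ``rf`` in place.

    Parameters
    ----------
    rf : (ntx, nrx, nt) float32
        Output echo tensor.
    tt : (n_el, nsc) float64
        One-way travel time element -> scatterer, seconds.
    dd : (n_el, nsc) float64
        Element -> scatterer distance, mm (for geometric spreading).
    refl : (nsc,) float64
        Scatterer reflectivities.
    pulse : (np_,) float64
        Excitation samples at rate ``fs``.
    fs, t0 : float
        Sampling rate (Hz) and time of the first sample (s).
    eps_mm : float
        Spreading regularizer (mm), typically one grid step.
    """
    ntx, nrx, nt = rf.shape
    nsc = refl.shape[0]
    npulse = pulse.shape[0]
    for tx in range(ntx):
        for rx in range(nrx):
            trace = rf[tx, rx]
            for s in range(nsc):
                tau = tt[tx, s] + tt[rx, s] - t0
                amp = refl[s] / (np.sqrt(dd[tx, s] * dd[rx, s]) + eps_mm)
                pos = tau * fs
                i0 = int(np.floor(pos))
                frac = pos - i0
                for k in range(npulse):
                    j = i0 + k
                    if 0 <= j < nt - 1:
                        v = amp * pulse[k]
                        trace[j] += (1.0 - frac) * v
                        trace[j + 1] += frac * v


@njit(cache=True, fastmath=True)
def direct_deposit(rf, t_pair, d_pair, pulse, fs, t0, eps_mm):
    """Add the transmitter -> receiver direct arrival to every trace."""
    ntx, nrx, nt = rf.shape
    npulse = pulse.shape[0]
    for tx in range(ntx):
        for rx in range(nrx):
            trace = rf[tx, rx]
            tau = t_pair[tx, rx] - t0
            amp = 1.0 / (np.sqrt(d_pair[tx, rx]) + eps_mm)
            pos = tau * fs
            i0 = int(np.floor(pos))
            frac = pos - i0
            for k in range(npulse):
                j = i0 + k
                if 0 <= j < nt - 1:
                    v = amp * pulse[k]
                    trace[j] += (1.0 - frac) * v
                    trace[j + 1] += frac * v


@njit(cache=True, fastmath=True)
def das_sum(rf_re, rf_im, t_px, fs, t0, use_pair, out_re, out_im, out_pow):
    """Full-matrix delay-and-sum of the analytic echo tensor.

    ``t_px`` holds one-way travel times (s) from each element to each
    image pixel; a trace sample is fetched at the two-way time with
    linear interpolation, out-of-range delays contribute zero.
    ``out_pow`` accumulates the per-pair sample power (for optional
    coherence-factor weighting).
    """
    ntx, nrx, nt = rf_re.shape
    npx = t_px.shape[1]
    for tx in range(ntx):
        for rx in range(nrx):
            if not use_pair[tx, rx]:
                continue
            tre = rf_re[tx, rx]
            tim = rf_im[tx, rx]
            for p in range(npx):
                pos = (t_px[tx, p] + t_px[rx, p] - t0) * fs
                i0 = int(np.floor(pos))
                if 0 <= i0 < nt - 1:
                    f = pos - i0
                    sr = (1.0 - f) * tre[i0] + f * tre[i0 + 1]
                    si = (1.0 - f) * tim[i0] + f * tim[i0 + 1]
                    out_re[p] += sr
                    out_im[p] += si
                    out_pow[p] += sr * sr + si * si
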