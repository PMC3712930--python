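"""EMG preprocessing: notch filtering, trial RMS, MVC normalization, channel merging.

The pipeline reduces each 3-second isometric trial to a single scalar per
muscle: the signal is notch-filtered at the mains frequency, summarized by
its full-window RMS, normalized by the RMS recorded during that muscle's
maximum voluntary contraction (MVC), and the radial/ulnar wrist extensor
and flexor channels are averaged into single ECR/U and FCR/U channels.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .datatypes import CHANNELS7, CHANNELS9
from .exceptions import ParameterError, SchemaError


def notch_filter(x: np.ndarray, fs: float, f0: float = 60.0, q: float = 30.0) -> np.ndarray:
    """Remove mains interference with a zero-phase second-order IIR notch.

    Applied forward-backward (``filtfilt``) so the passband is phase-neutral;
    RMS summaries are unaffected by the (doubled) notch attenuation outside
    a ~2 Hz band around ``f0``.

    Parameters
    ----------
    x : sample series (1-D) or (n_samples, n_channels) array.
    fs : sampling rate in Hz; must exceed ``2 * f0``.
    f0 : notch center frequency in Hz (default 60).
    q : quality factor of the notch (default 30, i.e. 2 Hz bandwidth at 60 Hz).
    """
    if fs <= 2.0 * f0:
        raise ParameterError(f"sampling rate {fs} Hz must exceed twice the notch frequency {f0} Hz")
    x = np.asarray(x, dtype=float)
    b, a = sps.iirnotch(f0, q, fs=fs)
    return sps.filtfilt(b, a, x, axis=0)


def bandpass_filter(x: np.ndarray, fs: float, low: float = 20.0, high: float = 500.0,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass (default 20-500 Hz).

    Acquisition hardware already bandpasses real recordings; this is applied
    to synthetic raw signals so they share the same spectral support.  The
    upper edge is capped just below Nyquist when ``high`` reaches it.
    """
    if fs <= 2.0 * low:
        raise ParameterError("sampling rate too low for the requested passband")
    x = np.asarray(x, dtype=float)
    high = min(high, 0.99 * fs / 2.0)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def trial_rms(x: np.ndarray) -> float:
    """Root-mean-square of a trial signal over its entire window."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ParameterError("cannot compute RMS of an empty signal")
    return float(np.sqrt(np.mean(np.square(x))))


def normalize_mvc(rms: float, mvc_rms: float) -> float:
    """Normalize a trial RMS by the muscle's MVC RMS.

    Values above 1 are retained: activations can exceed the maximal-trial
    reference, notably for paretic extensors whose MVC is itself depressed.
    """
    if mvc_rms <= 0:
        raise ParameterError("MVC RMS must be positive; channel unusable for normalization")
    return float(rms) / float(mvc_rms)


def mvc_reference(maximal_trial_signals: list[np.ndarray]) -> float:
    """MVC RMS for one electrode: the max trial RMS over all maximal maneuvers."""
    if not maximal_trial_signals:
        raise ParameterError("need at least one maximal-contraction trial")
    return max(trial_rms(s) for s in maximal_trial_signals)


def merge_wrist_channels(values9: np.ndarray) -> np.ndarray:
    """Merge the 9 raw channels into the canonical 7 by averaging wrist pairs.

    ECR/U = (ECR + ECU) / 2 and FCR/U = (FCR + FCU) / 2; the five hand
    channels pass through unchanged.  Input must follow the canonical
    9-channel order ``THE, FDI, HTH, EDC, FDS, ECR, ECU, FCR, FCU``.
    """
    values9 = np.asarray(values9, dtype=float)
    if values9.shape[-1] != len(CHANNELS9):
        raise SchemaError(f"expected {len(CHANNELS9)} channels, got {values9.shape[-1]}")
    out = np.empty(values9.shape[:-1] + (len(CHANNELS7),), dtype=float)
    out[..., :5] = values9[..., :5]
    out[..., 5] = 0.5 * (values9[..., 5] + values9[..., 6])   # ECR/U
    out[..., 6] = 0.5 * (values9[..., 7] + values9[..., 8])   # FCR/U
    return out


def process_raw_trial(signals9: np.ndarray, mvc_rms9: np.ndarray, fs: float = 1000.0,
                      apply_bandpass: bool = False) -> np.ndarray:
    """Full chain: raw 9-channel trial signals -> 7-channel activation vector.

    ``signals9`` is (n_samples, 9); ``mvc_rms9`` the per-electrode MVC RMS
    references.  Notch filter, full-window RMS, MVC normalization, then
    wrist-channel merging.
    """
    signals9 = np.asarray(signals9, dtype=float)
    if signals9.ndim != 2 or signals9.shape[1] != len(CHANNELS9):
        raise SchemaError("signals9 must be (n_samples, 9)")
    mvc_rms9 = np.asarray(mvc_rms9, dtype=float)
    if mvc_rms9.shape != (len(CHANNELS9),):
        raise SchemaError("mvc_rms9 must have 9 entries")
    x = signals9
    if apply_bandpass:
        x = bandpass_filter(x, fs)
    x = notch_filter(x, fs)
    rms9 = np.sqrt(np.mean(np.square(x), axis=0))
    norm9 = np.array([normalize_mvc(r, m) for r, m in zip(rms9, mvc_rms9)])
    return merge_wrist_channels(norm9)
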