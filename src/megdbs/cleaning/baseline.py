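"""Per-channel log-power baseline correction for cleaned spectra.

tSSS shifts the broadband power level of every channel (it reconstructs the
interior field and drops part of the sensor noise), which inflates the
band-power error against the reference even where the artefacts are gone.
The correction subtracts, per channel, the mean log10-power offset between
the cleaned and the reference spectrum over 15-125 Hz (excluding the line
bands at 49-51 and 99-101 Hz) from the cleaned log spectrum at all
frequencies.
"""

from __future__ import annotations

import numpy as np

from ..spectral import SpectrumEstimate


def baseline_correct(clean_spec: SpectrumEstimate, ref_spec: SpectrumEstimate,
                     fmin: float = 15.0, fmax: float = 125.0,
                     exclude=((49.0, 51.0), (99.0, 101.0))) -> SpectrumEstimate:
    """Align each channel's broadband log10 power with the reference."""
    if clean_spec.freqs.shape != ref_spec.freqs.shape or not np.allclose(
            clean_spec.freqs, ref_spec.freqs):
        raise ValueError("spectra have different frequency axes")
    f = clean_spec.freqs
    mask = (f >= fmin) & (f <= fmax)
    for lo, hi in exclude:
        mask &= ~((f >= lo) & (f <= hi))
    if not mask.any():
        raise ValueError("baseline band covers no frequency bins")
    delta = np.mean(np.log10(clean_spec.power[:, mask])
                    - np.log10(ref_spec.power[:, mask]), axis=1)
    factor = 10.0 ** (-delta)[:, None]
    per_win = clean_spec.per_window_power
    if per_win is not None:
        per_win = per_win * factor[..., None]
    return clean_spec.copy_with_power(clean_spec.power * factor,
                                      per_window_power=per_win)
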