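"""Published summary tables from the ten-day droplet-microfluidics study
of single-cell *Neurospora crassa* circadian oscillators.

The raw image data of the original experiments are not distributed; these
are the printed summary statistics the analysis operates on directly —
per-droplet-size period statistics, the singleton-ensemble periodogram
ANOVA components, and the reported oscillator-summary correlations.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

__all__ = [
    "load_period_by_droplet_size",
    "periodogram_anova_components",
    "reported_correlations",
    "GOODNESS_OF_FIT",
]


def load_period_by_droplet_size() -> pd.DataFrame:
    """Mean and variance of single-cell oscillator periods (h^2 for the
    variance) by cells-per-droplet a = 1..20, at the primary and secondary
    periodogram harmonics, for the reference strain."""
    with importlib.resources.files("dropclock.data").joinpath(
        "period_by_droplet_size.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def periodogram_anova_components() -> dict:
    """Harmonic-ANOVA components of the 868-singleton average periodogram
    over 170 time points: five model frequencies (2 df each, SS scaled so
    the total is 1) and the error row."""
    return {
        "freqs_per_h": np.array([0.0353, 0.0471, 0.0575, 0.0706, 0.0824]),
        "periods_h": np.array([28.0, 21.0, 17.0, 14.0, 12.0]),
        "ss_model": np.array([0.045225, 0.150372, 0.160925, 0.104017, 0.067837]),
        "ss_error": 0.471624,
        "df_error": 160,
        "n_points": 170,
    }


def reported_correlations() -> dict:
    """Pearson correlations among per-cell amplitude, period and phase of
    868 singleton oscillators."""
    return {
        "amplitude_period": 0.1095,
        "phase_period": -0.1986,
        "amplitude_phase": -0.1226,
    }


#: chi-squared fit of the stochastic-model average periodogram to the
#: observed singleton average periodogram: (chi2, df)
GOODNESS_OF_FIT = (130.231, 137)
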