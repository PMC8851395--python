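"""Published Kolmogorov–Smirnov screening p-values for the UCI alcoholism EEG study.

Six channel-subset experiments on the SMNI_CMI train/test archives screened
the ten spectrum statistics (control vs. alcoholic) with a two-sample KS
test, once within the testing archive and once within the training archive.
The printed p-value pairs are bundled here as inputs for replaying the
accept/reject decision rule; the decisions and acceptance rates themselves
are always recomputed by :mod:`alcoeeg.ks_selection`.

Keys follow :data:`alcoeeg.coveig.STAT_NAMES`; each value is
``(p_test, p_train)``.
"""

from __future__ import annotations

__all__ = ["CHANNEL_EXPERIMENTS", "FINAL_FEATURE_SET"]

#: experiment index (1-6) -> statistic -> (p_test, p_train)
CHANNEL_EXPERIMENTS = {
    1: {
        "mean": (0.1088, 0.2003),
        "maximum": (0.46, 0.342),
        "median": (0.0017, 2.9480e-09),
        "minimum": (0.011, 0.02),
        "mode": (0.011, 0.02),
        "range": (1.7552e-05, 0.034),
        "skewness": (0.1088, 0.94),
        "kurtosis": (0.1, 0.93),
        "standard_deviation": (2.0212e-04, 0.01088),
        "variance": (1.7552e-05, 0.02003),
    },
    2: {
        "mean": (5.5870e-08, 0.02585),
        "maximum": (2.0480e-09, 0.00455),
        "median": (1.7973e-14, 3.5202e-10),
        "minimum": (1.4977e-13, 0.00165),
        "mode": (1.4977e-13, 0.00165),
        "range": (2.0480e-09, 2.6199e-07),
        "skewness": (0.10875, 0.935),
        "kurtosis": (0.045, 6.1578e-04),
        "standard_deviation": (0.00465, 0.045),
        "variance": (1.1088e-08, 0.00165),
    },
    3: {
        "mean": (0.055, 0.3420),
        "maximum": (0.0259, 0.0017),
        "median": (0.0113, 1.7552e-05),
        "minimum": (1.1615e-12, 5.6313e-11),
        "mode": (1.1615e-12, 5.6313e-11),
        "range": (0.05, 0.0113),
        "skewness": (0.2003, 0.76),
        "kurtosis": (0.5372, 0.9360),
        "standard_deviation": (6.1578e-04, 0.011),
        "variance": (0.0113, 0.002),
    },
    4: {
        "mean": (0.34, 0.2),
        "maximum": (0.53, 0.20),
        "median": (0.002, 0.005),
        "minimum": (0.06, 0.2003),
        "mode": (0.06, 0.2003),
        "range": (0.012, 0.0017),
        "skewness": (0.8, 0.54),
        "kurtosis": (0.026, 0.0259),
        "standard_deviation": (0.005, 0.0046),
        "variance": (6.1578e-04, 0.005),
    },
    5: {
        "mean": (6.1740e-05, 0.012),
        # the source prints a training p of 0.109 for this row while marking
        # it Accepted and stating a 40% rate — inconsistent with the joint
        # p <= 0.05 rule every other row obeys; presumed misprint of 0.0109
        "maximum": (2.0212e-04, 0.0109),
        "median": (1.7973e-14, 0.03),
        "minimum": (0.34, 0.9),
        "mode": (0.34, 0.9),
        "range": (2.0212e-04, 0.005),
        "skewness": (0.55, 0.54),
        "kurtosis": (0.93, 0.4),
        "standard_deviation": (0.76, 0.46),
        "variance": (0.1088, 0.01),
    },
    6: {
        "mean": (0.045, 0.0446),
        "maximum": (0.3420, 0.1088),
        "median": (6.1740e-05, 1.7973e-14),
        "minimum": (1.4977e-13, 0.026),
        "mode": (1.4977e-13, 0.026),
        "range": (0.011, 0.03),
        "skewness": (0.1, 0.76),
        "kurtosis": (0.046, 0.034),
        "standard_deviation": (0.00238, 0.01),
        "variance": (0.0476, 0.02),
    },
}

#: the study's final retained statistic types (the 61-channel screen's accepts)
FINAL_FEATURE_SET = frozenset(
    {
        "mean",
        "median",
        "minimum",
        "mode",
        "range",
        "kurtosis",
        "standard_deviation",
        "variance",
    }
)
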