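"""Shared fixtures: fast synthetic cohorts and a result-table fixture
encoding the study's printed per-bin ratios."""

from __future__ import annotations

import numpy as np
import pytest

from nmrbin.binning import BinSpec, bin_cohort
from nmrbin.simulate import CohortDesign, default_signature_library, simulate_cohort
from nmrbin.types import BinTestResult

# Printed per-bin HSC/LSC ratios and significance tiers of the study's
# metabolite table (week 14, week 22). Multi-bin metabolites whose
# bin-level ratios are not printed carry their metabolite-level value on
# every bin, so the mean is preserved.
TABLE1_BIN_ROWS = [
    # (bin, ratio14, q14, ratio22, q22)
    ("7.93", 1.53, 0.50, 1.41, 0.07),
    ("1.52", 0.76, 0.50, 0.78, 0.07),
    ("0.88", 0.65, 0.50, 0.75, 0.07),
    ("2.18", 0.81, 0.50, 0.86, 0.07),
    ("1.06", 0.73, 0.01, 0.73, 0.01),
    ("5.64", 1.15, 0.50, 4.76, 0.01),
    ("5.63", 1.15, 0.50, 4.76, 0.01),
    ("5.62", 1.15, 0.50, 4.76, 0.01),
    ("0.84", 0.84, 0.50, 1.37, 0.07),
    ("5.94", 2.27, 0.07, 1.36, 0.50),
    ("6.13", 2.27, 0.07, 1.36, 0.50),
    ("6.12", 2.27, 0.07, 1.36, 0.50),
    ("6.11", 2.27, 0.07, 1.36, 0.50),
    ("7.89", 2.27, 0.07, 1.36, 0.50),
    ("7.86", 2.27, 0.07, 1.36, 0.50),
    ("0.77", 0.64, 0.50, 1.54, 0.07),
    ("0.76", 0.64, 0.50, 1.54, 0.07),
    ("0.75", 0.64, 0.50, 1.54, 0.07),
    ("0.74", 0.64, 0.50, 1.54, 0.07),
    ("0.73", 0.64, 0.50, 1.54, 0.07),
    ("6.65", 0.80, 0.50, 0.62, 0.07),
    ("7.82", 0.80, 0.50, 0.62, 0.07),
    ("7.68", 0.80, 0.50, 0.62, 0.07),
    ("7.49", 0.80, 0.50, 0.62, 0.07),
]


def _result(bin_label, week, ratio, q):
    return BinTestResult(
        bin_label=bin_label,
        week=week,
        ratio_hsc_lsc=ratio,
        log2_effect=float(np.log2(ratio)),
        t_stat=0.0,
        df=10.0,
        p_raw=min(q, 1.0),
        q_fdr=q,
        tier="lt_0.05" if q < 0.05 else ("lt_0.1" if q < 0.1 else "ns"),
    )


@pytest.fixture(scope="session")
def table1_bin_results() -> list[BinTestResult]:
    out = []
    for b, r14, q14, r22, q22 in TABLE1_BIN_ROWS:
        out.append(_result(b, "14", r14, q14))
        out.append(_result(b, "22", r22, q22))
    return out


@pytest.fixture(scope="session")
def fast_design() -> CohortDesign:
    """Default study conditions at reduced spectral sampling (8 points per
    bin instead of 64) so cohort-level tests stay fast; n, noise, CV and
    planted ratios are the defaults."""
    return CohortDesign(points_per_bin=8, seed=20240538)


@pytest.fixture(scope="session")
def fast_cohort(fast_design):
    return simulate_cohort(fast_design)


@pytest.fixture(scope="session")
def fast_binned(fast_cohort, fast_design):
    spectra, meta, truth = fast_cohort
    matrix = bin_cohort(spectra, fast_design.bin_spec())
    return matrix, meta, truth


@pytest.fixture(scope="session")
def library():
    return default_signature_library()


@pytest.fixture
def default_binspec() -> BinSpec:
    return BinSpec()
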