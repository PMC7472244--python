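"""Method-agreement statistics for comparing a wearable-sensor method
against a reference system: RMSE, MAPE with a four-tier classification,
within-band time percentage (E10), Bland–Altman limits of agreement with
a conditional log transform, and paired difference tests.

Sign convention (documented prominently because Bland–Altman conventions
vary): differences are **reference − test**, so a positive bias means the
test method *underestimates* the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

__all__ = [
    "PairedMeasures",
    "AgreementReport",
    "TimeSeriesPair",
    "rmse_mape",
    "classify_mape",
    "e10",
    "align_timeseries",
    "bland_altman",
    "paired_difference_test",
    "agreement_report",
]

NORMALITY_ALPHA = 0.05

# MAPE agreement tiers; boundaries are inclusive on the left class:
# <=5 excellent, (5, 10] good, (10, 15] acceptable, >15 unacceptable.
_MAPE_TIERS = ((5.0, "excellent"), (10.0, "good"), (15.0, "acceptable"))


@dataclass
class PairedMeasures:
    """Paired per-observation values of the test and reference method."""

    test: np.ndarray
    reference: np.ndarray
    measure: str = ""
    units: str = ""
    groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.test = np.asarray(self.test, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.test.shape != self.reference.shape or self.test.ndim != 1:
            raise ValueError("test and reference must be equal-length 1-D arrays")
        if np.any(~np.isfinite(self.test)) or np.any(~np.isfinite(self.reference)):
            raise ValueError("paired measures contain non-finite values; drop incomplete pairs first")

    @property
    def n(self) -> int:
        return self.test.size


@dataclass
class TimeSeriesPair:
    """Reference and test angle traces on a common 100 Hz base."""

    time: np.ndarray
    reference: np.ndarray
    test: np.ndarray
    offset_samples: int = 0
    rate_hz: float = 100.0


@dataclass
class AgreementReport:
    measure: str
    units: str
    n: int
    rmse: float
    mape_mean: float
    mape_sd: float
    mape_class: str
    bias: float
    loa_lower: float
    loa_upper: float
    log_transformed: bool
    normality_p: float
    test_name: str
    p_value: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def classify_mape(mape: float) -> str:
    """Four-tier agreement class of a MAPE value (percent)."""
    if not np.isfinite(mape) or mape < 0:
        raise ValueError("MAPE must be a finite non-negative percentage")
    for bound, label in _MAPE_TIERS:
        if mape <= bound:
            return label
    return "unacceptable"


def rmse_mape(pairs: PairedMeasures) -> dict:
    """RMSE and MAPE (mean ± SD across observations) with the tier class.

    Pairs whose reference value is zero are excluded from MAPE (undefined)
    with a warning; RMSE uses all pairs.
    """
    if pairs.n < 2:
        raise ValueError("need at least two paired observations")
    err = pairs.test - pairs.reference
    rmse = float(np.sqrt(np.mean(err**2)))
    nonzero = pairs.reference != 0
    if not nonzero.all():
        warnings.warn(f"{int((~nonzero).sum())} pairs with zero reference excluded from MAPE", stacklevel=2)
    if not nonzero.any():
        raise ValueError("MAPE undefined: all reference values are zero")
    ape = np.abs(err[nonzero]) / np.abs(pairs.reference[nonzero]) * 100.0
    mape = float(ape.mean())
    sd = float(ape.std(ddof=1)) if ape.size > 1 else 0.0
    return {"rmse": rmse, "mape_mean": mape, "mape_sd": sd, "mape_class": classify_mape(mape)}


def e10(pair: TimeSeriesPair, rom_ref: float, band_fraction: float = 0.10) -> float:
    """Percentage of time the test error stays within ±band_fraction of the
    reference range of motion (inclusive at the boundary)."""
    if rom_ref <= 0:
        raise ValueError("reference ROM must be positive")
    err = np.abs(pair.test - pair.reference)
    band = band_fraction * rom_ref
    return 100.0 * float(np.count_nonzero(err <= band)) / err.size


def _resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased rational-ratio resampling."""
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator, padtype="line")


def align_timeseries(
    reference: np.ndarray,
    test: np.ndarray,
    ref_rate_hz: float = 100.0,
    test_rate_hz: float = 1125.0,
) -> TimeSeriesPair:
    """Resample the test trace to the reference rate and synchronize on the
    point of maximum flexion, cropping to the overlap.

    Both traces must contain an interior maximum (a flexion peak); monotone
    ramps are rejected.  The recovered offset (samples at the reference
    rate, positive = test lags) is exposed for audit.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.size < 3 or tst.size < 3:
        raise ValueError("traces too short to align")
    test_rs = _resample_to(tst, test_rate_hz, ref_rate_hz) if test_rate_hz != ref_rate_hz else tst.copy()
    i_ref = int(np.argmax(ref))
    i_tst = int(np.argmax(test_rs))
    if i_ref in (0, ref.size - 1) or i_tst in (0, test_rs.size - 1):
        raise ValueError("no interior flexion maximum; cannot synchronize")
    offset = i_tst - i_ref
    if offset >= 0:
        test_al = test_rs[offset:]
        ref_al = ref.copy()
    else:
        test_al = test_rs
        ref_al = ref[-offset:]
    m = min(ref_al.size, test_al.size)
    t = np.arange(m) / ref_rate_hz
    return TimeSeriesPair(time=t, reference=ref_al[:m], test=test_al[:m], offset_samples=offset, rate_hz=ref_rate_hz)


def bland_altman(pairs: PairedMeasures, alpha: float = NORMALITY_ALPHA) -> dict:
    """Bland–Altman bias and 95% limits of agreement (bias ± 1.96 SD).

    Differences are reference − test (positive bias = test underestimates).
    Normality of the differences is gated by Shapiro–Wilk; on failure the
    analysis is recomputed on log-transformed values (unitless differences
    log ref − log test), flagged in the output.
    """
    if pairs.n < 3:
        raise ValueError("Bland–Altman needs at least three pairs")
    d = pairs.reference - pairs.test
    if np.allclose(d, d[0]):
        p_norm = 1.0  # constant differences: trivially no evidence against normality
    else:
        p_norm = float(stats.shapiro(d).pvalue)
    log_flag = False
    if p_norm < alpha:
        if np.any(pairs.reference <= 0) or np.any(pairs.test <= 0):
            raise ValueError(
                "differences are non-normal but values are not strictly positive; log transform impossible"
            )
        d = np.log(pairs.reference) - np.log(pairs.test)
        log_flag = True
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "loa_lower": bias - 1.96 * sd,
        "loa_upper": bias + 1.96 * sd,
        "log_transformed": log_flag,
        "normality_p": p_norm,
    }


def paired_difference_test(a, b, alpha: float = NORMALITY_ALPHA) -> dict:
    """Paired t-test, or Wilcoxon signed-rank when differences are non-normal.

    Identical inputs (zero-variance differences) are reported as an exact
    tie: t-test with p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need equal-length 1-D samples with n >= 3")
    d = a - b
    if np.allclose(d, 0.0):
        return {"test_name": "paired t-test", "p_value": 1.0}
    if np.allclose(d, d[0]):
        normal = True  # constant nonzero shift: Shapiro undefined, treat as normal
    else:
        normal = float(stats.shapiro(d).pvalue) >= alpha
    if normal:
        res = stats.ttest_rel(a, b)
        return {"test_name": "paired t-test", "p_value": float(res.pvalue)}
    res = stats.wilcoxon(a, b, zero_method="wilcox")
    return {"test_name": "wilcoxon signed-rank", "p_value": float(res.pvalue)}


def agreement_report(pairs: PairedMeasures) -> AgreementReport:
    """Full per-measure agreement suite combined into one report."""
    em = rmse_mape(pairs)
    ba = bland_altman(pairs)
    pt = paired_difference_test(pairs.test, pairs.reference)
    return AgreementReport(
        measure=pairs.measure,
        units=pairs.units,
        n=pairs.n,
        rmse=em["rmse"],
        mape_mean=em["mape_mean"],
        mape_sd=em["mape_sd"],
        mape_class=em["mape_class"],
        bias=ba["bias"],
        loa_lower=ba["loa_lower"],
        loa_upper=ba["loa_upper"],
        log_transformed=ba["log_transformed"],
        normality_p=ba["normality_p"],
        test_name=pt["test_name"],
        p_value=pt["p_value"],
    )
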