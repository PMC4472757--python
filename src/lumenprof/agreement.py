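"""Cross-modality agreement: regression, correlation and Bland-Altman.

Paired per-vessel mean lumen areas from two modalities (e.g. in vivo CT vs
histology) are compared three ways: ordinary least squares of modality A on
modality B with Pearson's r and its two-sided t-test p-value; Bland-Altman
bias and 1.96-SD limits of agreement on the paired differences; and the
same regression repeated within each time point.  The regression direction
(CT as response on histology) matches the convention of plotting the imaging
readout against the reference method; it is configurable by swapping inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "regress",
    "bland_altman",
    "per_timepoint_correlation",
    "agreement_analysis",
    "plot_agreement",
]


@dataclass
class PairedMeasurements:
    """Per-vessel paired means from two modalities, with labels."""

    modality_a: np.ndarray      # e.g. micro-CT lumen area, mm^2
    modality_b: np.ndarray      # e.g. histology lumen area, mm^2
    vessel_id: list | None = None
    side: list | None = None
    timepoint_days: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.modality_a = np.asarray(self.modality_a, dtype=float)
        self.modality_b = np.asarray(self.modality_b, dtype=float)
        if self.modality_a.shape != self.modality_b.shape or self.modality_a.ndim != 1:
            raise ValueError("modalities must be matching 1-D arrays")
        if len(self.modality_a) < 2:
            raise ValueError("need at least two paired measurements")
        if np.any(self.modality_a <= 0) or np.any(self.modality_b <= 0):
            raise ValueError("areas must be positive")
        if self.timepoint_days is not None:
            self.timepoint_days = np.asarray(self.timepoint_days)
            if len(self.timepoint_days) != len(self.modality_a):
                raise ValueError("timepoint labels must match the pairs")

    def __len__(self) -> int:
        return len(self.modality_a)


@dataclass
class AgreementResult:
    """Regression + Bland-Altman summary for one set of pairs."""

    slope: float
    intercept: float
    r: float
    p_two_sided: float
    bias: float
    loa_low: float
    loa_high: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "p": self.p_two_sided,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
        }


def regress(pairs: PairedMeasurements) -> tuple[float, float, float, float]:
    """OLS of modality A on modality B: (slope, intercept, r, p).

    r is Pearson's correlation; p is the two-sided t-test on r with n-2
    degrees of freedom.  Requires n >= 3 and non-zero predictor variance.
    """
    if len(pairs) < 3:
        raise ValueError("regression needs at least three pairs")
    x, y = pairs.modality_b, pairs.modality_a
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor modality")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)


def bland_altman(pairs: PairedMeasurements) -> tuple[float, float, float]:
    """Bias and 1.96-SD limits of agreement of the paired differences.

    Differences are A - B; the limits are bias -/+ 1.96 times the sample SD
    (ddof=1) and are expected to cover ~95% of differences under normality.
    """
    d = pairs.modality_a - pairs.modality_b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def per_timepoint_correlation(pairs: PairedMeasurements) -> pd.DataFrame:
    """Regression repeated within each time point group.

    Groups with fewer than three pairs or a constant predictor are skipped
    with a warning, mirroring how undersized cohorts are dropped from
    correlation panels.
    """
    if pairs.timepoint_days is None:
        raise ValueError("pairs carry no timepoint labels")
    rows = []
    for tp in pd.unique(pairs.timepoint_days):
        sel = pairs.timepoint_days == tp
        sub = PairedMeasurements(
            modality_a=pairs.modality_a[sel], modality_b=pairs.modality_b[sel]
        )
        if len(sub) < 3:
            warnings.warn(
                f"timepoint {tp}: only {len(sub)} pairs, skipped", UserWarning, stacklevel=2
            )
            continue
        if np.ptp(sub.modality_b) == 0:
            warnings.warn(
                f"timepoint {tp}: zero predictor variance, skipped", UserWarning, stacklevel=2
            )
            continue
        slope, intercept, r, p = regress(sub)
        rows.append(
            {"timepoint_days": tp, "slope": slope, "intercept": intercept, "r": r, "p": p, "n": len(sub)}
        )
    return pd.DataFrame(rows, columns=["timepoint_days", "slope", "intercept", "r", "p", "n"])


def agreement_analysis(pairs: PairedMeasurements) -> AgreementResult:
    """Combined regression + Bland-Altman summary."""
    slope, intercept, r, p = regress(pairs)
    bias, lo, hi = bland_altman(pairs)
    return AgreementResult(
        slope=slope, intercept=intercept, r=r, p_two_sided=p,
        bias=bias, loa_low=lo, loa_high=hi, n=len(pairs),
    )


def plot_agreement(pairs: PairedMeasurements, out_path, labels=("micro-CT", "histology")):
    """Scatter-with-fit and Bland-Altman panels saved to ``out_path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    slope, intercept, r, p = regress(pairs)
    bias, lo, hi = bland_altman(pairs)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    x, y = pairs.modality_b, pairs.modality_a
    ax1.scatter(x, y, s=18, color="tab:blue")
    xs = np.linspace(x.min(), x.max(), 50)
    ax1.plot(xs, slope * xs + intercept, color="tab:red", lw=1.2)
    ax1.set_xlabel(f"{labels[1]} lumen area (mm$^2$)")
    ax1.set_ylabel(f"{labels[0]} lumen area (mm$^2$)")
    ax1.set_title(f"slope={slope:.2f}, r={r:.2f}, p={p:.2g}")
    mean = (x + y) / 2
    diff = y - x
    ax2.scatter(mean, diff, s=18, color="tab:blue")
    for yy, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax2.axhline(yy, color="tab:red", ls=style, lw=1.0)
    ax2.set_xlabel("mean of methods (mm$^2$)")
    ax2.set_ylabel(f"{labels[0]} - {labels[1]} (mm$^2$)")
    ax2.set_title(f"bias={bias:.3f} [{lo:.3f}, {hi:.3f}]")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
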