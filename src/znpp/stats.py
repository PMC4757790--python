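"""Method-comparison statistics for device-vs-reference ZnPP measurements.

The pipeline the clinical evaluation uses: (1) scale the instrument's
arbitrary-unit readings to reference (HPLC) units with a robust
zero-offset proportional fit; (2) Bland-Altman agreement with robust limits
of agreement, 1.96 x the Maronna-Zamar tau-estimate of scale of the paired
differences, with percentile-bootstrap confidence intervals; (3) ROC
(Youden) optimal cutpoint and contingency-table diagnostics against the
50-umol/mol iron-deficiency classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "DiagnosticResult",
    "robust_proportional_slope",
    "scale_to_reference",
    "tau_location_scale",
    "tau_scale",
    "robust_bland_altman",
    "loa_ci_halfwidth_factor",
    "roc_optimal_cutpoint",
    "diagnostic_metrics_from_counts",
    "diagnostic_metrics_from_rates",
    "classify_iron_status",
    "IronStatus",
    "bland_altman_plot",
]

_BISQUARE_C = 4.685
_TAU_C1 = 4.5
_TAU_C2 = 3.0
# Normal-consistency constant of the tau-scale: E[min(Z^2, b^2)] with
# b = c2 * qnorm(3/4), because c1/c2 cut on the raw (unscaled) MAD.
_TAU_B = _TAU_C2 * norm.ppf(0.75)
_TAU_CONSISTENCY = float(
    2.0 * ((1.0 - _TAU_B**2) * norm.cdf(_TAU_B) - _TAU_B * norm.pdf(_TAU_B) + _TAU_B**2)
    - 1.0
)


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-subject device and reference values (common subjects, same order)."""

    device: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.device, dtype=float)
        r = np.asarray(self.reference, dtype=float)
        if d.shape != r.shape or d.ndim != 1 or d.size < 3:
            raise ValueError("paired data must be equal-length 1-D arrays, n >= 3")
        if not (np.isfinite(d).all() and np.isfinite(r).all()):
            raise ValueError("paired data must be finite")
        object.__setattr__(self, "device", d)
        object.__setattr__(self, "reference", r)

    def __len__(self) -> int:
        return int(self.device.size)


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    loa: float
    ci_bias: tuple[float, float] | None
    ci_loa: tuple[float, float] | None
    n_boot: int
    seed: int | None


@dataclass(frozen=True)
class DiagnosticResult:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float | None = None
    counts: tuple[int, int, int, int] | None = None  # (tp, fp, fn, tn)
    youden_j: float | None = None


def robust_proportional_slope(paired: PairedMeasurements) -> float:
    """Slope of a zero-offset straight line, robust to gross outliers.

    M-type iteratively reweighted least squares with Tukey bisquare weights
    (tuning 4.685), residual scale 1.4826 x median absolute residual,
    starting from the median of the per-subject ratios.  Deterministic;
    at most 50 iterations, tolerance 1e-8.
    """
    dev, ref = paired.device, paired.reference
    if np.all(ref == 0):
        raise ValueError("reference values are all zero")
    nz = ref != 0
    b = float(np.median(dev[nz] / ref[nz]))
    for _ in range(50):
        r = dev - b * ref
        s = 1.4826 * float(np.median(np.abs(r)))
        if s == 0:
            break
        u = r / (_BISQUARE_C * s)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        denom = float(np.sum(w * ref * ref))
        if denom == 0:
            break
        b_new = float(np.sum(w * dev * ref) / denom)
        if abs(b_new - b) <= 1e-8 * max(1.0, abs(b)):
            b = b_new
            break
        b = b_new
    return b


def scale_to_reference(paired: PairedMeasurements) -> PairedMeasurements:
    """Rescale the device values to reference units (divide by the slope)."""
    slope = robust_proportional_slope(paired)
    if slope == 0:
        raise ValueError("degenerate zero slope; cannot scale")
    return PairedMeasurements(paired.device / slope, paired.reference)


def tau_location_scale(values) -> tuple[float, float]:
    """Maronna-Zamar tau-estimates of location and scale (c1=4.5, c2=3.0).

    Location: bisquare-weighted mean around the median, weights on
    (x - median)/(c1 * s0) with s0 the raw median absolute deviation.
    Scale: s0 * sqrt(mean(min(u^2, c2^2)) / k), u = (x - tau-location)/s0,
    where k is the normal-consistency constant E[min(Z^2, (c2*qnorm(3/4))^2)]
    so the estimate is consistent for the s.d. under normality.  Constant
    input returns scale 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("tau estimates need n >= 2")
    med = float(np.median(x))
    xabs = np.abs(x - med)
    s0 = float(np.median(xabs))  # raw MAD; consistency handled by k
    if s0 == 0:
        return med, 0.0
    u = xabs / (_TAU_C1 * s0)
    w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    mu = float(np.sum(w * x) / np.sum(w))
    rho = np.minimum(((x - mu) / s0) ** 2, _TAU_C2**2)
    tau = s0 * math.sqrt(float(rho.mean()) / _TAU_CONSISTENCY)
    return mu, tau


def tau_scale(values) -> float:
    """Robust s.d.: the tau-estimate of scale (normal-consistent)."""
    return tau_location_scale(values)[1]


def robust_bland_altman(
    paired: PairedMeasurements,
    n_boot: int = 2000,
    seed: int | None = None,
) -> AgreementResult:
    """Robust Bland-Altman agreement between device and reference.

    Differences d = device - reference; bias = tau-location(d); limits of
    agreement = 1.96 x tau-scale(d).  Percentile-bootstrap 95% CIs for both
    (seeded); with n < 5 the point estimates are returned without CIs.
    """
    d = paired.device - paired.reference
    bias, scale = tau_location_scale(d)
    loa = 1.96 * scale
    if len(paired) < 5:
        return AgreementResult(bias, loa, None, None, 0, seed)
    rng = np.random.default_rng(seed)
    boots_bias = np.empty(n_boot)
    boots_loa = np.empty(n_boot)
    n = d.size
    for i in range(n_boot):
        sample = d[rng.integers(0, n, n)]
        b_mu, b_s = tau_location_scale(sample)
        boots_bias[i] = b_mu
        boots_loa[i] = 1.96 * b_s
    ci_bias = tuple(np.percentile(boots_bias, [2.5, 97.5]))
    ci_loa = tuple(np.percentile(boots_loa, [2.5, 97.5]))
    return AgreementResult(bias, loa, ci_bias, ci_loa, n_boot, seed)


def loa_ci_halfwidth_factor(n: int) -> float:
    """Approximate 95%-CI half-width of limits of agreement, as a multiple
    of the s.d. of the differences: 1.96 * sqrt(3/n).  n = 56 gives ~0.45."""
    if n < 2:
        raise ValueError("need n >= 2")
    return 1.96 * math.sqrt(3.0 / n)


def roc_optimal_cutpoint(scores, labels) -> DiagnosticResult:
    """Youden-optimal threshold: maximise sens + spec - 1 over all midpoints
    between adjacent distinct scores; ties broken toward higher specificity
    (the larger threshold).  Positive prediction is score > threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best = None
    for thr in candidates:
        pred = s > thr
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        fn = n_pos - tp
        tn = n_neg - fp
        sens = tp / n_pos
        spec = tn / n_neg
        j = sens + spec - 1.0
        # ties toward higher specificity = larger threshold; candidates are
        # scanned in increasing order so >= keeps the later (larger) one
        if best is None or j >= best[0] - 1e-12:
            if best is None or j > best[0] + 1e-12 or spec >= best[1].specificity:
                best = (j, _from_counts(tp, fp, fn, tn, thr, j))
    return best[1]


def _from_counts(tp, fp, fn, tn, threshold=None, youden=None) -> DiagnosticResult:
    n = tp + fp + fn + tn
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return DiagnosticResult(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        threshold=threshold,
        counts=(tp, fp, fn, tn),
        youden_j=youden if youden is not None else sens + spec - 1.0,
    )


def diagnostic_metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> DiagnosticResult:
    """Sensitivity/specificity/PPV/NPV from a 2x2 contingency table."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    return _from_counts(tp, fp, fn, tn)


def diagnostic_metrics_from_rates(
    sensitivity: float, specificity: float, prevalence: float
) -> DiagnosticResult:
    """Predictive values from (sens, spec, prevalence) via Bayes' identity."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    p, q = prevalence, 1.0 - prevalence
    pos = sensitivity * p + (1.0 - specificity) * q
    neg = (1.0 - sensitivity) * p + specificity * q
    ppv = sensitivity * p / pos if pos > 0 else float("nan")
    npv = specificity * q / neg if neg > 0 else float("nan")
    return DiagnosticResult(
        sensitivity=sensitivity, specificity=specificity, ppv=ppv, npv=npv
    )


@dataclass(frozen=True)
class IronStatus:
    deficient: bool
    indeterminate_zone: bool
    value: float
    cutoff: float


def classify_iron_status(znpp_value: float, cutoff: float = 50.0) -> IronStatus:
    """Functional iron deficiency: strictly above the cutoff (default
    50 umol ZnPP per mol haem).  Values in 40-50 are additionally flagged as
    the indeterminate zone, where elevations do not necessarily indicate
    iron deficiency."""
    if not math.isfinite(znpp_value):
        raise ValueError("ZnPP value must be finite")
    deficient = znpp_value > cutoff
    indeterminate = (not deficient) and (cutoff - 10.0 <= znpp_value <= cutoff)
    return IronStatus(deficient, indeterminate, znpp_value, cutoff)


def bland_altman_plot(paired: PairedMeasurements, result: AgreementResult, path) -> None:
    """Bland-Altman panel (difference vs mean, bias and LoA lines) to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean = (paired.device + paired.reference) / 2.0
    diff = paired.device - paired.reference
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=18, color="0.2")
    ax.axhline(result.bias, ls="--", color="tab:blue", label=f"bias {result.bias:.1f}")
    for sign in (+1, -1):
        ax.axhline(result.bias + sign * result.loa, color="tab:blue")
    ax.set_xlabel("mean of methods (umol ZnPP / mol haem)")
    ax.set_ylabel("device - reference")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
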