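"""Behavioural and statistical metrics.

Dexterity of one evaluation is summarised from the four force outputs
(F1-CST, F1-RST, F2-CST, F2-RST):

    FineMotor_k = 0.75 * CST_k + 0.25 * RST_k      (fine, fractionated force)
    Force_k     = 0.25 * CST_k + 0.75 * RST_k      (gross force / strength)
    I = |FineMotor_1 - FineMotor_2| / (FineMotor_1 + FineMotor_2)

I is the finger-individuation index: 1 for a perfectly individuated press,
0 when both fingers produce equal fine-motor force.

The module also provides the enslaving-slope regression (OLS of
uninstructed on instructed force with a classical t-based 95% CI), the
paired t-test report of per-cluster synaptic-weight changes between two
states, and the RMSE / regression-coefficient / VAF agreement metrics used
by the noise-robustness analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["DexterityRecord", "SlopeFit", "WeightChangeReport", "RobustnessCell",
           "dexterity", "fine_motor", "gross_force", "fit_enslaving_slope",
           "weight_change_report", "compare_to_reference", "WEIGHT_PAIRINGS"]


@dataclass(frozen=True)
class DexterityRecord:
    fine_motor: tuple[float, float]
    gross_force: tuple[float, float]
    individuation: float
    #: True when fine_motor sums to zero and I is undefined
    undefined: bool = False


def fine_motor(fo: np.ndarray) -> tuple[float, float]:
    fo = np.asarray(fo, dtype=float)
    return (0.75 * fo[0] + 0.25 * fo[1], 0.75 * fo[2] + 0.25 * fo[3])


def gross_force(fo: np.ndarray) -> tuple[float, float]:
    fo = np.asarray(fo, dtype=float)
    return (0.25 * fo[0] + 0.75 * fo[1], 0.25 * fo[2] + 0.75 * fo[3])


def dexterity(fo: np.ndarray) -> DexterityRecord:
    """Fine/gross forces and the individuation index of one evaluation."""
    fo = np.asarray(fo, dtype=float)
    if fo.shape != (4,):
        raise ValueError(f"expected 4 force outputs, got shape {fo.shape}")
    fine = fine_motor(fo)
    gross = gross_force(fo)
    total = fine[0] + fine[1]
    if total == 0.0:
        return DexterityRecord(fine, gross, float("nan"), undefined=True)
    ind = abs(fine[0] - fine[1]) / total
    return DexterityRecord(fine, gross, ind)


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    intercept: float
    ci95: tuple[float, float]
    n_points: int


def fit_enslaving_slope(points: Sequence[tuple[float, float]]) -> SlopeFit:
    """OLS of uninstructed force on instructed force.

    The 95% CI uses the t distribution with n-2 degrees of freedom; on
    noiseless affine data the CI has zero width.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (instructed, uninstructed) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate abscissa: all instructed forces identical")
    res = stats.linregress(x, y)
    n = len(x)
    half = stats.t.ppf(0.975, n - 2) * res.stderr
    return SlopeFit(slope=float(res.slope), intercept=float(res.intercept),
                    ci95=(float(res.slope - half), float(res.slope + half)),
                    n_points=n)


#: The ten (hidden cluster -> output channel) pairings analysed after
#: recovery: per finger, focal excitatory / shared CS / focal inhibitory to
#: the CST output, and focal inhibitory / RS to the RST output.
WEIGHT_PAIRINGS: tuple[tuple[str, int, str], ...] = (
    ("focal_exc_f1", 0, "f1_cst"), ("shared_cs", 0, "f1_cst"), ("focal_inh_f1", 0, "f1_cst"),
    ("focal_inh_f1", 1, "f1_rst"), ("rs", 1, "f1_rst"),
    ("focal_exc_f2", 2, "f2_cst"), ("shared_cs", 2, "f2_cst"), ("focal_inh_f2", 2, "f2_cst"),
    ("focal_inh_f2", 3, "f2_rst"), ("rs", 3, "f2_rst"),
)


@dataclass(frozen=True)
class WeightChangeRow:
    group: str
    output: str
    n: int
    mean_pre: float
    mean_post: float
    mean_diff: float
    t_statistic: float
    p_value: float
    direction: str          # "increase" / "decrease" / "none"
    degenerate: bool = False


@dataclass(frozen=True)
class WeightChangeReport:
    rows: tuple[WeightChangeRow, ...]

    def row(self, group: str, output: str) -> WeightChangeRow:
        for r in self.rows:
            if r.group == group and r.output == output:
                return r
        raise KeyError((group, output))


def weight_change_report(pre, post) -> WeightChangeReport:
    """Paired t-tests on surviving neurons' output weights, per pairing.

    ``pre`` and ``post`` are :class:`~fingernet.network.NetworkState`
    snapshots sharing layout, masks and neuron status; only neurons with
    nonzero status and a connected (mask 1) weight enter the pairing.
    Zero-variance differences are reported as degenerate rather than p=0.
    """
    if pre.layout.slices != post.layout.slices:
        raise ValueError("states do not share a layout")
    alive = post.masks.neuron_status != 0
    rows = []
    for group, k, out_name in WEIGHT_PAIRINGS:
        idx = pre.layout.indices(group)
        idx = idx[alive[idx] & (post.masks.output_mask[idx, k] > 0)]
        a = pre.output_weights[idx, k]
        b = post.output_weights[idx, k]
        diff = b - a
        mean_diff = float(diff.mean()) if len(diff) else float("nan")
        if len(diff) < 2 or np.allclose(diff.std(ddof=1), 0.0):
            rows.append(WeightChangeRow(
                group=group, output=out_name, n=len(diff),
                mean_pre=float(a.mean()) if len(a) else float("nan"),
                mean_post=float(b.mean()) if len(b) else float("nan"),
                mean_diff=mean_diff, t_statistic=float("nan"), p_value=float("nan"),
                direction="none" if not mean_diff else
                ("increase" if mean_diff > 0 else "decrease"),
                degenerate=True))
            continue
        t, p = stats.ttest_rel(b, a)
        rows.append(WeightChangeRow(
            group=group, output=out_name, n=len(diff),
            mean_pre=float(a.mean()), mean_post=float(b.mean()), mean_diff=mean_diff,
            t_statistic=float(t), p_value=float(p),
            direction="increase" if mean_diff > 0 else "decrease"))
    return WeightChangeReport(rows=tuple(rows))


@dataclass(frozen=True)
class RobustnessCell:
    noise_wo: float
    noise_hidden: float
    rmse: float
    regression_coefficient: float
    vaf: float
    #: True when the reference series is constant and VAF/slope undefined
    undefined: bool = False


def compare_to_reference(outputs: np.ndarray, reference: np.ndarray,
                         noise_wo: float = 0.0, noise_hidden: float = 0.0) -> RobustnessCell:
    """Agreement of a (noisy) output series with a reference series.

    rmse = sqrt(mean((out - ref)^2)); the regression coefficient is the OLS
    slope of out on ref; vaf = 1 - var(out - ref) / var(ref).
    """
    out = np.asarray(outputs, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    if out.shape != ref.shape:
        raise ValueError("output and reference series must have equal length")
    rmse = float(np.sqrt(np.mean((out - ref) ** 2)))
    if np.ptp(ref) == 0.0:
        return RobustnessCell(noise_wo, noise_hidden, rmse, float("nan"), float("nan"),
                              undefined=True)
    slope = float(stats.linregress(ref, out).slope)
    vaf = float(1.0 - np.var(out - ref) / np.var(ref))
    return RobustnessCell(noise_wo, noise_hidden, rmse, slope, vaf)
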