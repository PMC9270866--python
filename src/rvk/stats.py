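"""Paired Baseline-vs-TRA statistics and cohort report tables.

Each animal serves as its own control, so comparisons use Student's t-test
for dependent observations (two-sided, alpha = 0.05), normality of the paired
differences is screened with the Shapiro-Wilk test, and the Wilcoxon
signed-rank test is reported alongside as a distribution-free confirmation.
The Wilcoxon p-value is computed from the exact permutation distribution of
signed mid-ranks (zeros dropped, Wilcoxon's original convention) for up to 25
informative pairs, and from the tie-corrected normal approximation with
continuity correction above that.  No multiplicity correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateTestError, PairingError, ParameterError

__all__ = [
    "PairedSample",
    "StatResult",
    "paired_t_test",
    "shapiro_wilk",
    "wilcoxon_signed_rank",
    "build_report",
]


@dataclass(frozen=True)
class PairedSample:
    """Paired per-recording values for one variable across the cohort."""

    ids: tuple[str, ...]
    baseline: np.ndarray
    tra: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self):
        base = np.asarray(self.baseline, dtype=float)
        post = np.asarray(self.tra, dtype=float)
        if len(self.ids) != len(base) or len(base) != len(post):
            raise PairingError(
                f"ids/baseline/tra lengths differ: "
                f"{len(self.ids)}/{len(base)}/{len(post)}"
            )
        if len(base) < 2:
            raise ParameterError("paired sample needs >= 2 pairs")
        if len(set(self.ids)) != len(self.ids):
            raise PairingError("recording ids must be unique")
        object.__setattr__(self, "baseline", base)
        object.__setattr__(self, "tra", post)

    @property
    def differences(self) -> np.ndarray:
        return self.tra - self.baseline

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class StatResult:
    """One test outcome with the mean +/- SD of both states."""

    test: str
    statistic: float
    p_value: float
    n: int
    mean_baseline: float = float("nan")
    sd_baseline: float = float("nan")
    mean_tra: float = float("nan")
    sd_tra: float = float("nan")
    normal: bool | None = None
    note: str = ""

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p_value {self.p_value} outside [0, 1]")


def _state_moments(sample: PairedSample) -> dict[str, float]:
    return {
        "mean_baseline": float(np.mean(sample.baseline)),
        "sd_baseline": float(np.std(sample.baseline, ddof=1)),
        "mean_tra": float(np.mean(sample.tra)),
        "sd_tra": float(np.std(sample.tra, ddof=1)),
    }


def paired_t_test(sample: PairedSample) -> StatResult:
    """Student's t-test for dependent observations (two-sided).

    t = mean(d) / (sd(d)/sqrt(n)) on the paired differences d with n-1
    degrees of freedom.  Zero-variance differences are a degenerate test.
    """
    d = sample.differences
    n = sample.n
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateTestError("paired differences have zero variance")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return StatResult(
        test="paired t", statistic=t, p_value=p, n=n, **_state_moments(sample)
    )


def shapiro_wilk(values: Sequence[float]) -> StatResult:
    """Shapiro-Wilk normality test (Royston approximation, via scipy).

    Intended for 3 <= n <= 50 (the small-sample regime the approximation was
    fitted for); larger n is computed with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ParameterError("Shapiro-Wilk needs a 1-D sample with n >= 3")
    if np.std(x) == 0:
        raise DegenerateTestError("sample has zero variance")
    if len(x) > 50:
        warnings.warn("Shapiro-Wilk beyond n = 50: approximation regime exceeded")
    w, p = sps.shapiro(x)
    return StatResult(
        test="shapiro-wilk", statistic=float(w), p_value=float(p), n=len(x),
        normal=bool(p >= 0.05),
    )


def _exact_signed_rank_p(ranks2: np.ndarray, w_plus2: int) -> float:
    """Exact two-sided p for W+ given doubled mid-ranks (integers).

    Convolves the sign-flip distribution of sum(ranks) (2^m equally likely
    subsets); p = min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    lower = counts[: w_plus2 + 1].sum()
    upper = counts[w_plus2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(sample: PairedSample, *, exact_max_n: int = 25) -> StatResult:
    """Wilcoxon signed-rank test on the paired differences.

    Zero differences are dropped; ties get mid-ranks.  The p-value is exact
    (full sign-flip distribution) for up to ``exact_max_n`` informative pairs,
    otherwise a tie-corrected normal approximation with continuity correction.
    """
    d = sample.differences
    d = d[d != 0.0]
    m = len(d)
    if m == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if m <= exact_max_n:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        p = _exact_signed_rank_p(ranks2, int(round(2.0 * w_plus)))
        note = "exact"
    else:
        mean = m * (m + 1) / 4.0
        tie_sizes = np.unique(ranks, return_counts=True)[1]
        var = m * (m + 1) * (2 * m + 1) / 24.0 - np.sum(
            tie_sizes**3 - tie_sizes
        ) / 48.0
        if var <= 0:
            raise DegenerateTestError("zero variance in signed-rank statistic")
        cc = 0.5 * np.sign(w_plus - mean)
        z = (w_plus - mean - cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        note = "normal approximation"
    return StatResult(
        test="wilcoxon signed-rank", statistic=w_plus, p_value=p, n=sample.n,
        note=note, **_state_moments(sample),
    )


# ---------------------------------------------------------------------------
# cohort report

#: report row order: haemodynamics then geometry, mirroring the study tables
REPORT_VARIABLES = (
    ("hr_bpm", "HR (b/min)"),
    ("lvp_mmhg", "LVP (mmHg)"),
    ("rvp_mmhg", "RVP (mmHg)"),
    ("cvp_mmhg", "CVP (mmHg)"),
    ("taa_mm2", "TAA area (mm2)"),
    ("ta_reduction_pct", "TA reduction (%)"),
    ("edv_ml", "RV EDV (ml)"),
    ("csa_basal_mm2", "RV CSA basal (mm2)"),
    ("csa_mid_mm2", "RV CSA mid (mm2)"),
    ("csa_lower_mm2", "RV CSA lower (mm2)"),
    ("roc_basal_mm", "RV ROC basal (mm)"),
    ("roc_mid_mm", "RV ROC mid (mm)"),
    ("roc_lower_mm", "RV ROC lower (mm)"),
)


def build_report(
    per_recording: Mapping[str, Mapping[str, Mapping[str, float]]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cohort table: mean +/- SD per state, paired-t and Wilcoxon p, normality.

    ``per_recording`` maps recording id -> state ('Baseline'/'TRA') ->
    variable -> value.  Any variable present in every recording's both states
    is reported; the derived 'TA reduction (%)' row summarizes the per-animal
    percent annular reduction (TRA column only, no paired test).  The output
    is invariant to the ordering of ``per_recording``.
    """
    if len(per_recording) < 2:
        raise ParameterError("report needs >= 2 paired recordings")
    ids = tuple(sorted(per_recording))
    for rid in ids:
        states = per_recording[rid]
        for state in ("Baseline", "TRA"):
            if state not in states:
                raise PairingError(f"recording {rid!r} missing state {state!r}")

    common = set.intersection(
        *(set(per_recording[rid][s]) for rid in ids for s in ("Baseline", "TRA"))
    )
    known = [v for v, _ in REPORT_VARIABLES if v in common or v == "ta_reduction_pct"]
    extra = sorted(common - {v for v, _ in REPORT_VARIABLES})
    pretty = dict(REPORT_VARIABLES)

    rows = []
    for var in known + extra:
        if var == "ta_reduction_pct":
            if "taa_mm2" not in common:
                continue
            red = np.array(
                [
                    100.0
                    * (
                        1.0
                        - per_recording[rid]["TRA"]["taa_mm2"]
                        / per_recording[rid]["Baseline"]["taa_mm2"]
                    )
                    for rid in ids
                ]
            )
            rows.append(
                {
                    "variable": pretty.get(var, var),
                    "key": var,
                    "n": len(ids),
                    "baseline_mean": float("nan"),
                    "baseline_sd": float("nan"),
                    "tra_mean": float(np.mean(red)),
                    "tra_sd": float(np.std(red, ddof=1)),
                    "t_p": float("nan"),
                    "wilcoxon_p": float("nan"),
                    "shapiro_p": float("nan"),
                    "normal": None,
                    "note": "per-animal 100*(1 - TAA_TRA/TAA_Baseline)",
                }
            )
            continue
        sample = PairedSample(
            ids=ids,
            baseline=np.array([per_recording[rid]["Baseline"][var] for rid in ids]),
            tra=np.array([per_recording[rid]["TRA"][var] for rid in ids]),
            name=var,
        )
        note = ""
        try:
            t_res = paired_t_test(sample)
            w_res = wilcoxon_signed_rank(sample)
            t_p, w_p = t_res.p_value, w_res.p_value
            stat_t = t_res.statistic
        except DegenerateTestError:
            t_p = w_p = float("nan")
            stat_t = float("nan")
            note = "degenerate: identical paired values"
        try:
            s_res = shapiro_wilk(sample.differences)
            shapiro_p, normal = s_res.p_value, s_res.normal
        except DegenerateTestError:
            shapiro_p, normal = float("nan"), None
        rows.append(
            {
                "variable": pretty.get(var, var),
                "key": var,
                "n": sample.n,
                "baseline_mean": float(np.mean(sample.baseline)),
                "baseline_sd": float(np.std(sample.baseline, ddof=1)),
                "tra_mean": float(np.mean(sample.tra)),
                "tra_sd": float(np.std(sample.tra, ddof=1)),
                "t_statistic": stat_t,
                "t_p": t_p,
                "wilcoxon_p": w_p,
                "shapiro_p": shapiro_p,
                "normal": normal,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Human-readable mean +/- SD table with p-values."""
    lines = [f"{'variable':<22} {'Baseline':>16} {'TRA':>16} {'t p':>8} {'W p':>8}"]
    for _, r in report.iterrows():
        def ms(mean, sd):
            if np.isnan(mean):
                return ""
            return f"{mean:.4g} ± {sd:.3g}"

        def pv(p):
            return "" if np.isnan(p) else f"{p:.3g}"

        lines.append(
            f"{r['variable']:<22} {ms(r['baseline_mean'], r['baseline_sd']):>16} "
            f"{ms(r['tra_mean'], r['tra_sd']):>16} {pv(r['t_p']):>8} "
            f"{pv(r['wilcoxon_p']):>8}"
        )
    return "\n".join(lines)
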