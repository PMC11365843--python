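"""Agreement and robustness statistics for BVL estimates.

Mirrors the assessment machinery used for longitudinal atrophy methods:
Bland-Altman style difference summaries (median and quartile-based IQR as
the headline numbers, classic mean +/- 1.96 SD limits alongside), the
intraclass correlation coefficient, and the Pitman test for equality of
variances of paired samples (correlation between per-pair sums and
differences; a significant positive correlation means the first member of
each pair has the larger variance).

Quantile convention: linear interpolation (numpy default, type 7) --
documented here because IQR endpoints are headline outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateInputError(ValueError):
    pass


@dataclass
class AgreementReport:
    n: int
    median_diff: float
    iqr_low: float
    iqr_high: float
    p95_abs_diff: float
    mean_diff: float
    loa_low: float
    loa_high: float
    icc: float

    def to_dict(self) -> dict:
        return {k: (int(v) if k == "n" else float(v)) for k, v in asdict(self).items()}


@dataclass
class PitmanResult:
    correlation: float
    p_value: float
    method: str
    sd_a: float
    sd_b: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update({k: float(d[k]) for k in ("correlation", "p_value", "sd_a", "sd_b")})
        return d


def icc_absolute(x, y, form: str = "ICC2") -> float:
    """Single-rater ICC between two measurement sets on the same subjects.

    ``ICC2`` is the two-way random-effects absolute-agreement form (default);
    ``ICC3`` the two-way mixed consistency form.  Computed via pingouin.
    """
    import pingouin as pg

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "score": np.concatenate([x, y]),
        }
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        # degenerate inputs (zero residual variance) hit harmless 0/0 paths
        _warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    label = {"ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)"}.get(form, form)
    return float(table.set_index("Type").loc[label, "ICC"])


def agreement(x_list, y_list, icc_form: str = "ICC2") -> AgreementReport:
    """Bland-Altman style agreement of two per-pair estimate sets (d = x - y)."""
    x = np.asarray(x_list, float)
    y = np.asarray(y_list, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D sequences")
    if len(x) < 3:
        raise DegenerateInputError("need at least 3 pairs")
    d = x - y
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        icc = 1.0 if np.allclose(x, y) else 0.0
    else:
        icc = icc_absolute(x, y, form=icc_form)
    return AgreementReport(
        n=len(d),
        median_diff=float(med),
        iqr_low=float(q1),
        iqr_high=float(q3),
        p95_abs_diff=float(np.percentile(np.abs(d), 95)),
        mean_diff=mean,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        icc=icc,
    )


def pitman_test(a_list, b_list, method: str = "spearman") -> PitmanResult:
    """Pitman test for equal variances of paired samples.

    Correlates per-pair sums ``a + b`` with differences ``a - b``;
    ``corr > 0`` indicates ``var(a) > var(b)``.  ``method='pearson'`` is the
    classical Pitman-Morgan form (t-approximated p); ``'spearman'`` the rank
    variant (default).
    """
    a = np.asarray(a_list, float)
    b = np.asarray(b_list, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1D sequences")
    if len(a) < 4:
        raise DegenerateInputError("need at least 4 pairs")
    s = a + b
    d = a - b
    if np.ptp(s) == 0 or np.ptp(d) == 0:
        raise DegenerateInputError("zero variance in sums or differences")
    if method == "pearson":
        r, p = stats.pearsonr(s, d)
    elif method == "spearman":
        r, p = stats.spearmanr(s, d)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return PitmanResult(
        correlation=float(r),
        p_value=float(p),
        method=method,
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
    )


# --- phantom study analogues -------------------------------------------------


def run_study_analogues(results: pd.DataFrame, truth: pd.DataFrame | None = None) -> dict:
    """The three phantom-based analogues of the method's published assessments.

    ``results`` is a cohort table with at least columns ``pair_id, bvl_fw,
    bvl_bw, bvl, dbpv``; ``truth`` (optional) the phantom truth table with
    ``pair_id, true_bvl_percent``.

    Sections:

    (i)   internal consistency -- Bland-Altman of forward vs backward
          per-direction estimates;
    (ii)  agreement of the final estimate against ground truth (the phantom
          stands in for the reference method);
    (iii) robustness -- distribution width of estimates on zero-change pairs
          and a Pitman comparison of uncorrected vs corrected estimates.
    """
    report: dict = {}
    fw = results["bvl_fw"].to_numpy() / results.get("m_siena", pd.Series([1.0] * len(results))).to_numpy()
    bw = results["bvl_bw"].to_numpy() / results.get("m_siena", pd.Series([1.0] * len(results))).to_numpy()
    report["internal_consistency"] = agreement(fw, bw).to_dict()

    if truth is not None:
        merged = results.merge(truth[["pair_id", "true_bvl_percent"]], on="pair_id")
        report["agreement_vs_truth"] = agreement(
            merged["bvl"].to_numpy(), merged["true_bvl_percent"].to_numpy()
        ).to_dict()

        null = merged[merged["true_bvl_percent"] == 0]
        if len(null) >= 4:
            est = null["bvl"].to_numpy()
            raw = null["dbpv"].to_numpy()
            sec = {
                "n": int(len(null)),
                "mean_bvl": float(est.mean()),
                "sd_bvl": float(est.std(ddof=1)),
                "se_mean": float(est.std(ddof=1) / np.sqrt(len(est))),
                "sd_uncorrected_dbpv": float(raw.std(ddof=1)),
                "p95_abs_bvl": float(np.percentile(np.abs(est), 95)),
            }
            try:
                sec["pitman_uncorrected_vs_corrected"] = pitman_test(raw, est).to_dict()
            except DegenerateInputError:
                sec["pitman_uncorrected_vs_corrected"] = None
            report["robustness_null_pairs"] = sec
    return report


def write_report(report: dict, json_path, md_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)
    if md_path is not None:
        lines = ["# Evaluation report", ""]
        for section, content in report.items():
            lines.append(f"## {section}")
            lines.append("")
            lines.append("```json")
            lines.append(json.dumps(content, indent=2))
            lines.append("```")
            lines.append("")
        with open(md_path, "w") as fh:
            fh.write("\n".join(lines))
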