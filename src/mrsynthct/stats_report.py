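"""Cohort statistics and end-to-end study orchestration.

Runs phantom generation, segmentation, synthetic-CT synthesis and all
three evaluation stages per case, then aggregates into the three report
tables (per-class overlap; histogram similarity; gamma pass rates) with
Welch two-sample t-tests between the water-equivalent and bulk-density
results and a normal-approximation power analysis verifying the cohort
size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import ceil, sqrt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import autoseg, gammaeval, histsim, overlap, phantom, synthct

__all__ = [
    "TestResult",
    "SimilarityReport",
    "welch_t_test",
    "required_sample_size",
    "run_study",
    "HIST_METRICS",
    "metric_direction",
]

#: histogram metrics and whether higher is better
HIST_METRICS = {
    "correlation": "higher",
    "chi_square": "lower",
    "intersection": "higher",
    "bhattacharyya": "lower",
}

GAMMA_LABELS = {(3.0, 3.0): "3mm/3%", (2.0, 2.0): "2mm/2%", (1.0, 1.0): "1mm/1%"}


def metric_direction(metric: str) -> str:
    """'higher' or 'lower' = which side favours a better match."""
    if metric in HIST_METRICS:
        return HIST_METRICS[metric]
    return "higher"  # gamma pass rates


@dataclass(frozen=True)
class TestResult:
    """Welch two-sample t-test outcome."""

    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    degenerate: bool = False


def welch_t_test(x, y) -> TestResult:
    """Welch's unequal-variance t-test, two-sided.

    t = (mean x − mean y) / sqrt(sx²/nx + sy²/ny) with Welch–Satterthwaite
    degrees of freedom. If both samples have zero variance and equal
    means the statistic is undefined; reported as t=0, p=1 with the
    ``degenerate`` flag set.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    nx, ny = x.size, y.size
    mx, my = float(x.mean()), float(y.mean())
    vx, vy = float(x.var(ddof=1)), float(y.var(ddof=1))
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return TestResult(0.0, float(nx + ny - 2), 1.0, mx, my, 0.0, 0.0, True)
        return TestResult(
            float(np.sign(mx - my)) * np.inf, float(nx + ny - 2), 0.0, mx, my, 0.0, 0.0, True
        )
    t = (mx - my) / sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(t, df, p, mx, my, sqrt(vx), sqrt(vy), False)


def required_sample_size(
    power: float = 0.9, alpha: float = 0.05, standardized_effect: float = 1.0
) -> int:
    """Smallest per-group n for a two-sample comparison, normal approximation:

        n = ceil( 2 (z_{1-alpha/2} + z_{power})^2 / effect^2 )
    """
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("power and alpha must lie in (0, 1)")
    if standardized_effect <= 0:
        raise ValueError("standardized effect must be positive")
    z_a = float(sps.norm.ppf(1.0 - alpha / 2.0))
    z_b = float(sps.norm.ppf(power))
    return ceil(2.0 * (z_a + z_b) ** 2 / standardized_effect**2)


@dataclass
class SimilarityReport:
    """Aggregate study report: per-class overlap, histogram and gamma
    tables with improvement rows and Welch p-values, plus per-case data."""

    n_cases: int
    seed: int
    overlap_table: pd.DataFrame
    hist_table: pd.DataFrame
    gamma_table: pd.DataFrame
    power_table: pd.DataFrame
    per_case_hist: pd.DataFrame
    per_case_gamma: pd.DataFrame
    welch: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.overlap_table.to_csv(outdir / "overlap_table.csv")
        self.hist_table.to_csv(outdir / "histogram_table.csv")
        self.gamma_table.to_csv(outdir / "gamma_table.csv")
        self.power_table.to_csv(outdir / "power_table.csv")
        self.per_case_hist.to_csv(outdir / "per_case_histogram.csv", index=False)
        self.per_case_gamma.to_csv(outdir / "per_case_gamma.csv", index=False)
        summary = {
            "n_cases": self.n_cases,
            "seed": self.seed,
            "welch": {
                k: {"t": r.t, "df": r.df, "p": r.p} for k, r in self.welch.items()
            },
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def _evaluate_case(case, rules, priors, hu_table, criteria):
    body = autoseg.segment_body(case.petra, rules)
    predicted = autoseg.classify_tissues(
        case.t1, case.t2, case.petra, body, rules, priors
    )
    wct = synthct.synthesize_wct(body)
    bct = synthct.synthesize_bct(predicted, hu_table)

    h_ref = histsim.build_histogram(case.reference_ct)
    hist_rows = {}
    for name, img in (("wct", wct), ("bct", bct)):
        sc = histsim.compare_histograms(h_ref, histsim.build_histogram(img))
        hist_rows[name] = {
            "correlation": sc.correlation,
            "chi_square": sc.chi_square,
            "intersection": sc.intersection,
            "bhattacharyya": sc.bhattacharyya,
        }

    roi = gammaeval.roi_from_body(body, mode="2d")
    gamma_rows = {}
    for crit in criteria:
        label = GAMMA_LABELS.get((crit.dta_mm, crit.dd_percent), f"{crit.dta_mm}mm/{crit.dd_percent}%")
        for name, img in (("wct", wct), ("bct", bct)):
            g = gammaeval.gamma_map(case.reference_ct, img, crit, roi)
            gamma_rows[(label, name)] = gammaeval.pass_rate(g)

    return predicted, hist_rows, gamma_rows


def _paired_table(per_case: pd.DataFrame, metrics, directions) -> tuple[pd.DataFrame, dict]:
    """Build mean/SD/improvement/p rows from a per-case frame with an
    'image' column ('wct'/'bct') and one column per metric."""
    rows = {}
    welch_results = {}
    for image in ("wct", "bct"):
        sub = per_case[per_case["image"] == image]
        rows[f"ct_vs_{image}_mean"] = {m: sub[m].mean() for m in metrics}
        rows[f"ct_vs_{image}_sd"] = {
            m: (sub[m].std(ddof=1) if len(sub) > 1 else 0.0) for m in metrics
        }
    improvement = {}
    pvals = {}
    for m in metrics:
        w = per_case.loc[per_case["image"] == "wct", m].to_numpy()
        b = per_case.loc[per_case["image"] == "bct", m].to_numpy()
        sign = 1.0 if directions[m] == "higher" else -1.0
        improvement[m] = sign * (b.mean() - w.mean())
        if len(w) >= 2 and len(b) >= 2:
            res = welch_t_test(w, b)
            welch_results[m] = res
            pvals[m] = res.p
        else:
            pvals[m] = float("nan")
    rows["improvement"] = improvement
    rows["p_value"] = pvals
    return pd.DataFrame(rows).T[list(metrics)], welch_results


def run_study(
    spec: phantom.PhantomSpec | None = None,
    n_cases: int = 20,
    rules: autoseg.RuleSet | None = None,
    priors: autoseg.AtlasPrior | None = None,
    hu_table: synthct.HUTable | None = None,
    criteria=gammaeval.DEFAULT_CRITERIA,
) -> SimilarityReport:
    """Run the full pipeline on a phantom cohort and aggregate the report.

    Deterministic for a given ``spec`` (the seed lives in the spec).
    """
    spec = spec or phantom.PhantomSpec()
    rules = rules or autoseg.default_rules()
    priors = priors or autoseg.default_priors()
    hu_table = hu_table or synthct.HUTable()

    overlap_pairs = []
    hist_records = []
    gamma_records = []
    for case_id in range(n_cases):
        case = phantom.generate_case(spec, case_id)
        try:
            predicted, hist_rows, gamma_rows = _evaluate_case(
                case, rules, priors, hu_table, criteria
            )
        except Exception as exc:  # tag failures with their provenance
            raise type(exc)(f"case {case_id}: {exc}") from exc
        overlap_pairs.append((predicted, case.truth))
        for image, scores in hist_rows.items():
            hist_records.append({"case": case_id, "image": image, **scores})
        for (label, image), rate in gamma_rows.items():
            gamma_records.append(
                {"case": case_id, "image": image, "criteria": label, "pass_rate": rate}
            )

    overlap_table = overlap.cohort_overlap_table(overlap_pairs)
    per_case_hist = pd.DataFrame(hist_records)
    per_case_gamma = pd.DataFrame(gamma_records)

    hist_table, hist_welch = _paired_table(
        per_case_hist, list(HIST_METRICS), HIST_METRICS
    )

    gamma_wide = per_case_gamma.pivot_table(
        index=["case", "image"], columns="criteria", values="pass_rate"
    ).reset_index()
    labels = [GAMMA_LABELS[(c.dta_mm, c.dd_percent)] for c in criteria
              if (c.dta_mm, c.dd_percent) in GAMMA_LABELS]
    gamma_table, gamma_welch = _paired_table(
        gamma_wide, labels, {lbl: "higher" for lbl in labels}
    )

    welch = {f"hist_{k}": v for k, v in hist_welch.items()}
    welch.update({f"gamma_{k}": v for k, v in gamma_welch.items()})

    power_rows = []
    for key, res in welch.items():
        pooled_sd = sqrt((res.sd_x**2 + res.sd_y**2) / 2.0)
        effect = abs(res.mean_x - res.mean_y) / pooled_sd if pooled_sd > 0 else np.inf
        req = required_sample_size(0.9, 0.05, effect) if np.isfinite(effect) else 1
        power_rows.append(
            {
                "metric": key,
                "standardized_effect": effect,
                "required_n_per_group": req,
                "n_cases": n_cases,
                "verified": n_cases >= req,
            }
        )
    if power_rows:
        power_table = pd.DataFrame(power_rows).set_index("metric")
    else:  # single-case cohort: no tests, no power analysis
        power_table = pd.DataFrame(
            columns=["standardized_effect", "required_n_per_group", "n_cases", "verified"]
        )

    return SimilarityReport(
        n_cases=n_cases,
        seed=spec.seed,
        overlap_table=overlap_table,
        hist_table=hist_table,
        gamma_table=gamma_table,
        power_table=power_table,
        per_case_hist=per_case_hist,
        per_case_gamma=per_case_gamma,
        welch=welch,
    )
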