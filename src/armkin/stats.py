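"""Cohort statistics battery for the outcome table and clinical covariates.

For each task the battery runs, per outcome, a Kruskal-Wallis test across
MACS levels with post-hoc Mann-Whitney U tests; dependencies between the
three joint-specific parameter families (AVS, angles at PTA, ROM) of one
joint angle are handled with the sequentially rejective Holm-Bonferroni
method, whose three-step ladder at overall alpha 0.05 is
0.05/3 (~0.0167), 0.025, 0.05. Clinical-kinematic associations use Pearson
or (point-)biserial correlations classified by magnitude (<0.30 little or
no, 0.30-0.50 low, 0.50-0.70 moderate, >0.70 high, 0.90-1.00 very high),
and a forward stepwise regression of the APS on age, MACS level, grip
force, muscle strength and muscle tone identifies the dominant predictors.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from armkin.kinematics import CHANNELS

MACS_LEVELS = ("I", "II", "III")
MACS_NUMERIC = {"I": 1, "II": 2, "III": 3}

#: regression predictors, in declared (tie-break) order
REGRESSION_PREDICTORS = ("age", "macs", "grip_force", "strength", "tone")

GLOBAL_OUTCOMES = ("APS", "duration", "vmax", "timing_vmax", "straightness")


# ---------------------------------------------------------------------------
# elementary tests


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Rank-based H statistic (tie-corrected) and chi-square p (k-1 df).

    Degenerate input with every observation identical returns H = 0, p = 1.
    """
    arrays = [np.asarray(g, float) for g in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need >=2 non-empty groups")
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValueError("need a total of >=3 observations")
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    H, p = sps.kruskal(*arrays)
    return float(H), float(p)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is the smaller of the two U's.

    The p-value is exact for small tie-free samples and uses the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    u_min = min(float(res.statistic), len(a) * len(b) - float(res.statistic))
    return u_min, float(res.pvalue)


def holm_bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> pd.DataFrame:
    """Sequentially rejective Holm-Bonferroni step-down procedure.

    Sorts the m p-values ascending, compares the i-th (1-based) to
    ``alpha / (m - i + 1)`` and stops at the first failure, so rejections
    form a prefix of the sorted order (for m = 3: 0.0167 / 0.025 / 0.05).
    Returns a table in the *input* order with rank, threshold and decision.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return pd.DataFrame(columns=["p", "rank", "threshold", "reject"])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = alpha / (m - np.arange(m))  # rank i (0-based): alpha/(m-i)
    reject_sorted = np.zeros(m, bool)
    for i, idx in enumerate(order):
        if p[idx] <= thresholds[i]:
            reject_sorted[i] = True
        else:
            break
    out = pd.DataFrame({"p": p})
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    out["rank"] = ranks
    out["threshold"] = thresholds[ranks - 1]
    rej = np.zeros(m, bool)
    rej[order] = reject_sorted
    out["reject"] = rej
    return out


# ---------------------------------------------------------------------------
# correlations


def classify_correlation(r: float) -> str:
    """Magnitude band of a correlation coefficient.

    <0.30 little or no; 0.30 to 0.50 low; 0.50 to 0.70 moderate;
    >0.70 high; 0.90 to 1.00 very high (pure function of ``abs(r)``).
    """
    a = abs(float(r))
    if not np.isfinite(a) or a > 1 + 1e-9:
        raise ValueError(f"not a correlation coefficient: {r!r}")
    if a >= 0.90:
        return "very high"
    if a > 0.70:
        return "high"
    if a >= 0.50:
        return "moderate"
    if a >= 0.30:
        return "low"
    return "little or no"


def correlate_and_classify(
    x: Sequence[float],
    y: Sequence[float],
    variable_type: str = "continuous",
) -> tuple[float, float, str]:
    """Correlation between a clinical and a kinematic variable.

    ``variable_type`` describes ``x``: ``"continuous"`` uses Pearson;
    ``"dichotomous"`` uses the point-biserial coefficient (Pearson with 0/1
    coding); ``"biserial"`` applies the normality-based biserial adjustment
    to the point-biserial value. Missing pairs are dropped; zero variance in
    either variable is an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if variable_type == "continuous":
        r, p = sps.pearsonr(x, y)
    elif variable_type in ("dichotomous", "biserial"):
        levels = np.unique(x)
        if levels.size != 2:
            raise ValueError("dichotomous variable must take exactly 2 values")
        x01 = (x == levels[1]).astype(float)
        r, p = sps.pearsonr(x01, y)
        if variable_type == "biserial":
            prop = x01.mean()
            z = sps.norm.ppf(prop)
            r = r * np.sqrt(prop * (1 - prop)) / sps.norm.pdf(z)
            r = float(np.clip(r, -1.0, 1.0))
    else:
        raise ValueError(f"unknown variable_type {variable_type!r}")
    return float(r), float(p), classify_correlation(r)


# ---------------------------------------------------------------------------
# forward stepwise regression


@dataclass
class StepwiseResult:
    """Forward-selection outcome: predictors in entry order with the
    per-step and final coefficient of determination."""

    selected: list[str]
    step_r2: list[float]
    final_r2: float
    coefficients: dict[str, float]
    entry_p: list[float]
    n: int

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "step_r2": self.step_r2,
            "final_r2": self.final_r2,
            "coefficients": self.coefficients,
            "entry_p": self.entry_p,
            "n": self.n,
        }


def forward_stepwise_regression(
    data: pd.DataFrame,
    response: str = "APS",
    predictors: Sequence[str] = REGRESSION_PREDICTORS,
    alpha_enter: float = 0.05,
) -> StepwiseResult:
    """Pure forward selection by the partial-F (equivalently t) test.

    At each step the candidate with the smallest partial-F p-value enters
    if that p-value is below ``alpha_enter``; ties break by declared
    predictor order; no removal step. MACS levels are coded numerically
    1-3 when a ``macs`` column holds level labels. Complete-case analysis.
    """
    df = data[[response, *predictors]].copy()
    if "macs" in df.columns and df["macs"].dtype == object:
        df["macs"] = df["macs"].map(MACS_NUMERIC)
    df = df.dropna()
    n = len(df)
    if n < len(predictors) + 2:
        raise ValueError(f"need >= {len(predictors) + 2} complete cases, have {n}")
    y = df[response].to_numpy(float)
    selected: list[str] = []
    step_r2: list[float] = []
    entry_p: list[float] = []
    remaining = list(predictors)
    model = None
    while remaining:
        best_p, best_name, best_fit = np.inf, None, None
        for name in remaining:  # declared order = tie-break order
            X = sm.add_constant(df[selected + [name]].to_numpy(float))
            fit = sm.OLS(y, X).fit()
            p_add = float(fit.pvalues[-1])
            if p_add < best_p - 1e-15:
                best_p, best_name, best_fit = p_add, name, fit
        if best_name is None or best_p >= alpha_enter:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        entry_p.append(best_p)
        step_r2.append(float(best_fit.rsquared))
        model = best_fit
    if model is None:
        return StepwiseResult([], [], 0.0, {}, [], n)
    coefs = dict(zip(["intercept", *selected], map(float, model.params)))
    return StepwiseResult(selected, step_r2, step_r2[-1], coefs, entry_p, n)


# ---------------------------------------------------------------------------
# the full battery


#: joint angle -> its three parameter families, the Holm family (m = 3)
def _joint_families(channel: str) -> list[str]:
    return [f"AVS_{channel}", f"PTA_{channel}", f"ROM_{channel}"]


CLINICAL_CONTINUOUS = (
    "age", "grip_force", "strength", "tone", "tpd", "stereognosis",
    "aha", "ma2_rom", "ma2_accuracy", "ma2_dexterity", "ma2_fluency",
)


@dataclass
class StatsReport:
    """Group comparisons, correlations and regression, per task."""

    group_tests: pd.DataFrame
    posthoc: pd.DataFrame
    correlations: pd.DataFrame
    regression: dict[str, StepwiseResult]
    excluded: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "group_tests": self.group_tests.to_dict(orient="records"),
                "posthoc": self.posthoc.to_dict(orient="records"),
                "correlations": self.correlations.to_dict(orient="records"),
                "regression": {t: r.to_dict() for t, r in self.regression.items()},
                "excluded": self.excluded,
            },
            indent=2,
            default=float,
        )

    def save(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.group_tests.to_csv(directory / "group_tests.csv", index=False)
        self.posthoc.to_csv(directory / "posthoc.csv", index=False)
        self.correlations.to_csv(directory / "correlations.csv", index=False)
        (directory / "report.json").write_text(self.to_json())

    def correlations_table(self, min_abs_r: float = 0.30) -> pd.DataFrame:
        """Rendering helper mirroring the published tables, which display
        only correlations of at least 0.30; computation is unaffected."""
        c = self.correlations
        return c[c["r"].abs() >= min_abs_r].reset_index(drop=True)


def run_group_comparison(
    outcome_table: pd.DataFrame,
    clinical_table: pd.DataFrame,
    alpha: float = 0.05,
    run_regression: bool = True,
) -> StatsReport:
    """Run the full statistics battery on per-subject task outcomes.

    ``outcome_table`` holds one row per subject x task (columns ``APS``,
    spatiotemporal metrics and ``AVS_/PTA_/ROM_<channel>``);
    ``clinical_table`` one row per subject with ``macs`` and the clinical
    covariates. Per task: Kruskal-Wallis across MACS levels for every
    outcome, Holm-corrected within each joint angle over its three
    parameter families; post-hoc Mann-Whitney U over the three pairwise
    MACS contrasts (Holm-corrected) wherever the omnibus test rejects;
    Pearson correlations of clinical scores with kinematic outcomes; and
    the forward stepwise APS regression. Subjects missing a score are
    dropped pairwise and counted in ``excluded``.
    """
    merged = outcome_table.merge(clinical_table, on="subject", how="inner")
    excluded = {"subjects_without_clinical":
                int(outcome_table["subject"].nunique()
                    - merged["subject"].nunique())}

    joint_outcomes = [fam for ch in CHANNELS for fam in _joint_families(ch)]
    all_outcomes = [c for c in (*GLOBAL_OUTCOMES, *joint_outcomes)
                    if c in merged.columns]

    gt_rows, ph_rows, corr_rows = [], [], []
    for task, dft in merged.groupby("task"):
        groups_present = [g for g in MACS_LEVELS if (dft["macs"] == g).any()]
        for outcome in all_outcomes:
            samples = [dft.loc[dft["macs"] == g, outcome].dropna()
                       for g in groups_present]
            samples = [s for s in samples if len(s) > 0]
            if len(samples) < 2 or sum(map(len, samples)) < 3:
                continue
            H, p = kruskal_wallis(*samples)
            gt_rows.append({"task": task, "outcome": outcome, "H": H, "p": p})
        gt = pd.DataFrame([r for r in gt_rows if r["task"] == task])
        if gt.empty:
            continue
        # Holm within each joint angle across its 3 parameter families
        reject = pd.Series(False, index=gt.index)
        threshold = pd.Series(np.nan, index=gt.index)
        for ch in CHANNELS:
            fam = gt[gt["outcome"].isin(_joint_families(ch))]
            if fam.empty:
                continue
            holm = holm_bonferroni(fam["p"].to_numpy(), alpha=alpha)
            reject[fam.index] = holm["reject"].to_numpy()
            threshold[fam.index] = holm["threshold"].to_numpy()
        glob = gt[gt["outcome"].isin(GLOBAL_OUTCOMES)]
        reject[glob.index] = glob["p"] < alpha
        threshold[glob.index] = alpha
        for i in gt.index:
            gt_rows[_row_pos(gt_rows, task, gt.loc[i, "outcome"])].update(
                reject=bool(reject[i]), threshold=float(threshold[i])
            )
        # post-hoc pairwise MWU for rejected outcomes, Holm over 3 contrasts
        pairs = list(itertools.combinations(groups_present, 2))
        for i in gt.index[reject]:
            outcome = gt.loc[i, "outcome"]
            rows = []
            for ga, gb in pairs:
                a = dft.loc[dft["macs"] == ga, outcome].dropna()
                b = dft.loc[dft["macs"] == gb, outcome].dropna()
                if len(a) < 2 or len(b) < 2:
                    rows.append({"task": task, "outcome": outcome,
                                 "pair": f"{ga}-{gb}", "U": np.nan, "p": np.nan,
                                 "applicable": False})
                    continue
                U, p = mann_whitney(a, b)
                rows.append({"task": task, "outcome": outcome,
                             "pair": f"{ga}-{gb}", "U": U, "p": p,
                             "applicable": True})
            ps = [r["p"] for r in rows if r["applicable"]]
            if ps:
                holm = holm_bonferroni(ps, alpha=alpha)
                it = iter(holm.itertuples())
                for r in rows:
                    if r["applicable"]:
                        h = next(it)
                        r["threshold"] = float(h.threshold)
                        r["reject"] = bool(h.reject)
            ph_rows.extend(rows)
        # clinical-kinematic correlations
        for clin in CLINICAL_CONTINUOUS:
            if clin not in dft.columns:
                continue
            for outcome in all_outcomes:
                x = dft[clin].to_numpy(float)
                y = dft[outcome].to_numpy(float)
                try:
                    r, p, cat = correlate_and_classify(x, y, "continuous")
                except ValueError:
                    continue
                corr_rows.append({"task": task, "clinical": clin,
                                  "outcome": outcome, "r": r, "p": p,
                                  "type": "pearson", "category": cat})

    regression: dict[str, StepwiseResult] = {}
    if run_regression:
        for task, dft in merged.groupby("task"):
            cols = [p for p in REGRESSION_PREDICTORS if p in dft.columns]
            if "APS" in dft.columns and len(cols) == len(REGRESSION_PREDICTORS):
                try:
                    regression[task] = forward_stepwise_regression(dft)
                except ValueError:
                    pass

    return StatsReport(
        group_tests=pd.DataFrame(gt_rows),
        posthoc=pd.DataFrame(
            ph_rows, columns=["task", "outcome", "pair", "U", "p",
                              "applicable", "threshold", "reject"]
        ),
        correlations=pd.DataFrame(
            corr_rows, columns=["task", "clinical", "outcome", "r", "p",
                                "type", "category"]
        ),
        regression=regression,
        excluded=excluded,
    )


def _row_pos(rows: list[dict], task: str, outcome: str) -> int:
    for i, r in enumerate(rows):
        if r["task"] == task and r["outcome"] == outcome:
            return i
    raise KeyError((task, outcome))
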