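"""Goodness-of-fit metrics, experimental conditions and nonparametric statistics.

The experimental design crosses three input conditions with two
torque models:

* EGEC -- estimated GRF and estimated COP,
* EGMC -- estimated GRF and measured COP,
* MGEC -- measured GRF and estimated COP,

each fed to model M (inverse dynamics) and model N (hybrid
EMG-informed neuromusculoskeletal model), giving six condition
labels (EGEC-M ... MGEC-N).  The fully measured configuration is the
control: by construction it reproduces the measured torques exactly
under model M.

Per trial and joint, predicted torques (body-mass normalised,
resampled to 100 stance samples) are compared with the measured
reference via R^2 = 1 - SS_res/SS_tot (which may be negative) and
RMSE.  Within- and between-subject comparisons use the Friedman rank
test (tie-corrected) followed by Dunn-Bonferroni post-hoc tests at
p = 0.05; the parametric branch is deliberately not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "ConditionLabel",
    "ConditionResult",
    "CONDITIONS",
    "fit_metrics",
    "friedman_test",
    "dunn_bonferroni",
    "summarize",
]


@dataclass(frozen=True)
class ConditionLabel:
    """One cell of the condition x model design."""

    grf_source: str  # "estimated" | "measured"
    cop_source: str  # "estimated" | "measured"
    model: str       # "M" (inverse dynamics) | "N" (hybrid)

    def __post_init__(self) -> None:
        if self.grf_source not in ("estimated", "measured"):
            raise ValueError(f"bad grf_source {self.grf_source!r}")
        if self.cop_source not in ("estimated", "measured"):
            raise ValueError(f"bad cop_source {self.cop_source!r}")
        if self.model not in ("M", "N"):
            raise ValueError(f"bad model {self.model!r}")

    @property
    def name(self) -> str:
        if self.grf_source == "measured" and self.cop_source == "measured":
            return f"CONTROL-{self.model}"  # oracle configuration, not a study condition
        g = "EG" if self.grf_source == "estimated" else "MG"
        c = "EC" if self.cop_source == "estimated" else "MC"
        return f"{g}{c}-{self.model}"


#: The six study conditions in table order.
CONDITIONS: tuple[ConditionLabel, ...] = tuple(
    ConditionLabel(g, c, m)
    for (g, c) in (("estimated", "estimated"), ("estimated", "measured"),
                   ("measured", "estimated"))
    for m in ("M", "N")
)


@dataclass
class ConditionResult:
    """R^2/RMSE of one trial x joint x condition cell."""

    subject: str
    trial: int
    joint: str
    condition: ConditionLabel
    torque_pred: np.ndarray  # length 100, Nm/kg
    torque_meas: np.ndarray  # length 100, Nm/kg
    r2: float = field(init=False)
    rmse: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.torque_pred) != 100 or len(self.torque_meas) != 100:
            raise ValueError("torque series must be phase-normalised to 100 samples")
        self.r2, self.rmse = fit_metrics(self.torque_meas, self.torque_pred)


def fit_metrics(y_meas, y_pred) -> tuple[float, float]:
    """(R^2, RMSE) of a prediction against a measured series.

    ``R^2 = 1 - SS_res / SS_tot`` about the mean of the measured
    series (not a squared correlation); it is negative when the
    prediction is worse than the measured mean.
    """
    y_meas = np.asarray(y_meas, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_meas.shape != y_pred.shape or y_meas.ndim != 1 or len(y_meas) < 2:
        raise ValueError("series must be 1-D, equal length and have >= 2 samples")
    ss_tot = float(np.sum((y_meas - y_meas.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("measured series has zero variance; R^2 is undefined")
    ss_res = float(np.sum((y_meas - y_pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((y_meas - y_pred) ** 2)))
    return r2, rmse


def friedman_test(data) -> tuple[float, int, float]:
    """Tie-corrected Friedman rank test over a blocks x treatments matrix.

    Blocks (rows) are the repeated-measures units; treatments
    (columns) are ranked within each block with mid-ranks for ties.
    Returns (chi-square statistic, degrees of freedom, p value).
    """
    a = np.asarray(data, dtype=float)
    if a.ndim != 2 or a.shape[1] < 2 or a.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 blocks and >= 2 treatments")
    n, k = a.shape
    ranks = np.apply_along_axis(_stats.rankdata, 1, a)
    rank_sums = ranks.sum(axis=0)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in a:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)
    if correction > 0:
        chi2 /= correction
    else:
        chi2 = 0.0  # all rows fully tied
    df = k - 1
    p = float(_stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return float(chi2), df, p


def dunn_bonferroni(data, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Dunn post-hoc tests with Bonferroni correction.

    z statistics are built from mean ranks of the within-block
    ranking; two-sided normal p values are multiplied by the number of
    comparisons and capped at 1.  Returns a DataFrame with one row per
    treatment pair.
    """
    a = np.asarray(data, dtype=float)
    if a.ndim != 2 or a.shape[1] < 2 or a.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 blocks and >= 2 treatments")
    n, k = a.shape
    ranks = np.apply_along_axis(_stats.rankdata, 1, a)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    n_comp = k * (k - 1) // 2
    rows = []
    for i, j in combinations(range(k), 2):
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * float(_stats.norm.sf(abs(z)))
        p_adj = min(1.0, p_raw * n_comp)
        rows.append({"treatment_a": i, "treatment_b": j, "z": float(z),
                     "p_raw": p_raw, "p_adj": p_adj,
                     "significant": bool(p_adj < alpha)})
    return pd.DataFrame(rows)


def summarize(results: list[ConditionResult]) -> dict[str, pd.DataFrame]:
    """Cohort tables: per-condition x joint mean +- SD of R^2 and RMSE.

    Returns ``{"r2": ..., "rmse": ..., "long": ...}`` where the first
    two are 6-condition x 3-joint tables of ``mean +- SD`` strings and
    ``long`` is the tidy per-trial table feeding the statistics.
    Empty design cells raise.
    """
    if not results:
        raise ValueError("no results to summarise")
    long = pd.DataFrame([
        {"subject": r.subject, "trial": r.trial, "joint": r.joint,
         "condition": r.condition.name, "r2": r.r2, "rmse": r.rmse}
        for r in results
    ])
    joints = ["hip", "knee", "ankle"]
    cond_names = [c.name for c in CONDITIONS if any(
        r.condition.name == c.name for r in results)]
    tables = {}
    for metric in ("r2", "rmse"):
        cells = {}
        for cond in cond_names:
            row = {}
            for joint in joints:
                sel = long[(long.condition == cond) & (long.joint == joint)][metric]
                if sel.empty:
                    raise ValueError(f"empty design cell: {cond} x {joint}")
                row[joint] = f"{sel.mean():.3f} ± {sel.std(ddof=0):.3f}"
            cells[cond] = row
        tables[metric] = pd.DataFrame(cells).T[joints]
    tables["long"] = long
    return tables
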