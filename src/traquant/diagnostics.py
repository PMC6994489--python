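"""ROC analysis of the patient-level measures between cohort groups.

The AUC is computed through the Wilcoxon-Mann-Whitney identity (ties count
one half) and oriented so that AUC >= 0.5.  The confidence interval and the
two-sided p-value against AUC = 0.5 use the Hanley-McNeil standard error
with a normal approximation by default (the classic ROC reporting style),
with the DeLong variance available as an option.  No multiple-testing
correction is applied across the default comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .config import PipelineConfig

__all__ = ["RocResult", "roc", "run_comparisons", "DEFAULT_PLAN", "plot_roc"]

#: The default comparison plan: the TRA+ percentage (measure 1) between
#: healthy/localized and metastatic, and the CD45 difference (measure 3)
#: between all three group pairs.  Each row is (measure, group_a, group_b)
#: with group_b treated as the positive (disease) class.
DEFAULT_PLAN: list[tuple[str, str, str]] = [
    ("mean_pct_tra", "healthy", "metastatic"),
    ("mean_pct_tra", "localized", "metastatic"),
    ("cd45_diff", "healthy", "metastatic"),
    ("cd45_diff", "localized", "metastatic"),
    ("cd45_diff", "healthy", "localized"),
]

#: Measures that require the minimum-TRA+-cells inclusion rule.
_DIFF_MEASURES = {"cd45_diff"}


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    curve: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)
    n_pos: int
    n_neg: int
    se: float
    method: str = "hanley"

    def __post_init__(self) -> None:
        if not 0.5 <= self.auc <= 1.0 + 1e-12:
            raise ValueError("auc must lie in [0.5, 1] after orientation")
        if not self.ci_low <= self.auc <= self.ci_high + 1e-12:
            raise ValueError("CI must bracket the AUC")


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(random positive > random negative), ties counted one half."""
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)
    r_pos = ranks[: len(pos)].sum()
    n_pos, n_neg = len(pos), len(neg)
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def _hanley_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    n_pos, n_neg = len(pos), len(neg)
    var = 0.0
    if n_pos > 1:
        var += np.var(v10, ddof=1) / n_pos
    if n_neg > 1:
        var += np.var(v01, ddof=1) / n_neg
    return float(np.sqrt(var))


def roc(
    scores,
    labels,
    method: str = "hanley",
    conf_level: float = 0.95,
) -> RocResult:
    """ROC of per-patient scores; ``labels`` truthy = positive class.

    The orientation (sign of the scores) is chosen so AUC >= 0.5; the
    reported curve uses the oriented scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both groups must be non-empty")
    if method not in ("hanley", "delong"):
        raise ValueError("method must be 'hanley' or 'delong'")

    pos, neg = scores[labels], scores[~labels]
    auc = _mann_whitney_auc(pos, neg)
    oriented = scores if auc >= 0.5 else -scores
    if auc < 0.5:
        auc = 1.0 - auc
        pos, neg = -pos, -neg

    se = _hanley_se(auc, n_pos, n_neg) if method == "hanley" else _delong_se(pos, neg)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    ci_low = float(np.clip(auc - z * se, 0.0, 1.0))
    ci_high = float(np.clip(auc + z * se, 0.0, 1.0))
    if se > 0:
        p = float(2.0 * stats.norm.sf((auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else 0.0

    fpr, tpr, _ = _sk_roc_curve(labels, oriented, drop_intermediate=False)
    return RocResult(
        auc=float(auc),
        ci_low=ci_low,
        ci_high=min(ci_high, 1.0),
        p_value=min(p, 1.0),
        curve=(fpr, tpr),
        n_pos=n_pos,
        n_neg=n_neg,
        se=se,
        method=method,
    )


def run_comparisons(
    summaries: pd.DataFrame,
    plan: list[tuple[str, str, str]] | None = None,
    cfg: PipelineConfig | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """One ROC per plan row over the patient-summary table.

    For the CD45-difference measure only patients flagged
    ``included_in_diff`` enter; with ``strict=True`` a comparison whose
    group has fewer than two included patients raises, otherwise it yields
    a NaN row with a note.
    """
    cfg = cfg or PipelineConfig()
    plan = DEFAULT_PLAN if plan is None else plan
    rows = []
    for measure, group_a, group_b in plan:
        sub = summaries[summaries["group"].isin([group_a, group_b])]
        if measure in _DIFF_MEASURES:
            sub = sub[sub["included_in_diff"].astype(bool)]
        note = ""
        result = None
        n_a = int((sub["group"] == group_a).sum())
        n_b = int((sub["group"] == group_b).sum())
        if measure in _DIFF_MEASURES and min(n_a, n_b) < 2:
            msg = (
                f"{measure} {group_a} vs {group_b}: fewer than 2 included "
                f"patients in a group (n_a={n_a}, n_b={n_b})"
            )
            if strict:
                raise ValueError(msg)
            note = msg
        elif min(n_a, n_b) < 1:
            msg = f"{measure} {group_a} vs {group_b}: empty group"
            if strict:
                raise ValueError(msg)
            note = msg
        else:
            result = roc(
                sub[measure].to_numpy(float),
                (sub["group"] == group_b).to_numpy(),
                method=cfg.roc_method,
            )
        rows.append(
            {
                "measure": measure,
                "group_a": group_a,
                "group_b": group_b,
                "n_a": n_a,
                "n_b": n_b,
                "auc": result.auc if result else np.nan,
                "ci_low": result.ci_low if result else np.nan,
                "ci_high": result.ci_high if result else np.nan,
                "p_value": result.p_value if result else np.nan,
                "method": cfg.roc_method,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def plot_roc(results: dict[str, RocResult], path) -> None:
    """Save an overlay plot of ROC curves (one line per comparison)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, res in results.items():
        fpr, tpr = res.curve
        ax.plot(fpr, tpr, label=f"{name} (AUC {res.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
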