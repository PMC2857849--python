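"""Comparison metrics for predicted vs true breeding values.

All metrics are computed over whichever animals the caller supplies —
typically the validation (non-phenotyped) set:

* accuracy — Pearson correlation between true and predicted BV;
* regression slope of true on predicted — cov(true, pred)/var(pred);
  a slope near 1 indicates unbiased dispersion, below 1 inflated predictions;
* top-N overlap — percent of the true top-N animals recovered in the
  predicted top-N (ties broken by descending value, then ascending id);
* cross-time-point EBV correlation matrix;
* within-full-sib-family spread of predictions (pedigree BLUP gives
  unphenotyped full sibs identical parent-average EBVs; marker-based
  matrices expose Mendelian sampling and spread them out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, NumericalError
from .pedigree import Pedigree


def _aligned(true_bv: pd.Series, pred_bv: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    if not true_bv.index.equals(pred_bv.index):
        common = true_bv.index.intersection(pred_bv.index)
        if len(common) == 0:
            raise DataError("true and predicted BV share no individuals")
        true_bv, pred_bv = true_bv.loc[common], pred_bv.loc[common]
    return true_bv.to_numpy(dtype=float), pred_bv.to_numpy(dtype=float)


def accuracy(true_bv: pd.Series, pred_bv: pd.Series) -> float:
    """Pearson correlation between true and predicted breeding values."""
    t, p = _aligned(true_bv, pred_bv)
    if len(t) < 3:
        raise DataError("need >= 3 animals")
    if np.var(t) == 0.0 or np.var(p) == 0.0:
        raise NumericalError("accuracy undefined: zero variance")
    return float(np.corrcoef(t, p)[0, 1])


def regression_true_on_pred(true_bv: pd.Series, pred_bv: pd.Series) -> float:
    """OLS slope of true on predicted BV: cov(true, pred) / var(pred)."""
    t, p = _aligned(true_bv, pred_bv)
    if len(t) < 3:
        raise DataError("need >= 3 animals")
    vp = np.var(p, ddof=1)
    if vp == 0.0:
        raise NumericalError("regression undefined: zero predictor variance")
    return float(np.cov(t, p, ddof=1)[0, 1] / vp)


def _top_ids(values: pd.Series, n: int) -> set[str]:
    order = values.to_frame("v").assign(_id=values.index.astype(str))
    order = order.sort_values(["v", "_id"], ascending=[False, True])
    return set(order.index[:n].astype(str))


def topn_overlap(true_bv: pd.Series, pred_bv: pd.Series, n: int = 20) -> float:
    """Percent of the true top-n set present in the predicted top-n set."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    t, p = true_bv, pred_bv
    common = t.index.intersection(p.index)
    if len(common) < n:
        raise ConfigError(f"top-{n} requested but only {len(common)} animals")
    t, p = t.loc[common], p.loc[common]
    return 100.0 * len(_top_ids(t, n) & _top_ids(p, n)) / n


def ebv_correlations(ebv: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of EBVs across fitted time points.

    ``ebv`` is wide: index = animal, one column per time point.
    """
    if ebv.shape[1] < 2:
        raise DataError("need >= 2 time points")
    X = ebv.to_numpy(dtype=float)
    if (np.var(X, axis=0) == 0.0).any():
        bad = [c for c, v in zip(ebv.columns, np.var(X, axis=0)) if v == 0.0]
        raise NumericalError(f"zero-variance time points: {bad}")
    corr = np.corrcoef(X, rowvar=False)
    return pd.DataFrame(corr, index=ebv.columns, columns=ebv.columns)


def family_spread(pred_bv: pd.Series, ped: Pedigree) -> pd.DataFrame:
    """Within-full-sib-family spread of predictions.

    One row per full-sib family (same sire and dam, both known) having at
    least one member in ``pred_bv``: member count, mean, SD (ddof=1; reported
    as 0 with ``singleton=True`` for one-member families).
    """
    idx = set(pred_bv.index.astype(str))
    rows = []
    for (sire, dam), members in ped.full_sib_families().items():
        present = [m for m in members if m in idx]
        if not present:
            continue
        vals = pred_bv.loc[present].to_numpy(dtype=float)
        singleton = len(vals) == 1
        rows.append(
            {
                "sire": sire,
                "dam": dam,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": 0.0 if singleton else float(vals.std(ddof=1)),
                "singleton": singleton,
            }
        )
    return pd.DataFrame(
        rows, columns=["sire", "dam", "n", "mean", "sd", "singleton"]
    )


@dataclass
class MethodEvaluation:
    """All comparison metrics for one relationship-matrix method."""

    method: str
    accuracy: float | None
    regression_slope: float | None
    topn_overlap_pct: float | None
    pred_variance: float
    ebv_corr: pd.DataFrame | None
    family_spread: pd.DataFrame

    def summary_row(self) -> dict:
        fam = self.family_spread
        multi = fam[~fam["singleton"]] if len(fam) else fam
        return {
            "method": self.method,
            "accuracy": self.accuracy,
            "regression_slope": self.regression_slope,
            "topn_overlap_pct": self.topn_overlap_pct,
            "pred_variance": self.pred_variance,
            "mean_family_sd": float(multi["sd"].mean()) if len(multi) else np.nan,
        }


def evaluate_method(
    method: str,
    pred_bv: pd.Series,
    ebv: pd.DataFrame | None,
    ped: Pedigree,
    true_bv: pd.Series | None = None,
    top_n: int = 20,
    validation_ids: list[str] | None = None,
) -> MethodEvaluation:
    """Assemble the full metric set for one method.

    Truth-dependent metrics are ``None`` when ``true_bv`` is not supplied.
    Metrics are restricted to ``validation_ids`` when given.
    """
    if validation_ids is not None:
        pred_eval = pred_bv.loc[[i for i in validation_ids if i in pred_bv.index]]
    else:
        pred_eval = pred_bv
    acc = slope = overlap = None
    if true_bv is not None:
        tv = true_bv.loc[pred_eval.index]
        acc = accuracy(tv, pred_eval)
        slope = regression_true_on_pred(tv, pred_eval)
        overlap = topn_overlap(tv, pred_eval, n=top_n)
    return MethodEvaluation(
        method=method,
        accuracy=acc,
        regression_slope=slope,
        topn_overlap_pct=overlap,
        pred_variance=float(pred_eval.var(ddof=1)),
        ebv_corr=ebv_correlations(ebv) if ebv is not None else None,
        family_spread=family_spread(pred_eval, ped),
    )


def plot_family_spread(
    evaluations: list[MethodEvaluation], path: str, max_families: int = 8
) -> None:
    """Optional strip plot of per-family predicted BVs (largest families)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, len(evaluations), figsize=(4 * len(evaluations), 3), squeeze=False
    )
    for ax, ev in zip(axes[0], evaluations):
        fam = ev.family_spread.sort_values("n", ascending=False).head(max_families)
        ax.bar(range(len(fam)), fam["sd"])
        ax.set_title(f"{ev.method}: within-family SD")
        ax.set_xlabel("family")
        ax.set_ylabel("SD of predicted BV")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
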