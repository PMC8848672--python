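"""Monte-Carlo performance criteria and benchmark-shaped report tables.

Per (scenario, estimator) cell over B replicates of the exposure
coefficient beta_hat:

    bias      B_MC  = mean(beta_hat - beta)
    variance  V_MC  = sum (beta_hat - mean)^2 / (B - 1)
    mse       MSE_MC = sum (beta_hat - beta)^2 / (B - 1)
    rrmse     RRMSE_MC = 100 * sqrt(MSE_MC) / beta
    coverage  100 * fraction of Wald intervals containing beta

Note the MSE divisor is (B - 1), not B; it is kept that way deliberately
so the summaries match the benchmark tables cell for cell, which implies
MSE - variance = (bias)^2 * B/(B-1) rather than bias^2 exactly.

The published RRMSE cells are reproducible only with beta^2 in the
denominator (twice the value the displayed formula gives with beta = 0.5);
``rrmse_denominator="beta_squared"`` switches to that convention.  The
stated formula is the default; neither convention is endorsed as correct.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "MetricsRow",
    "mc_bias",
    "mc_variance",
    "mc_mse",
    "mc_rrmse",
    "empirical_coverage",
    "normal_coverage",
    "summarize_cell",
    "summarize",
    "write_report_tables",
]


@dataclass(frozen=True)
class MetricsRow:
    scenario: str
    estimator_label: str
    bias: float
    variance: float        # natural scale (tables print x 10^-3)
    mse: float             # natural scale
    rrmse: float           # percent
    coverage: float        # percent
    n_used: int            # replicates included (failures excluded)


def _clean(estimates) -> np.ndarray:
    a = np.asarray(estimates, dtype=float)
    if a.size == 0:
        raise ValueError("no estimates supplied")
    return a


def mc_bias(estimates, beta_true: float) -> float:
    """Mean deviation of the estimates from the true coefficient."""
    return float(np.mean(_clean(estimates) - beta_true))


def mc_variance(estimates) -> float:
    """Unbiased sample variance of the estimates (divisor B-1)."""
    a = _clean(estimates)
    if a.size < 2:
        raise ValueError("variance needs at least 2 estimates")
    return float(np.var(a, ddof=1))


def mc_mse(estimates, beta_true: float) -> float:
    """Sum of squared deviations from the TRUE coefficient over (B-1)."""
    a = _clean(estimates)
    if a.size < 2:
        raise ValueError("mse needs at least 2 estimates")
    return float(np.sum((a - beta_true) ** 2) / (a.size - 1))


def mc_rrmse(mse: float, beta_true: float, denominator: str = "beta") -> float:
    """Relative root MSE in percent: 100*sqrt(MSE)/beta.

    ``denominator="beta_squared"`` reproduces the published tables'
    convention (100*sqrt(MSE)/beta^2).
    """
    if beta_true == 0.0:
        raise ValueError("rrmse is undefined for beta = 0")
    if mse < 0.0:
        raise ValueError(f"mse must be >= 0, got {mse}")
    if denominator == "beta":
        return float(100.0 * np.sqrt(mse) / beta_true)
    if denominator == "beta_squared":
        return float(100.0 * np.sqrt(mse) / beta_true**2)
    raise ValueError(f"unknown rrmse denominator {denominator!r}")


def empirical_coverage(ci_lower, ci_upper, beta_true: float) -> float:
    """Percent of intervals containing the true coefficient."""
    lo = _clean(ci_lower)
    hi = _clean(ci_upper)
    if lo.shape != hi.shape:
        raise ValueError("ci bounds have mismatched shapes")
    return float(100.0 * np.mean((lo <= beta_true) & (beta_true <= hi)))


def normal_coverage(bias: float, variance: float, level: float = 0.95) -> float:
    """Closed-form coverage of a normal estimator with the given Monte-Carlo
    bias and variance: Phi(z - b/sd) - Phi(-z - b/sd), in percent.

    Used as a consistency cross-check on the empirical coverage.
    """
    if variance <= 0.0:
        raise ValueError(f"variance must be > 0, got {variance}")
    z = norm.ppf(0.5 + level / 2.0)
    shift = bias / np.sqrt(variance)
    return float(100.0 * (norm.cdf(z - shift) - norm.cdf(-z - shift)))


def summarize_cell(
    cell: pd.DataFrame,
    beta_true: float,
    rrmse_denominator: str = "beta",
) -> MetricsRow:
    """Summaries for one (scenario, estimator) slice of the tidy frame.

    Failed replicates (NaN beta) are dropped with the divisor adjusted;
    ``n_used`` reports how many remain.
    """
    ok = cell[np.isfinite(cell["beta"].to_numpy(dtype=float))]
    betas = ok["beta"].to_numpy(dtype=float)
    mse = mc_mse(betas, beta_true)
    return MetricsRow(
        scenario=str(cell["scenario"].iloc[0]),
        estimator_label=str(cell["estimator"].iloc[0]),
        bias=mc_bias(betas, beta_true),
        variance=mc_variance(betas),
        mse=mse,
        rrmse=mc_rrmse(mse, beta_true, rrmse_denominator),
        coverage=empirical_coverage(
            ok["ci_lower"].to_numpy(dtype=float),
            ok["ci_upper"].to_numpy(dtype=float),
            beta_true,
        ),
        n_used=len(ok),
    )


def summarize(
    frame: pd.DataFrame,
    beta_true: float = 0.5,
    rrmse_denominator: str = "beta",
) -> pd.DataFrame:
    """Per-cell metrics for a tidy per-replicate frame.

    Returns one row per (scenario, estimator) with bias, variance, mse,
    rrmse, coverage, n_used; variance and mse on the natural scale.
    """
    rows = []
    for (_, _), cell in frame.groupby(["scenario", "estimator"], sort=False):
        rows.append(summarize_cell(cell, beta_true, rrmse_denominator).__dict__)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Benchmark-shaped report tables
# --------------------------------------------------------------------------

_SCENARIO_BLOCKS = {
    "table3.tsv": ("MAR 1", "MAR 2", "MAR 3"),
    "table4.tsv": ("MNAR 1", "MNAR 2", "MNAR 3"),
    "table5.tsv": ("MNAR 4", "MNAR 5", "MNAR 6"),
}


def _estimator_order(metrics: pd.DataFrame) -> list[str]:
    labels = list(dict.fromkeys(metrics["estimator_label"]))

    def key(lab: str):
        if lab == "CCA":
            return (0, 0)
        if lab.startswith("IPPW(model "):
            return (1, int(lab[len("IPPW(model "):-1]))
        return (2, 0)

    return sorted(labels, key=key)


def write_report_tables(metrics: pd.DataFrame, out_dir) -> list[Path]:
    """Write four TSVs shaped like the benchmark result tables.

    Three accuracy tables (three scenarios each; rows scenario x metric,
    columns CCA + response models, bias rounded to 2 decimals, variance
    and MSE to 3 decimals on the x10^-3 scale, RRMSE to 1 decimal) and one
    coverage table (all nine scenarios, 1 decimal).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    order = _estimator_order(metrics)
    idx = metrics.set_index(["scenario", "estimator_label"])
    written: list[Path] = []

    def fetch(scen, est, col):
        try:
            return idx.loc[(scen, est), col]
        except KeyError:
            return np.nan

    display = [
        ("Bias", "bias", lambda v: f"{v:.2f}"),
        ("Variance (10^-3)", "variance", lambda v: f"{v * 1e3:.3f}"),
        ("MSE (10^-3)", "mse", lambda v: f"{v * 1e3:.3f}"),
        ("RRMSE (%)", "rrmse", lambda v: f"{v:.1f}"),
    ]
    present = set(metrics["scenario"])
    for fname, scens in _SCENARIO_BLOCKS.items():
        block = [s for s in scens if s in present]
        if not block:
            continue
        rows = []
        for scen in block:
            for disp, col, fmt in display:
                row = {"scenario": scen, "metric": disp}
                for est in order:
                    v = fetch(scen, est, col)
                    row[est] = fmt(v) if np.isfinite(v) else ""
                rows.append(row)
        path = out_dir / fname
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)

    rows = []
    for scen in [s for b in _SCENARIO_BLOCKS.values() for s in b if s in present]:
        row = {"scenario": scen, "metric": "Coverage (%)"}
        for est in order:
            v = fetch(scen, est, "coverage")
            row[est] = f"{v:.1f}" if np.isfinite(v) else ""
        rows.append(row)
    path = out_dir / "table6.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    written.append(path)
    return written
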