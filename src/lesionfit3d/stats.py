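"""Method-agreement statistics for paired manual vs ellipsoid measurements.

Implements the comparison battery used when judging a new measurement method
against a clinical reference on the same subjects: paired t-test, Pearson
correlation, Bland–Altman bias and limits of agreement, Lilliefors-style
Kolmogorov–Smirnov normality check, absolute relative percentage difference
of cohort means, and per-score mean ± SD summaries.

Conventions: differences are ``y - x`` (second method minus first), standard
deviations are sample (n−1) everywhere, and the denominator of the relative
percentage difference is the ellipsoid-method mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyInputError, UndefinedStatisticError, ValidationError
from .pirads import round_half_away

__all__ = [
    "AgreementReport",
    "relative_pct_diff",
    "bland_altman",
    "pearson_r",
    "paired_t",
    "ks_normality",
    "summarize_by_score",
    "compare_methods",
    "agreement_plots",
]

MEASUREMENT_COLUMNS = ("manual_tv_cc", "auto_tv_cc", "manual_tmd_cm", "auto_tmd_cm")


def _paired(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError(f"paired inputs differ in length: {x.size} vs {y.size}")
    if x.size < min_n:
        raise ValidationError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    return x, y


def relative_pct_diff(manual_mean: float, ellipsoid_mean: float) -> float:
    """Absolute relative percentage difference, ellipsoid mean as denominator.

    ``100 * |ellipsoid - manual| / ellipsoid``.  Report tables round this to
    the nearest integer (halves away from zero) via
    :func:`lesionfit3d.pirads.round_half_away`.
    """
    if not ellipsoid_mean > 0:
        raise UndefinedStatisticError(
            f"ellipsoid mean must be positive, got {ellipsoid_mean}"
        )
    return 100.0 * abs(ellipsoid_mean - manual_mean) / ellipsoid_mean


def bland_altman(x, y) -> dict[str, float]:
    """Bland–Altman bias and 95% limits of agreement for differences y − x.

    LoA = bias ± 1.96·SD(d), sample (n−1) SD.
    """
    x, y = _paired(x, y, min_n=2)
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd": sd,
    }


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation."""
    x, y = _paired(x, y, min_n=3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    return float(sps.pearsonr(x, y).statistic)


def paired_t(x, y) -> dict[str, float]:
    """Two-sided paired t-test on differences y − x (n−1 df).

    All-zero differences are a defined degenerate case: t = 0, p = 1.
    """
    x, y = _paired(x, y, min_n=2)
    d = y - x
    if np.all(d == 0):
        return {"t_stat": 0.0, "p_value": 1.0}
    if d.std(ddof=1) == 0:
        # constant nonzero difference: infinite evidence against zero bias
        return {"t_stat": float(np.inf) * np.sign(d.mean()), "p_value": 0.0}
    res = sps.ttest_rel(y, x)
    return {"t_stat": float(res.statistic), "p_value": float(res.pvalue)}


def ks_normality(x) -> float:
    """Lilliefors-style one-sample KS normality p-value.

    Tests against a normal distribution with mean/SD estimated from the
    sample (plain KS with plugged-in parameters is anti-conservative).
    p-values come from the Lilliefors table and are clipped to its range.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 5:
        raise ValidationError(f"normality test needs n >= 5, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("inputs must be finite")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("normality undefined for constant input")
    from statsmodels.stats.diagnostic import lilliefors

    _, p = lilliefors(x, dist="norm")
    return float(min(max(p, 0.0), 1.0))


def summarize_by_score(table: pd.DataFrame) -> pd.DataFrame:
    """Per-score mean ± SD of the four measurement columns.

    SD is sample (n−1); scores represented by a single subject report SD as
    NaN (absent).  Returns a frame indexed by ``initial_score`` with columns
    ``<col>_mean``, ``<col>_sd`` and ``n``.
    """
    if len(table) == 0:
        raise EmptyInputError("cannot summarize an empty cohort table")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table lacks measurement columns: {missing}")
    g = table.groupby("initial_score")
    out = {}
    for col in MEASUREMENT_COLUMNS:
        out[f"{col}_mean"] = g[col].mean()
        out[f"{col}_sd"] = g[col].std(ddof=1)
    out["n"] = g.size()
    return pd.DataFrame(out)


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement battery for one paired measurement (e.g. TV or TMD)."""

    label: str
    n: int
    bias: float
    loa_low: float
    loa_high: float
    pearson_r: float
    t_stat: float
    p_value: float
    ks_p: float | None
    rel_pct_diff: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "pearson_r": self.pearson_r,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "ks_p": self.ks_p,
            "rel_pct_diff": self.rel_pct_diff,
            "rel_pct_diff_int": round_half_away(self.rel_pct_diff),
        }

    def summary(self) -> str:
        ks = "n/a" if self.ks_p is None else f"{self.ks_p:.3f}"
        return "\n".join(
            [
                f"Agreement: {self.label} (n={self.n})",
                f"  bias (ellipsoid - manual)  {self.bias:+.4f}",
                f"  95% limits of agreement    [{self.loa_low:+.4f}, {self.loa_high:+.4f}]",
                f"  Pearson r                  {self.pearson_r:.3f}",
                f"  paired t (p)               {self.t_stat:.3f} ({self.p_value:.4f})",
                f"  KS normality p (diffs)     {ks}",
                f"  relative % difference      {round_half_away(self.rel_pct_diff)}%",
            ]
        )


def compare_methods(manual, ellipsoid, label: str = "measurement") -> AgreementReport:
    """Run the full agreement battery of this package on one paired column."""
    x, y = _paired(manual, ellipsoid, min_n=3)
    ba = bland_altman(x, y)
    t = paired_t(x, y)
    d = y - x
    try:
        ks_p = ks_normality(d) if d.size >= 5 else None
    except UndefinedStatisticError:
        ks_p = None
    return AgreementReport(
        label=label,
        n=int(x.size),
        bias=ba["bias"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        pearson_r=pearson_r(x, y),
        t_stat=t["t_stat"],
        p_value=t["p_value"],
        ks_p=ks_p,
        rel_pct_diff=relative_pct_diff(float(x.mean()), float(y.mean())),
    )


def agreement_plots(manual, ellipsoid, outdir, label: str = "measurement") -> list[str]:
    """Optional convenience figures: scatter, Bland–Altman, violin.

    Numeric reports are the contract; these files are visual aids only.
    Returns the written file paths.
    """
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = _paired(manual, ellipsoid, min_n=2)
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=18)
    lim = [0, max(x.max(), y.max()) * 1.1]
    ax.plot(lim, lim, "k--", lw=0.8)
    ax.set_xlabel(f"manual {label}")
    ax.set_ylabel(f"ellipsoid {label}")
    path = outdir / f"scatter_{label}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    ba = bland_altman(x, y)
    mean_xy = (x + y) / 2
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(mean_xy, y - x, s=18)
    for v, style in ((ba["bias"], "-"), (ba["loa_low"], ":"), (ba["loa_high"], ":")):
        ax.axhline(v, color="b", ls=style, lw=0.9)
    ax.set_xlabel(f"mean {label}")
    ax.set_ylabel("difference (ellipsoid - manual)")
    path = outdir / f"bland_altman_{label}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.violinplot([x, y], showmeans=True)
    ax.set_xticks([1, 2], ["manual", "ellipsoid"])
    ax.set_ylabel(label)
    path = outdir / f"violin_{label}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))
    return written
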