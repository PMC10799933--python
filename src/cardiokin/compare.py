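"""Treatment deltas, frequency ratios and cross-tracker agreement.

All inputs are tidy pandas tables.  Summary tables carry one row per
(tracker, frequency, parameter) with a ``mean`` column; per-beat tables are
the flat schema produced by :func:`cardiokin.beats.beats_table`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PairingError, UndefinedRatioError

__all__ = [
    "treatment_delta",
    "frequency_ratio",
    "cross_tracker_agreement",
    "kinematics_anova",
    "normality_check",
]

KEY = ["tracker", "frequency", "parameter"]


def treatment_delta(control: pd.DataFrame, treated: pd.DataFrame) -> pd.DataFrame:
    """Treated-minus-control difference of the group means, per key.

    Both inputs need matching (tracker, frequency, parameter) keys and a
    ``mean`` column.  Besides the raw delta (ms or profile units) a
    control-normalized column ``delta_over_control`` is emitted, covering
    both readings of a "normalized for the control mean value" report.
    """
    c = control.set_index(KEY)["mean"]
    t = treated.set_index(KEY)["mean"]
    missing = sorted(set(c.index.symmetric_difference(t.index)))
    if missing:
        raise PairingError(missing)
    out = pd.DataFrame(
        {
            "control_mean": c,
            "treated_mean": t,
            "delta": t - c,
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["delta_over_control"] = np.where(
            out["control_mean"] != 0, out["delta"] / out["control_mean"], np.nan
        )
    return out.reset_index()


def frequency_ratio(summaries: pd.DataFrame, base_frequency: float) -> pd.DataFrame:
    """mean(f) / mean(base) per tracker and parameter, for every non-base f.

    Mirrors the comparison of parameter means at the higher pacing rates
    against the lowest one.  A zero base mean is undefined.
    """
    if base_frequency not in set(summaries["frequency"]):
        raise UndefinedRatioError(f"base frequency {base_frequency} not present")
    base = summaries[summaries["frequency"] == base_frequency].set_index(
        ["tracker", "parameter"]
    )["mean"]
    rows = []
    for freq, grp in summaries.groupby("frequency"):
        if freq == base_frequency:
            continue
        g = grp.set_index(["tracker", "parameter"])["mean"]
        for key, val in g.items():
            if key not in base.index:
                raise PairingError([key])
            b = base.loc[key]
            if b == 0:
                raise UndefinedRatioError(f"zero base mean for {key}")
            rows.append(
                {
                    "tracker": key[0],
                    "parameter": key[1],
                    "frequency": freq,
                    "base_frequency": base_frequency,
                    "ratio": val / b,
                }
            )
    return pd.DataFrame(rows)


def cross_tracker_agreement(
    beat_tables: dict[str, pd.DataFrame],
    parameters: tuple[str, ...] = (
        "beat_duration_ms",
        "t_theta_c_ms",
        "t_theta_r_ms",
        "t_theta_cr_ms",
    ),
) -> pd.DataFrame:
    """Pairwise agreement of per-beat parameters across trackers.

    For every tracker pair and parameter: mean absolute difference and
    Spearman rank correlation over beats, aligned on beat index.  Unequal
    beat counts are intersected with a warning.
    """
    if len(beat_tables) < 2:
        raise ValueError("need per-beat tables from at least two trackers")
    names = sorted(beat_tables)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            ta = beat_tables[na].set_index("beat_index")
            tb = beat_tables[nb].set_index("beat_index")
            common = ta.index.intersection(tb.index)
            if len(ta) != len(tb) or len(common) < len(ta):
                warnings.warn(
                    f"beat count mismatch between {na} ({len(ta)}) and "
                    f"{nb} ({len(tb)}); aligned on {len(common)} shared beats"
                )
            for param in parameters:
                a = ta.loc[common, param].to_numpy(dtype=float)
                b = tb.loc[common, param].to_numpy(dtype=float)
                mad = float(np.mean(np.abs(a - b))) if len(common) else np.nan
                if len(common) >= 2 and np.std(a) > 0 and np.std(b) > 0:
                    rho = float(stats.spearmanr(a, b).statistic)
                elif len(common) >= 1 and np.allclose(a - b, (a - b)[0]):
                    rho = 1.0  # identical up to a constant shift
                else:
                    rho = np.nan
                rows.append(
                    {
                        "tracker_a": na,
                        "tracker_b": nb,
                        "parameter": param,
                        "n_beats": len(common),
                        "mean_abs_diff": mad,
                        "spearman_rho": rho,
                    }
                )
    return pd.DataFrame(rows)


def kinematics_anova(
    per_beat: pd.DataFrame,
    parameter: str,
    within: str = "arm",
    between: str = "tracker",
) -> pd.DataFrame:
    """Two-way ANOVA convenience wrapper (statsmodels OLS + anova_lm).

    A standard-routine convenience for screening factor effects on a beat
    parameter — not a re-derivation of any statistical machinery.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = per_beat.rename(columns={parameter: "y"})[["y", within, between]].dropna()
    model = ols(f"y ~ C({within}) * C({between})", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def normality_check(values: np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov test against a fitted normal; (statistic, p)."""
    values = np.asarray(values, dtype=float)
    res = stats.kstest(values, "norm", args=(values.mean(), values.std(ddof=1)))
    return float(res.statistic), float(res.pvalue)
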