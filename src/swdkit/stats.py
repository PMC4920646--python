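"""Statistical battery for the normalized seizure and band-power metrics.

Matches the analysis design: non-repeated-measures two-way ANOVA with drug
and time (20-min epoch) as factors on the normalized values, Dunnett
contrasts of each drug arm vs vehicle on animal-level treatment means,
Sidak-corrected per-epoch drug-vs-vehicle comparisons for the time course,
and an unpaired t-test for SWD peak frequency.  Unbalanced designs use a
marginal (type-III) decomposition with sum-to-zero contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "anova_two_way",
    "dunnett_vs_vehicle",
    "sidak_per_epoch",
    "peak_freq_test",
]


def anova_two_way(
    table: pd.DataFrame,
    value_col: str,
    *,
    drug_col: str = "dose_arm",
    time_col: str = "epoch_index",
) -> pd.DataFrame:
    """Two-way ANOVA (drug x time), type-III sums of squares.

    ``table`` holds one row per animal x epoch with the normalized value.
    Returns the ANOVA table with F, df and p for drug, time and the
    interaction.
    """
    df = table[[drug_col, time_col, value_col]].dropna().copy()
    if df[drug_col].nunique() < 2 or df[time_col].nunique() < 2:
        raise ValueError("need at least two levels per factor")
    df = df.rename(columns={drug_col: "drug", time_col: "time", value_col: "value"})
    model = smf.ols(
        "value ~ C(drug, Sum) * C(time, Sum)",
        data=df,
    ).fit()
    return sm.stats.anova_lm(model, typ=3)


def dunnett_vs_vehicle(
    animal_means: pd.DataFrame,
    *,
    value_col: str,
    arm_col: str = "dose_arm",
    vehicle: str = "vehicle",
) -> pd.DataFrame:
    """Dunnett's many-to-one comparisons of drug arms against vehicle.

    ``animal_means`` has one row per animal with its treatment-period mean.
    """
    arms = [a for a in animal_means[arm_col].unique() if a != vehicle]
    if not arms:
        raise ValueError("no drug arms to compare")
    control = animal_means.loc[animal_means[arm_col] == vehicle, value_col].dropna().to_numpy()
    samples = [
        animal_means.loc[animal_means[arm_col] == a, value_col].dropna().to_numpy()
        for a in arms
    ]
    res = sps.dunnett(*samples, control=control)
    return pd.DataFrame(
        {"dose_arm": arms, "statistic": res.statistic, "pvalue": res.pvalue}
    )


def sidak_per_epoch(
    table: pd.DataFrame,
    value_col: str,
    *,
    arm: str,
    vehicle: str = "vehicle",
    arm_col: str = "dose_arm",
    time_col: str = "epoch_index",
    epochs: list[int] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-epoch drug-vs-vehicle t-tests with Sidak family-wise correction.

    The adjusted p-value for m epoch comparisons is 1 - (1 - p)^m; a
    comparison is significant when the adjusted p falls below ``alpha``.
    """
    if epochs is None:
        epochs = sorted(
            set(table.loc[table[arm_col] == arm, time_col]).intersection(
                table.loc[table[arm_col] == vehicle, time_col]
            )
        )
    m = len(epochs)
    rows = []
    for e in epochs:
        a = table.loc[(table[arm_col] == arm) & (table[time_col] == e), value_col].dropna()
        v = table.loc[(table[arm_col] == vehicle) & (table[time_col] == e), value_col].dropna()
        if len(a) < 2 or len(v) < 2:
            rows.append({"epoch_index": e, "t": np.nan, "pvalue": np.nan,
                         "pvalue_sidak": np.nan, "significant": False})
            continue
        t, p = sps.ttest_ind(a, v, equal_var=True)
        p_adj = float(1.0 - (1.0 - p) ** m)
        rows.append(
            {
                "epoch_index": e,
                "t": float(t),
                "pvalue": float(p),
                "pvalue_sidak": p_adj,
                "significant": bool(p_adj < alpha),
            }
        )
    return pd.DataFrame(rows)


def peak_freq_test(
    freqs_a: np.ndarray,
    freqs_b: np.ndarray,
    *,
    equal_var: bool = True,
) -> dict:
    """Unpaired two-sided t-test on animal-level SWD peak frequencies.

    Pooled-variance by default; set ``equal_var=False`` for Welch.
    """
    a = np.asarray(pd.Series(freqs_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(freqs_b).dropna(), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two animals per arm")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return {
        "t": float(t),
        "pvalue": float(p),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
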