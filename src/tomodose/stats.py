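"""Statistical comparison of FWHM measurements across processing arms.

Two analyses mirror the study design: a Tukey-Kramer all-pairs comparison
of the four groups (reference dose, and the low-dose arms without
processing / with MSBF / with pix2pix; unequal n allowed), and a two-way
ANOVA with factors processing (3 low-dose arms) x dose (2 reduced levels),
Type II sums of squares for unbalanced cells.  The reference arm has no
dose factor and therefore joins only the Tukey-Kramer comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

PROCESSING_ARMS = ("reference", "without", "msbf", "pix2pix")


@dataclass
class GroupedMeasurements:
    """Tidy measurement values with processing-arm and dose labels."""

    values: np.ndarray
    arm: np.ndarray  # one of PROCESSING_ARMS per value
    dose: np.ndarray | None = None  # e.g. {"reduce50", "reduce75"}; None for Tukey-only

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.arm = np.asarray(self.arm)
        if self.dose is not None:
            self.dose = np.asarray(self.dose)
            if len(self.dose) != len(self.values):
                raise ValueError("dose labels must match values")
        if len(self.arm) != len(self.values):
            raise ValueError("arm labels must match values")
        groups = pd.Series(self.values).groupby(self.arm).count()
        if len(groups) < 2:
            raise ValueError("need at least 2 groups")
        if (groups < 2).any():
            raise ValueError("every group needs n >= 2")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, value: str = "value", arm: str = "arm", dose: str | None = "dose"
    ) -> "GroupedMeasurements":
        return cls(
            df[value].to_numpy(),
            df[arm].to_numpy(),
            df[dose].to_numpy() if dose is not None and dose in df else None,
        )


def tukey_kramer(g: GroupedMeasurements, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey-Kramer comparison with unequal group sizes.

    For groups i, j: difference of means, standard error
    ``sqrt(MS_within / 2 * (1/n_i + 1/n_j))``, p-value from the studentized
    range distribution with the pooled within-group df, and the
    ``1 - alpha`` simultaneous confidence interval.  Rows are ordered as in
    the published comparison tables (each group versus every other).
    """
    labels = [a for a in PROCESSING_ARMS if a in set(g.arm)]
    labels += sorted(set(g.arm) - set(PROCESSING_ARMS))
    data = {lab: g.values[g.arm == lab] for lab in labels}
    ns = {lab: len(v) for lab, v in data.items()}
    means = {lab: float(v.mean()) for lab, v in data.items()}
    k = len(labels)
    n_total = sum(ns.values())
    df_within = n_total - k
    if df_within < 1:
        raise ValueError("not enough observations for within-group variance")
    ss_within = sum(float(((v - means[lab]) ** 2).sum()) for lab, v in data.items())
    ms_within = ss_within / df_within

    q_crit = sps.studentized_range.ppf(1.0 - alpha, k, df_within)
    rows = []
    for a in labels:
        for b in labels:
            if a == b:
                continue
            diff = means[a] - means[b]
            se = np.sqrt(ms_within / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0.0:
                p = 1.0
            else:
                q = abs(diff) / se
                p = float(np.clip(sps.studentized_range.sf(q, k, df_within), 0.0, 1.0))
            hw = q_crit * se
            rows.append(
                {
                    "group1": a,
                    "group2": b,
                    "difference": diff,
                    "se": se,
                    "p": p,
                    "ci_low": diff - hw,
                    "ci_high": diff + hw,
                }
            )
    return pd.DataFrame(rows)


def two_way_anova(g: GroupedMeasurements) -> pd.DataFrame:
    """Two-way ANOVA (processing x dose), Type II SS.

    Returns rows Processing / Dose / Processing x Dose / Error with df, SS,
    MS, F and p.  The reference arm is excluded (it has no dose factor);
    any empty factorial cell is an error.
    """
    if g.dose is None:
        raise ValueError("dose labels required for the factorial analysis")
    keep = g.arm != "reference"
    df = pd.DataFrame(
        {"value": g.values[keep], "processing": g.arm[keep], "dose": g.dose[keep]}
    )
    cells = df.groupby(["processing", "dose"], observed=True).size().unstack()
    if cells.isna().any().any() or (cells < 1).any().any():
        raise ValueError("empty processing x dose cell")

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("value ~ C(processing) * C(dose)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    rename = {
        "C(processing)": "Processing",
        "C(dose)": "Dose",
        "C(processing):C(dose)": "Processing x Dose",
        "Residual": "Error",
    }
    out = []
    for raw, name in rename.items():
        row = table.loc[raw]
        ms_val = row["sum_sq"] / row["df"]
        out.append(
            {
                "source": name,
                "df": int(row["df"]),
                "ss": float(row["sum_sq"]),
                "ms": float(ms_val),
                "F": float(row["F"]) if np.isfinite(row["F"]) else np.nan,
                "p": float(row["PR(>F)"]) if np.isfinite(row["PR(>F)"]) else np.nan,
            }
        )
    return pd.DataFrame(out)
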