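"""Age-at-onset contrasts between carrier classes.

Cox proportional-hazards models compare bi-allelic (CH or homozygous),
multi-hit *cis* and wild-type samples against a configurable reference
group (heterozygous carriers by default), honouring left truncation at the
age of first record and right censoring at the last.  Ties are handled by
the Efron approximation (the lifelines default).  Kaplan-Meier curves
provide the non-parametric view of the same contrasts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter


def check_eligibility(
    class_counts: pd.Series, min_biallelic: int = 5, min_het: int = 100
) -> bool:
    """Gene-trait eligibility: >= 5 two-hit carriers and >= 100 heterozygotes."""
    two_hit = int(class_counts.get("CH", 0)) + int(class_counts.get("hom", 0))
    return two_hit >= min_biallelic and int(class_counts.get("het", 0)) >= min_het


def fit_carrier_cox(
    data: pd.DataFrame,
    reference_class: str = "het",
    contrast_classes: tuple[str, ...] = ("CH", "hom", "cis", "WT"),
    covariate_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Hazard ratios for carrier classes against a reference group.

    ``data`` needs ``entry_age``, ``exit_age``, ``event`` and
    ``carrier_class`` columns (plus any covariates).  One indicator column
    per contrast class enters a single partial-likelihood fit with left
    truncation.  Classes absent from the data are skipped; classes with
    zero events are flagged with NaN estimates rather than dropped
    silently.  Proportionality is not tested.

    Returns one row per contrast with ``hr``, Wald 95% bounds, ``p``, and
    per-class sample/event counts.
    """
    required = {"entry_age", "exit_age", "event", "carrier_class"}
    if not required <= set(data.columns):
        raise ValueError(f"missing columns: {sorted(required - set(data.columns))}")
    if (data["entry_age"] >= data["exit_age"]).any():
        raise ValueError("entry must precede exit for every sample")
    if data["event"].sum() == 0:
        raise ValueError("no events observed; nothing to fit")

    present = [
        c for c in contrast_classes if (data["carrier_class"] == c).any()
    ]
    keep = data["carrier_class"].isin(present + [reference_class])
    df = data.loc[keep].copy()
    ind_cols = []
    for c in present:
        col = f"is_{c}"
        df[col] = (df["carrier_class"] == c).astype(float)
        ind_cols.append(col)

    fit_cols = ["entry_age", "exit_age", "event"] + ind_cols + list(covariate_cols)
    cph = CoxPHFitter()
    cph.fit(
        df[fit_cols],
        duration_col="exit_age",
        event_col="event",
        entry_col="entry_age",
    )
    summary = cph.summary
    rows = []
    for c in present:
        col = f"is_{c}"
        n_class = int((df["carrier_class"] == c).sum())
        events_class = int(df.loc[df["carrier_class"] == c, "event"].sum())
        if events_class == 0:
            warnings.warn(f"class {c!r} has zero events; HR undefined")
            rows.append(
                {
                    "contrast": c,
                    "reference": reference_class,
                    "hr": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "n": n_class,
                    "n_events": 0,
                }
            )
            continue
        s = summary.loc[col]
        rows.append(
            {
                "contrast": c,
                "reference": reference_class,
                "hr": float(s["exp(coef)"]),
                "ci_low": float(s["exp(coef) lower 95%"]),
                "ci_high": float(s["exp(coef) upper 95%"]),
                "p": float(s["p"]),
                "n": n_class,
                "n_events": events_class,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["log_likelihood"] = float(cph.log_likelihood_)
    return out


def kaplan_meier(data: pd.DataFrame, group_col: str = "carrier_class") -> pd.DataFrame:
    """Product-limit survival estimates per group with 95% bands.

    Honours left truncation via the entry ages.  Empty groups are omitted
    with a warning.  Returns long-format (group, time, survival, ci_low,
    ci_high).
    """
    if data["event"].sum() == 0 and len(data):
        # survival identically one; still return the step skeleton
        pass
    frames = []
    for g, sub in data.groupby(group_col):
        if sub.empty:
            warnings.warn(f"group {g!r} empty; omitted")
            continue
        km = KaplanMeierFitter()
        km.fit(
            sub["exit_age"],
            event_observed=sub["event"],
            entry=sub["entry_age"],
            label=str(g),
        )
        sf = km.survival_function_
        ci = km.confidence_interval_
        frames.append(
            pd.DataFrame(
                {
                    "group": str(g),
                    "time": sf.index.to_numpy(),
                    "survival": sf.iloc[:, 0].to_numpy(),
                    "ci_low": ci.iloc[:, 0].to_numpy(),
                    "ci_high": ci.iloc[:, 1].to_numpy(),
                }
            )
        )
    if not frames:
        raise ValueError("no non-empty groups")
    return pd.concat(frames, ignore_index=True)
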