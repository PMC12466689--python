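"""Treatment-episode construction over each horse's consultation timeline.

Definitions (all windows configurable):

* **initial treatment** — a treated consultation with no antibiotic
  treatment of the same horse in the preceding 30 days (dates d-30 .. d-1
  inclusive, so a prior treatment exactly 30 days earlier makes the
  consultation non-initial);
* **follow-up treatment** — another treated consultation of the same horse
  1-7 days after an initial treatment (day-0 second products are
  combinations, not follow-ups);
* **substance switch** — an initial/follow-up pair, both with exactly one
  antibiotic product, whose substance-class signatures differ; the earliest
  such follow-up is the switch target;
* **repeated treatment** — a horse with >= 2 treated consultations at least
  30 days (and at most one year) apart;
* **return time** — days from any consultation to the horse's next
  consultation, analysed in a 1-21 day window, stratified by whether the
  index consultation was treated.

Follow-up linkage never crosses horses or practices.  Timestamps are
day-resolution throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "label_episodes",
    "repeated_treatment_horses",
    "detect_switches",
    "return_time_distribution",
]

KEY = ["practice_id", "horse_id", "date"]


def _per_horse_treated_dates(consultations: pd.DataFrame,
                             treated_col: str) -> pd.DataFrame:
    d = consultations.copy()
    d["_date"] = pd.to_datetime(d["date"])
    if d.duplicated(subset=KEY).any():
        raise ValueError("consultations are not unique by (practice, horse, day)")
    return d.sort_values(["practice_id", "horse_id", "_date"])


def label_episodes(consultations: pd.DataFrame,
                   treated_col: str = "treated",
                   lookback_days: int = 30,
                   followup_days: int = 7) -> pd.DataFrame:
    """Label every treated consultation with its episode role.

    Returns one row per treated consultation with ``is_initial``,
    ``has_followup_treatment_7d`` (another treated consultation of the same
    horse within ``followup_days`` after it) and ``followup_offsets`` (day
    offsets of those treated consultations, each in ``[1, followup_days]``).
    """
    d = _per_horse_treated_dates(consultations, treated_col)
    treated = d[d[treated_col].astype(bool)]
    rows = []
    for (prac, horse), grp in treated.groupby(["practice_id", "horse_id"],
                                              sort=False):
        days = grp["_date"].to_numpy().astype("datetime64[D]").astype("int64")
        dates = grp["date"].to_numpy()
        for i, day in enumerate(days):
            lo = np.searchsorted(days, day - lookback_days, side="left")
            prior = days[lo:i]
            is_initial = prior.size == 0
            hi = np.searchsorted(days, day + followup_days, side="right")
            offsets = (days[i + 1:hi] - day).tolist()
            rows.append({
                "practice_id": prac, "horse_id": horse, "date": dates[i],
                "is_treated": True,
                "is_initial": bool(is_initial),
                "has_followup_treatment_7d": len(offsets) > 0,
                "followup_offsets": offsets,
            })
    return pd.DataFrame(rows, columns=KEY + [
        "is_treated", "is_initial", "has_followup_treatment_7d",
        "followup_offsets"])


def repeated_treatment_horses(consultations: pd.DataFrame,
                              treated_col: str = "treated",
                              min_gap_days: int = 30,
                              horizon_days: int = 365) -> dict:
    """Share of horses with >= 2 treated consultations ``min_gap`` to
    ``horizon`` days apart.  Denominator: all horses in the frame."""
    d = _per_horse_treated_dates(consultations, treated_col)
    n_horses = d.groupby(["practice_id", "horse_id"]).ngroups
    treated = d[d[treated_col].astype(bool)]
    n_repeat = 0
    for _, grp in treated.groupby(["practice_id", "horse_id"], sort=False):
        days = grp["_date"].to_numpy().astype("datetime64[D]").astype("int64")
        if days.size < 2:
            continue
        for i, day in enumerate(days[:-1]):
            lo = np.searchsorted(days, day + min_gap_days, side="left")
            hi = np.searchsorted(days, day + horizon_days, side="right")
            if hi > lo:
                n_repeat += 1
                break
    return {
        "n_horses": int(n_horses),
        "n_repeated": int(n_repeat),
        "proportion": n_repeat / n_horses if n_horses else 0.0,
    }


def detect_switches(consultations: pd.DataFrame,
                    treatment: pd.DataFrame,
                    followup_days: int = 7,
                    lookback_days: int = 30) -> pd.DataFrame:
    """Detect antibiotic switches between initial and follow-up treatments.

    Restricted to consultations with exactly one antibiotic product (a
    fixed-dose combination counts as one product).  For each such initial
    treatment, the earliest single-product follow-up within
    ``followup_days`` whose substance-class signature differs yields one
    switch event; same-signature follow-ups produce none.
    """
    labels = label_episodes(consultations, lookback_days=lookback_days,
                            followup_days=followup_days)
    t = treatment[KEY + ["n_products", "single_product_class"]].copy()
    merged = labels.merge(t, on=KEY, how="left")
    single = merged[merged["n_products"] == 1].copy()
    single["_date"] = pd.to_datetime(single["date"])
    events = []
    for (prac, horse), grp in single.groupby(["practice_id", "horse_id"],
                                             sort=False):
        grp = grp.sort_values("_date")
        days = grp["_date"].to_numpy().astype("datetime64[D]").astype("int64")
        classes = grp["single_product_class"].to_numpy()
        dates = grp["date"].to_numpy()
        initial = grp["is_initial"].to_numpy()
        for i, day in enumerate(days):
            if not initial[i]:
                continue
            hi = np.searchsorted(days, day + followup_days, side="right")
            for j in range(i + 1, hi):
                if classes[j] != classes[i]:
                    events.append({
                        "practice_id": prac, "horse_id": horse,
                        "initial_date": dates[i], "followup_date": dates[j],
                        "day_offset": int(days[j] - day),
                        "from_class": classes[i], "to_class": classes[j],
                    })
                    break
    return pd.DataFrame(events, columns=[
        "practice_id", "horse_id", "initial_date", "followup_date",
        "day_offset", "from_class", "to_class"])


def return_time_distribution(consultations: pd.DataFrame,
                             treated_col: str = "treated",
                             window: tuple[int, int] = (1, 21)) -> pd.DataFrame:
    """Days-to-next-consultation histogram, stratified by index treatment.

    For every consultation with a later consultation of the same horse,
    the day offset to the *next* one is kept if it falls inside ``window``.
    Shares and cumulative shares are normalised within each stratum.
    """
    d = _per_horse_treated_dates(consultations, treated_col)
    g = d.groupby(["practice_id", "horse_id"], sort=False)
    next_date = g["_date"].shift(-1)
    offsets = (next_date - d["_date"]).dt.days
    keep = offsets.between(window[0], window[1])
    strata = d[treated_col].astype(bool)
    rows = []
    for treated in (True, False):
        off = offsets[keep & (strata == treated)]
        total = len(off)
        counts = off.value_counts().sort_index()
        cum = 0.0
        for day in range(window[0], window[1] + 1):
            c = int(counts.get(day, 0))
            share = c / total if total else np.nan
            cum += share if total else 0.0
            rows.append({
                "stratum": "treated" if treated else "untreated",
                "day": day, "count": c,
                "share": share,
                "cumulative_share": cum if total else np.nan,
            })
    return pd.DataFrame(rows)
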