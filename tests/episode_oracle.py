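"""Brute-force all-pairs episode oracle and random timeline generator.

Kept deliberately naive (O(n^2) scans over each horse's timeline) and
independent of the package's windowed implementation, so it can certify
the episode engine on randomly generated timelines.
"""

from datetime import date, timedelta

import numpy as np
import pandas as pd

BASE = date(2020, 1, 1)
KEY = ["practice_id", "horse_id", "date"]


def random_timelines(rng: np.random.Generator, n_horses: int,
                     max_visits: int = 12, day_range: int = 130,
                     classes=("sulfonamides", "beta-lactams",
                              "aminoglycosides")):
    """Random per-horse consultation timelines with treatment annotations.

    Returns (consultations, treatment) frames in the shapes the episode
    module consumes: consultations carry a `treated` flag; treatment rows
    exist for treated consultations with `n_products` (1 or 2) and the
    single product's class signature.
    """
    cons_rows, treat_rows = [], []
    for h in range(n_horses):
        practice = f"P{h % 3}"
        horse = f"H{h}"
        n = int(rng.integers(1, max_visits + 1))
        days = sorted(rng.choice(day_range, size=min(n, day_range),
                                 replace=False).tolist())
        for d in days:
            treated = bool(rng.random() < 0.45)
            cons_rows.append({"practice_id": practice, "horse_id": horse,
                              "date": BASE + timedelta(days=int(d)),
                              "treated": treated})
            if treated:
                n_products = 1 if rng.random() < 0.8 else 2
                cls = classes[int(rng.integers(len(classes)))]
                treat_rows.append({
                    "practice_id": practice, "horse_id": horse,
                    "date": BASE + timedelta(days=int(d)),
                    "n_products": n_products,
                    "single_product_class": cls if n_products == 1 else pd.NA,
                })
    return pd.DataFrame(cons_rows), pd.DataFrame(treat_rows)


def _day(d):
    return (d - BASE).days


def brute_labels(consultations: pd.DataFrame, lookback_days=30,
                 followup_days=7) -> list[dict]:
    out = []
    for (p, h), grp in consultations.groupby(["practice_id", "horse_id"]):
        treated_days = sorted(_day(d) for d, t in
                              zip(grp["date"], grp["treated"]) if t)
        for d in treated_days:
            prior = [e for e in treated_days
                     if d - lookback_days <= e <= d - 1]
            offsets = [e - d for e in treated_days
                       if d + 1 <= e <= d + followup_days]
            out.append({"practice_id": p, "horse_id": h,
                        "date": BASE + timedelta(days=d),
                        "is_initial": len(prior) == 0,
                        "has_followup_treatment_7d": len(offsets) > 0,
                        "followup_offsets": offsets})
    return out


def brute_repeated(consultations: pd.DataFrame, min_gap_days=30,
                   horizon_days=365) -> int:
    n = 0
    for (_, _), grp in consultations.groupby(["practice_id", "horse_id"]):
        days = sorted(_day(d) for d, t in
                      zip(grp["date"], grp["treated"]) if t)
        if any(min_gap_days <= days[j] - days[i] <= horizon_days
               for i in range(len(days)) for j in range(i + 1, len(days))):
            n += 1
    return n


def brute_switches(consultations: pd.DataFrame, treatment: pd.DataFrame,
                   lookback_days=30, followup_days=7) -> list[tuple]:
    labels = {(r["practice_id"], r["horse_id"], r["date"]): r
              for r in brute_labels(consultations, lookback_days,
                                    followup_days)}
    single = treatment[treatment["n_products"] == 1]
    events = []
    for (p, h), grp in single.groupby(["practice_id", "horse_id"]):
        items = sorted(zip(grp["date"], grp["single_product_class"]),
                       key=lambda x: x[0])
        for i, (d, cls) in enumerate(items):
            lab = labels.get((p, h, d))
            if lab is None or not lab["is_initial"]:
                continue
            for d2, cls2 in items[i + 1:]:
                off = _day(d2) - _day(d)
                if off > followup_days:
                    break
                if cls2 != cls:
                    events.append((p, h, d, d2, off, cls, cls2))
                    break
    return sorted(events)
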