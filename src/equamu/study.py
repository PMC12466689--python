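"""End-to-end study object: records in, estimates out.

:class:`AmuStudy` wires the whole monitoring pipeline together in the
model/results idiom: construct it from a record frame and a horse frame
(plus optional catalogs), call :meth:`AmuStudy.fit`, and read the
estimates off the returned :class:`AmuResults` — overall and per-practice
treatment prevalence, pooled (practice-adjusted) prevalence, yearly trend,
substance-class and combination breakdowns, indication table, episode
structure and the age-spline fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

from . import catalog as _catalog
from . import episodes as _episodes
from . import indications as _indications
from . import records as _records
from . import stats as _stats

__all__ = ["AmuStudy", "AmuResults"]

KEY = ["practice_id", "horse_id", "date"]


@dataclass
class AmuResults:
    """Fitted pipeline outputs; every percentage carries a Wilson CI."""

    consultations: pd.DataFrame = field(repr=False)
    applications: pd.DataFrame = field(repr=False)
    treatment: pd.DataFrame = field(repr=False)
    filter_report: _records.StudyFilterReport = field(repr=False)
    n_unresolved_products: int = 0

    overall: _stats.PrevalenceEstimate | None = None
    multi_product: _stats.PrevalenceEstimate | None = None
    human_product: _stats.PrevalenceEstimate | None = None
    hpcia_per_treatment: _stats.PrevalenceEstimate | None = None
    nonauthorized_per_treatment: _stats.PrevalenceEstimate | None = None
    nonauthorized_per_application: _stats.PrevalenceEstimate | None = None
    combination_counts: pd.Series | None = None
    class_counts: pd.Series | None = None
    route_shares: pd.Series | None = None

    pooled: _stats.MetaPrevalence | None = None
    practice_table: pd.DataFrame | None = None
    trend: pd.DataFrame | None = None

    indication_table: pd.DataFrame | None = None
    n_assigned: int = 0

    episode_labels: pd.DataFrame | None = field(default=None, repr=False)
    initial_share: _stats.PrevalenceEstimate | None = None
    followup_share: _stats.PrevalenceEstimate | None = None
    switches: pd.DataFrame | None = field(default=None, repr=False)
    repeated: dict | None = None
    return_times: pd.DataFrame | None = field(default=None, repr=False)

    age_fit: _stats.AgeSplineResults | None = None
    n_age_excluded_missing: int = 0
    n_age_excluded_implausible: int = 0

    def summary(self) -> str:
        """Human-readable study summary."""
        L = []
        n = len(self.consultations)
        n_horses = self.consultations.groupby(
            ["practice_id", "horse_id"]).ngroups
        n_prac = self.consultations["practice_id"].nunique()
        L.append("Antimicrobial-use monitoring summary")
        L.append("=" * 44)
        L.append(f"consultations: {n}   horses: {n_horses}   "
                 f"practices: {n_prac}")
        if self.overall:
            L.append(f"treated consultations: {self.overall.k} "
                     f"({self.overall})")
        if self.multi_product:
            L.append(f"  with multiple antibiotics: {self.multi_product}")
        if self.human_product:
            L.append(f"  with human pharmaceuticals: {self.human_product}")
        if self.hpcia_per_treatment:
            L.append(f"  HPCIA (per treated consultation): "
                     f"{self.hpcia_per_treatment}")
        if self.pooled:
            lo = _stats.round_pct(100 * self.pooled.lower)
            hi = _stats.round_pct(100 * self.pooled.upper)
            L.append(f"practice-adjusted prevalence (common-effect pooling): "
                     f"{self.pooled.point_pct}% (95% CI {lo}-{hi}%)")
        if self.combination_counts is not None:
            c = self.combination_counts
            L.append("combination categories (treated consultations): "
                     + ", ".join(f"{k}={v}" for k, v in c.items()))
        if self.initial_share:
            L.append(f"initial treatments: {self.initial_share}")
        if self.followup_share:
            L.append(f"  of which followed by treatment within 7 d: "
                     f"{self.followup_share}")
        if self.switches is not None:
            L.append(f"  substance-class switches: {len(self.switches)}")
        if self.repeated:
            p = _stats.round_pct(100 * self.repeated["proportion"])
            L.append(f"horses treated repeatedly (>=30 d apart, <=1 y): "
                     f"{self.repeated['n_repeated']}/"
                     f"{self.repeated['n_horses']} ({p}%)")
        if self.age_fit is not None:
            L.append(f"age model: minimum treatment probability at "
                     f"{self.age_fit.minimum_age:.1f} y "
                     f"(n = {self.age_fit.n_obs} aged consultations)")
        return "\n".join(L)


class AmuStudy:
    """The full monitoring analysis as a fittable model object.

    Parameters
    ----------
    records, horses
        Frames in the schemas of :mod:`equamu.records`.
    drug_catalog, keyword_catalog
        Default to the packaged fixtures.
    min_patients, window
        Study inclusion filters (practice size, calendar window).
    """

    def __init__(self, records: pd.DataFrame, horses: pd.DataFrame,
                 drug_catalog: _catalog.DrugCatalog | None = None,
                 keyword_catalog: _indications.KeywordCatalog | None = None,
                 min_patients: int = 100,
                 window: tuple[_date, _date] = _records.DEFAULT_WINDOW):
        self.records = records
        self.horses = horses
        self.drug_catalog = drug_catalog or _catalog.default_catalog()
        self.keyword_catalog = keyword_catalog or _indications.default_keywords()
        self.min_patients = min_patients
        self.window = window

    @classmethod
    def from_files(cls, records_path, horses_path, records_map=None,
                   horses_map=None, **kwargs) -> "AmuStudy":
        recs, _ = _records.read_records(records_path, column_map=records_map)
        horses = _records.read_horses(horses_path, column_map=horses_map)
        return cls(recs, horses, **kwargs)

    def fit(self, spline_df: int = 3, min_aged: int = 500,
            lookback_days: int = 30, followup_days: int = 7) -> AmuResults:
        cons = _records.consolidate_consultations(self.records)
        cons, report = _records.apply_inclusion_filters(
            cons, min_patients=self.min_patients, window=self.window)
        cons = _records.compute_age(cons, self.horses)

        # restrict record-level views to retained consultations
        recs = self.records.merge(cons[KEY], on=KEY, how="inner")
        apps, n_unresolved = _catalog.classify_administrations(
            recs, self.drug_catalog)
        treatment = _catalog.classify_consultation_treatment(
            recs, self.drug_catalog)
        cons = cons.merge(treatment[KEY + ["treated"]], on=KEY, how="left")
        cons["treated"] = cons["treated"].notna() & cons["treated"].eq(True)

        res = AmuResults(consultations=cons, applications=apps,
                         treatment=treatment, filter_report=report,
                         n_unresolved_products=n_unresolved)
        n = len(cons)
        if n == 0:
            return res

        # headline prevalences
        k = int(cons["treated"].sum())
        res.overall = _stats.wilson_interval(k, n)
        if k > 0:
            t = treatment
            res.multi_product = _stats.wilson_interval(
                int((t["n_products"] >= 2).sum()), k)
            res.human_product = _stats.wilson_interval(
                int(t["any_human_product"].sum()), k)
            res.hpcia_per_treatment = _stats.wilson_interval(
                int(t["any_hpcia"].sum()), k)
            res.nonauthorized_per_treatment = _stats.wilson_interval(
                int(t["any_nonauthorized"].sum()), k)
            n_apps = len(apps.drop_duplicates(
                subset=KEY + ["product_id", "substance"]))
            n_apps_nonauth = len(apps[~apps["authorized_food_horse"].astype(bool)]
                                 .drop_duplicates(subset=KEY + ["product_id",
                                                               "substance"]))
            res.nonauthorized_per_application = _stats.wilson_interval(
                n_apps_nonauth, n_apps)
            res.combination_counts = t["combination"].value_counts()
            res.class_counts = (
                apps.drop_duplicates(subset=KEY + ["product_id", "substance"])
                ["substance_class"].value_counts())
            res.route_shares = (
                apps.drop_duplicates(subset=KEY + ["product_id"])
                ["route"].value_counts(normalize=True))

        # practice-level pooling and trend
        per = cons.groupby("practice_id")["treated"].agg(["sum", "size"])
        res.practice_table = per.rename(
            columns={"sum": "k", "size": "n"}).reset_index()
        res.practice_table["estimate"] = (
            res.practice_table["k"] / res.practice_table["n"])
        if k > 0:
            res.pooled = _stats.pooled_prevalence(
                list(zip(per["sum"].astype(int), per["size"].astype(int))))
        res.trend = _stats.yearly_trend(cons)

        # indications
        assigned = _indications.assign_indications(cons, self.keyword_catalog)
        res.n_assigned = int((assigned["categories"].map(len) > 0).sum())
        res.indication_table = _indications.indication_summary(
            assigned, treatment=cons, applications=apps)

        # episodes
        if k > 0:
            labels = _episodes.label_episodes(
                cons, lookback_days=lookback_days,
                followup_days=followup_days)
            res.episode_labels = labels
            n_initial = int(labels["is_initial"].sum())
            res.initial_share = _stats.wilson_interval(n_initial, k)
            if n_initial > 0:
                res.followup_share = _stats.wilson_interval(
                    int(labels.loc[labels["is_initial"],
                                   "has_followup_treatment_7d"].sum()),
                    n_initial)
            res.switches = _episodes.detect_switches(
                cons, treatment, followup_days=followup_days,
                lookback_days=lookback_days)
        res.repeated = _episodes.repeated_treatment_horses(cons)
        res.return_times = _episodes.return_time_distribution(cons)

        # age model
        aged = cons[cons["age_plausible"]]
        res.n_age_excluded_missing = int(cons["age_years"].isna().sum())
        res.n_age_excluded_implausible = int(
            (~cons["age_plausible"] & cons["age_years"].notna()).sum())
        if len(aged) >= min_aged and aged["treated"].nunique() == 2:
            model = _stats.AgeSplineModel(
                aged["age_years"].to_numpy(),
                aged["treated"].to_numpy(), df=spline_df)
            res.age_fit = model.fit()
        return res
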