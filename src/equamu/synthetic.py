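"""Synthetic practice-management datasets with known ground truth.

The generator emulates the statistical structure of routine equine
practice records so every pipeline stage can be validated without access
to real (privacy-restricted) data:

* 57 practices of heterogeneous size (clipped log-normal, median ~430
  patients) and heterogeneous treatment prevalence (Beta-distributed, with
  a configurable share of zero-use practices);
* per-horse consultation timelines with return-time dynamics — horses whose
  last consultation involved antibiotic treatment return earlier;
* treatment status drawn from a logistic model combining a practice effect,
  a U-shaped age effect and an indication effect, with a global intercept
  calibrated so the expected overall prevalence equals the configured
  target (default 7% of consultations);
* follow-up treatment episodes: after a treated consultation the next visit
  is, with configured probability, scheduled within 1-7 days and treated
  again, with a configurable probability of switching substance class;
* free-text entries assembled from the packaged keyword catalog, with a
  controlled rate of misleading keywords so classifier validation sampling
  can itself be validated.

Determinism: identical ``(config, seed)`` gives identical output; all
randomness flows through one :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from . import catalog as _catalog
from . import indications as _indications

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "paper_like_config",
    "generate_dataset",
    "generate_followups",
]


# Per-category generation profile: (share of assigned consultations,
# treated share among that category's consultations).  These are the study
# conditions the generator emulates.
INDICATION_PROFILE: dict[str, tuple[float, float]] = {
    "Blood/Hematopoietic organs": (0.0003, 0.238),
    "Dermatology": (0.185, 0.083),
    "Diagnostics/Therapy": (0.233, 0.032),
    "Endocrinology": (0.008, 0.077),
    "Immune system": (0.005, 0.068),
    "Intoxication": (0.001, 0.090),
    "Cardiology": (0.018, 0.080),
    "Neurology": (0.030, 0.035),
    "Emergency": (0.007, 0.187),
    "Oncology": (0.006, 0.139),
    "Ophthalmology": (0.029, 0.539),
    "Orthopedics": (0.120, 0.054),
    "Otology": (0.002, 0.128),
    "Respiratory system": (0.104, 0.126),
    "Routine exam/prevention": (0.090, 0.064),
    "Systemic disease": (0.008, 0.228),
    "Trauma": (0.041, 0.366),
    "Unclear/unspecified": (0.005, 0.184),
    "Urogenital system": (0.061, 0.081),
    "Digestive system": (0.045, 0.062),
}

#: systemic product mix (product_id -> weight), sulfonamide-TMP and
#: aminopenicillin dominated
SYSTEMIC_PRODUCT_MIX = {
    "EQ001": 0.40, "EQ026": 0.045, "EQ002": 0.145, "EQ003": 0.035,
    "EQ004": 0.065, "EQ025": 0.035, "EQ009": 0.011, "EQ005": 0.04,
    "EQ010": 0.045, "EQ011": 0.018, "EQ012": 0.012, "EQ014": 0.010,
    "EQ013": 0.0005, "EQ015": 0.008, "EQ022": 0.035, "EQ023": 0.006,
    "EQ017": 0.0005, "EQ019": 0.001, "EQ016": 0.004, "EQ021": 0.010,
}

#: topical mix used for eye/ear indications (human eye preparations frequent)
TOPICAL_PRODUCT_MIX = {
    "EQ006": 0.44, "EQ024": 0.13, "EQ007": 0.11, "EQ021": 0.17,
    "EQ016": 0.05, "EQ008": 0.06, "EQ018": 0.02, "EQ020": 0.02,
}

#: second product of an empirical combination (gentamicin + penicillin is
#: the classic perioperative pairing)
COMBO_SECOND_MIX = {"EQ005": 0.45, "EQ004": 0.30, "EQ003": 0.10,
                    "EQ010": 0.05, "EQ022": 0.10}

_FILLERS = ["vorstellung", "wegen", "heute", "besitzerin", "telefonisch",
            "besprochen", "stall", "termin"]
_NO_INDICATION_TEXTS = ["sattelanpassung", "osteopathie", "akupunktur",
                        "bestandsbesuch", "wegegeld", "anfahrt",
                        "beratungsgespräch"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator (defaults emulate a 57-practice,
    six-year routine-records study at 7% overall treatment prevalence)."""

    n_practices: int = 57
    patients_median: float = 430.0
    patients_sigma: float = 1.2
    patients_min: int = 100
    patients_max: int = 6500
    mean_consultations_per_horse: float = 4.4
    max_consultations_per_horse: int = 40
    window: tuple[_date, _date] = (_date(2018, 1, 1), _date(2023, 12, 31))

    target_prevalence: float = 0.07
    practice_prevalence_alpha: float = 2.5
    practice_prevalence_beta: float = 27.0
    zero_practice_prob: float = 10.0 / 57.0

    # age structure and age effect (logit scale)
    young_frac: float = 0.08
    adult_age_mean: float = 13.5
    adult_age_sd: float = 8.0
    missing_birthdate_prob: float = 0.375
    age_effect: str = "quadratic_u"          # "constant" | "quadratic_u"
    age_effect_min: float = 12.5             # age of minimum treatment odds
    age_effect_amplitude: float = 0.76       # logit rise at ages 0 and 40

    # indications and free text
    indication_frac: float = 0.324
    second_indication_prob: float = 0.08
    error_rate_text: float = 0.23

    # episode structure
    followup_prob: float = 0.334             # treated follow-up within 7 d
    switch_prob: float = 0.088               # class switch on follow-up
    followup_geom_q: float = 0.34            # day-offset distribution (1-7)
    empirical_combination_prob: float = 0.021

    # return-time dynamics (index consultation treated vs not)
    return_short_prob_treated: float = 0.58
    return_short_prob_untreated: float = 0.45
    return_geom_q_treated: float = 0.2734    # P(return day 1-2) = 0.472
    return_geom_q_untreated: float = 0.1515  # P(return day 1-2) = 0.280
    long_gap_min: int = 22
    long_gap_max: int = 365

    def validate(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("empty study window")
        for name in ("target_prevalence", "zero_practice_prob",
                     "indication_frac", "error_rate_text", "followup_prob",
                     "switch_prob", "empirical_combination_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.age_effect not in ("constant", "quadratic_u"):
            raise ValueError(f"unknown age_effect {self.age_effect!r}")

    def age_effect_logit(self, age):
        """Logit-scale age effect (relative; the level is calibrated away)."""
        age = np.asarray(age, dtype=float)
        if self.age_effect == "constant":
            return np.zeros_like(age)
        m, amp = self.age_effect_min, self.age_effect_amplitude
        scale = np.where(age < m, m, 40.0 - m)
        return amp * ((age - m) / scale) ** 2


def paper_like_config(**overrides) -> SyntheticConfig:
    """The bundled default configuration (see class defaults)."""
    return replace(SyntheticConfig(), **overrides)


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    config: SyntheticConfig
    calibration_shift: float
    overall_prevalence: float                 # mean assigned probability
    practice_table: pd.DataFrame              # per-practice truth
    consultations: pd.DataFrame               # per-consultation truth
    age_minimum: float


@dataclass
class SyntheticDataset:
    records: pd.DataFrame
    horses: pd.DataFrame
    truth: GroundTruth


def _safe_terms_by_category(kw: _indications.KeywordCatalog) -> dict[str, list[tuple[str, ...]]]:
    """Terms whose token sequence cannot trigger another category.

    A term is generation-safe iff no term of a *different* category occurs
    as a contiguous token subsequence inside it.  Only safe terms are used
    to build texts, so that with error_rate_text = 0 the classifier's
    assignment equals the generated labels exactly.
    """
    terms = list(kw.entries.items())
    out: dict[str, list[tuple[str, ...]]] = {}
    for tokens, cat in terms:
        safe = True
        for other, ocat in terms:
            if ocat == cat or len(other) > len(tokens):
                continue
            n = len(other)
            if any(tuple(tokens[i:i + n]) == other
                   for i in range(len(tokens) - n + 1)):
                safe = False
                break
        if safe:
            out.setdefault(cat, []).append(tokens)
    missing = [c for c in _indications.CATEGORIES if not out.get(c)]
    if missing:
        raise ValueError(f"no generation-safe keywords for {missing}")
    return out


def _geometric_days(u: np.ndarray, q: float, cap: int | None = None) -> np.ndarray:
    """Inverse-CDF geometric on {1, 2, ...}; optionally truncated at cap."""
    if cap is not None:
        u = u * (1.0 - (1.0 - q) ** cap)
    d = 1 + np.floor(np.log1p(-u) / np.log1p(-q)).astype(np.int64)
    return np.maximum(d, 1)


def _draw_ages(rng: np.random.Generator, n: int, cfg: SyntheticConfig) -> np.ndarray:
    young = rng.random(n) < cfg.young_frac
    ages = np.empty(n)
    ages[young] = rng.uniform(0.0, 3.0, young.sum())
    a = (0.0 - cfg.adult_age_mean) / cfg.adult_age_sd
    b = (40.0 - cfg.adult_age_mean) / cfg.adult_age_sd
    ages[~young] = truncnorm.ppf(rng.random((~young).sum()), a, b,
                                 loc=cfg.adult_age_mean, scale=cfg.adult_age_sd)
    return ages


class _Chain:
    """Vectorised per-horse visit chain, deterministic given its uniforms.

    Running the chain for a candidate intercept shift ``s`` yields the mean
    of the per-consultation treatment probabilities actually assigned;
    bisection on ``s`` calibrates that mean to the configured target.  The
    same pre-drawn uniforms are reused for every candidate (common random
    numbers), so the final flags are an unbiased Bernoulli draw from the
    calibrated probabilities.
    """

    def __init__(self, cfg: SyntheticConfig, rng: np.random.Generator):
        self.cfg = cfg
        # practices
        np_ = cfg.n_practices
        mu = np.log(cfg.patients_median)
        sizes = np.exp(rng.normal(mu, cfg.patients_sigma, np_))
        self.sizes = np.clip(sizes, cfg.patients_min, cfg.patients_max).astype(int)
        self.zero_use = rng.random(np_) < cfg.zero_practice_prob
        prev = rng.beta(cfg.practice_prevalence_alpha,
                        cfg.practice_prevalence_beta, np_)
        self.practice_prev = np.where(self.zero_use, 0.0, prev)
        mean_nonzero = max(self.practice_prev[~self.zero_use].mean(), 1e-6) \
            if (~self.zero_use).any() else 1e-6
        self.practice_off = np.where(
            self.zero_use, 0.0,
            logit(np.clip(self.practice_prev, 1e-6, 1 - 1e-6)) - logit(mean_nonzero))

        # horses
        n_h = int(self.sizes.sum())
        self.n_horses = n_h
        self.h_prac = np.repeat(np.arange(np_), self.sizes)
        self.age0 = _draw_ages(rng, n_h, cfg)
        self.missing_birth = rng.random(n_h) < cfg.missing_birthdate_prob
        lam = max(cfg.mean_consultations_per_horse - 1.0, 0.0)
        self.n_visits = 1 + np.minimum(rng.poisson(lam, n_h),
                                       cfg.max_consultations_per_horse - 1)
        self.window_days = (cfg.window[1] - cfg.window[0]).days
        self.first_day = rng.integers(0, self.window_days + 1, n_h)

        # per-(horse, visit) draws independent of the calibration shift
        K = int(self.n_visits.max())
        self.K = K
        self.U_treat = rng.random((K, n_h))
        self.U_fu = rng.random((K, n_h))
        self.U_short = rng.random((K, n_h))
        self.U_gap = rng.random((K, n_h))
        has_ind = rng.random((K, n_h)) < cfg.indication_frac
        cats = list(INDICATION_PROFILE)
        shares = np.array([INDICATION_PROFILE[c][0] for c in cats])
        shares = shares / shares.sum()
        cat_idx = rng.choice(len(cats), size=(K, n_h), p=shares)
        self.cat_idx = np.where(has_ind, cat_idx, -1).astype(np.int16)
        self.second_cat = np.where(
            has_ind & (rng.random((K, n_h)) < cfg.second_indication_prob),
            rng.choice(len(cats), size=(K, n_h), p=shares), -1).astype(np.int16)
        self.categories = cats
        treated_share_assigned = sum(
            s * t for s, t in INDICATION_PROFILE.values()) / shares.sum()
        self.ind_off = np.array(
            [logit(INDICATION_PROFILE[c][1]) - logit(treated_share_assigned)
             for c in cats])
        base = float(np.clip(cfg.target_prevalence, 1e-6, 1 - 1e-6))
        unassigned = (base - cfg.indication_frac * treated_share_assigned) \
            / max(1.0 - cfg.indication_frac, 1e-9)
        unassigned = float(np.clip(unassigned, 1e-4, 1 - 1e-4))
        self.unassigned_off = float(logit(unassigned) - logit(base))

    def run(self, s: float):
        cfg = self.cfg
        n_h, K = self.n_horses, self.K
        day = self.first_day.astype(np.int64).copy()
        prev_treated = np.zeros(n_h, dtype=bool)
        day_mat = np.full((K, n_h), -1, dtype=np.int64)
        treated_mat = np.zeros((K, n_h), dtype=bool)
        fu_mat = np.zeros((K, n_h), dtype=bool)
        p_mat = np.zeros((K, n_h))
        active_mat = np.zeros((K, n_h), dtype=bool)
        base_logit = float(logit(np.clip(cfg.target_prevalence,
                                         1e-6, 1 - 1e-6)))
        zero = self.zero_use[self.h_prac]
        prac_off = self.practice_off[self.h_prac]
        psum, pcount = 0.0, 0
        for k in range(K):
            active = (k < self.n_visits) & (day <= self.window_days)
            if not active.any():
                break
            age = self.age0 + day / 365.25
            ind = self.cat_idx[k]
            off = np.where(ind >= 0, self.ind_off[np.maximum(ind, 0)],
                           self.unassigned_off)
            ind2 = self.second_cat[k]
            off = off + np.where(ind2 >= 0, self.ind_off[np.maximum(ind2, 0)], 0.0)
            eta = base_logit + s + prac_off + cfg.age_effect_logit(age) + off
            p = np.where(zero, 0.0, expit(eta))
            fu_slot = prev_treated & (self.U_fu[k] < cfg.followup_prob) & ~zero
            p_used = np.where(fu_slot, 1.0, p)
            treated = np.where(fu_slot, True, self.U_treat[k] < p)
            psum += p_used[active].sum()
            pcount += int(active.sum())
            day_mat[k] = day
            treated_mat[k] = treated & active
            fu_mat[k] = fu_slot & active
            p_mat[k] = p_used
            active_mat[k] = active
            # gap to next visit
            if k + 1 < K:
                next_fu = treated & (self.U_fu[k + 1] < cfg.followup_prob) & ~zero
                fu_gap = _geometric_days(self.U_gap[k + 1], cfg.followup_geom_q,
                                         cap=7)
                q = np.where(treated, cfg.return_geom_q_treated,
                             cfg.return_geom_q_untreated)
                short_p = np.where(treated, cfg.return_short_prob_treated,
                                   cfg.return_short_prob_untreated)
                short = self.U_short[k + 1] < short_p
                # magnitude uniform re-mapped through each stratum's own q,
                # so draws stay common across candidate shifts
                short_gap = 1 + np.floor(
                    np.log1p(-self.U_gap[k + 1]) / np.log1p(-q)).astype(np.int64)
                long_gap = cfg.long_gap_min + np.floor(
                    self.U_gap[k + 1] * (cfg.long_gap_max - cfg.long_gap_min)
                ).astype(np.int64)
                gap = np.where(next_fu, fu_gap,
                               np.where(short, np.maximum(short_gap, 1), long_gap))
                day = day + gap
            prev_treated = treated
        mean_p = psum / max(pcount, 1)
        return mean_p, day_mat, treated_mat, fu_mat, p_mat, active_mat

    def calibrate(self, tol: float = 1e-5, max_iter: int = 50) -> float:
        target = self.cfg.target_prevalence
        lo, hi = -4.0, 4.0
        f_lo = self.run(lo)[0] - target
        f_hi = self.run(hi)[0] - target
        if f_lo > 0 or f_hi < 0:
            raise ValueError("calibration target outside achievable range")
        s = 0.0
        for _ in range(max_iter):
            s = 0.5 * (lo + hi)
            f = self.run(s)[0] - target
            if abs(f) < tol:
                break
            if f > 0:
                hi = s
            else:
                lo = s
        return s


def _choose(rng: np.random.Generator, mix: dict[str, float]) -> str:
    ids = list(mix)
    w = np.array([mix[i] for i in ids], dtype=float)
    return ids[rng.choice(len(ids), p=w / w.sum())]


def generate_dataset(config: SyntheticConfig | None = None,
                     seed: int = 0) -> SyntheticDataset:
    """Generate a full synthetic dataset with ground truth.

    Returns schema-valid ``records`` and ``horses`` frames (direct input to
    the records module) plus a :class:`GroundTruth` object.  Deterministic
    given ``(config, seed)``.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    drug_cat = _catalog.default_catalog()
    keywords = _indications.default_keywords()
    safe_terms = _safe_terms_by_category(keywords)

    chain = _Chain(cfg, rng)
    if cfg.target_prevalence == 0.0 or bool(chain.zero_use.all()):
        shift = 0.0
        _, day_mat, treated_mat, fu_mat, p_mat, active_mat = chain.run(-np.inf)
        mean_p = 0.0
    else:
        shift = chain.calibrate()
        mean_p, day_mat, treated_mat, fu_mat, p_mat, active_mat = chain.run(shift)

    cats = chain.categories
    window_start = cfg.window[0]

    # ---- flatten the chain into a consultation-level truth table ----
    k_idx, h_idx = np.nonzero(active_mat)
    order = np.lexsort((k_idx, h_idx))
    k_idx, h_idx = k_idx[order], h_idx[order]
    cons = pd.DataFrame({
        "h": h_idx,
        "practice": chain.h_prac[h_idx],
        "day": day_mat[k_idx, h_idx],
        "treated": treated_mat[k_idx, h_idx],
        "followup_slot": fu_mat[k_idx, h_idx],
        "p_treated": p_mat[k_idx, h_idx],
        "cat1": chain.cat_idx[k_idx, h_idx],
        "cat2": chain.second_cat[k_idx, h_idx],
        "age": chain.age0[h_idx] + day_mat[k_idx, h_idx] / 365.25,
    })
    cons["practice_id"] = "P" + cons["practice"].astype(str).str.zfill(3)
    cons["horse_id"] = "H" + cons["h"].astype(str).str.zfill(6)
    cons["date"] = [window_start + timedelta(days=int(d)) for d in cons["day"]]

    # ---- product assignment (sequential per horse for switches) ----
    eye_like = {cats.index("Ophthalmology"), cats.index("Otology")}
    prev_product: dict[int, str] = {}
    products_col: list[tuple[str, ...]] = []
    switched_col: list[bool] = []
    cat_frame = drug_cat.as_frame().drop_duplicates("product_id").set_index("product_id")
    systemic_singles_by_class: dict[str, list[str]] = {}
    for pid, row in cat_frame.iterrows():
        if pid in SYSTEMIC_PRODUCT_MIX and row["n_substances"] == 1:
            systemic_singles_by_class.setdefault(row["class_signature"], []).append(pid)
    for h, treated, fu, c1 in zip(cons["h"], cons["treated"],
                                  cons["followup_slot"], cons["cat1"]):
        if not treated:
            products_col.append(())
            switched_col.append(False)
            continue
        prev = prev_product.get(h)
        if fu and prev is not None:
            if rng.random() < cfg.switch_prob:
                prev_sig = cat_frame.loc[prev, "class_signature"]
                options = [p for sig, ps in systemic_singles_by_class.items()
                           if sig != prev_sig for p in ps]
                pid = options[int(rng.integers(len(options)))] if options \
                    else _choose(rng, SYSTEMIC_PRODUCT_MIX)
                products = (pid,)
                switched_col.append(True)
            else:
                # follow-up continues the previous product
                products = (prev,)
                switched_col.append(False)
        else:
            mix = TOPICAL_PRODUCT_MIX if int(c1) in eye_like else SYSTEMIC_PRODUCT_MIX
            pid = _choose(rng, mix)
            products = (pid,)
            if (not fu) and rng.random() < cfg.empirical_combination_prob:
                second = _choose(rng, COMBO_SECOND_MIX)
                if second != pid:
                    products = (pid, second)
            switched_col.append(False)
        products_col.append(products)
        prev_product[h] = products[0]
    cons["products"] = products_col
    cons["switched"] = switched_col

    # ---- free text ----
    texts = []
    true_cats = []
    n_cats = len(cats)
    for c1, c2 in zip(cons["cat1"], cons["cat2"]):
        if c1 < 0:
            texts.append(_NO_INDICATION_TEXTS[int(rng.integers(len(_NO_INDICATION_TEXTS)))])
            true_cats.append(())
            continue
        labels = {cats[int(c1)]}
        if c2 >= 0:
            labels.add(cats[int(c2)])
        parts = []
        for lab in sorted(labels):
            terms = safe_terms[lab]
            parts.append(" ".join(terms[int(rng.integers(len(terms)))]))
        if rng.random() < cfg.error_rate_text and len(labels) < n_cats:
            other = int(rng.integers(n_cats))
            while cats[other] in labels:
                other = int(rng.integers(n_cats))
            terms = safe_terms[cats[other]]
            parts.append(" ".join(terms[int(rng.integers(len(terms)))]))
        lead = _FILLERS[int(rng.integers(len(_FILLERS)))]
        texts.append(lead + " " + " und ".join(parts))
        true_cats.append(tuple(sorted(labels)))
    cons["text"] = texts
    cons["true_categories"] = true_cats

    # ---- explode into invoiced-item records ----
    rec_rows = []
    extra_item = rng.random(len(cons)) < 0.3
    for i, row in enumerate(cons.itertuples(index=False)):
        base = {"practice_id": row.practice_id, "horse_id": row.horse_id,
                "date": row.date}
        rec_rows.append({**base, "item_kind": "procedure",
                         "anamnesis_text": row.text, "diagnosis_text": "",
                         "description_text": "", "product_id": None,
                         "quantity": None})
        if extra_item[i]:
            rec_rows.append({**base, "item_kind": "other",
                             "anamnesis_text": "", "diagnosis_text": "",
                             "description_text": "wegegeld",
                             "product_id": None, "quantity": None})
        for pid in row.products:
            rec_rows.append({**base, "item_kind": "pharmaceutical",
                             "anamnesis_text": "", "diagnosis_text": "",
                             "description_text": "", "product_id": pid,
                             "quantity": 1.0})
    records = pd.DataFrame(rec_rows, columns=[
        "practice_id", "horse_id", "date", "item_kind", "anamnesis_text",
        "diagnosis_text", "description_text", "product_id", "quantity"])

    # ---- horses frame ----
    h_ids = ("H" + pd.Series(np.arange(chain.n_horses)).astype(str)
             .str.zfill(6)).to_numpy()
    p_ids = ("P" + pd.Series(chain.h_prac).astype(str)
             .str.zfill(3)).to_numpy()
    birth = []
    for i in range(chain.n_horses):
        if chain.missing_birth[i]:
            birth.append(None)
        else:
            birth.append(window_start
                         + timedelta(days=int(chain.first_day[i]))
                         - timedelta(days=int(round(chain.age0[i] * 365.25))))
    horses = pd.DataFrame({
        "practice_id": p_ids, "horse_id": h_ids, "birth_date": birth,
        "death_date": None, "sex": "", "breed": "",
    })
    # keep only horses that actually have a record (a registered patient
    # is a horse with >= 1 record in the window)
    horses = horses[horses["horse_id"].isin(cons["horse_id"].unique())]
    horses = horses.reset_index(drop=True)

    # ---- ground truth ----
    per_prac = cons.groupby("practice")
    practice_table = pd.DataFrame({
        "practice_id": ("P" + pd.Series(np.arange(cfg.n_practices)).astype(str)
                        .str.zfill(3)).to_numpy(),
        "n_patients_drawn": chain.sizes,
        "zero_use": chain.zero_use,
        "config_prevalence": chain.practice_prev,
    })
    realized = per_prac["p_treated"].mean()
    nc = per_prac.size()
    practice_table["true_prevalence"] = practice_table.index.map(realized).fillna(0.0)
    practice_table["n_consultations"] = practice_table.index.map(nc).fillna(0).astype(int)
    truth_cons = cons[["practice_id", "horse_id", "date", "treated",
                       "followup_slot", "switched", "p_treated",
                       "true_categories", "products", "age"]].copy()
    truth = GroundTruth(
        config=cfg, calibration_shift=float(shift),
        overall_prevalence=float(cons["p_treated"].mean()),
        practice_table=practice_table, consultations=truth_cons,
        age_minimum=cfg.age_effect_min,
    )
    return SyntheticDataset(records=records, horses=horses, truth=truth)


def generate_followups(records: pd.DataFrame,
                       drug_catalog: _catalog.DrugCatalog | None = None,
                       followup_prob: float = 0.334,
                       switch_prob: float = 0.088,
                       offset_geom_q: float = 0.34,
                       seed: int = 0) -> pd.DataFrame:
    """Append follow-up treatment consultations to an existing record set.

    For each treated consultation, with probability ``followup_prob`` a new
    treated consultation is created 1-7 days later (truncated-geometric
    offset).  With probability ``switch_prob`` the follow-up product has a
    different substance-class signature (a detectable switch); otherwise
    the same product is repeated.  Returns the *additional* records only.
    """
    cat = drug_catalog or _catalog.default_catalog()
    rng = np.random.default_rng(seed)
    pharm = records[records["item_kind"] == "pharmaceutical"]
    key = ["practice_id", "horse_id", "date"]
    existing = set(map(tuple, records[key].itertuples(index=False)))
    first = pharm.sort_values(key).drop_duplicates(subset=key)
    singles_by_sig: dict[str, list[str]] = {}
    for pid, p in cat.products.items():
        singles_by_sig.setdefault(p.class_signature, []).append(pid)
    rows = []
    for row in first.itertuples(index=False):
        if rng.random() >= followup_prob:
            continue
        offset = int(_geometric_days(np.array([rng.random()]),
                                     offset_geom_q, cap=7)[0])
        new_date = row.date + timedelta(days=offset)
        if (row.practice_id, row.horse_id, new_date) in existing:
            continue
        pid = row.product_id
        if rng.random() < switch_prob:
            sig = cat[pid].class_signature
            options = [p for s, ps in singles_by_sig.items()
                       if s != sig for p in ps]
            if options:
                pid = options[int(rng.integers(len(options)))]
        rows.append({"practice_id": row.practice_id, "horse_id": row.horse_id,
                     "date": new_date, "item_kind": "pharmaceutical",
                     "anamnesis_text": "nachbehandlung", "diagnosis_text": "",
                     "description_text": "", "product_id": pid,
                     "quantity": 1.0})
        existing.add((row.practice_id, row.horse_id, new_date))
    return pd.DataFrame(rows, columns=records.columns)
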