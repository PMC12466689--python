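"""Keyword-based assignment of consultations to indication categories.

Each consultation's concatenated free text (anamnesis + diagnoses +
descriptions) is screened against a keyword catalog in which every term maps
to exactly one of 20 diagnostic categories.  A consultation is labelled with
every category for which at least one of its terms occurs — multi-label
assignment is expected (a horse can present with a wound and a cough).

Matching is token-based: text is lower-cased, split on any non-word
character (hyphens split; German umlauts and eszett are kept), and a term
matches iff its token sequence occurs contiguously in the normalized token
stream.  This deliberately reproduces the known failure mode of dictionary
classifiers on clinical free text — "influenza" in a vaccination note still
maps to the respiratory category — which is why the module also ships the
validation-sampling machinery used to quantify that error rate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .stats import PrevalenceEstimate, round_pct, wilson_interval

__all__ = [
    "CATEGORIES",
    "KeywordCatalog",
    "ValidationResult",
    "normalize_text",
    "load_keywords",
    "default_keywords",
    "match_indications",
    "assign_indications",
    "indication_summary",
    "draw_validation_sample",
    "score_validation",
]

#: The 20 diagnostic categories.
CATEGORIES = (
    "Blood/Hematopoietic organs",
    "Dermatology",
    "Diagnostics/Therapy",
    "Endocrinology",
    "Immune system",
    "Intoxication",
    "Cardiology",
    "Neurology",
    "Emergency",
    "Oncology",
    "Ophthalmology",
    "Orthopedics",
    "Otology",
    "Respiratory system",
    "Routine exam/prevention",
    "Systemic disease",
    "Trauma",
    "Unclear/unspecified",
    "Urogenital system",
    "Digestive system",
)

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def normalize_text(text: str) -> list[str]:
    """Lower-case, strip punctuation, split into tokens (hyphens split)."""
    if not text:
        return []
    return _TOKEN_RE.findall(str(text).lower())


@dataclass
class KeywordCatalog:
    """Terms (token tuples) mapping each to exactly one category."""

    entries: dict[tuple[str, ...], str] = field(default_factory=dict)

    def __post_init__(self):
        self._by_length: dict[int, dict[tuple[str, ...], str]] = {}
        for term, cat in self.entries.items():
            self._by_length.setdefault(len(term), {})[term] = cat

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, term: str, category: str) -> None:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        tokens = tuple(normalize_text(term))
        if not tokens:
            raise ValueError(f"term {term!r} empty after normalization")
        prev = self.entries.get(tokens)
        if prev is not None and prev != category:
            raise ValueError(
                f"term {term!r} already mapped to {prev!r}; every term must "
                "map to exactly one category")
        self.entries[tokens] = category
        self._by_length.setdefault(len(tokens), {})[tokens] = category

    def match(self, text: str) -> dict[str, list[str]]:
        """Category -> matched terms, for one free-text string."""
        tokens = normalize_text(text)
        found: dict[str, list[str]] = {}
        for n, terms in self._by_length.items():
            if len(tokens) < n:
                continue
            for i in range(len(tokens) - n + 1):
                gram = tuple(tokens[i:i + n])
                cat = terms.get(gram)
                if cat is not None:
                    found.setdefault(cat, []).append(" ".join(gram))
        return {c: sorted(set(ts)) for c, ts in found.items()}

    def terms_for(self, category: str) -> list[str]:
        return sorted(" ".join(t) for t, c in self.entries.items()
                      if c == category)


def load_keywords(path) -> KeywordCatalog:
    """Load a two-column delimited keyword file (term, category)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if not {"term", "category"}.issubset(df.columns):
        raise ValueError("keyword file needs columns 'term' and 'category'")
    cat = KeywordCatalog()
    for _, row in df.iterrows():
        cat.add(row["term"], row["category"])
    return cat


def default_keywords() -> KeywordCatalog:
    """The packaged demonstration keyword catalog (~200 terms)."""
    ref = resources.files("equamu.data").joinpath("keywords.csv")
    with resources.as_file(ref) as path:
        return load_keywords(path)


def match_indications(text: str, catalog: KeywordCatalog) -> dict[str, list[str]]:
    """Match one consultation text; returns category -> matched terms."""
    return catalog.match(text)


def assign_indications(consultations: pd.DataFrame,
                       catalog: KeywordCatalog,
                       text_col: str = "combined_text") -> pd.DataFrame:
    """Assign categories to every consultation in a frame.

    Adds ``categories`` (sorted tuple, possibly empty) and ``matched_terms``
    columns; identical text always yields identical assignment.
    """
    out = consultations.copy()
    cache: dict[str, tuple[tuple[str, ...], dict]] = {}
    cats_col, terms_col = [], []
    for text in out[text_col].fillna(""):
        hit = cache.get(text)
        if hit is None:
            m = catalog.match(text)
            hit = (tuple(sorted(m.keys())), m)
            cache[text] = hit
        cats_col.append(hit[0])
        terms_col.append(hit[1])
    out["categories"] = cats_col
    out["matched_terms"] = terms_col
    return out


def indication_summary(assignments: pd.DataFrame,
                       treatment: pd.DataFrame | None = None,
                       applications: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-category table of consultation counts, treated shares and routes.

    A consultation with k categories contributes to k rows.
    ``share_of_assigned_pct`` uses the total number of category-assignments
    as denominator; ``treated`` percentages use each row's consultation
    count.  Route shares (among applications of treated consultations in the
    category) are included when ``applications`` is given.
    """
    key = ["practice_id", "horse_id", "date"]
    a = assignments[assignments["categories"].map(len) > 0]
    if len(a) == 0:
        return pd.DataFrame(columns=["category", "n_consultations",
                                     "share_of_assigned_pct", "treated_pct",
                                     "treated_lower_pct", "treated_upper_pct"])
    long = a[key + ["categories"]].explode("categories").rename(
        columns={"categories": "category"})
    if treatment is not None:
        long = long.merge(treatment[key + ["treated"]], on=key, how="left")
        long["treated"] = long["treated"].notna() & long["treated"].eq(True)
    else:
        long["treated"] = False
    total_assignments = len(long)
    rows = []
    for cat, sub in long.groupby("category", sort=False):
        n = len(sub)
        k = int(sub["treated"].sum())
        est = wilson_interval(k, n)
        row = {
            "category": cat,
            "n_consultations": n,
            "share_of_assigned_pct": round_pct(100.0 * n / total_assignments),
            "n_treated": k,
            "treated_pct": est.point_pct,
            "treated_lower_pct": est.ci_pct[0],
            "treated_upper_pct": est.ci_pct[1],
        }
        if applications is not None:
            tr = sub[sub["treated"]][key]
            ap = applications.merge(tr, on=key, how="inner")
            nt = len(ap)
            for route in ("oral", "parenteral", "topical"):
                share = 100.0 * (ap["route"] == route).sum() / nt if nt else np.nan
                row[f"route_{route}_pct"] = round_pct(share) if nt else np.nan
        rows.append(row)
    order = {c: i for i, c in enumerate(CATEGORIES)}
    out = pd.DataFrame(rows)
    return out.sort_values("category",
                           key=lambda s: s.map(order)).reset_index(drop=True)


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of manually scoring a validation sample of assignments."""

    sample_size: int
    n_incorrect: int
    error_rate: float
    wilson: PrevalenceEstimate

    @property
    def error_pct(self) -> float:
        return round_pct(100.0 * self.error_rate)


def draw_validation_sample(assignments: pd.DataFrame, n: int = 300,
                           seed: int | None = None,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Uniform sample (without replacement) of consultations with >= 1
    assigned category, for manual review."""
    pool = assignments[assignments["categories"].map(len) > 0]
    if n > len(pool):
        raise ValueError(
            f"requested sample of {n} exceeds {len(pool)} assigned consultations")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return pool.iloc[np.sort(idx)].reset_index(drop=True)


def score_validation(sample_size: int, n_incorrect: int,
                     ci_level: float = 0.95) -> ValidationResult:
    """Summarise a scored validation sample (error rate with Wilson CI)."""
    if not 0 <= n_incorrect <= sample_size:
        raise ValueError("need 0 <= n_incorrect <= sample_size")
    est = wilson_interval(n_incorrect, sample_size, ci_level=ci_level)
    return ValidationResult(sample_size=sample_size, n_incorrect=n_incorrect,
                            error_rate=n_incorrect / sample_size, wilson=est)
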