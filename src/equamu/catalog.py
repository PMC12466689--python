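"""Antibiotic product catalog and per-consultation treatment classification.

Products are pharmaceutical preparations with one or more antibacterial
active substances.  Every substance belongs to one of 13 substance classes;
four classes form the WHO Highest-Priority Critically Important
Antimicrobials (HPCIA): 3rd/4th-generation cephalosporins, fluoroquinolones,
macrolides and polymyxins.  A product with >= 2 antibacterial substances is a
*fixed-dose combination* (e.g. sulfonamide + trimethoprim); >= 2 distinct
products at one consultation form an *empirical combination*.

The packaged catalog (``data/products.csv``) is a curated demonstration
fixture covering the substances relevant to equine practice; real catalogs
in the same delimited format can be loaded with :func:`load_catalog`.

Two denominators coexist throughout the analysis: *consultations with
treatment* (one per treated consultation) and *applications/deliveries*
(one per administered product per substance it contains).  Every summary
labels which one it uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "SUBSTANCE_CLASSES",
    "HPCIA_CLASSES",
    "Substance",
    "Product",
    "DrugCatalog",
    "load_catalog",
    "default_catalog",
    "classify_administrations",
    "classify_consultation_treatment",
    "classify_combination",
]

SUBSTANCE_CLASSES = (
    "aminoglycosides",
    "beta-lactams",
    "sulfonamides",
    "amphenicols",
    "cephalosporins-1/2gen",
    "cephalosporins-3/4gen",
    "fluoroquinolones",
    "polymyxins",
    "steroid-antibiotics",
    "tetracyclines",
    "macrolides",
    "nitroimidazoles",
    "lincosamides",
)

#: WHO highest-priority critically important antimicrobial classes.
HPCIA_CLASSES = frozenset(
    {"cephalosporins-3/4gen", "fluoroquinolones", "macrolides", "polymyxins"})

ROUTES = ("oral", "parenteral", "topical")


@dataclass(frozen=True)
class Substance:
    name: str
    substance_class: str
    concentration: str | None = None

    @property
    def hpcia(self) -> bool:
        return self.substance_class in HPCIA_CLASSES


@dataclass(frozen=True)
class Product:
    product_id: str
    trade_name: str
    origin: str                     # "veterinary" | "human"
    default_route: str              # "oral" | "parenteral" | "topical"
    authorized_food_horse: bool
    substances: tuple[Substance, ...]

    @property
    def fixed_dose_combination(self) -> bool:
        return len(self.substances) >= 2

    @property
    def substance_classes(self) -> tuple[str, ...]:
        return tuple(s.substance_class for s in self.substances)

    @property
    def class_signature(self) -> str:
        """Sorted unique classes, '+'-joined (single class for most products)."""
        return "+".join(sorted(set(self.substance_classes)))

    @property
    def any_hpcia(self) -> bool:
        return any(s.hpcia for s in self.substances)


@dataclass
class DrugCatalog:
    products: dict[str, Product] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.products)

    def __contains__(self, product_id: str) -> bool:
        return product_id in self.products

    def __getitem__(self, product_id: str) -> Product:
        return self.products[product_id]

    def as_frame(self) -> pd.DataFrame:
        """One row per (product, substance) — the long 'application' view."""
        rows = []
        for p in self.products.values():
            for s in p.substances:
                rows.append({
                    "product_id": p.product_id,
                    "trade_name": p.trade_name,
                    "origin": p.origin,
                    "route": p.default_route,
                    "authorized_food_horse": p.authorized_food_horse,
                    "fixed_dose_combination": p.fixed_dose_combination,
                    "n_substances": len(p.substances),
                    "class_signature": p.class_signature,
                    "substance": s.name,
                    "substance_class": s.substance_class,
                    "hpcia": s.hpcia,
                })
        return pd.DataFrame(rows)


def _parse_substances(spec: str, context: str) -> tuple[Substance, ...]:
    subs = []
    for part in str(spec).split(";"):
        part = part.strip()
        if not part:
            continue
        bits = part.split(":")
        if len(bits) < 2:
            raise ValueError(f"{context}: substance entry {part!r} needs "
                             "'name:class[:concentration]'")
        name, cls = bits[0].strip().lower(), bits[1].strip().lower()
        conc = bits[2].strip() if len(bits) > 2 else None
        if cls not in SUBSTANCE_CLASSES:
            raise ValueError(f"{context}: unknown substance class {cls!r}")
        subs.append(Substance(name=name, substance_class=cls,
                              concentration=conc))
    if not subs:
        raise ValueError(f"{context}: product without substances")
    return tuple(subs)


def load_catalog(path) -> DrugCatalog:
    """Load a product catalog from delimited text.

    Columns: product_id, trade_name, origin, route, authorized_food_horse,
    substances (semicolon-separated ``name:class[:concentration]``).
    Duplicate product ids and unknown classes or routes are fatal.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    catalog = DrugCatalog()
    for _, row in df.iterrows():
        pid = row["product_id"].strip()
        ctx = f"product {pid!r}"
        if pid in catalog.products:
            raise ValueError(f"duplicate product_id {pid!r}")
        origin = row["origin"].strip().lower()
        if origin not in ("veterinary", "human"):
            raise ValueError(f"{ctx}: unknown origin {origin!r}")
        route = row["route"].strip().lower()
        if route not in ROUTES:
            raise ValueError(f"{ctx}: unknown route {route!r}")
        auth = row["authorized_food_horse"].strip().lower() in ("1", "true", "yes")
        catalog.products[pid] = Product(
            product_id=pid,
            trade_name=row["trade_name"].strip(),
            origin=origin,
            default_route=route,
            authorized_food_horse=auth,
            substances=_parse_substances(row["substances"], ctx),
        )
    return catalog


def default_catalog() -> DrugCatalog:
    """The packaged demonstration catalog."""
    ref = resources.files("equamu.data").joinpath("products.csv")
    with resources.as_file(ref) as path:
        return load_catalog(path)


def classify_administrations(records: pd.DataFrame,
                             catalog: DrugCatalog) -> tuple[pd.DataFrame, int]:
    """Expand pharmaceutical records into the long application table.

    Returns one row per (consultation, product record, substance) with class,
    route, origin and authorization flags, plus the count of records whose
    product_id could not be resolved against the catalog (those
    consultations are excluded as unclassifiable, not silently kept).
    """
    pharm = records[records["item_kind"] == "pharmaceutical"]
    if len(pharm) == 0:
        return pd.DataFrame(columns=[
            "practice_id", "horse_id", "date", "product_id", "route",
            "origin", "authorized_food_horse", "fixed_dose_combination",
            "n_substances", "class_signature", "substance",
            "substance_class", "hpcia"]), 0
    unresolved = ~pharm["product_id"].isin(catalog.products.keys())
    n_unresolved = int(unresolved.sum())
    pharm = pharm[~unresolved]
    cat = catalog.as_frame()
    apps = pharm[["practice_id", "horse_id", "date", "product_id"]].merge(
        cat.drop(columns=["trade_name"]), on="product_id", how="left")
    return apps, n_unresolved


def classify_consultation_treatment(records: pd.DataFrame,
                                    catalog: DrugCatalog) -> pd.DataFrame:
    """Per-consultation antibiotic treatment summary.

    One row per consultation that has >= 1 resolvable antibiotic
    administration, with: number of distinct products, number of
    applications (product x substance), the class multiset, HPCIA /
    human-origin / non-authorized flags (ORs over products), the route
    multiset, and the combination category from
    :func:`classify_combination`.
    """
    apps, _ = classify_administrations(records, catalog)
    if len(apps) == 0:
        return pd.DataFrame(columns=[
            "practice_id", "horse_id", "date", "n_products", "n_applications",
            "substance_classes", "routes", "any_hpcia", "any_human_product",
            "any_nonauthorized", "single_product_class", "combination"])
    key = ["practice_id", "horse_id", "date"]
    # product level: one row per distinct product at the consultation;
    # application level: one row per distinct product x substance (a product
    # invoiced twice on one day counts once)
    prod = apps.drop_duplicates(subset=key + ["product_id"]).copy()
    apps_d = apps.drop_duplicates(subset=key + ["product_id", "substance"])
    g = apps_d.groupby(key, sort=True)
    gp = prod.groupby(key, sort=True)
    out = pd.DataFrame({
        "n_products": gp["product_id"].nunique(),
        "n_applications": g.size(),
        "substance_classes": g["substance_class"].agg(tuple),
        "routes": gp["route"].agg(tuple),
        "any_hpcia": g["hpcia"].any(),
        "any_human_product": gp["origin"].agg(lambda s: (s == "human").any()),
        "any_nonauthorized": gp["authorized_food_horse"].agg(lambda s: (~s.astype(bool)).any()),
        "max_substances_per_product": gp["n_substances"].max(),
        "class_signatures": gp["class_signature"].agg(tuple),
    }).reset_index()
    single = out["n_products"] == 1
    out["single_product_class"] = pd.NA
    out.loc[single, "single_product_class"] = out.loc[single, "class_signatures"].map(
        lambda t: t[0])
    out["combination"] = [
        classify_combination(np_, ms_) for np_, ms_ in
        zip(out["n_products"], out["max_substances_per_product"])
    ]
    out["treated"] = True
    return out


def classify_combination(n_products: int, max_substances_per_product: int) -> str:
    """Combination category of a treated consultation.

    * ``single``: one product with one substance
    * ``fixed_dose``: one product that is itself a fixed-dose combination
    * ``empirical``: >= 2 distinct products (the sub-case where one of them
      is itself a fixed-dose combination is folded into ``empirical`` for
      headline counts)
    """
    if n_products < 1:
        raise ValueError("combination classification requires a treated "
                         "consultation (>= 1 product)")
    if n_products == 1:
        return "fixed_dose" if max_substances_per_product >= 2 else "single"
    return "empirical"
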