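import pandas as pd
import pytest

from equamu.catalog import default_catalog
from equamu.indications import default_keywords
from equamu.synthetic import generate_dataset, paper_like_config


@pytest.fixture(scope="session")
def drug_cat():
    return default_catalog()


@pytest.fixture(scope="session")
def keywords():
    return default_keywords()


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully structured synthetic dataset (~5k consultations)."""
    cfg = paper_like_config(n_practices=8, patients_median=120,
                            patients_sigma=0.5, patients_min=50,
                            patients_max=800)
    return generate_dataset(cfg, seed=42)


def make_records(rows):
    """Build a schema-valid record frame from compact tuples:
    (practice, horse, date, kind, text, product_id)."""
    out = []
    for practice, horse, date, kind, text, product in rows:
        out.append({
            "practice_id": practice, "horse_id": horse,
            "date": pd.Timestamp(date).date(), "item_kind": kind,
            "anamnesis_text": text, "diagnosis_text": "",
            "description_text": "", "product_id": product,
            "quantity": 1.0 if product else None,
        })
    return pd.DataFrame(out, columns=[
        "practice_id", "horse_id", "date", "item_kind", "anamnesis_text",
        "diagnosis_text", "description_text", "product_id", "quantity"])
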