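import numpy as np
import pytest

from nutrimatch.data import FoodDatabase, FoodRecord, NutrientSchema


@pytest.fixture
def tiny_schema() -> NutrientSchema:
    return NutrientSchema(names=("KCAL", "SUGR", "CALC"), units={})


def make_db(schema, rows, source="query_db", lactose=None):
    """Build a FoodDatabase from (id, description, nutrient-vector) rows."""
    records = []
    for i, (fid, desc, nut) in enumerate(rows):
        records.append(
            FoodRecord(
                food_id=fid,
                source=source,
                name=desc.split(",")[0],
                description=desc,
                nutrients=np.asarray(nut, dtype=float),
                lactose_g=None if lactose is None else lactose[i],
            )
        )
    return FoodDatabase(schema=schema, records=records, source=source)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
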