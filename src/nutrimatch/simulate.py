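"""Synthetic paired food databases with known ground-truth links.

Real paired recall/composition data cannot be redistributed, so this
module generates the structure the matching and prediction methods rely
on:

* a shared 62-nutrient panel per 100 g, log-normal per nutrient, with a
  latent *dairy factor* per food that drives lactose and couples it
  positively to sugar, calcium, potassium and riboflavin and negatively to
  fiber and iron;
* about 23% lactose-free foods (exactly 0 g lactose);
* comma-structured descriptions whose first chunk carries the food
  identity;
* a target database holding, for every query food, a true counterpart with
  per-nutrient multiplicative noise and a perturbed description, plus
  independent distractor foods, branded near-duplicates, and "dry-mix"
  records with all per-100 g values scaled far up;
* the query-to-target link table and the true lactose per query.

Everything is deterministic under the configured seed.  The archetype
catalog (food heads, their dairy levels, base nutrient magnitudes) is
fixed module-level structure, independent of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (
    FoodDatabase,
    FoodRecord,
    GroundTruthLink,
    NutrientSchema,
    default_schema,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "generate_bundle",
    "make_multifood_queries",
    "RegressionProblem",
    "generate_zero_inflated_regression",
]


# ---------------------------------------------------------------------------
# archetype catalog (fixed, seed-independent)

# (head, dairy level in [0, 1]); 0 = lactose-free archetype
_DAIRY_HEADS = [
    ("Milk", 0.95), ("Yogurt", 0.90), ("Milkshake", 0.80), ("Cheese", 0.70),
    ("Ice cream", 0.60), ("Custard", 0.60), ("Pudding", 0.55),
    ("Cocoa drink", 0.50), ("Alfredo pasta", 0.45), ("Macaroni and cheese", 0.40),
    ("Cream soup", 0.35), ("Pizza", 0.30), ("Lasagna", 0.30),
    ("Cheeseburger", 0.25), ("Scrambled eggs", 0.20), ("Mashed potatoes", 0.18),
]
_FREE_HEADS = [
    ("Lettuce", 0.0), ("Apple", 0.0), ("Rice", 0.0), ("Chicken breast", 0.0),
    ("Almond milk", 0.0), ("Soy milk", 0.0), ("Orange juice", 0.0),
    ("Black beans", 0.0), ("Oatmeal with water", 0.0), ("Salmon", 0.0),
    ("Bread", 0.0), ("Tofu", 0.0), ("Peanut butter", 0.0), ("Broccoli", 0.0),
    ("Tortilla chips", 0.0), ("Coffee", 0.0),
]

_DETAILS = [
    "whole", "lowfat", "nonfat", "raw", "cooked", "baked", "plain",
    "with added vitamin D", "reduced sodium", "sweetened", "unsweetened",
    "homemade", "ready-to-serve", "frozen", "canned", "NFS", "fried",
    "from concentrate",
]

# small synonym map for description perturbation
_SYNONYMS = {
    "lowfat": "low fat",
    "nonfat": "fat free",
    "cooked": "prepared",
    "ready-to-serve": "ready to serve",
    "unsweetened": "no sugar added",
}

_BRANDS = ["DairyBest", "Valley Farms", "Hilltop", "NutriCo", "Sunrise Foods"]

# variety chunks making each record's description (near-)unique, as in real
# composition tables where records differ in a few details
_VARIETIES = [
    "vanilla", "chocolate", "strawberry", "cheddar", "swiss", "2% fat",
    "1% fat", "whole grain", "Italian style", "country style", "original",
    "light", "extra creamy", "small curd", "Greek", "honey", "cinnamon",
    "garden", "classic", "spicy", "mild", "aged", "smoked", "golden",
]

# log-scale base magnitudes for the named key nutrients (per 100 g)
_KEY_BASES = {
    "KCAL": 160.0, "PROT": 6.0, "TFAT": 6.0, "CARB": 18.0, "MOIS": 60.0,
    "SUGR": 6.0, "FIBE": 1.5, "CALC": 90.0, "IRON": 1.0, "MAGN": 20.0,
    "PHOS": 95.0, "POTA": 160.0, "SODI": 140.0, "VB2": 0.2, "CHOLE": 15.0,
}

# dairy-factor couplings on the log scale: lactose-rich foods are sugar-,
# calcium-, potassium- and riboflavin-rich and fiber- and iron-poor
_COUPLINGS = {
    "SUGR": 1.2, "CALC": 1.5, "POTA": 0.8, "VB2": 1.0, "PHOS": 0.6,
    "CHOLE": 0.5, "FIBE": -1.5, "IRON": -1.0,
}


def _catalog_arrays(schema: NutrientSchema):
    """Base log-magnitudes, coupling vector, and per-head signatures.

    Deterministic and independent of the bundle seed: archetypes are part
    of the generator's definition, not of a draw.
    """
    rng = np.random.default_rng(20240917)
    p = len(schema)
    log_base = np.empty(p)
    for j, name in enumerate(schema.names):
        if name in _KEY_BASES:
            log_base[j] = math.log(_KEY_BASES[name])
        else:
            # minor components: log-uniform between 0.01 and 2 per 100 g
            log_base[j] = rng.uniform(math.log(0.01), math.log(2.0))
    coupling = np.array([_COUPLINGS.get(n, 0.0) for n in schema.names])
    heads = _DAIRY_HEADS + _FREE_HEADS
    head_sig = rng.normal(0.0, 0.6, size=(len(heads), p))
    head_details = [
        list(rng.choice(len(_DETAILS), size=6, replace=False)) for _ in heads
    ]
    return log_base, coupling, heads, head_sig, head_details


# ---------------------------------------------------------------------------
# configuration / bundle


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the emulated study conditions."""

    n_foods: int = 200
    zero_fraction: float = 0.23
    nutrient_noise_cv: float = 0.02
    description_perturb_rate: float = 0.2
    branded_fraction: float = 0.10
    drymix_fraction: float = 0.05
    distractor_fraction: float = 1.0
    dairy_serving_threshold: float = 0.1
    food_log_sigma: float = 0.35  # per-food nutrient individuality (log scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_foods < 10:
            raise ValueError("n_foods must be >= 10")
        for name in (
            "zero_fraction",
            "description_perturb_rate",
            "branded_fraction",
            "drymix_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nutrient_noise_cv < 0:
            raise ValueError("nutrient_noise_cv must be >= 0")


@dataclass
class SyntheticBundle:
    query_db: FoodDatabase
    target_db: FoodDatabase
    links: list[GroundTruthLink]
    true_lactose: dict[str, float]
    config: SyntheticConfig


def _sigma_from_cv(cv: float) -> float:
    """Log-normal sigma giving a multiplicative coefficient of variation cv."""
    return math.sqrt(math.log(1.0 + cv * cv))


def _make_description(
    head: str, detail_idx: list[int], rng, used: set[str] | None = None
) -> tuple[str, list[str]]:
    """A comma-structured description, unique within ``used`` if given."""
    for _ in range(100):
        details = []
        if rng.random() < 0.8:
            details.append(_VARIETIES[int(rng.integers(len(_VARIETIES)))])
        n_details = int(rng.integers(1, 4))
        chosen = rng.choice(
            detail_idx, size=min(n_details, len(detail_idx)), replace=False
        )
        details.extend(_DETAILS[i] for i in chosen)
        desc = ", ".join([head] + details)
        if used is None or desc not in used:
            break
    if used is not None:
        used.add(desc)
    return desc, details


def _perturb_description(head: str, details: list[str], rate: float, rng) -> str:
    """With probability ``rate``, apply one perturbation to the details.

    Cross-database counterparts of the same food typically differ in a
    single detail: one chunk dropped, one synonym swap, or one extra chunk.
    The identity-bearing first chunk is never touched.
    """
    kept = list(details)
    if rng.random() < rate:
        op = int(rng.integers(3))
        swappable = [i for i, d in enumerate(kept) if d in _SYNONYMS]
        if op == 1 and swappable:
            i = swappable[int(rng.integers(len(swappable)))]
            kept[i] = _SYNONYMS[kept[i]]
        elif op <= 1 and kept:
            kept.pop(int(rng.integers(len(kept))))
        else:
            kept.append(_DETAILS[int(rng.integers(len(_DETAILS)))])
    return ", ".join([head] + kept)


def generate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate a paired query/target database bundle with known links."""
    schema = default_schema()
    log_base, coupling, heads, head_sig, head_details = _catalog_arrays(schema)
    rng = np.random.default_rng(cfg.seed)
    p = len(schema)
    n = cfg.n_foods
    n_zero = round(cfg.zero_fraction * n)

    dairy_idx = [i for i, (_, d0) in enumerate(heads) if d0 > 0]
    free_idx = [i for i, (_, d0) in enumerate(heads) if d0 == 0]

    used_descriptions: set[str] = set()

    def draw_food(force_free: bool):
        h = int(rng.choice(free_idx if force_free else dairy_idx))
        head, d0 = heads[h]
        if force_free:
            d = 0.0
            lactose = 0.0
        else:
            d = float(np.clip(d0 + rng.normal(0.0, 0.12), 0.05, 1.0))
            lactose = 12.0 * d**1.5 * math.exp(rng.normal(0.0, 0.2))
        log_nut = log_base + head_sig[h] + coupling * d + rng.normal(
            0.0, cfg.food_log_sigma, size=p
        )
        nut = np.exp(log_nut)
        desc, details = _make_description(head, head_details[h], rng, used_descriptions)
        return h, head, d, lactose, nut, desc, details

    # --- query foods: exactly n_zero lactose-free
    is_free = np.zeros(n, dtype=bool)
    is_free[:n_zero] = True
    rng.shuffle(is_free)
    queries: list[FoodRecord] = []
    meta = []  # (head idx, head, d, details) per query
    true_lactose: dict[str, float] = {}
    for i in range(n):
        h, head, d, lactose, nut, desc, details = draw_food(bool(is_free[i]))
        qid = f"{i:08d}"
        year = str(rng.choice(["2014", "2016"]))
        queries.append(
            FoodRecord(
                food_id=qid,
                source="synthetic",
                name=head,
                description=desc,
                nutrients=nut,
                year=year,
                dairy_servings=round(1.8 * d, 3),
            )
        )
        meta.append((h, head, d, details))
        true_lactose[qid] = lactose

    # --- true targets: noisy copies with perturbed descriptions
    sigma = _sigma_from_cv(cfg.nutrient_noise_cv)
    targets: list[FoodRecord] = []
    links: list[GroundTruthLink] = []
    for i, q in enumerate(queries):
        h, head, d, details = meta[i]
        noise = np.exp(rng.normal(0.0, sigma, size=p)) if sigma > 0 else 1.0
        lactose = true_lactose[q.food_id]
        lactose_t = (
            lactose * math.exp(rng.normal(0.0, sigma)) if lactose > 0 and sigma > 0
            else lactose
        )
        desc = (
            _perturb_description(head, details, cfg.description_perturb_rate, rng)
            if cfg.description_perturb_rate > 0
            else q.description
        )
        tid = f"{50000 + i}"
        targets.append(
            FoodRecord(
                food_id=tid,
                source="synthetic",
                name=head,
                description=desc,
                nutrients=q.nutrients * noise,
                lactose_g=lactose_t,
            )
        )
        links.append(GroundTruthLink(query_id=q.food_id, target_id=tid))

    # --- independent distractors
    n_distract = round(cfg.distractor_fraction * n)
    n_drymix = round(cfg.drymix_fraction * n_distract)
    for i in range(n_distract):
        _, head, d, lactose, nut, desc, _ = draw_food(bool(rng.random() < cfg.zero_fraction))
        drymix = i < n_drymix
        if drymix:
            # per-100 g values of an unprepared dry mix: everything scales up
            nut = nut * 8.0
            lactose = lactose * 8.0
            desc = desc + ", dry mix (unprepared)"
        targets.append(
            FoodRecord(
                food_id=f"{60000 + i}",
                source="synthetic",
                name=head,
                description=desc,
                nutrients=nut,
                lactose_g=lactose,
                is_drymix=drymix,
            )
        )

    # --- branded near-duplicates of query foods (unlinked lookalikes)
    n_brand = round(cfg.branded_fraction * n)
    # a brand variant's formulation is about as close to the query as the
    # true cross-database counterpart; only the description tells them apart
    brand_sigma = _sigma_from_cv(max(cfg.nutrient_noise_cv, 0.02))
    brand_src = rng.choice(n, size=n_brand, replace=False) if n_brand else []
    for i, qi in enumerate(brand_src):
        q = queries[qi]
        h, head, d, details = meta[qi]
        brand = _BRANDS[int(rng.integers(len(_BRANDS)))]
        lactose = true_lactose[q.food_id]
        targets.append(
            FoodRecord(
                food_id=f"{70000 + i}",
                source="synthetic",
                name=f"{brand} {head}",
                description=f"{brand} {head}, " + ", ".join(details),
                nutrients=q.nutrients * np.exp(rng.normal(0.0, brand_sigma, size=p)),
                lactose_g=lactose * math.exp(rng.normal(0.0, brand_sigma))
                if lactose > 0
                else 0.0,
                is_branded=True,
            )
        )

    return SyntheticBundle(
        query_db=FoodDatabase(schema=schema, records=queries, source="query_db"),
        target_db=FoodDatabase(schema=schema, records=targets, source="target_db"),
        links=links,
        true_lactose=true_lactose,
        config=cfg,
    )


def make_multifood_queries(bundle: SyntheticBundle, fraction: float) -> SyntheticBundle:
    """Replace a fraction of query descriptions with "A or B" composites.

    A composite query names two foods with differing lactose in one
    description (the first chunk becomes "A or B") and is linked to both
    targets, emulating multi-food recall descriptions whose single correct
    match is unknowable from the description alone.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0:
        return bundle
    rng = np.random.default_rng(bundle.config.seed + 104729)
    n = len(bundle.query_db)
    n_multi = round(fraction * n)
    chosen = rng.choice(n, size=n_multi, replace=False)
    link_by_query = {ln.query_id: ln.target_id for ln in bundle.links}

    new_queries = [replace(r) for r in bundle.query_db.records]
    new_links = list(bundle.links)
    for qi in chosen:
        q = new_queries[qi]
        # partner with a different head and differing lactose
        for _ in range(50):
            pj = int(rng.integers(n))
            partner = bundle.query_db.records[pj]
            if (
                partner.name != q.name
                and abs(
                    bundle.true_lactose[partner.food_id]
                    - bundle.true_lactose[q.food_id]
                )
                > 0.5
            ):
                break
        else:
            continue
        rest = q.description.split(",")[1:]
        q.description = ", ".join(
            [f"{q.name} or {partner.name}"] + [c.strip() for c in rest]
        )
        q.name = f"{q.name} or {partner.name}"
        new_links.append(
            GroundTruthLink(
                query_id=q.food_id, target_id=link_by_query[partner.food_id]
            )
        )

    query_db = FoodDatabase(
        schema=bundle.query_db.schema, records=new_queries, source="query_db"
    )
    return SyntheticBundle(
        query_db=query_db,
        target_db=bundle.target_db,
        links=new_links,
        true_lactose=dict(bundle.true_lactose),
        config=bundle.config,
    )


# ---------------------------------------------------------------------------
# zero-inflated regression problems


@dataclass
class RegressionProblem:
    """Simulated zero-inflated regression data with known sparse signal."""

    X: pd.DataFrame
    y: np.ndarray
    support: list[str]  # names of the truly predictive nutrients
    zero_class: np.ndarray  # 1 = structurally non-zero
    beta: np.ndarray


#: planted signal: positive dairy markers, negative plant markers
_SIGNAL_BETA = {
    "SUGR": 3.0, "CALC": 2.5, "POTA": 2.0, "VB2": 1.5,
    "FIBE": -2.0, "IRON": -1.5,
}


def generate_zero_inflated_regression(
    n: int = 400,
    zero_fraction: float = 0.23,
    snr: float = 5.0,
    seed: int = 0,
) -> RegressionProblem:
    """Simulate ``y = z * max(0, b0 + X beta + eps)`` with structural zeros.

    ``X`` is standard normal over the 62-nutrient panel; ``beta`` is sparse
    with known support; the structural-zero class ``z`` follows a noisy
    linear rule aligned with the signal (zero_fraction of rows are zero);
    the noise variance is set from the signal variance and ``snr``.
    """
    schema = default_schema()
    rng = np.random.default_rng(seed)
    p = len(schema)
    X = rng.normal(size=(n, p))
    beta = np.array([_SIGNAL_BETA.get(name, 0.0) for name in schema.names])
    score = X @ beta
    s = float(score.std())
    # structural-zero rule: noisy threshold on the same latent signal
    margin = score + rng.normal(0.0, 0.1 * s, size=n)
    thresh = np.quantile(margin, zero_fraction)
    z = (margin > thresh).astype(int)
    eps = rng.normal(0.0, s / math.sqrt(snr), size=n)
    # offset keeps the non-zero class mostly clear of the clip at 0, so the
    # observed zero/non-zero labels track the structural class
    raw = score - thresh + 0.7 * s + eps
    y = z * np.maximum(0.0, raw)
    return RegressionProblem(
        X=pd.DataFrame(X, columns=list(schema.names)),
        y=y,
        support=[name for name in schema.names if _SIGNAL_BETA.get(name, 0.0) != 0.0],
        zero_class=z,
        beta=beta,
    )
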