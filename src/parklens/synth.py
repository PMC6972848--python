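"""Synthetic photo/user/park data with known latent structure.

Emulates the kind of dataset behind a city-scale social-media park-use
study: users upload public photographs, "favourite" other people's
photographs, and take geotagged photographs inside urban parks.  A
machine-vision service is emulated by drawing keyword sets (up to ten
labels per image) from category-specific vocabularies that partially
overlap through a shared vocabulary.  Every latent quantity a downstream
stage tries to recover is recorded as ground truth:

* per-photo true content category,
* per-user residential status (local vs tourist) and two latent
  preference axes per channel (public uploads, favourites),
* the true regression coefficients of the park-photo count process
  (negative binomial with a log upload-count offset) and of the
  park-photo composition process (Dirichlet, log-linear concentrations).

All randomness flows through one ``numpy.random.Generator`` seeded from
``SynthConfig.seed``, so identical configs serialize byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

_FOREIGN_COUNTRIES = ("AU", "CN", "DE", "FR", "GB", "ID", "IN", "JP", "KR", "US")

# Synthetic WGS84 bounding box in which park polygons are laid out.
_BBOX = (103.60, 1.20, 104.00, 1.50)  # lon_min, lat_min, lon_max, lat_max


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults describe a down-scaled city: ~60% of park users are
    tourists (the study city saw 2,758 of 4,674), photographs carry
    5-10 keywords, and a fifth of keyword draws come from a shared
    vocabulary so that categories overlap the way machine-vision labels
    do.
    """

    n_users: int = 800
    tourist_fraction: float = 0.59
    n_parks: int = 12
    n_categories: int = 10
    vocab_size_per_category: int = 30
    shared_vocab_size: int = 40
    keywords_min: int = 5
    keywords_max: int = 10
    shared_vocab_weight: float = 0.2
    photos_per_user_mean: float = 30.0   # public uploads
    favs_per_user_mean: float = 20.0
    latent_axis_sd: tuple[float, float] = (1.3, 1.0)
    cross_channel_corr: float = 0.35
    axis_effect: float = 1.5             # logit-scale strength of the axes
    beta_count: tuple[float, ...] = (-1.8, -0.4, 0.25, 0.4, 0.1, 0.2)
    theta_count: float = 2.0
    beta_comp: np.ndarray | None = None  # (6, n_categories); default built on use
    local_home_geotag_p: float = 0.9
    tourist_home_geotag_p: float = 0.2
    profile_country_p: float = 0.5
    home_country: str = "SG"
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_users, (int, np.integer)) or self.n_users < 1:
            raise ConfigurationError("n_users must be a positive integer")
        for name in ("n_parks", "n_categories", "vocab_size_per_category",
                     "shared_vocab_size"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if not 0.0 <= self.tourist_fraction <= 1.0:
            raise ConfigurationError("tourist_fraction must lie in [0, 1]")
        if not (1 <= self.keywords_min <= self.keywords_max <= 10):
            raise ConfigurationError(
                "keywords_min/keywords_max must satisfy 1 <= min <= max <= 10")
        if not 0.0 <= self.shared_vocab_weight <= 1.0:
            raise ConfigurationError("shared_vocab_weight must lie in [0, 1]")
        if self.photos_per_user_mean <= 0 or self.favs_per_user_mean < 0:
            raise ConfigurationError("photos_per_user_mean must be positive")
        if any(s <= 0 for s in self.latent_axis_sd):
            raise ConfigurationError("latent_axis_sd entries must be positive")
        if not -1.0 < self.cross_channel_corr < 1.0:
            raise ConfigurationError("cross_channel_corr must lie in (-1, 1)")
        if self.theta_count <= 0:
            raise ConfigurationError("theta_count must be positive")
        if len(self.beta_count) != 6:
            raise ConfigurationError(
                "beta_count must have 6 entries "
                "(intercept, tourist, pA1, pA2, fA1, fA2)")
        if self.beta_comp is not None:
            bc = np.asarray(self.beta_comp, dtype=float)
            if bc.shape != (6, self.n_categories):
                raise ConfigurationError(
                    "beta_comp must have shape (6, n_categories)")


@dataclass
class SyntheticDataset:
    """Generated photos/users/parks plus the ground truth behind them."""

    photos: pd.DataFrame         # photo_id, user_id, channel, keywords, lon, lat, park_id, country
    users: pd.DataFrame          # user_id, profile_country, n_public_uploads
    parks: dict                  # GeoJSON FeatureCollection (WGS84 lon/lat)
    truth: dict                  # photo_category, user_truth, params


def axis_directions(n_categories: int) -> tuple[np.ndarray, np.ndarray]:
    """Two orthogonal zero-sum contrast directions over the categories.

    Axis 1 opposes the first third of categories to the second third
    ('Landscapes vs People' in spirit); axis 2 opposes two groups within
    the remaining third ('Wildlife vs City').  Unit-norm.
    """
    C = n_categories
    t = max(1, C // 3)
    v1 = np.zeros(C)
    v1[:t] = 1.0
    v1[t:2 * t] = -1.0
    rest = C - 2 * t
    v2 = np.zeros(C)
    if rest >= 2:
        h = rest // 2
        v2[2 * t:2 * t + h] = 1.0
        v2[2 * t + h:] = -1.0
    else:  # too few categories for a disjoint second axis
        v2[0] = 1.0
        v2[-1] = -1.0
        v2 -= v2.mean()
    return v1 / np.linalg.norm(v1), v2 / np.linalg.norm(v2)


def _default_beta_comp(C: int) -> np.ndarray:
    v1, v2 = axis_directions(C)
    beta = np.zeros((6, C))
    beta[0] = np.log(2.0)        # baseline concentration 2 per part
    beta[1] = -0.5 * v2          # tourists: more 'city', less 'wildlife'
    beta[2] = 0.4 * v1
    beta[3] = 0.5 * v2
    beta[4] = 0.2 * v1
    beta[5] = 0.2 * v2
    return beta


def _category_vocab(c: int, size: int) -> list[str]:
    return [f"c{c:02d}w{i:02d}" for i in range(size)]


def _shared_vocab(size: int) -> list[str]:
    return [f"sharedw{i:02d}" for i in range(size)]


def _draw_keywords(rng: np.random.Generator, cat_vocab: list[str],
                   shared_vocab: list[str], k: int, w: float) -> list[str]:
    # Mixture draw without replacement: each attempt picks the shared pool
    # with probability w, the category pool otherwise.
    kws: set[str] = set()
    limit = len(cat_vocab) + len(shared_vocab)
    k = min(k, limit)
    while len(kws) < k:
        pool = shared_vocab if rng.random() < w else cat_vocab
        kws.add(pool[rng.integers(len(pool))])
    return sorted(kws)


def generate_keyword_photos(
    n_photos: int,
    n_categories: int = 10,
    vocab_size_per_category: int = 30,
    shared_vocab_size: int = 40,
    shared_vocab_weight: float = 0.2,
    keywords_min: int = 5,
    keywords_max: int = 10,
    seed: int | np.random.Generator = 0,
    category_probs: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Photos with keyword sets drawn from category vocabularies.

    Returns a photo table (photo_id, user_id, channel, keywords) and the
    true category of each photo.  Convenience entry point for clustering
    experiments; :func:`generate_dataset` uses the same keyword model.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vocabs = [_category_vocab(c, vocab_size_per_category) for c in range(n_categories)]
    shared = _shared_vocab(shared_vocab_size)
    if category_probs is None:
        category_probs = np.full(n_categories, 1.0 / n_categories)
    cats = rng.choice(n_categories, size=n_photos, p=category_probs)
    ks = rng.integers(keywords_min, keywords_max + 1, size=n_photos)
    rows = []
    for i in range(n_photos):
        rows.append({
            "photo_id": f"p{i:06d}",
            "user_id": f"u{i:06d}",
            "channel": "park",
            "keywords": _draw_keywords(rng, vocabs[cats[i]], shared,
                                       int(ks[i]), shared_vocab_weight),
        })
    photos = pd.DataFrame(rows)
    truth = pd.Series(cats, index=photos["photo_id"], name="category")
    return photos, truth


def park_features(n_parks: int) -> dict:
    """Axis-aligned rectangular parks on a grid in the synthetic bbox.

    Sizes vary deterministically with the park index so that areas (and
    the smallest-area overlap rule downstream) are distinguishable.
    """
    lon0, lat0, lon1, lat1 = _BBOX
    ncol = int(np.ceil(np.sqrt(n_parks)))
    nrow = int(np.ceil(n_parks / ncol))
    dlon = (lon1 - lon0) / ncol
    dlat = (lat1 - lat0) / nrow
    features = []
    for i in range(n_parks):
        r, c = divmod(i, ncol)
        cx = lon0 + (c + 0.5) * dlon
        cy = lat0 + (r + 0.5) * dlat
        # half-width fraction of the cell; < 0.5 keeps parks disjoint
        scale = 0.20 + 0.025 * ((i * 37) % 10)
        hw, hh = scale * dlon, scale * dlat
        ring = [
            [cx - hw, cy - hh], [cx + hw, cy - hh],
            [cx + hw, cy + hh], [cx - hw, cy + hh],
            [cx - hw, cy - hh],
        ]
        features.append({
            "type": "Feature",
            "properties": {"park_id": f"park{i:03d}"},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    return {"type": "FeatureCollection", "features": features}


def _park_bounds(feature: dict) -> tuple[float, float, float, float]:
    ring = np.asarray(feature["geometry"]["coordinates"][0])
    return ring[:, 0].min(), ring[:, 1].min(), ring[:, 0].max(), ring[:, 1].max()


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate the full synthetic study per the configured processes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    C = config.n_categories
    n = config.n_users

    vocabs = [_category_vocab(c, config.vocab_size_per_category) for c in range(C)]
    shared = _shared_vocab(config.shared_vocab_size)
    v1, v2 = axis_directions(C)
    beta_comp = (np.asarray(config.beta_comp, dtype=float)
                 if config.beta_comp is not None else _default_beta_comp(C))
    beta_count = np.asarray(config.beta_count, dtype=float)

    # --- users -----------------------------------------------------------
    is_tourist = rng.random(n) < config.tourist_fraction
    user_country = np.where(
        is_tourist,
        np.asarray(_FOREIGN_COUNTRIES)[rng.integers(0, len(_FOREIGN_COUNTRIES), n)],
        config.home_country,
    )
    has_profile = rng.random(n) < config.profile_country_p
    # Cross-channel correlated latent axes (public, favourited) per axis.
    rho = config.cross_channel_corr
    chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    ax = {}
    for a, sd in enumerate(config.latent_axis_sd):
        zz = rng.standard_normal((n, 2)) @ chol.T * sd
        ax[f"pA{a + 1}"] = zz[:, 0]
        ax[f"fA{a + 1}"] = zz[:, 1]

    n_public = np.maximum(1, rng.poisson(config.photos_per_user_mean, size=n))
    n_fav = rng.poisson(config.favs_per_user_mean, size=n)

    # Park-photo counts: NB2 with a log upload-count offset.
    X = np.column_stack([
        np.ones(n), is_tourist.astype(float),
        ax["pA1"], ax["pA2"], ax["fA1"], ax["fA2"],
    ])
    mu = n_public * np.exp(X @ beta_count)
    lam = rng.gamma(config.theta_count, mu / config.theta_count)
    n_park = rng.poisson(lam)

    # Channel compositions.
    def softmax(logits):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    p_public = softmax(config.axis_effect
                       * (np.outer(ax["pA1"], v1) + np.outer(ax["pA2"], v2)))
    p_fav = softmax(config.axis_effect
                    * (np.outer(ax["fA1"], v1) + np.outer(ax["fA2"], v2)))
    alpha_park = np.exp(X @ beta_comp)  # (n, C)

    # Park choice: tourists concentrate on low-index parks, locals on
    # high-index parks, giving each park a residential-status skew.
    order = np.arange(config.n_parks)
    w_tourist = np.exp(-0.35 * order)
    w_local = w_tourist[::-1].copy()
    w_tourist /= w_tourist.sum()
    w_local /= w_local.sum()
    parks = park_features(config.n_parks)
    bounds = [_park_bounds(f) for f in parks["features"]]
    park_ids = [f["properties"]["park_id"] for f in parks["features"]]

    photo_rows = []
    truth_cat = {}
    pid = 0

    def new_photo(user, channel, cat, lon=None, lat=None, park=None, country=None):
        nonlocal pid
        photo_id = f"p{pid:06d}"
        pid += 1
        k = int(rng.integers(config.keywords_min, config.keywords_max + 1))
        photo_rows.append({
            "photo_id": photo_id,
            "user_id": user,
            "channel": channel,
            "keywords": _draw_keywords(rng, vocabs[cat], shared, k,
                                       config.shared_vocab_weight),
            "lon": lon, "lat": lat, "park_id": park, "country": country,
        })
        truth_cat[photo_id] = int(cat)

    user_ids = [f"u{i:04d}" for i in range(n)]
    for i, uid in enumerate(user_ids):
        home_p = (config.tourist_home_geotag_p if is_tourist[i]
                  else config.local_home_geotag_p)
        # public uploads
        cats = rng.choice(C, size=n_public[i], p=p_public[i])
        at_home = rng.random(n_public[i]) < home_p
        for j in range(n_public[i]):
            if at_home[j]:
                country = config.home_country
            elif is_tourist[i]:
                country = user_country[i]
            else:
                country = _FOREIGN_COUNTRIES[rng.integers(len(_FOREIGN_COUNTRIES))]
            new_photo(uid, "public", cats[j], country=country)
        # favourited photos (others' content; no geotag used downstream)
        cats = rng.choice(C, size=n_fav[i], p=p_fav[i])
        for j in range(n_fav[i]):
            new_photo(uid, "favourited", cats[j])
        # park photos
        if n_park[i] > 0:
            comp = rng.dirichlet(alpha_park[i])
            cats = rng.choice(C, size=n_park[i], p=comp)
            weights = w_tourist if is_tourist[i] else w_local
            pk = rng.choice(config.n_parks, size=n_park[i], p=weights)
            for j in range(n_park[i]):
                x0, y0, x1, y1 = bounds[pk[j]]
                lon = x0 + rng.random() * (x1 - x0)
                lat = y0 + rng.random() * (y1 - y0)
                new_photo(uid, "park", cats[j], lon=lon, lat=lat,
                          park=park_ids[pk[j]], country=config.home_country)

    photos = pd.DataFrame(photo_rows)
    users = pd.DataFrame({
        "user_id": user_ids,
        "profile_country": [user_country[i] if has_profile[i] else None
                            for i in range(n)],
        "n_public_uploads": n_public,
    })
    user_truth = pd.DataFrame({
        "user_id": user_ids,
        "status": np.where(is_tourist, "tourist", "local"),
        "country": user_country,
        "pA1": ax["pA1"], "pA2": ax["pA2"],
        "fA1": ax["fA1"], "fA2": ax["fA2"],
        "n_park_photos": n_park,
    })
    truth = {
        "photo_category": pd.Series(truth_cat, name="category"),
        "user_truth": user_truth,
        "params": {
            "beta_count": beta_count.tolist(),
            "theta_count": config.theta_count,
            "beta_comp": beta_comp.tolist(),
            "axis_dir_1": v1.tolist(),
            "axis_dir_2": v2.tolist(),
            "axis_effect": config.axis_effect,
            "cross_channel_corr": config.cross_channel_corr,
        },
    }
    return SyntheticDataset(photos=photos, users=users, parks=parks, truth=truth)


# --- serialization -------------------------------------------------------

def _jsonable(v):
    if v is None:
        return None
    if isinstance(v, float) and np.isnan(v):
        return None
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def write_dataset(ds: SyntheticDataset, directory: str | Path) -> dict:
    """Write photos.jsonl / users.csv / parks.geojson / truth.jsonl.

    Returns a manifest mapping file names to record counts; the manifest
    is also written as ``manifest.json``.  Output is byte-deterministic
    for a given dataset.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with open(directory / "photos.jsonl", "w") as fh:
        for row in ds.photos.to_dict(orient="records"):
            fh.write(json.dumps({k: _jsonable(v) for k, v in row.items()},
                                sort_keys=True) + "\n")
    ds.users.to_csv(directory / "users.csv", index=False)
    with open(directory / "parks.geojson", "w") as fh:
        json.dump(ds.parks, fh, sort_keys=True)
        fh.write("\n")
    n_truth = 0
    with open(directory / "truth.jsonl", "w") as fh:
        fh.write(json.dumps({"kind": "params", **ds.truth["params"]},
                            sort_keys=True) + "\n")
        n_truth += 1
        for row in ds.truth["user_truth"].to_dict(orient="records"):
            fh.write(json.dumps({"kind": "user",
                                 **{k: _jsonable(v) for k, v in row.items()}},
                                sort_keys=True) + "\n")
            n_truth += 1
        for photo_id, cat in ds.truth["photo_category"].items():
            fh.write(json.dumps({"kind": "photo", "photo_id": photo_id,
                                 "category": int(cat)}, sort_keys=True) + "\n")
            n_truth += 1

    manifest = {
        "photos.jsonl": int(len(ds.photos)),
        "users.csv": int(len(ds.users)),
        "parks.geojson": int(len(ds.parks["features"])),
        "truth.jsonl": n_truth,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return manifest


def read_dataset(directory: str | Path) -> SyntheticDataset:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    photo_rows = []
    with open(directory / "photos.jsonl") as fh:
        for line in fh:
            photo_rows.append(json.loads(line))
    photos = pd.DataFrame(
        photo_rows,
        columns=["photo_id", "user_id", "channel", "keywords",
                 "lon", "lat", "park_id", "country"])
    users = pd.read_csv(directory / "users.csv",
                        dtype={"profile_country": "object"})
    users["profile_country"] = users["profile_country"].where(
        users["profile_country"].notna(), None)
    with open(directory / "parks.geojson") as fh:
        parks = json.load(fh)
    params, user_rows, photo_cat = {}, [], {}
    with open(directory / "truth.jsonl") as fh:
        for line in fh:
            obj = json.loads(line)
            kind = obj.pop("kind")
            if kind == "params":
                params = obj
            elif kind == "user":
                user_rows.append(obj)
            else:
                photo_cat[obj["photo_id"]] = obj["category"]
    truth = {
        "photo_category": pd.Series(photo_cat, name="category", dtype=int),
        "user_truth": pd.DataFrame(user_rows),
        "params": params,
    }
    return SyntheticDataset(photos=photos, users=users, parks=parks, truth=truth)


def dataset_config_from_dict(d: dict) -> SynthConfig:
    """Build a SynthConfig from a plain mapping (e.g. parsed YAML)."""
    names = {f.name for f in dataclasses.fields(SynthConfig)}
    unknown = set(d) - names
    if unknown:
        raise ConfigurationError(
            f"unknown synth config field(s): {sorted(unknown)}")
    d = dict(d)
    for key in ("latent_axis_sd", "beta_count"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if d.get("beta_comp") is not None:
        d["beta_comp"] = np.asarray(d["beta_comp"], dtype=float)
    return SynthConfig(**d)
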