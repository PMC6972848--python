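"""End-to-end pipeline: simulate -> cluster -> assess -> users -> models
-> freq -> spatial.

Each stage reads its predecessors' files from one working directory and
writes its own, so stages can be re-run individually.  All outputs are
deterministic for a fixed configuration (timing never enters output
files), and every stochastic stage has an explicit seed.

Clustering cost grows quadratically with the number of photographs, so
channels larger than ``max_cluster_photos`` are clustered on a seeded
random subsample; the remaining photographs are then assigned to the
cluster with the highest mean Jaccard similarity to its sampled
members.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist

from . import accuracy as acc
from . import cluster as cl
from . import freq as fq
from . import models as md
from . import spatial as sp
from . import synth
from . import users as us
from .exceptions import ConfigurationError, ParklensError

logger = logging.getLogger("parklens")

STAGES = ("simulate", "cluster", "assess", "users", "models", "freq", "spatial")


@dataclass
class PipelineConfig:
    workdir: str = "parklens_run"
    home_country: str = "SG"
    synth: dict = field(default_factory=dict)
    # clustering
    k_max: int = 30
    sample_fraction: float = 0.1
    initial_cutoff: int = 20
    top_n_keywords: int = 10
    max_cluster_photos: int = 4000
    channels: tuple = ("park", "public", "favourited")
    # assessment
    per_stratum: int = 30
    kappa_weights: str = "linear"
    # eligibility thresholds
    min_public: int = 10
    min_park_photos: int = 5
    min_park_users: int = 3
    status_subsample_cap: int = 50
    # frequency comparison
    reps: int = 50
    # regression
    dirichlet_categories: list | None = None
    stepwise: bool = False
    seeds: dict = field(default_factory=lambda: {
        "simulate": 1, "cluster": 2, "assess": 3, "users": 4, "freq": 5})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigurationError(
                f"unknown pipeline config field(s): {sorted(unknown)}")
        cfg = cls(**d)
        if not all(k in STAGES[:6] or k in cfg.seeds for k in cfg.seeds):
            raise ConfigurationError("seeds keys must name pipeline stages")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def override_seed(self, seed: int) -> None:
        """Derive all stage seeds from one master seed."""
        self.seeds = {name: (seed * 10 + i) % (2 ** 31)
                      for i, name in enumerate(
                          ("simulate", "cluster", "assess", "users", "freq"))}
        self.synth = dict(self.synth, seed=self.seeds["simulate"])


def _require(cfg: PipelineConfig, stage: str, *files: str) -> Path:
    wd = Path(cfg.workdir)
    for f in files:
        if not (wd / f).exists():
            raise ParklensError(
                f"stage {stage!r} is missing its input file {wd / f}")
    return wd


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1, default=float)
        fh.write("\n")


def _read_photos(wd: Path) -> pd.DataFrame:
    rows = []
    with open(wd / "photos.jsonl") as fh:
        for line in fh:
            rows.append(json.loads(line))
    return pd.DataFrame(rows)


# --- stages --------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> dict:
    scfg = synth.dataset_config_from_dict(
        dict(cfg.synth, seed=cfg.synth.get("seed", cfg.seeds["simulate"])))
    ds = synth.generate_dataset(scfg)
    manifest = synth.write_dataset(ds, cfg.workdir)
    return {"files": manifest, "n_photos": manifest["photos.jsonl"],
            "n_users": manifest["users.csv"], "seed": scfg.seed}


def _extend_assignments(bits: np.ndarray, sample_idx: np.ndarray,
                        labels_sample: np.ndarray) -> np.ndarray:
    """Assign unsampled photos to the cluster with the highest mean
    Jaccard similarity to the cluster's sampled members."""
    n = bits.shape[0]
    labels = np.full(n, -1, dtype=int)
    labels[sample_idx] = labels_sample
    rest = np.flatnonzero(labels < 0)
    if len(rest) == 0:
        return labels
    sims = 1.0 - cdist(bits[rest], bits[sample_idx], metric="jaccard")
    k = labels_sample.max() + 1
    means = np.stack([sims[:, labels_sample == c].mean(axis=1)
                      for c in range(k)], axis=1)
    labels[rest] = means.argmax(axis=1)
    return labels


def stage_cluster(cfg: PipelineConfig) -> dict:
    wd = _require(cfg, "cluster", "photos.jsonl")
    photos = _read_photos(wd)
    rng = np.random.default_rng(cfg.seeds["cluster"])
    all_assign = []
    models = {}
    for channel in cfg.channels:
        sub = photos[photos["channel"] == channel].reset_index(drop=True)
        if len(sub) < 5:
            continue
        bm = cl.build_binary_matrix(sub)
        n = len(bm.photo_ids)
        if n > cfg.max_cluster_photos:
            sample_idx = np.sort(rng.choice(n, size=cfg.max_cluster_photos,
                                            replace=False))
        else:
            sample_idx = np.arange(n)
        bm_s = cl.BinaryKeywordMatrix(
            [bm.photo_ids[i] for i in sample_idx], bm.vocabulary,
            bm.bits[sample_idx])
        dm = cl.jaccard_distances(bm_s)
        dend = cl.ward_cluster(dm)
        k_max = min(cfg.k_max, len(sample_idx) - 1)
        graph = cl.evaluation_graph(dend, dm, k_max,
                                    sample_fraction=cfg.sample_fraction,
                                    seed=cfg.seeds["cluster"])
        k = cl.lmethod_knee(graph, initial_cutoff=cfg.initial_cutoff)
        model = cl.cut_and_label(
            dend, k, sub.iloc[sample_idx], top_n=cfg.top_n_keywords)
        labels = _extend_assignments(
            bm.bits, sample_idx,
            model.assignments.reindex(bm_s.photo_ids).to_numpy())
        all_assign.append(pd.DataFrame({
            "photo_id": bm.photo_ids, "channel": channel,
            "category": labels, "aggregated_category": labels}))
        models[channel] = {
            "k": int(k),
            "n_photos": int(n),
            "n_clustered": int(len(sample_idx)),
            "labels": {str(c): model.labels[c] for c in model.labels},
            "evaluation_graph": {"k": graph.k_values.tolist(),
                                 "eval": graph.eval.tolist()},
            "seed": cfg.seeds["cluster"],
            "params": {"k_max": k_max,
                       "sample_fraction": cfg.sample_fraction,
                       "initial_cutoff": cfg.initial_cutoff},
        }
    if not all_assign:
        raise ParklensError("stage 'cluster' found no channel with >= 5 photos")
    assignments = pd.concat(all_assign, ignore_index=True)
    assignments.to_csv(wd / "assignments.csv", index=False)
    _write_json(wd / "cluster_models.json", models)
    return {"channels": {c: models[c]["k"] for c in models}}


def _read_assignments(wd: Path) -> pd.DataFrame:
    return pd.read_csv(wd / "assignments.csv")


def _read_truth_categories(wd: Path) -> pd.Series:
    cats = {}
    with open(wd / "truth.jsonl") as fh:
        for line in fh:
            obj = json.loads(line)
            if obj.get("kind") == "photo":
                cats[obj["photo_id"]] = obj["category"]
    return pd.Series(cats, name="category")


def stage_assess(cfg: PipelineConfig) -> dict:
    wd = _require(cfg, "assess", "assignments.csv", "truth.jsonl")
    assignments = _read_assignments(wd)
    truth = _read_truth_categories(wd)
    report = {}
    for channel, sub in assignments.groupby("channel"):
        auto = sub.set_index("photo_id")["category"]
        # Synthetic observer: label each photo with the cluster category
        # that is the majority vote for the photo's true category.
        true_cat = truth.reindex(auto.index)
        majority = (pd.DataFrame({"auto": auto, "true": true_cat})
                    .groupby("true")["auto"]
                    .agg(lambda s: s.value_counts().sort_index().idxmax()))
        manual = true_cat.map(majority)
        ids = acc.stratified_sample(auto, cfg.per_stratum,
                                    seed=cfg.seeds["assess"])
        cm = acc.confusion(auto.loc[ids], manual.loc[ids],
                           categories=sorted(auto.unique()))
        rep = acc.accuracy_report(cm, weights=cfg.kappa_weights)
        report[channel] = {
            "n_assessed": cm.total,
            "overall_accuracy": rep.overall_accuracy,
            "weighted_kappa": rep.weighted_kappa,
            "mutual_misclassification": [
                [str(a), str(b), r] for a, b, r in rep.mutual_misclassification],
        }
    _write_json(wd / "accuracy_report.json", report)
    return {ch: {"accuracy": report[ch]["overall_accuracy"],
                 "kappa": report[ch]["weighted_kappa"]} for ch in report}


def stage_users(cfg: PipelineConfig) -> dict:
    wd = _require(cfg, "users", "photos.jsonl", "users.csv", "assignments.csv")
    photos = _read_photos(wd)
    users = pd.read_csv(wd / "users.csv", dtype={"profile_country": "object"})
    assignments = _read_assignments(wd)
    photos = photos.merge(
        assignments[["photo_id", "category"]], on="photo_id", how="left")
    status = us.assign_status_frame(
        users, photos, cfg.home_country, seed=cfg.seeds["users"],
        subsample_cap=cfg.status_subsample_cap)
    users["status"] = status.reindex(users["user_id"]).to_numpy()
    users.to_csv(wd / "users_status.csv", index=False)

    axes_frames = []
    pca_out = {}
    for channel, prefix in (("public", "p"), ("favourited", "f")):
        sub = photos[(photos["channel"] == channel)
                     & photos["category"].notna()]
        if not len(sub):
            continue
        cats = sorted(sub["category"].unique())
        comp = us.user_composition(sub, cats)
        pca = us.robust_pca(comp, n_components=2, seed=cfg.seeds["users"])
        axes_frames.append(pd.DataFrame(
            pca.scores, index=comp.user_ids,
            columns=[f"{prefix}PC1", f"{prefix}PC2"]))
        pca_out[channel] = {
            "explained_variance": pca.explained_variance.tolist(),
            "loadings_clr": pca.loadings_clr.tolist(),
            "categories": [int(c) for c in pca.categories],
            "robust": bool(pca.robust),
        }
    axes = pd.concat(axes_frames, axis=1)
    axes.index.name = "user_id"
    axes.to_csv(wd / "axes.csv")
    _write_json(wd / "pca.json", pca_out)
    n_local = int((users["status"] == "local").sum())
    n_tourist = int((users["status"] == "tourist").sum())
    return {"n_local": n_local, "n_tourist": n_tourist,
            "n_unresolved": int((users["status"] == "unresolved").sum()),
            "channels": list(pca_out)}


def _model_inputs(cfg: PipelineConfig):
    wd = _require(cfg, "models", "photos.jsonl", "users_status.csv",
                  "axes.csv", "assignments.csv")
    photos = _read_photos(wd)
    users = pd.read_csv(wd / "users_status.csv",
                        dtype={"profile_country": "object"})
    axes = pd.read_csv(wd / "axes.csv", index_col="user_id")
    assignments = _read_assignments(wd)
    photos = photos.merge(
        assignments[["photo_id", "aggregated_category"]],
        on="photo_id", how="left")
    return wd, photos, users, axes


def stage_models(cfg: PipelineConfig) -> dict:
    wd, photos, users, axes = _model_inputs(cfg)
    park = photos[photos["channel"] == "park"]
    park_counts = park.groupby("user_id").size()
    n_fav = photos[photos["channel"] == "favourited"].groupby("user_id").size()

    users = users.set_index("user_id")
    eligible = users.index[
        (users["status"].isin(["local", "tourist"]))
        & (users["n_public_uploads"] >= cfg.min_public)
        & (users.index.isin(n_fav.index))
        & (users.index.isin(axes.dropna().index))]
    X = axes.loc[eligible, ["pPC1", "pPC2", "fPC1", "fPC2"]].copy()
    X.insert(0, "status_tourist",
             (users.loc[eligible, "status"] == "tourist").astype(float))
    Xs = md.scale_regressors(X)
    y = park_counts.reindex(eligible).fillna(0).astype(int)
    off = users.loc[eligible, "n_public_uploads"].astype(float)

    def nb_fit_fn(names):
        return md.fit_nb_offset(y, off, Xs[names])

    nb = nb_fit_fn(list(Xs.columns))
    out = {
        "n": nb.n, "theta": nb.theta, "loglik": nb.loglik, "aic": nb.aic,
        "beta": nb.beta.to_dict(), "se": nb.se.to_dict(),
        "pvalues": nb.pvalues.to_dict(),
        "vif": md.vif(Xs).to_dict(),
    }
    if cfg.stepwise:
        trace = md.stepwise_aic(nb_fit_fn, list(Xs.columns))
        out["stepwise"] = {"steps": [[s or "", a] for s, a in trace.steps],
                           "kept": trace.kept}
        nb = trace.final
    _write_json(wd / "nb_fit.json", out)

    # Dirichlet: park-photo composition of users with enough park photos
    park_cat = park.dropna(subset=["aggregated_category"])
    if cfg.dirichlet_categories is not None:
        park_cat = park_cat[park_cat["aggregated_category"]
                            .isin(cfg.dirichlet_categories)]
    counts = park_cat.groupby("user_id").size()
    d_users = [u for u in eligible
               if counts.get(u, 0) >= cfg.min_park_photos]
    dir_out = {"n": len(d_users)}
    cats = sorted(park_cat["aggregated_category"].unique())
    n_params = (len(Xs.columns) + 1) * len(cats)
    if len(d_users) < 3 * n_params:
        dir_out["skipped"] = (
            f"only {len(d_users)} eligible users for {n_params} parameters; "
            "need at least 3 users per parameter")
    else:
        comp = us.user_composition(
            park_cat[park_cat["user_id"].isin(d_users)], cats,
            category_col="aggregated_category")
        comp = md.dirichlet_compress(comp)
        Xd = Xs.loc[comp.user_ids]
        fit = md.fit_dirichlet(comp, Xd)
        dir_out.update({
            "components": [int(c) for c in fit.components],
            "loglik": fit.loglik, "aic": fit.aic,
            "beta": {str(c): fit.beta[c].to_dict() for c in fit.beta.columns},
            "se": {str(c): fit.se[c].to_dict() for c in fit.se.columns},
        })
    _write_json(wd / "dirichlet_fit.json", dir_out)
    return {"nb_n": out["n"], "dirichlet_n": dir_out["n"]}


def stage_freq(cfg: PipelineConfig) -> dict:
    wd = _require(cfg, "freq", "photos.jsonl", "users_status.csv",
                  "assignments.csv")
    photos = _read_photos(wd)
    users = pd.read_csv(wd / "users_status.csv",
                        dtype={"profile_country": "object"})
    assignments = _read_assignments(wd)
    park = photos[photos["channel"] == "park"].merge(
        assignments[["photo_id", "category"]], on="photo_id", how="inner")
    table = fq.resample_frequencies(
        park, users, reps=cfg.reps, seed=cfg.seeds["freq"],
        groups=["local", "tourist"])
    long = (table.mean_freq.reset_index(names="group")
            .melt(id_vars="group", var_name="category", value_name="mean_freq"))
    long["reps"] = table.reps
    long["seed"] = table.seed
    long.to_csv(wd / "frequencies.csv", index=False)
    tests = fq.frequency_tests(park, users, reps=cfg.reps,
                               seed=cfg.seeds["freq"],
                               groups=["local", "tourist"])
    tests.to_csv(wd / "tests.csv", index=False)
    return {"n_categories": len(table.categories), "reps": table.reps}


def stage_spatial(cfg: PipelineConfig) -> dict:
    wd = _require(cfg, "spatial", "photos.jsonl", "users_status.csv",
                  "parks.geojson", "axes.csv")
    photos = _read_photos(wd)
    users = pd.read_csv(wd / "users_status.csv",
                        dtype={"profile_country": "object"})
    axes = pd.read_csv(wd / "axes.csv", index_col="user_id")
    with open(wd / "parks.geojson") as fh:
        parks = sp.load_parks(json.load(fh))
    park_photos = photos[photos["channel"] == "park"].copy()
    mapping = sp.assign_parks(park_photos, parks)
    park_photos["park_id"] = mapping.reindex(park_photos["photo_id"]).to_numpy()
    summaries = sp.park_user_summary(
        park_photos, users, parks, axes=axes, min_users=cfg.min_park_users)
    rows = []
    for s in summaries:
        row = {"park_id": s.park_id, "n_users": s.n_users,
               "n_tourists": s.n_tourists, "n_locals": s.n_locals,
               "skew": s.skew, "area_km2": s.area_km2, "small": s.small}
        for c in axes.columns:
            row[f"mean_{c}"] = (s.mean_axis or {}).get(c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(wd / "park_summaries.csv", index=False)
    _write_json(wd / "park_summaries.geojson",
                sp.summaries_to_geojson(summaries, parks))
    n_occupied = sum(1 for s in summaries if s.n_users > 0)
    return {"n_parks": len(summaries), "n_occupied": n_occupied}


_STAGE_FN = {
    "simulate": stage_simulate, "cluster": stage_cluster,
    "assess": stage_assess, "users": stage_users, "models": stage_models,
    "freq": stage_freq, "spatial": stage_spatial,
}


def run(config: PipelineConfig, stages=None) -> dict:
    """Run the requested stages in pipeline order; returns the report.

    The report (also written to ``report.json``) records per-stage
    counts and seeds, never timing, so identical configs yield
    byte-identical outputs.
    """
    stages = list(STAGES) if stages is None else [s for s in STAGES
                                                  if s in set(stages)]
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    report = {"stages": {}, "seeds": dict(config.seeds)}
    for name in stages:
        logger.info("stage=%s event=start", name)
        result = _STAGE_FN[name](config)
        report["stages"][name] = result
        logger.info("stage=%s event=done %s", name, result)
    _write_json(wd / "report.json", report)
    return report
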