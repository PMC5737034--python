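"""End-to-end workflow: three input TSVs (or a simulation block) to a
results directory of stage outputs plus a run manifest.

Stage order mirrors the analysis: rarefy -> rarity -> diversity ->
niche/indicator analysis -> ordination (NMDS/ANOSIM/Mantel) -> RDA/VPA/dbRDA
-> neutral model.  Stages are individually re-runnable; a stage whose
outputs exist under an identical configuration hash is skipped.  All
randomness flows from the single configured seed (per-stage seeds are fixed
offsets from it).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    OTUTable,
    bray_curtis,
    env_distance,
    geographic_distance,
    rarefy,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    to_relative,
    write_metadata,
    write_otu_table,
    write_taxonomy,
)
from .diversity import alpha_diversity, dissimilarity_cv, group_tests
from .habitat_niche import indval, niche_breadth, strict_specialist_summary
from .ncm import fit_ncm, ncm_by_rank
from .ordination import anosim, dbrda_by_rank, matrix_correlation, nmds, rda, vpa
from .rarity import classify_rarity, multicola_profile, rarity_summary
from .synthetic import MetacommunityDesign, simulate_metacommunity

log = logging.getLogger("rarebiome")

STAGES = (
    "simulate",
    "rarefy",
    "rarity",
    "diversity",
    "niche",
    "ordination",
    "rda_vpa",
    "ncm",
)

# fixed per-stage seed offsets so every permutation procedure logs and uses
# its own reproducible stream derived from the one configured seed
SEED_OFFSETS = {
    "simulate": 0,
    "rarefy": 101,
    "indval": 202,
    "nmds": 303,
    "anosim": 404,
    "mantel": 505,
    "rda": 606,
}


@dataclass
class RunConfig:
    """A YAML-backed configuration; unknown keys round-trip untouched."""

    raw: dict

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=False)

    def get(self, *keys, default=None):
        node = self.raw
        for k in keys:
            if not isinstance(node, dict) or k not in node:
                return default
            node = node[k]
        return node

    @property
    def seed(self) -> int:
        seed = self.get("seed")
        if seed is None:
            raise ValueError("config must set an explicit top-level seed")
        return int(seed)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + SEED_OFFSETS[stage]) % (2**31 - 1)

    def hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class PipelineState:
    """Lazily materialized intermediate products shared between stages."""

    def __init__(self, config: RunConfig):
        self.config = config
        self._cache: dict = {}

    def _load_inputs(self):
        cfg = self.config
        if cfg.get("simulate") is not None:
            params = dict(cfg.get("simulate") or {})
            params.setdefault("seed", cfg.stage_seed("simulate"))
            design = MetacommunityDesign(**params)
            table, taxonomy, meta, truth = simulate_metacommunity(design)
            self._cache.update(table=table, taxonomy=taxonomy, meta=meta, truth=truth)
        else:
            inputs = cfg.get("inputs")
            if not inputs:
                raise ValueError("config needs either a 'simulate' or an 'inputs' block")
            table = read_otu_table(
                inputs["otu_table"], inputs.get("orientation", "otus_as_rows")
            )
            taxonomy = read_taxonomy(inputs["taxonomy"])
            meta = read_metadata(inputs["metadata"])
            self._cache.update(
                table=table, taxonomy=taxonomy, meta=meta.aligned_to(table), truth=None
            )

    def __getattr__(self, name):
        if name.startswith("_"):
            raise AttributeError(name)
        if name not in self._cache:
            getter = getattr(self, f"_get_{name}", None)
            if getter is None:
                self._load_inputs()
                if name not in self._cache:
                    raise AttributeError(name)
            else:
                self._cache[name] = getter()
        return self._cache[name]

    def _get_rarefied(self) -> OTUTable:
        depth = self.config.get("rarefy", "depth")
        if depth is None:
            depth = int(self.table.sample_sums.min())
        return rarefy(self.table, int(depth), self.config.stage_seed("rarefy"))

    def _get_rel(self):
        return to_relative(self.rarefied)

    def _get_bray(self):
        return bray_curtis(self.rarefied)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t")


def run_all(
    config: RunConfig,
    stages=None,
    force: bool = False,
) -> Path:
    """Execute the requested stages (default: all applicable) and return the
    output directory.  Prerequisites of a requested stage are computed in
    memory; only requested stages write outputs."""
    outdir = Path(config.get("output_dir", default="results"))
    outdir.mkdir(parents=True, exist_ok=True)
    state = PipelineState(config)

    wanted = list(stages) if stages else list(STAGES)
    unknown = [s for s in wanted if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    if config.get("simulate") is None and "simulate" in wanted and stages is None:
        wanted.remove("simulate")

    manifest_path = outdir / "manifest.json"
    previous = {}
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
    cfg_hash = config.hash()
    manifest = {
        "tool": "rarebiome",
        "version": __version__,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "stage_seeds": {k: config.stage_seed(k) for k in SEED_OFFSETS},
        "stages": dict(previous.get("stages", {})) if previous.get("config_hash") == cfg_hash else {},
    }

    for stage in wanted:
        entry = manifest["stages"].get(stage)
        if (
            not force
            and entry
            and previous.get("config_hash") == cfg_hash
            and all((outdir / f).exists() for f in entry.get("outputs", []))
        ):
            log.info("stage %s: outputs current, skipping", stage)
            continue
        t0 = time.perf_counter()
        outputs = _STAGE_FUNCS[stage](state, config, outdir)
        dt = time.perf_counter() - t0
        manifest["stages"][stage] = {"seconds": round(dt, 3), "outputs": outputs}
        log.info("stage %s: done in %.2fs (%d outputs)", stage, dt, len(outputs))
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(state, config, outdir):
    write_otu_table(state.table, outdir / "otu_table.tsv")
    write_taxonomy(state.taxonomy, outdir / "taxonomy.tsv")
    write_metadata(state.meta, outdir / "metadata.tsv")
    truth = state.truth
    gt = pd.DataFrame(
        {
            "regional_p": truth.regional_p,
            "specialist": truth.specialist.to_numpy(),
            "home_habitat": truth.home_habitat.reindex(state.table.otu_ids).fillna(""),
        },
        index=state.table.otu_ids,
    )
    _write(gt, outdir / "ground_truth.tsv")
    return ["otu_table.tsv", "taxonomy.tsv", "metadata.tsv", "ground_truth.tsv"]


def _stage_rarefy(state, config, outdir):
    write_otu_table(state.rarefied, outdir / "rarefied.tsv")
    return ["rarefied.tsv"]


def _stage_rarity(state, config, outdir):
    partition = classify_rarity(
        state.rel,
        rare_cut=float(config.get("rarity", "rare_cut", default=1e-4)),
        abundant_cut=float(config.get("rarity", "abundant_cut", default=1e-2)),
    )
    partition.categories.rename("category").to_csv(outdir / "rarity_partition.tsv", sep="\t")
    summary = rarity_summary(partition, state.rarefied)
    _write(summary.round(2), outdir / "rarity_summary.tsv")
    cutoffs = config.get("rarity", "multicola_cutoffs")
    profile = (
        multicola_profile(state.rarefied, [float(c) for c in cutoffs])
        if cutoffs
        else multicola_profile(state.rarefied)
    )
    _write(profile.table, outdir / "multicola.tsv")
    state._cache["partition"] = partition
    return ["rarity_partition.tsv", "rarity_summary.tsv", "multicola.tsv"]


def _stage_diversity(state, config, outdir):
    alpha = alpha_diversity(state.rarefied)
    _write(alpha, outdir / "alpha_diversity.tsv")
    habitat = state.meta.habitat.reindex(state.rarefied.sample_ids)
    season = state.meta.season.reindex(state.rarefied.sample_ids)
    tests = []
    for index in alpha.columns:
        vals = alpha[index].dropna()
        for label, grouping in (("habitat", habitat), ("season", season)):
            try:
                res = group_tests(vals, grouping.reindex(vals.index), method="anova")
                tests.append(
                    {"index": index, "grouping": label, "F": res["statistic"], "p": res["p"]}
                )
            except Exception as exc:  # degenerate index on tiny runs
                tests.append({"index": index, "grouping": label, "F": np.nan, "p": np.nan})
                log.warning("ANOVA failed for %s by %s: %s", index, label, exc)
    _write(pd.DataFrame(tests).set_index("index"), outdir / "diversity_tests.tsv")
    cv = dissimilarity_cv(state.bray, habitat)
    _write(cv, outdir / "dissimilarity_cv.tsv")
    return ["alpha_diversity.tsv", "diversity_tests.tsv", "dissimilarity_cv.tsv"]


def _stage_niche(state, config, outdir):
    habitat = state.meta.habitat.reindex(state.rarefied.sample_ids)
    nb = niche_breadth(
        state.rel,
        habitat,
        min_mean_abund=float(config.get("niche", "min_mean_abund", default=2e-5)),
        generalist_cut=float(config.get("niche", "generalist_cut", default=3.0)),
        specialist_cut=float(config.get("niche", "specialist_cut", default=1.5)),
    )
    _write(nb, outdir / "niche_breadth.tsv")
    res = indval(
        state.rarefied,
        habitat,
        n_perm=int(config.get("indval", "n_perm", default=999)),
        seed=config.stage_seed("indval"),
        alpha=float(config.get("indval", "alpha", default=0.05)),
        min_component=float(config.get("indval", "min_component", default=0.8)),
        abundance_filter=float(config.get("indval", "abundance_filter", default=2e-5)),
    )
    _write(res.table, outdir / "indval.tsv")
    strict_specialist_summary(res).rename("n_strict").to_csv(
        outdir / "strict_specialists.tsv", sep="\t"
    )
    state._cache["indval_result"] = res
    return ["niche_breadth.tsv", "indval.tsv", "strict_specialists.tsv"]


def _stage_ordination(state, config, outdir):
    habitat = state.meta.habitat.reindex(state.rarefied.sample_ids)
    season = state.meta.season.reindex(state.rarefied.sample_ids)
    n_perm = int(config.get("ordination", "n_perm", default=999))
    nm = nmds(
        state.bray,
        restarts=int(config.get("ordination", "restarts", default=20)),
        seed=config.stage_seed("nmds"),
    )
    scores = nm.scores.copy()
    scores["stress"] = nm.stress
    _write(scores, outdir / "nmds_scores.tsv")
    rows = []
    for label, grouping in (("habitat", habitat), ("season", season)):
        res = anosim(state.bray, grouping, n_perm=n_perm, seed=config.stage_seed("anosim"))
        rows.append({"grouping": label, "R": res.R, "p": res.p, "n_perm": res.n_perm})
    _write(pd.DataFrame(rows).set_index("grouping"), outdir / "anosim.tsv")

    mantel_rows = []
    matrices = {"bray_curtis": state.bray}
    if state.meta.env_columns:
        matrices["environment"] = env_distance(state.meta.aligned_to(state.rarefied))
    if "latitude" in state.meta.data.columns:
        matrices["geographic"] = geographic_distance(state.meta.aligned_to(state.rarefied))
    names = list(matrices)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = matrix_correlation(
                matrices[a], matrices[b], n_perm=n_perm, seed=config.stage_seed("mantel")
            )
            mantel_rows.append({"pair": f"{a}~{b}", "rho": res.rho, "p": res.p})
    _write(pd.DataFrame(mantel_rows).set_index("pair"), outdir / "mantel.tsv")
    return ["nmds_scores.tsv", "anosim.tsv", "mantel.tsv"]


def _stage_rda_vpa(state, config, outdir):
    meta = state.meta.aligned_to(state.rarefied)
    env_cols = config.get("rda", "predictors") or meta.env_columns
    predictors = meta.data[list(env_cols) + ["habitat"]].copy()
    res = rda(
        state.rarefied,
        predictors,
        n_perm=int(config.get("rda", "n_perm", default=999)),
        seed=config.stage_seed("rda"),
        vif_cut=float(config.get("rda", "vif_cut", default=20.0)),
        forward_alpha=float(config.get("rda", "forward_alpha", default=0.05)),
    )
    summary = pd.DataFrame(
        [
            {
                "explained": res.explained,
                "adj_r2": res.adj_r2,
                "pseudo_F": res.pseudo_f,
                "p": res.p,
                "selected": ",".join(res.selected),
                "dropped_vif": ",".join(res.dropped_vif),
            }
        ],
        index=["rda"],
    )
    _write(summary, outdir / "rda_summary.tsv")
    _write(res.scores, outdir / "rda_scores.tsv")

    blocks = {
        "E": meta.data[list(env_cols)],
        "V": meta.data[["habitat"]],
        "S": meta.data[["season"]],
    }
    vp = vpa(state.rarefied, blocks)
    vpa_rows = {**vp.fractions, "residual": vp.residual}
    pd.Series(vpa_rows, name="fraction").to_csv(outdir / "vpa.tsv", sep="\t")

    ranks = config.get("ranks") or list(dbrda_ranks_default())
    grad = dbrda_by_rank(state.rarefied, state.taxonomy, meta.data[list(env_cols)], ranks=ranks)
    _write(grad, outdir / "dbrda_by_rank.tsv")
    return ["rda_summary.tsv", "rda_scores.tsv", "vpa.tsv", "dbrda_by_rank.tsv"]


def dbrda_ranks_default():
    from .data_model import AGG_RANKS

    return AGG_RANKS


def _stage_ncm(state, config, outdir):
    fit = fit_ncm(state.rarefied)
    _write(fit.table, outdir / "ncm_fit.tsv")
    summary = pd.DataFrame(
        [
            {
                "m": fit.m,
                "N": fit.N,
                "Nm": fit.Nm,
                "d": fit.d,
                "r2": fit.r2,
                "n_samples": fit.n_samples,
                **{f"n_{k}": v for k, v in fit.position_counts().items()},
            }
        ],
        index=["ncm"],
    )
    _write(summary, outdir / "ncm_summary.tsv")
    ranks = config.get("ranks") or list(dbrda_ranks_default())
    _write(ncm_by_rank(state.rarefied, state.taxonomy, ranks=ranks), outdir / "ncm_by_rank.tsv")
    return ["ncm_fit.tsv", "ncm_summary.tsv", "ncm_by_rank.tsv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "rarefy": _stage_rarefy,
    "rarity": _stage_rarity,
    "diversity": _stage_diversity,
    "niche": _stage_niche,
    "ordination": _stage_ordination,
    "rda_vpa": _stage_rda_vpa,
    "ncm": _stage_ncm,
}
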