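"""End-to-end orchestration: synth -> deconfound -> CCA -> downstream stages.

A run is driven by a nested config dict (typically loaded from YAML), one
global seed fanned out to per-stage child seeds, and an artifact directory.
Every stage writes UTF-8 CSV (header row, empty fields for missing values)
or JSON, and every stage can be re-run in isolation from the serialized
outputs of its upstream stages.  A manifest records the config hash, the
seed fan-out and library versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from hcdn import clustering, deconfound, divergence, interactions, latent, phewas, projection, synth
from hcdn.cca import CCAModel, VariatePair, fit_cca, transform_to_variates

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = (
    "synth",
    "deconfound",
    "cca",
    "divergence",
    "phewas",
    "clustering",
    "interactions",
    "latent",
    "projection",
)

#: Demo-scale configuration: a 2,000-subject synthetic cohort with the three
#: planted leading canonical correlations, reduced table widths and bootstrap
#: counts so a full run completes in well under a minute.
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "stages": list(STAGES),
    "synth": {
        "n_subjects": 2000,
        "k_planted": 3,
        "planted_rhos": [0.51, 0.42, 0.39],
        "n_phenotypes": 60,
        "n_risk_factors": 63,
    },
    "cca": {"k": 3},
    "divergence": {"B": 50, "lower_pct": 10.0, "upper_pct": 90.0},
    "phewas": {"modes": [1], "lower_pct": 5.0, "upper_pct": 95.0},
    "clustering": {"levels": 3},
    "interactions": {"B": 200, "n_risk_outcomes": 2, "modes": [1], "sides": ["DN"]},
    "latent": {"B": 25, "n_components": 3},
    "projection": {"n_external": 400, "n_phenotypes": 157, "B": 200},
}


def load_config(path: str | Path) -> dict:
    """Load a YAML config, overlaying it on the demo defaults."""
    user = yaml.safe_load(Path(path).read_text()) or {}
    config = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in user.items():
        if isinstance(value, Mapping) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _child_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).generate_state(len(STAGES), np.uint32)
    return {stage: int(s % (2**31)) for stage, s in zip(STAGES, children)}


def _synth_config(config: Mapping, seed: int) -> synth.SynthConfig:
    kwargs = dict(config.get("synth", {}))
    if "planted_rhos" in kwargs:
        kwargs["planted_rhos"] = tuple(kwargs["planted_rhos"])
    if "hit_regions" in kwargs:
        kwargs["hit_regions"] = {
            int(m): v for m, v in kwargs["hit_regions"].items()
        }
    return synth.SynthConfig(seed=seed, **kwargs)


class PipelineState:
    """Lazy store of stage artifacts, backed by the output directory."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self._cache: dict[str, Any] = {}

    def put(self, name: str, obj: Any) -> None:
        self._cache[name] = obj

    def table(self, name: str) -> pd.DataFrame:
        if name not in self._cache:
            path = self.out_dir / f"{name}.csv"
            if not path.exists():
                raise FileNotFoundError(
                    f"stage input '{name}' not found; run its upstream stage first"
                )
            self._cache[name] = pd.read_csv(path)
        return self._cache[name]

    def model(self) -> CCAModel:
        if "cca_model" not in self._cache:
            path = self.out_dir / "cca_model.json"
            if not path.exists():
                raise FileNotFoundError("cca_model.json not found; run the cca stage first")
            self._cache["cca_model"] = CCAModel.load(path)
        return self._cache["cca_model"]

    def variates(self) -> VariatePair:
        if "variates_pair" not in self._cache:
            df = self.table("variates")
            self._cache["variates_pair"] = VariatePair(
                L_X=df[[c for c in df.columns if c.startswith("DN_")]].rename(
                    columns=lambda c: c[3:]
                ),
                L_Y=df[[c for c in df.columns if c.startswith("HC_")]].rename(
                    columns=lambda c: c[3:]
                ),
            )
        return self._cache["variates_pair"]


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)


def run_pipeline(
    config: Mapping | str | Path | None = None,
    out_dir: str | Path = "hcdn_run",
    stages: list[str] | None = None,
) -> Path:
    """Execute the configured stages in order and write all artifacts.

    ``config`` may be a dict, a YAML path, or None (demo defaults).  Fully
    deterministic given (config, seed): the global seed fans out to fixed
    per-stage child seeds recorded in the manifest.
    """
    if config is None:
        config = json.loads(json.dumps(DEFAULT_CONFIG))
    elif isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        base = json.loads(json.dumps(DEFAULT_CONFIG))
        for key, value in config.items():
            if isinstance(value, Mapping) and isinstance(base.get(key), dict):
                base[key].update(value)
            else:
                base[key] = value
        config = base

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    seeds = _child_seeds(seed)
    run_stages = stages or config.get("stages", list(STAGES))
    state = PipelineState(out)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="a")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("hcdn")
    root.addHandler(handler)
    prior_level = root.level
    if root.getEffectiveLevel() > logging.INFO:
        root.setLevel(logging.INFO)
    try:
        for stage in run_stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            logger.info("running stage %s (seed %d)", stage, seeds[stage])
            _STAGE_FUNCS[stage](state, config, seeds[stage])
    finally:
        root.removeHandler(handler)
        root.setLevel(prior_level)
        handler.close()

    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "stage_seeds": seeds,
        "stages_run": list(run_stages),
        "versions": {
            "hcdn": __import__("hcdn").__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


# ---------------------------------------------------------------- stages


def _stage_synth(state: PipelineState, config: Mapping, seed: int) -> None:
    scfg = _synth_config(config, seed)
    cohort = synth.generate_cohort(scfg)
    structure = synth.make_planted_structure(cohort, scfg)
    X, Y = synth.generate_brain_volumes(cohort, structure, scfg)
    pheno, risk = synth.generate_phenotype_tables(cohort, structure, scfg)

    state.put("cohort", cohort)
    state.put("volumes_dn", X)
    state.put("volumes_hc", Y)
    state.put("phenotypes", pheno)
    state.put("risk_factors", risk)
    state.put("structure", structure)

    _write(cohort, state.out_dir / "cohort.csv")
    _write(X, state.out_dir / "volumes_dn.csv")
    _write(Y, state.out_dir / "volumes_hc.csv")
    _write(pheno, state.out_dir / "phenotypes.csv")
    _write(risk, state.out_dir / "risk_factors.csv")
    meta = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(scfg).items()
            if not isinstance(v, Mapping)
        },
        "seed": seed,
        "oracle_canonical_correlations": synth.oracle_canonical_correlations(
            structure, scfg
        ).tolist(),
        "cohort_summary": synth.cohort_summary(cohort),
    }
    (state.out_dir / "synth_meta.json").write_text(json.dumps(meta, indent=2, default=str))


def _stage_deconfound(state: PipelineState, config: Mapping, seed: int) -> None:
    cohort = state.table("cohort")
    spec = deconfound.ConfoundSpec()
    for name in ("volumes_dn", "volumes_hc"):
        resid = deconfound.residualize_confounds(state.table(name), cohort, spec)
        clean = deconfound.standardize_columns(resid)
        state.put(f"{name}_clean", clean)
        _write(clean, state.out_dir / f"{name}_clean.csv")


def _stage_cca(state: PipelineState, config: Mapping, seed: int) -> None:
    k = int(config.get("cca", {}).get("k", 25))
    X = state.table("volumes_dn_clean")
    Y = state.table("volumes_hc_clean")
    model = fit_cca(X, Y, k=k)
    model.save(state.out_dir / "cca_model.json")
    state.put("cca_model", model)
    variates = transform_to_variates(model, X, Y)
    joined = pd.concat(
        [variates.L_X.add_prefix("DN_"), variates.L_Y.add_prefix("HC_")], axis=1
    )
    state._cache.pop("variates_pair", None)
    state.put("variates", joined)
    _write(joined, state.out_dir / "variates.csv")
    _write(
        pd.DataFrame({"mode": np.arange(1, k + 1), "canonical_correlation": model.rhos}),
        state.out_dir / "canonical_correlations.csv",
    )


def _stage_divergence(state: PipelineState, config: Mapping, seed: int) -> None:
    dcfg = config.get("divergence", {})
    X = state.table("volumes_dn_clean")
    Y = state.table("volumes_hc_clean")
    history = state.table("cohort")["family_history"].to_numpy()
    dist = divergence.bootstrap_group_difference(
        X, Y, history, state.model(), B=int(dcfg.get("B", 100)), seed=seed
    )
    hits = divergence.detect_hits(
        dist,
        lower_pct=float(dcfg.get("lower_pct", 10.0)),
        upper_pct=float(dcfg.get("upper_pct", 90.0)),
    )
    state.put("divergence_hits", hits)
    _write(hits, state.out_dir / "divergence_hits.csv")


def _stage_phewas(state: PipelineState, config: Mapping, seed: int) -> None:
    pcfg = config.get("phewas", {})
    cohort = state.table("cohort")
    pheno = state.table("phenotypes")
    variates = state.variates()
    categories = synth.assign_categories(list(pheno.columns))
    dosage = cohort["genotype"].map(phewas.dosage_score).to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy()

    for mode in pcfg.get("modes", [1]):
        j = int(mode) - 1
        predicted = phewas.stacked_dosage_prediction(variates, dosage, sex, j)
        for s in ("male", "female"):
            in_sex = sex == s
            tails = phewas.select_tails(
                predicted[in_sex],
                lower_pct=float(pcfg.get("lower_pct", 5.0)),
                upper_pct=float(pcfg.get("upper_pct", 95.0)),
            )
            take = np.flatnonzero(in_sex)[tails]
            scan = phewas.phenome_scan(
                predicted.iloc[take], pheno.iloc[take], categories=categories
            )
            _write(scan, state.out_dir / "phewas" / f"mode{mode:02d}_{s}.csv")
            state.put(f"phewas_mode{mode:02d}_{s}", scan)


def _stage_clustering(state: PipelineState, config: Mapping, seed: int) -> None:
    ccfg = config.get("clustering", {})
    cohort = state.table("cohort")
    risk = state.table("risk_factors")
    variates_z = deconfound.standardize_columns(state.table("variates"))
    risk_z = deconfound.standardize_columns(risk)

    trees: dict[str, np.ndarray] = {}
    for g in synth.GENOTYPES:
        ind = (cohort["genotype"] == g).to_numpy(dtype=float)
        if ind.sum() < 2:
            logger.warning("genotype %s has <2 carriers; clustering skipped", g)
            continue
        cross = clustering.genotype_masked_spearman(variates_z, ind, risk_z)
        tree = clustering.ward_cluster(cross)
        trees[g] = tree
        tag = g.replace("/", "")
        _write(
            pd.DataFrame(tree, columns=["left", "right", "distance", "size"]),
            state.out_dir / "clustering" / f"linkage_{tag}.csv",
        )
        (state.out_dir / "clustering" / f"dendrogram_{tag}.nwk").write_text(
            clustering.linkage_to_newick(tree, list(cross.index))
        )
        labels = clustering.cut_tree_levels(tree, levels=int(ccfg.get("levels", 3)))
        _write(
            pd.DataFrame({"risk_factor": cross.index, "cluster": labels}),
            state.out_dir / "clustering" / f"clusters_{tag}.csv",
        )

    names = sorted(trees)
    comp = pd.DataFrame(1.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = clustering.compare_cluster_models(trees[a], trees[b])
            comp.loc[a, b] = comp.loc[b, a] = r
    state.put("cluster_model_comparison", comp)
    _write(comp, state.out_dir / "clustering" / "model_comparison.csv", index=True)


def _stage_interactions(state: PipelineState, config: Mapping, seed: int) -> None:
    icfg = config.get("interactions", {})
    cohort = state.table("cohort")
    risk = state.table("risk_factors")
    variates = state.variates()
    B = int(icfg.get("B", 1000))
    sides = icfg.get("sides", ["DN", "HC"])
    modes = [int(m) for m in icfg.get("modes", [1])]
    outcomes = list(risk.columns[: int(icfg.get("n_risk_outcomes", 2))])

    rng = np.random.default_rng(seed)
    for s in ("male", "female"):
        mask = (cohort["sex"] == s).to_numpy()
        geno = cohort["genotype"].to_numpy()[mask]
        age = cohort["age"].to_numpy()[mask]
        blocks = []
        for side in sides:
            L = variates.L_X if side == "DN" else variates.L_Y
            for mode in modes:
                var = L.iloc[:, mode - 1].to_numpy()[mask]
                design = interactions.build_interaction_design(var, geno, age)
                for outcome_name, family in [(o, "linear") for o in outcomes] + [
                    ("family_history", "logistic")
                ]:
                    y = (
                        cohort["family_history"].to_numpy()[mask]
                        if outcome_name == "family_history"
                        else risk[outcome_name].to_numpy()[mask]
                    )
                    masked = interactions.permutation_mask(
                        y, design, family=family, B=B,
                        seed=int(rng.integers(2**31)),
                    )
                    masked.insert(0, "model", f"{side}_mode{mode:02d}")
                    masked.insert(1, "outcome", outcome_name)
                    masked.insert(2, "family", family)
                    blocks.append(masked.reset_index(names="term"))
        table = pd.concat(blocks, ignore_index=True)
        _write(table, state.out_dir / "interactions" / f"masked_{s}.csv")
        state.put(f"interactions_{s}", table)


def _stage_latent(state: PipelineState, config: Mapping, seed: int) -> None:
    lcfg = config.get("latent", {})
    risk = state.table("risk_factors")
    variates = state.variates()
    M = latent.correlation_matrix(variates, risk)
    axes = latent.latent_axes(M, n_components=int(lcfg.get("n_components", 3)))
    _write(axes.projections, state.out_dir / "latent" / "projections.csv", index=True)
    _write(axes.weights, state.out_dir / "latent" / "weights.csv", index=True)
    _write(
        pd.DataFrame(
            {
                "component": np.arange(1, len(axes.explained_variance) + 1),
                "explained_variance_fraction": axes.explained_variance,
            }
        ),
        state.out_dir / "latent" / "explained_variance.csv",
    )
    agree = latent.reliability_bootstrap(
        variates, risk, scheme="split_half", B=int(lcfg.get("B", 100)), seed=seed
    )
    summary = agree.describe(percentiles=[0.05, 0.5, 0.95])
    _write(agree, state.out_dir / "latent" / "split_half_agreement.csv")
    _write(summary, state.out_dir / "latent" / "split_half_summary.csv", index=True)
    state.put("latent_axes", axes)


def _stage_projection(state: PipelineState, config: Mapping, seed: int) -> None:
    pcfg = config.get("projection", {})
    model = state.model()
    # synthesize an external cohort from the same stated world, new seed
    scfg = _synth_config(config, seed)
    scfg = synth.SynthConfig(
        **{
            **{k: v for k, v in vars(scfg).items()},
            "n_subjects": int(pcfg.get("n_external", 400)),
            "n_phenotypes": int(pcfg.get("n_phenotypes", 157)),
            "seed": seed,
        }
    )
    cohort = synth.generate_cohort(scfg)
    structure = synth.make_planted_structure(cohort, scfg)
    X, Y = synth.generate_brain_volumes(cohort, structure, scfg)
    pheno, _risk = synth.generate_phenotype_tables(cohort, structure, scfg)
    spec = deconfound.ConfoundSpec()
    X = deconfound.standardize_columns(deconfound.residualize_confounds(X, cohort, spec))
    Y = deconfound.standardize_columns(deconfound.residualize_confounds(Y, cohort, spec))

    variates = projection.project_external(model, X, Y)
    scan = projection.permutation_corr_scan(
        variates, pheno, B=int(pcfg.get("B", 1000)), seed=seed
    )
    _write(scan, state.out_dir / "projection" / "external_scan.csv")
    state.put("projection_scan", scan)


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "deconfound": _stage_deconfound,
    "cca": _stage_cca,
    "divergence": _stage_divergence,
    "phewas": _stage_phewas,
    "clustering": _stage_clustering,
    "interactions": _stage_interactions,
    "latent": _stage_latent,
    "projection": _stage_projection,
}
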