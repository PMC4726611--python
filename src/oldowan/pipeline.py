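"""End-to-end pipeline: simulate -> standardize -> train -> null model -> compare.

Every stage writes its artifact to the output directory, so each can be
re-run or inspected independently; all randomness flows from a single seed
through spawned child seeds, making the whole run reproducible byte for byte.

The default configuration encodes a synthetic analogue of the DK comparison:
a large two-material experimental assemblage calibrates the null model and the
behavior trees; a separate site assemblage (97 basalt cores, 9 quartzite
cores) is filtered by a taphonomic scenario — basalt flakes retained with
probability 0.6 and a fifth of basalt cores knapped inefficiently (thicker,
narrower flakes), quartzite production removed entirely and replaced by 233
imported OBC flakes — and then compared against the null expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .inference import AssemblageComparison, AssemblageReport, core_morphology_check
from .io import write_assemblage, write_flake_table
from .morphometrics import DEFAULT_GM_FIELDS, standardize_table
from .nullmodel import LeastEffortNullModel
from .simulate import (
    Assemblage,
    SimParams,
    TaphonomyParams,
    apply_taphonomy,
    generate_experimental_assemblage,
)
from .tree import BehaviorTreeModel

#: Synthetic DK scenario defaults (see module docstring).
DEFAULT_CONFIG: dict = {
    "experiment": {"basalt": {"n_cores": 146}, "quartzite": {"n_cores": 73}},
    "site": {"basalt": {"n_cores": 97}, "quartzite": {"n_cores": 9}},
    "site_deviants": {
        "basalt": {"fraction": 0.2, "offsets": {"ST": 0.18, "SW": -0.35}},
    },
    "taphonomy": {
        "basalt": {"retention_fraction": 0.6},
        "quartzite": {"retention_fraction": 0.0, "import_counts": {"OBC": 233}},
    },
    "tree": {"min_leaf": 5, "trim_reps": 100},
    "compare": {"envelope_rule": "any", "contrast_test": "welch"},
    "gm_fields": list(DEFAULT_GM_FIELDS),
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    outdir: str | Path = "oldowan_run"
    experiment: dict = field(default_factory=lambda: DEFAULT_CONFIG["experiment"])
    site: dict = field(default_factory=lambda: DEFAULT_CONFIG["site"])
    site_deviants: dict = field(
        default_factory=lambda: DEFAULT_CONFIG["site_deviants"])
    taphonomy: dict = field(default_factory=lambda: DEFAULT_CONFIG["taphonomy"])
    tree: dict = field(default_factory=lambda: DEFAULT_CONFIG["tree"])
    compare: dict = field(default_factory=lambda: DEFAULT_CONFIG["compare"])
    gm_fields: list = field(default_factory=lambda: DEFAULT_CONFIG["gm_fields"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _sim_params_for(spec: dict, material: str, seed: int,
                    deviant: dict | None = None) -> list[SimParams]:
    """Build SimParams for one material, optionally splitting off deviant cores."""
    n = int(spec.get("n_cores", 0))
    extra = {k: v for k, v in spec.items() if k != "n_cores"}
    if not deviant:
        return [SimParams(n_cores=n, material=material, seed=seed, **extra)]
    n_dev = int(round(float(deviant["fraction"]) * n))
    offsets = {str(k): float(v) for k, v in deviant["offsets"].items()}
    base = SimParams(n_cores=n - n_dev, material=material, seed=seed, **extra)
    means = dict(base.measure_means)
    for k, dv in offsets.items():
        means[k] = means[k] + dv
    # distinct core-id prefix so the two sub-populations never collide
    dev = SimParams(n_cores=n_dev, material=material, seed=seed + 1,
                    measure_means=means,
                    core_id_prefix=f"{material[:2].upper()}X", **extra)
    return [base, dev]


def run_pipeline(config: RunConfig) -> AssemblageReport:
    """Execute every stage, persisting all intermediate artifacts.

    Returns the final :class:`AssemblageReport`; artifacts land in
    ``config.outdir`` (experimental and site CSVs, tree JSON, null-model JSON,
    report JSON and text summary). Idempotent for a fixed seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = {name: _child_seed(child) for name, child in zip(
        ("experiment", "site", "taphonomy", "tree"), root.spawn(4))}
    gm_fields = tuple(config.gm_fields)

    # --- experimental replication assemblage -------------------------------
    exp_params = []
    for i, (material, spec) in enumerate(sorted(config.experiment.items())):
        exp_params.extend(_sim_params_for(spec, material,
                                          seeds["experiment"] + 10 * i))
    experimental = generate_experimental_assemblage(exp_params)
    experimental.flakes = standardize_table(experimental.flakes, gm_fields)
    write_assemblage(experimental, outdir / "experimental_flakes.csv",
                     outdir / "experimental_cores.csv")

    # --- behavior trees -----------------------------------------------------
    labelled = experimental.flakes[experimental.flakes["behavior"] != ""]
    tree_opts = dict(config.tree)
    tree_results = BehaviorTreeModel(labelled).fit(seed=seeds["tree"], **tree_opts)
    tree_results.to_json(outdir / "behavior_trees.json")

    # --- null model ---------------------------------------------------------
    null = LeastEffortNullModel(experimental).fit()
    # core-morphology sanity check on the experimental cores
    morph = {}
    for material in sorted(experimental.cores["material"].unique()):
        cores = experimental.cores[experimental.cores["material"] == material]
        counts = (experimental.flakes[
            experimental.flakes["material"] == material]
            .groupby("core_id").size().reindex(cores["core_id"], fill_value=0))
        try:
            h, p, posthoc = core_morphology_check(cores, counts.to_numpy())
            morph[material] = {"H": h, "p": p,
                               "posthoc": posthoc.to_dict(orient="records")}
        except ParameterError:
            pass
    null.meta["core_morphology"] = morph
    null.to_json(outdir / "null_model.json")

    # --- synthetic site assemblage + taphonomy ------------------------------
    site_parts = []
    site_cores = []
    for i, (material, spec) in enumerate(sorted(config.site.items())):
        params = _sim_params_for(spec, material, seeds["site"] + 10 * i,
                                 deviant=config.site_deviants.get(material))
        produced = generate_experimental_assemblage(params)
        taph_spec = dict(config.taphonomy.get(material, {}))
        taph = TaphonomyParams(seed=seeds["taphonomy"] + 10 * i,
                               import_material=material, **taph_spec)
        recovered = apply_taphonomy(produced, taph)
        site_parts.append(recovered.flakes)
        site_cores.append(recovered.cores)
    site = Assemblage(
        flakes=pd.concat(site_parts, ignore_index=True),
        cores=pd.concat(site_cores, ignore_index=True),
        labels_hidden=True,
    )
    site.flakes = standardize_table(site.flakes, gm_fields)
    write_assemblage(site, outdir / "site_flakes.csv", outdir / "site_cores.csv")

    # --- comparison ---------------------------------------------------------
    n_cores = {m: int(spec.get("n_cores", 0))
               for m, spec in config.site.items()}
    report = AssemblageComparison(site, null, tree_results, n_cores=n_cores,
                                  **config.compare).fit()
    report.core_morphology = morph
    report.meta["seed"] = config.seed
    report.to_json(outdir / "report.json")
    (outdir / "report.txt").write_text(report.summary() + "\n", encoding="utf-8")
    classified = tree_results.predict(
        site.flakes[site.flakes["whole"]])
    write_flake_table(classified, outdir / "site_classified.csv")
    return report
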