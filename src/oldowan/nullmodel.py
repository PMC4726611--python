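"""Least-effort null expectations built from an experimental assemblage.

Three expectation surfaces are derived from a labelled experimental
assemblage and later compared against archaeological material:

* **Yield table** — mean detached pieces per core and mean whole-flake count
  per behavior per core, by raw material. Multiplied by an archaeological
  core count this gives the number of flakes a site *should* contain if every
  core was reduced to exhaustion under least-effort production.
* **Behavior proportions** — the experimental mix of OBA–OBD whole flakes,
  the "experimental expectation" distribution.
* **Morphological envelopes** — per (material, standardized measure) sample
  mean and SD with mean ± 2 SD bounds. A flake is *outside expected
  variation* when any measure falls strictly outside its closed interval
  (the union rule; an all-measures intersection rule is available).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .morphometrics import STANDARDIZED_MEASURES
from .simulate import BEHAVIORS, Assemblage

__all__ = [
    "YieldTable", "Envelope", "build_yield_table", "build_envelope",
    "flag_outside", "LeastEffortNullModel", "NullModelResults",
]


@dataclass
class YieldTable:
    """Mean per-core yields for one material.

    ``flakes_per_core`` counts every detached piece (whole and broken);
    ``per_behavior`` counts whole, behavior-labelled flakes only.
    """

    material: str
    flakes_per_core: float
    per_behavior: dict[str, float]
    n_cores: int

    def behavior_proportions(self) -> dict[str, float]:
        total = sum(self.per_behavior.values())
        return {b: v / total for b, v in self.per_behavior.items()}


@dataclass
class Envelope:
    """Mean ± 2 SD expectation band per standardized measure, one material."""

    material: str
    stats: pd.DataFrame  # index: measure; columns: mean, sd, lower, upper
    n: int = 0

    def bounds(self, measure: str) -> tuple[float, float]:
        row = self.stats.loc[measure]
        return float(row["lower"]), float(row["upper"])


def build_yield_table(assemblage: Assemblage, material: str) -> YieldTable:
    """Per-core averages for one material; zero-flake cores count in the denominator."""
    cores = assemblage.cores[assemblage.cores["material"] == material]
    if len(cores) == 0:
        raise ParameterError(f"assemblage has no {material} cores")
    flakes = assemblage.flakes[assemblage.flakes["material"] == material]
    labelled = flakes["behavior"].fillna("").astype(str)
    n_cores = len(cores)
    per_behavior = {
        b: float((labelled == b).sum()) / n_cores for b in BEHAVIORS
    }
    return YieldTable(
        material=material,
        flakes_per_core=len(flakes) / n_cores,
        per_behavior=per_behavior,
        n_cores=n_cores,
    )


def build_envelope(flakes: pd.DataFrame, material: str,
                   measures: tuple[str, ...] = STANDARDIZED_MEASURES) -> Envelope:
    """Sample mean/SD (n-1 denominator) and ± 2 SD bounds per measure."""
    sub = flakes[flakes["material"] == material] if "material" in flakes.columns \
        else flakes
    if len(sub) < 2:
        raise ParameterError(
            f"need at least 2 {material} flakes to build an envelope"
        )
    rows = {}
    for m in measures:
        if m not in sub.columns:
            raise ParameterError(f"flake table lacks standardized measure {m!r}")
        vals = sub[m].to_numpy(dtype=float)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        rows[m] = {"mean": mean, "sd": sd,
                   "lower": mean - 2.0 * sd, "upper": mean + 2.0 * sd}
    stats = pd.DataFrame.from_dict(rows, orient="index")[
        ["mean", "sd", "lower", "upper"]]
    return Envelope(material=material, stats=stats, n=len(sub))


def flag_outside(envelope: Envelope, flake, material: str | None = None,
                 rule: str = "any") -> tuple[bool, list[str]]:
    """Whether a standardized flake falls outside the expectation envelope.

    Intervals are closed: a value exactly on a bound is inside. Under the
    default ``any`` rule a single violated measure puts the flake outside;
    under ``all`` every measure must be violated.
    """
    mat = material if material is not None else flake.get("material")
    if mat is not None and mat != envelope.material:
        raise ParameterError(
            f"envelope is for {envelope.material!r}, flake is {mat!r}"
        )
    violated = []
    for m in envelope.stats.index:
        lo, hi = envelope.bounds(m)
        v = float(flake[m])
        if v < lo or v > hi:
            violated.append(m)
    if rule == "any":
        return len(violated) > 0, violated
    if rule == "all":
        return len(violated) == len(envelope.stats.index), violated
    raise ParameterError(f"unknown envelope rule {rule!r}")


def flag_outside_table(envelope: Envelope, flakes: pd.DataFrame,
                       rule: str = "any") -> pd.Series:
    """Vectorized outside-envelope flags for a standardized flake table."""
    n_violated = np.zeros(len(flakes), dtype=int)
    for m in envelope.stats.index:
        lo, hi = envelope.bounds(m)
        v = flakes[m].to_numpy(dtype=float)
        n_violated += ((v < lo) | (v > hi)).astype(int)
    if rule == "any":
        out = n_violated > 0
    elif rule == "all":
        out = n_violated == len(envelope.stats.index)
    else:
        raise ParameterError(f"unknown envelope rule {rule!r}")
    return pd.Series(out, index=flakes.index, name="outside_envelope")


class LeastEffortNullModel:
    """Null-model builder over a labelled, standardized experimental assemblage.

    Parameters
    ----------
    assemblage : Assemblage
        Experimental assemblage whose flake table already carries the
        standardized measure columns.
    measures : tuple of str
        Envelope measures (defaults to the six standardized variables).
    """

    def __init__(self, assemblage: Assemblage,
                 measures: tuple[str, ...] = STANDARDIZED_MEASURES):
        if assemblage.n_cores == 0:
            raise ParameterError("cannot build a null model without cores")
        self.assemblage = assemblage
        self.measures = measures

    def fit(self) -> "NullModelResults":
        materials = sorted(self.assemblage.cores["material"].unique())
        yields, envelopes = {}, {}
        for m in materials:
            yields[m] = build_yield_table(self.assemblage, m)
            whole = self.assemblage.flakes[
                (self.assemblage.flakes["material"] == m)
                & (self.assemblage.flakes["behavior"].fillna("") != "")
            ]
            envelopes[m] = build_envelope(whole, m, self.measures)
        return NullModelResults(yields=yields, envelopes=envelopes)


@dataclass
class NullModelResults:
    """Per-material least-effort expectations (yields, proportions, envelopes)."""

    yields: dict[str, YieldTable]
    envelopes: dict[str, Envelope]
    meta: dict = field(default_factory=dict)

    @property
    def materials(self) -> list[str]:
        return sorted(self.yields)

    def summary(self) -> str:
        lines = ["Least-effort null model", "=" * 23]
        for m in self.materials:
            y = self.yields[m]
            env = self.envelopes[m]
            props = y.behavior_proportions()
            lines.append(f"\n[{m}] {y.n_cores} cores, "
                         f"{y.flakes_per_core:.2f} flakes/core")
            lines.append("  behavior means/core: " + "  ".join(
                f"{b}={y.per_behavior[b]:.2f}" for b in BEHAVIORS))
            lines.append("  behavior proportions: " + "  ".join(
                f"{b}={props[b]:.3f}" for b in BEHAVIORS))
            lines.append("  envelopes (mean ± 2 SD):")
            lines.append("  " + env.stats.round(3).to_string().replace("\n", "\n  "))
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "yields": {
                m: {"flakes_per_core": y.flakes_per_core,
                    "per_behavior": y.per_behavior, "n_cores": y.n_cores}
                for m, y in self.yields.items()
            },
            "envelopes": {
                m: {"n": env.n, "measures": list(env.stats.index),
                    "stats": env.stats.to_dict(orient="index")}
                for m, env in self.envelopes.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "NullModelResults":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        yields = {
            m: YieldTable(material=m,
                          flakes_per_core=float(d["flakes_per_core"]),
                          per_behavior={k: float(v)
                                        for k, v in d["per_behavior"].items()},
                          n_cores=int(d["n_cores"]))
            for m, d in payload["yields"].items()
        }
        envelopes = {}
        for m, d in payload["envelopes"].items():
            stats = pd.DataFrame.from_dict(d["stats"], orient="index")[
                ["mean", "sd", "lower", "upper"]]
            if "measures" in d:  # restore pre-serialization row order
                stats = stats.reindex(d["measures"])
            envelopes[m] = Envelope(material=m, stats=stats, n=int(d["n"]))
        return cls(yields=yields, envelopes=envelopes)
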