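"""Statistical comparison of archaeological assemblages against the null model.

Given an archaeological flake table, the least-effort null expectations, and
the trained behavior trees, this module answers the site-level questions:

* Did the site yield the number of flakes its cores should have produced
  under exhaustive least-effort reduction (expected vs actual counts,
  recovery percentage, observed flakes per core)?
* What mix of production behaviors does the classified assemblage show, and
  what is the feasible range of the *true* mix once the classifier's
  misclassification rates are propagated?
* Do the classified proportions differ from the experimental expectation
  (Yates-corrected chi-square on 2x2 count tables)?
* Do flakes falling outside the 2-SD morphological envelopes differ
  systematically from those within (per-measure two-sample contrasts)?
* Sanity check: does initial core morphology predict flake yield
  (Kruskal-Wallis across core-shape classes, Tukey HSD post hoc)?
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError
from .morphometrics import STANDARDIZED_MEASURES
from .nullmodel import NullModelResults, YieldTable, flag_outside_table
from .simulate import BEHAVIORS, Assemblage
from .tree import BehaviorTreeResults, MisclassMatrix

__all__ = [
    "expected_flakes", "recovery_ratio", "observed_yield", "behavior_bounds",
    "chi_square_yates", "contrast_within_outside", "core_morphology_check",
    "AssemblageComparison", "AssemblageReport",
]


def expected_flakes(n_cores: int, yield_table: "YieldTable | float",
                    material: str | None = None) -> float:
    """Expected flake count for ``n_cores`` exhaustively reduced cores.

    ``yield_table`` may be a YieldTable or a plain flakes-per-core rate.
    Returns the unrounded product; use :func:`round_expected` for the
    reporting convention (whole flakes for large expectations, one decimal
    for small ones).
    """
    if n_cores < 0:
        raise ParameterError("n_cores must be >= 0")
    if isinstance(yield_table, YieldTable):
        if material is not None and material != yield_table.material:
            raise ParameterError(
                f"yield table is for {yield_table.material!r}, not {material!r}"
            )
        rate = yield_table.flakes_per_core
    else:
        rate = float(yield_table)
    return n_cores * rate


def round_expected(value: float) -> float:
    """Report whole flakes when the expectation is large, one decimal otherwise."""
    return float(round(value)) if value >= 100 else round(value, 1)


def recovery_ratio(actual: float, expected: float) -> float:
    """Recovered flakes as a percentage of the least-effort expectation."""
    if expected <= 0:
        raise ParameterError("expected count must be positive")
    return 100.0 * actual / expected


def observed_yield(actual_flakes: float, n_cores: int) -> float:
    """Observed flakes per core at the site."""
    if n_cores <= 0:
        raise ParameterError("n_cores must be positive")
    return actual_flakes / n_cores


def behavior_bounds(counts: Mapping[str, float],
                    mm: "MisclassMatrix | pd.DataFrame",
                    ) -> dict[str, dict[str, float]]:
    """Feasible range of true behavior proportions given misclassification.

    For each behavior ``b`` with ``n_b`` flakes classified as ``b``:

    * minimum true count — only the diagonal survives:
      ``n_b * P(true=b | classified=b)``;
    * maximum true count — every classified-``b`` flake is truly ``b`` and
      every other class contributes its full cross-flow:
      ``n_b + sum over c != b of n_c * P(true=b | classified=c)``.

    These bracket every reallocation consistent with the matrix rows. Counts
    are converted to proportions of the classified total; the point estimate
    is the classified proportion itself.
    """
    table = mm.table if isinstance(mm, MisclassMatrix) else mm
    counts = {b: float(n) for b, n in counts.items() if float(n) > 0}
    total = sum(counts.values())
    if total <= 0:
        raise ParameterError("behavior counts are all zero")
    for b in counts:
        if b not in table.index or table.loc[b].isna().any():
            raise ParameterError(
                f"misclassification row for classified behavior {b!r} is "
                "missing or undefined"
            )
    out: dict[str, dict[str, float]] = {}
    for b in BEHAVIORS:
        n_b = counts.get(b, 0.0)
        p_diag = float(table.loc[b, b]) / 100.0 if b in counts else 0.0
        min_count = n_b * p_diag
        inflow = sum(
            n_c * float(table.loc[c, b]) / 100.0
            for c, n_c in counts.items() if c != b
        )
        max_count = n_b + inflow
        out[b] = {
            "point": n_b / total,
            "min": min_count / total,
            "max": min(max_count / total, 1.0),
        }
    return out


def chi_square_yates(observed) -> tuple[float, int, float]:
    """Chi-square test of a contingency table, Yates-corrected when 2x2.

    For a 2x2 table the statistic is ``sum((max(|O-E|-0.5, 0))^2 / E)`` with
    expected counts from the marginal products (the continuity-corrected term
    is clamped at zero). Larger tables fall back to the uncorrected Pearson
    test with ``df = (r-1)(c-1)``.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ParameterError("observed must be an r x c table with r, c >= 2")
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ParameterError("observed counts must be non-negative, not all zero")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if not np.all(expected > 0):
        raise ParameterError("all expected cell counts must be positive")
    if obs.shape != (2, 2):
        stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
        return float(stat), int(df), float(p)
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    stat = float(np.sum(adj**2 / expected))
    p = float(sps.chi2.sf(stat, df=1))
    return stat, 1, p


def contrast_within_outside(inside: pd.DataFrame, outside: pd.DataFrame,
                            measures: tuple[str, ...] = STANDARDIZED_MEASURES,
                            test: str = "welch", alpha: float = 0.05,
                            holm: bool = False) -> pd.DataFrame:
    """Per-measure comparison of within-envelope vs outside-envelope flakes.

    Returns a table with group means, the two-sided p-value (Welch's t by
    default, Mann-Whitney U via ``test='mannwhitney'``) and a significance
    flag at ``alpha``. A Holm correction across measures is available but
    off by default (per-dimension p-values are reported raw). Groups smaller
    than 2 yield an undefined (NaN) p-value, flagged not-significant.
    """
    if len(inside) == 0 or len(outside) == 0:
        raise ParameterError("both flake groups must be non-empty")
    if test not in ("welch", "mannwhitney"):
        raise ParameterError(f"unknown contrast test {test!r}")
    rows = []
    for m in measures:
        a = inside[m].to_numpy(dtype=float)
        b = outside[m].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            p = np.nan
        elif np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0  # all values identical: no evidence of any difference
        elif test == "welch":
            p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({
            "measure": m,
            "mean_within": float(np.mean(a)),
            "mean_outside": float(np.mean(b)),
            "n_within": len(a),
            "n_outside": len(b),
            "p_value": p,
            "test": test,
        })
    out = pd.DataFrame(rows).set_index("measure")
    pvals = out["p_value"].to_numpy()
    if holm:
        order = np.argsort(pvals)
        k = len(pvals)
        adj = np.full(k, np.nan)
        running = 0.0
        for rank, i in enumerate(order):
            if np.isnan(pvals[i]):
                continue
            running = max(running, (k - rank) * pvals[i])
            adj[i] = min(running, 1.0)
        out["p_value"] = adj
    out["significant"] = (out["p_value"] < alpha).fillna(False)
    return out


def shape_classes(cores: pd.DataFrame,
                  bins: tuple[float, ...] = (1.2, 1.5)) -> pd.Series:
    """Bin cores into shape classes by elongation (length / width)."""
    ratio = cores["length"].to_numpy(dtype=float) / cores["width"].to_numpy(dtype=float)
    labels = ["compact", "intermediate", "elongate"][: len(bins) + 1]
    cls = np.digitize(ratio, bins)
    return pd.Series([labels[i] for i in cls], index=cores.index,
                     name="shape_class")


def core_morphology_check(cores: pd.DataFrame, flakes_per_core,
                          bins: tuple[float, ...] = (1.2, 1.5),
                          ) -> tuple[float, float, pd.DataFrame]:
    """Does initial core shape predict flake yield? It should not.

    Cores are binned into shape classes by their elongation ratio; yields are
    compared across classes with a Kruskal-Wallis test, followed by a Tukey
    HSD post-hoc table. Under least-effort reduction no relationship is
    expected (large p-values).
    """
    yields = np.asarray(flakes_per_core, dtype=float)
    if len(yields) != len(cores):
        raise ParameterError("flakes_per_core must align with the core table")
    classes = shape_classes(cores, bins)
    groups = [yields[(classes == c).to_numpy()] for c in classes.unique()]
    names = list(classes.unique())
    keep = [i for i, g in enumerate(groups) if len(g) >= 2]
    groups = [groups[i] for i in keep]
    names = [names[i] for i in keep]
    if len(groups) < 2:
        raise ParameterError("need at least two shape classes with >= 2 cores")
    h_stat, p = sps.kruskal(*groups)
    tukey = sps.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "mean_diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                "p_value": float(tukey.pvalue[i, j]),
            })
    return float(h_stat), float(p), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results interface

class AssemblageComparison:
    """Compare an archaeological assemblage against least-effort expectations.

    Parameters
    ----------
    assemblage : Assemblage
        Archaeological (or synthetic-archaeological) assemblage whose flake
        table carries the standardized measure columns. True labels, if
        present, are never used: classification comes from ``trees``.
    null : NullModelResults
        Experimental yield tables and envelopes.
    trees : BehaviorTreeResults
        Trimmed behavior trees with misclassification matrices.
    n_cores : mapping material -> int, optional
        Archaeological core counts; defaults to the assemblage's own core
        inventory.
    """

    def __init__(self, assemblage: Assemblage, null: NullModelResults,
                 trees: BehaviorTreeResults,
                 n_cores: Mapping[str, int] | None = None,
                 envelope_rule: str = "any", contrast_test: str = "welch"):
        self.assemblage = assemblage
        self.null = null
        self.trees = trees
        if n_cores is None:
            counts = assemblage.cores.groupby("material").size()
            n_cores = {str(m): int(n) for m, n in counts.items()}
        self.n_cores = dict(n_cores)
        self.envelope_rule = envelope_rule
        self.contrast_test = contrast_test

    def fit(self) -> "AssemblageReport":
        flakes = self.assemblage.flakes
        per_material: dict[str, dict] = {}
        materials = sorted(set(self.n_cores) | set(flakes["material"].unique()))
        for mat in materials:
            if mat not in self.null.yields:
                raise ParameterError(f"null model lacks material {mat!r}")
            sub = flakes[flakes["material"] == mat]
            n_cores = int(self.n_cores.get(mat, 0))
            actual = len(sub)
            entry: dict = {"n_cores": n_cores, "n_flakes_actual": actual}
            if n_cores > 0:
                exp = expected_flakes(n_cores, self.null.yields[mat])
                entry["n_flakes_expected"] = round_expected(exp)
                entry["n_flakes_expected_raw"] = exp
                entry["recovery_percent"] = round(recovery_ratio(actual, exp), 1)
                entry["flakes_per_core_observed"] = round(
                    observed_yield(actual, n_cores), 1)

            whole = sub[sub["whole"]] if "whole" in sub.columns else sub
            if len(whole):
                classified = self.trees.predict(whole)
                pred = classified["predicted_behavior"]
                counts = {b: int((pred == b).sum()) for b in BEHAVIORS}
                total = sum(counts.values())
                entry["behavior_counts"] = counts
                entry["behavior_proportions"] = {
                    b: counts[b] / total for b in BEHAVIORS}
                mm = self.trees.misclassification.get(
                    mat, self.trees.misclassification.get("combined"))
                entry["behavior_bounds"] = behavior_bounds(
                    {b: n for b, n in counts.items() if n > 0}, mm)
                entry["null_behavior_proportions"] = (
                    self.null.yields[mat].behavior_proportions())

                env = self.null.envelopes[mat]
                outside = flag_outside_table(env, whole, rule=self.envelope_rule)
                entry["n_outside_envelope"] = int(outside.sum())
                entry["n_within_envelope"] = int((~outside).sum())
                if 2 <= outside.sum() and 2 <= (~outside).sum():
                    contrasts = contrast_within_outside(
                        whole.loc[~outside], whole.loc[outside],
                        test=self.contrast_test)
                    entry["contrasts"] = contrasts
            per_material[mat] = entry

        chi = None
        mats_with_counts = [m for m in materials
                            if "n_flakes_expected" in per_material[m]]
        if len(mats_with_counts) == 2:
            table = [[per_material[m]["n_flakes_actual"] for m in mats_with_counts],
                     [per_material[m]["n_flakes_expected"] for m in mats_with_counts]]
            stat, df, p = chi_square_yates(table)
            chi = {"statistic": stat, "df": df, "p": p, "yates": True,
                   "table": table, "materials": mats_with_counts}
        return AssemblageReport(per_material=per_material, chi_square=chi,
                                envelope_rule=self.envelope_rule)


@dataclass
class AssemblageReport:
    """Results of the archaeological-vs-null comparison."""

    per_material: dict[str, dict]
    chi_square: dict | None = None
    core_morphology: dict | None = None
    envelope_rule: str = "any"
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, pd.DataFrame):
                return obj.replace({np.nan: None}).to_dict(orient="index")
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, float)):
                f = float(obj)
                return None if np.isnan(f) else f
            if isinstance(obj, (np.integer, int)):
                return int(obj)
            if isinstance(obj, (np.bool_, bool)):
                return bool(obj)
            return obj

        return clean({
            "per_material": self.per_material,
            "chi_square": self.chi_square,
            "core_morphology": self.core_morphology,
            "envelope_rule": self.envelope_rule,
            "meta": self.meta,
        })

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def summary(self) -> str:
        lines = ["Assemblage comparison against least-effort expectations",
                 "=" * 56]
        for mat, e in self.per_material.items():
            lines.append(f"\n[{mat}]")
            if "n_flakes_expected" in e:
                lines.append(
                    f"  cores: {e['n_cores']}  expected flakes: "
                    f"{e['n_flakes_expected']}  actual: {e['n_flakes_actual']}"
                    f"  recovery: {e['recovery_percent']}%"
                    f"  flakes/core observed: {e['flakes_per_core_observed']}")
            if "behavior_proportions" in e:
                lines.append("  classified behavior mix (point [min, max]):")
                for b in BEHAVIORS:
                    bb = e["behavior_bounds"][b]
                    null_p = e["null_behavior_proportions"][b]
                    lines.append(
                        f"    {b}: {bb['point']:.3f} "
                        f"[{bb['min']:.3f}, {bb['max']:.3f}]"
                        f"  (null expectation {null_p:.3f})")
            if "n_outside_envelope" in e:
                lines.append(
                    f"  envelope ({self.envelope_rule} rule): "
                    f"{e['n_within_envelope']} within, "
                    f"{e['n_outside_envelope']} outside")
            if "contrasts" in e:
                lines.append("  within vs outside contrasts:")
                lines.append("  " + e["contrasts"].round(4).to_string()
                             .replace("\n", "\n  "))
        if self.chi_square:
            c = self.chi_square
            lines.append(
                f"\nYates chi-square (actual vs expected by material): "
                f"{c['statistic']:.2f}, df={c['df']}, p={c['p']:.4g}")
        if self.core_morphology:
            c = self.core_morphology
            lines.append(
                f"\nCore morphology vs yield (Kruskal-Wallis): "
                + ", ".join(f"{m}: H={d['H']:.2f} p={d['p']:.3f}"
                            for m, d in c.items()))
        return "\n".join(lines)
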