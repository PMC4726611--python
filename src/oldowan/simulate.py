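"""Least-effort core-reduction simulator.

The null model of Oldowan production treats every flake removal as an
independent event: the knapper strikes whatever acceptable platform the core
offers, with no forethought to core shape. Four production behaviors exhaust
the possibilities on a cobble core:

* **OBA** — strike an unmodified, acutely angled cortical edge. The platform
  is therefore fully cortical (platform cortex = 100%). The first removal
  from an unflaked cobble is necessarily OBA.
* **OBB** — strike a cortical platform adjacent to a previous removal's scar,
  using its ridges to guide the fracture. Platform still cortical; dorsal
  cortex reduced relative to OBA.
* **OBC** — bifacial removal: flip the core and use a previous flake scar as
  the platform, so platform cortex = 0%.
* **OBD** — oblique, perimeter-directed removal producing a side-struck flake
  (width exceeds length) with an off-centre point of percussion.

The simulator reproduces the *statistical* signature of exhaustive
least-effort reduction on the two Olduvai Gorge raw materials — per-core
flake yields, behavior mix, and size-standardized shape distributions — not
the fracture mechanics of individual blows. Per-core whole-flake counts per
behavior are drawn at the calibrated per-behavior means (the OBA
count is shifted so every core opens with an OBA removal); the remaining
detached pieces (broken/non-diagnostic debitage that brings the total per
core up to the replication average) are emitted with an empty behavior label
and ``whole = False``.

Shape variables are drawn per behavior from truncated normals at the
calibrated experimental means/SDs, then reconstructed into raw
millimetre measurements through a lognormal per-flake size factor so that
geometric-mean size standardization can be exercised end to end: the drawn
shape vector satisfies a unit geometric mean over the standardization set by
construction (the standardized platform thickness absorbs the constraint), so
standardizing the reconstructed raw flake recovers the drawn vector exactly.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .morphometrics import FLAKE_MEASUREMENTS

BEHAVIORS: tuple[str, ...] = ("OBA", "OBB", "OBC", "OBD")
MATERIALS: tuple[str, ...] = ("basalt", "quartzite")

#: Mean whole-flake counts per core by behavior, and mean total detached
#: pieces per core, for exhaustive least-effort reduction of each material.
YIELD_DEFAULTS: dict[str, dict[str, float]] = {
    "basalt": {"OBA": 1.33, "OBB": 1.90, "OBC": 2.02, "OBD": 1.23, "total": 8.67},
    "quartzite": {"OBA": 1.54, "OBB": 2.25, "OBC": 1.62, "OBD": 0.79, "total": 9.60},
}

#: Experimental (mean, SD) of each size-standardized measure by material.
SHAPE_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "basalt": {
        "SL": (1.672, 0.435),
        "SW": (1.940, 0.428),
        "ST": (0.482, 0.119),
        "SMAX": (2.489, 0.430),
        "SBT": (0.451, 0.148),
        "SAREA": (0.563, 0.104),
    },
    "quartzite": {
        "SL": (1.689, 0.412),
        "SW": (1.456, 0.350),
        "ST": (0.441, 0.152),
        "SMAX": (2.352, 0.377),
        "SBT": (0.493, 0.130),
        "SAREA": (0.677, 0.139),
    },
}

#: Standardized platform width (mean, SD); not part of the reported envelope
#: set, chosen so the raw platform width sits near the flake's geometric mean.
PLATFORM_WIDTH_SHAPE: tuple[float, float] = (1.10, 0.20)

#: Behavior-conditional cortex model. Platform cortex is pinned at 100% for
#: OBA and 0% for OBC by definition; OBB platforms are cortical with some
#: fully cortical, OBD platforms are a mixture of scar (0%) and partly
#: cortical surfaces. Dorsal cortex declines with reduction stage.
CORTEX_DEFAULTS: dict[str, dict[str, tuple]] = {
    "OBA": {"platform": ("const", 100.0), "dorsal": ("clipnorm", 75.0, 15.0, 0.0, 100.0)},
    "OBB": {"platform": ("clipnorm", 85.0, 15.0, 1.0, 100.0),
            "dorsal": ("clipnorm", 45.0, 18.0, 0.0, 100.0)},
    "OBC": {"platform": ("const", 0.0), "dorsal": ("clipnorm", 10.0, 10.0, 0.0, 100.0)},
    "OBD": {"platform": ("zero_mix", 0.45, 40.0, 20.0),
            "dorsal": ("clipnorm", 12.0, 10.0, 0.0, 100.0)},
}

#: Additive offsets on standardized measure means by behavior. OBD flakes are
#: side-struck: relatively wider and shorter than the assemblage average.
SHAPE_OFFSETS: dict[str, dict[str, float]] = {
    "OBD": {"SW": 0.25, "SL": -0.10},
}

#: Lognormal per-flake size factor (log-mean by material, common log-SD).
SIZE_LOG_MEAN: dict[str, float] = {"basalt": np.log(26.0), "quartzite": np.log(24.0)}
SIZE_LOG_SD: float = 0.30

_CORE_SHAPE_OF_MATERIAL = {"basalt": "rounded_cobble", "quartzite": "tabular_block"}


@dataclass
class CoreSpec:
    """Initial morphology of a single core before reduction.

    Dimensions in mm (length >= width >= thickness > 0), weight in grams.
    """

    core_id: str
    material: str
    length: float
    width: float
    thickness: float
    weight: float
    shape: str = ""

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ParameterError(f"unknown material {self.material!r}")
        if not self.shape:
            self.shape = _CORE_SHAPE_OF_MATERIAL[self.material]
        if not (self.length >= self.width >= self.thickness > 0):
            raise ParameterError(
                f"core {self.core_id}: need length >= width >= thickness > 0"
            )
        if self.weight <= 0:
            raise ParameterError(f"core {self.core_id}: weight must be positive")


@dataclass
class SimParams:
    """Parameters of the least-effort reduction simulator for one material.

    Defaults replicate the study conditions of the experimental replication
    assemblage (per-core behavior yields, shape-variable distributions, and
    cortex signatures). ``per_behavior_yield`` holds mean whole-flake counts
    per core; ``nondiagnostic_mean`` is the mean count of additional broken /
    non-diagnostic detached pieces per core, so that the total detached count
    per core matches the replication average.
    """

    n_cores: int
    material: str
    per_behavior_yield: dict[str, float] = field(default_factory=dict)
    nondiagnostic_mean: float | None = None
    measure_means: dict[str, float] = field(default_factory=dict)
    measure_sds: dict[str, float] = field(default_factory=dict)
    cortex_model: dict[str, dict[str, tuple]] = field(default_factory=dict)
    shape_offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    size_log_mean: float | None = None
    size_log_sd: float = SIZE_LOG_SD
    core_id_prefix: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ParameterError(f"unknown material {self.material!r}")
        if self.n_cores < 0:
            raise ParameterError("n_cores must be >= 0")
        defaults = YIELD_DEFAULTS[self.material]
        if not self.per_behavior_yield:
            self.per_behavior_yield = {b: defaults[b] for b in BEHAVIORS}
        if self.nondiagnostic_mean is None:
            self.nondiagnostic_mean = max(
                defaults["total"] - sum(self.per_behavior_yield.values()), 0.0
            )
        shape = SHAPE_DEFAULTS[self.material]
        if not self.measure_means:
            self.measure_means = {m: shape[m][0] for m in shape}
        if not self.measure_sds:
            self.measure_sds = {m: shape[m][1] for m in shape}
        if not self.cortex_model:
            self.cortex_model = CORTEX_DEFAULTS
        if not self.shape_offsets:
            self.shape_offsets = SHAPE_OFFSETS
        if self.size_log_mean is None:
            self.size_log_mean = SIZE_LOG_MEAN[self.material]
        self.validate()

    def validate(self) -> None:
        for b, y in self.per_behavior_yield.items():
            if b not in BEHAVIORS:
                raise ParameterError(f"unknown behavior {b!r} in per_behavior_yield")
            if not np.isfinite(y) or y < 0:
                raise ParameterError(f"yield for {b} must be finite and >= 0")
        if self.nondiagnostic_mean < 0 or not np.isfinite(self.nondiagnostic_mean):
            raise ParameterError("nondiagnostic_mean must be finite and >= 0")
        for m, mu in self.measure_means.items():
            sd = self.measure_sds.get(m)
            if sd is None:
                raise ParameterError(f"measure {m!r} has a mean but no SD")
            if not (np.isfinite(mu) and np.isfinite(sd)) or sd < 0 or mu <= 0:
                raise ParameterError(f"invalid normal parameters for measure {m!r}")

    def replace(self, **kwargs) -> "SimParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TaphonomyParams:
    """Post-depositional filter turning a produced assemblage into a recovered one.

    ``retention_fraction`` — probability a produced flake remains on site,
    either a scalar or a per-behavior mapping (non-diagnostic pieces use the
    scalar, or the mean of the mapping). ``import_counts`` — flakes of each
    behavior added from off-site production (drawn from the experimental
    generative model for ``import_material``).
    """

    retention_fraction: float | Mapping[str, float] = 1.0
    import_counts: Mapping[str, int] = field(default_factory=dict)
    import_material: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            [self.retention_fraction]
            if np.isscalar(self.retention_fraction)
            else list(self.retention_fraction.values())
        )
        for f in fracs:
            if not (0.0 <= float(f) <= 1.0):
                raise ParameterError("retention_fraction must lie in [0, 1]")
        for b, n in self.import_counts.items():
            if b not in BEHAVIORS:
                raise ParameterError(f"unknown behavior {b!r} in import_counts")
            if int(n) < 0:
                raise ParameterError("import_counts must be >= 0")

    def retention_for(self, behavior: str) -> float:
        if np.isscalar(self.retention_fraction):
            return float(self.retention_fraction)
        mapping = dict(self.retention_fraction)
        if behavior in mapping:
            return float(mapping[behavior])
        return float(np.mean(list(mapping.values())))


@dataclass
class Assemblage:
    """A set of detached pieces plus the core inventory that produced them.

    ``flakes`` has one row per detached piece (canonical measurement columns,
    behavior empty for non-diagnostic pieces); ``cores`` one row per core.
    ``labels_hidden`` marks assemblages whose true behavior labels must not be
    used for inference (they are retained only to score recovery in tests).
    """

    flakes: pd.DataFrame
    cores: pd.DataFrame
    labels_hidden: bool = False

    @property
    def n_flakes(self) -> int:
        return len(self.flakes)

    @property
    def n_cores(self) -> int:
        return len(self.cores)


FLAKE_COLUMNS: tuple[str, ...] = (
    ("core_id", "flake_index", "material", "behavior", "whole") + FLAKE_MEASUREMENTS
)
CORE_COLUMNS: tuple[str, ...] = (
    "core_id", "material", "shape", "length", "width", "thickness", "weight",
)


def _clipnorm(rng: np.random.Generator, mean: float, sd: float,
              lo: float, hi: float, n: int) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=n), lo, hi)


def _draw_cortex(rng: np.random.Generator, model: tuple, n: int) -> np.ndarray:
    kind = model[0]
    if kind == "const":
        return np.full(n, float(model[1]))
    if kind == "clipnorm":
        _, mean, sd, lo, hi = model
        return _clipnorm(rng, mean, sd, lo, hi, n)
    if kind == "zero_mix":
        _, p_zero, mean, sd = model
        vals = _clipnorm(rng, mean, sd, 1.0, 100.0, n)
        vals[rng.random(n) < p_zero] = 0.0
        return vals
    raise ParameterError(f"unknown cortex model kind {kind!r}")


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray | float,
                      sd: float, n: int, lo: float = 1e-6) -> np.ndarray:
    """Normal draws conditioned on being > lo (rejection resampling)."""
    out = rng.normal(mean, sd, size=n)
    bad = out <= lo
    while bad.any():
        mu = mean[bad] if np.ndim(mean) else mean
        out[bad] = rng.normal(mu, sd, size=int(bad.sum()))
        bad = out <= lo
    return out


def _draw_flakes(behaviors: Sequence[str], params: SimParams,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Draw measurement rows for flakes with the given (latent) behaviors."""
    n = len(behaviors)
    beh = np.asarray(behaviors)
    means = params.measure_means
    sds = params.measure_sds

    std: dict[str, np.ndarray] = {}
    for m in ("SL", "SW", "ST", "SMAX", "SBT", "SAREA"):
        mu = np.full(n, means[m])
        for b, offs in params.shape_offsets.items():
            if m in offs:
                mu[beh == b] += offs[m]
        std[m] = _truncated_normal(rng, mu, sds[m], n)

    # side-struck OBD flakes: width strictly exceeds length
    is_d = beh == "OBD"
    swap = is_d & (std["SW"] <= std["SL"])
    std["SL"][swap], std["SW"][swap] = std["SW"][swap].copy(), std["SL"][swap].copy()

    # the longest dimension cannot be shorter than length or width
    floor = 1.02 * np.maximum(std["SL"], std["SW"])
    std["SMAX"] = np.maximum(std["SMAX"], floor)

    spw = _truncated_normal(rng, PLATFORM_WIDTH_SHAPE[0], PLATFORM_WIDTH_SHAPE[1],
                            n, lo=0.2)
    # unit geometric mean over the standardization set, by construction
    spt = 1.0 / (std["SL"] * std["SW"] * std["ST"] * std["SBT"] * std["SMAX"] * spw)

    # platform asymmetry: left fraction of platform width; OBD struck off-centre
    frac = np.clip(rng.normal(0.5, 0.04, size=n), 0.25, 0.75)
    if is_d.any():
        nd = int(is_d.sum())
        side = np.where(rng.random(nd) < 0.5, 1.0, -1.0)
        frac[is_d] = 0.5 + side * np.clip(rng.normal(0.20, 0.06, size=nd), 0.05, 0.40)

    jit_l = np.clip(1.0 + rng.normal(0.0, 0.08, size=n), 0.1, None)
    jit_r = np.clip(1.0 + rng.normal(0.0, 0.08, size=n), 0.1, None)

    platform_cortex = np.empty(n)
    dorsal_cortex = np.empty(n)
    for b in BEHAVIORS:
        mask = beh == b
        if mask.any():
            model = params.cortex_model[b]
            platform_cortex[mask] = _draw_cortex(rng, model["platform"], int(mask.sum()))
            dorsal_cortex[mask] = _draw_cortex(rng, model["dorsal"], int(mask.sum()))

    g = rng.lognormal(params.size_log_mean, params.size_log_sd, size=n)

    return pd.DataFrame({
        "length": std["SL"] * g,
        "width": std["SW"] * g,
        "thickness": std["ST"] * g,
        "bulbar_thickness": std["SBT"] * g,
        "platform_width": spw * g,
        "left_platform_width": frac * spw * g,
        "right_platform_width": (1.0 - frac) * spw * g,
        "platform_thickness": spt * g,
        "left_platform_thickness": spt * jit_l * g,
        "right_platform_thickness": spt * jit_r * g,
        "maximum_dimension": std["SMAX"] * g,
        "platform_cortex": platform_cortex,
        "dorsal_cortex": dorsal_cortex,
        "platform_area": std["SAREA"] * g**2,
    })


def simulate_reduction(core: CoreSpec, params: SimParams,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Reduce one core to exhaustion under the least-effort null model.

    Returns a flake table (one row per detached piece). Whole, measurable
    flakes carry their true behavior label; broken/non-diagnostic pieces have
    an empty label and ``whole = False``. The first removal is always OBA:
    an unflaked cobble offers only unmodified acute edges. Reduction stops
    when the core's platform budget — the drawn per-behavior counts — is
    exhausted.
    """
    params.validate()
    y = params.per_behavior_yield
    n_a = 1 + rng.poisson(max(y["OBA"] - 1.0, 0.0))
    counts = {"OBA": n_a}
    for b in ("OBB", "OBC", "OBD"):
        counts[b] = int(rng.poisson(y[b]))
    n_nd = int(rng.poisson(params.nondiagnostic_mean))

    latent = [b for b in BEHAVIORS for _ in range(counts[b])]
    nd_latent = [BEHAVIORS[i] for i in rng.choice(len(BEHAVIORS), size=n_nd)]
    # removal order: OBA opens the core; later removals are exchangeable events
    rest = latent[1:] + nd_latent
    order = rng.permutation(len(rest))
    seq_latent = [latent[0]] + [rest[i] for i in order]
    whole_flags = [True] * (len(latent)) + [False] * n_nd
    seq_whole = [whole_flags[0]] + [whole_flags[1:][i] for i in order]

    flakes = _draw_flakes(seq_latent, params, rng)
    flakes.insert(0, "core_id", core.core_id)
    flakes.insert(1, "flake_index", np.arange(1, len(flakes) + 1))
    flakes.insert(2, "material", core.material)
    flakes.insert(3, "behavior", [b if w else "" for b, w in zip(seq_latent, seq_whole)])
    flakes.insert(4, "whole", seq_whole)
    return flakes


def generate_cores(params: SimParams, rng: np.random.Generator) -> list[CoreSpec]:
    """Draw an inventory of unreduced cores for one material.

    Basalt cores emulate river-rounded cobbles; quartzite cores emulate
    tabular blocks (flatter, from a bedded outcrop). Weight follows an
    ellipsoid volume at the material's density.
    """
    cores = []
    density = {"basalt": 2.9e-3, "quartzite": 2.65e-3}[params.material]  # g/mm^3
    for i in range(params.n_cores):
        length = rng.lognormal(np.log(95.0), 0.18)
        if params.material == "basalt":
            width = length * rng.uniform(0.70, 0.95)
            thickness = width * rng.uniform(0.60, 0.95)
        else:
            width = length * rng.uniform(0.60, 0.90)
            thickness = width * rng.uniform(0.30, 0.60)
        weight = (np.pi / 6.0) * length * width * thickness * density
        prefix = params.core_id_prefix or params.material[:2].upper()
        cores.append(CoreSpec(
            core_id=f"{prefix}{i + 1:04d}",
            material=params.material,
            length=float(length), width=float(width), thickness=float(thickness),
            weight=float(weight),
        ))
    return cores


def generate_experimental_assemblage(
    params: SimParams | Sequence[SimParams],
) -> Assemblage:
    """Reduce a full inventory of cores and collect the labelled assemblage.

    Accepts one parameter set, or several (e.g. one per raw material) whose
    outputs are concatenated. Fully deterministic for a fixed seed.
    """
    param_list = [params] if isinstance(params, SimParams) else list(params)
    flake_parts: list[pd.DataFrame] = []
    core_rows: list[dict] = []
    for p in param_list:
        rng = np.random.default_rng(p.seed)
        for core in generate_cores(p, rng):
            core_rows.append({
                "core_id": core.core_id, "material": core.material,
                "shape": core.shape, "length": core.length, "width": core.width,
                "thickness": core.thickness, "weight": core.weight,
            })
            flake_parts.append(simulate_reduction(core, p, rng))
    if flake_parts:
        flakes = pd.concat(flake_parts, ignore_index=True)
    else:
        flakes = pd.DataFrame(columns=list(FLAKE_COLUMNS))
    cores = pd.DataFrame(core_rows, columns=list(CORE_COLUMNS))
    return Assemblage(flakes=flakes, cores=cores)


def apply_taphonomy(assemblage: Assemblage, taph: TaphonomyParams,
                    sim_params: SimParams | None = None) -> Assemblage:
    """Thin and augment an assemblage to emulate transport and winnowing.

    Each produced flake is kept independently with its behavior's retention
    probability; imported flakes (produced off-site) are drawn from the
    experimental generative model and appended. True behavior labels are
    preserved for recovery scoring but the result is flagged
    ``labels_hidden`` so inference stages treat it as unlabelled.
    """
    rng = np.random.default_rng(taph.seed)
    flakes = assemblage.flakes

    if len(flakes):
        probs = np.array([taph.retention_for(b)
                          for b in flakes["behavior"].fillna("")])
        keep = rng.random(len(flakes)) < probs
        retained = flakes.loc[keep].copy()
    else:
        retained = flakes.copy()

    imports: list[pd.DataFrame] = []
    if taph.import_counts:
        material = taph.import_material
        if material is None:
            mats = assemblage.flakes["material"].unique() if len(assemblage.flakes) else []
            if len(mats) != 1:
                raise ParameterError(
                    "import_material must be given when the assemblage is not "
                    "single-material"
                )
            material = str(mats[0])
        p = sim_params if sim_params is not None else SimParams(
            n_cores=0, material=material, seed=taph.seed + 1
        )
        k = 0
        for b in BEHAVIORS:
            n = int(taph.import_counts.get(b, 0))
            if n == 0:
                continue
            block = _draw_flakes([b] * n, p, rng)
            block.insert(0, "core_id", [f"import-{b}-{k + j + 1:04d}" for j in range(n)])
            block.insert(1, "flake_index", 1)
            block.insert(2, "material", material)
            block.insert(3, "behavior", b)
            block.insert(4, "whole", True)
            imports.append(block)
            k += n
    parts = [df for df in (retained, *imports) if len(df)]
    out = (pd.concat(parts, ignore_index=True) if parts
           else flakes.iloc[0:0].copy())
    return Assemblage(flakes=out, cores=assemblage.cores.copy(), labels_hidden=True)
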