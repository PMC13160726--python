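"""Synthetic cohort generator.

Draws a binary latent class per sample, class-conditional variables
(independent Gaussians for continuous, Bernoulli/categorical for discrete),
then masks whole modality blocks with class-dependent availability — the
modular-missingness structure the fusion chain assumes. A transcription of
the published baseline table for a six-block osteoporotic-fracture cohort is
provided as the default parameter set; :func:`plant_signal` rewrites a block's
continuous means to a chosen standardized effect size for controlled
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import CohortTable, ModalityPartition, VariableSpec

__all__ = [
    "VariableParams",
    "GeneratorParams",
    "CohortTruth",
    "table1_default_params",
    "default_params",
    "generate",
    "plant_signal",
]


@dataclass(frozen=True)
class VariableParams:
    """Class-conditional distribution of one variable.

    For continuous kind: (mean, sd) per class. For binary: event proportion
    per class. For categorical: probability vector over ``categories`` per
    class. Index 0 = control class, index 1 = event class.
    """

    name: str
    block: str
    kind: str
    mean: tuple[float, float] | None = None
    sd: tuple[float, float] | None = None
    proportion: tuple[float, float] | None = None
    categories: tuple[str, ...] | None = None
    probs: tuple[tuple[float, ...], tuple[float, ...]] | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if self.mean is None or self.sd is None:
                raise ValueError(f"{self.name}: continuous variables need mean and sd")
            if any(s <= 0 for s in self.sd):
                raise ValueError(f"{self.name}: SDs must be positive")
        elif self.kind == "binary":
            if self.proportion is None or not all(0 <= p <= 1 for p in self.proportion):
                raise ValueError(f"{self.name}: binary proportions must lie in [0,1]")
        elif self.kind == "categorical":
            if self.categories is None or self.probs is None:
                raise ValueError(f"{self.name}: categorical variables need categories+probs")
            for pv in self.probs:
                if len(pv) != len(self.categories):
                    raise ValueError(f"{self.name}: probs length mismatch")
                if abs(sum(pv) - 1.0) > 1e-9 or any(p < 0 for p in pv):
                    raise ValueError(f"{self.name}: probs must be a distribution")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    def to_spec(self) -> VariableSpec:
        return VariableSpec(self.name, self.kind, categories=self.categories, unit=self.unit)


@dataclass(frozen=True)
class GeneratorParams:
    """Full recipe for one synthetic cohort."""

    n_samples: int
    prevalence: float
    variables: tuple[VariableParams, ...]
    block_order: tuple[str, ...]
    #: block -> (availability in control class, availability in event class)
    availability: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed_prefix: int = 1
    seed: int = 0
    #: within-block equicorrelation of continuous variables (0 = independent)
    equicorrelation: float = 0.0
    #: clamp continuous draws at zero (for physically positive quantities)
    truncate_at_zero: bool = False
    #: if True, ignore class-dependent availability and use the control value
    mcar: bool = False
    #: if True, blocks are observed as nested layers: block t can only be
    #: observed when block t-1 is, with continuation probabilities chosen so
    #: marginal availabilities match the configured values (exactly when they
    #: are non-increasing along the chain, else via their running minimum).
    #: Mirrors examination pathways where deeper workups imply earlier ones.
    nested: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0,1)")
        if not 0 <= self.equicorrelation < 1:
            raise ValueError("equicorrelation must lie in [0,1)")
        blocks_used = {v.block for v in self.variables}
        if blocks_used != set(self.block_order):
            raise ValueError("block_order must name exactly the blocks used by variables")
        avail = dict(self.availability)
        for b in self.block_order:
            avail.setdefault(b, (1.0, 1.0))
        for b, (a0, a1) in avail.items():
            if not (0 <= a0 <= 1 and 0 <= a1 <= 1):
                raise ValueError(f"availability of {b!r} must lie in [0,1]")
        object.__setattr__(self, "availability", avail)
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "block_order", tuple(self.block_order))

    def to_dict(self) -> dict:
        vars_out = []
        for v in self.variables:
            d = {"name": v.name, "block": v.block, "kind": v.kind}
            if v.kind == "continuous":
                d["mean"], d["sd"] = list(v.mean), list(v.sd)
            elif v.kind == "binary":
                d["proportion"] = list(v.proportion)
            else:
                d["categories"] = list(v.categories)
                d["probs"] = [list(p) for p in v.probs]
            if v.unit:
                d["unit"] = v.unit
            vars_out.append(d)
        return {
            "n_samples": self.n_samples,
            "prevalence": self.prevalence,
            "variables": vars_out,
            "block_order": list(self.block_order),
            "availability": {b: list(a) for b, a in self.availability.items()},
            "fixed_prefix": self.fixed_prefix,
            "seed": self.seed,
            "equicorrelation": self.equicorrelation,
            "truncate_at_zero": self.truncate_at_zero,
            "mcar": self.mcar,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        variables = []
        for v in d["variables"]:
            kw = {"name": v["name"], "block": v["block"], "kind": v["kind"],
                  "unit": v.get("unit", "")}
            if v["kind"] == "continuous":
                kw["mean"], kw["sd"] = tuple(v["mean"]), tuple(v["sd"])
            elif v["kind"] == "binary":
                kw["proportion"] = tuple(v["proportion"])
            else:
                kw["categories"] = tuple(v["categories"])
                kw["probs"] = tuple(tuple(p) for p in v["probs"])
            variables.append(VariableParams(**kw))
        return cls(
            n_samples=int(d["n_samples"]),
            prevalence=float(d["prevalence"]),
            variables=tuple(variables),
            block_order=tuple(d["block_order"]),
            availability={b: tuple(a) for b, a in d.get("availability", {}).items()},
            fixed_prefix=int(d.get("fixed_prefix", 1)),
            seed=int(d.get("seed", 0)),
            equicorrelation=float(d.get("equicorrelation", 0.0)),
            truncate_at_zero=bool(d.get("truncate_at_zero", False)),
            mcar=bool(d.get("mcar", False)),
        )

    def partition(self) -> ModalityPartition:
        return ModalityPartition(
            tuple(
                (b, tuple(v.name for v in self.variables if v.block == b))
                for b in self.block_order
            ),
            fixed_prefix=self.fixed_prefix,
        )

    def block_variables(self, block: str) -> list[VariableParams]:
        return [v for v in self.variables if v.block == block]


@dataclass
class CohortTruth:
    """Latent ground truth of one generated cohort."""

    latent_class: pd.Series
    block_observed: pd.DataFrame

    def to_csv(self, path) -> None:
        frame = self.block_observed.astype(int).copy()
        frame.insert(0, "latent_class", self.latent_class)
        frame.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# default parameter sets
# ---------------------------------------------------------------------------


def table1_default_params(n_samples: int = 1287, seed: int = 0) -> GeneratorParams:
    """Six-block parameter set transcribed from the published baseline table.

    Class 1 = fracture cohort (n=643), class 0 = control cohort (n=644);
    block availabilities come from the per-block class sample counts. Marital
    status and ethnicity frequencies are not reported and are filled with
    fixed, class-uninformative vectors.
    """
    marital = ("unmarried", "married", "divorced", "widowed")
    marital_p = (0.03, 0.62, 0.05, 0.30)
    ethnic = ("han", "hui", "manchu", "mongolian", "other")
    ethnic_p = (0.92, 0.03, 0.02, 0.02, 0.01)
    v = [
        # demographics -------------------------------------------------------
        VariableParams("gender_male", "demographics", "binary", proportion=(0.7640, 0.2083)),
        VariableParams("age", "demographics", "continuous",
                       mean=(84.38, 76.98), sd=(6.807, 8.747), unit="years"),
        VariableParams("marital_status", "demographics", "categorical",
                       categories=marital, probs=(marital_p, marital_p)),
        VariableParams("ethnicity", "demographics", "categorical",
                       categories=ethnic, probs=(ethnic_p, ethnic_p)),
        VariableParams("fracture_history", "demographics", "binary",
                       proportion=(0.1273, 0.2193)),
        VariableParams("smoking_history", "demographics", "binary",
                       proportion=(0.2733, 0.05288)),
        VariableParams("smoking_duration", "demographics", "continuous",
                       mean=(31.06, 35.76), sd=(15.94, 8.982), unit="years"),
        VariableParams("alcohol_history", "demographics", "binary",
                       proportion=(0.1040, 0.04199)),
        VariableParams("alcohol_duration", "demographics", "continuous",
                       mean=(32.63, 27.59), sd=(11.08, 6.957), unit="years"),
        # bone mineral density ----------------------------------------------
        VariableParams("femoral_neck_bmd", "bmd", "continuous",
                       mean=(0.8008, 0.6292), sd=(0.1535, 0.1136)),
        VariableParams("femoral_neck_bmd_tscore", "bmd", "continuous",
                       mean=(-1.322, -2.551), sd=(1.224, 1.007)),
        VariableParams("total_hip_bmd", "bmd", "continuous",
                       mean=(0.8902, 0.6675), sd=(0.1691, 0.1300)),
        VariableParams("total_hip_bmd_tscore", "bmd", "continuous",
                       mean=(0.7553, -2.391), sd=(1.310, 1.110)),
        VariableParams("lumbar_spine_bmd_tscore", "bmd", "continuous",
                       mean=(0.7577, -2.060), sd=(2.062, 1.623)),
        VariableParams("mechanical_index", "bmd", "continuous",
                       mean=(1.378, 1.236), sd=(0.6540, 0.5271)),
        VariableParams("curvature_ratio", "bmd", "continuous",
                       mean=(8.348, 9.310), sd=(6.950, 9.528)),
        VariableParams("section_modulus", "bmd", "continuous",
                       mean=(581.3, 401.3), sd=(246.8, 145.9)),
        # bone turnover markers ---------------------------------------------
        VariableParams("ipth", "bone_turnover", "continuous",
                       mean=(47.92, 49.03), sd=(28.28, 24.78), unit="pg/ml"),
        VariableParams("vitamin_d_25oh", "bone_turnover", "continuous",
                       mean=(18.29, 16.62), sd=(10.11, 8.891), unit="ng/ml"),
        VariableParams("tpinp", "bone_turnover", "continuous",
                       mean=(42.52, 48.81), sd=(26.45, 34.93), unit="ng/ml"),
        VariableParams("beta_ctx", "bone_turnover", "continuous",
                       mean=(0.4070, 0.4940), sd=(0.2375, 0.3226), unit="ng/ml"),
        VariableParams("n_mid", "bone_turnover", "continuous",
                       mean=(13.68, 14.21), sd=(6.078, 7.749), unit="ng/ml"),
        # biochemical examination -------------------------------------------
        VariableParams("albumin_globulin_ratio", "biochemical", "continuous",
                       mean=(1.974, 1.954), sd=(4.643, 3.025)),
        VariableParams("calcium", "biochemical", "continuous",
                       mean=(2.270, 2.283), sd=(0.1331, 0.1174), unit="mmol/L"),
        VariableParams("alkaline_phosphatase", "biochemical", "continuous",
                       mean=(56.75, 63.34), sd=(27.55, 25.78), unit="IU/L"),
        VariableParams("creatinine", "biochemical", "continuous",
                       mean=(91.13, 67.45), sd=(47.05, 23.68), unit="mmol/L"),
        VariableParams("total_cholesterol", "biochemical", "continuous",
                       mean=(4.049, 4.468), sd=(0.9931, 1.131), unit="mmol/L"),
        VariableParams("ldl_c", "biochemical", "continuous",
                       mean=(2.138, 2.452), sd=(0.7664, 0.9122), unit="mmol/L"),
        VariableParams("hdl_c", "biochemical", "continuous",
                       mean=(1.284, 1.432), sd=(0.3271, 0.3801), unit="mmol/L"),
        VariableParams("triglycerides", "biochemical", "continuous",
                       mean=(1.412, 1.327), sd=(1.091, 0.7557), unit="mmol/L"),
        # hemoglobin ---------------------------------------------------------
        VariableParams("hemoglobin", "hemoglobin", "continuous",
                       mean=(121.4, 106.3), sd=(23.53, 30.81), unit="g/L"),
        # glycosylated hemoglobin -------------------------------------------
        VariableParams("hba1c", "hba1c", "continuous",
                       mean=(6.460, 6.719), sd=(1.328, 1.477), unit="%"),
    ]
    # per-block class sample counts over 644 controls / 643 fracture cases
    availability = {
        "demographics": (1.0, 1.0),
        "bmd": (513 / 644, 171 / 643),
        "bone_turnover": (511 / 644, 258 / 643),
        "biochemical": (508 / 644, 176 / 643),
        "hemoglobin": (425 / 644, 206 / 643),
        "hba1c": (520 / 644, 145 / 643),
    }
    return GeneratorParams(
        n_samples=n_samples,
        prevalence=643 / 1287,
        variables=tuple(v),
        block_order=("demographics", "bmd", "bone_turnover", "biochemical",
                     "hemoglobin", "hba1c"),
        availability=availability,
        fixed_prefix=2,  # demographics then BMD are pinned in the study design
        seed=seed,
    )


def default_params(
    n_samples: int = 2000,
    n_blocks: int = 6,
    vars_per_block: int = 3,
    effect: float = 1.0,
    prevalence: float = 0.5,
    availability: float = 1.0,
    seed: int = 0,
) -> GeneratorParams:
    """Generic cohort where every block carries independent signal.

    Each block holds ``vars_per_block`` standard-normal variables whose
    class-conditional means are separated by ``effect`` SDs. Used for
    monotonicity, no-harm, and ordering experiments.
    """
    variables = []
    blocks = tuple(f"block{b + 1}" for b in range(n_blocks))
    for b, block in enumerate(blocks):
        for j in range(vars_per_block):
            variables.append(
                VariableParams(f"{block}_v{j + 1}", block, "continuous",
                               mean=(0.0, effect), sd=(1.0, 1.0))
            )
    avail = {b: (1.0, 1.0) if i == 0 else (availability, availability)
             for i, b in enumerate(blocks)}
    return GeneratorParams(
        n_samples=n_samples, prevalence=prevalence, variables=tuple(variables),
        block_order=blocks, availability=avail, fixed_prefix=1, seed=seed,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate(params: GeneratorParams, seed: int | None = None) -> tuple[CohortTable, CohortTruth]:
    """Draw one cohort; fully reproducible from (params, seed)."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_samples
    cls = (rng.random(n) < params.prevalence).astype(int)

    cols: dict[str, np.ndarray | pd.Series] = {}
    # optional shared within-block factor for equicorrelated continuous draws
    rho = params.equicorrelation
    block_factor = {b: rng.standard_normal(n) for b in params.block_order} if rho > 0 else {}

    for vp in params.variables:
        if vp.kind == "continuous":
            mean = np.where(cls == 1, vp.mean[1], vp.mean[0])
            sd = np.where(cls == 1, vp.sd[1], vp.sd[0])
            z = rng.standard_normal(n)
            if rho > 0:
                z = np.sqrt(rho) * block_factor[vp.block] + np.sqrt(1 - rho) * z
            vals = mean + sd * z
            if params.truncate_at_zero:
                vals = np.maximum(vals, 0.0)
            cols[vp.name] = vals
        elif vp.kind == "binary":
            p = np.where(cls == 1, vp.proportion[1], vp.proportion[0])
            cols[vp.name] = (rng.random(n) < p).astype(float)
        else:
            u = rng.random(n)
            out = np.empty(n, dtype=object)
            for c in (0, 1):
                rows = cls == c
                edges = np.cumsum(vp.probs[c])
                idx = np.searchsorted(edges, u[rows], side="right")
                idx = np.minimum(idx, len(vp.categories) - 1)
                out[rows] = np.array(vp.categories, dtype=object)[idx]
            cols[vp.name] = out

    index = pd.Index([f"s{i:05d}" for i in range(n)], name="sample_id")
    values = pd.DataFrame(cols, index=index)

    observed = {}
    reach = np.ones((n,), dtype=bool)
    reach_prob = {0: 1.0, 1: 1.0}
    for b in params.block_order:
        a0, a1 = params.availability[b]
        if params.mcar:
            a1 = a0
        if params.nested:
            cont = {}
            for c, a in ((0, a0), (1, a1)):
                cont[c] = min(1.0, a / reach_prob[c]) if reach_prob[c] > 0 else 0.0
                reach_prob[c] *= cont[c]
            p_cont = np.where(cls == 1, cont[1], cont[0])
            obs = reach & (rng.random(n) < p_cont)
            reach = obs
        else:
            p_obs = np.where(cls == 1, a1, a0)
            obs = rng.random(n) < p_obs
        observed[b] = obs
        if not obs.all():
            block_vars = [v.name for v in params.block_variables(b)]
            values.loc[~obs, block_vars] = np.nan
    block_observed = pd.DataFrame(observed, index=index)

    table = CohortTable(
        values=values,
        outcome=pd.Series(cls, index=index, name="outcome"),
        variables=[vp.to_spec() for vp in params.variables],
    )
    truth = CohortTruth(
        latent_class=pd.Series(cls, index=index, name="latent_class"),
        block_observed=block_observed,
    )
    return table, truth


def plant_signal(params: GeneratorParams, block_name: str, effect: float) -> GeneratorParams:
    """Rewrite a block's continuous variables to a standardized effect d.

    Class-conditional means become separated by ``effect`` SDs (control mean
    unchanged, event mean shifted); d=0 turns the block into pure noise.
    """
    if block_name not in params.block_order:
        raise KeyError(f"unknown block {block_name!r}")
    targets = [v for v in params.block_variables(block_name) if v.kind == "continuous"]
    if not targets:
        raise ValueError(f"block {block_name!r} has no continuous variables")
    new_vars = []
    for vp in params.variables:
        if vp.block == block_name and vp.kind == "continuous":
            sd0 = vp.sd[0]
            new_vars.append(replace(vp, mean=(vp.mean[0], vp.mean[0] + effect * sd0),
                                    sd=(sd0, sd0)))
        else:
            new_vars.append(vp)
    return replace(params, variables=tuple(new_vars))
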